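"""Age-matched resampling burden test against enumeration oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import make_carrier_df, make_cases
from mosaicburden.burden import (
    _ranksum_p_batch,
    bonferroni_threshold,
    burden_scan,
    draw_age_matched_set,
    phenotype_burden,
)
from mosaicburden.types import (
    AgeMatchError,
    ResamplingParams,
    SampleRecord,
    ValidationError,
)


def enumerate_exact_p(flags, target_idx, strict=True):
    """Oracle: exhaustive subsets of the pool at equal ages."""
    flags = np.asarray(flags, dtype=bool)
    n = len(target_idx)
    obs = flags[list(target_idx)].mean()
    vals = [
        flags[list(c)].mean() for c in itertools.combinations(range(len(flags)), n)
    ]
    if strict:
        return np.mean([v > obs for v in vals])
    return np.mean([v >= obs for v in vals])


@pytest.mark.parametrize(
    "alpha,n,expected", [(0.05, 20, 0.0025), (0.05, 1, 0.05), (0.01, 4, 0.0025)]
)
def test_bonferroni_threshold(alpha, n, expected):
    assert bonferroni_threshold(alpha, n) == pytest.approx(expected, abs=1e-15)


def test_bonferroni_threshold_rejects_zero_tests():
    with pytest.raises(ValidationError):
        bonferroni_threshold(0.05, 0)


def test_vectorised_ranksum_matches_scipy():
    rng = np.random.default_rng(5)
    x = rng.normal(50, 8, (50, 12))
    y = rng.normal(55, 8, 9)
    mine = _ranksum_p_batch(x, y)
    ref = np.array([stats.ranksums(row, y).pvalue for row in x])
    np.testing.assert_allclose(mine, ref, atol=1e-12)
    # all-tied ages: p exactly 1, never NaN
    tied = _ranksum_p_batch(np.full((3, 5), 50.0), np.full(7, 50.0))
    np.testing.assert_allclose(tied, 1.0)


def test_draw_accepts_everything_with_identical_ages():
    samples, _ = make_cases(30, [False] * 30)
    drawn, attempts = draw_age_matched_set(
        samples, [50.0] * 10, 10, ResamplingParams(seed=1)
    )
    assert len(drawn) == 10 and attempts == 1
    assert len({s.sample_id for s in drawn}) == 10  # without replacement


def test_draw_entire_pool_is_self_matching():
    ages = list(np.linspace(40, 70, 12))
    samples, _ = make_cases(12, [False] * 12, ages=ages)
    drawn, attempts = draw_age_matched_set(
        samples, ages, 12, ResamplingParams(seed=2)
    )
    assert sorted(s.sample_id for s in drawn) == sorted(s.sample_id for s in samples)
    assert attempts == 1


def test_two_strata_acceptance_filter_matches_target_age():
    """Old-only target: accepted sets are pulled toward the old stratum."""
    rng = np.random.default_rng(6)
    n = 300
    old = rng.random(n) < 0.75
    ages = np.where(old, 65.0, 45.0)
    samples, _ = make_cases(n, [False] * n, ages=ages)
    target_ages = [65.0] * 8
    params = ResamplingParams(seed=3, max_draw_factor=500)
    means, rejected = [], 0
    gen = np.random.default_rng(7)
    for _ in range(300):
        drawn, attempts = draw_age_matched_set(samples, target_ages, 8, params, rng=gen)
        rejected += attempts - 1
        means.append(np.mean([s.age for s in drawn]))
    assert rejected > 0  # acceptance rate materially below 1
    sd = np.std(means, ddof=1)
    assert abs(np.mean(means) - 65.0) <= 2 * sd


def test_unmatchable_ages_raise_named_error():
    ages = [45.0] * 96 + [80.0] * 4
    phen = ["X"] * 96 + ["T"] * 4
    samples, tbl = make_cases(100, [False] * 100, ages=ages, phenotypes=phen)
    with pytest.raises(AgeMatchError, match="T"):
        phenotype_burden(
            samples, tbl, "T", params=ResamplingParams(seed=4, max_draw_factor=2)
        )


def test_worked_example_one_sixth():
    """Pool of 4 with carriers {0,1}; target {0,2} has freq 0.5; only the
    subset {0,1} exceeds it, so the literal empirical p is 1/6."""
    samples, tbl = make_cases(
        4, [True, True, False, False], phenotypes=["T", "X", "T", "X"]
    )
    exact = enumerate_exact_p([1, 1, 0, 0], [0, 2])
    assert exact == pytest.approx(1 / 6)
    res = phenotype_burden(
        samples, tbl, "T", params=ResamplingParams(n_resamples=40_000, seed=5)
    )
    se = np.sqrt(exact * (1 - exact) / 40_000)
    assert abs(res.empirical_p - exact) <= 3 * se
    assert res.observed_freq == 0.5 and res.n_cases == 2


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_matches_enumeration_oracle_on_random_small_pools(seed):
    rng = np.random.default_rng(seed)
    pool_n = int(rng.integers(8, 13))
    n_target = int(rng.integers(2, pool_n - 2))
    flags = rng.random(pool_n) < 0.4
    phen = ["T" if i < n_target else "X" for i in range(pool_n)]
    samples, tbl = make_cases(pool_n, flags, phenotypes=phen)
    exact = enumerate_exact_p(flags, range(n_target))
    res = phenotype_burden(
        samples, tbl, "T", params=ResamplingParams(n_resamples=30_000, seed=seed)
    )
    se = np.sqrt(max(exact * (1 - exact), 1e-9) / 30_000)
    assert abs(res.empirical_p - exact) <= max(3 * se, 1e-3)


def test_maximal_burden_gives_zero_literal_p_and_addone_floor():
    """Target holds every carrier: no resample can exceed it."""
    flags = [True, True, False, False, False, False]
    phen = ["T", "T", "T", "X", "X", "X"]
    samples, tbl = make_cases(6, flags, phenotypes=phen)
    res = phenotype_burden(
        samples, tbl, "T", params=ResamplingParams(n_resamples=5000, seed=6)
    )
    assert res.empirical_p_literal == 0.0
    assert res.empirical_p_add_one == pytest.approx(1 / 5001)


def test_tie_rule_and_addone_orderings():
    flags = [True, False, True, False, False, False, True, False]
    phen = ["T"] * 4 + ["X"] * 4
    samples, tbl = make_cases(8, flags, phenotypes=phen)
    strict = phenotype_burden(
        samples, tbl, "T",
        params=ResamplingParams(n_resamples=5000, seed=7, tie_rule="strict_greater"),
    )
    geq = phenotype_burden(
        samples, tbl, "T",
        params=ResamplingParams(n_resamples=5000, seed=7, tie_rule="greater_or_equal"),
    )
    assert geq.n_exceeding >= strict.n_exceeding
    assert strict.empirical_p_add_one > strict.empirical_p_literal
    assert 0 < strict.empirical_p_add_one <= 1


def test_determinism_and_pool_order_invariance():
    rng = np.random.default_rng(8)
    flags = (rng.random(40) < 0.25).tolist()
    phen = ["T" if i < 10 else "X" for i in range(40)]
    ages = rng.uniform(40, 70, 40).tolist()
    samples, tbl = make_cases(40, flags, ages=ages, phenotypes=phen)
    params = ResamplingParams(n_resamples=2000, seed=9)
    r1 = phenotype_burden(samples, tbl, "T", params=params)
    r2 = phenotype_burden(samples, tbl, "T", params=params)
    assert r1 == r2
    # relabel + permute the pool: same answer in distribution; with the
    # same seed the set of (age, flag) pairs drawn is identical because
    # ages/flags are permuted consistently -> p within Monte-Carlo error
    perm = rng.permutation(40)
    samples_p = [
        SampleRecord(f"R{i}", "case", samples[j].phenotype, samples[j].age, 30.0)
        for i, j in enumerate(perm)
    ]
    tbl_p = make_carrier_df([s.sample_id for s in samples_p], [flags[j] for j in perm])
    r3 = phenotype_burden(samples_p, tbl_p, "T", params=params)
    assert abs(r3.empirical_p - r1.empirical_p) < 4 * np.sqrt(
        max(r1.empirical_p * (1 - r1.empirical_p), 1e-4) / 2000
    )


def test_burden_scan_flags_enriched_phenotype_and_gene():
    """5x carrier rate in one phenotype; extra carriers all in PPM1D."""
    rng = np.random.default_rng(10)
    n = 1200
    phen = np.array(["T"] * 200 + ["A"] * 250 + ["B"] * 250 + ["C"] * 250 + ["D"] * 250)
    base = rng.random(n) < 0.04
    boost = (phen == "T") & (rng.random(n) < 0.16)
    flags = base | boost
    genes = []
    for i in range(n):
        if boost[i]:
            genes.append(frozenset({"PPM1D"}))
        elif base[i]:
            genes.append(frozenset({rng.choice(["TET2", "ASXL1", "DNMT3A"])}))
        else:
            genes.append(frozenset())
    samples, _ = make_cases(n, flags, phenotypes=phen.tolist())
    tbl = make_carrier_df([s.sample_id for s in samples], flags, genes)
    results = burden_scan(samples, tbl, ResamplingParams(n_resamples=4000, seed=11))
    assert len(results) == 5 * 5  # 5 phenotypes x (all + 4 genes)
    overall = {r.phenotype: r for r in results if r.gene is None}
    assert overall["T"].significant
    assert overall["T"].significance_threshold == pytest.approx(0.01)  # 0.05/5
    t_genes = {r.gene: r for r in results if r.phenotype == "T" and r.gene}
    assert min(t_genes, key=lambda g: t_genes[g].empirical_p_add_one) == "PPM1D"


def test_burden_scan_requires_two_phenotypes():
    samples, tbl = make_cases(10, [True] + [False] * 9, phenotypes=["T"] * 10)
    with pytest.raises(ValidationError):
        burden_scan(samples, tbl)
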
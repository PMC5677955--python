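"""Empirical age-matched resampling burden test.

For a phenotype of N cases, random sets of N samples are drawn without
replacement from the pool of *all* cancer cases (the target phenotype
included).  Because mosaic prevalence rises steeply with age, a
candidate set is accepted only when a two-sided Wilcoxon rank-sum test
of its ages against the target phenotype's ages is non-significant.
The empirical p-value is the fraction of accepted sets whose
mosaic-PTV carrier frequency exceeds the target's — overall, or
restricted to one candidate gene.  Significance across the phenotype
scan is controlled by Bonferroni at 0.05 divided by the number of
phenotypes tested (0.05/20 = 0.0025 at the reference design).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    AgeMatchError,
    BurdenResult,
    CANDIDATE_GENES,
    ResamplingParams,
    SampleRecord,
    ValidationError,
)

__all__ = [
    "bonferroni_threshold",
    "draw_age_matched_set",
    "phenotype_burden",
    "burden_scan",
]

_BATCH = 512  # candidate sets drawn per vectorised batch


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValidationError(f"n_tests must be >= 1, got {n_tests}")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    return alpha / n_tests


def _ranksum_p_batch(set_ages: np.ndarray, target_ages: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p for each row of ``set_ages``.

    Normal approximation without tie correction, matching
    scipy.stats.ranksums row-wise (verified in tests).
    """
    b, n1 = set_ages.shape
    n2 = len(target_ages)
    combined = np.concatenate(
        [set_ages, np.broadcast_to(target_ages, (b, n2))], axis=1
    )
    ranks = stats.rankdata(combined, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    expected = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (w - expected) / sd
    return 2.0 * stats.norm.sf(np.abs(z))


def draw_age_matched_set(
    pool: Sequence[SampleRecord],
    target_ages: Sequence[float],
    n: int,
    params: ResamplingParams = ResamplingParams(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SampleRecord], int]:
    """Draw one age-matched random set of ``n`` samples from the pool.

    Samples uniformly without replacement, accepting the first draw
    whose two-sided rank-sum age p-value against ``target_ages``
    exceeds ``age_match_alpha``.  Returns ``(accepted_set,
    n_attempts)``; raises :class:`AgeMatchError` after
    ``max_draw_factor`` rejections.
    """
    if n > len(pool):
        raise ValidationError(f"cannot draw {n} from a pool of {len(pool)}")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    target = np.asarray(target_ages, dtype=float)
    pool_ages = np.array([s.age for s in pool])
    for attempt in range(1, params.max_draw_factor + 1):
        idx = rng.choice(len(pool), size=n, replace=False)
        p = stats.ranksums(pool_ages[idx], target).pvalue
        if p > params.age_match_alpha:
            return [pool[i] for i in idx], attempt
    raise AgeMatchError(
        f"no age-matched set found in {params.max_draw_factor} attempts"
    )


def _accepted_counts(
    pool_ages: np.ndarray,
    pool_flags: np.ndarray,
    target_ages: np.ndarray,
    n: int,
    params: ResamplingParams,
    rng: np.random.Generator,
    phenotype: str,
) -> np.ndarray:
    """Carrier counts of B accepted age-matched N-subsets of the pool.

    Fast path: when every age in pool and target is identical the
    rank-sum filter accepts every draw (p = 1) and the carrier count
    of a uniform random subset is exactly hypergeometric, so counts
    are sampled directly.  Otherwise candidate subsets are drawn in
    vectorised batches and filtered by the rank-sum acceptance test.
    """
    B = params.n_resamples
    pool_n = len(pool_ages)
    all_equal = (
        np.ptp(pool_ages) == 0
        and np.ptp(target_ages) == 0
        and pool_ages[0] == target_ages[0]
    )
    if all_equal:
        k = int(pool_flags.sum())
        return rng.hypergeometric(k, pool_n - k, n, size=B)

    counts = np.empty(B, dtype=np.int64)
    accepted = 0
    attempts = 0
    max_attempts = B * params.max_draw_factor
    while accepted < B:
        batch = min(_BATCH, max_attempts - attempts)
        if batch <= 0:
            raise AgeMatchError(
                f"phenotype {phenotype!r}: acceptance rate below "
                f"1/{params.max_draw_factor}; age distribution unmatched"
            )
        keys = rng.random((batch, pool_n))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        pvals = _ranksum_p_batch(pool_ages[idx], target_ages)
        ok = pvals > params.age_match_alpha
        take = min(int(ok.sum()), B - accepted)
        if take:
            counts[accepted : accepted + take] = pool_flags[idx[ok][:take]].sum(axis=1)
            accepted += take
        attempts += batch
    return counts


def _case_arrays(
    samples: Sequence[SampleRecord],
    carrier_table,
    gene: Optional[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cases = [s for s in samples if s.status == "case"]
    if not cases:
        raise ValidationError("no cases in sample list")
    missing = [s.sample_id for s in cases if s.sample_id not in carrier_table.index]
    if missing:
        raise ValidationError(f"carrier table missing cases: {missing[:5]}")
    sub = carrier_table.loc[[s.sample_id for s in cases]]
    if gene is None:
        flags = sub["is_carrier"].to_numpy(dtype=bool)
    else:
        flags = np.array([gene in gs for gs in sub["carrier_genes"]], dtype=bool)
    ages = np.array([s.age for s in cases])
    phen = np.array([s.phenotype for s in cases], dtype=object)
    return ages, flags, phen


def phenotype_burden(
    samples: Sequence[SampleRecord],
    carrier_table,
    phenotype: str,
    gene: Optional[str] = None,
    params: ResamplingParams = ResamplingParams(),
    significance_threshold: float = 0.05 / 20,
    rng: Optional[np.random.Generator] = None,
) -> BurdenResult:
    """Age-matched resampling burden test for one phenotype.

    ``gene=None`` tests overall mosaic-PTV carrier frequency;
    otherwise the frequency of carriers with a mosaic PTV in that
    gene.  Both the literal fraction (exceedances / B) and the
    add-one estimate ((exceedances + 1) / (B + 1)) are reported; the
    ``p_correction`` policy selects which drives ``empirical_p`` and
    the significance flag.
    """
    ages, flags, phen = _case_arrays(samples, carrier_table, gene)
    mask = phen == phenotype
    n = int(mask.sum())
    if n < 1:
        raise ValidationError(f"phenotype {phenotype!r} has no cases")
    observed = flags[mask].mean()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    counts = _accepted_counts(
        ages, flags, ages[mask], n, params, rng, phenotype
    )
    freqs = counts / n
    if params.tie_rule == "strict_greater":
        n_exceed = int((freqs > observed).sum())
    else:
        n_exceed = int((freqs >= observed).sum())
    b = len(counts)
    literal = n_exceed / b
    add_one = (n_exceed + 1) / (b + 1)
    p = literal if params.p_correction == "literal_fraction" else add_one
    return BurdenResult(
        phenotype=phenotype,
        gene=gene,
        n_cases=n,
        observed_freq=float(observed),
        n_accepted_sets=b,
        n_exceeding=n_exceed,
        empirical_p=p,
        empirical_p_literal=literal,
        empirical_p_add_one=add_one,
        significance_threshold=significance_threshold,
        significant=bool(p < significance_threshold),
    )


def burden_scan(
    samples: Sequence[SampleRecord],
    carrier_table,
    params: ResamplingParams = ResamplingParams(),
    genes: Sequence[str] = CANDIDATE_GENES,
) -> list[BurdenResult]:
    """Run the burden test for every phenotype and every (phenotype, gene).

    The Bonferroni threshold is recomputed from the number of
    phenotypes present in the data (0.05 / n_phenotypes), applied to
    both the overall and the per-gene tests.  Each test draws from an
    independent child stream of ``params.seed`` so individual tests
    can be reproduced in isolation.
    """
    phenotypes = sorted(
        {s.phenotype for s in samples if s.status == "case" and s.phenotype}
    )
    if len(phenotypes) < 2:
        raise ValidationError("burden scan requires at least 2 phenotypes")
    threshold = bonferroni_threshold(0.05, len(phenotypes))
    seeds = np.random.SeedSequence(params.seed).spawn(
        len(phenotypes) * (1 + len(genes))
    )
    results = []
    k = 0
    for phen in phenotypes:
        for gene in (None, *genes):
            results.append(
                phenotype_burden(
                    samples,
                    carrier_table,
                    phen,
                    gene=gene,
                    params=params,
                    significance_threshold=threshold,
                    rng=np.random.default_rng(seeds[k]),
                )
            )
            k += 1
    return results
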
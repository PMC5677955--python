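"""Logistic association, covariate tests and contingency summaries."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_carrier_df
from mosaicburden import (
    CohortConfig,
    carrier_covariate_test,
    fit_carrier_model,
    generate_cohort,
    population_contingency,
)
from mosaicburden.types import SampleRecord, SeparationError, ValidationError


def _two_by_two(case_carriers, case_total, ctrl_carriers, ctrl_total):
    samples, flags = [], []
    for i in range(case_total):
        samples.append(SampleRecord(f"A{i}", "case", "GBM", 60.0, 33.0))
        flags.append(i < case_carriers)
    for i in range(ctrl_total):
        samples.append(SampleRecord(f"B{i}", "control", None, 50.0, 29.0))
        flags.append(i < ctrl_carriers)
    return samples, make_carrier_df([s.sample_id for s in samples], flags)


def test_no_covariate_fit_equals_closed_form_2x2_or():
    """Saturated one-predictor logistic coefficient equals the sample OR."""
    samples, tbl = _two_by_two(10, 100, 5, 100)
    res = fit_carrier_model(samples, tbl, covariates=())
    expected = (10 * 95) / (90 * 5)
    assert res.odds_ratio == pytest.approx(expected, abs=1e-9)
    assert res.or_ci_low <= res.odds_ratio <= res.or_ci_high
    assert res.n_cases == 100 and res.n_controls == 100


def test_result_invariant_to_sample_relabeling_and_order():
    samples, tbl = _two_by_two(12, 90, 7, 110)
    res1 = fit_carrier_model(samples, tbl, covariates=())
    relabeled = [
        SampleRecord(f"Z{i}", s.status, s.phenotype, s.age, s.mean_coverage)
        for i, s in enumerate(samples)
    ]
    tbl2 = make_carrier_df(
        [s.sample_id for s in relabeled], tbl["is_carrier"].tolist()
    )
    res2 = fit_carrier_model(relabeled[::-1], tbl2, covariates=())
    assert res1.odds_ratio == pytest.approx(res2.odds_ratio, rel=1e-9)
    assert res1.p_value == pytest.approx(res2.p_value, rel=1e-9)


def test_phenotype_exclusion_drops_samples_before_fit():
    samples, tbl = _two_by_two(10, 100, 5, 100)
    # all cases are GBM: excluding it empties the case cohort
    with pytest.raises(ValidationError):
        fit_carrier_model(samples, tbl, covariates=(), excluded_phenotypes=("GBM",))
    # excluding an absent phenotype changes nothing
    res2 = fit_carrier_model(
        samples, tbl, covariates=(), excluded_phenotypes=("BRCA",)
    )
    assert res2.n_cases == 100
    assert res2.excluded_phenotypes == ("BRCA",)


def test_null_ci_covers_one():
    """Carrier status independent of case status: CI covers OR=1 ~95%."""
    rng = np.random.default_rng(0)
    covered = 0
    n_seeds = 100
    for _ in range(n_seeds):
        samples = [
            SampleRecord(
                f"S{i}", "case" if i < 400 else "control",
                "GBM" if i < 400 else None, 55.0, 31.0,
            )
            for i in range(800)
        ]
        flags = rng.random(800) < 0.05
        tbl = make_carrier_df([s.sample_id for s in samples], flags)
        res = fit_carrier_model(samples, tbl, covariates=())
        if res.testable and res.or_ci_low <= 1.0 <= res.or_ci_high:
            covered += 1
    assert covered >= 88  # ~95% nominal, 3 MC sd margin


def test_age_confounded_recovery_adjusted_vs_unadjusted():
    """Age adjustment removes the upward bias from younger controls."""
    hits_adj = 0
    biased_up = 0
    n_seeds = 25
    for seed in range(n_seeds):
        cfg = CohortConfig(
            n_cases=8000, n_controls=6000, carrier_base_rate=0.03,
            carrier_case_log_or=np.log(1.26), seed=300 + seed,
        )
        samples, _, truth = generate_cohort(cfg, with_sites=False)
        tbl = make_carrier_df(
            truth["sample_id"], truth["is_carrier"].tolist()
        )
        adj = fit_carrier_model(samples, tbl, covariates=("age",))
        raw = fit_carrier_model(samples, tbl, covariates=())
        if adj.or_ci_low <= 1.26 <= adj.or_ci_high:
            hits_adj += 1
        if raw.odds_ratio > adj.odds_ratio:
            biased_up += 1
    assert hits_adj >= round(0.9 * n_seeds)
    assert biased_up >= round(0.9 * n_seeds)  # controls are younger


def test_missing_carrier_rows_is_error():
    samples, tbl = _two_by_two(5, 20, 5, 20)
    with pytest.raises(ValidationError):
        fit_carrier_model(samples, tbl.iloc[:10], covariates=())


def test_constant_covariate_not_testable():
    rng = np.random.default_rng(1)
    carrier = rng.random(200) < 0.2
    res = carrier_covariate_test(carrier, np.ones(200), rng.uniform(40, 70, 200))
    assert not res.testable and "constant" in res.note


def test_covariate_equal_to_carrier_raises_separation():
    rng = np.random.default_rng(2)
    carrier = rng.random(300) < 0.3
    with pytest.raises(SeparationError):
        carrier_covariate_test(
            carrier, carrier.astype(float), rng.uniform(40, 70, 300)
        )


def test_independent_covariate_type_i_calibration():
    """Covariate independent of carrier status rejects at ~5%."""
    rng = np.random.default_rng(3)
    rejections = 0
    n_sims = 200
    for _ in range(n_sims):
        carrier = rng.random(500) < 0.1
        cov = rng.normal(size=500)
        age = rng.uniform(40, 70, 500)
        res = carrier_covariate_test(carrier, cov, age)
        rejections += res.p_value < 0.05
    assert 2 <= rejections <= 22  # nominal 10/200


def test_population_contingency_printed_rates():
    """26/153 carriers (~17%) vs 1104/10870 non-carriers (~10%)."""
    res = population_contingency(26, 153, 1104, 10870)
    assert res.event_rate_carriers == pytest.approx(16.99, abs=0.01)
    assert res.event_rate_noncarriers == pytest.approx(10.16, abs=0.01)
    assert round(res.event_rate_carriers) == 17
    assert round(res.event_rate_noncarriers) == 10
    assert (res.a, res.b, res.c, res.d) == (26, 127, 1104, 9766)
    assert not res.or_corrected


def test_population_contingency_ptv_only_cohort():
    """11/83 carriers: rate 13.25%, crude OR ~1.350."""
    res = population_contingency(11, 83, 1105, 10867)
    assert res.event_rate_carriers == pytest.approx(13.25, abs=0.01)
    assert res.crude_or == pytest.approx((11 * 9762) / (72 * 1105), rel=1e-12)
    assert res.crude_or == pytest.approx(1.350, abs=0.001)


def test_population_contingency_zero_cells_flagged():
    res = population_contingency(0, 10, 0, 10)
    assert res.event_rate_carriers == 0.0
    assert res.or_corrected
    assert res.crude_or == pytest.approx(1.0)  # 0.5-corrected symmetric table
    with pytest.raises(ValidationError):
        population_contingency(11, 10, 0, 10)


def test_population_contingency_age_adjustment():
    rng = np.random.default_rng(4)
    n = 2000
    carrier = rng.random(n) < 0.05
    age = rng.uniform(40, 80, n)
    event = rng.random(n) < 1 / (1 + np.exp(-(-4 + 0.05 * age)))
    res = population_contingency(
        int((carrier & event).sum()), int(carrier.sum()),
        int((~carrier & event).sum()), int((~carrier).sum()),
        ages=age, carrier_flags=carrier, event_flags=event,
    )
    assert res.age_adjusted_p is not None
    assert 0 < res.age_adjusted_p <= 1
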
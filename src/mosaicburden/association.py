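"""Case-control association of mosaic carrier status with cancer.

The central model is a binomial GLM (logistic regression) of cancer
status on mosaic-PTV carrier status, adjusted for age at DNA
collection and mean candidate-gene coverage — the two nuisance
variables that differ systematically between a cancer cohort and
population controls.  The carrier odds ratio is exp(coefficient) with
a 95% Wald CI on the log-odds scale.

Also provided: a generic carrier-vs-covariate test (e.g. treatment
history), and a 2x2 carrier-by-prior-cancer contingency summary for
population cohorts with clinical registries.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .types import (
    AssociationResult,
    ContingencyResult,
    SampleRecord,
    SeparationError,
    ValidationError,
)

__all__ = [
    "fit_binary_glm",
    "fit_carrier_model",
    "carrier_covariate_test",
    "population_contingency",
]

_Z975 = norm.ppf(0.975)


def fit_binary_glm(
    y: np.ndarray,
    X: pd.DataFrame,
    term: str,
    n_cases: int,
    n_controls: int,
    covariates: tuple[str, ...] = (),
    excluded_phenotypes: tuple[str, ...] = (),
) -> AssociationResult:
    """Fit a binomial GLM and summarise one term as an odds ratio.

    Raises :class:`SeparationError` when the fit shows the signature of
    complete separation (unbounded coefficient / exploding standard
    error), for which a Wald summary would be meaningless.
    """
    design = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        if "separation" in type(exc).__name__.lower() or "Separation" in str(exc):
            raise SeparationError(
                f"perfect separation fitting term {term!r}; consider an exact "
                "or penalized (Firth) fallback"
            ) from exc
        raise
    coef = float(fit.params[term])
    se = float(fit.bse[term])
    if abs(coef) > 15 or se > 100 or not math.isfinite(se):
        raise SeparationError(
            f"term {term!r} is effectively separated (coef={coef:.3g}, "
            f"se={se:.3g}); consider an exact or penalized (Firth) fallback"
        )
    return AssociationResult(
        term=term,
        odds_ratio=math.exp(coef),
        or_ci_low=math.exp(coef - _Z975 * se),
        or_ci_high=math.exp(coef + _Z975 * se),
        p_value=float(fit.pvalues[term]),
        n_cases=n_cases,
        n_controls=n_controls,
        covariates=covariates,
        excluded_phenotypes=excluded_phenotypes,
    )


def fit_carrier_model(
    samples: Sequence[SampleRecord],
    carrier_table: pd.DataFrame,
    covariates: Sequence[str] = ("age", "coverage"),
    excluded_phenotypes: Sequence[str] = (),
) -> AssociationResult:
    """Logistic model of case status on carrier status plus covariates.

    ``covariates`` is a subset of {"age", "coverage"}; samples whose
    phenotype is in ``excluded_phenotypes`` are dropped before fitting
    (e.g. removing breast and ovarian cancer cases to test whether the
    association generalises beyond the known PPM1D link).  Requires at
    least one carrier in each cohort after exclusions.
    """
    bad = set(covariates) - {"age", "coverage"}
    if bad:
        raise ValidationError(f"unknown covariates: {sorted(bad)}")
    excluded = set(excluded_phenotypes)
    kept = [s for s in samples if s.phenotype not in excluded]
    missing = [s.sample_id for s in kept if s.sample_id not in carrier_table.index]
    if missing:
        raise ValidationError(
            f"samples missing from carrier table: {missing[:5]}"
        )
    y = np.array([s.status == "case" for s in kept], dtype=float)
    carrier = carrier_table.loc[[s.sample_id for s in kept], "is_carrier"].to_numpy(
        dtype=float
    )
    n_cases = int(y.sum())
    n_controls = len(kept) - n_cases
    if n_cases == 0 or n_controls == 0:
        raise ValidationError("both cohorts must be non-empty after exclusions")
    if carrier[y == 1].sum() < 1 or carrier[y == 0].sum() < 1:
        return AssociationResult(
            term="carrier",
            odds_ratio=float("nan"),
            or_ci_low=float("nan"),
            or_ci_high=float("nan"),
            p_value=float("nan"),
            n_cases=n_cases,
            n_controls=n_controls,
            covariates=tuple(covariates),
            excluded_phenotypes=tuple(sorted(excluded)),
            testable=False,
            note="no carriers in one cohort; association not testable",
        )
    cols: dict[str, np.ndarray] = {"carrier": carrier}
    if "age" in covariates:
        cols["age"] = np.array([s.age for s in kept])
    if "coverage" in covariates:
        cols["coverage"] = np.array([s.mean_coverage for s in kept])
    return fit_binary_glm(
        y,
        pd.DataFrame(cols),
        term="carrier",
        n_cases=n_cases,
        n_controls=n_controls,
        covariates=tuple(c for c in ("age", "coverage") if c in covariates),
        excluded_phenotypes=tuple(sorted(excluded)),
    )


def carrier_covariate_test(
    carrier_flags: Sequence[bool] | np.ndarray,
    covariate: Sequence[float] | np.ndarray,
    age: Sequence[float] | np.ndarray,
    covariate_name: str = "covariate",
) -> AssociationResult:
    """Age-adjusted test of a covariate against carrier status.

    Logistic model of carrier status on the covariate plus age; used
    for clinical variables such as treatment history.  A constant
    covariate yields a ``testable=False`` result; a covariate that
    separates carriers perfectly raises :class:`SeparationError`.
    """
    carrier = np.asarray(carrier_flags, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    age_arr = np.asarray(age, dtype=float)
    if not (len(carrier) == len(cov) == len(age_arr)):
        raise ValidationError("carrier, covariate and age must be equal length")
    n_carriers = int(carrier.sum())
    n_non = len(carrier) - n_carriers
    if np.ptp(cov) == 0:
        return AssociationResult(
            term=covariate_name,
            odds_ratio=float("nan"),
            or_ci_low=float("nan"),
            or_ci_high=float("nan"),
            p_value=float("nan"),
            n_cases=n_carriers,
            n_controls=n_non,
            covariates=("age",),
            testable=False,
            note="constant covariate; not testable",
        )
    return fit_binary_glm(
        carrier,
        pd.DataFrame({covariate_name: cov, "age": age_arr}),
        term=covariate_name,
        n_cases=n_carriers,
        n_controls=n_non,
        covariates=("age",),
    )


def population_contingency(
    carriers_with_event: int,
    carriers_total: int,
    noncarriers_with_event: int,
    noncarriers_total: int,
    ages: Optional[Sequence[float]] = None,
    carrier_flags: Optional[Sequence[bool]] = None,
    event_flags: Optional[Sequence[bool]] = None,
) -> ContingencyResult:
    """Carrier-vs-event 2x2 summary for a population cohort.

    Event rates are reported as percentages of each carrier stratum;
    the crude odds ratio is (a*d)/(b*c).  Any zero cell triggers the
    Haldane-Anscombe 0.5 correction, flagged via ``or_corrected``.
    When per-sample ``ages``, ``carrier_flags`` and ``event_flags``
    are supplied, an age-adjusted logistic p-value for the carrier
    term is added.
    """
    if carriers_with_event > carriers_total or noncarriers_with_event > noncarriers_total:
        raise ValidationError("event counts cannot exceed group totals")
    if min(carriers_with_event, carriers_total, noncarriers_with_event,
           noncarriers_total) < 0:
        raise ValidationError("all counts must be non-negative")
    a = carriers_with_event
    b = carriers_total - carriers_with_event
    c = noncarriers_with_event
    d = noncarriers_total - noncarriers_with_event
    corrected = 0 in (a, b, c, d)
    if corrected:
        a_, b_, c_, d_ = (x + 0.5 for x in (a, b, c, d))
    else:
        a_, b_, c_, d_ = a, b, c, d
    crude_or = (a_ * d_) / (b_ * c_)

    age_adjusted_p: Optional[float] = None
    if ages is not None:
        if carrier_flags is None or event_flags is None:
            raise ValidationError(
                "ages require carrier_flags and event_flags for adjustment"
            )
        res = fit_binary_glm(
            np.asarray(event_flags, dtype=float),
            pd.DataFrame(
                {
                    "carrier": np.asarray(carrier_flags, dtype=float),
                    "age": np.asarray(ages, dtype=float),
                }
            ),
            term="carrier",
            n_cases=int(np.sum(event_flags)),
            n_controls=int(len(ages) - np.sum(event_flags)),
            covariates=("age",),
        )
        age_adjusted_p = res.p_value

    return ContingencyResult(
        a=a,
        b=b,
        c=c,
        d=d,
        event_rate_carriers=100.0 * a / carriers_total if carriers_total else float("nan"),
        event_rate_noncarriers=100.0 * c / noncarriers_total if noncarriers_total else float("nan"),
        crude_or=crude_or,
        or_corrected=corrected,
        age_adjusted_p=age_adjusted_p,
    )
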
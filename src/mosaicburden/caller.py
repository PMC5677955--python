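"""Binomial allele-balance mosaic calling and carrier aggregation.

A germline heterozygote is expected to show allele balance 0.5; a
clonal (mosaic) variant confined to a fraction of blood cells shows a
significantly lower balance.  Each non-reference genotype gets a
one-sided lower-tail exact binomial test of its alternative read count
against Binomial(depth, 0.5); genotypes with p below a fixed
significance cutoff *and* depth strictly above a coverage gate are
classified mosaic.  No multiple-testing correction is applied across
sites — the cutoff is a fixed operating point, not an inference.

Depth throughout means the sum of the AD field (informative reads),
not the VCF DP field.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AssociationResult,
    CallerParams,
    MosaicCall,
    PTV_CONSEQUENCES,
    SampleRecord,
    SiteObservation,
    ValidationError,
)

logger = logging.getLogger("mosaicburden")

__all__ = [
    "binomial_ab_test",
    "call_mosaic",
    "call_sites",
    "carrier_table",
    "coverage_bias_check",
]


def binomial_ab_test(
    alt_reads: int, depth: int, null_af: float = 0.5, two_sided: bool = False
) -> float:
    """Exact binomial allele-balance p-value.

    Returns P(X <= alt_reads) for X ~ Binomial(depth, null_af): the
    lower-tail probability of seeing this few alternative reads at a
    true heterozygous site.  With ``two_sided`` the minimum-likelihood
    two-sided exact test is used instead.
    """
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    if not 1 <= alt_reads <= depth:
        raise ValidationError(
            f"alt_reads must satisfy 1 <= alt <= depth, got alt={alt_reads}, "
            f"depth={depth}"
        )
    if two_sided:
        return float(stats.binomtest(alt_reads, depth, null_af).pvalue)
    return float(stats.binom.cdf(alt_reads, depth, null_af))


def _batch_p_values(
    alt: np.ndarray, depth: np.ndarray, params: CallerParams
) -> np.ndarray:
    if params.two_sided:
        return np.array(
            [
                stats.binomtest(int(a), int(d), params.null_af).pvalue
                for a, d in zip(alt, depth)
            ]
        )
    return stats.binom.cdf(alt, depth, params.null_af)


def call_mosaic(site: SiteObservation, params: CallerParams = CallerParams()) -> MosaicCall:
    """Classify one genotype as mosaic or germline.

    ``is_mosaic`` requires both p < alpha and depth strictly above the
    coverage gate (more than ``depth_min`` reads); the p-value is
    populated even when the depth gate fails.
    """
    p = binomial_ab_test(
        site.alt_reads, site.depth, params.null_af, params.two_sided
    )
    return MosaicCall(
        sample_id=site.sample_id,
        site_id=site.site_id,
        gene=site.gene,
        depth=site.depth,
        alt_reads=site.alt_reads,
        allele_balance=site.allele_balance,
        p_value=p,
        is_mosaic=bool(p < params.alpha and site.depth > params.depth_min),
    )


def call_sites(
    sites: Sequence[SiteObservation], params: CallerParams = CallerParams()
) -> list[MosaicCall]:
    """Vectorised :func:`call_mosaic` over a site list."""
    if not sites:
        return []
    alt = np.array([s.alt_reads for s in sites])
    depth = np.array([s.ref_reads + s.alt_reads for s in sites])
    if (alt < 1).any() or (alt > depth).any():
        raise ValidationError("sites must have 1 <= alt_reads <= depth")
    pvals = _batch_p_values(alt, depth, params)
    flags = (pvals < params.alpha) & (depth > params.depth_min)
    return [
        MosaicCall(
            sample_id=s.sample_id,
            site_id=s.site_id,
            gene=s.gene,
            depth=int(d),
            alt_reads=int(a),
            allele_balance=float(a / d),
            p_value=float(p),
            is_mosaic=bool(f),
        )
        for s, d, a, p, f in zip(sites, depth, alt, pvals, flags)
    ]


def carrier_table(
    samples: Sequence[SampleRecord], mosaic_ptv_calls: Iterable[MosaicCall]
) -> pd.DataFrame:
    """Aggregate mosaic-PTV calls to per-sample carrier status.

    Input calls must already be restricted to PTV consequences
    (apply :func:`mosaicburden.io.filter_ptv` upstream).  Every
    metadata sample appears in the output, non-carriers included.

    Returns a DataFrame indexed by sample_id with columns
    ``is_carrier`` (bool: at least one mosaic call), ``carrier_genes``
    (frozenset of genes with a mosaic call) and ``n_mosaic_ptv``.
    """
    known = {s.sample_id for s in samples}
    genes_by_sample: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    for call in mosaic_ptv_calls:
        if call.sample_id not in known:
            raise ValidationError(
                f"call for unknown sample {call.sample_id!r}"
            )
        if call.is_mosaic:
            genes_by_sample.setdefault(call.sample_id, set()).add(call.gene)
            counts[call.sample_id] = counts.get(call.sample_id, 0) + 1
    ids = [s.sample_id for s in samples]
    return pd.DataFrame(
        {
            "is_carrier": [sid in genes_by_sample for sid in ids],
            "carrier_genes": [
                frozenset(genes_by_sample.get(sid, ())) for sid in ids
            ],
            "n_mosaic_ptv": [counts.get(sid, 0) for sid in ids],
        },
        index=pd.Index(ids, name="sample_id"),
    )


def coverage_bias_check(
    samples: Sequence[SampleRecord],
    ptv_calls: Sequence[MosaicCall],
    adjust_age: bool = False,
) -> AssociationResult:
    """QC: does sequencing depth at PTV sites differ by cancer status?

    Among samples carrying at least one PTV genotype, fits a binomial
    GLM of case/control status on the per-carrier mean PTV-site depth
    (optionally age-adjusted) and reports the depth term.  A
    significant depth term would signal unequal mosaic-detection
    sensitivity between cohorts.  Degenerate designs (fewer than two
    PTV carriers in either cohort) yield a ``testable=False`` result
    instead of an exception.
    """
    from .association import fit_binary_glm  # local import to avoid cycle

    depth_by_sample: dict[str, list[int]] = {}
    for call in ptv_calls:
        depth_by_sample.setdefault(call.sample_id, []).append(call.depth)
    rows = [
        (s.status == "case", float(np.mean(depth_by_sample[s.sample_id])), s.age)
        for s in samples
        if s.sample_id in depth_by_sample
    ]
    not_testable = AssociationResult(
        term="depth",
        odds_ratio=float("nan"),
        or_ci_low=float("nan"),
        or_ci_high=float("nan"),
        p_value=float("nan"),
        n_cases=sum(r[0] for r in rows),
        n_controls=sum(not r[0] for r in rows),
        covariates=("age",) if adjust_age else (),
        testable=False,
        note="fewer than two PTV carriers in one cohort; depth bias not testable",
    )
    n_case = sum(r[0] for r in rows)
    n_ctrl = len(rows) - n_case
    if n_case < 2 or n_ctrl < 2:
        return not_testable
    y = np.array([r[0] for r in rows], dtype=float)
    cols = {"depth": np.array([r[1] for r in rows])}
    if adjust_age:
        cols["age"] = np.array([r[2] for r in rows])
    return fit_binary_glm(
        y,
        pd.DataFrame(cols),
        term="depth",
        n_cases=n_case,
        n_controls=n_ctrl,
        covariates=("age",) if adjust_age else (),
    )
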
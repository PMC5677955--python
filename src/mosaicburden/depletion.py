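"""Blood-vs-tumor depletion of mosaic variants.

If a blood-detected mosaic PTV were a residual trace of a tumor driver
event, the tumor should carry the allele at equal or higher fraction.
Instead, blood mosaics are essentially absent from matched tumor DNA
(only a small contamination floor remains), which is tested here with
a paired one-sided Wilcoxon signed-rank test (blood allele balance
greater than tumor).  A companion coverage comparison checks that the
deficit is not a sensitivity artifact: tumors are sequenced at similar
or better depth.

The exact signed-rank null (all 2^n sign assignments, ties handled via
midranks) is used for n <= 25; larger n uses the normal approximation
with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import PairedBalance, SiteObservation, ValidationError

__all__ = [
    "PairedBalance",
    "DepletionSummary",
    "CoverageSummary",
    "paired_balances",
    "depletion_test",
    "coverage_comparison",
]

EXACT_N_MAX = 25


@dataclass(frozen=True)
class DepletionSummary:
    """One-sided signed-rank comparison of blood vs tumor allele balance."""

    n: int
    statistic: float  # W+ : rank sum of pairs with blood_ab > tumor_ab
    p_value: float
    median_blood_ab: float
    median_tumor_ab: float
    method: str  # "exact" | "normal_approx" | "not_testable"
    testable: bool = True
    gene: Optional[str] = None


@dataclass(frozen=True)
class CoverageSummary:
    """Paired blood-vs-tumor depth comparison at mosaic sites."""

    n: int
    blood_mean_depth: float
    tumor_mean_depth: float
    mean_difference: float  # tumor - blood
    direction: str  # "tumor >= blood" | "blood > tumor"
    p_value: Optional[float]
    testable: bool = True


def paired_balances(sites: Sequence[SiteObservation]) -> list[PairedBalance]:
    """Extract blood/tumor allele-balance pairs from annotated sites.

    Sites without tumor reads, or with zero tumor depth, are skipped
    (standard inclusion rule: both libraries must cover the site).
    """
    pairs = []
    for s in sites:
        if s.tumor_ref_reads is None or s.tumor_alt_reads is None:
            continue
        tumor_depth = s.tumor_ref_reads + s.tumor_alt_reads
        if tumor_depth < 1:
            continue
        pairs.append(
            PairedBalance(
                sample_id=s.sample_id,
                gene=s.gene,
                site_id=s.site_id,
                blood_ab=s.allele_balance,
                tumor_ab=s.tumor_alt_reads / tumor_depth,
                blood_depth=s.depth,
                tumor_depth=tumor_depth,
            )
        )
    return pairs


def _exact_signed_rank_sf(doubled_ranks: np.ndarray, doubled_w: int) -> float:
    """P(W+ >= w) under the exact sign-flip null.

    Dynamic programme over the 2^n equiprobable sign assignments of
    the (doubled, hence integer even with midrank ties) ranks:
    the count polynomial prod_i (1 + x^{r_i}) is accumulated and the
    upper tail summed.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return float(counts[doubled_w:].sum() / 2 ** len(doubled_ranks))


def signed_rank_greater(diffs: np.ndarray) -> tuple[float, float, str]:
    """One-sided signed-rank test that the differences are positive.

    Zero differences are dropped (standard convention).  Returns
    ``(W+, p, method)``; raises ValidationError on empty input after
    zero removal (callers convert that to a not-testable summary).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValidationError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        doubled = np.rint(2 * ranks).astype(int)
        p = _exact_signed_rank_sf(doubled, int(round(2 * w_plus)))
        return w_plus, p, "exact"
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 from the null variance
    _, t = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (t**3 - t).sum() / 48.0
    z = (w_plus - mu - 0.5) / np.sqrt(var)
    return w_plus, float(stats.norm.sf(z)), "normal_approx"


def _one_depletion(pairs: Sequence[PairedBalance], gene: Optional[str]) -> DepletionSummary:
    blood = np.array([p.blood_ab for p in pairs])
    tumor = np.array([p.tumor_ab for p in pairs])
    try:
        w, p, method = signed_rank_greater(blood - tumor)
    except ValidationError:
        return DepletionSummary(
            n=len(pairs),
            statistic=float("nan"),
            p_value=float("nan"),
            median_blood_ab=float(np.median(blood)) if len(blood) else float("nan"),
            median_tumor_ab=float(np.median(tumor)) if len(tumor) else float("nan"),
            method="not_testable",
            testable=False,
            gene=gene,
        )
    return DepletionSummary(
        n=len(pairs),
        statistic=w,
        p_value=p,
        median_blood_ab=float(np.median(blood)),
        median_tumor_ab=float(np.median(tumor)),
        method=method,
        testable=True,
        gene=gene,
    )


def depletion_test(
    pairs: Sequence[PairedBalance], per_gene: bool = False
) -> DepletionSummary | dict[str, DepletionSummary]:
    """Test whether blood mosaic allele balance exceeds the tumor's.

    Paired Wilcoxon signed-rank, one-sided alternative blood > tumor.
    ``per_gene=True`` returns one summary per gene (the pooled test is
    under key ``"all"``); otherwise a single pooled summary.
    """
    if not pairs:
        raise ValidationError("depletion_test requires at least one pair")
    if not per_gene:
        return _one_depletion(pairs, gene=None)
    out = {"all": _one_depletion(pairs, gene=None)}
    for gene in sorted({p.gene for p in pairs}):
        sub = [p for p in pairs if p.gene == gene]
        out[gene] = _one_depletion(sub, gene=gene)
    return out


def coverage_comparison(pairs: Sequence[PairedBalance]) -> CoverageSummary:
    """Compare sequencing depth between blood and tumor at mosaic sites.

    Two-sided paired signed-rank on the depths, with the direction of
    the mean difference reported.  All-tied depths give p = None and
    ``testable=False`` (difference exactly zero).
    """
    if len(pairs) < 2:
        raise ValidationError("coverage comparison requires n >= 2 pairs")
    blood = np.array([p.blood_depth for p in pairs], dtype=float)
    tumor = np.array([p.tumor_depth for p in pairs], dtype=float)
    diff = tumor - blood
    mean_diff = float(diff.mean())
    direction = "tumor >= blood" if mean_diff >= 0 else "blood > tumor"
    if np.all(diff == 0):
        return CoverageSummary(
            n=len(pairs),
            blood_mean_depth=float(blood.mean()),
            tumor_mean_depth=float(tumor.mean()),
            mean_difference=0.0,
            direction="tumor >= blood",
            p_value=None,
            testable=False,
        )
    # two-sided: double the smaller one-sided exact/approx tail
    w_hi, p_hi, _ = signed_rank_greater(diff)
    _, p_lo, _ = signed_rank_greater(-diff)
    return CoverageSummary(
        n=len(pairs),
        blood_mean_depth=float(blood.mean()),
        tumor_mean_depth=float(tumor.mean()),
        mean_difference=mean_diff,
        direction=direction,
        p_value=min(1.0, 2.0 * min(p_hi, p_lo)),
        testable=True,
    )
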
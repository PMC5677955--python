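"""Shared record types for the mosaic-PTV burden pipeline.

The analysis revolves around four genes recurrently mutated in clonal
hematopoiesis (PPM1D, TET2, ASXL1, DNMT3A).  Per-sample non-reference
genotypes at candidate-gene sites are classified as mosaic (clonal,
allele balance significantly below the heterozygous 0.5) or germline,
carrier status is aggregated per sample, and carriers are tested for
association with solid-tumor cancer status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

CANDIDATE_GENES: tuple[str, ...] = ("PPM1D", "TET2", "ASXL1", "DNMT3A")

#: Controlled vocabulary of variant consequences the pipeline accepts.
CONSEQUENCES: frozenset[str] = frozenset(
    {"stop_gained", "splice_essential", "frameshift", "missense", "other"}
)

#: Protein-truncating consequence classes: stop gain, essential splice
#: site, frameshift.
PTV_CONSEQUENCES: frozenset[str] = frozenset(
    {"stop_gained", "splice_essential", "frameshift"}
)


class ValidationError(ValueError):
    """Input data violates a pipeline contract."""


class ConfigError(ValidationError):
    """A configuration object violates one of its invariants."""


class SeparationError(RuntimeError):
    """Perfect separation in a logistic fit; estimates are unbounded.

    Consider an exact (conditional) test or a penalized (Firth-type)
    fit for such degenerate designs.
    """


class AgeMatchError(RuntimeError):
    """Age-matched resampling could not reach the required acceptance rate."""


@dataclass(frozen=True)
class SampleRecord:
    """One study participant.

    ``mean_coverage`` is the mean sequencing depth over the candidate-gene
    target region, the coverage covariate of the association model.
    Controls carry no cancer phenotype label.
    """

    sample_id: str
    status: str  # "case" | "control"
    phenotype: Optional[str]
    age: float
    mean_coverage: float

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValidationError(
                f"status must be 'case' or 'control', got {self.status!r}"
            )
        if not self.age > 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        if self.status == "control" and self.phenotype is not None:
            raise ValidationError(
                f"control sample {self.sample_id} must have phenotype=None"
            )


@dataclass(frozen=True)
class SiteObservation:
    """One called non-reference genotype at a candidate-gene site.

    A record exists only because a non-reference genotype was called, so
    ``alt_reads >= 1``.  Depth is defined as ``ref_reads + alt_reads``
    (the informative reads of the AD field, not the VCF DP field).
    Paired tumor read counts are present when the sample has a matched
    tumor library covering the site.
    """

    sample_id: str
    gene: str
    site_id: str
    ref_reads: int
    alt_reads: int
    consequence: str
    exon_rank: Optional[int] = None
    exon_total: Optional[int] = None
    tumor_ref_reads: Optional[int] = None
    tumor_alt_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if self.alt_reads < 1:
            raise ValidationError(
                f"site {self.site_id}/{self.sample_id}: alt_reads must be >= 1"
            )
        if self.ref_reads < 0:
            raise ValidationError(
                f"site {self.site_id}/{self.sample_id}: negative ref_reads"
            )
        if (
            self.exon_rank is not None
            and self.exon_total is not None
            and self.exon_rank > self.exon_total
        ):
            raise ValidationError(
                f"site {self.site_id}: exon_rank {self.exon_rank} exceeds "
                f"exon_total {self.exon_total}"
            )

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def allele_balance(self) -> float:
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class MosaicCall:
    """Binomial allele-balance verdict for one SiteObservation."""

    sample_id: str
    site_id: str
    gene: str
    depth: int
    alt_reads: int
    allele_balance: float
    p_value: float
    is_mosaic: bool


@dataclass(frozen=True)
class CallerParams:
    """Mosaic-calling thresholds.

    A genotype is mosaic when its one-sided lower-tail binomial p-value
    falls below ``alpha`` *and* its depth strictly exceeds ``depth_min``
    (more than 20x coverage, i.e. at least 21 informative reads, by
    default).  ``null_af`` is the heterozygous expectation.
    """

    alpha: float = 0.001
    depth_min: int = 20
    null_af: float = 0.5
    two_sided: bool = False  # off by default; the claim is directional

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if self.depth_min < 0:
            raise ConfigError(f"depth_min must be >= 0, got {self.depth_min}")
        if not 0 < self.null_af < 1:
            raise ConfigError(f"null_af must be in (0,1), got {self.null_af}")


@dataclass(frozen=True)
class AssociationResult:
    """Summary of one logistic (binomial GLM) term.

    ``odds_ratio`` is exp(coefficient) with a 95% Wald CI on the
    log-odds scale.  ``testable`` is False for degenerate designs
    (e.g. a constant covariate or a single cohort), in which case the
    numeric fields are NaN and ``note`` explains why.
    """

    term: str
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    p_value: float
    n_cases: int
    n_controls: int
    covariates: tuple[str, ...] = ()
    excluded_phenotypes: tuple[str, ...] = ()
    testable: bool = True
    note: str = ""


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 carrier-by-event table with rates and crude odds ratio.

    Cells: a = carrier & event, b = carrier & no event,
    c = non-carrier & event, d = non-carrier & no event.
    Rates are percentages.  When any cell is zero the crude OR uses the
    Haldane-Anscombe 0.5 correction and ``or_corrected`` is set.
    """

    a: int
    b: int
    c: int
    d: int
    event_rate_carriers: float
    event_rate_noncarriers: float
    crude_or: float
    or_corrected: bool = False
    age_adjusted_p: Optional[float] = None


@dataclass(frozen=True)
class ExonEnrichment:
    """Per-exon distribution of PTVs within one gene.

    ``last_exon_fraction`` is None when ``total_ptv == 0`` (undefined,
    flagged rather than raised).
    """

    gene: str
    counts_by_exon: dict[int, int]
    last_exon_count: int
    total_ptv: int
    last_exon_fraction: Optional[float]


@dataclass(frozen=True)
class ResamplingParams:
    """Age-matched resampling settings for the burden test.

    ``n_resamples`` accepted sets are drawn per test; candidate sets are
    accepted when a two-sided Wilcoxon rank-sum test of their ages
    against the target phenotype's ages gives p > ``age_match_alpha``.
    At most ``max_draw_factor`` attempts are allowed per accepted set
    before the phenotype is declared unmatched.

    ``tie_rule``: 'strict_greater' counts resampled sets whose carrier
    frequency strictly exceeds the target's; 'greater_or_equal' also
    counts ties.  ``p_correction``: 'literal_fraction' reports
    exceedances/B; 'add_one' reports (exceedances+1)/(B+1).  Both values
    are always computed; the policy selects which one drives the
    significance flag.
    """

    n_resamples: int = 10_000
    age_match_alpha: float = 0.05
    max_draw_factor: int = 50
    tie_rule: str = "strict_greater"
    p_correction: str = "literal_fraction"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ConfigError("n_resamples must be >= 1")
        if not 0 < self.age_match_alpha < 1:
            raise ConfigError("age_match_alpha must be in (0,1)")
        if self.max_draw_factor < 1:
            raise ConfigError("max_draw_factor must be >= 1")
        if self.tie_rule not in ("strict_greater", "greater_or_equal"):
            raise ConfigError(f"unknown tie_rule {self.tie_rule!r}")
        if self.p_correction not in ("literal_fraction", "add_one"):
            raise ConfigError(f"unknown p_correction {self.p_correction!r}")


@dataclass(frozen=True)
class BurdenResult:
    """Empirical age-matched resampling outcome for one phenotype.

    ``gene`` is None for the all-genes (overall carrier) test.
    ``empirical_p`` is the value selected by the p_correction policy;
    both the literal fraction and the add-one estimate are carried.
    """

    phenotype: str
    gene: Optional[str]
    n_cases: int
    observed_freq: float
    n_accepted_sets: int
    n_exceeding: int
    empirical_p: float
    empirical_p_literal: float
    empirical_p_add_one: float
    significance_threshold: float
    significant: bool


@dataclass(frozen=True)
class PairedBalance:
    """Blood and matched-tumor allele balance at one mosaic site."""

    sample_id: str
    gene: str
    site_id: str
    blood_ab: float
    tumor_ab: float
    blood_depth: int
    tumor_depth: int

    def __post_init__(self) -> None:
        if not (0 <= self.blood_ab <= 1 and 0 <= self.tumor_ab <= 1):
            raise ValidationError(
                f"site {self.site_id}: allele balances must lie in [0,1]"
            )
        if self.blood_depth < 1 or self.tumor_depth < 1:
            raise ValidationError(
                f"site {self.site_id}: both depths must be >= 1 for inclusion"
            )
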
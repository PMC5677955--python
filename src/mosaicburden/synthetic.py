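"""Synthetic cohort generator.

Emulates the statistical structure of a blood-DNA mosaic-variant
case-control study: a cancer cohort sequenced somewhat deeper (mean
33x) and roughly ten years older than the control cohort (mean 29x),
rare (<1%) mosaic PTV carriers whose prevalence rises log-linearly
with age, clonal allele fractions well below the heterozygous 0.5,
background germline heterozygous sites at allele fraction 0.5, ~20
cancer phenotype labels, and paired tumor reads in which blood mosaics
are depleted to a small residual fraction.

The generator works at the level of called genotypes (read counts per
site), not raw reads: no FASTQ/BAM simulation, no clonal dynamics, no
multi-allelic sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .types import (
    CANDIDATE_GENES,
    ConfigError,
    SampleRecord,
    SiteObservation,
)

__all__ = ["CohortConfig", "generate_cohort", "write_fixtures", "default_phenotype_counts"]

# Gene -> (chromosome, first position, exon count) used for fixture VCFs
# and exon-rank simulation.  TET2 is represented by its three-exon
# blood-expressed transcript; PPM1D and ASXL1 PTVs concentrate in the
# final exon (the gain-of-function pattern), TET2 in exon 3, DNMT3A has
# no positional pattern.
GENE_LAYOUT: dict[str, tuple[str, int, int]] = {
    "PPM1D": ("17", 60_600_000, 6),
    "TET2": ("4", 106_000_000, 3),
    "ASXL1": ("20", 32_400_000, 13),
    "DNMT3A": ("2", 25_200_000, 23),
}

# Default share of mosaic PTVs per gene, reflecting the usual clonal-
# hematopoiesis spectrum (DNMT3A most frequent).
DEFAULT_GENE_WEIGHTS: dict[str, float] = {
    "PPM1D": 0.12,
    "TET2": 0.25,
    "ASXL1": 0.18,
    "DNMT3A": 0.45,
}

# Consequence mix for background germline het sites (mostly non-PTV, a
# small PTV tail to exercise the consequence filter) and for mosaic PTVs.
_GERMLINE_CONSEQUENCES = ("missense", "other", "stop_gained", "frameshift", "splice_essential")
_GERMLINE_CONSEQ_P = (0.55, 0.35, 0.04, 0.03, 0.03)
_MOSAIC_CONSEQUENCES = ("stop_gained", "frameshift", "splice_essential")
_MOSAIC_CONSEQ_P = (0.45, 0.35, 0.20)

#: Twenty solid-tumor phenotype labels (TCGA study abbreviations) with
#: relative cohort shares used to build the default phenotype table.
_DEFAULT_PHENOTYPE_SHARES: dict[str, float] = {
    "BRCA": 0.135, "OV": 0.055, "LUAD": 0.065, "LUSC": 0.060, "GBM": 0.055,
    "SKCM": 0.050, "COAD": 0.055, "HNSC": 0.065, "PRAD": 0.060, "KIRC": 0.060,
    "LGG": 0.055, "THCA": 0.055, "STAD": 0.045, "BLCA": 0.045, "LIHC": 0.040,
    "CESC": 0.035, "SARC": 0.030, "PAAD": 0.030, "ESCA": 0.025, "UCEC": 0.080,
}


def default_phenotype_counts(n_cases: int) -> dict[str, int]:
    """Distribute ``n_cases`` across the 20 default phenotype labels.

    Largest-remainder apportionment so the counts sum exactly to
    ``n_cases``.
    """
    labels = list(_DEFAULT_PHENOTYPE_SHARES)
    shares = np.array([_DEFAULT_PHENOTYPE_SHARES[k] for k in labels])
    shares = shares / shares.sum()
    raw = shares * n_cases
    counts = np.floor(raw).astype(int)
    remainder = n_cases - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return dict(zip(labels, counts.tolist()))


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for cohort simulation.

    Defaults mirror the design the analysis assumes: 7979 cases vs 6177
    controls, case/control mean target coverage 33x/29x, a ~10-year mean
    age gap (cases 60 +- 12, controls 50 +- 12, truncated at 18), a base
    carrier prevalence below 1% rising with age (log-odds slope per
    year), a conditional case-carrier log odds ratio of log(1.26), clonal
    allele fractions uniform on (0.10, 0.20), and a residual tumor allele
    fraction of 0.02 at blood-mosaic sites.
    """

    n_cases: int = 7979
    n_controls: int = 6177
    phenotype_labels: Optional[Mapping[str, int]] = None
    case_age_mean: float = 60.0
    case_age_sd: float = 12.0
    control_age_mean: float = 50.0
    control_age_sd: float = 12.0
    age_min: float = 18.0
    case_depth_mean: float = 33.0
    control_depth_mean: float = 29.0
    coverage_cv: float = 0.10
    depth_model: str = "poisson"  # "poisson" | "negbin"
    depth_dispersion: float = 10.0  # NB size parameter when depth_model="negbin"
    carrier_base_rate: float = 0.008
    carrier_ref_age: float = 60.0
    carrier_age_slope: float = 0.07
    carrier_case_log_or: float = math.log(1.26)
    gene_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_WEIGHTS)
    )
    mosaic_af_range: tuple[float, float] = (0.10, 0.20)
    tumor_depletion_af: float = 0.02
    tumor_depth_gain: float = 4.0
    germline_site_rate: float = 1.0
    last_exon_concentration: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if self.phenotype_labels is not None:
            total = sum(self.phenotype_labels.values())
            if total != self.n_cases:
                raise ConfigError(
                    f"per-phenotype case counts sum to {total}, expected "
                    f"n_cases={self.n_cases}"
                )
            if any(v < 0 for v in self.phenotype_labels.values()):
                raise ConfigError("phenotype counts must be non-negative")
        if set(self.gene_weights) != set(CANDIDATE_GENES):
            raise ConfigError(
                f"gene_weights must cover exactly {CANDIDATE_GENES}"
            )
        if not math.isclose(sum(self.gene_weights.values()), 1.0, abs_tol=1e-9):
            raise ConfigError("gene_weights must sum to 1")
        lo, hi = self.mosaic_af_range
        if not (0.0 < lo < hi < 0.5):
            raise ConfigError(
                "mosaic_af_range must be strictly inside (0, 0.5) with lo < hi"
            )
        if not self.tumor_depletion_af < lo:
            raise ConfigError(
                "tumor_depletion_af must lie below the mosaic AF range"
            )
        if not 0.0 <= self.carrier_base_rate < 1.0:
            raise ConfigError("carrier_base_rate must be in [0,1)")
        if self.depth_model not in ("poisson", "negbin"):
            raise ConfigError(f"unknown depth_model {self.depth_model!r}")
        if not 0.0 <= self.coverage_cv < 1.0:
            raise ConfigError("coverage_cv must be in [0,1)")
        if not 0.0 <= self.last_exon_concentration <= 1.0:
            raise ConfigError("last_exon_concentration must be in [0,1]")

    def phenotype_counts(self) -> dict[str, int]:
        if self.phenotype_labels is not None:
            return dict(self.phenotype_labels)
        return default_phenotype_counts(self.n_cases)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, size: int
) -> np.ndarray:
    """Normal draws truncated below at ``low`` (rejection sampling)."""
    out = rng.normal(mean, sd, size)
    bad = out < low
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < low
    return out


def _site_depths(
    rng: np.random.Generator, sample_means: np.ndarray, config: CohortConfig
) -> np.ndarray:
    """Per-site depths around per-sample latent means, floor 1."""
    if config.depth_model == "poisson":
        d = rng.poisson(sample_means)
    else:
        # NB with mean m and size theta: var = m + m^2/theta
        theta = config.depth_dispersion
        d = rng.negative_binomial(theta, theta / (theta + sample_means))
    return np.maximum(d, 1)


def _truncated_binomial(
    rng: np.random.Generator, n: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Binomial(n, p) conditioned on being >= 1 (vectorised redraw).

    A site record only exists when the variant was called, so the
    emitted alternative read count is at least one.
    """
    out = rng.binomial(n, p)
    bad = out < 1
    while bad.any():
        out[bad] = rng.binomial(n[bad], p[bad] if p.ndim else p)
        bad = out < 1
    return out


def _exon_ranks(
    rng: np.random.Generator, genes: np.ndarray, mosaic: bool, config: CohortConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (exon_rank, exon_total) per site.

    Mosaic PTVs in PPM1D, ASXL1 and TET2 concentrate in a hotspot exon
    (the last exon; exon 3 is the last for the three-exon TET2
    transcript) with probability ``last_exon_concentration``; DNMT3A
    and all germline sites are uniform across exons.
    """
    totals = np.array([GENE_LAYOUT[g][2] for g in genes])
    ranks = rng.integers(1, totals + 1)
    if mosaic:
        hot = np.isin(genes, ("PPM1D", "ASXL1", "TET2"))
        in_hotspot = rng.random(len(genes)) < config.last_exon_concentration
        ranks = np.where(hot & in_hotspot, totals, ranks)
    return ranks, totals


def generate_cohort(
    config: CohortConfig,
    with_sites: bool = True,
) -> tuple[list[SampleRecord], list[SiteObservation], pd.DataFrame]:
    """Simulate a cohort of samples and their candidate-gene genotypes.

    Carrier status is drawn per sample from a logit-linear model
    (intercept at ``carrier_base_rate`` for a reference-age control,
    plus ``carrier_age_slope`` per year and ``carrier_case_log_or`` for
    cases).  Each carrier receives exactly one mosaic PTV with a true
    allele fraction uniform on ``mosaic_af_range``; every sample also
    receives Poisson(``germline_site_rate``) germline heterozygous
    sites (true AF 0.5) per candidate gene.  Read counts are binomial
    around per-site Poisson (or negative-binomial) depths.  Case
    samples carry paired tumor reads: ``tumor_depletion_af`` at mosaic
    sites, 0.5 at germline sites, with tumor depth >= blood depth.

    Returns ``(samples, sites, truth)`` where ``truth`` is a per-sample
    DataFrame of the ground-truth carrier labels (columns sample_id,
    is_case, phenotype, age, mean_coverage, is_carrier, carrier_gene,
    true_af) for parameter-recovery checks.

    ``with_sites=False`` skips read-level simulation and returns an
    empty site list; the sample table and carrier truth are identical
    to the full run (reads are drawn after the truth in the random
    stream).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_cases] = True

    sample_ids = np.array([f"S{i:06d}" for i in range(n)])
    phen_counts = config.phenotype_counts()
    phen_pool = np.repeat(
        np.array(list(phen_counts), dtype=object),
        np.array(list(phen_counts.values())),
    )
    phenotypes = np.full(n, None, dtype=object)
    phenotypes[: config.n_cases] = rng.permutation(phen_pool)

    ages = np.empty(n)
    ages[is_case] = _truncated_normal(
        rng, config.case_age_mean, config.case_age_sd, config.age_min, config.n_cases
    )
    ages[~is_case] = _truncated_normal(
        rng, config.control_age_mean, config.control_age_sd, config.age_min,
        config.n_controls,
    )

    depth_means = np.where(is_case, config.case_depth_mean, config.control_depth_mean)
    if config.coverage_cv > 0:
        shape = 1.0 / config.coverage_cv**2
        mean_cov = rng.gamma(shape, depth_means / shape)
    else:
        mean_cov = depth_means.astype(float)

    # --- carrier truth ----------------------------------------------------
    if config.carrier_base_rate > 0:
        logit0 = math.log(config.carrier_base_rate / (1 - config.carrier_base_rate))
        eta = (
            logit0
            + config.carrier_age_slope * (ages - config.carrier_ref_age)
            + config.carrier_case_log_or * is_case
        )
        p_carrier = 1.0 / (1.0 + np.exp(-eta))
    else:
        p_carrier = np.zeros(n)
    is_carrier = rng.random(n) < p_carrier
    carrier_idx = np.flatnonzero(is_carrier)
    genes_arr = np.array(CANDIDATE_GENES, dtype=object)
    weights = np.array([config.gene_weights[g] for g in CANDIDATE_GENES])
    carrier_gene = rng.choice(genes_arr, size=len(carrier_idx), p=weights)
    lo, hi = config.mosaic_af_range
    carrier_af = rng.uniform(lo, hi, len(carrier_idx))

    samples = [
        SampleRecord(
            sample_id=str(sample_ids[i]),
            status="case" if is_case[i] else "control",
            phenotype=phenotypes[i],
            age=float(ages[i]),
            mean_coverage=float(mean_cov[i]),
        )
        for i in range(n)
    ]

    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "is_case": is_case,
            "phenotype": phenotypes,
            "age": ages,
            "mean_coverage": mean_cov,
            "is_carrier": is_carrier,
            "carrier_gene": pd.Series(index=range(n), dtype=object),
            "true_af": np.nan,
        }
    )
    truth.loc[carrier_idx, "carrier_gene"] = carrier_gene
    truth.loc[carrier_idx, "true_af"] = carrier_af

    if not with_sites:
        return samples, [], truth

    # --- site table (vectorised, then materialised) -----------------------
    # germline background: Poisson(rate) sites per sample per gene
    g_counts = rng.poisson(config.germline_site_rate, size=(n, len(CANDIDATE_GENES)))
    flat_counts = g_counts.ravel()
    g_sample = np.repeat(np.repeat(np.arange(n), len(CANDIDATE_GENES)), flat_counts)
    g_gene = np.repeat(np.tile(genes_arr, n), flat_counts)
    g_af = np.full(len(g_sample), 0.5)
    g_conseq = rng.choice(_GERMLINE_CONSEQUENCES, size=len(g_sample), p=_GERMLINE_CONSEQ_P)
    g_rank, g_total = _exon_ranks(rng, g_gene, mosaic=False, config=config)

    m_sample = carrier_idx
    m_gene = carrier_gene
    m_af = carrier_af
    m_conseq = rng.choice(_MOSAIC_CONSEQUENCES, size=len(m_sample), p=_MOSAIC_CONSEQ_P)
    m_rank, m_total = _exon_ranks(rng, m_gene, mosaic=True, config=config)

    s_sample = np.concatenate([m_sample, g_sample]).astype(int)
    s_gene = np.concatenate([m_gene, g_gene])
    s_af = np.concatenate([m_af, g_af])
    s_conseq = np.concatenate([m_conseq, g_conseq])
    s_rank = np.concatenate([m_rank, g_rank]).astype(int)
    s_total = np.concatenate([m_total, g_total]).astype(int)
    s_is_mosaic = np.zeros(len(s_sample), dtype=bool)
    s_is_mosaic[: len(m_sample)] = True

    n_sites = len(s_sample)
    depths = _site_depths(rng, mean_cov[s_sample], config)
    alts = _truncated_binomial(rng, depths, s_af)
    refs = depths - alts

    s_case = is_case[s_sample]
    tumor_depth = np.where(
        s_case, depths + rng.poisson(config.tumor_depth_gain, n_sites), 0
    )
    tumor_af = np.where(s_is_mosaic, config.tumor_depletion_af, 0.5)
    tumor_alt = np.where(s_case, rng.binomial(np.maximum(tumor_depth, 1), tumor_af), 0)
    tumor_ref = tumor_depth - tumor_alt

    site_ids = np.array([f"v{i:07d}" for i in range(n_sites)])

    sites: list[SiteObservation] = []
    for j in range(n_sites):
        i = s_sample[j]
        sites.append(
            SiteObservation(
                sample_id=str(sample_ids[i]),
                gene=str(s_gene[j]),
                site_id=str(site_ids[j]),
                ref_reads=int(refs[j]),
                alt_reads=int(alts[j]),
                consequence=str(s_conseq[j]),
                exon_rank=int(s_rank[j]),
                exon_total=int(s_total[j]),
                tumor_ref_reads=int(tumor_ref[j]) if s_case[j] else None,
                tumor_alt_reads=int(tumor_alt[j]) if s_case[j] else None,
            )
        )
    return samples, sites, truth


# ---------------------------------------------------------------------------
# fixture writing


def _vcf_header(samples: Sequence[SampleRecord]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in sorted({layout[0] for layout in GENE_LAYOUT.values()}):
        header.contigs.add(chrom, length=250_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in samples:
        header.add_sample(s.sample_id)
    return header


def write_fixtures(
    samples: Sequence[SampleRecord],
    sites: Sequence[SiteObservation],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three standard input files plus tumor pairs.

    Emits ``cohort.vcf`` (VCF 4.2 with GT/AD/DP, one record per site,
    sample columns in metadata order), ``samples.tsv``,
    ``annotation.tsv`` and — when any site carries tumor reads —
    ``pairs.tsv``.  The files round-trip losslessly through
    :func:`mosaicburden.io.read_inputs`.
    """
    if not samples:
        raise ValidationError("write_fixtures requires a non-empty sample list")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "metadata": out / "samples.tsv",
        "annotation": out / "annotation.tsv",
    }

    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "status": [s.status for s in samples],
            "phenotype": [s.phenotype if s.phenotype is not None else "NA" for s in samples],
            "age": [s.age for s in samples],
            "mean_coverage": [s.mean_coverage for s in samples],
        }
    )
    meta.to_csv(paths["metadata"], sep="\t", index=False)

    # deterministic coordinates: per-gene counter in site order
    gene_counter = {g: 0 for g in GENE_LAYOUT}
    coords: dict[str, tuple[str, int]] = {}
    anno_rows = []
    for site in sites:
        chrom, start, _ = GENE_LAYOUT[site.gene]
        gene_counter[site.gene] += 1
        coords[site.site_id] = (chrom, start + gene_counter[site.gene])
        anno_rows.append(
            {
                "site_id": site.site_id,
                "gene": site.gene,
                "transcript": f"ENST_{site.gene}",
                "consequence": site.consequence,
                "exon_rank": site.exon_rank if site.exon_rank is not None else "NA",
                "exon_total": site.exon_total if site.exon_total is not None else "NA",
            }
        )
    pd.DataFrame(
        anno_rows,
        columns=["site_id", "gene", "transcript", "consequence", "exon_rank", "exon_total"],
    ).to_csv(paths["annotation"], sep="\t", index=False)

    header = _vcf_header(samples)
    default_dp = {s.sample_id: max(int(round(s.mean_coverage)), 1) for s in samples}
    with pysam.VariantFile(str(paths["vcf"]), "w", header=header) as vcf:
        for site in sorted(sites, key=lambda s: (coords[s.site_id][0], coords[s.site_id][1])):
            chrom, pos = coords[site.site_id]
            rec = vcf.new_record(
                contig=chrom, start=pos - 1, stop=pos, alleles=("A", "T"),
                id=site.site_id,
            )
            for s in samples:
                fmt = rec.samples[s.sample_id]
                if s.sample_id == site.sample_id:
                    fmt["GT"] = (0, 1)
                    fmt["AD"] = (site.ref_reads, site.alt_reads)
                    fmt["DP"] = site.depth
                else:
                    dp = default_dp[s.sample_id]
                    fmt["GT"] = (0, 0)
                    fmt["AD"] = (dp, 0)
                    fmt["DP"] = dp
            vcf.write(rec)

    paired = [s for s in sites if s.tumor_ref_reads is not None]
    if paired:
        paths["pairs"] = out / "pairs.tsv"
        pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in paired],
                "site_id": [s.site_id for s in paired],
                "gene": [s.gene for s in paired],
                "blood_ref": [s.ref_reads for s in paired],
                "blood_alt": [s.alt_reads for s in paired],
                "tumor_ref": [s.tumor_ref_reads for s in paired],
                "tumor_alt": [s.tumor_alt_reads for s in paired],
            }
        ).to_csv(paths["pairs"], sep="\t", index=False)
    return paths
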
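"""Input readers, PTV consequence filtering and exon-position summaries.

The pipeline consumes three files: a VCF 4.2 with per-genotype GT/AD/DP,
a sample metadata TSV (sample_id, status, phenotype, age, mean_coverage)
and a variant annotation TSV (site_id, gene, transcript, consequence,
exon_rank, exon_total) — a minimal projection of VEP output, pre-reduced
to one row per site.  Raw VEP splice strings are mapped to the single
``splice_essential`` class at read time.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .types import (
    CONSEQUENCES,
    PTV_CONSEQUENCES,
    ExonEnrichment,
    SampleRecord,
    SiteObservation,
    ValidationError,
)

logger = logging.getLogger("mosaicburden")

__all__ = ["read_inputs", "read_metadata", "filter_ptv", "exon_enrichment",
           "exon_concentration_test"]

# raw VEP consequence strings accepted on input, folded to the
# controlled vocabulary (logged when applied)
_VEP_ALIASES = {
    "splice_donor_variant": "splice_essential",
    "splice_acceptor_variant": "splice_essential",
    "stop_gained": "stop_gained",
    "frameshift_variant": "frameshift",
    "missense_variant": "missense",
}


def _normalise_consequence(raw: str) -> str:
    if raw in CONSEQUENCES:
        return raw
    if raw in _VEP_ALIASES:
        logger.debug("consequence alias applied: %s -> %s", raw, _VEP_ALIASES[raw])
        return _VEP_ALIASES[raw]
    raise ValidationError(f"unknown consequence label {raw!r}")


def read_metadata(metadata_path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata TSV into SampleRecords."""
    meta = pd.read_csv(
        metadata_path, sep="\t", dtype={"sample_id": str},
        float_precision="round_trip",
    )
    required = {"sample_id", "status", "phenotype", "age", "mean_coverage"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    records = []
    for row in meta.itertuples(index=False):
        phen = None if (pd.isna(row.phenotype) or row.phenotype == "NA") else str(row.phenotype)
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                status=str(row.status),
                phenotype=phen,
                age=float(row.age),
                mean_coverage=float(row.mean_coverage),
            )
        )
    return records


def read_inputs(
    vcf_path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path,
    pairs_path: Optional[str | Path] = None,
    max_skip_fraction: float = 0.10,
) -> tuple[list[SampleRecord], list[SiteObservation]]:
    """Read and cross-validate the three standard input files.

    One :class:`SiteObservation` is emitted per non-reference genotype
    per sample, with read counts taken from the AD field.  Genotypes
    with missing AD, or AD summing to zero, are dropped with a logged
    count; more than ``max_skip_fraction`` of non-reference genotypes
    skipped is an error.  Every VCF sample must appear in the metadata
    and every VCF record must have an annotation row.  An optional
    tumor pairs TSV (sample_id, site_id, gene, blood_ref, blood_alt,
    tumor_ref, tumor_alt) re-attaches paired tumor read counts.
    """
    samples = read_metadata(metadata_path)
    known_ids = {s.sample_id for s in samples}

    anno = pd.read_csv(
        annotation_path, sep="\t", dtype={"site_id": str}, na_values=["NA"]
    )
    required = {"site_id", "gene", "consequence", "exon_rank", "exon_total"}
    missing = required - set(anno.columns)
    if missing:
        raise ValidationError(f"annotation missing columns: {sorted(missing)}")
    if anno["site_id"].duplicated().any():
        dups = anno.loc[anno["site_id"].duplicated(), "site_id"].tolist()
        raise ValidationError(
            f"annotation must be pre-reduced to one row per site; duplicated: {dups[:5]}"
        )
    anno_map: dict[str, tuple[str, str, Optional[int], Optional[int]]] = {}
    for row in anno.itertuples(index=False):
        conseq = _normalise_consequence(str(row.consequence))
        rank = None if pd.isna(row.exon_rank) else int(row.exon_rank)
        total = None if pd.isna(row.exon_total) else int(row.exon_total)
        anno_map[str(row.site_id)] = (str(row.gene), conseq, rank, total)

    pairs: dict[tuple[str, str], tuple[int, int]] = {}
    if pairs_path is not None:
        ptab = pd.read_csv(pairs_path, sep="\t", dtype={"sample_id": str, "site_id": str})
        for row in ptab.itertuples(index=False):
            pairs[(str(row.sample_id), str(row.site_id))] = (
                int(row.tumor_ref), int(row.tumor_alt)
            )

    sites: list[SiteObservation] = []
    n_nonref = 0
    n_skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        offenders = sorted(set(vcf_samples) - known_ids)
        if offenders:
            raise ValidationError(
                f"VCF samples absent from metadata: {offenders}"
            )
        for rec in vcf:
            site_id = rec.id
            if site_id is None or site_id not in anno_map:
                raise ValidationError(
                    f"VCF record at {rec.chrom}:{rec.pos} ({site_id!r}) has no "
                    "annotation row"
                )
            gene, conseq, rank, total = anno_map[site_id]
            for sid in vcf_samples:
                fmt = rec.samples[sid]
                gt = fmt.get("GT")
                if gt is None or not any(a not in (0, None) for a in gt):
                    continue  # hom-ref or missing genotype: no observation
                n_nonref += 1
                ad = fmt.get("AD")
                if ad is None or any(a is None for a in ad) or sum(ad) == 0:
                    n_skipped += 1
                    logger.warning(
                        "skipping %s at %s: missing or empty AD", sid, site_id
                    )
                    continue
                ref_reads, alt_reads = int(ad[0]), int(ad[1])
                if alt_reads < 1:
                    n_skipped += 1
                    logger.warning(
                        "skipping %s at %s: non-ref genotype with zero alt reads",
                        sid, site_id,
                    )
                    continue
                dp = fmt.get("DP")
                if dp is not None and dp != ref_reads + alt_reads:
                    logger.debug(
                        "%s at %s: DP=%s differs from AD sum %d (AD sum used)",
                        sid, site_id, dp, ref_reads + alt_reads,
                    )
                tumor = pairs.get((sid, site_id))
                sites.append(
                    SiteObservation(
                        sample_id=sid,
                        gene=gene,
                        site_id=site_id,
                        ref_reads=ref_reads,
                        alt_reads=alt_reads,
                        consequence=conseq,
                        exon_rank=rank,
                        exon_total=total,
                        tumor_ref_reads=tumor[0] if tumor else None,
                        tumor_alt_reads=tumor[1] if tumor else None,
                    )
                )
    if n_skipped:
        logger.info("skipped %d/%d non-reference genotypes", n_skipped, n_nonref)
    if n_nonref and n_skipped / n_nonref > max_skip_fraction:
        raise ValidationError(
            f"{n_skipped}/{n_nonref} non-reference genotypes skipped "
            f"(> {max_skip_fraction:.0%}); input looks malformed"
        )
    return samples, sites


def filter_ptv(sites: Iterable[SiteObservation]) -> list[SiteObservation]:
    """Keep protein-truncating consequences, preserving order.

    Retains exactly {stop_gained, splice_essential, frameshift}.  An
    unknown consequence label is an error, never a silent pass-through.
    """
    kept = []
    for site in sites:
        if site.consequence not in CONSEQUENCES:
            raise ValidationError(
                f"site {site.site_id}: unknown consequence {site.consequence!r}"
            )
        if site.consequence in PTV_CONSEQUENCES:
            kept.append(site)
    return kept


def exon_enrichment(
    ptv_sites: Sequence[SiteObservation], gene: str
) -> ExonEnrichment:
    """Count PTVs per exon and the final-exon fraction for one gene.

    Truncating variants in the last exon escape nonsense-mediated decay
    and can act as gain-of-function alleles; their concentration is the
    signature of interest.  Empty input yields ``total_ptv == 0`` with
    an undefined (None) fraction, not an exception.
    """
    counts: dict[int, int] = {}
    last = 0
    for site in ptv_sites:
        if site.gene != gene:
            raise ValidationError(
                f"site {site.site_id} belongs to {site.gene}, not {gene}"
            )
        if site.exon_rank is None or site.exon_total is None:
            raise ValidationError(
                f"site {site.site_id}: exon_rank/exon_total required"
            )
        counts[site.exon_rank] = counts.get(site.exon_rank, 0) + 1
        if site.exon_rank == site.exon_total:
            last += 1
    total = len(ptv_sites)
    return ExonEnrichment(
        gene=gene,
        counts_by_exon=dict(sorted(counts.items())),
        last_exon_count=last,
        total_ptv=total,
        last_exon_fraction=last / total if total else None,
    )


def exon_concentration_test(
    enrichment: ExonEnrichment, n_exons: int, length_fraction: Optional[float] = None
) -> Optional[float]:
    """Optional diagnostic: exact binomial test of last-exon concentration.

    Two-sided exact binomial test of the last-exon count against a
    uniform-across-coding-length null (``length_fraction``, defaulting
    to 1/``n_exons`` when exon lengths are unknown).  This is an
    extension beyond the raw counts the enrichment summary reports.
    Returns None for empty input.
    """
    from scipy.stats import binomtest

    if enrichment.total_ptv == 0:
        return None
    p0 = length_fraction if length_fraction is not None else 1.0 / n_exons
    return float(
        binomtest(enrichment.last_exon_count, enrichment.total_ptv, p0).pvalue
    )
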
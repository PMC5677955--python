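"""End-to-end orchestration: simulate/read -> call -> associate -> burden -> depletion.

Each stage communicates through its declared interface (lists of
records / DataFrames) and writes a plain-text artifact; a manifest
records package and library versions, the seed, all parameters and
input checksums, so a bundle is reproducible from its manifest alone.
The single pipeline seed is fanned out deterministically to per-stage
substreams, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import fit_carrier_model
from .burden import burden_scan
from .caller import call_sites, carrier_table, coverage_bias_check
from .depletion import coverage_comparison, depletion_test, paired_balances
from .io import filter_ptv, read_inputs
from .synthetic import CohortConfig, generate_cohort
from .types import (
    AssociationResult,
    CallerParams,
    ConfigError,
    ResamplingParams,
    SeparationError,
    ValidationError,
)

logger = logging.getLogger("mosaicburden")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Full-pipeline configuration.

    Exactly one of ``cohort`` (simulation mode) or the three input
    paths (``vcf``/``metadata``/``annotation``, file mode) must be
    supplied.  ``seed`` governs every stochastic stage.
    """

    out_dir: str | Path
    cohort: Optional[CohortConfig] = None
    vcf: Optional[str] = None
    metadata: Optional[str] = None
    annotation: Optional[str] = None
    pairs: Optional[str] = None
    caller: CallerParams = field(default_factory=CallerParams)
    resampling: ResamplingParams = field(default_factory=ResamplingParams)
    covariates: tuple[str, ...] = ("age", "coverage")
    excluded_phenotypes: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        sim = self.cohort is not None
        files = any(x is not None for x in (self.vcf, self.metadata, self.annotation))
        if sim == files:
            raise ConfigError(
                "exactly one of simulation config or input paths must be supplied"
            )
        if files and not all(
            x is not None for x in (self.vcf, self.metadata, self.annotation)
        ):
            raise ConfigError("file mode requires vcf, metadata and annotation paths")


def _assoc_to_dict(res: AssociationResult) -> dict:
    return dataclasses.asdict(res)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(obj):
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write the report bundle.

    Writes ``calls.tsv``, ``assoc.json``, ``burden.tsv``,
    ``depletion.json`` and ``manifest.json`` under ``config.out_dir``
    and returns the bundle as a dict.  Any stage failure halts the
    run with the stage named; degenerate-but-valid situations (no
    carriers, no tumor pairs) complete with warnings recorded in the
    bundle.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    seeds = np.random.SeedSequence(config.seed).spawn(2)

    # --- stage: inputs ----------------------------------------------------
    stage = "inputs"
    checksums: dict[str, str] = {}
    try:
        if config.cohort is not None:
            sim_cfg = dataclasses.replace(
                config.cohort, seed=int(seeds[0].generate_state(1)[0] % (2**31))
            )
            samples, sites, _truth = generate_cohort(sim_cfg)
        else:
            samples, sites = read_inputs(
                config.vcf, config.metadata, config.annotation, config.pairs
            )
            for key in ("vcf", "metadata", "annotation", "pairs"):
                path = getattr(config, key)
                if path is not None:
                    checksums[key] = _sha256(path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.info("stage=inputs samples=%d sites=%d", len(samples), len(sites))

    # --- stage: call ------------------------------------------------------
    stage = "call"
    try:
        ptv_sites = filter_ptv(sites)
        ptv_calls = call_sites(ptv_sites, config.caller)
        carriers = carrier_table(samples, ptv_calls)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    calls_df = pd.DataFrame(
        [dataclasses.asdict(c) for c in ptv_calls],
        columns=[
            "sample_id", "site_id", "gene", "depth", "alt_reads",
            "allele_balance", "p_value", "is_mosaic",
        ],
    )
    calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)
    logger.info(
        "stage=call ptv_sites=%d mosaic=%d carriers=%d",
        len(ptv_sites), int(calls_df["is_mosaic"].sum()) if len(calls_df) else 0,
        int(carriers["is_carrier"].sum()),
    )

    # --- stage: qc --------------------------------------------------------
    stage = "qc"
    try:
        qc = coverage_bias_check(samples, ptv_calls)
        if not qc.testable:
            warnings.append(f"qc: {qc.note}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- stage: associate -------------------------------------------------
    stage = "associate"
    assoc_report: dict = {"qc_coverage_bias": _assoc_to_dict(qc)}
    try:
        primary = fit_carrier_model(
            samples, carriers, covariates=config.covariates
        )
        assoc_report["carrier"] = _assoc_to_dict(primary)
        if not primary.testable:
            warnings.append(f"associate: {primary.note}")
        if config.excluded_phenotypes:
            excl = fit_carrier_model(
                samples,
                carriers,
                covariates=config.covariates,
                excluded_phenotypes=config.excluded_phenotypes,
            )
            assoc_report["carrier_excluding_phenotypes"] = _assoc_to_dict(excl)
    except SeparationError as exc:
        warnings.append(f"associate: {exc}")
        assoc_report["carrier"] = {"error": str(exc)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "assoc.json").write_text(
        json.dumps(assoc_report, indent=2, default=_json_default, sort_keys=True)
    )

    # --- stage: burden ----------------------------------------------------
    stage = "burden"
    try:
        phenotypes = {s.phenotype for s in samples if s.status == "case" and s.phenotype}
        if len(phenotypes) >= 2 and carriers["is_carrier"].any():
            rs = dataclasses.replace(
                config.resampling,
                seed=int(seeds[1].generate_state(1)[0] % (2**31)),
            )
            burden = burden_scan(samples, carriers, rs)
            burden_df = pd.DataFrame([dataclasses.asdict(b) for b in burden])
            burden_df["gene"] = burden_df["gene"].fillna("all")
        else:
            warnings.append("burden: skipped (needs >=2 phenotypes and >=1 carrier)")
            burden_df = pd.DataFrame()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    burden_df.to_csv(out / "burden.tsv", sep="\t", index=False)

    # --- stage: depletion -------------------------------------------------
    stage = "depletion"
    try:
        mosaic_ids = {
            (c.sample_id, c.site_id) for c in ptv_calls if c.is_mosaic
        }
        mosaic_sites = [
            s for s in ptv_sites if (s.sample_id, s.site_id) in mosaic_ids
        ]
        pairs = paired_balances(mosaic_sites)
        if pairs:
            dep = depletion_test(pairs, per_gene=True)
            depletion_report = {
                key: dataclasses.asdict(summary) for key, summary in dep.items()
            }
            if len(pairs) >= 2:
                depletion_report["coverage"] = dataclasses.asdict(
                    coverage_comparison(pairs)
                )
        else:
            warnings.append("depletion: skipped (no paired tumor reads at mosaic sites)")
            depletion_report = {}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "depletion.json").write_text(
        json.dumps(depletion_report, indent=2, default=_json_default, sort_keys=True)
    )

    # --- manifest ---------------------------------------------------------
    manifest = {
        "package": "mosaicburden",
        "version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "parameters": {
            "caller": dataclasses.asdict(config.caller),
            "resampling": dataclasses.asdict(config.resampling),
            "covariates": list(config.covariates),
            "excluded_phenotypes": list(config.excluded_phenotypes),
            "cohort": dataclasses.asdict(config.cohort) if config.cohort else None,
        },
        "input_checksums": checksums,
        "warnings": warnings,
        "n_samples": len(samples),
        "n_sites": len(sites),
        "n_carriers": int(carriers["is_carrier"].sum()),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default, sort_keys=True)
    )
    return {
        "assoc": assoc_report,
        "burden": burden_df,
        "depletion": depletion_report,
        "manifest": manifest,
        "warnings": warnings,
    }
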
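from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mosaicburden import CohortConfig, generate_cohort
from mosaicburden.types import SampleRecord


def make_carrier_df(ids, flags, genes=None):
    """Build a carrier table by hand for burden/association tests."""
    genes = genes if genes is not None else [frozenset()] * len(ids)
    return pd.DataFrame(
        {
            "is_carrier": list(flags),
            "carrier_genes": [frozenset(g) for g in genes],
            "n_mosaic_ptv": [1 if f else 0 for f in flags],
        },
        index=pd.Index(list(ids), name="sample_id"),
    )


def make_cases(n, carrier_flags, ages=None, phenotypes=None):
    """Uniform helper: n case SampleRecords plus a matching carrier table."""
    ids = [f"S{i:04d}" for i in range(n)]
    ages = ages if ages is not None else [50.0] * n
    phenotypes = phenotypes if phenotypes is not None else ["X"] * n
    samples = [
        SampleRecord(ids[i], "case", phenotypes[i], float(ages[i]), 30.0)
        for i in range(n)
    ]
    return samples, make_carrier_df(ids, carrier_flags)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with enough carriers to exercise every stage."""
    cfg = CohortConfig(
        n_cases=400,
        n_controls=300,
        phenotype_labels={"GBM": 100, "SKCM": 100, "LUAD": 100, "OV": 100},
        carrier_base_rate=0.05,
        seed=20,
    )
    samples, sites, truth = generate_cohort(cfg)
    return cfg, samples, sites, truth


@pytest.fixture(scope="session")
def fixture_dir(small_cohort, tmp_path_factory):
    from mosaicburden import write_fixtures

    _, samples, sites, _ = small_cohort
    out = tmp_path_factory.mktemp("fixtures")
    return write_fixtures(samples, sites, out)
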
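"""Shared fixtures: a small seeded cohort and its on-disk form."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import desertscan as ds
from desertscan.simulate import SweepSpec


def small_sim_params(seed: int = 11, **overrides) -> ds.SimParams:
    """A cheap cohort: 2 x 120 kbp, 24+12 samples, one 12 kbp sweep."""
    defaults = dict(
        seed=seed,
        chrom_lengths={"chr1": 120_000, "chr2": 120_000},
        n_samples={"cultivated": 24, "wild": 12},
        sweeps=[SweepSpec("chr1", 60_000, 6_000)],
        blocus_region=("chr2", 60_000, 70_338),
        blocus_n_sites=50,
        gene_density=1e-4,
    )
    defaults.update(overrides)
    return ds.SimParams(**defaults)


@pytest.fixture(scope="session")
def small_cohort() -> ds.SimResult:
    return ds.simulate_cohort(small_sim_params())


@pytest.fixture(scope="session")
def small_fixture_dir(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    paths = ds.emit_fixture(small_cohort, out)
    return paths


def make_site_table(
    chroms, positions, refs=None, alts=None, **annotations
) -> ds.SiteTable:
    n = len(positions)
    refs = refs if refs is not None else ["A"] * n
    alts = alts if alts is not None else ["T"] * n
    from desertscan.core import classify_variant

    df = pd.DataFrame(
        {
            "chrom": chroms if not isinstance(chroms, str) else [chroms] * n,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "variant_class": [
                classify_variant(r, a.split(",")[0]) for r, a in zip(refs, alts)
            ],
            "multiallelic": [("," in a) for a in alts],
        }
    )
    for key, vals in annotations.items():
        df[key] = vals
    return ds.SiteTable(df)
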
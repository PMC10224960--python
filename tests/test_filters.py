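"""Site filtering semantics (boundaries, strictness, missing annotations),
brute-force oracle agreement and the shared/private variation partition."""

from __future__ import annotations

import math

import numpy as np
import pytest

import desertscan as ds
from desertscan.core import MISSING
from desertscan.filters import DEFAULT_ANNOTATION_THRESHOLDS, FilterParams

from conftest import make_site_table


def gm_of(rows) -> ds.GenotypeMatrix:
    codes = np.asarray(rows, dtype=np.int8)
    return ds.GenotypeMatrix([f"s{i}" for i in range(codes.shape[1])], codes)


def test_missing_fraction_boundary_at_656_samples():
    # 66/656 = 0.1006 exceeds the 10% bound; 65/656 = 0.0991 passes
    for n_missing, passes in ((0, True), (65, True), (66, False), (656, False)):
        row = np.zeros((1, 656), dtype=np.int8)
        row[0, :n_missing] = MISSING
        row[0, -1] = 1 if n_missing < 656 else MISSING
        frac = ds.site_missing_fraction(gm_of(row))[0]
        assert math.isclose(frac, n_missing / 656)
        assert (frac <= 0.10) == passes


def test_minor_allele_frequency_examples_and_boundaries():
    # 100 samples -> 200 called alleles
    one_alt = np.zeros((1, 100), np.int8); one_alt[0, 0] = 1
    three_alt = np.zeros((1, 100), np.int8); three_alt[0, :3] = 1
    all_alt = np.full((1, 100), 2, np.int8)
    none_called = np.full((1, 100), MISSING, np.int8)
    maf = lambda rows: ds.minor_allele_frequency(gm_of(rows))[0]
    assert maf(one_alt) == pytest.approx(0.005)       # fails min_maf 0.01
    assert maf(three_alt) == pytest.approx(0.015)     # passes
    assert maf(all_alt) == 0.0                        # reference is the minor allele
    assert math.isnan(maf(none_called))               # undefined -> site fails


def test_maf_invariant_under_ref_alt_swap():
    rng = np.random.default_rng(0)
    codes = rng.integers(-1, 3, size=(200, 40)).astype(np.int8)
    swapped = codes.copy()
    swapped[codes == 0] = 2
    swapped[codes == 2] = 0
    np.testing.assert_allclose(
        ds.minor_allele_frequency(gm_of(codes)),
        ds.minor_allele_frequency(gm_of(swapped)),
        equal_nan=True,
    )


def test_depth_bounds_inclusive_and_annotation_strictness():
    # 10 called samples: DP in [20, 100] passes; DP=19 fails; MQ=30 fails (strict >)
    codes = np.tile(np.array([[1] * 10]), (4, 1)).astype(np.int8)
    sites = make_site_table(
        "chr1", [0, 10, 20, 30],
        DP=[20.0, 19.0, 100.0, 101.0],
        MQ=[31.0, 31.0, 30.0, 31.0],
    )
    res = ds.apply_site_filters(sites, gm_of(codes), FilterParams())
    assert res.per_filter_pass["depth"].tolist() == [True, False, True, False]
    assert res.per_filter_pass["MQ"].tolist() == [True, True, False, True]


def test_absent_annotation_skips_filter_by_default_but_can_fail():
    codes = np.array([[1] * 10], np.int8)
    sites = make_site_table("chr1", [0])  # all annotations NaN
    res = ds.apply_site_filters(sites, gm_of(codes), FilterParams())
    assert res.mask[0]
    strict = FilterParams(skip_if_absent=False)
    res2 = ds.apply_site_filters(sites, gm_of(codes), strict)
    assert not res2.mask[0]


def _brute_force_pass(site_row, codes_row, params: FilterParams):
    """Independent per-site re-evaluation of every filter rule."""
    failures = set()
    if params.biallelic_only and site_row["multiallelic"]:
        failures.add("biallelic")
    n = len(codes_row)
    n_missing = sum(1 for c in codes_row if c == MISSING)
    if n_missing / n > params.max_missing_fraction:
        failures.add("missing")
    called = [c for c in codes_row if c != MISSING]
    if not called:
        failures.add("maf")
    else:
        af = sum(called) / (2 * len(called))
        if min(af, 1 - af) <= params.min_maf:
            failures.add("maf")
    dp = site_row["DP"]
    if math.isnan(dp):
        if not params.skip_if_absent:
            failures.add("depth")
    elif not (params.depth_low * len(called) <= dp <= params.depth_high * len(called)):
        failures.add("depth")
    for key, (op, thr) in params.annotation_thresholds.items():
        v = site_row[key]
        if math.isnan(v):
            if not params.skip_if_absent:
                failures.add(key)
        elif op == ">" and not v > thr:
            failures.add(key)
        elif op == "<" and not v < thr:
            failures.add(key)
    return failures


@pytest.fixture(scope="module")
def thousand_site_fixture():
    """1,000 sites with deliberate per-filter violations (simulator output)."""
    params_sim = dict(
        seed=21,
        chrom_lengths={"chr1": 60_000},
        n_samples={"cultivated": 30, "wild": 20},
        sweeps=[],
        blocus_region=("chr1", 50_000, 55_000),
        blocus_n_sites=50,
        annotation_fail_fraction=0.15,
        missing_rate=0.08,
        site_density=0.0182,
    )
    r = ds.simulate_cohort(ds.SimParams(**params_sim))
    keep = np.zeros(r.sites.n_sites, dtype=bool)
    keep[:1000] = True
    return r.sites.subset(keep), r.genotypes.subset_sites(keep)


def test_filter_mask_equals_brute_force_oracle(thousand_site_fixture):
    sites, gm = thousand_site_fixture
    params = FilterParams()
    res = ds.apply_site_filters(sites, gm, params)
    for i in range(sites.n_sites):
        failures = _brute_force_pass(sites.df.iloc[i], gm.codes[i], params)
        assert res.mask[i] == (not failures), f"site {i}: {failures}"
        for name, passed in res.per_filter_pass.items():
            assert passed[i] == (name not in failures)


def test_rejection_counts_attribute_every_failed_filter(thousand_site_fixture):
    sites, gm = thousand_site_fixture
    res = ds.apply_site_filters(sites, gm)
    for name, mask in res.per_filter_pass.items():
        assert res.rejection_counts[name] == int((~mask).sum())


def test_filter_conjunction_is_order_independent(thousand_site_fixture):
    sites, gm = thousand_site_fixture
    base = ds.apply_site_filters(sites, gm, FilterParams())
    reordered = FilterParams(
        annotation_thresholds=dict(
            reversed(list(DEFAULT_ANNOTATION_THRESHOLDS.items()))
        )
    )
    res2 = ds.apply_site_filters(sites, gm, reordered)
    assert (base.mask == res2.mask).all()


def test_filter_params_invariants():
    with pytest.raises(ValueError):
        FilterParams(max_missing_fraction=1.0)
    with pytest.raises(ValueError):
        FilterParams(min_maf=0.5)
    with pytest.raises(ValueError):
        FilterParams(depth_low=10, depth_high=2)


# --- shared/private variation partition -----------------------------------

def test_venn_private_and_full_intersection_cells():
    pops = ds.PopulationSpec({"a0": "A", "a1": "A", "b0": "B", "c0": "C"})
    codes = np.array(
        [
            [1, 0, 0, 0],   # private to A
            [1, 2, 1, 1],   # everywhere
            [0, 0, 0, 0],   # absent -> uncounted
            [0, MISSING, 1, 1],  # B & C
        ],
        dtype=np.int8,
    )
    sites = make_site_table("chr1", [0, 10, 20, 30])
    gm = ds.GenotypeMatrix(["a0", "a1", "b0", "c0"], codes)
    venn = ds.partition_shared_variation(gm, sites, pops, ["A", "B", "C"])
    assert venn.counts[("A",)]["SNV"] == 1
    assert venn.counts[("A", "B", "C")]["SNV"] == 1
    assert venn.counts[("B", "C")]["SNV"] == 1
    assert venn.total == 3


def test_venn_unknown_group_label_raises(small_cohort):
    with pytest.raises(KeyError):
        ds.partition_shared_variation(
            small_cohort.genotypes,
            small_cohort.sites,
            small_cohort.populations,
            ["cultivated", "nope"],
        )


def test_venn_matches_exhaustive_enumeration():
    rng = np.random.default_rng(3)
    n_sites, samples = 500, ["a0", "a1", "b0", "b1", "c0", "c1"]
    pops = ds.PopulationSpec(
        {"a0": "A", "a1": "A", "b0": "B", "b1": "B", "c0": "C", "c1": "C"}
    )
    codes = rng.choice(
        np.array([-1, 0, 0, 0, 1, 2], dtype=np.int8), size=(n_sites, 6)
    )
    refs = ["A"] * n_sites
    alts = rng.choice(["T", "TT"], size=n_sites).tolist()  # mix SNVs and indels
    sites = make_site_table("chr1", np.arange(n_sites) * 3, refs=refs, alts=alts)
    gm = ds.GenotypeMatrix(samples, codes)
    venn = ds.partition_shared_variation(gm, sites, pops, ["A", "B", "C"])
    # exhaustive oracle
    expected: dict[tuple[str, ...], dict[str, int]] = {}
    present_any = 0
    for i in range(n_sites):
        subset = []
        for g, idx in (("A", [0, 1]), ("B", [2, 3]), ("C", [4, 5])):
            if any(codes[i, j] > 0 for j in idx):
                subset.append(g)
        if not subset:
            continue
        present_any += 1
        cls = "SNV" if sites.df["variant_class"].iloc[i] == "SNV" else "indel"
        cell = expected.setdefault(tuple(subset), {"SNV": 0, "indel": 0})
        cell[cls] += 1
    assert venn.counts == expected
    assert venn.total == present_any  # cells sum to variants present somewhere
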
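"""Window tiling, B-locus screening, per-window population statistics
(brute-force oracle) and desert calling semantics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import desertscan as ds
from desertscan.core import MISSING
from desertscan.deserts import (
    DesertThresholds,
    call_desert_windows,
    make_windows,
    pop_maf_mask,
    private_deserts,
    window_population_stats,
)

from conftest import make_site_table


def test_make_windows_arithmetic_and_boundaries():
    ws = make_windows({"c": 10_000})
    assert len(ws) == 9
    assert (ws.regions[-1].start, ws.regions[-1].end) == (8000, 10_000)
    assert len(make_windows({"c": 1999})) == 0
    assert len(make_windows({"c": 2000})) == 1
    with pytest.raises(ValueError):
        make_windows({"c": 10_000}, step=0)


def test_every_interior_base_covered_by_exactly_two_windows():
    L = 12_000
    ws = make_windows({"c": L})
    cover = np.zeros(L, dtype=int)
    for r in ws:
        cover[r.start:r.end] += 1
    assert (cover[1000: L - 1000] == 2).all()
    assert (cover[:1000] == 1).all()


def test_blocus_selection_hand_case():
    # 20 region sites; sample0 carries 3, sample1 carries 16, sample2 has
    # carried sites masked as missing (missing calls never count)
    codes = np.zeros((20, 3), dtype=np.int8)
    codes[:3, 0] = 1
    codes[:16, 1] = 2
    codes[:20, 2] = 1
    codes[:20, 2] = MISSING
    sites = make_site_table("chr2", np.arange(20) * 100)
    gm = ds.GenotypeMatrix(["low", "high", "gone"], codes)
    region = ds.GenomicRegion("chr2", 0, 5000)
    sel = ds.select_blocus_accessions(gm, sites, region, max_variants=5)
    assert sel.counts == {"low": 3, "high": 16, "gone": 0}
    assert sel.selected == ["low", "gone"]


def test_blocus_no_variants_selects_everyone():
    sites = make_site_table("chr9", [100])
    gm = ds.GenotypeMatrix(["a", "b"], np.array([[1, 1]], np.int8))
    region = ds.GenomicRegion("chr2", 0, 10_338)
    sel = ds.select_blocus_accessions(gm, sites, region)
    assert sel.selected == ["a", "b"]


def test_blocus_recovers_simulated_truth(small_cohort):
    r = small_cohort
    sel = ds.select_blocus_accessions(
        r.genotypes, r.sites, ds.GenomicRegion(*r.params.blocus_region)
    )
    truth_low = {s for s, m in r.truth.blocus_modes.items() if m == "low"}
    assert set(sel.selected) == truth_low


def test_pop_maf_mask_excludes_fixed_and_rare_sites():
    codes = np.array(
        [
            [2, 2, 2, 2],    # fixed alt in pop -> MAF 0 -> excluded
            [0, 0, 0, 0],    # monomorphic ref -> excluded
            [1, 0, 0, 0],    # MAF 1/8 -> kept at 0.05
            [1, 1, 1, 1],    # MAF 0.5
        ],
        dtype=np.int8,
    )
    gm = ds.GenotypeMatrix(["a", "b", "c", "d"], codes)
    assert pop_maf_mask(gm, ["a", "b", "c", "d"], 0.05).tolist() == [
        False, False, True, True,
    ]


def _coverage_frame(windows, samples, depth, covered):
    wdf = windows.to_frame()
    rows = []
    for i, (_, w) in enumerate(wdf.iterrows()):
        for j, s in enumerate(samples):
            rows.append(
                {
                    "chrom": w["chrom"],
                    "start": w["start"],
                    "end": w["end"],
                    "sample": s,
                    "mean_depth": depth[i][j],
                    "covered_bases": covered[i][j],
                }
            )
    return pd.DataFrame(rows)


def test_window_stats_variant_count_example():
    windows = make_windows({"chr1": 5000})
    sites = make_site_table("chr1", [1500, 2500])
    gm = ds.GenotypeMatrix(["a", "b"], np.array([[1, 0], [0, 1]], np.int8))
    cov = _coverage_frame(
        windows, ["a", "b"],
        [[6, 6]] * len(windows), [[2000, 2000]] * len(windows),
    )
    stats = window_population_stats(windows, sites, gm, cov, ["a", "b"])
    by_window = dict(zip(stats["start"], stats["n_variants"]))
    assert by_window[1000] == 2  # window [1000,3000) holds both sites
    assert by_window[0] == 1 and by_window[2000] == 1
    assert by_window[3000] == 0


def test_window_stats_zero_coverage_window():
    windows = make_windows({"chr1": 3000})
    sites = make_site_table("chr1", [10])
    gm = ds.GenotypeMatrix(["a"], np.array([[1]], np.int8))
    cov = _coverage_frame(windows, ["a"], [[0], [0]], [[0], [0]])
    stats = window_population_stats(windows, sites, gm, cov, ["a"])
    assert (stats["mean_depth"] == 0).all()
    assert (stats["covered_fraction"] == 0).all()
    assert (stats["samples_with_reads_fraction"] == 0).all()


def test_window_stats_match_bruteforce_oracle(small_cohort):
    """All four statistics equal an independent per-window recomputation."""
    r = small_cohort
    pop = r.populations.samples_of("wild")
    keep = pop_maf_mask(r.genotypes, pop, 0.05)
    sites = r.sites.subset(keep)
    gm = r.genotypes.subset_sites(keep)
    windows = make_windows(r.params.chrom_lengths)
    for mode in ("population_sites", "max_per_accession"):
        stats = window_population_stats(
            windows, sites, gm, r.coverage, pop, count_mode=mode
        )
        idx = gm.sample_indices(pop)
        cov = r.coverage[r.coverage["sample"].isin(pop)]
        rng = np.random.default_rng(0)
        for row_i in rng.choice(len(stats), 50, replace=False):
            row = stats.iloc[row_i]
            chrom, start, end = row["chrom"], row["start"], row["end"]
            in_w = (
                (sites.df["chrom"] == chrom)
                & (sites.df["pos"] >= start)
                & (sites.df["pos"] < end)
            ).to_numpy()
            carrier = gm.codes[np.ix_(in_w, idx)] > 0
            if mode == "population_sites":
                expected_count = int(carrier.any(axis=1).sum())
            else:
                expected_count = int(carrier.sum(axis=0).max()) if carrier.size else 0
            assert row["n_variants"] == expected_count
            wcov = cov[
                (cov["chrom"] == chrom) & (cov["start"] == start)
            ]
            depths = {s: 0.0 for s in pop}
            covered = {s: 0.0 for s in pop}
            for _, c in wcov.iterrows():
                depths[c["sample"]] = c["mean_depth"]
                covered[c["sample"]] = c["covered_bases"]
            assert row["mean_depth"] == pytest.approx(
                sum(depths.values()) / len(pop)
            )
            prod = 1.0
            for s in pop:
                prod *= 1.0 - min(covered[s] / (end - start), 1.0)
            assert row["covered_fraction"] == pytest.approx(1.0 - prod)
            assert row["samples_with_reads_fraction"] == pytest.approx(
                sum(1 for s in pop if covered[s] > 0) / len(pop)
            )


def test_desert_call_boundaries_are_inclusive():
    thr = DesertThresholds.cultivated()
    stats = pd.DataFrame(
        {
            "chrom": ["c"] * 4,
            "start": [0, 1000, 2000, 3000],
            "end": [2000, 3000, 4000, 5000],
            "n_variants": [2, 3, 2, 2],
            "mean_depth": [6.0, 6.0, 5.99, 6.0],
            "covered_fraction": [0.9, 0.9, 0.9, 0.9],
            "samples_with_reads_fraction": [0.9, 0.9, 0.9, 0.89],
        }
    )
    flagged = call_desert_windows(stats, thr)
    assert [r.start for r in flagged] == [0]  # exact-boundary window passes


def test_desert_call_matches_conjunction_oracle():
    rng = np.random.default_rng(9)
    n = 200
    stats = pd.DataFrame(
        {
            "chrom": ["c"] * n,
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 2000,
            "n_variants": rng.integers(0, 6, n),
            "mean_depth": rng.uniform(3, 9, n),
            "covered_fraction": rng.uniform(0.7, 1.0, n),
            "samples_with_reads_fraction": rng.uniform(0.7, 1.0, n),
        }
    )
    thr = DesertThresholds.wild()
    flagged = call_desert_windows(stats, thr)
    starts = {r.start for r in flagged}
    for _, row in stats.iterrows():
        expected = (
            row["n_variants"] <= 4
            and row["mean_depth"] >= 4
            and row["covered_fraction"] >= 0.8
            and row["samples_with_reads_fraction"] >= 0.9
        )
        assert (row["start"] in starts) == expected


def test_private_desert_identity_and_merge_order():
    cult = ds.RegionSet([("c", 0, 2000), ("c", 1000, 3000), ("c", 6000, 8000),
                         ("c", 12_000, 14_000)])
    wild = ds.RegionSet([("c", 2000, 2500), ("c", 6000, 8000)])
    res = private_deserts(cult, wild, max_gap=1000)
    assert res.cultivated_bp == 7000  # union of cultivated windows
    assert res.shared_bp + res.private_bp == res.cultivated_bp
    assert res.shared_bp == 2500
    # private pieces [0,2000) and [2500,3000): gap 500 merges afterwards
    assert [(r.start, r.end) for r in res.private_merged] == [
        (0, 3000), (12_000, 14_000)
    ]
    # merging happens after subtraction: raw private keeps the two pieces
    assert [(r.start, r.end) for r in res.private_raw] == [
        (0, 2000), (2500, 3000), (12_000, 14_000)
    ]


def test_wild_desert_calls_ignore_cultivated_genotypes(small_cohort):
    """Population isolation: shuffling cultivated genotypes cannot change
    the wild population's desert calls."""
    r = small_cohort
    wild = r.populations.samples_of("wild")
    keep = pop_maf_mask(r.genotypes, wild, 0.05)
    windows = make_windows(r.params.chrom_lengths)
    stats1 = window_population_stats(
        windows, r.sites.subset(keep), r.genotypes.subset_sites(keep),
        r.coverage, wild,
    )
    codes = r.genotypes.codes.copy()
    cult_idx = r.genotypes.sample_indices(r.populations.samples_of("cultivated"))
    rng = np.random.default_rng(1)
    codes[:, cult_idx] = rng.permutation(codes[:, cult_idx], axis=0)
    gm2 = ds.GenotypeMatrix(r.genotypes.samples, codes)
    keep2 = pop_maf_mask(gm2, wild, 0.05)
    assert (keep2 == keep).all()
    stats2 = window_population_stats(
        windows, r.sites.subset(keep2), gm2.subset_sites(keep2), r.coverage, wild
    )
    pd.testing.assert_frame_equal(stats1, stats2)


def test_empty_population_is_an_error(small_cohort):
    windows = make_windows(small_cohort.params.chrom_lengths)
    with pytest.raises(ValueError, match="empty population"):
        window_population_stats(
            windows, small_cohort.sites, small_cohort.genotypes,
            small_cohort.coverage, [],
        )
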
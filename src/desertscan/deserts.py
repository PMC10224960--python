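"""Variation-desert detection: B-locus accession selection, 2 kbp/1 kbp
window statistics, desert calling, merging, and the private-desert
difference between populations.

A "variation desert" is a window that is well covered by reads in a
population yet carries (almost) no segregating variation there — the
expected footprint of a selective sweep fixed by breeding. The scan follows
the bolting-locus logic of domesticated beet: accessions are first screened
for low variant counts at the B-locus (the *BvBTC1* bolting gene, 10,338 bp
including introns, which separates crop-type biennials from annual wild
beets), then per-population window statistics are computed over a canonical
2 kbp / 1 kbp sliding tiling, thresholded, and the cultivated-only desert
base pairs extracted.

All threshold comparisons are inclusive: a window sitting exactly on a
bound ("no more than two variants", "min. depth six") passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MISSING, SiteTable
from .regions import (
    GenomicRegion,
    RegionSet,
    SubtractResult,
    merge_regions,
    region_union,
    subtract_regions,
)

WINDOW_SIZE_DEFAULT = 2000
WINDOW_STEP_DEFAULT = 1000


@dataclass
class DesertThresholds:
    """Per-population desert-calling thresholds.

    Cultivated defaults follow the sugar-beet settings (max 2 variants,
    mean depth >= 6, >= 90% of the window covered, >= 90% of samples with
    reads); :meth:`wild` gives the relaxed sea-beet settings (4 variants,
    depth 4, 80% width) that account for the lower mapping coverage of the
    wild material.
    """

    max_variants: int = 2
    min_mean_depth: float = 6.0
    min_window_covered_fraction: float = 0.9
    min_samples_with_reads_fraction: float = 0.9
    count_mode: str = "population_sites"

    def __post_init__(self) -> None:
        if self.max_variants < 0:
            raise ValueError("max_variants must be >= 0")
        for frac in (
            self.min_window_covered_fraction,
            self.min_samples_with_reads_fraction,
        ):
            if not 0 < frac <= 1:
                raise ValueError("fractions must be in (0, 1]")
        if self.count_mode not in ("population_sites", "max_per_accession"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")

    @classmethod
    def cultivated(cls) -> "DesertThresholds":
        return cls()

    @classmethod
    def wild(cls) -> "DesertThresholds":
        return cls(
            max_variants=4,
            min_mean_depth=4.0,
            min_window_covered_fraction=0.8,
            min_samples_with_reads_fraction=0.9,
        )


def make_windows(
    chrom_lengths: dict[str, int],
    size: int = WINDOW_SIZE_DEFAULT,
    step: int = WINDOW_STEP_DEFAULT,
) -> RegionSet:
    """Canonical sliding-window tiling [i*step, i*step+size) per chromosome.

    Windows whose end would exceed the chromosome are dropped (no trailing
    remainder window).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if size < step:
        raise ValueError("window size must be >= step")
    regions = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n = (length - size) // step + 1 if length >= size else 0
        for i in range(n):
            regions.append(GenomicRegion(chrom, i * step, i * step + size))
    return RegionSet(regions)


@dataclass
class BlocusSelection:
    region: GenomicRegion
    max_variants: int
    selected: list[str]
    counts: dict[str, int]


def select_blocus_accessions(
    gm: GenotypeMatrix,
    sites: SiteTable,
    region: GenomicRegion,
    max_variants: int = 5,
    samples: Optional[Sequence[str]] = None,
) -> BlocusSelection:
    """Keep accessions with at most ``max_variants`` variants at the B-locus.

    A sample's count is the number of region sites where its genotype is
    non-missing and carries at least one alt allele. With no variants in the
    region every sample is selected.
    """
    if region.start >= region.end:  # GenomicRegion already enforces this
        raise ValueError("empty B-locus region")
    df = sites.df
    in_region = (
        (df["chrom"].to_numpy() == region.chrom)
        & (df["pos"].to_numpy() >= region.start)
        & (df["pos"].to_numpy() < region.end)
    )
    sub = gm.codes[in_region]
    carrier = (sub != MISSING) & (sub > 0)
    per_sample = carrier.sum(axis=0)
    names = gm.samples if samples is None else list(samples)
    idx = gm.sample_indices(names)
    counts = {s: int(per_sample[i]) for s, i in zip(names, idx)}
    selected = [s for s in names if counts[s] <= max_variants]
    return BlocusSelection(
        region=region, max_variants=max_variants, selected=selected, counts=counts
    )


def pop_maf_mask(
    gm: GenotypeMatrix, pop_samples: Sequence[str], min_maf: float = 0.05
) -> np.ndarray:
    """Sites with within-population MAF >= ``min_maf`` (called alleles only).

    The desert scan excludes low-frequency variants per analysis population
    to discount reference and sequencing errors; a site monomorphic within
    the population (including alt-fixed sites) is excluded.
    """
    idx = gm.sample_indices(pop_samples)
    sub = gm.codes[:, idx]
    called = sub != MISSING
    alt = np.where(called, sub, 0).sum(axis=1).astype(float)
    denom = 2.0 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(denom > 0, alt / denom, np.nan)
    maf = np.minimum(af, 1.0 - af)
    return np.where(np.isnan(maf), False, maf >= min_maf)


def _site_window_pairs(
    pos: np.ndarray, length_hint: int, size: int, step: int
) -> tuple[np.ndarray, np.ndarray]:
    """(site_index, window_index) pairs for a regular tiling on one chrom."""
    first = np.maximum(0, (pos - size) // step + 1)
    last = pos // step  # inclusive
    n_pairs = (last - first + 1).clip(min=0)
    site_idx = np.repeat(np.arange(pos.size), n_pairs)
    offsets = np.concatenate([np.arange(k) for k in n_pairs]) if pos.size else np.empty(0, int)
    win_idx = np.repeat(first, n_pairs) + offsets
    return site_idx, win_idx


def window_population_stats(
    windows: RegionSet,
    sites: SiteTable,
    gm: GenotypeMatrix,
    coverage: pd.DataFrame,
    pop_samples: Sequence[str],
    count_mode: str = "population_sites",
) -> pd.DataFrame:
    """Per-window variant counts and coverage statistics for one population.

    ``sites``/``gm`` should already be restricted to the variants relevant
    to the scan (biallelic, within-population MAF >= 0.05). Variant counts:

    * ``population_sites`` — sites in the window where at least one
      population sample carries an alt allele;
    * ``max_per_accession`` — the maximum over population samples of the
      per-sample count of alt-carrying sites in the window.

    Coverage columns aggregate the per-sample coverage table: mean depth is
    the population mean of per-sample mean depths; the covered fraction is
    the estimated fraction of window bases with pooled population depth >= 1
    (complement-product across samples, exact under independent per-sample
    coverage); the samples-with-reads fraction counts samples with any
    covered base.
    """
    if not pop_samples:
        raise ValueError("empty population")
    if count_mode not in ("population_sites", "max_per_accession"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    wdf = windows.to_frame()
    if len(wdf) == 0:
        raise ValueError("no windows")
    sizes = (wdf["end"] - wdf["start"]).unique()
    steps = {
        chrom: np.diff(grp["start"].to_numpy())
        for chrom, grp in wdf.groupby("chrom")
    }
    size = int(sizes[0])
    step_vals = np.concatenate([d for d in steps.values() if d.size]) if any(
        d.size for d in steps.values()
    ) else np.array([size])
    if len(sizes) != 1 or (step_vals != step_vals[0]).any():
        raise ValueError("windows must come from a regular tiling")
    step = int(step_vals[0]) if step_vals.size else size

    idx = gm.sample_indices(pop_samples)
    codes = gm.codes[:, idx]
    carrier = codes > 0  # non-missing alt-carrying

    counts = np.zeros(len(wdf), dtype=np.int64)
    win_offset = 0
    sdf = sites.df
    for chrom, grp in wdf.groupby("chrom", sort=False):
        n_windows = len(grp)
        site_rows = np.nonzero(sdf["chrom"].to_numpy() == chrom)[0]
        pos = sdf["pos"].to_numpy()[site_rows]
        s_idx, w_idx = _site_window_pairs(pos, n_windows, size, step)
        keep = w_idx < n_windows
        s_idx, w_idx = s_idx[keep], w_idx[keep]
        if count_mode == "population_sites":
            seg = carrier[site_rows].any(axis=1)
            np.add.at(counts, win_offset + w_idx, seg[s_idx])
        else:
            per_sample = np.zeros((n_windows, len(idx)), dtype=np.int64)
            np.add.at(per_sample, w_idx, carrier[site_rows][s_idx])
            counts[win_offset: win_offset + n_windows] = per_sample.max(axis=1)
        win_offset += n_windows

    cov = coverage[coverage["sample"].isin(set(pop_samples))]
    key = wdf[["chrom", "start", "end"]].copy()
    length = size
    grouped = cov.groupby(["chrom", "start", "end"], sort=False).agg(
        mean_depth=("mean_depth", "mean"),
        log_not_covered=(
            "covered_bases",
            lambda cb: np.log1p(-np.minimum(cb / length, 1.0) + 0.0).sum()
            if (cb < length).all()
            else -np.inf,
        ),
        n_with_reads=("covered_bases", lambda cb: (cb > 0).sum()),
        n_rows=("covered_bases", "size"),
    )
    merged = key.merge(
        grouped.reset_index(), on=["chrom", "start", "end"], how="left"
    )
    n_pop = len(pop_samples)
    mean_depth = merged["mean_depth"].fillna(0.0).to_numpy()
    log_nc = merged["log_not_covered"].fillna(0.0).to_numpy()
    covered_fraction = 1.0 - np.exp(log_nc)
    covered_fraction[np.isneginf(log_nc)] = 1.0
    # samples absent from the table have no reads in the window
    n_with_reads = merged["n_with_reads"].fillna(0).to_numpy()
    samples_with_reads_fraction = n_with_reads / n_pop
    # mean depth over the population counts absent samples as zero depth
    n_rows = merged["n_rows"].fillna(0).to_numpy()
    mean_depth = mean_depth * n_rows / n_pop

    out = wdf.copy()
    out["n_variants"] = counts
    out["mean_depth"] = mean_depth
    out["covered_fraction"] = covered_fraction
    out["samples_with_reads_fraction"] = samples_with_reads_fraction
    return out


def call_desert_windows(
    stats: pd.DataFrame, thresholds: DesertThresholds
) -> RegionSet:
    """Flag windows passing the desert conjunction (all bounds inclusive)."""
    mask = (
        (stats["n_variants"] <= thresholds.max_variants)
        & (stats["mean_depth"] >= thresholds.min_mean_depth)
        & (stats["covered_fraction"] >= thresholds.min_window_covered_fraction)
        & (
            stats["samples_with_reads_fraction"]
            >= thresholds.min_samples_with_reads_fraction
        )
    )
    sub = stats.loc[mask]
    return RegionSet(
        GenomicRegion(c, int(s), int(e))
        for c, s, e in zip(sub["chrom"], sub["start"], sub["end"])
    )


@dataclass
class PrivateDesertResult:
    """Cultivated-vs-wild desert bookkeeping.

    ``cultivated_bp``/``wild_bp`` are union bp of flagged windows;
    ``shared_bp`` + ``private_bp`` = ``cultivated_bp`` (bp resolution,
    computed before gap-merging); ``private_merged`` applies the 1 kbp gap
    merge to the private remainder.
    """

    cultivated_bp: int
    wild_bp: int
    shared_bp: int
    private_bp: int
    private_raw: RegionSet
    private_merged: RegionSet


def private_deserts(
    cultivated_windows: RegionSet,
    wild_windows: RegionSet,
    max_gap: int = 1000,
) -> PrivateDesertResult:
    """Deserts private to the cultivated population, then gap-merged.

    Shared/private bp are computed on the window unions *before* merging;
    the ``max_gap`` merge applies only to the private remainder.
    """
    cult = region_union(cultivated_windows)
    wild = region_union(wild_windows)
    sub: SubtractResult = subtract_regions(cult, wild)
    return PrivateDesertResult(
        cultivated_bp=cult.total_bp,
        wild_bp=wild.total_bp,
        shared_bp=sub.shared_bp,
        private_bp=sub.private_bp,
        private_raw=sub.difference,
        private_merged=merge_regions(sub.difference, max_gap=max_gap),
    )


# re-exported interval algebra (part of this module's public surface)
__all__ = [
    "DesertThresholds",
    "BlocusSelection",
    "PrivateDesertResult",
    "make_windows",
    "select_blocus_accessions",
    "pop_maf_mask",
    "window_population_stats",
    "call_desert_windows",
    "merge_regions",
    "subtract_regions",
    "private_deserts",
]
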
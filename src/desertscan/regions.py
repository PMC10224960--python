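"""Half-open genomic intervals and exact base-pair interval algebra.

The scan stages reason about unions, gap-tolerant merges, differences and
intersections of window sets at single-base resolution, with inclusive
boundary semantics (a gap of exactly ``max_gap`` still merges). The
implementations are plain sorted-endpoint sweeps so those semantics are
explicit; tests check them against per-base boolean oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomicRegion:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty region {self.chrom}:{self.start}-{self.end} (start >= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class RegionSet:
    """A (chrom, start)-sorted collection of half-open regions.

    Not implicitly merged: overlapping regions are preserved unless an
    algebra operation is applied.
    """

    def __init__(self, regions: Iterable[GenomicRegion | tuple] = ()) -> None:
        items = [
            r if isinstance(r, GenomicRegion) else GenomicRegion(*r)
            for r in regions
        ]
        self.regions: list[GenomicRegion] = sorted(
            items, key=lambda r: (r.chrom, r.start, r.end)
        )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[GenomicRegion]:
        return iter(self.regions)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegionSet) and self.regions == other.regions

    def __repr__(self) -> str:
        return f"RegionSet({len(self.regions)} regions, {self.total_bp} bp)"

    @property
    def total_bp(self) -> int:
        return sum(r.length for r in self.regions)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.chrom, None)
        return list(seen)

    def on(self, chrom: str) -> list[GenomicRegion]:
        return [r for r in self.regions if r.chrom == chrom]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
            }
        )

    def is_disjoint(self) -> bool:
        for a, b in zip(self.regions, self.regions[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                return False
        return True


def merge_regions(regions: RegionSet, max_gap: int = 0) -> RegionSet:
    """Union overlapping/adjacent regions, then bridge gaps of up to ``max_gap`` bp.

    A single left-to-right sweep with the condition ``next.start - cur.end <=
    max_gap`` performs both steps at once (overlap gives a negative gap).
    Boundary is inclusive: a gap of exactly ``max_gap`` merges.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[GenomicRegion] = []
    for r in regions:
        if merged and merged[-1].chrom == r.chrom and r.start - merged[-1].end <= max_gap:
            last = merged[-1]
            if r.end > last.end:
                merged[-1] = GenomicRegion(last.chrom, last.start, r.end)
        else:
            merged.append(r)
    return RegionSet(merged)


def _chrom_boundaries(regions: list[GenomicRegion]) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint union of one chromosome's regions as (starts, ends) arrays."""
    starts, ends = [], []
    for r in sorted(regions, key=lambda r: r.start):
        if starts and r.start <= ends[-1]:
            ends[-1] = max(ends[-1], r.end)
        else:
            starts.append(r.start)
            ends.append(r.end)
    return np.asarray(starts), np.asarray(ends)


@dataclass
class SubtractResult:
    """Base-pair difference a \\ b plus the shared/private bp bookkeeping."""

    difference: RegionSet
    private_bp: int
    shared_bp: int
    total_bp: int  # |union(a)|


def subtract_regions(a: RegionSet, b: RegionSet) -> SubtractResult:
    """Exact bp-resolution set difference of the unions of ``a`` and ``b``.

    Also reports shared bp (|a ∩ b|) and private bp (|a| − shared), both on
    the union of ``a``, so ``private_bp + shared_bp == total_bp`` always.
    """
    out: list[GenomicRegion] = []
    shared = 0
    total = 0
    b_by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in b:
        b_by_chrom.setdefault(r.chrom, []).append(r)
    a_by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in a:
        a_by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, a_regions in a_by_chrom.items():
        a_starts, a_ends = _chrom_boundaries(a_regions)
        total += int((a_ends - a_starts).sum())
        if chrom in b_by_chrom:
            b_starts, b_ends = _chrom_boundaries(b_by_chrom[chrom])
        else:
            b_starts = b_ends = np.empty(0, dtype=int)
        for s, e in zip(a_starts, a_ends):
            cur = int(s)
            for bs, be in zip(b_starts, b_ends):
                if be <= cur:
                    continue
                if bs >= e:
                    break
                ov_start = max(cur, int(bs))
                ov_end = min(int(e), int(be))
                if ov_start < ov_end:
                    shared += ov_end - ov_start
                    if cur < ov_start:
                        out.append(GenomicRegion(chrom, cur, ov_start))
                    cur = ov_end
                if cur >= e:
                    break
            if cur < e:
                out.append(GenomicRegion(chrom, cur, int(e)))
    return SubtractResult(
        difference=RegionSet(out),
        private_bp=total - shared,
        shared_bp=shared,
        total_bp=total,
    )


def intersect_regions(a: RegionSet, b: RegionSet) -> tuple[RegionSet, int]:
    """bp-resolution intersection of the unions of ``a`` and ``b`` (symmetric)."""
    out: list[GenomicRegion] = []
    bp = 0
    b_by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in b:
        b_by_chrom.setdefault(r.chrom, []).append(r)
    a_by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in a:
        a_by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, a_regions in a_by_chrom.items():
        if chrom not in b_by_chrom:
            continue
        a_starts, a_ends = _chrom_boundaries(a_regions)
        b_starts, b_ends = _chrom_boundaries(b_by_chrom[chrom])
        i = j = 0
        while i < len(a_starts) and j < len(b_starts):
            s = max(int(a_starts[i]), int(b_starts[j]))
            e = min(int(a_ends[i]), int(b_ends[j]))
            if s < e:
                out.append(GenomicRegion(chrom, s, e))
                bp += e - s
            if a_ends[i] < b_ends[j]:
                i += 1
            else:
                j += 1
    return RegionSet(out), bp


def region_union(regions: RegionSet) -> RegionSet:
    """Disjoint union (merge with zero gap tolerance for touching regions)."""
    return merge_regions(regions, max_gap=0)


def coverage_mask(regions: RegionSet, chrom: str, length: int) -> np.ndarray:
    """Boolean per-base membership mask; intended for small oracles, not scans."""
    mask = np.zeros(length, dtype=bool)
    for r in regions.on(chrom):
        mask[max(0, r.start):min(length, r.end)] = True
    return mask
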
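"""Site-level quality filtering and the shared/private variation partition.

The filter set mirrors a GATK ``SelectVariants`` hard-filtering pass on a
joint multi-sample callset: biallelic sites with at most 10% missing
genotypes, minor allele frequency above 1%, total site depth between 2N and
10N reads (N = samples with a non-missing genotype at the site, bounds
inclusive) and strict annotation thresholds (MQ > 30, SOR < 3, QD > 2,
FS < 60, MQRankSum > −12.5, ReadPosRankSum > −8, BaseQRankSum > −12.5,
MLEAF > 0.01). A missing annotation skips its filter by default, matching
GATK's behaviour on absent annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MISSING, PopulationSpec, SiteTable

#: (operator, threshold) per annotation; strict comparisons as printed.
DEFAULT_ANNOTATION_THRESHOLDS: dict[str, tuple[str, float]] = {
    "MLEAF": (">", 0.01),
    "MQ": (">", 30.0),
    "SOR": ("<", 3.0),
    "QD": (">", 2.0),
    "FS": ("<", 60.0),
    "MQRankSum": (">", -12.5),
    "ReadPosRankSum": (">", -8.0),
    "BaseQRankSum": (">", -12.5),
}


@dataclass
class FilterParams:
    max_missing_fraction: float = 0.10
    min_maf: float = 0.01
    depth_low: float = 2.0   # multiples of N (covering samples), inclusive
    depth_high: float = 10.0
    biallelic_only: bool = True
    annotation_thresholds: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANNOTATION_THRESHOLDS)
    )
    skip_if_absent: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_fraction < 1:
            raise ValueError("max_missing_fraction must be in [0, 1)")
        if not 0 < self.min_maf < 0.5:
            raise ValueError("min_maf must be in (0, 0.5)")
        if self.depth_low >= self.depth_high:
            raise ValueError("depth_low must be < depth_high")


def site_missing_fraction(gm: GenotypeMatrix) -> np.ndarray:
    """Fraction of samples with a missing genotype, per site."""
    return (gm.codes == MISSING).mean(axis=1)


def minor_allele_frequency(gm: GenotypeMatrix) -> np.ndarray:
    """MAF per site over called alleles only; NaN when no genotype is called.

    All-hom-alt sites have MAF 0 (the reference allele is the minor allele,
    at frequency zero). Invariant under swapping ref/alt labels.
    """
    called = gm.codes != MISSING
    alt = np.where(called, gm.codes, 0).sum(axis=1).astype(float)
    denom = 2.0 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(denom > 0, alt / denom, np.nan)
    return np.minimum(af, 1.0 - af)


@dataclass
class FilterResult:
    mask: np.ndarray
    sites: SiteTable
    genotypes: GenotypeMatrix
    rejection_counts: dict[str, int]
    per_filter_pass: dict[str, np.ndarray]


def _filter_masks(
    sites: SiteTable, gm: GenotypeMatrix, params: FilterParams
) -> dict[str, np.ndarray]:
    df = sites.df
    n = sites.n_sites
    masks: dict[str, np.ndarray] = {}
    if params.biallelic_only:
        masks["biallelic"] = ~df["multiallelic"].to_numpy()
    masks["missing"] = site_missing_fraction(gm) <= params.max_missing_fraction
    maf = minor_allele_frequency(gm)
    masks["maf"] = np.where(np.isnan(maf), False, maf > params.min_maf)
    n_called = (gm.codes != MISSING).sum(axis=1)
    dp = df["DP"].to_numpy(dtype=float)
    depth_ok = (dp >= params.depth_low * n_called) & (dp <= params.depth_high * n_called)
    if params.skip_if_absent:
        masks["depth"] = np.where(np.isnan(dp), True, depth_ok)
    else:
        masks["depth"] = np.where(np.isnan(dp), False, depth_ok)
    for key, (op, thr) in params.annotation_thresholds.items():
        vals = df[key].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            ok = vals > thr if op == ">" else vals < thr
        absent = np.isnan(vals)
        masks[key] = np.where(absent, params.skip_if_absent, ok)
    for k, m in masks.items():
        masks[k] = np.asarray(m, dtype=bool)
        assert masks[k].shape == (n,)
    return masks


def apply_site_filters(
    sites: SiteTable, gm: GenotypeMatrix, params: Optional[FilterParams] = None
) -> FilterResult:
    """Apply all configured site filters as one conjunction.

    A site passes iff it passes every filter; the pass mask is therefore
    independent of filter application order. Rejection counts attribute each
    failing site to *every* filter it fails.
    """
    params = params or FilterParams()
    if sites.n_sites != gm.n_sites:
        raise ValueError("sites and genotypes disagree on site count")
    masks = _filter_masks(sites, gm, params)
    combined = np.ones(sites.n_sites, dtype=bool)
    for m in masks.values():
        combined &= m
    rejections = {name: int((~m).sum()) for name, m in masks.items()}
    return FilterResult(
        mask=combined,
        sites=sites.subset(combined),
        genotypes=gm.subset_sites(combined),
        rejection_counts=rejections,
        per_filter_pass=masks,
    )


@dataclass
class VennPartition:
    """Counts of variants present in exactly each non-empty group subset.

    ``counts`` maps a sorted tuple of group labels to per-class counts
    ({"SNV": n, "indel": n}). Presence of a variant in a group means at
    least one non-missing sample of that group carries an alt allele
    (or exceeds ``presence_min_freq`` when that mode is chosen).
    """

    groups: list[str]
    counts: dict[tuple[str, ...], dict[str, int]]

    @property
    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def total_by_class(self, variant_class: str) -> int:
        return sum(c.get(variant_class, 0) for c in self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subset": "&".join(subset),
                "n_groups": len(subset),
                "SNV": c.get("SNV", 0),
                "indel": c.get("indel", 0),
                "total": sum(c.values()),
            }
            for subset, c in sorted(self.counts.items(), key=lambda kv: (len(kv[0]), kv[0]))
        ]
        return pd.DataFrame(rows)


def partition_shared_variation(
    gm: GenotypeMatrix,
    sites: SiteTable,
    pops: PopulationSpec,
    groups: Sequence[str],
    presence_min_freq: Optional[float] = None,
) -> VennPartition:
    """Partition variants by the exact subset of groups they are present in.

    Counts are split by variant class (SNV vs indel, the latter pooling
    insertions and deletions). Variants absent from every group are not
    counted, so the subset cells sum to the number of variants present in
    at least one group.
    """
    pops.check_covers(gm)
    for g in groups:
        pops.samples_of(g)  # raises on unknown label
    presence = np.zeros((sites.n_sites, len(groups)), dtype=bool)
    for j, g in enumerate(groups):
        idx = gm.sample_indices(pops.samples_of(g))
        sub = gm.codes[:, idx]
        if presence_min_freq is None:
            presence[:, j] = (sub > 0).any(axis=1)
        else:
            called = sub != MISSING
            alt = np.where(called, sub, 0).sum(axis=1).astype(float)
            denom = 2.0 * called.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                freq = np.where(denom > 0, alt / denom, 0.0)
            presence[:, j] = freq > presence_min_freq
    vclass = np.where(
        sites.df["variant_class"].to_numpy() == "SNV", "SNV", "indel"
    )
    counts: dict[tuple[str, ...], dict[str, int]] = {}
    any_present = presence.any(axis=1)
    for i in np.nonzero(any_present)[0]:
        subset = tuple(g for j, g in enumerate(groups) if presence[i, j])
        cell = counts.setdefault(subset, {"SNV": 0, "indel": 0})
        cell[str(vclass[i])] += 1
    return VennPartition(groups=list(groups), counts=counts)
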
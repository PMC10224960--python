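"""Core in-memory containers shared by every pipeline stage.

All genomic coordinates are 0-based, half-open. Conversions to the 1-based
conventions of VCF and GFF3 happen only at the format boundary (:mod:`desertscan.io`).

Diploid genotypes are coded as small integers: ``0`` hom-ref, ``1`` het,
``2`` hom-alt, ``-1`` missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

#: INFO annotations carried through filtering (GATK naming).
ANNOTATION_KEYS: tuple[str, ...] = (
    "MQ", "DP", "QD", "FS", "SOR", "MQRankSum", "ReadPosRankSum",
    "BaseQRankSum", "MLEAF",
)

SITE_COLUMNS: tuple[str, ...] = (
    "chrom", "pos", "ref", "alt", "variant_class", "multiallelic",
)


def classify_variant(ref: str, alt: str) -> str:
    """Classify a ref/alt allele pair as ``SNV``, ``insertion`` or ``deletion``.

    The first ALT allele decides the class at multi-allelic records; those are
    flagged separately and removed by the biallelic filter downstream.
    """
    if len(ref) == len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(alt) < len(ref):
        return "deletion"
    # equal-length MNP: treat as SNV-like substitution block
    return "SNV"


@dataclass
class SiteTable:
    """Variant sites with alleles, class and (optional) GATK-style annotations.

    ``df`` has columns ``chrom, pos, ref, alt, variant_class, multiallelic``
    plus one float column per :data:`ANNOTATION_KEYS` entry (NaN = absent).
    ``alt`` holds comma-joined ALT alleles; ``pos`` is 0-based.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in SITE_COLUMNS:
            if col not in self.df.columns:
                raise ValueError(f"SiteTable missing column {col!r}")
        for key in ANNOTATION_KEYS:
            if key not in self.df.columns:
                self.df[key] = np.nan
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        if (df["pos"] < 0).any():
            raise ValueError("negative position in SiteTable")
        if (df["ref"].str.len() == 0).any():
            raise ValueError("empty REF allele")
        order = df.sort_values(["chrom", "pos"], kind="stable")
        if not (order.index.values == np.arange(len(df))).all():
            bad = df.index[(order.index.values != np.arange(len(df)))][0]
            raise ValueError(
                f"sites not sorted by (chrom, pos); first offender row {bad} "
                f"({df.loc[bad, 'chrom']}:{df.loc[bad, 'pos']})"
            )
        first_alt = df["alt"].str.split(",").str[0]
        expected = [
            classify_variant(r, a) for r, a in zip(df["ref"], first_alt)
        ]
        if not (df["variant_class"].values == np.asarray(expected)).all():
            raise ValueError("variant_class inconsistent with allele lengths")

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def subset(self, mask: np.ndarray) -> "SiteTable":
        return SiteTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()


@dataclass
class GenotypeMatrix:
    """Per-site diploid genotype codes for an ordered sample list.

    ``codes`` has shape (n_sites, n_samples), dtype int8, values in
    {HOM_REF, HET, HOM_ALT, MISSING}.
    """

    samples: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (sites x samples)")
        if self.codes.shape[1] != len(self.samples):
            raise ValueError("codes column count != number of samples")
        valid = np.isin(self.codes, (HOM_REF, HET, HOM_ALT, MISSING))
        if not valid.all():
            raise ValueError("genotype codes outside {0,1,2,-1}")

    @property
    def n_sites(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.codes[np.asarray(mask)])

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return np.asarray([index[n] for n in names], dtype=int)

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(list(names), self.codes[:, idx])


@dataclass
class PopulationSpec:
    """Assignment of every sample to exactly one group label."""

    mapping: dict[str, str]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples_of(self, group: str) -> list[str]:
        if group not in self.mapping.values():
            raise KeyError(f"unknown group label {group!r}")
        return [s for s, g in self.mapping.items() if g == group]

    def check_covers(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.samples if s not in self.mapping]
        if missing:
            raise ValueError(f"samples without group assignment: {missing[:5]}")


@dataclass
class GeneModel:
    """A gene span with the stranded CDS segments of one representative transcript.

    ``cds_segments`` are (start, end, phase) triples in genomic order,
    0-based half-open. ``usable_4dtv`` is False when the phase-adjusted CDS
    length is not a codon multiple, in which case the gene is excluded from
    fourfold-degenerate site calling.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_segments: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        segs = sorted(self.cds_segments)
        for (s0, e0, _), (s1, e1, _) in zip(segs, segs[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        for s, e, _ in segs:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"CDS segment [{s},{e}) outside gene span of {self.gene_id}"
                )
        self.cds_segments = segs

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds_segments)

    @property
    def first_phase(self) -> int:
        if not self.cds_segments:
            return 0
        segs = self.cds_segments if self.strand == "+" else self.cds_segments[::-1]
        return segs[0][2]

    @property
    def usable_4dtv(self) -> bool:
        if not self.cds_segments:
            return False
        return (self.cds_length - self.first_phase) % 3 == 0

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclass
class GeneSet:
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.start, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out


def alt_allele_counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Return (alt allele count, called allele count) per site.

    Missing genotypes contribute to neither numerator nor denominator.
    """
    codes = gm.codes
    called = codes != MISSING
    alt = np.where(called, codes, 0).sum(axis=1)
    return alt.astype(np.int64), 2 * called.sum(axis=1).astype(np.int64)
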
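"""Codon degeneracy, site context classification and distance thinning.

Variant sites are labelled ``exonic_4DTv``, ``exonic_other``, ``intron`` or
``intergenic``. A site is a 4DTv (fourfold-degenerate transversion-class)
site when it falls on the third position of a fourfold-degenerate codon of a
protein-coding gene, so that every substitution there is synonymous; such
sites are the pipeline's quasi-neutral variant class. "Intergenic" means
outside every annotated gene span, so UTRs and introns are not intergenic.

When gene spans overlap, exonic context takes precedence over intronic, and
among exonic candidates the gene whose representative transcript has the
longest CDS decides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, GeneSet, SiteTable

# Standard genetic code (DNA codons; '*' = stop).
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def codon_degeneracy(codon: str, position: int) -> int:
    """Degeneracy fold class (1..4) of ``position`` (1-based) in ``codon``.

    The fold class counts the distinct bases (including the incumbent one)
    that leave the encoded amino acid unchanged; 4 means fourfold degenerate.
    Stop codons are handled like any other translation product.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    if position not in (1, 2, 3):
        raise ValueError("codon position must be 1, 2 or 3")
    aa = GENETIC_CODE[codon]
    count = 0
    for b in _BASES:
        sub = codon[: position - 1] + b + codon[position:]
        if GENETIC_CODE[sub] == aa:
            count += 1
    return count


@dataclass
class _CodingMap:
    """Genomic-position -> coding-position lookup for one gene's transcript."""

    gene: GeneModel
    coding_seq: str
    genome_pos: np.ndarray  # genomic position of each coding base

    @classmethod
    def build(cls, gene: GeneModel, chrom_seq: str) -> "_CodingMap":
        segs = gene.cds_segments
        parts: list[str] = []
        positions: list[np.ndarray] = []
        for s, e, _ in segs:
            parts.append(chrom_seq[s:e])
            positions.append(np.arange(s, e))
        seq = "".join(parts)
        gpos = np.concatenate(positions) if positions else np.empty(0, dtype=int)
        if gene.strand == "-":
            seq = reverse_complement(seq)
            gpos = gpos[::-1]
        phase = gene.first_phase
        return cls(gene=gene, coding_seq=seq[phase:], genome_pos=gpos[phase:])

    def coding_index(self, pos: int) -> Optional[int]:
        hits = np.nonzero(self.genome_pos == pos)[0]
        return int(hits[0]) if hits.size else None


CONTEXT_LABELS = ("exonic_4DTv", "exonic_other", "intron", "intergenic")


def classify_sites(
    sites: SiteTable, genes: GeneSet, genome: dict[str, str]
) -> pd.DataFrame:
    """Assign a context label to every site.

    Returns a DataFrame aligned with ``sites`` carrying ``label``,
    ``gene_id``, ``codon`` and ``codon_position`` (codon fields only for
    exonic sites; codons are read on the coding strand). Indels inside a CDS
    are ``exonic_other`` — only SNVs can be 4DTv. Genes whose CDS length is
    not a codon multiple are unusable for degeneracy calls; their exonic
    sites also become ``exonic_other``.
    """
    span_trees: dict[str, IntervalTree] = {}
    for g in genes:
        span_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    cds_maps: dict[str, _CodingMap] = {}

    def coding_map(gene: GeneModel) -> _CodingMap:
        if gene.gene_id not in cds_maps:
            cds_maps[gene.gene_id] = _CodingMap.build(gene, genome[gene.chrom])
        return cds_maps[gene.gene_id]

    labels: list[str] = []
    gene_ids: list[Optional[str]] = []
    codons: list[Optional[str]] = []
    codon_positions: list[float] = []
    df = sites.df
    for chrom, pos, vclass, ref, alt in zip(
        df["chrom"], df["pos"], df["variant_class"], df["ref"], df["alt"]
    ):
        tree = span_trees.get(chrom)
        overlapping = sorted(
            (iv.data for iv in tree[pos]) if tree is not None else (),
            key=lambda g: (-g.cds_length, g.gene_id),
        )
        label, gene_id, codon, cpos = "intergenic", None, None, np.nan
        exonic_gene: Optional[GeneModel] = None
        intron_gene: Optional[GeneModel] = None
        for g in overlapping:
            in_cds = any(s <= pos < e for s, e, _ in g.cds_segments)
            if in_cds and exonic_gene is None:
                exonic_gene = g  # longest-CDS exonic gene wins (sorted above)
            elif not in_cds and intron_gene is None:
                intron_gene = g
        if exonic_gene is not None:
            gene_id = exonic_gene.gene_id
            cmap = coding_map(exonic_gene)
            ci = cmap.coding_index(int(pos))
            if ci is None or vclass != "SNV" or not exonic_gene.usable_4dtv:
                label = "exonic_other"
            else:
                codon_idx, within = divmod(ci, 3)
                codon = cmap.coding_seq[3 * codon_idx: 3 * codon_idx + 3]
                cpos = within + 1
                if len(codon) == 3:
                    fold = codon_degeneracy(codon, int(cpos))
                    alt_base = alt.split(",")[0]
                    if exonic_gene.strand == "-":
                        alt_base = alt_base.translate(_COMPLEMENT)
                    sub = codon[:within] + alt_base + codon[within + 1:]
                    synonymous = GENETIC_CODE.get(sub) == GENETIC_CODE[codon]
                    label = (
                        "exonic_4DTv"
                        if cpos == 3 and fold == 4 and synonymous
                        else "exonic_other"
                    )
                else:
                    label = "exonic_other"
        elif intron_gene is not None:
            label, gene_id = "intron", intron_gene.gene_id
        labels.append(label)
        gene_ids.append(gene_id)
        codons.append(codon)
        codon_positions.append(cpos)
    return pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "label": labels,
            "gene_id": gene_ids,
            "codon": codons,
            "codon_position": codon_positions,
        }
    )


def thin_by_distance(positions: Iterable[int], min_dist: int = 1000) -> np.ndarray:
    """Greedy left-to-right thinning of sorted positions on one chromosome.

    The first position is always kept; each later position is kept iff it is
    at least ``min_dist`` bp from the last kept one (a gap of exactly
    ``min_dist`` is allowed). Raises on unsorted input.
    """
    pos = np.asarray(list(positions), dtype=np.int64)
    if pos.size == 0:
        return pos
    if (np.diff(pos) < 0).any():
        raise ValueError("positions must be sorted")
    kept = [int(pos[0])]
    for p in pos[1:]:
        if p - kept[-1] >= min_dist:
            kept.append(int(p))
    return np.asarray(kept, dtype=np.int64)


def thin_sites(
    context: pd.DataFrame, label: str, min_dist: int = 1000
) -> pd.DataFrame:
    """Thin one context class of a classification table, per chromosome."""
    keep_rows: list[pd.DataFrame] = []
    sub = context[context["label"] == label]
    for chrom, grp in sub.groupby("chrom", sort=True):
        kept = thin_by_distance(grp["pos"].to_numpy(), min_dist)
        keep_rows.append(grp[grp["pos"].isin(kept)])
    if not keep_rows:
        return sub.iloc[:0]
    return pd.concat(keep_rows, axis=0).reset_index(drop=True)
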
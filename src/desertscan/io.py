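"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions at the boundary:

* VCF POS and GFF3 start/end are 1-based (GFF3 end-inclusive); both are
  converted to the internal 0-based half-open convention on read and back
  on write.
* BED is already 0-based half-open; no shift.

All outputs are UTF-8, tab-separated text.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .core import (
    ANNOTATION_KEYS,
    GeneModel,
    GeneSet,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    PopulationSpec,
    SiteTable,
    classify_variant,
)
from .regions import GenomicRegion, RegionSet

# cyvcf2 gt_types coding -> internal genotype codes
_CYVCF2_CODE = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}


def read_vcf(
    path: str | Path, sample_subset: Optional[Sequence[str]] = None
) -> tuple[SiteTable, GenotypeMatrix]:
    """Read a VCF v4.2 with GT fields into a (SiteTable, GenotypeMatrix) pair.

    POS is shifted to 0-based. Multi-allelic records are retained but flagged
    (the biallelic site filter removes them downstream). INFO annotations
    named in :data:`~desertscan.core.ANNOTATION_KEYS` are parsed when present.

    Raises ``ValueError`` for VCFs without a GT FORMAT field and for unsorted
    input (naming the first offending record).
    """
    path = str(path)
    vcf = VCF(path, gts012=False)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise ValueError(f"{path}: no GT FORMAT field in VCF header")
    samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in samples]
        if missing:
            raise ValueError(f"{path}: samples not in VCF: {missing[:5]}")
    chroms: list[str] = []
    pos: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    multi: list[bool] = []
    annot: dict[str, list[float]] = {k: [] for k in ANNOTATION_KEYS}
    codes_rows: list[np.ndarray] = []
    seen_chroms: set[str] = set()
    last_chrom: Optional[str] = None
    last_pos = -1
    for v in vcf:
        if v.CHROM != last_chrom:
            if v.CHROM in seen_chroms:
                raise ValueError(
                    f"{path}: unsorted VCF, chromosome {v.CHROM} re-appears at "
                    f"{v.CHROM}:{v.POS}"
                )
            seen_chroms.add(v.CHROM)
            last_chrom = v.CHROM
            last_pos = -1
        if v.POS - 1 < last_pos:
            raise ValueError(
                f"{path}: unsorted VCF, first offending record {v.CHROM}:{v.POS}"
            )
        last_pos = v.POS - 1
        alt_alleles = list(v.ALT)
        if not alt_alleles:
            continue  # monomorphic reference block: nothing to analyse
        chroms.append(v.CHROM)
        pos.append(v.POS - 1)
        refs.append(v.REF.upper())
        alts.append(",".join(a.upper() for a in alt_alleles))
        multi.append(len(alt_alleles) > 1)
        for key in ANNOTATION_KEYS:
            val = v.INFO.get(key)
            annot[key].append(float(val) if val is not None else math.nan)
        gt = np.asarray(v.gt_types)
        if len(alt_alleles) == 1:
            # allele index >1 at a biallelic-coded site is malformed input
            g = np.asarray(v.genotypes, dtype=object)
            alleles = np.array([row[:-1] for row in g], dtype=int)
            if (alleles > 1).any():
                bad = samples[int(np.argmax((alleles > 1).any(axis=1)))]
                raise ValueError(
                    f"{path}: allele index >1 at biallelic site "
                    f"{v.CHROM}:{v.POS} (sample {bad})"
                )
        codes_rows.append(
            np.fromiter((_CYVCF2_CODE[int(t)] for t in gt), dtype=np.int8, count=len(gt))
        )
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": refs,
            "alt": alts,
            "variant_class": [
                classify_variant(r, a.split(",")[0]) for r, a in zip(refs, alts)
            ],
            "multiallelic": np.asarray(multi, dtype=bool),
        }
    )
    for key in ANNOTATION_KEYS:
        df[key] = np.asarray(annot[key], dtype=float)
    codes = (
        np.vstack(codes_rows)
        if codes_rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    gm = GenotypeMatrix(samples, codes)
    if sample_subset is not None:
        gm = gm.subset_samples(list(sample_subset))
    return SiteTable(df), gm


_GT_STRING = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(
    sites: SiteTable,
    gm: GenotypeMatrix,
    path: str | Path,
    extra_header_lines: Sequence[str] = (),
) -> None:
    """Write a VCF v4.2 (plain text, POS 1-based) from internal containers."""
    if sites.n_sites != gm.n_sites:
        raise ValueError(
            f"inconsistent dimensions: {sites.n_sites} sites vs "
            f"{gm.n_sites} genotype rows"
        )
    df = sites.df
    lines: list[str] = ["##fileformat=VCFv4.2"]
    lines.extend(extra_header_lines)
    for chrom in dict.fromkeys(df["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    for key in ANNOTATION_KEYS:
        vtype = "Integer" if key == "DP" else "Float"
        lines.append(
            f'##INFO=<ID={key},Number=1,Type={vtype},Description="{key}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(gm.samples)
    lines.append("\t".join(header))
    ann = {k: df[k].to_numpy() for k in ANNOTATION_KEYS}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        for i in range(sites.n_sites):
            info_items = [
                (f"{k}={int(ann[k][i])}" if k == "DP" else f"{k}={ann[k][i]:.6g}")
                for k in ANNOTATION_KEYS
                if not math.isnan(ann[k][i])
            ]
            row = [
                str(df["chrom"].iat[i]),
                str(int(df["pos"].iat[i]) + 1),
                ".",
                df["ref"].iat[i],
                df["alt"].iat[i],
                ".",
                ".",
                ";".join(info_items) if info_items else ".",
                "GT",
            ]
            row.extend(_GT_STRING[int(c)] for c in gm.codes[i])
            fh.write("\t".join(row) + "\n")


def read_gff(path: str | Path) -> GeneSet:
    """Read GFF3 gene models, keeping one transcript per gene.

    When a gene has several transcripts the one with the longest total CDS
    represents the gene. Coordinates become 0-based half-open. CDS features
    outside their gene span raise ``ValueError``.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype="mRNA"))
        candidates: list[list[tuple[int, int, int]]] = []
        if transcripts:
            for tr in transcripts:
                segs = [
                    (c.start - 1, c.end, int(c.frame) if c.frame != "." else 0)
                    for c in db.children(tr, featuretype="CDS")
                ]
                if segs:
                    candidates.append(sorted(segs))
        else:
            segs = [
                (c.start - 1, c.end, int(c.frame) if c.frame != "." else 0)
                for c in db.children(gene, featuretype="CDS")
            ]
            if segs:
                candidates.append(sorted(segs))
        if not candidates:
            continue
        best = max(candidates, key=lambda segs: sum(e - s for s, e, _ in segs))
        gstart, gend = gene.start - 1, gene.end
        for s, e, _ in best:
            if s < gstart or e > gend:
                raise ValueError(
                    f"CDS [{s},{e}) outside span of gene {gene.id} "
                    f"[{gstart},{gend})"
                )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gstart,
                end=gend,
                strand=gene.strand if gene.strand in "+-" else "+",
                cds_segments=best,
            )
        )
    return GeneSet(genes)


def write_gff(genes: GeneSet, path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/CDS, 1-based inclusive)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tdesertscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tdesertscan\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for j, (s, e, phase) in enumerate(g.cds_segments):
                fh.write(
                    f"{g.chrom}\tdesertscan\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t"
                    f"{phase}\tID={tid}.cds{j};Parent={tid}\n"
                )


def read_bed(path: str | Path) -> RegionSet:
    """Read BED3(+) regions; no coordinate shift, no implicit merging."""
    regions: list[GenomicRegion] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({chrom}:{start}-{end})"
                )
            regions.append(GenomicRegion(chrom, start, end))
    return RegionSet(regions)


def write_bed(regions: RegionSet, path: str | Path, names: Sequence[str] = ()) -> None:
    """Write regions as sorted BED3 (BED4 when ``names`` given)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, r in enumerate(regions):
            row = [r.chrom, str(r.start), str(r.end)]
            if names:
                row.append(names[i])
            fh.write("\t".join(row) + "\n")


def read_sample_map(path: str | Path) -> PopulationSpec:
    """Read a TSV with columns ``sample`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample map needs a {col!r} column")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"{path}: sample {dup!r} assigned more than once")
    return PopulationSpec(dict(zip(df["sample"], df["group"])))


def write_sample_map(pops: PopulationSpec, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(pops.mapping), "group": list(pops.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


COVERAGE_COLUMNS = ("chrom", "start", "end", "sample", "mean_depth", "covered_bases")


def read_coverage(path: str | Path) -> pd.DataFrame:
    """Read the per-sample per-window coverage table."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: coverage table missing columns {missing}")
    return df


def write_coverage(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index=False, columns=list(COVERAGE_COLUMNS))


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
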
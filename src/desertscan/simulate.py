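"""Synthetic two-population diploid cohort generator with ground truth.

The generator emulates the statistical structure of a resequenced beet-like
cohort: a cultivated population and a wild (sea-beet-like) population that
diverged by drift from a common ancestor, genotyped at biallelic sites
relative to a reference genome at roughly sixfold coverage. It provides:

* ancestral allele frequencies from a symmetric neutral-like Beta(0.5, 0.5)
  spectrum; per-group frequencies from the Balding–Nichols model (Beta
  around the ancestral frequency with variance ``F p (1-p)``), genotypes in
  Hardy–Weinberg proportions within each group;
* planted sweeps: regions where the cultivated population lost diversity —
  each site is fixed with probability ``1 - residual_diversity_fraction``
  and surviving sites optionally have their frequency pushed to within the
  residual fraction of fixation (the hitchhiking caricature the XP-CLR
  stage is meant to detect);
* a B-locus analogue: a 10,338 bp region (the *BvBTC1* bolting-gene span)
  where per-accession variant counts are bimodal — crop-type accessions
  carry 0–5 variants, the rest 16–47;
* per-sample per-window coverage (depth ~ Poisson(mean depth), covered
  bases binomial with the Poisson per-base covered probability), GATK-style
  site annotations with a configurable fraction of deliberate failures per
  filter, gene models with stranded CDS for fourfold-degeneracy tests, and
  uniform random missing genotypes.

Everything is drawn from one seeded generator; the same seed reproduces the
fixture byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    ANNOTATION_KEYS,
    GeneModel,
    GeneSet,
    GenotypeMatrix,
    PopulationSpec,
    SiteTable,
)
from .deserts import make_windows
from .io import (
    write_bed,
    write_coverage,
    write_fasta,
    write_gff,
    write_sample_map,
    write_vcf,
)
from .regions import GenomicRegion, RegionSet

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SweepSpec:
    chrom: str
    center: int
    half_width: int
    residual_diversity_fraction: float = 0.05
    population: str = "cultivated"

    @property
    def region(self) -> GenomicRegion:
        return GenomicRegion(
            self.chrom, self.center - self.half_width, self.center + self.half_width
        )


def _default_sweeps() -> list[SweepSpec]:
    return [
        SweepSpec("chr1", 250_000, 10_000),
        SweepSpec("chr1", 700_000, 15_000),
        SweepSpec("chr2", 150_000, 6_000),
    ]


@dataclass
class SimParams:
    """Study conditions for the synthetic cohort.

    Defaults mirror the scale of the source study where it states them:
    206 cultivated + 54 wild accessions in the scan populations, ~0.018
    segregating sites per bp after filtering, roughly sixfold coverage, a
    10,338 bp B-locus with 0–5 vs 16–47 variant modes. The genome is two
    1 Mbp chromosomes — large enough for thousands of scan windows while
    keeping a simulation cheap.
    """

    n_samples: dict[str, int] = field(
        default_factory=lambda: {"cultivated": 206, "wild": 54}
    )
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    site_density: float = 0.0182  # segregating sites per bp
    fst: float = 0.1  # Balding-Nichols divergence parameter F
    ancestral_beta: float = 0.5
    sweeps: list[SweepSpec] = field(default_factory=_default_sweeps)
    push_to_fixation: bool = True
    mean_depth: float = 6.0
    missing_rate: float = 0.05
    gene_density: float = 5e-5  # genes per bp (~1 per 20 kbp)
    mean_cds_length: int = 900
    blocus_region: tuple[str, int, int] = ("chr2", 600_000, 610_338)
    blocus_n_sites: int = 60
    blocus_low_range: tuple[int, int] = (0, 5)
    blocus_high_range: tuple[int, int] = (16, 47)
    blocus_low_fraction: dict[str, float] = field(
        default_factory=lambda: {"cultivated": 0.85, "wild": 0.0}
    )
    annotation_fail_fraction: float = 0.02
    window_size: int = 2000
    window_step: int = 1000
    seed: Optional[int] = None  # mandatory; simulate_cohort refuses None

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("F must be in (0, 1)")
        for sw in self.sweeps:
            if not 0 <= sw.residual_diversity_fraction <= 1:
                raise ValueError("residual_diversity_fraction must be in [0, 1]")
            length = self.chrom_lengths.get(sw.chrom)
            if length is None or sw.center - sw.half_width < 0 or sw.center + sw.half_width > length:
                raise ValueError(
                    f"sweep at {sw.chrom}:{sw.center} outside chromosome bounds"
                )
        for g, n in self.n_samples.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 samples")
        if self.blocus_n_sites < self.blocus_high_range[1]:
            raise ValueError(
                "blocus_n_sites must cover the high variant-count mode"
            )


@dataclass
class SweepTruth:
    """Ground truth of the simulation, for recovery-based checks.

    ``regions`` maps population label -> planted sweep RegionSet;
    ``blocus_modes`` maps sample -> "low"/"high". The frequency arrays are
    kept so closed-form drift moments can be checked against the draws.
    """

    regions: dict[str, RegionSet]
    blocus_modes: dict[str, str]
    ancestral_freq: np.ndarray
    group_freqs: dict[str, np.ndarray]
    blocus_site_mask: np.ndarray


@dataclass
class SimResult:
    params: SimParams
    sites: SiteTable
    genotypes: GenotypeMatrix
    coverage: pd.DataFrame
    genes: GeneSet
    populations: PopulationSpec
    truth: SweepTruth
    reference: dict[str, str]


def _simulate_genes(params: SimParams, rng: np.random.Generator) -> GeneSet:
    genes: list[GeneModel] = []
    gid = 0
    for chrom in sorted(params.chrom_lengths):
        length = params.chrom_lengths[chrom]
        pos = int(rng.exponential(1.0 / params.gene_density)) + 200
        while pos < length - 6000:
            n_exons = int(rng.integers(1, 5))
            exon_lens = rng.integers(60, max(90, 2 * params.mean_cds_length // max(1, n_exons)), n_exons)
            total = int(exon_lens.sum())
            exon_lens[-1] += (3 - total % 3) % 3  # keep CDS a codon multiple
            intron_lens = rng.integers(60, 500, max(0, n_exons - 1))
            segs: list[tuple[int, int, int]] = []
            cursor = pos
            for i, el in enumerate(exon_lens):
                segs.append((cursor, cursor + int(el), 0))
                cursor += int(el)
                if i < n_exons - 1:
                    cursor += int(intron_lens[i])
            if cursor >= length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            # GFF3 phase per segment, in translation order
            order = segs if strand == "+" else segs[::-1]
            phased = []
            consumed = 0
            for s, e, _ in order:
                phased.append((s, e, (3 - consumed % 3) % 3))
                consumed += e - s
            segs = sorted(phased)
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:05d}",
                    chrom=chrom,
                    start=pos,
                    end=cursor,
                    strand=strand,
                    cds_segments=segs,
                )
            )
            gid += 1
            pos = cursor + int(rng.exponential(1.0 / params.gene_density)) + 200
    return GeneSet(genes)


def simulate_cohort(params: SimParams) -> SimResult:
    """Draw a full synthetic cohort with ground truth (deterministic per seed)."""
    if params.seed is None:
        raise ValueError("SimParams.seed is mandatory")
    rng = np.random.default_rng(params.seed)

    # reference genome
    reference = {
        chrom: "".join(
            _BASES[rng.integers(0, 4, params.chrom_lengths[chrom])]
        )
        for chrom in sorted(params.chrom_lengths)
    }

    genes = _simulate_genes(params, rng)

    # samples and populations
    groups = sorted(params.n_samples)
    sample_names: list[str] = []
    mapping: dict[str, str] = {}
    for g in groups:
        for i in range(params.n_samples[g]):
            name = f"{g}_{i:03d}"
            sample_names.append(name)
            mapping[name] = g
    pops = PopulationSpec(mapping)

    # segregating-site positions (background, excluding the B-locus region)
    b_chrom, b_start, b_end = params.blocus_region
    chrom_col: list[str] = []
    pos_list: list[np.ndarray] = []
    for chrom in sorted(params.chrom_lengths):
        length = params.chrom_lengths[chrom]
        n = rng.poisson(params.site_density * length)
        pos = np.sort(rng.choice(length, size=min(n, length), replace=False))
        if chrom == b_chrom:
            pos = pos[(pos < b_start) | (pos >= b_end)]
        pos_list.append(pos)
        chrom_col.extend([chrom] * pos.size)
    positions = np.concatenate(pos_list)
    chroms = np.asarray(chrom_col)
    n_sites = positions.size

    # ancestral and group frequencies (Balding-Nichols drift)
    p_anc = rng.beta(params.ancestral_beta, params.ancestral_beta, n_sites)
    p_anc = np.clip(p_anc, 1e-3, 1 - 1e-3)
    F = params.fst
    shape_scale = (1.0 - F) / F
    group_freqs: dict[str, np.ndarray] = {}
    for g in groups:
        group_freqs[g] = rng.beta(p_anc * shape_scale, (1.0 - p_anc) * shape_scale)

    # planted sweeps: thin diversity (fix sites) and push survivors
    truth_regions: dict[str, RegionSet] = {
        g: RegionSet(
            sw.region for sw in params.sweeps if sw.population == g
        )
        for g in groups
    }
    for sw in params.sweeps:
        q = group_freqs[sw.population]
        in_sweep = (
            (chroms == sw.chrom)
            & (positions >= sw.center - sw.half_width)
            & (positions < sw.center + sw.half_width)
        )
        res = sw.residual_diversity_fraction
        fixed = in_sweep & (rng.random(n_sites) >= res)
        q[fixed] = np.round(q[fixed])
        if params.push_to_fixation:
            survivors = in_sweep & ~fixed
            qs = q[survivors]
            q[survivors] = np.where(qs < 0.5, qs * res, 1.0 - (1.0 - qs) * res)
        group_freqs[sw.population] = q

    # genotypes: Hardy-Weinberg within group
    codes = np.empty((n_sites, len(sample_names)), dtype=np.int8)
    col = 0
    for g in groups:
        n_g = params.n_samples[g]
        q = group_freqs[g]
        codes[:, col: col + n_g] = rng.binomial(
            2, np.repeat(q[:, None], n_g, axis=1)
        ).astype(np.int8)
        col += n_g

    # B-locus analogue: bimodal per-accession variant counts
    n_b = params.blocus_n_sites
    b_pos = np.sort(
        rng.choice(np.arange(b_start, b_end), size=n_b, replace=False)
    )
    b_codes = np.zeros((n_b, len(sample_names)), dtype=np.int8)
    blocus_modes: dict[str, str] = {}
    lo0, lo1 = params.blocus_low_range
    hi0, hi1 = params.blocus_high_range
    for j, s in enumerate(sample_names):
        low_frac = params.blocus_low_fraction.get(mapping[s], 0.0)
        mode = "low" if rng.random() < low_frac else "high"
        blocus_modes[s] = mode
        k = int(rng.integers(lo0, lo1 + 1) if mode == "low" else rng.integers(hi0, hi1 + 1))
        carried = rng.choice(n_b, size=k, replace=False)
        b_codes[carried, j] = 1  # heterozygous carrier

    # splice the B-locus sites into the genome-wide tables
    insert_at = np.searchsorted(
        positions[chroms == b_chrom], b_pos
    ) + int((chroms < b_chrom).sum())
    positions = np.insert(positions, insert_at, b_pos)
    chroms = np.insert(chroms, insert_at, b_chrom)
    codes = np.insert(codes, insert_at, b_codes, axis=0)
    blocus_mask = np.zeros(positions.size, dtype=bool)
    blocus_mask[insert_at + np.arange(n_b)] = True
    p_anc = np.insert(p_anc, insert_at, np.nan)
    for g in groups:
        group_freqs[g] = np.insert(group_freqs[g], insert_at, np.nan)
    n_sites = positions.size

    # random missing genotypes
    miss = rng.random(codes.shape) < params.missing_rate
    codes[miss] = -1

    # alleles from the reference sequence
    ref_alleles = np.empty(n_sites, dtype="<U1")
    alt_alleles = np.empty(n_sites, dtype="<U1")
    offset = 0
    for chrom in sorted(params.chrom_lengths):
        sel = chroms == chrom
        seq = reference[chrom]
        refs = np.array([seq[p] for p in positions[sel]])
        shifts = rng.integers(1, 4, sel.sum())
        base_idx = np.searchsorted(_BASES, refs)
        alts = _BASES[(base_idx + shifts) % 4]
        ref_alleles[sel] = refs
        alt_alleles[sel] = alts
        offset += sel.sum()

    # annotations: mostly passing values, a controlled fraction failing
    n_called = (codes != -1).sum(axis=1)
    called_alleles = 2.0 * n_called
    alt_count = np.where(codes > 0, codes, 0).sum(axis=1)

    def with_failures(pass_vals: np.ndarray, fail_vals: np.ndarray) -> np.ndarray:
        fail = rng.random(n_sites) < params.annotation_fail_fraction
        return np.where(fail, fail_vals, pass_vals)

    annotations = {
        "MQ": with_failures(rng.uniform(35, 60, n_sites), rng.uniform(5, 29, n_sites)),
        "SOR": with_failures(rng.uniform(0.3, 2.5, n_sites), rng.uniform(3.2, 9, n_sites)),
        "QD": with_failures(rng.uniform(5, 35, n_sites), rng.uniform(0, 1.9, n_sites)),
        "FS": with_failures(rng.uniform(0, 20, n_sites), rng.uniform(61, 200, n_sites)),
        "MQRankSum": with_failures(rng.normal(0, 2, n_sites), rng.uniform(-20, -12.6, n_sites)),
        "ReadPosRankSum": with_failures(rng.normal(0, 2, n_sites), rng.uniform(-20, -8.1, n_sites)),
        "BaseQRankSum": with_failures(rng.normal(0, 2, n_sites), rng.uniform(-20, -12.6, n_sites)),
        "MLEAF": with_failures(
            np.clip(alt_count / np.maximum(called_alleles, 1), 0.011, 1.0),
            rng.uniform(0.0, 0.009, n_sites),
        ),
        "DP": with_failures(
            np.round(params.mean_depth * n_called).astype(float),
            np.round(rng.uniform(0, 1.9, n_sites) * n_called),
        ),
    }

    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions.astype(np.int64),
            "ref": ref_alleles,
            "alt": alt_alleles,
            "variant_class": "SNV",
            "multiallelic": False,
        }
    )
    for key in ANNOTATION_KEYS:
        df[key] = annotations[key]
    sites = SiteTable(df)
    gm = GenotypeMatrix(sample_names, codes)

    # per-sample per-window coverage
    windows = make_windows(
        params.chrom_lengths, params.window_size, params.window_step
    )
    wdf = windows.to_frame()
    n_w = len(wdf)
    n_s = len(sample_names)
    depth = rng.poisson(params.mean_depth, size=(n_w, n_s))
    covered = rng.binomial(params.window_size, 1.0 - np.exp(-depth))
    coverage = pd.DataFrame(
        {
            "chrom": np.repeat(wdf["chrom"].to_numpy(), n_s),
            "start": np.repeat(wdf["start"].to_numpy(), n_s),
            "end": np.repeat(wdf["end"].to_numpy(), n_s),
            "sample": np.tile(np.asarray(sample_names), n_w),
            "mean_depth": depth.reshape(-1).astype(float),
            "covered_bases": covered.reshape(-1),
        }
    )

    truth = SweepTruth(
        regions=truth_regions,
        blocus_modes=blocus_modes,
        ancestral_freq=p_anc,
        group_freqs=group_freqs,
        blocus_site_mask=blocus_mask,
    )
    return SimResult(
        params=params,
        sites=sites,
        genotypes=gm,
        coverage=coverage,
        genes=genes,
        populations=pops,
        truth=truth,
        reference=reference,
    )


FIXTURE_FILES = (
    "cohort.vcf",
    "truth_sweeps.bed",
    "genes.gff3",
    "samples.tsv",
    "coverage.tsv",
    "reference.fa",
)


def emit_fixture(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as plain-text files readable by :mod:`desertscan.io`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / name for name in FIXTURE_FILES}
    write_vcf(
        result.sites,
        result.genotypes,
        paths["cohort.vcf"],
        extra_header_lines=[f"##desertscan_simulation_seed={result.params.seed}"],
    )
    truth_regions: list[GenomicRegion] = []
    names: list[str] = []
    for pop, rs in sorted(result.truth.regions.items()):
        for r in rs:
            truth_regions.append(r)
            names.append(pop)
    order = np.argsort([(r.chrom, r.start) for r in truth_regions], axis=0)
    rs = RegionSet(truth_regions)
    name_by_region = {
        (r.chrom, r.start, r.end): n for r, n in zip(truth_regions, names)
    }
    write_bed(
        rs,
        paths["truth_sweeps.bed"],
        names=[name_by_region[(r.chrom, r.start, r.end)] for r in rs],
    )
    write_gff(result.genes, paths["genes.gff3"])
    write_sample_map(result.populations, paths["samples.tsv"])
    write_coverage(result.coverage, paths["coverage.tsv"])
    write_fasta(result.reference, paths["reference.fa"])
    return paths
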
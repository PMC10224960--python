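"""End-to-end orchestration: simulate -> filter -> context -> desert ->
xpclr -> report, with one config, per-stage logging and a checksum manifest.

A run is reproducible: the same config and seed give byte-identical outputs
and therefore an identical manifest. Stage failures abort the run with the
failing stage named; outputs of the failed stage keep a ``.partial`` suffix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .context import classify_sites, thin_sites
from .core import PopulationSpec
from .deserts import (
    DesertThresholds,
    call_desert_windows,
    make_windows,
    pop_maf_mask,
    private_deserts,
    select_blocus_accessions,
    window_population_stats,
)
from .filters import FilterParams, apply_site_filters, partition_shared_variation
from .io import (
    read_coverage,
    read_fasta,
    read_gff,
    read_sample_map,
    read_vcf,
    write_bed,
    write_vcf,
)
from .regions import GenomicRegion
from .report import gene_desert_classes, region_summary
from .simulate import SimParams, emit_fixture, simulate_cohort
from .xpclr import XpclrParams, normalize_and_top, overlap_regions, xpclr_scan

log = logging.getLogger("desertscan")

ALL_STAGES = ("simulate", "filter", "context", "desert", "xpclr", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str
    seed: Optional[int] = None
    stages: tuple[str, ...] = ALL_STAGES
    # inputs (ignored for stages fed by an earlier stage in the same run)
    vcf: Optional[str] = None
    gff: Optional[str] = None
    fasta: Optional[str] = None
    coverage: Optional[str] = None
    samples: Optional[str] = None
    sim: Optional[SimParams] = None
    filter_params: FilterParams = field(default_factory=FilterParams)
    cultivated_group: str = "cultivated"
    wild_group: str = "wild"
    cultivated_thresholds: DesertThresholds = field(
        default_factory=DesertThresholds.cultivated
    )
    wild_thresholds: DesertThresholds = field(default_factory=DesertThresholds.wild)
    blocus: Optional[tuple[str, int, int]] = None
    blocus_max_variants: int = 5
    desert_min_maf: float = 0.05
    desert_merge_gap: int = 1000
    xpclr_params: XpclrParams = field(default_factory=XpclrParams)
    thin_min_dist: int = 1000

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        stochastic = "simulate" in self.stages
        if stochastic and self.seed is None:
            raise ValueError("seed required when the simulate stage is enabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if kwargs.get("sim") is not None:
            sim = dict(kwargs["sim"])
            if "sweeps" in sim:
                from .simulate import SweepSpec

                sim["sweeps"] = [SweepSpec(**s) for s in sim["sweeps"]]
            kwargs["sim"] = SimParams(**sim)
        if kwargs.get("filter_params") is not None and not isinstance(
            kwargs.get("filter_params"), FilterParams
        ):
            kwargs["filter_params"] = FilterParams(**kwargs["filter_params"])
        for key, cls_ in (
            ("cultivated_thresholds", DesertThresholds),
            ("wild_thresholds", DesertThresholds),
        ):
            if kwargs.get(key) is not None and not isinstance(kwargs.get(key), cls_):
                kwargs[key] = cls_(**kwargs[key])
        if kwargs.get("xpclr_params") is not None and not isinstance(
            kwargs.get("xpclr_params"), XpclrParams
        ):
            kwargs["xpclr_params"] = XpclrParams(**kwargs["xpclr_params"])
        if kwargs.get("blocus") is not None:
            kwargs["blocus"] = tuple(kwargs["blocus"])
        return cls(**kwargs)

    def resolved_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (list, tuple)):
                return [enc(x) for x in obj]
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            return obj

        return enc(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    state: dict = {}
    t0 = time.time()

    def record(name: str, path: Path) -> Path:
        outputs[name] = path
        return path

    stage_fns = {
        "simulate": _stage_simulate,
        "filter": _stage_filter,
        "context": _stage_context,
        "desert": _stage_desert,
        "xpclr": _stage_xpclr,
        "report": _stage_report,
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        log.info("stage %s: start", stage)
        marker = set(outputs)
        try:
            stage_fns[stage](config, out, state, record)
        except Exception as exc:  # noqa: BLE001 - named-stage abort by contract
            for name in set(outputs) - marker:
                p = outputs[name]
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise PipelineError(stage, exc) from exc
        log.info("stage %s: done (%.1fs)", stage, time.time() - t0)

    # the resolved config names the run directory, so it is checksummed
    # separately and not part of the (location-independent) output map
    resolved = out / "run_config.yaml"
    with open(resolved, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.resolved_dict(), fh, sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "config_sha256": _sha256(resolved),
        "outputs": {
            name: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
            for name, p in sorted(outputs.items())
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _load_inputs(config: RunConfig, state: dict) -> None:
    """Populate state from files for a run that starts after simulate."""
    if "sites" not in state and config.vcf:
        state["sites"], state["gm"] = read_vcf(config.vcf)
    if "pops" not in state and config.samples:
        state["pops"] = read_sample_map(config.samples)
    if "coverage" not in state and config.coverage:
        state["coverage"] = read_coverage(config.coverage)
    if "genes" not in state and config.gff:
        state["genes"] = read_gff(config.gff)
    if "reference" not in state and config.fasta:
        state["reference"] = read_fasta(config.fasta)


def _stage_simulate(config: RunConfig, out: Path, state: dict, record) -> None:
    params = config.sim or SimParams()
    if params.seed is None:
        params = dataclasses.replace(params, seed=config.seed)
    result = simulate_cohort(params)
    sim_dir = out / "sim"
    paths = emit_fixture(result, sim_dir)
    for name, p in paths.items():
        record(f"sim/{name}", p)
    state.update(
        sites=result.sites,
        gm=result.genotypes,
        pops=result.populations,
        coverage=result.coverage,
        genes=result.genes,
        reference=result.reference,
        truth=result.truth,
        chrom_lengths=dict(params.chrom_lengths),
        blocus=(params.blocus_region if config.blocus is None else config.blocus),
    )


def _stage_filter(config: RunConfig, out: Path, state: dict, record) -> None:
    _load_inputs(config, state)
    sites, gm = state["sites"], state["gm"]
    log.info("filter: %d sites in", sites.n_sites)
    res = apply_site_filters(sites, gm, config.filter_params)
    for name, n in sorted(res.rejection_counts.items()):
        log.info("filter: %-16s rejects %d", name, n)
    log.info("filter: %d sites out", res.sites.n_sites)
    state["sites"], state["gm"] = res.sites, res.genotypes
    write_vcf(res.sites, res.genotypes, record("filtered_vcf", out / "filtered.vcf"))
    pd.DataFrame(
        sorted(res.rejection_counts.items()), columns=["filter", "rejected_sites"]
    ).to_csv(record("reject_counts", out / "reject_counts.tsv"), sep="\t", index=False)
    if "pops" in state:
        pops: PopulationSpec = state["pops"]
        venn = partition_shared_variation(
            res.genotypes, res.sites, pops, pops.groups
        )
        venn.to_frame().to_csv(
            record("venn", out / "venn.tsv"), sep="\t", index=False
        )


def _stage_context(config: RunConfig, out: Path, state: dict, record) -> None:
    _load_inputs(config, state)
    ctx = classify_sites(state["sites"], state["genes"], state["reference"])
    ctx.to_csv(record("context", out / "context.tsv"), sep="\t", index=False)
    thinned = thin_sites(ctx, "intergenic", config.thin_min_dist)
    thinned.to_csv(
        record("intergenic_thinned", out / "intergenic_thinned.tsv"),
        sep="\t",
        index=False,
    )
    fourfold = ctx[ctx["label"] == "exonic_4DTv"]
    fourfold.to_csv(
        record("sites_4dtv", out / "sites_4dtv.tsv"), sep="\t", index=False
    )
    state["context"] = ctx
    log.info(
        "context: %d 4DTv, %d intergenic (%d after 1 kbp thinning)",
        len(fourfold),
        int((ctx["label"] == "intergenic").sum()),
        len(thinned),
    )


def _chrom_lengths_from_state(state: dict) -> dict[str, int]:
    if "chrom_lengths" in state:
        return state["chrom_lengths"]
    cov = state["coverage"]
    return {
        str(chrom): int(grp["end"].max())
        for chrom, grp in cov.groupby("chrom")
    }


def _stage_desert(config: RunConfig, out: Path, state: dict, record) -> None:
    _load_inputs(config, state)
    sites, gm = state["sites"], state["gm"]
    pops: PopulationSpec = state["pops"]
    coverage = state["coverage"]
    chrom_lengths = _chrom_lengths_from_state(state)
    windows = make_windows(chrom_lengths)
    cult = pops.samples_of(config.cultivated_group)
    wild = pops.samples_of(config.wild_group)

    blocus = config.blocus or state.get("blocus")
    if blocus is not None:
        region = GenomicRegion(*blocus)
        sel = select_blocus_accessions(
            gm, sites, region, config.blocus_max_variants, samples=cult
        )
        cult = sel.selected
        log.info(
            "desert: B-locus selection keeps %d/%d cultivated accessions",
            len(cult),
            len(sel.counts),
        )
        pd.DataFrame(
            {
                "sample": list(sel.counts),
                "blocus_variants": list(sel.counts.values()),
                "selected": [s in set(sel.selected) for s in sel.counts],
            }
        ).to_csv(
            record("blocus_selection", out / "blocus_selection.tsv"),
            sep="\t",
            index=False,
        )
    flagged = {}
    for label, samples, thresholds in (
        ("cultivated", cult, config.cultivated_thresholds),
        ("wild", wild, config.wild_thresholds),
    ):
        keep = pop_maf_mask(gm, samples, config.desert_min_maf)
        stats = window_population_stats(
            windows,
            sites.subset(keep),
            gm.subset_sites(keep),
            coverage,
            samples,
            thresholds.count_mode,
        )
        flagged[label] = call_desert_windows(stats, thresholds)
        write_bed(
            flagged[label],
            record(f"deserts_{label}", out / f"deserts_{label}.bed"),
        )
        log.info(
            "desert: %s — %d/%d windows flagged",
            label,
            len(flagged[label]),
            len(windows),
        )
    priv = private_deserts(
        flagged["cultivated"], flagged["wild"], config.desert_merge_gap
    )
    write_bed(
        priv.private_merged,
        record("deserts_private_merged", out / "deserts_private_merged.bed"),
    )
    summary = {
        "cultivated_desert_bp": priv.cultivated_bp,
        "wild_desert_bp": priv.wild_bp,
        "shared_bp": priv.shared_bp,
        "private_bp": priv.private_bp,
        "private_merged": region_summary(priv.private_merged),
    }
    with open(record("desert_summary", out / "desert_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    state["private_deserts"] = priv.private_merged
    state["desert_summary"] = summary


def _stage_xpclr(config: RunConfig, out: Path, state: dict, record) -> None:
    _load_inputs(config, state)
    sites, gm = state["sites"], state["gm"]
    pops: PopulationSpec = state["pops"]
    chrom_lengths = _chrom_lengths_from_state(state)
    results = xpclr_scan(
        sites,
        gm,
        pops.samples_of(config.wild_group),
        pops.samples_of(config.cultivated_group),
        chrom_lengths,
        config.xpclr_params,
    )
    results, top, threshold = normalize_and_top(
        results, config.xpclr_params.top_fraction
    )
    results.to_csv(record("xpclr_scores", out / "xpclr_scores.tsv"), sep="\t", index=False)
    write_bed(top, record("xpclr_top", out / "xpclr_top.bed"))
    state["xpclr_top"] = top
    log.info(
        "xpclr: omega=%.4f, threshold z=%.3f, %d top windows",
        results.attrs.get("omega", float("nan")),
        threshold,
        len(top),
    )
    if "private_deserts" in state:
        bp, inter = overlap_regions(state["private_deserts"], top)
        write_bed(inter, record("desert_xpclr_overlap", out / "desert_xpclr_overlap.bed"))
        state["desert_xpclr_overlap_bp"] = bp
        log.info("xpclr: %d bp overlap with private deserts", bp)


def _stage_report(config: RunConfig, out: Path, state: dict, record) -> None:
    _load_inputs(config, state)
    if "private_deserts" not in state or "genes" not in state:
        log.info("report: nothing to report (need genes and deserts)")
        return
    records, summary = gene_desert_classes(state["genes"], state["private_deserts"])
    records.to_csv(record("gene_classes", out / "gene_classes.tsv"), sep="\t", index=False)
    if "desert_xpclr_overlap_bp" in state:
        summary["desert_xpclr_overlap_bp"] = state["desert_xpclr_overlap_bp"]
    with open(record("report_summary", out / "report_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    state["gene_summary"] = summary
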
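"""Gene–desert overlap classification, region summaries and the Evanno
delta-K model-choice table.

Gene "length" here is the genomic span (start to end, introns included).
Overlapping genes are partitioned into four mutually exclusive classes:

* ``partial``        — overlap < 90% of the gene span;
* ``ninety_plus``    — overlap >= 90% but the gene is not fully contained;
* ``complete_sole``  — gene span fully inside one desert and no other gene
  touches that desert;
* ``complete_shared``— fully inside a desert that also touches other genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneSet
from .regions import RegionSet

GENE_CLASSES = ("partial", "ninety_plus", "complete_sole", "complete_shared")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def gene_desert_classes(
    genes: GeneSet, deserts: RegionSet
) -> tuple[pd.DataFrame, dict]:
    """Classify every gene overlapping a desert by its overlap fraction.

    ``deserts`` must be disjoint (merged). Returns per-gene records and a
    summary with class counts and integer percentages (rounded half away
    from zero) of the total overlapping genes.
    """
    if not deserts.is_disjoint():
        raise ValueError("deserts must be disjoint (merge them first)")
    desert_list = list(deserts)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    ids: dict[str, np.ndarray] = {}
    for chrom in deserts.chroms():
        rs = [(i, r) for i, r in enumerate(desert_list) if r.chrom == chrom]
        starts[chrom] = np.asarray([r.start for _, r in rs])
        ends[chrom] = np.asarray([r.end for _, r in rs])
        ids[chrom] = np.asarray([i for i, _ in rs])

    rows = []
    genes_per_desert: dict[int, int] = {}
    per_gene_hits: list[tuple[int, dict]] = []
    for g in genes:
        if g.chrom not in starts:
            continue
        s_arr, e_arr, id_arr = starts[g.chrom], ends[g.chrom], ids[g.chrom]
        ov = np.minimum(e_arr, g.end) - np.maximum(s_arr, g.start)
        hit = ov > 0
        overlap_bp = int(ov[hit].sum())
        if overlap_bp == 0:
            continue
        container = np.nonzero((s_arr <= g.start) & (e_arr >= g.end))[0]
        desert_id = int(id_arr[container[0]]) if container.size else None
        rec = {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": g.start,
            "end": g.end,
            "gene_length": g.span_length,
            "overlap_bp": overlap_bp,
            "overlap_fraction": overlap_bp / g.span_length,
            "desert_id": desert_id,
        }
        for d in id_arr[hit]:
            genes_per_desert[int(d)] = genes_per_desert.get(int(d), 0) + 1
        per_gene_hits.append((desert_id, rec))
        rows.append(rec)

    for desert_id, rec in per_gene_hits:
        frac = rec["overlap_fraction"]
        if desert_id is not None:
            sole = genes_per_desert.get(desert_id, 0) == 1
            rec["class"] = "complete_sole" if sole else "complete_shared"
        elif frac >= 0.9:
            rec["class"] = "ninety_plus"
        else:
            rec["class"] = "partial"

    records = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "start", "end", "gene_length", "overlap_bp",
            "overlap_fraction", "desert_id", "class",
        ],
    )
    total = len(records)
    counts = {
        cls: int((records["class"] == cls).sum()) if total else 0
        for cls in GENE_CLASSES
    }
    summary = {
        "total_overlapping_genes": total,
        "counts": counts,
        "percent": {
            cls: _round_half_away(100.0 * n / total) if total else 0
            for cls, n in counts.items()
        },
        "mean_gene_length_kbp": (
            round(float(records["gene_length"].mean()) / 1000.0, 1) if total else 0.0
        ),
    }
    return records, summary


def region_summary(regions: RegionSet) -> dict:
    """Count, total bp, mean length (kbp, 1 decimal) and max length of regions."""
    n = len(regions)
    if n == 0:
        return {"count": 0, "total_bp": 0, "mean_length_kbp": 0.0, "max_length_bp": 0}
    lengths = np.asarray([r.length for r in regions])
    return {
        "count": n,
        "total_bp": int(lengths.sum()),
        "mean_length_kbp": round(float(lengths.mean()) / 1000.0, 1),
        "max_length_bp": int(lengths.max()),
    }


@dataclass
class EvannoTable:
    """Evanno delta-K table over admixture replicate log-probabilities.

    ``table`` is indexed by k with columns ``mean``, ``sd``, ``l_prime``,
    ``l_second_abs`` and ``delta_k``; ``best_k`` is the interior k with the
    largest defined delta-K.
    """

    table: pd.DataFrame
    best_k: int


def evanno_delta_k(log_probs: Mapping[int, Sequence[float]]) -> EvannoTable:
    """Evanno's second-order rate-of-change criterion for the number of
    ancestral populations k.

    ``L'(k) = mean L(k) - mean L(k-1)``; ``|L''(k)| = |L'(k+1) - L'(k)|``;
    ``delta_k = |L''(k)| / sd over runs of L(k)`` for interior k. Requires at
    least three consecutive k values with at least two runs each. A zero
    between-run sd makes delta-K undefined (NaN) at that k; if no interior k
    has a defined delta-K the table is unusable and a ``ValueError`` is
    raised. Adding a constant to every log-probability leaves delta-K
    unchanged.
    """
    ks = sorted(log_probs)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive k values")
    for k in ks:
        if len(log_probs[k]) < 2:
            raise ValueError(f"k={k}: need >= 2 replicate runs")
    mean = {k: float(np.mean(log_probs[k])) for k in ks}
    sd = {k: float(np.std(log_probs[k], ddof=1)) for k in ks}
    l_prime = {k: mean[k] - mean[k - 1] for k in ks[1:]}
    rows = []
    for k in ks:
        lp = l_prime.get(k, np.nan)
        if k in l_prime and (k + 1) in l_prime:
            lsec = abs(l_prime[k + 1] - l_prime[k])
            delta = lsec / sd[k] if sd[k] > 0 else np.nan
        else:
            lsec, delta = np.nan, np.nan
        rows.append(
            {
                "k": k,
                "mean": mean[k],
                "sd": sd[k],
                "l_prime": lp,
                "l_second_abs": lsec,
                "delta_k": delta,
            }
        )
    table = pd.DataFrame(rows).set_index("k")
    if table["delta_k"].isna().all():
        raise ValueError("delta-K undefined at every interior k (zero variance)")
    best_k = int(table["delta_k"].idxmax())
    return EvannoTable(table=table, best_k=best_k)
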
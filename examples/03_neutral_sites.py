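"""Extract quasi-neutral variant classes: fourfold-degenerate (4DTv) exonic
sites and distance-thinned intergenic sites."""

import desertscan as ds
from desertscan.context import classify_sites, codon_degeneracy, thin_sites

result = ds.simulate_cohort(ds.SimParams(
    seed=3,
    chrom_lengths={"chr1": 200_000},
    n_samples={"cultivated": 10, "wild": 10},
    sweeps=[],
    gene_density=3e-4,
    blocus_region=("chr1", 180_000, 190_338),
))

ctx = classify_sites(result.sites, result.genes, result.reference)
print("site context counts:")
print(ctx["label"].value_counts().to_string())

thinned = thin_sites(ctx, "intergenic", min_dist=1000)
print(f"\nintergenic sites: {(ctx['label'] == 'intergenic').sum()}"
      f" -> {len(thinned)} after 1 kbp distance thinning")

# degeneracy of a codon position: 4 means any substitution is synonymous
for codon, pos in (("GGA", 3), ("ATG", 3), ("CCT", 3)):
    print(f"codon {codon} position {pos}: {codon_degeneracy(codon, pos)}-fold")
# 4DTv sites sit at fourfold third positions, so variation there is
# effectively invisible to protein-level selection.
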
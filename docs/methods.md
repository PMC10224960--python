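# Methods

This note documents the models, parameter choices and numerical conventions
behind `desertscan`, and what the synthetic-cohort tests do and do not show
about real data.

## Coordinates and containers

All internal coordinates are 0-based half-open; VCF and GFF3 are converted
at the format boundary, BED passes through unshifted. Genotypes are diploid
codes (hom-ref / het / hom-alt / missing); phased separators are read as
unphased, and an allele index above 1 at a biallelic-coded record is
rejected as malformed. When a gene has several transcripts, the transcript
with the longest total CDS represents the gene everywhere (overlap classes,
codon reconstruction); the choice is arbitrary but deterministic.

## Site filtering

A site passes iff it passes *every* configured rule, so the pass mask is
order-independent by construction. Rules and boundaries:

| rule | default | boundary |
|---|---|---|
| biallelic | on | multi-allelic records dropped |
| missingness | ≤ 0.10 | inclusive ("at most 10%") |
| MAF (called alleles only) | > 0.01 | strict ("larger than 1%") |
| site depth DP | 2N ≤ DP ≤ 10N | inclusive; N = samples called at the site |
| annotations (MQ, SOR, QD, FS, rank sums, MLEAF) | as printed | strict `>`/`<` |

Absent annotations skip their rule by default (the GATK convention for
missing annotations); a strict mode fails them instead. Rejection counts
attribute a failing site to every rule it fails, so they sum to more than
the number of rejected sites.

Group "presence" for the shared/private partition means at least one
non-missing sample of the group carries an alt allele; an allele-frequency
threshold is available as an option since presence is not otherwise
identifiable from the cohort design.

## Site context and 4DTv sites

A site is `exonic_4DTv` when it is an SNV on the third position of a
fourfold-degenerate codon of a usable gene (CDS length a codon multiple
after phase adjustment), with the codon read on the coding strand. Genes
failing the codon-multiple check contribute `exonic_other` only. When gene
spans overlap, exonic context beats intronic, and among exonic candidates
the longest-CDS gene decides. "Intergenic" means outside every gene *span*;
introns and UTRs are not intergenic. Distance thinning is greedy
left-to-right per chromosome: the first position is kept, each later one
iff ≥ `min_dist` (default 1000 bp, inclusive) from the last kept — a
deterministic rule that attains maximality (re-adding any dropped position
violates the spacing).

## Desert scan

Windows are the canonical tiling `[i·step, i·step+size)` (2 kbp / 1 kbp;
trailing remainders dropped). Accessions enter the cultivated scan only if
they carry at most 5 variants in the B-locus region (10,338 bp), the
screen that separates crop-type from wild-type bolting haplotypes.

Per population, sites are pre-filtered to within-population MAF ≥ 0.05 (so
reference/sequencing errors and sites fixed for the alternate allele do
not count as variation), then each window gets four statistics:

* variant count — `population_sites` (default): sites with ≥ 1
  alt-carrying population sample; `max_per_accession`: the maximum
  per-accession count, the alternative reading of "variants per accession".
  Both are implemented because the two phrasings of the window rule differ;
  the choice is a config key.
* mean depth — population mean of per-sample mean window depths, counting
  samples absent from the coverage table as zero.
* covered fraction — the estimated fraction of window bases with pooled
  population depth ≥ 1. The coverage interface is per-sample per-window
  (`chrom, start, end, sample, mean_depth, covered_bases`), from which the
  pooled union is not identifiable; we use the complement product
  1 − Π_s(1 − covered_s/L), exact when per-sample covered bases fall
  independently and uniformly (true of the simulator, a good approximation
  for dense short-read coverage).
* samples-with-reads fraction — fraction of population samples with any
  covered base.

A window is a desert iff count ≤ max_variants AND depth ≥ min depth AND
covered fraction ≥ min width AND samples-with-reads ≥ min fraction — all
inclusive, so exact-boundary windows pass. Defaults: 2 / 6× / 0.9 / 0.9
for the cultivated population and 4 / 4× / 0.8 / 0.9 for the wild one
(the wild thresholds are relaxed for its lower mapping coverage).

Shared and private desert bp are computed at base-pair resolution on the
window unions *before* any gap-merging; the ≤ 1 kbp gap merge is applied
only to the private remainder, so `private + shared = cultivated` holds
exactly, always.

## XP-CLR-style composite likelihood

The scan is a reimplementation of the cross-population composite
likelihood ratio idea with an explicit, fully documented parameterisation;
it is not bit-compatible with the original tool, and physical distance
substitutes for genetic distance.

Frequencies are estimated from called alleles and clamped to
[1/(2n), 1 − 1/(2n)]. The drift variance ω is the genome-wide method of
moments, mean of (p₂−p₁)²/(p₁(1−p₁)) over sites polymorphic in the
reference population; it absorbs both drift and finite-sample noise, which
keeps the null self-consistent with the data it is fitted to. Per SNP the
density of p₂ is, with respect to Lebesgue measure on the open clamp
interval plus unit atoms at its two ends:

* null: normal(p₁, ω·p₁(1−p₁)) truncated to the interval, tail masses
  absorbed as boundary atoms;
* sweep: atoms only — mass p₁ at the upper clamp, 1−p₁ at the lower.

Both integrate to one, so c = 1 reduces exactly to the null and the window
score 2·(maxσ ℓ − ℓ_null) is non-negative (the σ grid, geometric over
10²–10⁶ bp, always includes the null). Scores are z-normalised over scored
windows and the top `q` fraction extracted with inclusive ties; constant
scores make the z-score undefined and raise.

Because the sweep component has no interior density, a drift-only genome
scores exactly zero in almost every window (typically 0–5 of ~190 windows
are positive); the statistic is strongly zero-inflated under its own null.
A genome whose windows all score zero therefore has no extractable top set
— the calibration machinery treats that defined degenerate outcome as an
empty top set. This is a known property of the parameterisation, not a
defect of the scan: sweep signals are orders of magnitude above the
zero floor.

## Synthetic cohort

The generator emulates the statistical structure of the study cohort, not
its sequences. Defaults are the study conditions where stated: 206
cultivated + 54 wild accessions, ~0.018 segregating sites per bp after
filtering, mean depth 6 ("roughly sixfold"), a 10,338 bp B-locus with 0–5
vs 16–47 per-accession variant modes, three planted cultivated sweeps of
20/30/12 kbp total extent with residual diversity 0.05. The genome is
2 × 1 Mbp — big enough for ~2,000 desert windows and ~190 scan windows per
cohort while keeping a simulation at a few seconds.

* Ancestral frequencies: Beta(0.5, 0.5) clipped away from 0/1 — a
  symmetric, boundary-heavy stand-in for a neutral folded spectrum.
* Drift: Balding–Nichols with F = 0.1 per group
  (q ~ Beta(p(1−F)/F, (1−p)(1−F)/F)), chosen for its closed-form moments
  (E[q] = p, Var[q] = F·p(1−p), E[2q(1−q)] = (1−F)·2p(1−p)) which the
  tests check directly against the draws.
* Genotypes: Hardy–Weinberg binomial within groups; uniform random
  missingness (5%).
* Sweeps: inside a planted region, each site is fixed in the target
  population (frequency rounded to 0/1) with probability 1 − residual;
  surviving sites are optionally pushed to within the residual fraction of
  fixation or loss. Density and heterozygosity therefore both scale by
  ~residual, and the pushed frequencies are what the XP-CLR stage detects.
* Coverage: per-sample per-window depth ~ Poisson(mean depth); covered
  bases ~ Binomial(L, 1 − e^(−depth)).
* Annotations: drawn from passing ranges with a configurable fraction
  (2%) forced below/above each threshold; DP is mean depth × called
  samples, inside the 2N–10N band unless deliberately failed; MLEAF
  mirrors the realised cohort alt frequency.
* B-locus: a fixed panel of 60 sites carries per-accession heterozygous
  variants, count drawn uniformly from the low (0–5) or high (16–47) mode;
  85% of cultivated accessions are low-mode, all wild accessions high-mode.
  Background sites are excluded from the region so the counts are exact.

All draws come from one seeded generator; a seed reproduces every output
file byte for byte, and the seed is recorded in the VCF header.

What the simulator does **not** model: linkage disequilibrium and
recombination (sites are exchangeable given frequencies), mapping bias and
coverage heterogeneity along the genome, indels (all simulated variants
are SNVs; indel handling is exercised through hand-built fixtures),
multi-allelic sites, and admixture between the populations. Recovery
results on synthetics therefore demonstrate the correctness of the scan
machinery under the stated model, not field performance on real
resequencing data.

## Known limitation: coverage threshold at the coverage mean

The cultivated desert rule requires mean window depth ≥ 6 while simulated
(and nominal study) coverage is ~6×. A population-mean depth statistic is
then centred exactly on its inclusive threshold, so any unbiased coverage
noise fails ~half of all windows on depth alone, in sweeps and background
alike. With 2-fold window overlap and the 1 kbp gap merge this caps
planted-sweep bp sensitivity near ~80% under the default conditions
(measured 79–82% over 10 seeds, with false-positive desert bp ≤ 0.4% of
the genome). Raising simulated depth or lowering the threshold would lift
sensitivity above 90%, but both are fixed study conditions, so the package
reports the honest number instead. On real data the same effect makes the
depth rule a stringent well-covered-regions screen rather than a mild
quality gate.

## Pipeline and determinism

`run_pipeline` executes simulate → filter → context → desert → xpclr →
report from one config; every stage logs in/out counts, outputs are
checksummed into a manifest, and identical config + seed reproduce
identical checksums (the resolved config itself, which names the output
directory, is checksummed separately). A failing stage aborts the run with
its name; its partial outputs keep a `.partial` suffix.
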
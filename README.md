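# desertscan

Detection of **variation deserts** and cross-population selection signals in
resequenced crop cohorts, built for the beet (*Beta vulgaris*) setting of a
cultivated population (sugar beet) contrasted against wild sea beets, but
applicable to any diploid two-population resequencing design.

Domestication and breeding drive selective sweeps: genomic regions where the
cultivated population has lost essentially all segregating variation while
the wild relative still varies. `desertscan` implements the full desk-side
analysis around that idea:

* **Site filtering** of a joint multi-sample VCF: biallelic sites with at
  most 10% missing genotypes, minor allele frequency MAF > 0.01, total site
  depth within 2N–10N reads (N = covering samples, bounds inclusive) and
  strict GATK-style annotation thresholds (MQ > 30, SOR < 3, QD > 2,
  FS < 60, MQRankSum > −12.5, ReadPosRankSum > −8, BaseQRankSum > −12.5,
  MLEAF > 0.01).
* **Shared/private variation partition** of filtered variants across taxon
  groups (the Venn cells of group presence), split into SNVs and indels.
* **Neutral site extraction**: fourfold-degenerate (4DTv) third codon
  positions from GFF3 gene models (strand-aware codon reconstruction) and
  intergenic variants thinned to a minimum spacing of 1 kbp.
* **Variation-desert scan**: accessions are first screened at the bolting
  locus (B-locus, the *BvBTC1* gene span of 10,338 bp; crop-type accessions
  carry at most 5 variants there, the rest 16–47). Per population, 2 kbp
  windows shifted by 1 kbp are scored for variant count (MAF ≥ 0.05 within
  the population), mean mapping depth, covered width and the fraction of
  samples with reads; a window is a desert when it is well covered yet has
  no more than 2 variants (4 for the wild population, with relaxed coverage
  bounds). Wild deserts are subtracted at bp resolution and the private
  remainder merged across gaps of up to 1 kbp.
* **XP-CLR-style scan**: a cross-population composite likelihood ratio over
  50 kbp / 10 kbp windows. Per SNP the object-population frequency p₂ is
  modelled as a mixture of a truncated-normal drift null around the
  reference frequency p₁ (variance ω·p₁(1−p₁), method-of-moments ω) and a
  hitchhiking component with mass p₁ at fixation and 1−p₁ at loss, mixed
  with weight c = 1 − exp(−d/σ) by distance d from the window centre; the
  score is 2·(maxσ ℓ − ℓ_null) ≥ 0, z-normalised genome-wide, top 5%
  extracted (ties included).
* **Reporting**: gene–desert overlap classes (partial / ≥90% / completely
  contained as the sole gene or shared), region summaries, and the Evanno
  ΔK criterion for choosing the number of admixture components.
* **Synthetic cohort generator**: Balding–Nichols drift (group frequencies
  Beta-distributed around an ancestral frequency with variance F·p(1−p)),
  Hardy–Weinberg genotypes, planted sweeps with known ground truth, a
  bimodal B-locus analogue, Poisson coverage (~6×) and controlled
  annotation failures — so every stage is testable without any download.

## Worked example

`examples/04_desert_scan.py` simulates a 400 kbp chromosome with 60
cultivated and 30 wild accessions and two planted sweeps, then runs the
desert scan:

```
B-locus screen keeps 51 of 60 cultivated accessions
cultivated: 19 of 399 windows are deserts
wild: 0 of 399 windows are deserts
cultivated desert bp 32000 = shared 0 + private 32000
private deserts after merging: {'count': 5, 'total_bp': 35000, 'mean_length_kbp': 7.0, 'max_length_bp': 19000}
planted sweep bp recovered: 29000/34000 (85% sensitivity)
```

The B-locus screen removes the 9 accessions simulated with a wild-type
(high-variation) bolting locus; the flagged windows concentrate on the two
planted sweeps; subtracting wild deserts leaves the cultivated-private bp,
and merging nearby pieces reconstructs sweeps close to their planted extent.

`examples/05_xpclr_scan.py` runs the composite likelihood scan at full
study scale (2 × 1 Mbp, 206 + 54 accessions, three planted sweeps):

```
scored 192 windows; method-of-moments drift variance omega = 0.361
top 5%: 9 windows above normalised threshold z = -0.13
planted sweep chr1:250000: inside the top-5% set
planted sweep chr1:700000: inside the top-5% set
planted sweep chr2:150000: inside the top-5% set
```

All three sweep centres fall inside the extracted top-5% window set.

The other examples cover simulation/fixture output, filtering and the
shared/private partition, 4DTv extraction, gene–desert classes and the
Evanno table. A thin CLI wraps the same functions
(`desertscan simulate|filter|context|desert|desert-private|xpclr|genes|evanno|run`);
`desertscan run --config run.yaml --seed N` executes the whole pipeline
reproducibly and writes a checksum manifest.

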
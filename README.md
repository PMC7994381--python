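# nbscreen

Multi-criteria driver-gene prioritization for copy-number-gain tumour
cohorts, modelled on integrative neuroblastoma genomics.

Segmental gain of distal chromosome 17q is the most common lesion in
neuroblastoma, and *MYCN* amplification its strongest clinical marker.
`nbscreen` is for computational biologists who want to reproduce, stress-test
or adapt the two screening strategies used to nominate driver genes in that
setting:

1. **Cohort screen** — every gene in a recurrently gained region is scored
   on five criteria: (1) differential over-expression in region-gain vs
   region-diploid tumours and (2) in *MYCN*-amplified vs non-amplified
   tumours, positive Pearson correlation of expression with (3) its own copy
   number and (4) *MYCN* expression, and (5) association with poor overall
   survival. A gene "passes" only at score 5/5.
2. **ChIP-seq coactivator-target screen** — genes are filtered for promoter
   co-occupancy (−1000/+100 bp around the TSS) of a coactivator plus MYCN,
   RNA Pol II, H3K27ac and H3K4me3; a strict coactivator fold-enrichment
   cutoff FE > 5 with FE-rank ordering; survival and *MYCN*-correlation
   criteria; and membership of a functional gene set. An E-box scanner
   annotates canonical (CACGTG) and non-canonical (CANNTG) MYC-family
   motifs.

## The statistics underneath

* Copy number: per-interval average ploidy `n` is the length-weighted mean of
  segmental calls; strata are loss (`n ≤ 1`), diploid, gain (`n ≥ 3`), with
  10 kb bins for chromosome-wide frequency profiles.
* Differential expression: per-gene NB GLM
  `K_gi ~ NB(s_i · exp(β₀ + β₁ x_i), α_g)` with median-of-ratios size factors
  `s_i`, method-of-moments dispersion `α_g`, a two-sided Wald χ²(1) test on
  `β₁`, BH adjustment, and a data-dependent fold-change cutoff: the lower
  quartile of all positive log2FCs among adjusted-significant genes
  (pass = `p_adj < 0.05` and `log2FC ≥` cutoff).
* Correlation: exact-t Pearson test, Bonferroni over the tested family,
  pass = `p_adj < 0.05` and `r > 0`.
* Survival: Kaplan–Meier product-limit curves, the two-group log-rank test,
  and Cox proportional-hazards fits by Newton–Raphson on the Breslow partial
  likelihood; genes are dichotomised at median expression and pass with
  `HR > 1` and log-rank `p < 0.05`. Multivariate and additive
  (one-covariate-at-a-time attenuation) models quantify independence from
  stage, age and amplification status.

A seeded synthetic-cohort generator (`nbscreen.synthetic_data`) plants a
known driver and ChIP target inside realistic cohort structure, so every
stage — and the full pipelines — can be validated against ground truth
without downloading anything.

## Worked example

```bash
python examples/run_cohort_screen.py
```

```
cohort: 200 samples, 401 genes; gain region chr17:1700000-2001000

top five region genes (rank order):
         score  log2fc_gain  log2fc_amp   r_cn  r_mycn     hr  logrank_p
gene_id
G0371        5        1.208       1.711  0.571   0.648  2.075      0.000
G0400        5        0.739       0.433  0.610   0.295  1.400      0.033
G0376        4        0.747       0.453  0.569   0.189  1.563      0.005
G0378        3        0.692       0.163  0.581   0.091  1.638      0.002
G0379        3        0.775       0.337  0.561   0.062  1.549      0.006

genes passing all five criteria: ['G0371', 'G0400']
planted driver gene:             G0371
```

The planted driver G0371 ranks first: it is roughly doubled in region-gain
tumours (log2FC 1.2, dosage plus its amplification effect), strongly
amplified-associated (log2FC 1.7), tracks both its copy number (r = 0.57)
and *MYCN* expression (r = 0.65), and halves survival (HR 2.1). At this seed
one neighbour (G0400) also reaches score 5 by riding the gain–amplification
association — exactly the false-positive mode the five-way intersection is
designed to suppress; across seed streams the driver is the unique score-5
gene in roughly 65–90% of cohorts (see `docs/methods.md` on why the
data-dependent fold-change threshold makes this boundary noisy). The other examples (`run_chip_screen.py`,
`cnv_frequency_profile.py`, `survival_analysis.py`, `ebox_annotation.py`)
walk through the remaining capabilities one at a time.

The same pipelines are available from the shell:

```bash
nbscreen simulate --seed 1 --outdir data
nbscreen screen --segments data/cohort/segments.tsv --counts data/cohort/counts.tsv \
    --clinical data/cohort/clinical.tsv --genes data/cohort/genes.gtf \
    --region chr17:1700000-2001000 --out screen.tsv
nbscreen chip-targets --peaks alyref=data/chip/alyref.narrowPeak ... --out targets.tsv
```

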
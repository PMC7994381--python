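# Methods

This note documents the models, numerical choices and known limitations of
`nbscreen`, in the order a user meets them: coordinate and format
conventions, the copy-number layer, the four statistical filters, the two
integrated screens, the synthetic-data generator, and what the passing test
suite does and does not demonstrate.

## Coordinates and formats

All genomic records are 0-based, half-open internally. GTF (1-based,
closed) is converted exactly once at the parsing boundary; a minus-strand
TSS is `end − 1` in internal coordinates. The segment-table dialect is our
own: TSV `sample, chrom, start, end, ploidy` in 0-based half-open
coordinates (real segment exports vary; adapting one is a five-line
reformat). narrowPeak column 7 (signalValue) is read as the fold enrichment
because that is where MACS2 writes its FE. Overlap of two half-open
intervals requires at least one shared base, so abutting intervals do not
overlap.

## Copy number

The average ploidy of an interval is the length-weighted mean of the
overlapping segments' ploidies, computed over covered bases only. Uncovered
bases are excluded from the weighting rather than imputed as diploid, so a
focal event inside a sparsely covered interval is not diluted; an interval
with zero coverage yields a missing value and the sample drops out of any
stratified analysis with a warning. Classification uses
loss `n ≤ 1` / diploid / gain `n ≥ 3`; the two boundary values belong to
loss and gain respectively (precedence gain, then loss, then diploid), the
reading that keeps the screen sensitive to gains. Frequency profiles use
10 kb bins by default, with an optional exclusion mask (e.g. for
centromeric bins) that reports masked bins with missing frequencies rather
than dropping rows.

## Differential expression

Counts are modelled per gene as NB with mean `s_i · exp(β₀ + β₁ x_i)` and
dispersion `α_g` (variance `μ + α μ²`). Size factors are median-of-ratios
over genes expressed in every sample, rescaled to geometric mean 1. The
dispersion is a pooled within-group method-of-moments estimate on
normalised counts, floored at 1e-8. This is deliberately *not* a
DESeq2-style shrinkage estimator: the stage is self-contained and exactly
specified, and on cohorts of ≥50 samples per arm with moderate dispersion
the difference is negligible (the null simulation in the suite confirms
uniform p-values by KS test). The group log-means are fitted by per-group
Fisher scoring (the information for a log-link NB log-mean is
`Σ μ/(1+αμ)`), and the Wald statistic `(β₁/se)²` is referred to χ²(1),
two-sided. A group whose counts sum to zero is floored at half a count so
the contrast stays finite; genes with zero counts in both groups are
untestable and excluded from multiplicity adjustment.

Filtering follows a data-dependent rule: with BH-adjusted p-values, the
log2FC cutoff is the lower quartile (linear-interpolation convention — no
convention is canonical, this is numpy's default) of all *positive* log2FCs
among adjusted-significant genes, and a gene passes with `p_adj < 0.05` AND
`log2FC ≥` cutoff (boundary inclusive). Only up-regulation can pass, by
construction of the positive-quartile rule — the screen looks for
over-expressed drivers. Note a structural property of this rule: it always
removes about a quarter of the up-regulated significant genes, and when the
significant set is very small (two or three genes) the quartile can land
*above* a gene that is genuinely differential. See "Limitations".

## Correlation criteria

Expression is `log2(count/s_i + 1)` for all correlation and survival
analyses; the pseudocount avoids log 0 and the scale matches how such
cohorts are usually plotted. Pearson r with the exact t transform
(`t = r·√((N−2)/(1−r²))`, N−2 df, two-sided) gives the raw p; Bonferroni is
applied over all genes testable in the run (pairs with fewer than 3
complete observations or zero variance are excluded from the family), and
a gene passes only with `p_adj < 0.05` and `r > 0`. Criterion 3 correlates
each gene against its own per-sample copy number, criterion 4 against the
MYCN expression vector.

## Survival

Kaplan–Meier and the two-group log-rank test are textbook implementations
(log-rank with the hypergeometric variance including the `(n−d)/(n−1)` tie
factor). Cox models maximise the Breslow partial likelihood by
Newton–Raphson with step-halving, gradient-norm tolerance 1e-8, at most 25
iterations; standard errors come from the observed information, and the
score test at β = 0 is also reported (for a single binary covariate it is
the log-rank score form). Breslow rather than Efron tie handling keeps the
updates closed-form; synthetic survival times are continuous so ties are
rare, and the suite verifies agreement with an independent implementation
on tie-free data. A fit whose coefficient exceeds 15 in absolute value
(HR > 3×10⁶) is flagged unconverged — that magnitude signals monotone
likelihood/complete separation, where the flat tail of the likelihood can
satisfy the gradient test without a finite maximiser. Unconverged genes are
skipped by the filters with a warning.

Median dichotomisation assigns ties (values equal to the median) to the
low group. The survival filter fits the univariate Cox model on the
high/low label and passes genes with `HR > 1` and *log-rank* `p < 0.05`
(the Wald p is reported alongside); no multiplicity adjustment is applied,
matching a per-gene "individual test" reading, so its null pass rate is
≈ 0.025 per gene (half of α, from the one-sided HR condition). Overall
survival is the default endpoint; `endpoint="efs"` switches to event-free
survival. The multivariate model adds stage/age/amplification covariates;
the additive attenuation table refits gene + one covariate at a time and
ranks covariates by |ΔHR| against the univariate fit.

## The cohort screen

Criteria 1–2 run the NB test transcriptome-wide (every gene in the count
table), each stratification computing its own quartile threshold, and the
passing sets are then restricted to region genes; this mirrors how such
cohorts are analysed (genome-wide DE, then a regional lens) and gives the
quartile rule a realistic family to work with. The correlation criteria
use a Bonferroni family of all genes tested in the run (all genes for the
MYCN criterion; all copy-number-covered genes for the dosage criterion).
The survival filter runs on region genes. Criterion 1 drops samples whose
region status is loss or missing; criteria 2–5 use all samples. The score
is the number of true flags; ranking is score descending, then survival HR
descending, then gain-DE adjusted p ascending, then gene id — fully
deterministic and input-order independent.

## The ChIP-seq target screen

Promoters are strand-aware −1000/+100 bp windows around the TSS, clipped
at the chromosome start; "presence at the promoter" is ≥1 bp peak overlap
(no minimum-overlap fraction — peak calls are already size-filtered
upstream). A peak overlapping two promoters counts for both genes. The
per-gene coactivator FE is the maximum over its assigned coactivator
peaks. The FE filter is strict (`FE > 5`): a gene at exactly 5.0 fails.
FE rank is descending FE with gene-id tie-break. The functional criterion
is membership of a user-supplied gene list; no curated ubiquitination
database is bundled, since that curation is irreducibly manual. The E-box
scanner reports every CANNTG 6-mer (canonical = CACGTG); both patterns are
reverse-complement palindromic *as patterns*, so scanning one strand finds
all sites, and windows containing N never match.

## Synthetic-data generator

The generator's defaults are the study conditions for all calibration and
recovery claims: 200 samples, 400 genes of which 60 lie in the gain
region, gain prevalence 0.5 (inside the 38–65% incidence range reported
for distal 17q gain), amplification prevalence 0.25, a gain–amplification
odds multiplier of 4 (the two lesions are strongly associated; the
conditional probabilities are solved so the marginal prevalence stays at
`p_gain`), dosage exponent 1, a planted driver with an extra
amplification effect of log2FC 1.5 and a planted hazard ratio of 2.5, NB
dispersion 0.1, baseline hazard 1/1500 events/day with administrative
censoring at 3000 days.

Free choices not pinned down by those conditions, fixed once as realistic
cohort structure: baseline gene means are logNormal(ln 100, 1.2) with the
driver and MYCN pinned at a well-expressed mean of 200 (drivers nominated
this way are abundant transcripts); size factors logNormal(0, 0.2);
per-sample segments tile the chromosome in 100 kb pieces with baseline
ploidy Normal(2, 0.1) truncated at 0, and gained samples draw one
Uniform(3, 4) ploidy for the whole region; MYCN's mean is ×4 in amplified
samples; survival is exponential with the hazard raised by `driver_hr` for
samples whose *observed* driver expression is above the cohort median,
censored at min(3000, Uniform(0, 6000)) days; the event-free endpoint uses
a 1.4× baseline hazard with the same planted effect; stage and age
covariates are independent Bernoulli(0.45)/Bernoulli(0.55). Exponential
survival satisfies proportional hazards exactly, which is all the filters
assume.

The ChIP fixture plants one target with all five marks in its promoter and
coactivator FE ~ Uniform(5.5, 10); decoys carry either an incomplete mark
combination or FE ~ Uniform(1, 5); one designated boundary decoy carries
all five marks at FE exactly 5.0 to exercise the strict cutoff. The
matched expression/survival cohort gives the target the driver-style
amplification and hazard effects so criteria 3–4 have real signal.

What the generator does **not** emulate: realistic breakpoint structure or
subclonality, GC/length biases, batch effects, non-proportional hazards,
informative censoring, read-level data, or correlated co-expression
modules. Passing tests therefore demonstrate that the pipeline's logic and
statistics are correct and calibrated under its stated model — not that
the screens would behave identically on any particular real cohort.

## Limitations

* The quartile-based fold-change rule is unstable when the
  adjusted-significant set is small. In the amplified-vs-non-amplified
  stratification the positive significant set can collapse to MYCN plus
  the driver itself, in which case the lower quartile of two values lies
  between them and eliminates the driver. Across seeded default cohorts
  the planted driver is the unique 5/5 gene in most runs (65–90%
  depending on the seed stream); the misses split between this degeneracy
  and an occasional neighbour gene riding the gain–amplification
  association through all five criteria. Both behaviours are properties of the screening rules at this
  cohort size, and are left visible rather than patched.
* The NB Wald test with MoM dispersion is anti-conservative for very small
  groups (< ~10 per arm); the screens are intended for cohort-scale data.
* Breslow tie handling biases Cox coefficients toward zero under heavy
  ties; with discretised survival times Efron handling would be
  preferable.
* `fe_rank` and the screen ranking are deterministic given the stated
  tie-breaks, but ties on real FE values are unlikely; the gene-id
  tie-break exists for reproducibility, not meaning.
* The gene-set criterion is exactly as good as the supplied list.
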
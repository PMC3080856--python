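# Methods

`rdnakit` reimplements, as a tested and reusable pipeline, the analysis
chain used to ask whether deletions in the Y-linked ribosomal DNA (rDNA)
array modulate genome-wide gene expression in *Drosophila melanogaster*.
Because the original microarray data are not bundled, every stage is
driven by a synthetic-data generator that reproduces the statistical
structure the analysis assumes; the tests and the acceptance script
therefore validate the *methods* (calibration, power, exactness,
recovery of planted truth), not the original study's specific gene lists.

## Study design being emulated

Four Y chromosomes in an isogenic background: a wild-type and three
deletion derivatives retaining ~87%, ~85% ("mild") and ~46% ("gross") of
the wild-type rDNA copy number. Each mutant is hybridized directly against
the wild-type on replicated two-color cDNA microarrays with balanced dye
orientation (default 6 arrays per comparison, alternating Cy5/Cy3
assignment). An XXY-female version of the experiment is obtained by
attenuating the same truth table (see below).

## Synthetic-data model

**Annotation.** Genes are placed on a D. melanogaster-like cytological
map: arms X, 2L, 2R, 3L, 3R (20 numbered divisions each, divisions 1–100)
plus the dot chromosome (arm 4, divisions 101–102). Default euchromatic
arm lengths (22.4, 23.0, 21.1, 24.5, 27.9, 1.35 Mb) are close to the
genome assembly. Genes are assigned to arms proportionally to length,
placed uniformly, and binned linearly into divisions. The default gene
count, 8073, is the number of unique analyzable gene IDs in the emulated
experiment.

**Truth.** A fraction (default 10%) of genes is "rDNA-sensitive". Each
sensitive gene draws a base log2 fold-change for the gross-deletion
contrast from N(0, 0.38²) truncated at ±2 (redrawn, not clipped); the
per-genotype effect is the base effect times a severity factor
(wild-type 0, mild-1 0.30, mild-2 0.35, gross 1.0). Consequences, by
construction: effect signs are identical across genotypes and sexes;
magnitudes scale with deletion severity; and ~87% of sensitive genes
change expression by at most 50% (|2^e − 1| ≤ 0.5), matching the
observation that most responses to rDNA deletion are small. The severity
factors are free simulation parameters, not biological claims; they are
chosen so that mild DE sets nest within the gross set under realistic
noise. The effect-size distribution itself is a design choice — the real
distribution is unknown — anchored only to the small-effect fraction.

**Females.** The XXY-female experiment is modelled as the same truth
table with all effects multiplied by a sex-attenuation factor (default
0.6) plus independent array noise. This encodes "same genes, same
directions, smaller responses and fewer detections in females" without
asserting a mechanism; the factor is a free parameter.

**Arrays.** Per gene, a baseline average log2 intensity A ~ N(10, 1.2²)
plus per-spot jitter N(0, 0.15²). The observed log-ratio per spot is
M = (effect of red-channel genotype − effect of green-channel genotype)
+ dye_bias(A) + N(0, noise_sd), with noise_sd defaulting to 0.25 (0.2 in
power analyses). The dye bias is a quadratic in (A − 10) with default
coefficients (0.15, −0.06, −0.015), giving loess normalization a real
intensity-dependent trend to remove. Channel intensities are
reconstructed as 2^(A ± M/2). A 2% fraction of spots fails QC at random.
Not simulated: spot morphology, background, print-tip structure, scanner
artifacts, and gene–gene correlation; intensities are generated directly
at the foreground level. Passing tests therefore show correctness and
calibration of the statistics under their nominal model, not robustness
to every artifact of real arrays.

**qPCR.** Ct(genotype) = base_ct − log2(copy fraction) + biological
N(0, ct_sd) shared across technical replicates + technical N(0, ct_sd);
defaults 5 biological × 3 technical replicates, ct_sd = 0.05 cycles.

All generators are bit-reproducible given parameters and a seed. The
pipeline expands one global seed into per-stage seeds by SHA-256 hashing
of the stage name, so stages can be re-run in isolation.

## Statistical methods

**Normalization.** Within each array, M is regressed on A by robust
local linear regression (loess, span 0.4, 3 robustness iterations, delta
speed-up of 1% of the A range) and replaced by the residuals. Arrays
with fewer than 20 pass-QC spots are rejected.

**Differential expression.** Because every mutant is compared directly
to the wild-type on the same arrays, a contrast is a one-sample problem
on dye-oriented M values (mutant-minus-reference). Per gene: mean
(log FC), unbiased variance s², df = n − 1; genes with fewer than 2
usable observations are not tested. Variances are moderated
empirical-Bayes style: the prior (d0, s0²) is estimated by matching
moments of log s² (digamma/trigamma corrections, trigamma inverted by
Newton iteration), then s²_post = (d0·s0² + df·s²)/(d0 + df) and
t = logFC / sqrt(s²_post/n), referred to Student's t on df + d0 degrees
of freedom, capped at the pooled residual df across genes (the standard
convention; the implementation is verified against R/limma's eBayes in
the test suite, which is used only as a cross-check oracle). d0 ≥ 1e6 is
treated as infinite. If every gene variance is zero the test falls back
to d0 = ∞ with a tiny positive prior variance and warns. The moderated F
of a single contrast is t². Raw p-values are Benjamini–Hochberg adjusted;
the default DE call is raw p < 0.001 and BH-adjusted p < 0.05, with the
ladder {0.05, 0.01, 0.005, 0.001} reported.

**Permutation FDR.** "Randomized versions of the dataset" are produced
by balanced sign flips: exactly half of a contrast's arrays (±1 for odd
counts) have their oriented M vector negated, re-randomizing the dye
assignment. Independent Bernoulli flips were rejected deliberately: with
6 arrays they leave |mean sign| ≥ 1/3 with probability 0.69, so genuine
effects leak into the null and the FDR is overestimated on datasets with
real signal; balanced flips cancel a common shift exactly while leaving
symmetric noise distributions unchanged. The FDR estimate at a cutoff is
the mean permuted discovery count divided by the observed count (capped
at 1; undefined-with-flag when the observed count is 0).

**Overlap between DE sets.** Two routes, kept deliberately separate: a
Monte-Carlo null that draws two uniform subsets of the matched sizes
from the universe and counts the intersection (empirical p with the
add-one convention, so never exactly 0), and the closed-form
hypergeometric distribution of that intersection, which serves as the
exact oracle the Monte-Carlo must converge to. The universe defaults to
the genes tested in both contrasts, and is an explicit parameter: the
choice materially changes the null mean, and the original analysis does
not state its universe. A third, fully empirical route re-analyses
balanced-sign-flipped versions of both datasets and intersects the
resulting calls. Direction concordance over an intersection is a 2×2
up/down table with a two-sided Fisher exact test. Fold-change
concordance is Spearman's ρ (average ranks, large-sample p), on signed
or absolute log fold-changes, over all shared tested genes or a DE-set
filter — both modes exist because the original figure does not state
which gene set its correlations used.

**Positional analyses.** Coordinates are 0-based half-open megabase
intervals; a gene belongs to a window iff its point position lies in
[start, start+width). Per-division DE counts are corrected by the
per-division count of represented (array-analyzable) genes; smoothing is
a centered 5-division moving average computed within each arm with
truncation at arm ends (no wraparound). The sliding scan (default 2-Mb
windows, 1-Mb steps; the last window of an arm truncates at the arm end
so that step = width tiles it exactly; arms shorter than the window get
one window) draws 1000 random gene sets of the DE set's size from the
represented genes and computes per-window empirical p-values against the
same window's null counts; a family-wise max-over-windows p is also
reported, since the original analysis does not state whether its
per-increment test was multiplicity-corrected. Boundary checks count DE
genes among the n nearest a chromosome end (proximal = centromeric end,
distal = telomere) with a binomial tail under the genome-wide DE rate.
Arm frequencies are tested by chi-square goodness-of-fit against the
representation expectation, with a per-arm exact binomial
(Bonferroni-combined) fallback when any expected count is below 5.

**Detection extrapolation.** Relative change per significant gene is
(2^|logFC| − 1)·100%, binned into [0,10), …, [40,50), [50,∞) percent —
|logFC| folding is used because the original axis does not distinguish
direction. Ordinary least squares on the four bins 10–20 … 40–50 against
bin index x = 2…5, projected to x = 1, estimates what a fully powered
experiment would have found below 10%; the excess over the observed
first bin is the estimated number of genes escaping detection. Negative
projections clamp to 0 with a flag. Regression on bin index rather than
midpoints is an affine reparameterization with identical projection.

**Enrichment.** One-sided hypergeometric upper-tail per flat category
label (no ontology DAG). The default multiplicity correction multiplies
each raw p by the number of categories containing at least one DE gene
(the cited enrichment tool's "modified Bonferroni"); plain Bonferroni
over all categories is available, since the exact denominator used
originally is not recoverable.

**Copy number.** Technical replicates are averaged within biological
replicates; each biological replicate's relative quantity is
efficiency^(mean reference Ct − replicate Ct) with efficiency default 2
(configurable in (1, 2]); the genotype estimate is the mean across
biological replicates, rescaled so the reference genotype reads exactly
100%, with the SD across biological replicates scaled identically. No
normalizer locus is required (the emulated assay design makes the rDNA
signal directly comparable), but a normalizer column is accepted.

## Numerical choices and degenerate inputs

- Trigamma inversion: Newton iteration from x = 0.5 + 1/y, 50-iteration
  cap, relative tolerance 1e-10; closed-form limits for y > 1e7 and
  y < 1e-6.
- Effect truncation uses rejection sampling, so no probability mass
  accumulates at ±max_abs_effect.
- Empirical p-values use (1 + #{null ≥ observed})/(reps + 1) throughout.
- Ratio profiles flag divisions with zero represented genes as NaN
  rather than dropping them.
- An empty DE set yields all-zero scans with p = 1 everywhere; an empty
  overlap intersection yields a zero direction table with the p-value
  flagged undefined; a zero observed DE count makes the permutation FDR
  undefined-with-flag instead of dividing by zero.
- Spot tables may contain duplicate spots per (gene, array); they are
  averaged after normalization.

## Problem sizes

Default analyses run at the emulated study scale: 8073 genes, 3
contrasts × 6 arrays, 10,000 overlap-null replicates, 1000 window-scan
randomizations. The validation suite uses 1200–8073 genes depending on
the property under test, and 2000–20,000 Monte-Carlo replicates chosen
so that each check's tolerance (binomial or oracle-based standard
errors) is meaningful.

## Known limitations

- Homoscedastic noise across genes makes the estimated prior df large;
  variance moderation is exercised, but its benefit over the ordinary t
  is smaller than on real arrays with heavy-tailed variances.
- The multi-array linear model is deliberately reduced to per-comparison
  one-sample fits, which matches the direct-comparison design but would
  not extend to connected designs with indirect contrasts.
- Venn tabulation is limited to 3 sets; no graphical output.
- The generator does not model correlated gene modules, so overlap and
  enrichment nulls are slightly conservative relative to real data.
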
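# Methods

`texqtl` implements the statistics of target-enriched extreme-QTL (X-QTL)
mapping: bulked-segregant analysis of very large F2 populations in which
only a panel of SNP markers is sequenced, at high depth, in each phenotypic
bulk. This note records the models, the numerical choices, and what the
simulations do and do not establish.

## The measurement model

An F2 population segregates two parental alleles (call them A and B) at
every marker. Truncation selection of a phenotypic bulk shifts the allele
frequency at markers linked to trait loci; sequencing the pooled DNA of a
bulk at depth *c* yields per-marker read counts `(countA, countB)` whose
expectation reflects the bulk allele frequency *p*. Two bulks are compared
per marker with the likelihood-ratio (G) test on the 2x2 allele-by-bulk
table,

    G = 2 * sum_cells O * ln(O / E),   p-value from chi-square(1 df),

and genome-wide significance is controlled with Benjamini–Hochberg FDR.

Read noise is suppressed by the smoothed statistic G': a tricube-weighted
moving average of G over a genetic-distance window,

    G'(x) = sum_j w_j G_j / sum_j w_j,   w(d) = (1 - |d/h|^3)^3,  |d| < h,

with kernel halfwidth *h* equal to half the window. The default window is
36 cM — equivalent to 9 Mb at the default uniform map of 4 cM/Mb — applied
per chromosome in genetic coordinates, truncated (and renormalized) at
chromosome ends.

## Forward simulator

Meiosis follows the Haldane model: crossovers per gamete per chromosome are
Poisson with mean length/100 cM, uniformly placed, no interference. Gametes
are generated with the exact Markov-chain form of this process at the
marker positions — parental origin switches between adjacent markers with
probability `r = (1 - exp(-2 d/100)) / 2` for spacing *d*. Because trait
loci are snapped to markers, this is the exact marginal law of the
continuous crossover process; nothing is approximated. Spontaneous
mutation flips alleles at gamete formation with probability 7.0e-9 per
locus, which is retained for completeness though numerically negligible.

Phenotypes are additive over the QTL: effect `sqrt(f_k)` on centred allele
dose for a locus carrying a fraction `f_k` of the genotypic variance, plus
a normal environmental deviate with `Ve = Vg (1 - h2) / h2` computed from
the realized genotypic variance. Bulks are the top/bottom (two-tailed) or
top/random-control (one-tailed) 10% of phenotypes; ties are broken by a
seeded shuffle so bulk sizes are exact. Sequencing draws
`countA ~ Binomial(depth, p)` at fixed nominal depth (a Poisson-depth mode
exists for the coverage-dispersion QC); an exact-tally mode stands in for
individual genotyping in the population-size panel.

Default study conditions for the power analysis: 5 chromosomes of 100 cM,
5 markers/cM, one QTL per chromosome (variance fractions 70/10/10/5/5%, or
five equal 20%), population 10,000, bulk fraction 0.1, G test with BH at
0.01, 100 replicates per grid cell.

*Detection scoring.* A QTL counts as detected when at least one
BH-significant marker lies within 10 cM of it, with each significant
marker assigned only to its nearest QTL. The 10 cM window is a package
choice (exposed as a parameter): with one QTL per chromosome it behaves as
"any significant marker near the locus" while preventing a marker from
counting for two loci.

*A calibration caveat.* Read sampling sits on top of the finite bulk's own
allele sampling, so at depths comparable to the number of bulk chromosomes
the raw G statistic is overdispersed relative to its nominal chi-square
null. This is a property of the measurement, not a bug; it is why the
G'/empirical-null route exists for mapping. The BH false-positive
guarantee is therefore checked in exact-tally mode, where the G-test null
is correctly calibrated.

## Marker-level pipeline for real count tables

1. **Replicate pooling.** With biological replicates, each marker is
   screened with repeated G tests: `G_total = sum_r G_r` decomposes into
   `G_pooled` (summed table) plus a heterogeneity component
   `G_het = G_total - G_pooled` on R-1 df. Markers with heterogeneity
   p < 0.01 (per marker, no multiplicity correction; configurable) are
   dropped, the rest pooled by summing counts.
2. **Depth normalization.** Target-enrichment coverage is grossly
   over-dispersed relative to Poisson (the `coverage_dispersion` QC
   compares the observed IQR with the Poisson IQR at the observed mean).
   Markers at or above a threshold in *every* bulk are downscaled
   proportionally so each bulk sums exactly to the threshold (A rounded to
   nearest, B = threshold - A); markers below it in any bulk are dropped,
   keeping the 2x2 table balanced.
3. **Empirical null and FDR.** The null G' sample comes from G tests
   between the *same* bulk of different replicate pairs (all pairs
   pooled), smoothed with the standard window, and fitted by maximum
   likelihood to a log-normal (zeros excluded with a logged count).
   Per-marker one-sided upper-tail p-values are BH-adjusted; markers with
   adjusted p < 0.01 are significant. Which replicate pairings form the
   null is an open choice; within-bulk pairs are the conservative one
   (no biological signal at all).

## Peak calling by model selection

A chromosome's QTL model is a set of QTL markers with bulk allele
frequencies. The expected G' curve of a model is built from recombination:

* **Two-locus decay** distal to the outermost QTL:
  `p_m = p_q (1 - r) + (1 - p_q) r`.
* **Three-locus interpolation** between adjacent QTL: the two flanking QTL
  states get a joint law constructed by tilting the unselected
  no-interference haplotype law with independent per-QTL selection
  weights. Tilting preserves the haplotype odds ratio
  `((1 - r12)/r12)^2`, so the joint is the closed-form Plackett 2x2 table
  with the stated margins; the marker then follows the flanks through
  independent crossovers in the two intervals. The construction is
  validated against a Monte-Carlo meiosis + acceptance-resampling oracle
  (agreement within Monte-Carlo error across a grid of frequencies and
  spacings) and is isolated in one function so it can be swapped.
* Frequencies map to expected G via the expected-count table at the
  working coverage (the normalization threshold), and expected G smooths
  to expected G' with the same tricube window. In the two-tailed design
  the low bulk is assumed to respond symmetrically (frequency `1 - p`);
  one-tailed uses a flat 0.5 control.

The search: candidate QTL markers are the strict local maxima of observed
G' plus the local minima of |dG'/dx| (slope of an ordinary linear
regression over the same window) — the latter capture the shoulders of
merged peaks, which are *not* maxima. Candidate frequencies invert the
one-to-one frequency-to-G' map at the observed G' (monotone bisection to
1e-6), oriented by the sign of the observed between-bulk frequency
difference. Backward elimination removes the QTL whose removal most
decreases

    BIC = 2 n ln(RMSE) + 2 m ln(n),

(n markers, m QTL, RMSE over all markers of the chromosome, floored at
1e-12) until no removal helps; ties break toward the lower fitted G'.
Refinement is coordinate descent per QTL: a 0.005-step frequency grid at
fixed position, a position scan over markers within half a window, and a
local joint polish (±2 markers x frequency grid), iterated to a fixed
point (hard cap 50 passes); elimination and refinement then alternate
until stable. The procedure is deterministic given the profile.

**Resolution floor.** Two QTL closer than about half the smoothing window
are not identifiable from the smoothed curve, while BIC at n = 500 markers
accepts any QTL improving RMSE by ~1.2% — enough for noise to split one
peak in two. The caller therefore enforces a minimum inter-QTL separation
(default window/2 = 18 cM) in candidate deduplication and refinement
moves. This floor reproduces the calibration behaviour of the method:
equal-frequency QTL merge essentially always below ~16-20 cM and separate
reliably beyond ~24-28 cM at the 36 cM window, with zero false peaks.

**Support intervals.** Residuals are treated as iid normal, so
`n RMSE^2 / sigma^2` is chi-square(n); the upper bound of the (1-alpha)
interval for sigma is `sqrt(n / chi2_{alpha/2, n}) * RMSE`. The focal QTL
slides to nearby markers (all other parameters fixed) and the interval is
the maximal contiguous run around the peak whose RMSE stays below the
bound; intervals touching a chromosome end are flagged clipped.

*Known limitation.* In single-QTL simulations at 5000x the interval covers
the true QTL marker in only ~50% of runs, not the nominal 95%: at n = 500
the bound admits only a ~6.6% RMSE increase (an interval of one or two
markers) while the position estimate itself wanders one or two markers.
The iid assumption ignores both the smoothing-induced residual correlation
and the estimator's own noise. The interval is reported as specified; read
it as a goodness-of-fit profile around the peak, not as a calibrated
confidence interval.

## Window-size calibration

Calibration chromosomes impose QTL allele frequencies directly: the high
bulk's frequency curve is the model's own expected curve around QTL at the
stated frequency (0.6), reads are binomial at 5000x, the comparison bulk
sits at 0.5 (high-vs-control design), 100 cM chromosome, 5 markers/cM. An
optional finite-bulk mode replaces the deterministic curves with the
frequencies of a sampled pool of gametes drawn from the conditional
Haldane Markov chain given their QTL alleles (exact two-state bridges
between QTL); it adds the haplotype-block noise of a real bulk and doubles
as an independent oracle for the three-locus curve, but the deterministic
mode is the calibration default. The G' significance line for these runs
is the upper 1% tail of a log-normal fitted to matched null simulations
(no QTL). A called peak is scored false when it lies more than half a
window from every true locus, so a legitimately merged two-QTL peak is
never scored false.

## What the synthetic data do not show

The simulator draws reads binomially at a nominal depth: it does not model
capture bias between alleles, the heavy-tailed coverage distribution of
target enrichment (which enters the pipeline only through normalization
and QC), base-calling error, or mis-mapping. Phenotypes are strictly
additive — no dominance, epistasis, or genotype-by-environment structure —
and meiosis has no crossover interference. Passing the simulation suite
therefore establishes the statistics conditional on this idealized
generative model, not robustness to those real-data artefacts.

## Problem sizes

Power cells simulate 10,000 individuals x 2,500 markers per replicate;
the shipped test suite runs 25-50 replicates per cell (the acceptance
script defaults to 100, matching the study conditions) and 50-100
replicates per calibration distance. These sizes keep a full run on a
single desktop core in the minutes range.
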
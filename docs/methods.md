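# Methods

This note documents the statistical model behind `rccpsa`, the defaults it
fixes where the underlying method leaves room, and what the synthetic data
used in testing does and does not show about real cohorts.

## Signature construction

A gene is *subtype-specific* for subtype s when (a) its median linear
expression in s is at least `min_fold` (default 2) times the median in
*each* of the other two subtypes, with a pseudocount of 1e−6 in the
denominator to guard against zero medians, and (b) a one-sided Wilcoxon
rank-sum test of s against each other subtype is significant at `alpha`
(default 0.05) after Holm correction. The Holm family is the pair of
contrasts belonging to one gene: the fold filter already restricts
attention to candidate genes, and correcting each gene's two contrasts
keeps the criterion meaningful at the small per-subtype sample sizes
(≥ 3) the selection accepts. Genes are ranked by the *minimum* of their
two pairwise fold changes, descending, with ties broken lexicographically
by gene identifier so the ranking is deterministic.

The signature matrix holds the median linear expression per subtype over
the training samples for the top-k genes per subtype (k = 58 gives the
canonical 174-gene matrix). Medians on the linear scale keep the columns
non-negative and robust to outlying samples.

Signature size is selected on an independent tuning cohort: for k on a
grid (default 2, 4, …, 100) the tuning samples are deconvolved with the
k-matrix, and Δ_k is the mean per-sample L1 distance between proportion
vectors under consecutive matrices. The largest k with Δ_k ≥ `change_tol`
(default 0.01, i.e. a 1-percentage-point average reassignment) is kept.
"Substantial change" is inherently a judgment call; the mean L1 shift
makes it a single interpretable number on the proportion scale.

## Deconvolution and standardization

Deconvolution is intrasample: the sample vector over the signature genes
and each signature column are independently mean-centered and scaled to
unit *sample* standard deviation (n−1 denominator; fixed so tests are
exact). Standardizing per sample across the signature genes — rather than
per gene across samples — is what makes the method reference-free: no
cohort-level normalization or batch correction is needed, and multiplying
a sample by any positive constant provably leaves its result unchanged.

Weights come from Huber M-estimation without intercept (tuning constant
1.345, IRLS with the residual scale re-estimated each iteration as
MAD/0.6745 about zero, relative parameter tolerance 1e−8, at most 200
iterations). An exact fit freezes the scale so the weights stay at one.
The solver is vectorized over many response vectors sharing the design,
which is what makes permutation nulls and cohort runs affordable; it
cross-checks against an independent robust-regression implementation to
1e−6 in the test suite.

Because the regression runs in standardized space, a linear-space mixture
α·cc + β·p + γ·h appears with coefficients α·sd_cc/sd_y and so on. The
reported proportions therefore divide the raw coefficients by the
signature-column standard deviations before truncating negatives to zero
and renormalizing to sum 1. Without that rescaling the spec-level
invariant "noiseless mixtures are recovered exactly" cannot hold whenever
the three columns have unequal spread, which they always do in practice.
If no weight is positive the sample is *non-decomposable*: no non-negative
subtype combination explains it, and an error is raised rather than a
fabricated composition. The permutation p-value is computed before that
check and attached to the error, so null-calibration studies suffer no
selection bias.

The goodness-of-fit statistic is the Pearson correlation between observed
and reconstructed vectors. Significance permutes the sample's standardized
values across gene positions (B = 999 by default, minimum 99) and uses the
add-one estimator p = (1 + #{null ≥ observed})/(B + 1), which is never
zero and is exactly uniform under the null by exchangeability. Cohort runs
derive one random stream per sample from the master seed and the sample
index, so results are independent of evaluation order and threading.

Calls: `p_psa` > 0.05 → non-significant; otherwise max proportion ≥ 0.95
→ unambiguous for that subtype; otherwise heterogeneous. Both thresholds
are configuration defaults.

## Prognostic index and risk groups

The packaged prognostic model is the fixed cubic
PI = 14.71·c − 25.46·c² + 12.21·c³ − 1.46 on the 0–1 ccRCC-proportion
scale, with HR = exp(PI). Its constant is retained verbatim and read as a
centering of the linear predictor; refitted models instead center the PI
to mean zero over their own training samples, since a Cox partial
likelihood does not identify an intercept.

Model refitting maximizes the Efron-tie partial likelihood over a cubic
polynomial basis or a restricted cubic spline (Harrell basis, default 4
knots at the 0.05/0.35/0.65/0.95 score quantiles). The raw polynomial
columns are nearly collinear on [0, 1] and stall Newton–Raphson far from
the optimum; the fit therefore runs on a QR-orthonormalized, centered
basis and maps coefficients and covariance back exactly — a pure
reparameterization of the same likelihood. Monotone likelihoods fall back
to a ridge penalty of 1e−4 with a warning. Model comparison offers
repeated stratified 10-fold cross-validation (held-out Efron partial
log-likelihood and Harrell C-index; fold assignment stratified by event
status and shared across candidates), full-data AIC = −2·logPL + 2·k, and
analysis of deviance for nested pairs (constants are not counted as
parameters, so null vs cubic has 3 df).

Risk-group discovery mimics a conditional inference tree with a survival
endpoint: at each node the candidate threshold (midpoints between
consecutive PI values leaving ≥ 20 samples per side) maximizing the
two-sample log-rank statistic is taken, and the split is accepted only if
its asymptotic χ²(1) p-value, Bonferroni-multiplied by the number of
candidates at that node, is below 0.05. Depth is capped at two and only
the more significant child split is accepted, so at most three leaves
arise — matching the intended good/intermediate/poor stratification.
Leaves are ordered into labels by their Cox-estimated hazard, not by PI
position, and group HRs are reported against the good group. Boundary PI
values assign to the lower-risk side (an arbitrary but documented
convention). If no split passes the gate, a single flagged group is
returned rather than an error.

Kaplan–Meier curves, the k-group log-rank test and one-factor Cox hazard
ratios come from lifelines; the Holm step-down adjustment is implemented
directly (sort ascending, multiply the i-th by m−i+1, cumulative-maximum,
cap at 1) and cross-checked against statsmodels.

## Synthetic data

The generators encode the structure the method assumes, with one
configuration object fixing the study conditions: 2000 genes of which 60
per subtype are planted markers at 8-fold up-regulation; multiplicative
lognormal noise with CV 0.05 (mean 1, standard for expression data);
cohorts with 70 % pure samples and 30 % drawn from Dirichlet(2, 2, 0.3),
an asymmetric law favoring clear-cell/papillary mixtures, echoing that
heterogeneous tumors are mostly ccRCC/pRCC blends; exponential survival
with rate 0.1·exp(PI(c)) per year and uniform censoring tuned by bisection
to a 30 % censoring fraction. All draws descend from a single seed;
identical configurations reproduce byte-identical outputs.

What passing tests show — and what they do not: mixtures here are exact
convex combinations of the very signature columns used for deconvolution,
plus independent multiplicative noise. Real tumors violate this in ways
the simulation deliberately omits: stromal and immune admixture,
batch/platform effects, FFPE degradation, correlated gene noise, and
reference profiles estimated from finite, imperfectly labeled cohorts.
Recovery of proportions to 1e−4 (noiseless) or MAE < 0.05 (5 % noise)
therefore validates the estimator's correctness, not its field accuracy.

## Problem sizes and numerical choices

Test and acceptance runs use a 1200-gene, 45-sample training cohort,
174-gene signatures, 1000-sample deconvolution cohorts, 500 × B=999
permutation replicates for null calibration, n = 800 with 20 seeds for
Cox coefficient recovery and n = 600 with 20 seeds for cutpoint recovery
— sizes chosen so each property is measured with comfortable statistical
resolution while the whole suite stays quick on a single CPU.

Degenerate inputs are errors, not silent results: constant vectors
(standardization), collinear signature columns (singular design),
all-censored survival, constant scores, out-of-range proportions and
p-values. Duplicate gene rows collapse to the row with the maximum mean
(a common microarray convention, logged); duplicate sample identifiers
are refused. Expression matrices declare their scale explicitly, and
log2 → linear conversion refuses an already-linear matrix so data can
never be exponentiated twice.

## Known limitations

- The published 174-gene list and the published risk cutpoints are not
  bundled; the packaged signature machinery reproduces the construction
  recipe, and a real signature in the same TSV format can be dropped in.
- The permutation scheme (values permuted across gene positions, fit
  correlation as statistic) is this package's concrete instantiation of a
  permutation significance test for deconvolution; other choices would
  give different absolute p-values with the same calibration guarantee.
- Whether weights should be constrained non-negative during fitting
  rather than truncated afterwards is an open modeling question; the
  truncate-then-renormalize rule is fixed here because proportions must
  be non-negative and sum to 100 %.
- Multivariate clinicopathological Cox modeling beyond a single score
  covariate, and treatment-trial stratification, are out of scope.
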
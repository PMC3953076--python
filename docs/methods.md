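# Methods

This note documents the statistical model behind `snpmeta`, the choices
made where conventions genuinely differ between software packages, and what
the simulation-based tests do and do not establish.

## Effect derivation

For a biallelic SNP with risk allele R, genotype counts (n_RR, n_RN, n_NN)
in cases and controls are collapsed to a 2×2 table under one of three
genetic models:

| model | exposed (a / c) | unexposed (b / d) |
|---|---|---|
| allele contrast | 2·n_RR + n_RN (allele count) | 2·n_NN + n_RN |
| dominant | n_RR + n_RN (carriers) | n_NN |
| recessive | n_RR | n_RN + n_NN |

The log odds ratio is ln(ad/bc) with Woolf's standard error
√(1/a + 1/b + 1/c + 1/d) and a Wald CI on the log scale. Degenerate
tables are handled by the Haldane–Anscombe rule: if any raw cell is 0, add
0.5 to all four cells and flag the estimate `corrected`. The correction is
triggered *only* by a zero cell, never applied routinely, so ordinary
tables are left untouched. An empty case or control group is an error, not
a correctable table.

Studies that publish only an OR with CI are converted back to
(log OR, se) via se = (ln U − ln L)/(2z). The z quantile is computed from
the normal distribution at the stated confidence level (1.959964… at 95%),
not hard-coded at 1.96; the reconstruction assumes the source built its CI
the same way, which is the standard convention but cannot be verified from
a printed interval. When a study provides both counts and a reported
effect, the counts win (they support all three models and avoid the
reconstruction assumption) and the choice is logged.

A note on symmetries used in the tests: swapping exposed/unexposed columns
negates the log OR, and transposing the table (exposure as rows) preserves
it; swapping the case/control *rows* inverts the OR — the three behave
differently and the test-suite asserts each one separately.

## Hardy–Weinberg screening

Controls are tested against HWE proportions (p², 2p(1−p), (1−p)²) with the
plain 1-df Pearson chi-square on the estimated allele frequency
p̂ = (2·n_RR + n_RN)/(2n). No Yates correction is applied by default — a
documented switch exists — and monomorphic samples return a degenerate
chi² = 0 flagged `monomorphic`. Studies with p < 0.05 are *flagged*, not
silently dropped: the pipeline's `hwe_policy` selects flag-only reporting,
exclusion, or both runs side by side, so the sensitivity of the pooled
estimate to HWE violations is itself part of the output. The 0.05
threshold matches the two-sided α used everywhere else in the package.

## Pooling and heterogeneity

Fixed-effect pooling is inverse-variance weighting w_i = 1/se_i²; it
yields Cochran's Q = Σ w_i (y_i − ŷ)² (χ² with k−1 df under homogeneity)
and I² = max(0, (Q − df)/Q)·100.

The random-effects estimate is one-step (non-iterated) DerSimonian–Laird:
τ² = max(0, (Q − (k−1))/C) with C = Σw − Σw²/Σw, then re-weighting by
w*_i = 1/(se_i² + τ²). Inference on the pooled log OR is a plain two-sided
Z-test with se = 1/√Σw*; no Knapp–Hartung adjustment and no alternative τ²
estimators (REML, Paule–Mandel) are offered — the one-step moment
estimator has a closed form that an independent transcription can verify
to machine precision, which is the backbone of the test suite. With a
single study the random-effects pool falls back to the fixed pool with a
logged notice. Random-effects is the headline output; the fixed-effect
row is always computed alongside.

## Subgroups and meta-regression

Subgroup analysis pools each stratum with DL (separate per-stratum τ²) and
tests between-stratum heterogeneity with Cochran's Q over the stratum
summaries, Q_between = Σ_g W_g (μ̂_g − μ̄)², W_g = 1/pooled_se_g², χ² with
G−1 df. Because each stratum carries its own τ², the classical identity
Q_within + Q_between = Q_total holds only for the all-fixed-weight variant;
that variant is retained as an internal oracle
(`q_decomposition_fixed`) and asserted exact in the tests, while the
reported statistic uses the random-effects stratum estimates (the common
"test for subgroup differences"). Four factors are built in: ethnicity,
sample size with the Large threshold at ≥500 cases (inclusive), control
source (population vs. hospital), and disease subtype — unsplit ("Mixed")
cohorts contribute to every analysis except the subtype contrast.

Meta-regression is the two-pass method-of-moments scheme: a 1/se² weighted
fit gives residual Q_E; τ² = max(0, (Q_E − (k−p)) / (Σw −
tr((XᵀWX)⁻¹XᵀW²X))); a final fit with weights 1/(se² + τ²) gives Wald z
tests per coefficient. MM was chosen over REML for the same reason as DL:
closed form, independently checkable, and with an intercept-only design it
reduces *exactly* to the DL pool — asserted to 1e−8 in the tests.
Categorical covariates are expanded to indicator columns (first level as
reference); rank-deficient designs raise an error naming the collinear
columns, and studies missing a requested covariate are dropped with a
logged count.

## Publication bias and sensitivity

Egger's test is the original unweighted OLS of the standardized effect
y_i/se_i on precision 1/se_i, with a two-sided t-test on the intercept at
k−2 df; weighted variants exist but are deliberately not used. When all
se are equal the precision column is constant and the regression is
degenerate; the result is flagged `low_dispersion` rather than silently
reported.

Begg's test uses the variance-stabilized deviates
u_i = (y_i − ŷ_fixed)/√(v_i − 1/Σw) and Kendall's S statistic against the
variances, with the continuity-corrected normal approximation
z = (|S|−1)/√(k(k−1)(2k+5)/18) (no tie correction; deviates from real
data are continuous). The implementation computes S by vectorized sign
counting and is checked against an explicit O(k²) pair loop.

Leave-one-out re-pools with DL after omitting each study in turn and
reports the largest absolute shift of the pooled log OR. Bonferroni
adjustment defaults to m = 3, the number of genetic models tested per SNP;
m is configurable and is raised automatically if more models are run.

Funnel output is data-only (points and pseudo-95% guide lines over an se
grid); rendering is left to the caller.

## The simulator

Each synthetic study draws control genotypes multinomially from HWE
proportions at an ethnicity-specific risk-allele frequency and case
genotypes from the exponentially tilted law P(g | case) ∝ P(g | control) ·
exp(θ_i g), the logistic per-allele model. Tilting HWE proportions yields
HWE case proportions with allele odds multiplied by exp(θ_i), so the
population allele-contrast OR equals exp(θ_i) *exactly*, and the
genotype-level ORs are exp(θ_i) and exp(2θ_i); recovery tolerances in the
tests rely on this identity. Study effects are θ_i = ln(true OR) +
N(0, τ²), the additive model DL assumes.

Defaults describe a 9p21-like ischemic-stroke literature: 21 studies;
per-allele OR 1.11; τ = 0.04 (between-study sd of the log OR, giving the
mild I² ≈ 20–30% typical of such literatures at these study sizes); risk
allele frequencies 0.48 (Caucasian), 0.50 (East Asian), 0.25 (African
American) — near one half in European/East-Asian ancestry and
substantially lower in African ancestry, a qualitative pattern only, since
printed per-population frequencies are not available; ethnicity mix
26:5:4; case counts drawn log-uniformly on [150, 12500] and controls on
[250, 65000], matching the orders-of-magnitude spread of real
association literatures; ~6% hospital-based controls. Covariates (age,
sex, BMI) are plausible fillers for exercising meta-regression, not
calibrated to any cohort.

RNG: every study uses `default_rng([seed, study_index])`, so changing k
extends the table without reshuffling earlier studies, and a seeded run is
bitwise reproducible.

What the simulator does *not* emulate: linkage disequilibrium among proxy
markers (the input table is assumed already harmonized to one marker and
risk-allele orientation via the `flip` column), genotyping error,
covariate-dependent effects, overlapping control panels between studies,
and selective publication. Passing recovery and calibration tests
therefore shows the estimators are correct under the stated sampling
model, not that real literatures satisfy that model.

## Numerical choices and problem sizes

- All tail probabilities come from scipy's normal/χ²/t distributions; no
  p-value is ever hard-coded.
- τ² and I² are truncated at zero; Q_p is defined as 1 when k = 1.
- Serialization rounds floats to 6 significant digits; NaN becomes an
  explicit missing marker.
- Monte-Carlo validation sizes: 2000 replicates for null calibration of
  the Z-test (binomial s.e. ≈ 0.005 on the rejection rate) and 500 for
  parameter recovery (s.e. ≈ 0.01 on coverage) — large enough that the
  nominal-level checks are meaningful, small enough to run routinely. At
  τ = 0 the DL interval slightly over-covers (empirically ≈ 0.96 at
  k = 21) because τ̂² is truncated at zero; this is a known property of
  the estimator, not a defect of the implementation.

## Known limitations

- Reconstructing se from a printed CI inherits the source's rounding; a
  CI printed to 2 decimals limits se precision to roughly 1%.
- The between-subgroup Q test treats stratum summaries as fixed quantities
  (standard practice); with very few studies per stratum its χ² reference
  is approximate.
- Meta-regression inference is Wald-type with no small-k correction; with
  k close to p the tests are anti-conservative.
- The Begg statistic's normal approximation is poor below k ≈ 10; the
  value of S is still exact.
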
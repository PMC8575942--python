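# Methods

`tsmr` implements two-sample Mendelian randomisation (MR) from GWAS summary
statistics: the estimation of total and direct causal effects of one or more
exposures (the motivating case is systolic and diastolic blood pressure, SBP
and DBP) on disease and lifespan outcomes, using genetic variants as
instrumental variables. This note documents the models, the conventions
chosen where several are defensible, what the synthetic-data generator does
and does not emulate, and known limitations.

## The model

For SNP *j*, let β̂X_j (SE σX_j) be its estimated association with the
exposure and β̂Y_j (SE σY_j) with the outcome, estimated in non-overlapping
samples and aligned to a shared effect allele. Under the instrumental-variable
assumptions each Wald ratio β̂Y_j / β̂X_j estimates the same causal effect θ.

**IVW with multiplicative random effects.** The headline estimator is the
weighted regression of β̂Y on β̂X through the origin with weights 1/σY², i.e.
θ̂ = Σ w_j β̂X_j β̂Y_j / Σ w_j β̂X_j². Cochran's Q on the residuals measures
heterogeneity; the fixed-effects SE is multiplied by max(1, √(Q/(k−1))) —
inflated when heterogeneity exceeds its expectation, never deflated. A single
SNP degrades to the Wald ratio with the first-order delta SE |σY/βX| (the
second-order form adding the exposure term is available by flag; it agrees
with Monte-Carlo propagation to within 2% in the tested regime).

**Weighted median.** Wald ratios are ordered; weights are the inverse
variances of the ratios, normalised; the estimate interpolates the weighted
empirical CDF at 0.5 using the percentile convention with the w_j/2 offset.
Consistent when >50% of weight comes from valid instruments. The SE is a
parametric bootstrap (resampling β̂X, β̂Y from their sampling normals; 1000
replicates by default, seed recorded in the result).

**MR-Egger.** The same weighted regression with an intercept, after
orienting every SNP so β̂X > 0 (the intercept is only identified under a sign
convention; with the generator's convention of reporting the
exposure-raising allele this orientation is a no-op). The slope is the
causal estimate under InSIDE; the intercept estimates average directional
pleiotropy. SEs carry the same multiplicative inflation with k−2 df. The
I²_GX statistic (precision-weighted dispersion of |β̂X|) gauges the
no-measurement-error assumption; below 0.9 the Egger estimate is suspect.
No SIMEX correction is implemented.

**MR-PRESSO.** The global test compares the observed leave-one-out weighted
residual sum of squares with its distribution under `n_sim` parametric
simulations drawing both β̂X and β̂Y from their sampling normals around the
fitted model; empirical p-values use the (1+exceedances)/(1+n_sim)
convention, so the smallest attainable per-SNP p is 1/(n_sim+1) — with
Bonferroni over k SNPs, `n_sim` must exceed ~k/0.05 for the outlier test to
have any power (the default 1000 suffices for k ≤ 50; raise it for larger
sets). The corrected estimate is IVW on non-outliers; the distortion test
compares the corrected-minus-raw shift against removal of random subsets of
the same size. Fewer than 4 SNPs is refused.

**Multivariable MR.** With p exposures, β̂Y is regressed on the k×p matrix
of exposure effects without intercept (weights 1/σY²), giving direct effects
conditional on the other exposures; SEs scale by max(1, √(Q/(k−p))). The
Egger analogue adds an intercept and orients on the first configured
exposure (orientation sensitivity can be probed by reordering). The
multivariable weighted median is implemented as weighted
least-absolute-deviations regression (IRLS), the construction used by the
established multivariable-median implementations, with a parametric
bootstrap SE; a median-of-bootstrap-fits construction was rejected because
every resample carries the full contamination fraction and therefore
inherits the IVW bias. Multivariable PRESSO mirrors the univariable logic
with leave-one-out multivariable residuals.

**Exposure-effect covariance.** SBP and DBP are estimated in the same
sample with phenotypic correlation ρ = 0.69, so their estimation errors
covary: cov(β̂X1_j, β̂X2_j) = ρ σ1_j σ2_j. This enters two statistics:

- *Conditional F (Sanderson–Windmeijer construction).* For exposure e, its
  SNP effects are regressed on the other exposures' SNP effects by iterated
  feasible GLS in which the per-SNP residual variance propagates the
  covariance model, var_j = σe² + δ'Σ_other δ − 2 δ'cov(other,e); the
  conditional F is the residual strength Q_e/(k − p + 1). The denominator
  k − p + 1 (rather than k − p) is used so a single exposure reduces exactly
  to the mean univariable F. Below 10 flags conditionally weak instruments.
  Note a genuine property of the covariance-aware statistic: when the noise
  correlation exceeds the genetic correlation, conditioning *raises* F
  slightly (correlated noise partially cancels), so equality with the
  marginal F holds in the orthogonal limit only for independent samples.
- *Modified Cochran's Q.* Q = Σ (β̂Y_j − θ'β̂X_j)² / s_j² with
  s_j² = σY_j² + θ'Σ_j θ, df = k − p, θ re-estimated under these weights by
  iterated GLS from the multivariable IVW start. Ignoring the covariance
  (ρ forced to 0) visibly inflates Q on correlated data.

**Diagnostics.** Per-SNP F = (β̂X/σX)²; mean F < 10 flags weak instruments.
Variance explained r² = Σ 2p_j(1−p_j)β̂_j² on the SD scale under
Hardy–Weinberg (an F-based approximation Σ F/(Σ F + n − k) is also provided;
the 2p(1−p)β² form is the default). The Steiger directionality test compares
variance explained in exposure versus outcome using the scale-free
summary-data form z²/(z²+n) per SNP — a deliberate convention for binary
outcomes (observed scale, no liability conversion) — with a Fisher-z
statistic on the set-level correlations. Power uses the standard
approximation that an MR design needs the observational sample size divided
by r²: detectable |effect| = (z_{1−α/2}+z_{power})/√(n r² cf(1−cf)), the
case-fraction factor dropping for continuous outcomes; defaults α = 0.05,
power = 0.80.

## Harmonisation conventions

Instruments are variants with p < 5×10⁻⁸ (strict), optionally restricted to
an externally replicated panel, then greedily clumped at r² < 0.001:
repeatedly take the smallest-p unclaimed variant as index and discard
unclaimed variants with r² ≥ threshold to it; ties break lexicographically
by rsID so the result is order-independent. Variant pairs absent from the
LD reference count as unlinked (with a warning; strict mode raises). When a
variant instruments several exposures it enters the merged multivariable
set with its smallest p-value.

Alignment flips the outcome beta (and eaf) when effect/other alleles are
swapped, tolerating strand flips. Palindromic variants (A/T, C/G) cannot be
strand-resolved from labels: those with eaf strictly inside (0.42, 0.58) on
either side are replaced by an LD proxy (r² ≥ 0.8, highest r² wins, ties by
rsID) when one is present in all tables, else excluded; the window
endpoints themselves are alignable. Palindromes outside the window align by
matching the minor-allele side across datasets; palindromes missing eaf on
either side are excluded (conservative). Variants missing from the outcome
GWAS are likewise proxy-substituted when possible. Proxies are attempted
only for outcome-missing variants and ambiguous palindromes. Every excluded
or substituted variant is logged with a reason, and the pipeline manifest
aggregates these logs, so |harmonised| + |terminal exclusions| = |instruments|.

The annotation screen removes instruments associated at p < 5×10⁻⁸ with any
listed secondary trait (BMI, education, smoking by default) from a
file-supplied long table (variant, trait, p) — a table-driven stand-in for
an interactive phenome-scan lookup; variants absent from the table pass.

The reader rejects non-SNP and identical alleles, non-positive SEs and
frequencies outside [0,1], counting rejects. p-values are always recomputed
from β/SE by the two-sided normal approximation after any transformation
(the source column is kept as `pvalue_reported`). Fixed-effects IVW
meta-analysis pools variants over the studies that carry them, recording a
per-variant contributing-study count (`n_studies`) so a strict-intersection
analysis is recoverable by filtering; composite endpoints built from
correlated subtypes should then have their SEs inflated by √(LDSC intercept)
— the intercept (1.337 in the motivating analysis) is a configuration
input, never estimated here. Evidence labels: strong iff p < 0.0125,
suggestive iff 0.0125 ≤ p < 0.05 (the boundary falls in the weaker band).

## The synthetic generator

All property and calibration tests run on `tsmr.simulate`, which emulates
the statistical structure of the motivating design. Default conditions:

- two exposures ("SBP", "DBP") with n = 757,601, trait SDs 20.1 and 11.2
  mmHg, per-SD effects; 760 causal SNPs with normal effects correlated at
  a genetic correlation of 0.7 across exposures and scaled so the realised
  causal r² is 0.0351/0.0381 — chosen so that the p < 5×10⁻⁸ subset
  numbers ~250–270 per trait with mean F in the 80s–90s and selected-subset
  variance explained near 2.6–3.3%, the regime of a large replicated
  blood-pressure panel;
- allele frequencies Uniform(0.05, 0.95); SEs 1/√(n·2p(1−p)) for
  continuous traits and 1/√(n·cf(1−cf)·2p(1−p)) for binary ones;
- estimation noise correlated at 0.69 across the exposures (same sample),
  and at overlap_fraction × √0.69 between exposure and outcome when sample
  overlap is switched on (default 0);
- outcomes: a binary composite (n = 420,531, case fraction 0.14, direct
  log-OR effects 0.604/0.166 ≈ OR 1.83/1.18) and a continuous standardised
  lifespan proxy (n = 389,166, direct effects −0.13/−0.07), matching the
  reported direct-effect magnitudes of the motivating analysis;
- pleiotropy off by default; balanced / directional / InSIDE-violating
  modes add a per-SNP outcome-scale term, defined relative to the
  exposure-raising allele; planted gross outliers add a fixed multiple of
  the outcome SE;
- harmonisation obstacles at low rates: one LD satellite per causal SNP
  (r² = 0.95) for clumping and proxy lookup, 5% palindromes (40% of them
  frequency-ambiguous), 3% of variants missing from the outcomes (half with
  a usable proxy), 6% of variants strongly annotated to a secondary trait,
  plus 60 null background SNPs;
- effect alleles are reported as the first exposure's raising allele, a
  common GWAS convention that also makes "directional" pleiotropy
  well-defined.

Deterministic given the seed; `StudyBundle.per_snp` carries the full truth.
What it does **not** emulate: genome-wide LD structure (satellite blocks
only), liability-scale binary traits (log-odds effects with analytic SEs),
winner's curse from discovery-stage selection, population stratification,
and sex-specific standardisation of the lifespan proxy (the outcome is
generated directly as a z-scored trait). Passing tests therefore certify
the statistics, not robustness to those real-data pathologies.

## Numerical choices and problem sizes

Closed-form weighted least squares throughout (no iterative optimisers
except the small IGMM/IRLS loops, tolerance 1e-10/1e-12, capped at 100
iterations); empirical p-values use the +1 convention; normal-theory CIs
everywhere (no t reference); odds ratios are exponentiated views of
log-odds estimates and report tables round to 2 decimals while JSON keeps
full precision. Degenerate inputs: k = 1 degrades IVW to the Wald ratio and
leaves I²_GX undefined; Egger needs k ≥ 3, PRESSO k ≥ 4, the multivariable
estimators k > p (collinear exposure columns raise a named error).

Calibration suites use deliberately modest problem sizes — 500 replicates
at k = 250 for type-I error and coverage, 200 replicates for outlier and
pleiotropy detection at k = 21 and 100 — sized so the full validation runs
in about a minute on one CPU while leaving binomial error bands of ±3%
around the nominal rates. Observed behaviour at these sizes: IVW type-I
error ≈ 0.05; multivariable coverage ≈ 93%, the ~2-point shortfall being
the textbook attenuation from measurement error in β̂X (NOME violation,
I²_GX ≈ 0.9 under the default conditions) which no IVW-family estimator
corrects; the univariable-positive / multivariable-null attenuation pattern
for a mediated second exposure reproduces robustly.

## Limitations

Only summary-data linear/log-linear MR: no individual-level models,
non-linear (J-curve) dose-response, sex-specific analyses, MR-RAPS/CAUSE/
mode-based estimators, liability-scale conversions or winner's-curse
corrections. LD clumping and proxy lookup are table-driven reimplementations
(greedy, deterministic), not queries against a genotype reference panel.
The LDSC intercept is an input, not estimated.
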
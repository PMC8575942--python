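# tsmr — two-sample Mendelian randomisation from GWAS summary statistics

`tsmr` estimates the causal effects of heritable exposures on disease and
lifespan outcomes using genetic variants as instrumental variables, when all
you have are GWAS summary statistics (per-SNP effect, SE, alleles,
frequency) from separate exposure and outcome samples. It was built around a
canonical question in cardiovascular epidemiology — do systolic and
diastolic blood pressure (SBP, DBP) each *directly* raise cardiovascular
risk and shorten lifespan, or does diastolic pressure act only through its
correlation with systolic? — and provides everything that analysis needs as
a reusable library:

- **summary-statistics I/O**: dialect-mapped TSV reading with validation,
  fixed-effects inverse-variance meta-analysis for composite endpoints,
  genomic-control SE inflation by √(LD-score-regression intercept), per-SD
  and per-unit effect rescaling;
- **instrument selection & harmonisation**: p < 5×10⁻⁸ selection, greedy
  LD clumping (r² < 0.001), lower-p retention for SNPs instrumenting
  several exposures, allele alignment with strand-flip tolerance,
  frequency-resolution of palindromic SNPs with an ambiguity window of
  (0.42, 0.58), LD-proxy substitution (r² ≥ 0.8), and a table-driven
  secondary-trait screen — every exclusion logged with a reason;
- **estimators**: per-SNP Wald ratios combined by IVW with multiplicative
  random effects, θ̂ = Σw_jβ̂X_jβ̂Y_j / Σw_jβ̂X_j² with w_j = 1/σY_j² and SE
  scaled by max(1, √(Q/(k−1))); weighted median; MR-Egger with its
  directional-pleiotropy intercept; MR-PRESSO global/outlier/distortion
  tests — and their multivariable analogues for direct effects, including
  the Sanderson–Windmeijer conditional F-statistic and the modified
  Cochran's Q with SNP-effect covariance cov(β̂X1, β̂X2) = ρ·σ1·σ2 from the
  exposures' phenotypic correlation (ρ = 0.69 by default);
- **diagnostics**: per-SNP F, variance explained Σ2p(1−p)β², I²_GX,
  Steiger directionality, power/detectable-effect calculations;
- **a synthetic GWAS generator** with ground truth, emulating the
  two-correlated-exposure design (instrument counts, F distribution,
  case fractions, LD satellites, palindromes, missing variants, optional
  pleiotropy and sample overlap) so the entire pipeline is testable with
  no downloads;
- **a pipeline** (`run_full_workflow`) chaining all of the above into
  labelled result tables (strong: p < 0.0125; suggestive: p < 0.05) with a
  machine-readable manifest, plus a thin `tsmr` CLI.

## Worked example

```python
from tsmr import (SyntheticTruth, generate_study, select_instruments,
                  harmonise, ivw, mv_ivw, conditional_f, ExposureCovarianceModel)

study = generate_study(SyntheticTruth(seed=7))      # SBP, DBP -> CVD, lifespan
sbp = study.exposures[0]
instruments = select_instruments(sbp, 5e-8, study.replicated_flags)
h = harmonise([sbp], study.outcomes["CVD"], instruments, study.ld)
print(ivw(h).exponentiated())
```

Running the bundled narrative scripts prints (abridged):

```text
$ python examples/01_simulate_study.py
SBP: 259 instruments harmonised (10 excluded or proxied)
  mean F = 85.1 (range 29.8-392.5), variance explained = 2.91%

$ python examples/02_total_effects.py
ivw              OR 2.14 (95% CI 2.03, 2.25)  p = 4.2e-186  k = 259
weighted_median  OR 2.15 (95% CI 1.98, 2.32)  p = 3.2e-78   k = 259
mr_egger         OR 2.47 (95% CI 2.10, 2.91)  p = 8.7e-28   k = 259
mr_presso        OR 2.14 (95% CI 2.03, 2.25)  PRESSO global p = 0.620

$ python examples/03_direct_effects.py
SBP: total OR 2.13  ->  direct OR 1.94 (truth 1.83)
DBP: total OR 1.84  ->  direct OR 1.12 (truth 1.18)
conditional F: {'SBP': 46.9, 'DBP': 50.4}
```

Read: each SD of (synthetic) systolic pressure roughly doubles the odds of
the cardiovascular composite in total; jointly modelling both pressures
shows the diastolic total effect is mostly mediated through systolic — its
direct odds ratio collapses towards the generating truth of 1.18 while the
systolic one persists — and conditional F ≈ 47–50 confirms the instruments
still separate the two correlated exposures. `examples/04` builds a
composite endpoint from four disease subtypes with √1.337 SE inflation, and
`examples/05` runs the full labelled workflow per SD and per 10/5 mmHg.

## CLI

```bash
tsmr simulate --seed 7 --out simdir/
tsmr meta --inputs a.tsv --inputs b.tsv --ldsc-intercept 1.337 --out composite.tsv
tsmr run --exposure simdir/exposure_SBP.tsv --exposure simdir/exposure_DBP.tsv \
         --exposure-sd 20.1 --exposure-sd 11.2 \
         --outcome simdir/outcome_CVD.tsv --ld simdir/ld.tsv \
         --proxies simdir/proxies.tsv --annotations simdir/annotations.tsv \
         --out report/
```

See `docs/methods.md` for the statistical conventions, the generator's
assumptions, and known limitations.
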
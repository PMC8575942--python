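"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of the blood-pressure MR
design: two highly correlated exposures (systolic and diastolic BP,
phenotypic correlation 0.69) instrumented by a few hundred genome-wide
significant SNPs explaining ~2.5-3% of variance each, binary cardiovascular
outcomes with realistic case fractions, and a continuous standardised
lifespan outcome.  Per-SNP effect estimates are the true effects plus
sampling noise with standard errors implied by sample size and allele
frequency; estimation noise is correlated across exposures measured in the
same sample, and optionally between exposure and outcome when their samples
overlap.  LD blocks, palindromic variants, variants missing from the
outcome with or without proxies, and an annotation table for the
pleiotropy screen give the harmonisation stage something real to do.

Everything is driven by a :class:`SyntheticTruth` record whose fields are
also the ground truth that recovery tests are scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .harmonise import LDReference
from .sumstats import SummaryStatsTable, table_from_frame

__all__ = [
    "ExposureSpec",
    "OutcomeSpec",
    "SubtypeSpec",
    "SyntheticTruth",
    "StudyBundle",
    "generate_study",
    "generate_composite_subtypes",
    "default_truth",
]

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class ExposureSpec:
    """One exposure GWAS: name, target causal r^2, native-unit SD, sample size."""

    name: str
    r2_target: float
    trait_sd: float | None = None
    n: float = 757_601.0


@dataclass
class OutcomeSpec:
    """One outcome GWAS with its per-exposure direct causal effects.

    ``causal_effects`` are on the outcome scale per SD of exposure
    (log odds ratio for binary outcomes, beta for continuous).
    """

    name: str
    causal_effects: tuple
    trait_type: str = "binary"
    n: float = 420_531.0
    case_fraction: float | None = 0.14
    overlap_fraction: float = 0.0


@dataclass
class SubtypeSpec:
    """A component endpoint of a composite outcome."""

    name: str
    n: float
    n_cases: float
    loading: float = 1.0


@dataclass
class SyntheticTruth:
    """Generating parameters, also the ground truth for recovery tests."""

    exposures: tuple = field(
        default_factory=lambda: (
            ExposureSpec("SBP", r2_target=0.0351, trait_sd=20.1),
            ExposureSpec("DBP", r2_target=0.0381, trait_sd=11.2),
        )
    )
    outcomes: tuple = field(
        default_factory=lambda: (
            OutcomeSpec("CVD", causal_effects=(0.604, 0.166), trait_type="binary", n=420_531, case_fraction=0.14),
            OutcomeSpec("lifespan", causal_effects=(-0.13, -0.07), trait_type="continuous", n=389_166, case_fraction=None),
        )
    )
    n_snps: int = 760
    n_null_snps: int = 60
    genetic_correlation: float = 0.7
    phenotypic_correlation: float = 0.69
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside-violating
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    effect_distribution: str = "normal"  # normal | heavy-tailed
    ld_block_size: int = 2
    ld_within_r2: float = 0.95
    palindrome_fraction: float = 0.05
    ambiguous_palindrome_fraction: float = 0.4
    missing_outcome_fraction: float = 0.03
    proxy_fraction: float = 0.5
    annotation_fraction: float = 0.06
    annotation_traits: tuple = ("BMI", "education", "smoking")
    n_outliers: int = 0
    outlier_scale: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not -1 <= self.genetic_correlation <= 1:
            raise ValueError("genetic_correlation must be in [-1, 1]")
        if not -1 <= self.phenotypic_correlation <= 1:
            raise ValueError("phenotypic_correlation must be in [-1, 1]")
        for e in self.exposures:
            if not 0 < e.r2_target < 1:
                raise ValueError(f"infeasible r2 target for {e.name}: {e.r2_target}")
        for o in self.outcomes:
            if o.trait_type == "binary" and not (0 < (o.case_fraction or 0) < 1):
                raise ValueError(f"case_fraction for {o.name} must be in (0, 1)")
            if len(o.causal_effects) != len(self.exposures):
                raise ValueError("causal_effects length must match the number of exposures")
        if self.n_snps <= 0 or self.n_null_snps < 0 or self.ld_block_size < 1:
            raise ValueError("counts must be positive")


@dataclass
class StudyBundle:
    """Everything :func:`generate_study` emits."""

    exposures: list
    outcomes: dict
    ld: LDReference
    annotations: pd.DataFrame
    truth: SyntheticTruth
    per_snp: pd.DataFrame
    replicated_flags: dict


def default_truth(**overrides) -> SyntheticTruth:
    """The default study conditions with selected fields overridden."""
    return SyntheticTruth(**overrides)


def _draw_effects(truth: SyntheticTruth, eaf: np.ndarray, rng) -> np.ndarray:
    """True per-allele exposure effects (SD scale), (m, p).

    Effects are multivariate normal across exposures with the configured
    genetic correlation, scaled per exposure so the realised total
    r^2 = sum 2p(1-p)b^2 hits the target exactly.  The heavy-tailed option
    multiplies by a common sqrt-inverse-gamma factor (t-like tails) for
    outlier stress tests.  Rows are then oriented so the first exposure's
    effect allele is the exposure-raising allele.
    """
    m = len(eaf)
    p = len(truth.exposures)
    c = np.full((p, p), truth.genetic_correlation)
    np.fill_diagonal(c, 1.0)
    chol = np.linalg.cholesky(c + 1e-12 * np.eye(p))
    g = rng.standard_normal((m, p)) @ chol.T
    if truth.effect_distribution == "heavy-tailed":
        df = 4.0
        g = g * np.sqrt(df / rng.chisquare(df, size=(m, 1)))
    elif truth.effect_distribution != "normal":
        raise ValueError(f"unknown effect_distribution {truth.effect_distribution!r}")
    het = 2.0 * eaf * (1.0 - eaf)
    b = np.empty_like(g)
    for e, spec in enumerate(truth.exposures):
        scale = np.sqrt(spec.r2_target / np.sum(het * g[:, e] ** 2))
        b[:, e] = g[:, e] * scale
    flip = np.where(b[:, 0] < 0, -1.0, 1.0)
    return b * flip[:, None]


def _alleles(truth: SyntheticTruth, m: int, rng):
    """Allele pairs with a planted fraction of palindromes."""
    pal = rng.random(m) < truth.palindrome_fraction
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    for j in range(m):
        pool = _PALINDROMIC_PAIRS if pal[j] else _NONPALINDROMIC_PAIRS
        ea[j], oa[j] = pool[rng.integers(len(pool))]
    return ea, oa, pal


def _noise_correlation(truth: SyntheticTruth) -> np.ndarray:
    """Correlation of estimation noise across (exposures..., outcomes...).

    Exposures share a sample, so their noise correlates at the phenotypic
    correlation; exposure-outcome noise correlates at
    overlap_fraction * sqrt(phenotypic_correlation); distinct outcome
    samples are independent.  The matrix is eigenvalue-clipped to the
    nearest PSD matrix if overlap settings push it outside.
    """
    p = len(truth.exposures)
    q = len(truth.outcomes)
    d = p + q
    C = np.eye(d)
    C[:p, :p] = truth.phenotypic_correlation
    np.fill_diagonal(C, 1.0)
    for o, spec in enumerate(truth.outcomes):
        r = spec.overlap_fraction * np.sqrt(max(truth.phenotypic_correlation, 0.0))
        C[:p, p + o] = r
        C[p + o, :p] = r
    vals, vecs = np.linalg.eigh(C)
    if vals.min() < 0:
        vals = np.clip(vals, 1e-8, None)
        C = vecs @ np.diag(vals) @ vecs.T
        dd = np.sqrt(np.diag(C))
        C = C / np.outer(dd, dd)
    return C


def generate_study(truth: SyntheticTruth) -> StudyBundle:
    """Generate one full two-sample study from a truth record.

    Produces one summary-statistics table per exposure and outcome
    (per-SD betas for exposures; log-odds or standardised betas for
    outcomes), an LD reference covering the planted LD blocks and proxy
    pairs, an annotation table for the secondary-trait screen, replication
    flags, and a per-SNP frame of true effects.  Deterministic given
    ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    m = truth.n_snps
    p = len(truth.exposures)
    q = len(truth.outcomes)

    eaf = rng.uniform(0.05, 0.95, size=m)
    ea, oa, pal = _alleles(truth, m, rng)
    # palindromes earmarked ambiguous get a frequency inside the window
    amb = pal & (rng.random(m) < truth.ambiguous_palindrome_fraction)
    eaf[amb] = rng.uniform(0.43, 0.57, size=int(amb.sum()))
    eaf[pal & ~amb] = np.where(rng.random(int((pal & ~amb).sum())) < 0.5,
                               rng.uniform(0.05, 0.40, size=int((pal & ~amb).sum())),
                               rng.uniform(0.60, 0.95, size=int((pal & ~amb).sum())))

    b = _draw_effects(truth, eaf, rng)  # (m, p) per-SD per-allele
    het = 2.0 * eaf * (1.0 - eaf)

    # pleiotropy on the outcome scale, defined relative to the
    # exposure-raising allele of the first exposure
    alpha = np.zeros(m)
    if truth.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, truth.pleiotropy_sd, size=m)
    elif truth.pleiotropy_mode == "directional":
        alpha = rng.normal(truth.pleiotropy_mean, truth.pleiotropy_sd, size=m)
    elif truth.pleiotropy_mode == "inside-violating":
        z = rng.standard_normal(m)
        bstd = (b[:, 0] - b[:, 0].mean()) / (b[:, 0].std() + 1e-30)
        alpha = truth.pleiotropy_mean + truth.pleiotropy_sd * (0.7 * bstd + np.sqrt(1 - 0.49) * z)
    elif truth.pleiotropy_mode != "none":
        raise ValueError(f"unknown pleiotropy_mode {truth.pleiotropy_mode!r}")

# standard errors from sample size and allele frequency
    se_x = np.empty((m, p))
    for e, spec in enumerate(truth.exposures):
        se_x[:, e] = 1.0 / np.sqrt(spec.n * het)
    se_y = np.empty((m, q))
    for o, spec in enumerate(truth.outcomes):
        if spec.trait_type == "binary":
            cf = spec.case_fraction
            se_y[:, o] = 1.0 / np.sqrt(spec.n * cf * (1.0 - cf) * het)
        else:
            se_y[:, o] = 1.0 / np.sqrt(spec.n * het)

    a = np.empty((m, q))
    for o, spec in enumerate(truth.outcomes):
        a[:, o] = b @ np.asarray(spec.causal_effects) + alpha

    # planted gross outliers: a fixed offset in units of the outcome SE
    outlier = np.zeros(m, dtype=bool)
    if truth.n_outliers > 0:
        idx = rng.choice(m, size=min(truth.n_outliers, m), replace=False)
        outlier[idx] = True
        a[idx, :] += truth.outlier_scale * se_y[idx, :]

    C = _noise_correlation(truth)
    chol = np.linalg.cholesky(C + 1e-12 * np.eye(p + q))
    eps = rng.standard_normal((m, p + q)) @ chol.T
    bhat = b + eps[:, :p] * se_x
    ahat = a + eps[:, p:] * se_y

    ids = np.array([f"rs{j + 1:06d}" for j in range(m)])

    # satellites in LD with each index SNP: tagged effect sqrt(r2) * b
    ld_pairs = {}
    proxies: dict[str, list] = {}
    sat_rows_x = [[] for _ in range(p)]
    sat_rows_y = [[] for _ in range(q)]
    n_sat = truth.ld_block_size - 1
    r_tag = np.sqrt(truth.ld_within_r2)
    sat_ids_all = []
    for j in range(m):
        for s in range(n_sat):
            sid = f"rs{j + 1:06d}s{s + 1}"
            sat_ids_all.append((j, sid))
            ld_pairs[frozenset((ids[j], sid))] = truth.ld_within_r2
            e_sat = rng.standard_normal(p + q)
            for e in range(p):
                sat_rows_x[e].append(
                    (sid, ea[j], oa[j], eaf[j], r_tag * b[j, e] + e_sat[e] * se_x[j, e], se_x[j, e])
                )
            for o in range(q):
                sat_rows_y[o].append(
                    (sid, ea[j], oa[j], eaf[j], r_tag * a[j, o] + e_sat[p + o] * se_y[j, o], se_y[j, o])
                )

    # null background SNPs (no effect anywhere)
    n0 = truth.n_null_snps
    null_ids = np.array([f"rs9{j:05d}n" for j in range(n0)])
    null_eaf = rng.uniform(0.05, 0.95, size=n0)
    null_het = 2.0 * null_eaf * (1.0 - null_eaf)
    null_ea, null_oa, _ = _alleles(truth, n0, rng)

    # variants missing from the outcome tables; half get a usable proxy
    missing = rng.random(m) < truth.missing_outcome_fraction
    has_proxy = missing & (rng.random(m) < truth.proxy_fraction) & (n_sat > 0)
    for j in np.flatnonzero(has_proxy):
        proxies[ids[j]] = [(f"rs{j + 1:06d}s1", truth.ld_within_r2)]

    exposures = []
    for e, spec in enumerate(truth.exposures):
        rows = {
            "variant_id": np.concatenate([ids, [r[0] for r in sat_rows_x[e]], null_ids]),
            "effect_allele": np.concatenate([ea, [r[1] for r in sat_rows_x[e]], null_ea]),
            "other_allele": np.concatenate([oa, [r[2] for r in sat_rows_x[e]], null_oa]),
            "eaf": np.concatenate([eaf, [r[3] for r in sat_rows_x[e]], null_eaf]),
            "beta": np.concatenate(
                [bhat[:, e], [r[4] for r in sat_rows_x[e]], rng.standard_normal(n0) / np.sqrt(spec.n * null_het)]
            ),
            "se": np.concatenate([se_x[:, e], [r[5] for r in sat_rows_x[e]], 1.0 / np.sqrt(spec.n * null_het)]),
            "n": spec.n,
        }
        exposures.append(
            table_from_frame(
                pd.DataFrame(rows), trait_name=spec.name, trait_type="continuous",
                trait_sd=spec.trait_sd, validate=False,
            )
        )

    outcomes = {}
    for o, spec in enumerate(truth.outcomes):
        keep = ~missing
        null_se_y = (
            1.0 / np.sqrt(spec.n * spec.case_fraction * (1 - spec.case_fraction) * null_het)
            if spec.trait_type == "binary"
            else 1.0 / np.sqrt(spec.n * null_het)
        )
        rows = {
            "variant_id": np.concatenate([ids[keep], [r[0] for r in sat_rows_y[o]], null_ids]),
            "effect_allele": np.concatenate([ea[keep], [r[1] for r in sat_rows_y[o]], null_ea]),
            "other_allele": np.concatenate([oa[keep], [r[2] for r in sat_rows_y[o]], null_oa]),
            "eaf": np.concatenate([eaf[keep], [r[3] for r in sat_rows_y[o]], null_eaf]),
            "beta": np.concatenate(
                [ahat[keep, o], [r[4] for r in sat_rows_y[o]], rng.standard_normal(n0) * null_se_y]
            ),
            "se": np.concatenate([se_y[keep, o], [r[5] for r in sat_rows_y[o]], null_se_y]),
            "n": spec.n,
        }
        df = pd.DataFrame(rows)
        if spec.trait_type == "binary":
            df["n_cases"] = spec.n * spec.case_fraction
        outcomes[spec.name] = table_from_frame(
            df, trait_name=spec.name, trait_type=spec.trait_type, validate=False,
        )

    # annotation table: a random subset of instruments strongly associated
    # with secondary traits (the screen's input)
    ann_rows = []
    annotated = rng.random(m) < truth.annotation_fraction
    for j in np.flatnonzero(annotated):
        trait = truth.annotation_traits[rng.integers(len(truth.annotation_traits))]
        ann_rows.append({"variant_id": ids[j], "trait": trait, "pvalue": 10.0 ** rng.uniform(-30, -8.5)})
    # plus some weak, screen-passing annotations
    for j in np.flatnonzero(rng.random(m) < truth.annotation_fraction):
        trait = truth.annotation_traits[rng.integers(len(truth.annotation_traits))]
        ann_rows.append({"variant_id": ids[j], "trait": trait, "pvalue": 10.0 ** rng.uniform(-6, -2)})
    annotations = pd.DataFrame(ann_rows, columns=["variant_id", "trait", "pvalue"])

    per_snp = pd.DataFrame(
        {
            "variant_id": ids,
            **{f"b_{spec.name}": b[:, e] for e, spec in enumerate(truth.exposures)},
            **{f"a_{spec.name}": a[:, o] for o, spec in enumerate(truth.outcomes)},
            "pleiotropy": alpha,
            "eaf": eaf,
            "palindromic": pal,
            "missing_in_outcome": missing,
            "outlier": outlier,
        }
    )

    replicated_flags = {vid: True for vid in ids}
    ld = LDReference(r2=ld_pairs, proxies=proxies)
    return StudyBundle(
        exposures=exposures,
        outcomes=outcomes,
        ld=ld,
        annotations=annotations,
        truth=truth,
        per_snp=per_snp,
        replicated_flags=replicated_flags,
    )


def generate_composite_subtypes(
    truth: SyntheticTruth,
    subtype_specs: list[SubtypeSpec],
    outcome_name: str = "CVD",
    noise_correlation: float = 0.3,
    study: StudyBundle | None = None,
    seed: int | None = None,
) -> dict[str, SummaryStatsTable]:
    """Per-subtype outcome tables sharing a latent liability.

    Each subtype's true per-SNP effect is ``loading`` times the composite
    outcome's true effect from the study; estimation noise is correlated
    across subtypes at ``noise_correlation`` (they are ascertained in the
    same cohort), which is what makes naive fixed-effects pooling of the
    subtypes anti-conservative and motivates the LDSC-intercept SE
    inflation downstream.
    """
    if study is None:
        study = generate_study(truth)
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    per = study.per_snp
    a = per[f"a_{outcome_name}"].to_numpy()
    eaf = per["eaf"].to_numpy()
    het = 2.0 * eaf * (1.0 - eaf)
    m = len(per)
    s = len(subtype_specs)
    C = np.full((s, s), noise_correlation)
    np.fill_diagonal(C, 1.0)
    eps = rng.standard_normal((m, s)) @ np.linalg.cholesky(C + 1e-12 * np.eye(s)).T
    base = study.exposures[0].df.set_index("variant_id")
    tables = {}
    for i, spec in enumerate(subtype_specs):
        cf = spec.n_cases / spec.n
        se = 1.0 / np.sqrt(spec.n * cf * (1.0 - cf) * het)
        beta = spec.loading * a + eps[:, i] * se
        df = pd.DataFrame(
            {
                "variant_id": per["variant_id"],
                "effect_allele": [base.loc[v, "effect_allele"] if v in base.index else "A" for v in per["variant_id"]],
                "other_allele": [base.loc[v, "other_allele"] if v in base.index else "G" for v in per["variant_id"]],
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "n": spec.n,
                "n_cases": spec.n_cases,
            }
        )
        tables[spec.name] = table_from_frame(
            df, trait_name=spec.name, trait_type="binary", validate=False
        )
    return tables
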
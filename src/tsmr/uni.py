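"""Univariable two-sample MR estimators and pleiotropy-robust sensitivity
analyses.

The causal effect of an exposure on an outcome is estimated from per-SNP
Wald ratios (SNP-outcome effect over SNP-exposure effect).  The primary
estimator is inverse-variance weighting with multiplicative random effects
(IVW-MRE): a weighted regression of outcome effects on exposure effects
through the origin, with the standard error scaled by sqrt(Q/(k-1)) when
Cochran's Q exceeds its expectation.  Sensitivity estimators relax the
no-pleiotropy assumption in different ways: the weighted median is
consistent when over half the weight comes from valid instruments; MR-Egger
adds an intercept whose deviation from zero signals directional pleiotropy;
MR-PRESSO detects per-SNP outliers against a simulated null and re-estimates
without them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .harmonise import HarmonisedSet

__all__ = [
    "MRResult",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "mr_egger",
    "mr_presso",
    "run_total_effects",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class MRResult:
    """One estimator's causal-effect estimate with diagnostics.

    ``estimate`` is on the outcome scale per unit (usually per SD) of
    exposure: a beta for continuous outcomes, a log odds ratio for binary
    ones — :meth:`exponentiated` gives the OR view.
    """

    method: str
    estimate: float
    se: float
    pvalue: float
    n_snps: int
    exposure: str = ""
    outcome: str = ""
    cochran_q: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    outliers: list = field(default_factory=list)
    global_p: float | None = None
    distortion_p: float | None = None
    seed: int | None = None
    note: str = ""

    @property
    def ci_low(self) -> float:
        return self.estimate - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + Z95 * self.se

    def exponentiated(self) -> dict:
        """Odds-ratio view for binary outcomes."""
        return {
            "or": float(np.exp(self.estimate)),
            "or_ci_low": float(np.exp(self.ci_low)),
            "or_ci_high": float(np.exp(self.ci_high)),
        }

    def to_dict(self) -> dict:
        d = {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_snps": self.n_snps,
            "cochran_q": self.cochran_q,
            "q_pvalue": self.q_pvalue,
            "egger_intercept": self.egger_intercept,
            "intercept_p": self.intercept_p,
            "global_p": self.global_p,
            "distortion_p": self.distortion_p,
            "n_outliers": len(self.outliers),
            "note": self.note,
        }
        return d


def _two_sided_p(z):
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratio(bx, se_x, by, se_y, second_order: bool = False, rng=None, n_draws: int = 0):
    """Per-SNP causal estimate by/bx with a delta-method standard error.

    First order (default) propagates outcome uncertainty only,
    se = |se_y/bx|, matching the IVW weighting convention; ``second_order``
    adds the exposure term: se^2 = se_y^2/bx^2 + by^2 se_x^2 / bx^4.
    """
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    ratio = by / bx
    if second_order:
        se = float(np.sqrt(se_y**2 / bx**2 + (by**2) * se_x**2 / bx**4))
    else:
        se = abs(se_y / bx)
    return ratio, se


def _extract(hset: HarmonisedSet, exposure_index: int):
    bx = hset.exposure_betas[:, exposure_index]
    sx = hset.exposure_ses[:, exposure_index]
    return bx, sx, hset.outcome_betas, hset.outcome_ses


def _names(hset, exposure_index):
    return hset.exposure_names[exposure_index], hset.outcome_name


def ivw(hset: HarmonisedSet, exposure_index: int = 0) -> MRResult:
    """IVW with multiplicative random effects.

    Weighted regression of beta_Y on beta_X through the origin with weights
    1/se_Y^2; the fixed-effects SE is inflated by sqrt(Q/(k-1)) when
    Cochran's Q exceeds k-1, never deflated.  A single SNP degrades to the
    Wald ratio.
    """
    bx, sx, by, sy = _extract(hset, exposure_index)
    k = len(bx)
    ename, oname = _names(hset, exposure_index)
    if k == 0:
        raise ValueError("empty instrument set")
    if k == 1:
        est, se = wald_ratio(bx[0], sx[0], by[0], sy[0])
        return MRResult(
            "ivw", float(est), float(se), _two_sided_p(est / se), 1,
            exposure=ename, outcome=oname, note="single SNP: Wald ratio",
        )
    w = 1.0 / sy**2
    sxx = np.sum(w * bx**2)
    est = float(np.sum(w * bx * by) / sxx)
    se_fixed = float(1.0 / np.sqrt(sxx))
    q = float(np.sum(w * (by - est * bx) ** 2))
    scale = max(1.0, np.sqrt(q / (k - 1)))
    se = se_fixed * scale
    return MRResult(
        "ivw", est, se, _two_sided_p(est / se), k,
        exposure=ename, outcome=oname,
        cochran_q=q, q_df=k - 1, q_pvalue=float(stats.chi2.sf(q, k - 1)),
    )


def _median_of_sorted(values, weights):
    """Weighted median with the w_j/2 percentile offset and linear interpolation."""
    order = np.argsort(values)
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    cum = np.cumsum(w) - w / 2.0
    if 0.5 <= cum[0]:
        return float(v[0])
    if 0.5 >= cum[-1]:
        return float(v[-1])
    i = int(np.searchsorted(cum, 0.5)) - 1
    frac = (0.5 - cum[i]) / (cum[i + 1] - cum[i])
    return float(v[i] + frac * (v[i + 1] - v[i]))


def weighted_median(
    hset: HarmonisedSet,
    exposure_index: int = 0,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Weighted-median estimator with a parametric-bootstrap standard error.

    Wald ratios are ordered and interpolated at cumulative weight 0.5 with
    inverse-variance weights; consistent when valid instruments carry more
    than half of the total weight.  The SE resamples (beta_X, beta_Y) from
    their sampling normals ``n_bootstrap`` times.
    """
    bx, sx, by, sy = _extract(hset, exposure_index)
    k = len(bx)
    ename, oname = _names(hset, exposure_index)
    if k == 0:
        raise ValueError("empty instrument set")
    ratios = by / bx
    wr_se = np.abs(sy / bx)
    weights = 1.0 / wr_se**2
    est = _median_of_sorted(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = np.finfo(float).tiny
        r = bys / bxs
        wgt = (bxs / sy) ** 2
        boots[b] = _median_of_sorted(r, wgt)
    se = float(np.std(boots, ddof=1))
    return MRResult(
        "weighted_median", est, se, _two_sided_p(est / se), k,
        exposure=ename, outcome=oname, seed=seed,
    )


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares: coefficients and unscaled covariance (sigma=1)."""
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    xtx = Xw.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ yw)
    cov = np.linalg.inv(xtx)
    resid = y - X @ coef
    return coef, cov, resid


def mr_egger(hset: HarmonisedSet, exposure_index: int = 0) -> MRResult:
    """MR-Egger regression: slope is the causal estimate, the intercept
    estimates average directional pleiotropy.

    SNPs are oriented so beta_X > 0 before fitting (the intercept is only
    identified under a sign convention); weights 1/se_Y^2; SEs use the same
    multiplicative random-effects inflation as IVW with k-2 degrees of
    freedom.
    """
    bx, sx, by, sy = _extract(hset, exposure_index)
    k = len(bx)
    ename, oname = _names(hset, exposure_index)
    if k < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    coef, cov, resid = _wls(X, by, w)
    q = float(np.sum(w * resid**2))
    scale2 = max(1.0, q / (k - 2))
    se_int = float(np.sqrt(cov[0, 0] * scale2))
    se_slope = float(np.sqrt(cov[1, 1] * scale2))
    return MRResult(
        "mr_egger", float(coef[1]), se_slope, _two_sided_p(coef[1] / se_slope), k,
        exposure=ename, outcome=oname,
        cochran_q=q, q_df=k - 2, q_pvalue=float(stats.chi2.sf(q, k - 2)),
        egger_intercept=float(coef[0]), intercept_se=se_int,
        intercept_p=_two_sided_p(coef[0] / se_int),
    )


def _loo_ivw(bx, by, w):
    """Leave-one-out fixed-effects IVW slopes, vectorised over SNPs."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def mr_presso(
    hset: HarmonisedSet,
    exposure_index: int = 0,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_p: float = 0.05,
    distortion: bool = True,
) -> MRResult:
    """MR-PRESSO: residual-sum-of-squares pleiotropy test with outlier
    removal and a distortion test.

    The observed RSS uses leave-one-out IVW predictions; its null
    distribution comes from ``n_sim`` parametric simulations drawing both
    beta_X and beta_Y from their sampling normals under the fitted model.
    Per-SNP outliers are flagged by their simulated residual distribution
    with Bonferroni correction; the corrected estimate is IVW on the
    non-outliers; the distortion test compares the corrected-vs-raw shift
    against removal of random SNP subsets of the same size.
    """
    bx, sx, by, sy = _extract(hset, exposure_index)
    k = len(bx)
    ename, oname = _names(hset, exposure_index)
    if k < 4:
        raise ValueError("MR-PRESSO needs at least 4 SNPs")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2

    theta_loo = _loo_ivw(bx, by, w)
    resid_obs = by - bx * theta_loo
    rss_j_obs = w * resid_obs**2
    rss_obs = float(np.sum(rss_j_obs))

    # parametric simulations under the (leave-one-out) fitted model
    bx_sim = rng.normal(bx[None, :], sx[None, :], size=(n_sim, k))
    by_sim = rng.normal((bx * theta_loo)[None, :], sy[None, :], size=(n_sim, k))
    sxy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    sxx = np.sum(w * bx_sim**2, axis=1, keepdims=True)
    theta_sim = (sxy - w * bx_sim * by_sim) / (sxx - w * bx_sim**2)
    rss_j_sim = w * (by_sim - bx_sim * theta_sim) ** 2
    rss_sim = rss_j_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    p_snp = (1 + np.sum(rss_j_sim >= rss_j_obs[None, :], axis=0)) / (n_sim + 1)
    outlier_mask = p_snp * k < outlier_p
    outliers = [hset.variant_ids[j] for j in np.flatnonzero(outlier_mask)]

    raw = ivw(hset, exposure_index)
    if outliers and k - len(outliers) >= 2:
        corrected = ivw(hset.subset(~outlier_mask), exposure_index)
        distortion_p = None
        if distortion:
            n_out = len(outliers)
            keep_idx = np.flatnonzero(~outlier_mask)
            d_obs = corrected.estimate - raw.estimate
            d_null = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(keep_idx, size=n_out, replace=False)
                m = np.ones(k, dtype=bool)
                m[drop] = False
                est_s = np.sum(w[m] * bx[m] * by[m]) / np.sum(w[m] * bx[m] ** 2)
                d_null[s] = est_s - raw.estimate
            distortion_p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))
        result = MRResult(
            "mr_presso", corrected.estimate, corrected.se, corrected.pvalue,
            corrected.n_snps, exposure=ename, outcome=oname,
            cochran_q=corrected.cochran_q, q_df=corrected.q_df,
            q_pvalue=corrected.q_pvalue, outliers=outliers,
            global_p=global_p, distortion_p=distortion_p, seed=seed,
            note="outlier-corrected",
        )
        return result
    return MRResult(
        "mr_presso", raw.estimate, raw.se, raw.pvalue, raw.n_snps,
        exposure=ename, outcome=oname, cochran_q=raw.cochran_q,
        q_df=raw.q_df, q_pvalue=raw.q_pvalue, outliers=outliers,
        global_p=global_p, seed=seed,
        note="no outliers removed",
    )


UNIVARIABLE_METHODS = {
    "ivw": ivw,
    "weighted_median": weighted_median,
    "mr_egger": mr_egger,
    "mr_presso": mr_presso,
}


def run_total_effects(
    hsets: dict,
    methods: tuple = ("ivw", "weighted_median", "mr_egger", "mr_presso"),
    n_bootstrap: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Total effects: every estimator for every harmonised (exposure,
    outcome) pair.

    ``hsets`` maps (exposure_name, outcome_name) to a single-exposure
    HarmonisedSet.  Returns one row per (exposure, outcome, method) with
    odds-ratio columns filled for binary outcomes.
    """
    rows = []
    for (ename, oname), hset in hsets.items():
        for method in methods:
            try:
                if method == "weighted_median":
                    res = weighted_median(hset, n_bootstrap=n_bootstrap, seed=seed)
                elif method == "mr_presso":
                    res = mr_presso(hset, n_sim=n_sim, seed=seed)
                else:
                    res = UNIVARIABLE_METHODS[method](hset)
            except (ValueError, ZeroDivisionError) as exc:
                warnings.warn(f"{method} failed for {ename}->{oname}: {exc}")
                continue
            row = res.to_dict()
            if hset.outcome_type == "binary":
                row.update(res.exponentiated())
            rows.append(row)
    return pd.DataFrame(rows)
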
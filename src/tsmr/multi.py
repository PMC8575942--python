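"""Multivariable MR: direct effects of several exposures estimated jointly.

With p exposures, SNP-outcome effects are regressed on the (k x p) matrix
of SNP-exposure effects (no intercept, weights 1/se_Y^2), giving for each
exposure its direct effect conditional on the others — the multivariable
analogue of IVW, again with multiplicative random-effects SE scaling.

Because the exposures here (systolic and diastolic blood pressure) are
measured in overlapping samples and phenotypically correlated (Pearson 0.69
in UK Biobank), their estimated SNP effects covary:
cov(bX1_j, bX2_j) = rho * se1_j * se2_j.  That covariance enters the
Sanderson-Windmeijer conditional F-statistic — instrument strength for one
exposure net of its prediction by the others — and the modified Cochran's Q
for instrument pleiotropy.  Egger, weighted-median and PRESSO analogues
provide the same pleiotropy-robust sensitivity suite as the univariable
module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonise import HarmonisedSet
from .uni import MRResult, _two_sided_p, _wls, ivw

__all__ = [
    "ExposureCovarianceModel",
    "mv_ivw",
    "conditional_f",
    "modified_q",
    "mv_egger",
    "mv_median",
    "mv_presso",
    "run_direct_effects",
]


@dataclass
class ExposureCovarianceModel:
    """Cross-exposure covariance of estimated SNP effects.

    Built from the phenotypic correlation matrix across exposures (for
    two blood-pressure traits a single scalar, default 0.69); the per-SNP
    covariance of estimated effects is rho_ab * se_a * se_b.
    """

    correlation: np.ndarray

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.correlation, dtype=float))
        if not np.allclose(c, c.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.linalg.eigvalsh(c) < -1e-10):
            raise ValueError("correlation matrix must be positive semidefinite")
        self.correlation = c

    @classmethod
    def from_rho(cls, rho: float, n_exposures: int = 2):
        c = np.full((n_exposures, n_exposures), float(rho))
        np.fill_diagonal(c, 1.0)
        return cls(c)

    def per_snp_cov(self, ses: np.ndarray) -> np.ndarray:
        """(k, p, p) covariance matrices: rho_ab * se_ja * se_jb."""
        return self.correlation[None, :, :] * ses[:, :, None] * ses[:, None, :]


def _mv_fit(hset: HarmonisedSet):
    X = hset.exposure_betas
    y = hset.outcome_betas
    w = 1.0 / hset.outcome_ses**2
    k, p = X.shape
    if k <= p:
        raise ValueError("need more SNPs than exposures")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"exposure matrix is rank-deficient (rank {rank} < {p}); "
            f"collinear columns among {hset.exposure_names}"
        )
    coef, cov, resid = _wls(X, y, w)
    q = float(np.sum(w * resid**2))
    return coef, cov, resid, q, w, k, p


def mv_ivw(hset: HarmonisedSet) -> list[MRResult]:
    """Multivariable IVW: direct effect per exposure, conditional on the rest.

    Weighted multiple regression of beta_Y on all exposure-effect columns
    without intercept, weights 1/se_Y^2; SEs carry the multiplicative
    random-effects factor max(1, sqrt(Q/(k-p))).
    """
    coef, cov, resid, q, w, k, p = _mv_fit(hset)
    scale2 = max(1.0, q / (k - p))
    results = []
    for e, name in enumerate(hset.exposure_names):
        se = float(np.sqrt(cov[e, e] * scale2))
        results.append(
            MRResult(
                "mv_ivw", float(coef[e]), se, _two_sided_p(coef[e] / se), k,
                exposure=name, outcome=hset.outcome_name,
                cochran_q=q, q_df=k - p, q_pvalue=float(stats.chi2.sf(q, k - p)),
            )
        )
    return results


def conditional_f(
    hset: HarmonisedSet,
    covariance_model: ExposureCovarianceModel | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> dict[str, float]:
    """Sanderson-Windmeijer conditional F-statistic per exposure.

    For exposure e, its SNP effects are regressed on the other exposures'
    SNP effects by iterated inverse-variance weighting in which the
    residual variance per SNP propagates the cross-exposure covariance of
    estimation errors, var_j = se_e^2 + d' Sigma_other d - 2 d' cov_other,e;
    the conditional F is the residual strength Q_e/(k - p + 1).  With a
    single exposure this reduces exactly to the mean univariable F.  Values
    below 10 flag conditionally weak instruments.
    """
    k, p = hset.exposure_betas.shape
    if covariance_model is None:
        covariance_model = ExposureCovarianceModel(np.eye(p))
    cov_snp = covariance_model.per_snp_cov(hset.exposure_ses)
    out: dict[str, float] = {}
    for e, name in enumerate(hset.exposure_names):
        be = hset.exposure_betas[:, e]
        if p == 1:
            q = float(np.sum((be / hset.exposure_ses[:, 0]) ** 2))
            out[name] = q / k
            continue
        others = [j for j in range(p) if j != e]
        Bo = hset.exposure_betas[:, others]
        var_e = cov_snp[:, e, e]
        Sig_oo = cov_snp[:, others, :][:, :, others]
        cov_oe = cov_snp[:, others, e]
        # iterated feasible GLS for the delta coefficients
        var_j = var_e.copy()
        delta = np.zeros(len(others))
        for _ in range(max_iter):
            w = 1.0 / var_j
            A = (Bo * w[:, None]).T @ Bo
            b = (Bo * w[:, None]).T @ be
            new_delta = np.linalg.solve(A, b)
            var_j = (
                var_e
                + np.einsum("a,jab,b->j", new_delta, Sig_oo, new_delta)
                - 2.0 * cov_oe @ new_delta
            )
            var_j = np.maximum(var_j, 1e-300)
            if np.max(np.abs(new_delta - delta)) < tol:
                delta = new_delta
                break
            delta = new_delta
        resid = be - Bo @ delta
        q = float(np.sum(resid**2 / var_j))
        out[name] = q / (k - p + 1)
    return out


def modified_q(
    hset: HarmonisedSet,
    covariance_model: ExposureCovarianceModel | None = None,
    theta: np.ndarray | None = None,
    iterate: bool = True,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    """Modified Cochran's Q for multivariable MR.

    Q = sum_j (beta_Yj - theta' beta_Xj)^2 / s_j^2 with per-SNP variance
    s_j^2 = se_Yj^2 + theta' Sigma_j theta, where Sigma_j is the covariance
    of the estimated exposure effects from the phenotypic-correlation
    model.  By default theta is re-estimated under these weights (iterated
    GLS starting from the multivariable IVW fit).  df = k - p; the p-value
    is from the chi-square reference.
    """
    X = hset.exposure_betas
    y = hset.outcome_betas
    k, p = X.shape
    if covariance_model is None:
        covariance_model = ExposureCovarianceModel(np.eye(p))
    cov_snp = covariance_model.per_snp_cov(hset.exposure_ses)
    sy2 = hset.outcome_ses**2
    if theta is None:
        theta = np.array([r.estimate for r in mv_ivw(hset)])
        if iterate:
            for _ in range(max_iter):
                s2 = sy2 + np.einsum("a,jab,b->j", theta, cov_snp, theta)
                w = 1.0 / s2
                A = (X * w[:, None]).T @ X
                b = (X * w[:, None]).T @ y
                new_theta = np.linalg.solve(A, b)
                if np.max(np.abs(new_theta - theta)) < tol:
                    theta = new_theta
                    break
                theta = new_theta
    theta = np.asarray(theta, dtype=float)
    s2 = sy2 + np.einsum("a,jab,b->j", theta, cov_snp, theta)
    q = float(np.sum((y - X @ theta) ** 2 / s2))
    df = k - p
    return {"q": q, "df": df, "pvalue": float(stats.chi2.sf(q, df)), "theta": theta}


def mv_egger(hset: HarmonisedSet, reference_exposure: int = 0) -> list[MRResult]:
    """Multivariable MR-Egger: mv_ivw plus an intercept column.

    SNPs are oriented so the reference exposure's effects are positive
    (the intercept needs a sign convention; the reference is the first
    configured exposure by default).  The intercept and its p-value are
    attached to every per-exposure result.
    """
    X = hset.exposure_betas
    y = hset.outcome_betas
    k, p = X.shape
    if k <= p + 1:
        raise ValueError("multivariable Egger needs more SNPs than exposures + 1")
    flip = np.sign(X[:, reference_exposure])
    flip[flip == 0] = 1.0
    Xf = X * flip[:, None]
    yf = y * flip
    w = 1.0 / hset.outcome_ses**2
    D = np.column_stack([np.ones(k), Xf])
    coef, cov, resid = _wls(D, yf, w)
    q = float(np.sum(w * resid**2))
    scale2 = max(1.0, q / (k - p - 1))
    se_int = float(np.sqrt(cov[0, 0] * scale2))
    results = []
    for e, name in enumerate(hset.exposure_names):
        se = float(np.sqrt(cov[e + 1, e + 1] * scale2))
        results.append(
            MRResult(
                "mv_egger", float(coef[e + 1]), se, _two_sided_p(coef[e + 1] / se), k,
                exposure=name, outcome=hset.outcome_name,
                cochran_q=q, q_df=k - p - 1, q_pvalue=float(stats.chi2.sf(q, k - p - 1)),
                egger_intercept=float(coef[0]), intercept_se=se_int,
                intercept_p=_two_sided_p(coef[0] / se_int),
            )
        )
    return results


def _wlad(X, y, w, theta0, max_iter=100, tol=1e-12):
    """Weighted least-absolute-deviations fit by iteratively reweighted LS."""
    theta = theta0.copy()
    for _ in range(max_iter):
        r = np.abs(y - X @ theta)
        wi = w / np.maximum(r, 1e-12)
        A = (X * wi[:, None]).T @ X
        new = np.linalg.solve(A, (X * wi[:, None]).T @ y)
        if np.max(np.abs(new - theta)) < tol:
            return new
        theta = new
    return theta


def mv_median(
    hset: HarmonisedSet,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> list[MRResult]:
    """Multivariable weighted median: weighted least-absolute-deviations
    regression of outcome effects on the exposure-effect columns.

    The L1 objective with weights 1/se_Y^2 is the multivariable analogue of
    the weighted median of Wald ratios and remains consistent when a
    minority of SNPs are invalid.  SEs come from a parametric bootstrap
    resampling (beta_X, beta_Y) from their sampling normals, ``n_bootstrap``
    replicates with the recorded seed.
    """
    k, p = hset.exposure_betas.shape
    if k < p + 2:
        raise ValueError("too few SNPs for the multivariable median")
    rng = np.random.default_rng(seed)
    X = hset.exposure_betas
    y = hset.outcome_betas
    w = 1.0 / hset.outcome_ses**2
    theta0 = np.array([r.estimate for r in mv_ivw(hset)])
    est = _wlad(X, y, w, theta0)
    fits = np.empty((n_bootstrap, p))
    for b in range(n_bootstrap):
        Xb = rng.normal(X, hset.exposure_ses)
        yb = rng.normal(y, hset.outcome_ses)
        try:
            fits[b] = _wlad(Xb, yb, w, est, max_iter=30)
        except np.linalg.LinAlgError:
            fits[b] = np.nan
    se = np.nanstd(fits, axis=0, ddof=1)
    return [
        MRResult(
            "mv_median", float(est[e]), float(se[e]), _two_sided_p(est[e] / se[e]), k,
            exposure=name, outcome=hset.outcome_name, seed=seed,
        )
        for e, name in enumerate(hset.exposure_names)
    ]


def _loo_mv(X, y, w):
    """Leave-one-out multivariable IVW predictions for each SNP."""
    k, p = X.shape
    A = (X * w[:, None]).T @ X
    b = (X * w[:, None]).T @ y
    preds = np.empty(k)
    thetas = np.empty((k, p))
    for j in range(k):
        xj = X[j]
        Aj = A - w[j] * np.outer(xj, xj)
        bj = b - w[j] * xj * y[j]
        th = np.linalg.solve(Aj, bj)
        thetas[j] = th
        preds[j] = xj @ th
    return preds, thetas


def mv_presso(
    hset: HarmonisedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_p: float = 0.05,
    distortion: bool = True,
) -> list[MRResult]:
    """Multivariable MR-PRESSO: global RSS test, per-SNP outliers and
    outlier-corrected direct effects, using leave-one-out multivariable IVW
    residuals."""
    X = hset.exposure_betas
    y = hset.outcome_betas
    k, p = X.shape
    if k < p + 3:
        raise ValueError("too few SNPs for multivariable MR-PRESSO")
    rng = np.random.default_rng(seed)
    w = 1.0 / hset.outcome_ses**2
    preds, _ = _loo_mv(X, y, w)
    rss_j_obs = w * (y - preds) ** 2
    rss_obs = float(np.sum(rss_j_obs))

    rss_j_sim = np.empty((n_sim, k))
    for s in range(n_sim):
        Xs = rng.normal(X, hset.exposure_ses)
        ys = rng.normal(preds, hset.outcome_ses)
        ps, _ = _loo_mv(Xs, ys, w)
        rss_j_sim[s] = w * (ys - ps) ** 2
    rss_sim = rss_j_sim.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_snp = (1 + np.sum(rss_j_sim >= rss_j_obs[None, :], axis=0)) / (n_sim + 1)
    outlier_mask = p_snp * k < outlier_p
    outliers = [hset.variant_ids[j] for j in np.flatnonzero(outlier_mask)]

    raw = mv_ivw(hset)
    if outliers and k - len(outliers) > p:
        corrected = mv_ivw(hset.subset(~outlier_mask))
        distortion_p = None
        if distortion:
            keep_idx = np.flatnonzero(~outlier_mask)
            d_obs = np.array([c.estimate - r.estimate for c, r in zip(corrected, raw)])
            d_null = np.empty((n_sim, p))
            for s in range(n_sim):
                drop = rng.choice(keep_idx, size=len(outliers), replace=False)
                m = np.ones(k, dtype=bool)
                m[drop] = False
                A = (X[m] * w[m, None]).T @ X[m]
                th = np.linalg.solve(A, (X[m] * w[m, None]).T @ y[m])
                d_null[s] = th - np.array([r.estimate for r in raw])
            dist = np.linalg.norm(d_obs)
            distortion_p = float(
                (1 + np.sum(np.linalg.norm(d_null, axis=1) >= dist)) / (n_sim + 1)
            )
        results = []
        for res in corrected:
            res.method = "mv_presso"
            res.outliers = outliers
            res.global_p = global_p
            res.distortion_p = distortion_p
            res.seed = seed
            res.note = "outlier-corrected"
            results.append(res)
        return results
    for res in raw:
        res.method = "mv_presso"
        res.outliers = outliers
        res.global_p = global_p
        res.seed = seed
        res.note = "no outliers removed"
    return raw


def run_direct_effects(
    hset: HarmonisedSet,
    covariance_model: ExposureCovarianceModel | None = None,
    methods: tuple = ("mv_ivw", "mv_median", "mv_egger", "mv_presso"),
    n_bootstrap: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
    covariate_hset: HarmonisedSet | None = None,
) -> dict:
    """Direct-effect suite for one multi-exposure harmonised set.

    Runs the requested multivariable estimators plus conditional F and the
    modified Q; returns {"results": DataFrame, "conditional_f": dict,
    "modified_q": dict}.  ``covariate_hset`` (same SNPs, extra exposure
    columns such as education / smoking / BMI) is analysed as a sensitivity
    fit when supplied.
    """
    dispatch = {
        "mv_ivw": lambda h: mv_ivw(h),
        "mv_egger": lambda h: mv_egger(h),
        "mv_median": lambda h: mv_median(h, n_bootstrap=n_bootstrap, seed=seed),
        "mv_presso": lambda h: mv_presso(h, n_sim=n_sim, seed=seed),
    }
    rows = []

    def collect(h, tag=""):
        for m in methods:
            try:
                for res in dispatch[m](h):
                    row = res.to_dict()
                    if tag:
                        row["method"] = f"{row['method']}{tag}"
                    if h.outcome_type == "binary":
                        row.update(res.exponentiated())
                    rows.append(row)
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"{m} failed for {h.outcome_name}: {exc}")

    collect(hset)
    if covariate_hset is not None:
        collect(covariate_hset, tag="+covariates")
    return {
        "results": pd.DataFrame(rows),
        "conditional_f": conditional_f(hset, covariance_model),
        "modified_q": modified_q(hset, covariance_model),
    }
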
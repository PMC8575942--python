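"""Instrument-strength, directionality and power diagnostics.

For a harmonised instrument set this module computes: per-SNP F statistics
(beta/se squared) with the mean-F < 10 weak-instrument rule of thumb; the
fraction of exposure variance explained, r^2 = sum 2 p (1-p) beta^2 on the
SD scale under Hardy-Weinberg; the I^2_GX statistic quantifying measurement
error in the SNP-exposure effects (NOME; values below 0.9 cast doubt on
MR-Egger); a Steiger directionality test comparing variance explained in
exposure versus outcome; and a power approximation for the smallest
detectable causal effect at given alpha and power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonise import HarmonisedSet

__all__ = [
    "InstrumentDiagnostics",
    "f_statistics",
    "variance_explained",
    "i_squared_gx",
    "steiger_test",
    "mr_power",
    "diagnose",
]


@dataclass
class InstrumentDiagnostics:
    """Summary of instrument quality for one exposure."""

    per_snp_f: np.ndarray
    f_mean: float
    f_min: float
    f_max: float
    weak: bool
    r2_explained: float | None = None
    i2_gx: float | None = None
    conditional_f: float | None = None
    steiger: dict | None = None
    power: dict | None = None


def f_statistics(hset: HarmonisedSet, exposure_index: int = 0) -> InstrumentDiagnostics:
    """Per-SNP F_j = (beta_Xj / se_Xj)^2 with mean/min/max summary.

    The mean F below 10 flags a potentially weak instrument set.
    """
    bx = hset.exposure_betas[:, exposure_index]
    sx = hset.exposure_ses[:, exposure_index]
    f = (bx / sx) ** 2
    return InstrumentDiagnostics(
        per_snp_f=f,
        f_mean=float(np.mean(f)),
        f_min=float(np.min(f)),
        f_max=float(np.max(f)),
        weak=bool(np.mean(f) < 10),
    )


def variance_explained(
    hset: HarmonisedSet,
    exposure_index: int = 0,
    allele_frequencies: np.ndarray | None = None,
    per_sd: bool = True,
) -> float:
    """Fraction of exposure variance explained: sum_j 2 p_j (1-p_j) beta_j^2.

    Betas must be on the SD scale (``per_sd=False`` rescales per-mmHg betas
    using the table's trait SD).  SNPs with missing allele frequency are
    skipped with a warning, yielding a partial r^2.
    """
    if hset.n_snps == 0:
        return 0.0
    bx = hset.exposure_betas[:, exposure_index]
    if not per_sd:
        sd = hset.exposure_sds[exposure_index]
        if not (np.isfinite(sd) and sd > 0):
            raise ValueError("per-mmHg betas need a trait SD for conversion")
        bx = bx / sd
    p = hset.eafs if allele_frequencies is None else np.asarray(allele_frequencies, dtype=float)
    ok = np.isfinite(p)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} SNPs lack eaf; r2 is partial")
    return float(np.sum(2.0 * p[ok] * (1.0 - p[ok]) * bx[ok] ** 2))


def variance_explained_from_f(hset: HarmonisedSet, exposure_index: int = 0) -> float:
    """F-based approximation r2 ~= sum F_j / (sum F_j + n - k); needs n."""
    if hset.exposure_n is None or not np.isfinite(hset.exposure_n[exposure_index]):
        raise ValueError("exposure sample size required")
    f = (hset.exposure_betas[:, exposure_index] / hset.exposure_ses[:, exposure_index]) ** 2
    n = float(hset.exposure_n[exposure_index])
    k = hset.n_snps
    return float(np.sum(f) / (np.sum(f) + n - k))


def i_squared_gx(hset: HarmonisedSet, exposure_index: int = 0) -> float | None:
    """I^2_GX: heterogeneity of SNP-exposure effects as a NOME gauge.

    Q_GX is the precision-weighted dispersion of |beta_X| around its
    weighted mean; I^2_GX = max(0, (Q_GX - (k-1)) / Q_GX).  Values below
    0.9 suggest the no-measurement-error assumption behind MR-Egger is
    violated.  Undefined for a single SNP (returns None with a warning).
    Computed on the magnitude scale so it is invariant to the arbitrary
    choice of effect allele.
    """
    k = hset.n_snps
    if k < 2:
        warnings.warn("I^2_GX undefined for fewer than 2 SNPs")
        return None
    bx = np.abs(hset.exposure_betas[:, exposure_index])
    sx = hset.exposure_ses[:, exposure_index]
    w = 1.0 / sx**2
    bbar = np.sum(w * bx) / np.sum(w)
    q = float(np.sum(w * (bx - bbar) ** 2))
    if q <= 0:
        return 0.0
    return float(max(0.0, (q - (k - 1)) / q))


def _pseudo_r2(beta, se, n):
    """Observed-scale per-SNP variance explained from summary data: z^2/(z^2+n)."""
    z2 = (np.asarray(beta) / np.asarray(se)) ** 2
    return z2 / (z2 + np.asarray(n, dtype=float))


def steiger_test(hset: HarmonisedSet, exposure_index: int = 0) -> dict:
    """Directionality check: do the instruments explain more variance of the
    exposure than of the outcome?

    Per-SNP r^2 on each side uses the scale-free summary-data form
    z^2/(z^2+n); set-level correlations r = sqrt(sum r^2) are compared with
    a Fisher-z statistic.  Direction ``exposure->outcome`` when the
    exposure side explains more.
    """
    if hset.exposure_n is None or hset.outcome_n is None:
        raise ValueError("Steiger test needs sample sizes for both traits")
    nx = float(hset.exposure_n[exposure_index])
    ny = float(hset.outcome_n)
    r2x = _pseudo_r2(hset.exposure_betas[:, exposure_index], hset.exposure_ses[:, exposure_index], nx)
    r2y = _pseudo_r2(hset.outcome_betas, hset.outcome_ses, ny)
    rx = float(np.sqrt(min(np.sum(r2x), 1.0)))
    ry = float(np.sqrt(min(np.sum(r2y), 1.0)))
    z = (np.arctanh(min(rx, 0.999999)) - np.arctanh(min(ry, 0.999999))) / np.sqrt(
        1.0 / (nx - 3.0) + 1.0 / (ny - 3.0)
    )
    return {
        "direction": "exposure->outcome" if rx > ry else ("outcome->exposure" if ry > rx else "undetermined"),
        "per_snp_forward": [bool(v) for v in r2x > r2y],
        "r2_exposure": float(np.sum(r2x)),
        "r2_outcome": float(np.sum(r2y)),
        "z": float(z),
        "pvalue": float(2.0 * stats.norm.sf(abs(z))),
    }


def mr_power(
    n: float,
    r2: float,
    case_fraction: float | None = None,
    alpha: float = 0.05,
    power: float = 0.8,
    effect: float | None = None,
) -> dict:
    """Smallest detectable causal effect, or achieved power for a stated one.

    Uses the standard approximation that an MR study needs the sample size
    of an observational study divided by the instrument's r^2.  For a
    continuous outcome the detectable effect per SD of exposure is
    (z_{1-alpha/2} + z_{power}) / sqrt(n r2); for a binary outcome the same
    on the log-odds scale with an extra cf (1-cf) factor for case balance.
    With ``effect`` given, returns the achieved power instead.
    """
    if not (0 < r2 <= 1):
        raise ValueError("r2 must be in (0, 1]")
    ncp_scale = n * r2
    if case_fraction is not None:
        if not (0 < case_fraction < 1):
            raise ValueError("case_fraction must be in (0, 1)")
        ncp_scale *= case_fraction * (1.0 - case_fraction)
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    if effect is None:
        z_b = stats.norm.ppf(power)
        detectable = (z_a + z_b) / np.sqrt(ncp_scale)
        out = {"detectable_effect": float(detectable), "alpha": alpha, "power": power}
        if case_fraction is not None:
            out["detectable_or"] = float(np.exp(detectable))
        return out
    achieved = stats.norm.cdf(abs(effect) * np.sqrt(ncp_scale) - z_a)
    return {"effect": float(effect), "alpha": alpha, "achieved_power": float(achieved)}


def diagnose(
    hset: HarmonisedSet,
    exposure_index: int = 0,
    alpha: float = 0.05,
    power: float = 0.8,
) -> InstrumentDiagnostics:
    """Full diagnostics bundle for one exposure of a harmonised set."""
    diag = f_statistics(hset, exposure_index)
    diag.r2_explained = variance_explained(hset, exposure_index)
    diag.i2_gx = i_squared_gx(hset, exposure_index)
    if hset.exposure_n is not None and hset.outcome_n is not None:
        diag.steiger = steiger_test(hset, exposure_index)
        diag.power = mr_power(
            hset.outcome_n,
            diag.r2_explained,
            case_fraction=hset.case_fraction,
            alpha=alpha,
            power=power,
        )
    return diag
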
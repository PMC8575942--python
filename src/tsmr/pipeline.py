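"""End-to-end workflow: instrument selection through labelled result tables.

Reproduces the full analysis sequence for a set of exposures and outcomes:
select strong, replicated instruments (p < 5e-8), greedily clump them at
r^2 < 0.001, harmonise against each outcome, compute instrument
diagnostics, run the univariable estimator suite per exposure-outcome pair
(plus the annotation-screened sensitivity repeat), run the multivariable
suite on the merged instrument set with conditional F and modified Q, and
attach evidence labels: p < 0.0125 (Bonferroni for two exposures by two
outcome groups) is strong evidence, 0.0125 <= p < 0.05 suggestive.
Estimates are reported per SD of exposure, and additionally per a fixed
native-unit increment (10 mmHg systolic / 5 mmHg diastolic) when trait SDs
are available.  A manifest records every threshold, seed and exclusion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import diagnose
from .harmonise import (
    HarmonisedSet,
    LDReference,
    clump,
    harmonise,
    merge_exposure_instruments,
    screen_annotations,
    select_instruments,
)
from .multi import ExposureCovarianceModel, conditional_f, modified_q, run_direct_effects
from .sumstats import SummaryStatsTable, read_summary_stats
from .uni import run_total_effects

__all__ = ["RunConfig", "label_evidence", "run_full_workflow", "PipelineError"]


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return str(obj)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and partial outputs."""

    def __init__(self, stage: str, cause: Exception, partial: dict | None = None):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial = partial or {}


@dataclass
class RunConfig:
    """Every analysis constant of the workflow in one record."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    palindrome_window: tuple = (0.42, 0.58)
    proxy_r2_min: float = 0.8
    rho: float = 0.69
    ldsc_intercept: float | None = None
    n_bootstrap: int = 1000
    n_sim: int = 1000
    seed: int = 0
    strong_alpha: float = 0.0125
    nominal_alpha: float = 0.05
    screen_traits: tuple = ("BMI", "education", "smoking")
    screen_p: float = 5e-8
    unit_increments: dict = field(default_factory=dict)  # exposure -> native-unit step

    def __post_init__(self):
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if not 0 <= self.clump_r2 <= 1:
            raise ValueError("clump_r2 must be in [0, 1]")
        if not 0 < self.strong_alpha < self.nominal_alpha < 1:
            raise ValueError("need 0 < strong_alpha < nominal_alpha < 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def label_evidence(
    results: pd.DataFrame,
    strong_alpha: float = 0.0125,
    nominal_alpha: float = 0.05,
    p_column: str = "pvalue",
) -> pd.DataFrame:
    """Attach evidence labels by p-value: strong below the Bonferroni
    threshold, suggestive below the nominal one, none otherwise.

    The boundary p = strong_alpha itself is labelled suggestive (the strong
    band is the strict inequality)."""
    out = results.copy()
    p = out[p_column]
    out["evidence"] = np.select(
        [p < strong_alpha, p < nominal_alpha], ["strong", "suggestive"], default="none"
    )
    return out


def _rescaled_view(results: pd.DataFrame, exposure_sds: dict, unit_increments: dict) -> pd.DataFrame:
    """Per-native-unit view of per-SD results: multiply by increment/SD."""
    rows = []
    for _, row in results.iterrows():
        sd = exposure_sds.get(row["exposure"])
        inc = unit_increments.get(row["exposure"])
        if sd is None or inc is None or not np.isfinite(sd):
            continue
        f = inc / sd
        r = row.copy()
        for col in ("estimate", "se", "ci_low", "ci_high"):
            r[col] = row[col] * f
        if "or" in row and np.isfinite(row.get("or", np.nan)):
            r["or"] = np.exp(r["estimate"])
            r["or_ci_low"] = np.exp(r["ci_low"])
            r["or_ci_high"] = np.exp(r["ci_high"])
        r["scale"] = f"per-{inc}-unit"
        rows.append(r)
    return pd.DataFrame(rows)


def run_full_workflow(
    exposures: list[SummaryStatsTable],
    outcomes: dict[str, SummaryStatsTable],
    ld: LDReference,
    config: RunConfig | None = None,
    annotations: pd.DataFrame | None = None,
    replicated_flags: dict | None = None,
    covariates: list[SummaryStatsTable] | None = None,
    out_dir=None,
) -> dict:
    """Run the complete analysis and return a report bundle.

    The bundle maps: ``univariable`` and ``multivariable`` to labelled
    per-SD result tables; ``univariable_screened`` to the
    annotation-screened sensitivity repeat; ``per_unit`` views when trait
    SDs and unit increments are configured; ``diagnostics`` to per-exposure
    instrument diagnostics; ``manifest`` to thresholds, seeds and every
    exclusion with its reason.  Any stage failure raises
    :class:`PipelineError` naming the stage, with partial outputs attached.
    """
    config = config or RunConfig()
    bundle: dict = {}
    manifest: dict = {
        "version": __version__,
        "config": {
            **{k: v for k, v in asdict(config).items()},
        },
        "exposures": [t.trait_name for t in exposures],
        "outcomes": list(outcomes),
        "exclusions": {},
        "instruments": {},
    }

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise PipelineError(name, exc, partial=bundle) from exc

    # --- instrument selection per exposure -------------------------------
    def _select():
        per_exp = {}
        for t in exposures:
            cands = select_instruments(t, config.p_threshold, replicated_flags)
            pmap = t.df.set_index("variant_id")["pvalue"]
            clumped = clump([(v, pmap[v]) for v in cands], ld, config.clump_r2)
            per_exp[t.trait_name] = {v: float(pmap[v]) for v in clumped}
        return per_exp

    per_exposure_instruments = stage("select_instruments", _select)
    manifest["instruments"]["univariable"] = {
        k: sorted(v) for k, v in per_exposure_instruments.items()
    }

    # --- univariable suite ------------------------------------------------
    def _univariable():
        hsets = {}
        diagnostics = {}
        for e_idx, t in enumerate(exposures):
            instruments = list(per_exposure_instruments[t.trait_name])
            for oname, otable in outcomes.items():
                h = harmonise(
                    [t], otable, instruments, ld,
                    palindrome_window=config.palindrome_window,
                    proxy_r2_min=config.proxy_r2_min,
                )
                hsets[(t.trait_name, oname)] = h
                manifest["exclusions"][f"{t.trait_name}->{oname}"] = dict(h.exclusion_log)
            diagnostics[t.trait_name] = diagnose(hsets[(t.trait_name, next(iter(outcomes)))])
        results = run_total_effects(
            hsets, n_bootstrap=config.n_bootstrap, n_sim=config.n_sim, seed=config.seed
        )
        return hsets, diagnostics, label_evidence(results, config.strong_alpha, config.nominal_alpha)

    hsets, diagnostics, uni_results = stage("univariable", _univariable)
    bundle["diagnostics"] = diagnostics
    bundle["univariable"] = uni_results

    # --- annotation-screened sensitivity ---------------------------------
    if annotations is not None and len(annotations):
        def _screened():
            screened_sets = {
                key: screen_annotations(h, annotations, list(config.screen_traits), config.screen_p)
                for key, h in hsets.items()
            }
            for key, h in screened_sets.items():
                name = f"{key[0]}->{key[1]}:screened"
                manifest["exclusions"][name] = {
                    v: r for v, r in h.exclusion_log.items() if r == "annotation-screened"
                }
            res = run_total_effects(
                screened_sets, methods=("ivw",),
                n_bootstrap=config.n_bootstrap, n_sim=config.n_sim, seed=config.seed,
            )
            return label_evidence(res, config.strong_alpha, config.nominal_alpha)

        bundle["univariable_screened"] = stage("annotation_screen", _screened)

    # --- multivariable suite ---------------------------------------------
    def _multivariable():
        merged = merge_exposure_instruments(
            (v, p, ename)
            for ename, vp in per_exposure_instruments.items()
            for v, p in vp.items()
        )
        mv_instruments = clump(list(merged.items()), ld, config.clump_r2)
        manifest["instruments"]["multivariable"] = sorted(mv_instruments)
        cov_model = ExposureCovarianceModel.from_rho(config.rho, len(exposures))
        rows = []
        cond_f = {}
        mod_q = {}
        for oname, otable in outcomes.items():
            h = harmonise(
                exposures, otable, mv_instruments, ld,
                palindrome_window=config.palindrome_window,
                proxy_r2_min=config.proxy_r2_min,
            )
            manifest["exclusions"][f"multivariable->{oname}"] = dict(h.exclusion_log)
            cov_h = None
            if covariates:
                cov_h = harmonise(
                    list(exposures) + list(covariates), otable, mv_instruments, ld,
                    palindrome_window=config.palindrome_window,
                    proxy_r2_min=config.proxy_r2_min,
                )
            out = run_direct_effects(
                h, cov_model,
                n_bootstrap=config.n_bootstrap, n_sim=config.n_sim, seed=config.seed,
                covariate_hset=cov_h,
            )
            rows.append(out["results"])
            cond_f[oname] = out["conditional_f"]
            mod_q[oname] = {k: v for k, v in out["modified_q"].items() if k != "theta"}
        results = pd.concat(rows, ignore_index=True)
        return label_evidence(results, config.strong_alpha, config.nominal_alpha), cond_f, mod_q

    mv_results, cond_f, mod_q = stage("multivariable", _multivariable)
    bundle["multivariable"] = mv_results
    bundle["conditional_f"] = cond_f
    bundle["modified_q"] = mod_q

    # --- native-unit views -------------------------------------------------
    exposure_sds = {t.trait_name: (t.trait_sd if t.trait_sd else np.nan) for t in exposures}
    if config.unit_increments:
        bundle["univariable_per_unit"] = _rescaled_view(uni_results, exposure_sds, config.unit_increments)
        bundle["multivariable_per_unit"] = _rescaled_view(mv_results, exposure_sds, config.unit_increments)

    manifest["seed"] = config.seed
    bundle["manifest"] = manifest

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key in ("univariable", "multivariable", "univariable_screened",
                    "univariable_per_unit", "multivariable_per_unit"):
            if key in bundle:
                bundle[key].to_csv(out / f"{key}.tsv", sep="\t", index=False)
        diag_json = {
            name: {
                "f_mean": d.f_mean, "f_min": d.f_min, "f_max": d.f_max,
                "r2_explained": d.r2_explained, "i2_gx": d.i2_gx,
                "steiger": d.steiger, "power": d.power,
            }
            for name, d in diagnostics.items()
        }
        diag_json["conditional_f"] = cond_f
        diag_json["modified_q"] = mod_q
        (out / "diagnostics.json").write_text(json.dumps(diag_json, indent=2, default=_json_default))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
    return bundle
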
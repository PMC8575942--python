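"""Multivariable MR: direct effects, conditional F, modified Q, sensitivity."""

from dataclasses import replace

import numpy as np
import pytest

from tsmr import harmonise
from tsmr.multi import (
    ExposureCovarianceModel,
    conditional_f,
    modified_q,
    mv_egger,
    mv_ivw,
    mv_median,
    mv_presso,
    run_direct_effects,
)
from tsmr.uni import ivw, mr_egger

from .conftest import plain_truth, quick_hset
from .test_diagnostics import toy_hset


def mv_toy(bx, sx, by, sy, names=("X1", "X2")):
    import tsmr

    bx = np.asarray(bx, dtype=float)
    k = bx.shape[0]
    return tsmr.HarmonisedSet(
        variant_ids=[f"rs{i}" for i in range(k)],
        exposure_names=list(names[: bx.shape[1]]),
        exposure_betas=bx,
        exposure_ses=np.asarray(sx, dtype=float),
        outcome_betas=np.asarray(by, dtype=float),
        outcome_ses=np.asarray(sy, dtype=float),
        eafs=np.full(k, 0.5),
        outcome_name="Y",
    )


class TestMVIVW:
    def test_single_exposure_equals_ivw(self, five_snp_hset):
        uni = ivw(five_snp_hset)
        mv = mv_ivw(five_snp_hset)[0]
        assert mv.estimate == pytest.approx(uni.estimate, abs=1e-14)
        assert mv.se == pytest.approx(uni.se, rel=1e-6)

    def test_null_second_exposure(self):
        """A second exposure with (noise-only) effects near zero leaves the
        first exposure's estimate at its univariable value."""
        rng = np.random.default_rng(0)
        k = 200
        bx1 = rng.uniform(0.03, 0.1, k)
        bx2 = rng.normal(0, 1e-4, k)
        by = 0.5 * bx1 + rng.normal(0, 0.005, k)
        h = mv_toy(np.column_stack([bx1, bx2]), np.full((k, 2), 0.004), by, np.full(k, 0.005))
        res = mv_ivw(h)
        assert res[0].estimate == pytest.approx(0.5, abs=0.01)
        assert abs(res[1].estimate) * 1e-4 < 0.01  # unconstrained but tiny leverage

    def test_collinear_exposures_rejected(self):
        bx1 = np.linspace(0.02, 0.1, 6)
        h = mv_toy(np.column_stack([bx1, 2 * bx1]), np.full((6, 2), 0.004),
                   0.5 * bx1, np.full(6, 0.005))
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            mv_ivw(h)

    def test_attenuation_pattern(self):
        """With direct effects (0.6, 0.0) and correlated genetics, the
        second exposure is positive univariably but null multivariably."""
        from tsmr import OutcomeSpec

        truth = plain_truth(
            seed=9, n_snps=300, genetic_correlation=0.7,
            outcomes=(OutcomeSpec("CVD", causal_effects=(0.6, 0.0)),
                      OutcomeSpec("lifespan", causal_effects=(0.0, 0.0), trait_type="continuous", n=389_166, case_fraction=None)),
        )
        h, _ = quick_hset(truth)
        uni2 = ivw(h.single(1))
        mv = mv_ivw(h)
        assert uni2.estimate > 0.2 and uni2.pvalue < 1e-6
        assert abs(mv[1].estimate) < 3 * mv[1].se
        assert mv[0].ci_low < 0.6 < mv[0].ci_high

    def test_order_invariance(self, five_snp_mv_hset):
        res = mv_ivw(five_snp_mv_hset)
        swapped = replace(
            five_snp_mv_hset,
            exposure_names=five_snp_mv_hset.exposure_names[::-1],
            exposure_betas=five_snp_mv_hset.exposure_betas[:, ::-1],
            exposure_ses=five_snp_mv_hset.exposure_ses[:, ::-1],
        )
        res_swapped = mv_ivw(swapped)
        assert res[0].estimate == pytest.approx(res_swapped[1].estimate)
        assert res[1].estimate == pytest.approx(res_swapped[0].estimate)


class TestConditionalF:
    def test_single_exposure_is_mean_f(self, five_snp_hset):
        f = (five_snp_hset.exposure_betas[:, 0] / five_snp_hset.exposure_ses[:, 0]) ** 2
        out = conditional_f(five_snp_hset)
        assert out["X"] == pytest.approx(np.mean(f))

    def test_orthogonal_limit(self):
        """With genetically unrelated exposures estimated in independent
        samples, conditioning costs little: conditional F within 5% of the
        unconditional mean F."""
        truth = plain_truth(seed=21, n_snps=400, genetic_correlation=0.0,
                            phenotypic_correlation=0.0)
        h, _ = quick_hset(truth)
        cm = ExposureCovarianceModel.from_rho(0.0, 2)
        cond = conditional_f(h, cm)
        for e in (0, 1):
            uncond = np.mean((h.exposure_betas[:, e] / h.exposure_ses[:, e]) ** 2)
            assert cond[h.exposure_names[e]] == pytest.approx(uncond, rel=0.05)

    def test_collinearity_weakens(self):
        truth = plain_truth(seed=22, n_snps=300, genetic_correlation=0.99)
        h, _ = quick_hset(truth)
        cm = ExposureCovarianceModel.from_rho(0.69, 2)
        cond = conditional_f(h, cm)
        uncond = np.mean((h.exposure_betas[:, 0] / h.exposure_ses[:, 0]) ** 2)
        assert cond["SBP"] < 10 < uncond

    def test_monotone_in_genetic_correlation(self):
        """With independent estimation samples, conditional instrument
        strength decays monotonically as the exposures' genetic effects
        become collinear, collapsing towards the weak-instrument regime."""
        cm = ExposureCovarianceModel.from_rho(0.0, 2)
        values = []
        for rho_g in (0.0, 0.5, 0.9, 0.99):
            truth = plain_truth(seed=30, n_snps=300, genetic_correlation=rho_g,
                                phenotypic_correlation=0.0)
            h, _ = quick_hset(truth)
            values.append(conditional_f(h, cm)["SBP"])
        assert values == sorted(values, reverse=True)
        assert values[-1] < 10 < values[0]


class TestModifiedQ:
    def test_exact_linear_zero(self):
        bx = np.column_stack([np.linspace(0.02, 0.1, 8), np.linspace(0.01, 0.05, 8)[::-1]])
        by = bx @ np.array([0.5, 0.2])
        h = mv_toy(bx, np.full((8, 2), 0.004), by, np.full(8, 0.005))
        out = modified_q(h, ExposureCovarianceModel.from_rho(0.69, 2))
        assert out["q"] == pytest.approx(0.0, abs=1e-16)
        assert out["df"] == 6

    def test_null_calibration(self):
        """Q/df near 1 under the null with the 0.69-correlation weights."""
        cm = ExposureCovarianceModel.from_rho(0.69, 2)
        ratios = []
        for seed in range(30):
            truth = plain_truth(seed=200 + seed, n_snps=150)
            h, _ = quick_hset(truth)
            out = modified_q(h, cm)
            ratios.append(out["q"] / out["df"])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_ignoring_covariance_inflates_q(self):
        """Setting rho = 0 on correlated data inflates Q relative to the
        correctly weighted statistic (paired over replicates)."""
        cm_true = ExposureCovarianceModel.from_rho(0.69, 2)
        cm_zero = ExposureCovarianceModel.from_rho(0.0, 2)
        from tsmr import OutcomeSpec

        diffs = []
        for seed in range(15):
            # a strong causal effect makes the covariance term matter
            truth = plain_truth(
                seed=400 + seed, n_snps=150,
                outcomes=(OutcomeSpec("Y", causal_effects=(2.0, 1.5), trait_type="continuous", n=5e4, case_fraction=None),),
            )
            h, _ = quick_hset(truth, outcome="Y")
            q_true = modified_q(h, cm_true)["q"]
            q_zero = modified_q(h, cm_zero)["q"]
            diffs.append(q_zero - q_true)
        assert np.mean(diffs) > 0


class TestMVEgger:
    def test_uniform_shift_recovered_as_intercept(self):
        rng = np.random.default_rng(1)
        bx = np.column_stack([rng.uniform(0.02, 0.1, 10), rng.uniform(0.01, 0.06, 10)])
        by = 0.02 + bx @ np.array([0.5, 0.2])
        h = mv_toy(bx, np.full((10, 2), 0.004), by, np.full(10, 0.005))
        res = mv_egger(h)
        assert res[0].egger_intercept == pytest.approx(0.02, abs=1e-10)
        assert res[0].estimate == pytest.approx(0.5, abs=1e-8)
        assert res[1].estimate == pytest.approx(0.2, abs=1e-8)

    def test_reduces_to_univariable(self, five_snp_hset):
        uni = mr_egger(five_snp_hset)
        mv = mv_egger(five_snp_hset)[0]
        assert mv.estimate == pytest.approx(uni.estimate, abs=1e-12)
        assert mv.egger_intercept == pytest.approx(uni.egger_intercept, abs=1e-12)

    def test_null_intercept_size(self):
        """Intercept p-values keep nominal size under the zero-pleiotropy
        generator."""
        rej = 0
        n_rep = 200
        for seed in range(n_rep):
            truth = plain_truth(seed=700 + seed, n_snps=60)
            h, _ = quick_hset(truth)
            if mv_egger(h)[0].intercept_p < 0.05:
                rej += 1
        rate = rej / n_rep
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestMVMedianPresso:
    def test_median_agrees_on_clean_data(self):
        truth = plain_truth(seed=31, n_snps=120)
        h, _ = quick_hset(truth)
        med = mv_median(h, n_bootstrap=400, seed=5)
        base = mv_ivw(h)
        for m, b in zip(med, base):
            assert m.estimate == pytest.approx(b.estimate, abs=3 * m.se)

    def test_median_resists_contamination(self):
        """30% gross outliers: the bootstrap median stays closer to the
        truth than plain multivariable IVW in most replicates."""
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            truth = plain_truth(seed=800 + seed, n_snps=60, n_outliers=18, outlier_scale=8.0)
            h, _ = quick_hset(truth)
            med = mv_median(h, n_bootstrap=300, seed=seed)
            base = mv_ivw(h)
            err_med = abs(med[0].estimate - 0.604)
            err_ivw = abs(base[0].estimate - 0.604)
            wins += err_med < err_ivw
        assert wins >= 0.7 * n_rep

    def test_median_refuses_tiny_sets(self):
        h = mv_toy(np.array([[0.1, 0.05], [0.2, 0.1], [0.15, 0.02]]),
                   np.full((3, 2), 0.01), np.zeros(3), np.full(3, 0.01))
        with pytest.raises(ValueError):
            mv_median(h)

    def test_presso_clean_null(self):
        truth = plain_truth(seed=33, n_snps=40)
        h, _ = quick_hset(truth)
        res = mv_presso(h, n_sim=300, seed=1)
        assert res[0].global_p > 0.05
        assert res[0].outliers == []

    def test_presso_flags_planted_outlier(self):
        truth = plain_truth(seed=34, n_snps=21, n_outliers=1, outlier_scale=10.0)
        h, study = quick_hset(truth)
        planted = study.per_snp.loc[study.per_snp["outlier"], "variant_id"].iloc[0]
        res = mv_presso(h, n_sim=1000, seed=2)
        assert planted in res[0].outliers
        corrected = res[0].estimate
        raw = mv_ivw(h)[0].estimate
        assert abs(corrected - 0.604) < abs(raw - 0.604)


class TestRunDirectEffects:
    def test_zero_covariate_leaves_estimates(self):
        truth = plain_truth(seed=41, n_snps=80)
        h, _ = quick_hset(truth)
        rng = np.random.default_rng(0)
        noise_col = rng.normal(0, 1e-6, h.n_snps)
        h_cov = replace(
            h,
            exposure_names=h.exposure_names + ["covariate"],
            exposure_betas=np.column_stack([h.exposure_betas, noise_col]),
            exposure_ses=np.column_stack([h.exposure_ses, np.full(h.n_snps, 0.004)]),
        )
        base = mv_ivw(h)
        ext = mv_ivw(h_cov)
        for b, e in zip(base, ext):
            assert e.estimate == pytest.approx(b.estimate, abs=2e-3)

    def test_bundle_shape(self):
        truth = plain_truth(seed=42, n_snps=60)
        h, _ = quick_hset(truth)
        out = run_direct_effects(h, n_bootstrap=100, n_sim=200, seed=0)
        res = out["results"]
        assert set(res["method"]) == {"mv_ivw", "mv_median", "mv_egger", "mv_presso"}
        assert len(res) == 4 * 2
        assert set(out["conditional_f"]) == {"SBP", "DBP"}
        assert out["modified_q"]["df"] == h.n_snps - 2
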
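"""Observational association layer: tables, logistic fits, trend, interaction."""

import numpy as np
import pandas as pd
import pytest

from vitdmr import association
from vitdmr._glm import SeparationError
from vitdmr.association import (contingency_or, fit_logistic, interaction_lrt,
                                per_allele_or, stratified_analysis, trend_test)
from vitdmr.simulate import generate_cohort
from vitdmr.phenotype import prepare_phenotype

from conftest import scaled_config


class TestContingencyOR:
    def test_identity_table(self):
        r = contingency_or(((10, 10), (10, 10)))
        assert r.estimate == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_zero_cell_uses_haldane_correction(self):
        r = contingency_or(((0, 10), (10, 10)))
        assert "haldane" in r.note
        assert r.estimate == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_or(((0, 0), (10, 10)))

    def test_agrees_with_logistic_on_same_table(self):
        # exp(slope) of the grouped logistic equals the cross-product OR
        table = ((698, 905), (133, 165))
        r = contingency_or(table)
        design = pd.DataFrame({"const": [1.0, 1.0], "exposed": [1.0, 0.0]})
        fit = fit_logistic(np.array([[698, 905], [133, 165]], float), design)
        assert r.estimate == pytest.approx(
            float(np.exp(fit.params[1])), abs=1e-8)


class TestLogistic:
    def test_intercept_only_balanced(self):
        y = np.array([0.0, 1.0] * 50)
        fit = fit_logistic(y, pd.DataFrame({"const": np.ones(100)}))
        assert fit.params[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.coef_table.loc["const", "or"] == pytest.approx(1.0, abs=1e-8)

    def test_grouped_mle_beats_grid(self):
        # log-likelihood at the optimum tops a 101-point grid around it
        events = np.array([13.0, 30.0, 40.0])
        totals = np.array([50.0, 60.0, 70.0])
        design = pd.DataFrame({"const": 1.0, "dose": [0.0, 1.0, 2.0]})
        fit = fit_logistic(np.column_stack([events, totals - events]), design)
        b0, b1 = fit.params

        def loglik(beta1):
            eta = b0 + beta1 * design["dose"].to_numpy()
            return float(np.sum(events * eta - totals * np.logaddexp(0, eta)))

        grid = np.linspace(b1 - 0.5, b1 + 0.5, 101)
        assert loglik(b1) >= max(loglik(g) for g in grid) - 1e-9

    def test_rank_deficiency_rejected(self):
        y = np.array([0.0, 1.0] * 10)
        X = pd.DataFrame({"const": np.ones(20), "dup": np.ones(20)})
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(y, X)

    def test_separation_detected(self):
        x = np.linspace(-1, 1, 40)
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(y, pd.DataFrame({"const": np.ones(40), "x": x}))

    def test_per_allele_requires_three_doses(self):
        with pytest.raises(ValueError):
            per_allele_or([1, 2], [3, 4])


class TestTrend:
    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 500
        for _ in range(reps):
            q = rng.integers(1, 6, 800).astype(float)
            y = rng.binomial(1, 0.4, 800).astype(float)
            rejections += trend_test(q, y) < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_monotone_gradient_detected(self):
        rng = np.random.default_rng(1)
        q = rng.integers(1, 6, 4000).astype(float)
        p = 1 / (1 + np.exp(-(-1.0 + 0.3 * q)))
        y = rng.binomial(1, p).astype(float)
        assert trend_test(q, y) < 1e-6

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            trend_test(np.ones(100), np.random.default_rng(0).binomial(1, 0.5, 100))


class TestStratified:
    def test_identical_strata_identical_ors(self, cohort):
        doubled = cohort.copy()
        doubled["grp"] = np.where(np.arange(len(doubled)) % 2 == 0, "a", "b")
        half = doubled[doubled.grp == "a"].copy()
        half["grp"] = "b"
        stacked = pd.concat([doubled[doubled.grp == "a"], half])
        res = stratified_analysis(stacked, "grp")
        assert res["a"].estimate == pytest.approx(res["b"].estimate, abs=1e-12)

    def test_effect_isolated_to_one_stratum(self):
        rng = np.random.default_rng(5)
        n = 8000
        strat = np.where(rng.random(n) < 0.5, "A", "B")
        x = rng.normal(12, 5, n)
        eta = np.where(strat == "A", -0.15 * (x - 12), 0.0)
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        df = pd.DataFrame({"y": y, "x_std": x, "grp": strat})
        res = stratified_analysis(df, "grp")
        assert res["A"].ci_high < 1.0
        assert res["B"].ci_low < 1.0 < res["B"].ci_high

    def test_case_only_strata_use_all_controls(self, cohort):
        res = stratified_analysis(cohort, "symptom_group")
        assert set(res) == {"none", "mild", "severe", "both"}
        n_controls = int((cohort.y == 0).sum())
        assert all(r.n_controls == n_controls for r in res.values())

    def test_small_stratum_skipped_with_warning(self, cohort):
        tiny = cohort.copy()
        tiny["grp"] = "big"
        tiny.loc[tiny.index[:5], "grp"] = "small"
        with pytest.warns(UserWarning, match="skipped"):
            res = stratified_analysis(tiny, "grp", min_n=50)
        assert "small" not in res


class TestInteractionLRT:
    def _cohort_with_interaction(self, coef, seed=0, n=4000):
        rng = np.random.default_rng(seed)
        z = rng.binomial(2, 0.5, n).astype(float)
        x = rng.normal(12, 5, n)
        eta = -0.5 + 0.05 * z - 0.02 * x + coef * z * (x - 12)
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        return pd.DataFrame({"y": y, "x_std": x, "snp": z})

    def test_null_calibration(self):
        reps, rejections = 500, 0
        for seed in range(reps):
            df = self._cohort_with_interaction(0.0, seed=seed, n=600)
            _, _, p = interaction_lrt(df, "snp")
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_strong_crossover_detected(self):
        df = self._cohort_with_interaction(0.08, seed=3, n=4000)
        stat, df_, p = interaction_lrt(df, "snp")
        assert df_ == 1
        assert p < 0.001

    def test_statistic_zero_when_interaction_mle_is_zero(self):
        # symmetric grouped data with homogeneous odds ratios across z strata:
        # the interaction MLE is 0, so the LRT statistic vanishes
        # cell odds ratios: (z=0) 1 vs 1/3 = 3; (z=1) 2 vs 2/3 = 3 - homogeneous
        cells = [  # (z, x, n_events, n_nonevents)
            (0.0, 0.0, 100, 300), (0.0, 1.0, 200, 200),
            (1.0, 0.0, 200, 300), (1.0, 1.0, 400, 200),
        ]
        rows = []
        for z, x, n1, n0 in cells:
            rows.extend([{"y": 1, "x_std": x, "snp": z}] * n1)
            rows.extend([{"y": 0, "x_std": x, "snp": z}] * n0)
        df = pd.DataFrame(rows)
        stat, _, p = interaction_lrt(df, "snp")
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-3)


def test_model_adjustments_preserve_strong_effect_sign(cohort):
    # with covariates independent of exposure and outcome, adjusting never
    # flips the sign of the (confounded) inverse 25-OHD association
    ors = [association.logistic_or(cohort, "x_std", model_label=m).estimate
           for m in ("crude", "modelI", "modelII")]
    assert all(o < 1.0 for o in ors)
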
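"""IV estimators: algebraic identities, oracles, and qualitative behaviour."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from vitdmr import iv
from vitdmr.iv import (NonIdentifiedError, WeakInstrumentError, control_function,
                       first_stage, lsmm, msmm, run_table4, two_stage, wald_ratio)
from vitdmr.simulate import generate_cohort

from conftest import scaled_config


class TestFirstStage:
    def test_partial_f_equals_squared_t(self, cohort):
        # single instrument: F == t^2 of its OLS coefficient (statsmodels oracle)
        fs = first_stage(cohort, "rs2282679", covariates=("age", "sex"))
        sub = cohort.dropna(subset=["x_std", "rs2282679", "age", "sex"])
        X = sm.add_constant(sub[["rs2282679", "age", "sex"]].astype(float))
        ref = sm.OLS(sub["x_std"].astype(float), X).fit()
        assert fs.partial_f == pytest.approx(ref.tvalues["rs2282679"] ** 2, abs=1e-8)

    def test_residuals_sum_to_zero(self, cohort):
        fs = first_stage(cohort, "overall")
        assert abs(fs.residuals.sum()) < 1e-6 * len(cohort)
        assert abs(fs.fitted_x.mean() - cohort["x_std"].mean()) < 1e-8

    def test_weak_flag_below_ten(self, cohort):
        weak = first_stage(cohort, "rs6013897")
        strong = first_stage(cohort, "overall")
        assert weak.partial_f < 10 and weak.weak
        assert strong.partial_f > 10 and not strong.weak

    def test_null_instrument_f_averages_one(self):
        # beta_x = 0 in the DGP: partial F ~ F(1, n-p), mean ~ 1
        from vitdmr.datatypes import SNPSpec
        null_snp = SNPSpec("rs_null", 0.3, 0.0, "synthesis")
        fstats = []
        for seed in range(150):
            cfg = scaled_config(n_population=6_000, n_cases=300, n_controls=300,
                                snps=[null_snp], gamma_u_x=0.0, gamma_u_y=0.0,
                                seed=seed)
            c = generate_cohort(cfg)
            fstats.append(first_stage(c, "rs_null", exposure="x_raw").partial_f)
        assert np.mean(fstats) == pytest.approx(1.0, abs=0.35)

    def test_constant_instrument_rejected(self, cohort):
        c = cohort.copy()
        c["flat"] = 1.0
        with pytest.raises(ValueError, match="variation"):
            first_stage(c, "flat")


class TestAlgebraicIdentities:
    def test_wald_equals_two_stage_for_binary_instrument(self, iv_frame):
        w = wald_ratio(iv_frame, "z", exposure="x")
        t = two_stage(iv_frame, "z", exposure="x", n_boot=50, seed=1)
        assert np.log(w.or_per_unit) == pytest.approx(
            np.log(t.or_per_unit), abs=1e-8)

    def test_wald_equals_two_stage_binary_with_covariates(self, iv_frame):
        w = wald_ratio(iv_frame, "z", covariates=("age", "sex"), exposure="x")
        t = two_stage(iv_frame, "z", covariates=("age", "sex"), exposure="x",
                      n_boot=50, seed=1)
        assert np.log(w.or_per_unit) == pytest.approx(
            np.log(t.or_per_unit), abs=1e-8)

    def test_control_function_reduces_to_two_stage_without_endogeneity(self, iv_frame):
        # fitted + residual = x: dropping the residual term changes little
        # when there is no confounding in the DGP
        cf = control_function(iv_frame, "z", exposure="x", n_boot=50, seed=2)
        ts = two_stage(iv_frame, "z", exposure="x", n_boot=50, seed=2)
        assert np.log(cf.or_per_unit) == pytest.approx(
            np.log(ts.or_per_unit), abs=0.05)

    def test_zero_numerator_gives_unit_or(self):
        # Y unrelated to Z by construction (perfectly balanced design)
        z = np.tile([0.0, 1.0, 2.0], 40)
        y = np.tile([1.0, 1.0, 1.0, 0.0, 0.0, 0.0], 20)
        x = 8.0 + 1.2 * z
        x[::2] += 1.0  # some exposure noise unrelated to y
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        w = wald_ratio(df, "z", exposure="x")
        assert w.or_per_unit == pytest.approx(1.0, abs=1e-6)


class TestGEstimators:
    def _grid_oracle(self, g, lo=-2.0, hi=2.0, n=100_000, tol=1e-8):
        """Independent root finder: dense grid + pure bisection."""
        grid = np.linspace(lo, hi, n)
        vals = np.array([g(t) for t in grid])
        sign = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
        mid = np.abs(grid[sign] + grid[sign + 1]) / 2
        k = sign[np.argmin(mid)]
        a, b = grid[k], grid[k + 1]
        fa = g(a)
        while b - a > tol:
            m = 0.5 * (a + b)
            fm = g(m)
            if fa * fm <= 0:
                b = m
            else:
                a, fa = m, fm
        return 0.5 * (a + b)

    def test_msmm_root_matches_grid_oracle(self, iv_frame):
        # data with a real protective effect, so the equation crosses zero
        d = iv._prepare(iv_frame, "z", (), "x")
        psi = iv._msmm_kernel(d.y, d.x, d.z, d.C)
        w = d.z - d.z.mean()

        def g(p):
            return float(np.sum(w * d.y * np.exp(-np.clip(p * d.x, -500, 500))))

        assert psi == pytest.approx(self._grid_oracle(g, n=20_001), abs=1e-6)

    def test_lsmm_root_matches_grid_oracle(self, iv_frame):
        d = iv._prepare(iv_frame, "z", (), "x")
        psi, assoc = iv._lsmm_kernel(d.y, d.x, d.z, d.C)
        X = np.column_stack([np.ones(d.n), d.z, d.x])
        eta = X @ assoc.beta
        w = d.z - d.z.mean()

        def g(p):
            return float(np.sum(w / (1.0 + np.exp(-(eta - p * d.x)))))

        assert psi == pytest.approx(self._grid_oracle(g, n=20_001), abs=1e-6)

    def test_msmm_zero_root_when_outcome_balanced_over_instrument(self):
        z = np.array([0.0, 1.0, 2.0] * 4)
        y = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0] * 2)
        x = np.arange(12.0)
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        # g(0) = sum (z - zbar) y = 0 exactly for this design
        d = iv._prepare(df, "z", (), "x")
        assert iv._msmm_kernel(d.y, d.x, d.z, d.C) == pytest.approx(0.0, abs=1e-8)

    def test_msmm_recovers_psi_under_loglinear_dgp(self):
        # prospective log-linear risk DGP: G-estimate recovers the true psi
        psi_true = -0.04
        estimates = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            n = 6000
            z = rng.binomial(2, 0.5, n).astype(float)
            x = 10.0 + 1.5 * z + rng.normal(0, 3, n)
            risk = np.exp(-2.2 + psi_true * x)
            y = rng.binomial(1, np.clip(risk, 0, 1)).astype(float)
            df = pd.DataFrame({"y": y, "x": x, "z": z})
            d = iv._prepare(df, "z", (), "x")
            estimates.append(iv._msmm_kernel(d.y, d.x, d.z, d.C))
        mean, se = np.mean(estimates), np.std(estimates) / np.sqrt(len(estimates))
        assert abs(mean - psi_true) < 2 * se + 1e-3

    def test_non_identified_reported_with_endpoints(self):
        # cases only in the top genotype group: every term of the estimating
        # function is positive, so it has no root at any psi
        z = np.array([0.0, 1.0, 2.0] * 10)
        y = (z == 2).astype(float)
        df = pd.DataFrame({"y": y, "x": np.linspace(5, 20, 30), "z": z})
        d = iv._prepare(df, "z", (), "x")
        with pytest.raises(NonIdentifiedError, match="sign change"):
            iv._msmm_kernel(d.y, d.x, d.z, d.C)


class TestEstimatorBehaviour:
    def test_bootstrap_reproducible(self, iv_frame):
        a = control_function(iv_frame, "z", exposure="x", n_boot=100, seed=9)
        b = control_function(iv_frame, "z", exposure="x", n_boot=100, seed=9)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_weak_instrument_refusal(self):
        rng = np.random.default_rng(0)
        n = 400
        df = pd.DataFrame({
            "y": rng.binomial(1, 0.5, n).astype(float),
            "x": rng.normal(12, 5, n),
            "z": rng.binomial(2, 0.5, n).astype(float),
        })
        # make the instrument-exposure slope essentially exactly zero
        slope = np.polyfit(df.z, df.x, 1)[0]
        df["x"] = df["x"] - slope * df["z"]
        with pytest.raises(WeakInstrumentError):
            wald_ratio(df, "z", exposure="x")

    def test_stronger_instrument_narrows_bootstrap_ci(self):
        from vitdmr.datatypes import SNPSpec
        wins, reps = 0, 100
        for seed in range(reps):
            widths = []
            for beta in (1.0, 2.0):
                cfg = scaled_config(
                    n_population=8_000, n_cases=400, n_controls=400,
                    snps=[SNPSpec("rs_s", 0.4, beta, "synthesis")],
                    gamma_u_x=0.0, gamma_u_y=0.0, month_effects=(0.0,) * 12,
                    seed=seed)
                c = generate_cohort(cfg)
                e = two_stage(c, "rs_s", exposure="x_raw", n_boot=60, seed=seed)
                widths.append(np.log(e.ci_high) - np.log(e.ci_low))
            wins += widths[1] < widths[0]
        assert wins >= 0.8 * reps


class TestTable4Grid:
    def test_grid_shape_and_failure_isolation(self, cohort):
        grid = run_table4(cohort, estimators=("wald",), n_boot=0, seed=0)
        assert len(grid) == 7 * 2  # instruments x adjustments
        assert set(grid["adjusted"]) == {"none", "age+sex"}
        # weak instruments are flagged, not dropped
        ok = grid[grid["note"] == ""]
        assert len(ok) >= 12
        assert (ok["or_per_unit"] > 0).all()
        assert ((ok["ci_low"] <= ok["or_per_unit"])
                & (ok["or_per_unit"] <= ok["ci_high"])).all()

    def test_duplicated_cohort_is_deterministic(self, cohort):
        doubled = pd.concat([cohort, cohort], ignore_index=True)
        a = run_table4(doubled, estimators=("wald",),
                       instruments=("overall",), n_boot=0, seed=3)
        b = run_table4(doubled, estimators=("wald",),
                       instruments=("overall",), n_boot=0, seed=3)
        pd.testing.assert_frame_equal(a, b)
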
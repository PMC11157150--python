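import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from heatacc.gam import (
    AdditiveModel,
    Factor,
    Linear,
    RandomIntercept,
    Spline,
    _cyclic_basis,
    _pspline_basis,
)


def _sine_data(seed=1, n=300, amp=1.0, sd=0.3):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    ind = rng.integers(0, 5, n)
    b_ind = rng.normal(0, 0.5, 5)
    y = amp * np.sin(2 * np.pi * x) + b_ind[ind] + rng.normal(0, sd, n)
    return pd.DataFrame({"x": x, "individual_id": [f"i{i}" for i in ind]}), y, ind


class TestBases:
    def test_pspline_partition_of_unity(self):
        x = np.linspace(0, 1, 50)
        B = _pspline_basis(x, 10, 0.0, 1.0)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_cyclic_partition_of_unity_and_periodicity(self):
        x = np.linspace(0, 24, 97)
        B = _cyclic_basis(x, 8, 24.0)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(
            _cyclic_basis(np.array([0.0]), 8, 24.0),
            _cyclic_basis(np.array([24.0]), 8, 24.0),
            atol=1e-10,
        )

    def test_cyclic_fit_joins_smoothly_at_wrap(self):
        rng = np.random.default_rng(3)
        h = rng.uniform(0, 24, 400)
        y = np.cos(2 * np.pi * h / 24) + rng.normal(0, 0.2, 400)
        df = pd.DataFrame({"hour": h})
        fit = AdditiveModel([Spline("hour", k=8, cyclic=True, period=24.0)]).fit(df, y)
        e0, _ = fit.partial_effect("s(hour)", np.array([0.001]))
        e24, _ = fit.partial_effect("s(hour)", np.array([23.999]))
        assert e0[0] == pytest.approx(e24[0], abs=0.01)


class TestFitting:
    def test_sine_recovery_with_random_intercepts(self):
        df, y, ind = _sine_data()
        fit = AdditiveModel([Spline("x", k=10), RandomIntercept("individual_id")]).fit(
            df, y
        )
        grid = np.linspace(0.05, 0.95, 21)
        est, se = fit.partial_effect("s(x)", grid)
        truth = np.sin(2 * np.pi * grid)
        truth = truth - truth.mean()
        est = est - est.mean()
        assert np.max(np.abs(est - truth)) < 0.25
        # noise variance recovered
        assert fit.phi == pytest.approx(0.09, abs=0.04)

    def test_matches_mgcv_reference(self, tmp_path):
        """The engine agrees with mgcv (REML P-spline + random intercept)."""
        df, y, ind = _sine_data()
        fit = AdditiveModel([Spline("x", k=10), RandomIntercept("individual_id")]).fit(
            df, y
        )
        grid = np.linspace(0.05, 0.95, 10)
        est, _ = fit.partial_effect("s(x)", grid)
        data_path = tmp_path / "d.csv"
        pd.DataFrame({"x": df["x"], "y": y, "ind": ind}).to_csv(data_path, index=False)
        script = tmp_path / "check.R"
        script.write_text(
            textwrap.dedent(
                f"""
                library(mgcv)
                d <- read.csv("{data_path}")
                d$ind <- factor(d$ind)
                fit <- gam(y ~ s(x, k=10, bs="ps") + s(ind, bs="re"),
                           data=d, method="REML")
                g <- data.frame(x=seq(0.05, 0.95, length.out=10),
                                ind=factor(0, levels=levels(d$ind)))
                pe <- predict(fit, g, type="terms")[, "s(x)"]
                cat(summary(fit)$s.table[1, 1], fit$sig2, pe, sep="\\n")
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        edf_r, sig2_r, pe_r = vals[0], vals[1], np.array(vals[2:])
        assert fit.term_edf("s(x)") == pytest.approx(edf_r, abs=0.2)
        assert fit.phi == pytest.approx(sig2_r, rel=0.05)
        np.testing.assert_allclose(est, pe_r, atol=0.05)

    def test_unpenalized_limit_recovers_least_squares(self):
        """With no penalized term the fit equals the normal-equation solution."""
        rng = np.random.default_rng(4)
        n = 60
        x = rng.uniform(0, 1, n)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.1, n)
        df = pd.DataFrame({"x": x})
        fit = AdditiveModel([Linear("x")]).fit(df, y)
        X = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-8)

    def test_smooth_of_pure_noise_shrinks_toward_null(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.uniform(0, 1, 200)})
        y = rng.normal(0, 1, 200)
        fit = AdditiveModel([Spline("x", k=10)]).fit(df, y)
        assert fit.term_edf("s(x)") < 3.5

    def test_quasibinomial_recovers_logit_slope_shape(self):
        rng = np.random.default_rng(7)
        n = 250
        x = rng.uniform(-2, 2, n)
        w = np.full(n, 50.0)
        p = 1 / (1 + np.exp(-x))
        y = rng.binomial(50, p) / 50.0
        df = pd.DataFrame({"x": x})
        fit = AdditiveModel([Spline("x", k=10)], family="quasibinomial").fit(
            df, y, weights=w
        )
        grid = np.linspace(-1.5, 1.5, 7)
        est, _ = fit.partial_effect("s(x)", grid)
        # logit-scale partial effect should track x (centered)
        assert np.corrcoef(est, grid)[0, 1] > 0.99
        assert np.polyfit(grid, est, 1)[0] == pytest.approx(1.0, abs=0.2)

    def test_null_partial_effect_flat_within_two_se(self):
        flat = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            df = pd.DataFrame({"x": rng.uniform(0, 1, 150)})
            y = rng.normal(0, 1, 150)
            fit = AdditiveModel([Spline("x", k=10)]).fit(df, y)
            est, se = fit.partial_effect("s(x)", np.linspace(0.1, 0.9, 9))
            if np.all(np.abs(est) <= 2 * se + 1e-9):
                flat += 1
        assert flat >= 8


class TestInference:
    def test_strong_smooth_significant_null_not(self):
        df, y, _ = _sine_data(seed=2, amp=1.0)
        fit = AdditiveModel([Spline("x", k=10), RandomIntercept("individual_id")]).fit(df, y)
        assert fit.smooth_test("s(x)")[3] < 1e-6
        df0, y0, _ = _sine_data(seed=2, amp=0.0)
        fit0 = AdditiveModel([Spline("x", k=10), RandomIntercept("individual_id")]).fit(df0, y0)
        assert fit0.smooth_test("s(x)")[3] > 0.05

    def test_factor_contrast_t_test(self):
        rng = np.random.default_rng(8)
        n = 200
        g = rng.choice(["a", "b"], n)
        y = (g == "b") * 1.0 + rng.normal(0, 0.5, n)
        fit = AdditiveModel([Factor("g")]).fit(pd.DataFrame({"g": g}), y)
        tab = fit.coef_table("g")
        assert tab["term"].iloc[0] == "g[b]"
        assert tab["estimate"].iloc[0] == pytest.approx(1.0, abs=0.25)
        assert tab["p_value"].iloc[0] < 1e-6


class TestConcurvity:
    def test_independent_covariates_near_zero(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"x": rng.uniform(0, 1, 200), "z": rng.uniform(0, 1, 200)})
        y = np.sin(2 * np.pi * df["x"]) + rng.normal(0, 0.3, 200)
        fit = AdditiveModel([Spline("x", k=8), Spline("z", k=8)]).fit(df, y.to_numpy())
        vals = fit.concurvity()
        assert vals["s(x)"] < 0.35 and vals["s(z)"] < 0.35

    def test_duplicated_covariate_near_one(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 1, 200)
        df = pd.DataFrame({"x": x, "x2": x + rng.normal(0, 1e-6, 200)})
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.3, 200)
        fit = AdditiveModel([Spline("x", k=8), Spline("x2", k=8)]).fit(df, y)
        assert fit.concurvity()["s(x)"] > 0.95

    def test_values_within_unit_interval(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"x": rng.uniform(0, 1, 100), "z": rng.uniform(0, 1, 100)})
        y = rng.normal(0, 1, 100)
        fit = AdditiveModel([Spline("x", k=6), Spline("z", k=6)]).fit(df, y)
        for v in fit.concurvity().values():
            assert 0.0 <= v <= 1.0
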
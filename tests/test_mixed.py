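"""Mixed models: reduction oracles, quadrature stability, LRT, contrasts, VIF."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from callcontext import mixed
from callcontext.mixed import (
    LEVEL_ORDERS,
    ModelSpec,
    build_design,
    fit_logistic_mixed,
    fit_model,
    fit_zip_mixed,
    likelihood_ratio_test,
    model_spec,
    pairwise_contrasts,
    response_differences,
    vif,
)


def simple_spec(family: str) -> ModelSpec:
    return ModelSpec("toy", "y", family, ("x",), (), group_col="g")


def poisson_data(n=600, beta0=0.8, beta1=0.5, seed=0, n_groups=12) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float)
    lam = np.exp(beta0 + beta1 * x)
    return pd.DataFrame({"y": rng.poisson(lam), "x": x, "g": np.arange(n) % n_groups})


def bernoulli_data(n=600, beta0=-0.3, beta1=0.9, seed=0, n_groups=12) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float)
    p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
    return pd.DataFrame({"y": rng.binomial(1, p), "x": x, "g": np.arange(n) % n_groups})


class TestReductionOracles:
    def test_zip_reduces_to_fixed_effect_zip_glm(self):
        """Data with no group effect: the mixed fit collapses to the
        fixed-effects zero-inflated Poisson (statsmodels oracle) within
        1e-3, and stays near a plain Poisson fit since the data carry no
        real zero excess."""
        from statsmodels.discrete.count_model import ZeroInflatedPoisson

        data = poisson_data(seed=1)
        fit = fit_zip_mixed(simple_spec("zip"), data)
        n = len(data)
        X = np.column_stack([np.ones(n), data["x"].to_numpy()])
        oracle = ZeroInflatedPoisson(
            data["y"].to_numpy(), X, exog_infl=np.ones((n, 1)), inflation="logit"
        ).fit(disp=0)
        assert fit.beta["intercept"] == pytest.approx(oracle.params[1], abs=1e-3)
        assert fit.beta["x"] == pytest.approx(oracle.params[2], abs=1e-3)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-4)
        assert fit.sigma_b < 0.05
        glm = sm.GLM(data["y"].to_numpy(), X, family=sm.families.Poisson()).fit()
        assert fit.beta["intercept"] == pytest.approx(glm.params[0], abs=0.02)
        assert fit.zi_prob < 0.02

    def test_logistic_reduces_to_logit_glm(self):
        data = bernoulli_data(seed=2)
        fit = fit_logistic_mixed(simple_spec("binomial"), data)
        X = sm.add_constant(data["x"].to_numpy())
        glm = sm.GLM(data["y"].to_numpy(), X, family=sm.families.Binomial()).fit()
        assert fit.beta["intercept"] == pytest.approx(glm.params[0], abs=1e-3)
        assert fit.beta["x"] == pytest.approx(glm.params[1], abs=1e-3)


class TestQuadrature:
    def test_loglik_stable_order_20_to_40(self):
        rng = np.random.default_rng(3)
        n, groups = 72, 9
        g = np.arange(n) % groups
        b = rng.normal(0, 0.4, groups)
        x = rng.binomial(1, 0.5, n).astype(float)
        y = rng.poisson(np.exp(0.5 + 0.5 * x + b[g]))
        data = pd.DataFrame({"y": y, "x": x, "g": g})
        f20 = fit_zip_mixed(simple_spec("zip"), data, quadrature_order=20)
        ll40 = mixed.marginal_loglik(f20, data, quadrature_order=40)
        assert abs(f20.loglik - ll40) < 1e-4
        assert f20.loglik == pytest.approx(mixed.marginal_loglik(f20, data), abs=1e-9)


class TestValidation:
    def test_negative_counts_direct_to_floor_flag(self):
        data = poisson_data()
        data.loc[0, "y"] = -2
        with pytest.raises(ValueError, match="floor"):
            fit_zip_mixed(simple_spec("zip"), data)

    def test_binary_response_required(self):
        data = poisson_data()
        with pytest.raises(ValueError, match="binary"):
            fit_logistic_mixed(simple_spec("binomial"), data)

    def test_single_group_rejected(self):
        data = poisson_data()
        data["g"] = 0
        with pytest.raises(ValueError, match="group"):
            fit_zip_mixed(simple_spec("zip"), data)

    def test_all_zero_response_flagged_as_separation(self):
        data = bernoulli_data()
        data["y"] = 0
        fit = fit_logistic_mixed(simple_spec("binomial"), data)
        assert fit.separation_suspected or fit.beta["intercept"] < -8


class TestLrt:
    def test_identical_models_give_chi2_zero(self):
        data = poisson_data(n=120)
        fit = fit_zip_mixed(simple_spec("zip"), data)
        res = likelihood_ratio_test(fit, fit)
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_full_loglik_at_least_null(self, playback_experiment):
        _, _, trials = playback_experiment
        full, null, lrt = fit_model(1, trials, quadrature_order=12, restarts=1)
        assert full.loglik >= null.loglik - 1e-6
        assert lrt.df == 4  # sex + receiver + 2 trigger dummies
        assert 0 <= lrt.p <= 1

    def test_non_nested_rejected(self):
        data = poisson_data(n=120)
        a = fit_zip_mixed(simple_spec("zip"), data)
        other = ModelSpec("toy2", "y", "zip", (), (), group_col="g")
        b = fit_zip_mixed(other, data)
        res = likelihood_ratio_test(a, b)  # nested: ok
        assert res.df == 1
        with pytest.raises(ValueError):
            likelihood_ratio_test(b, a)  # reversed: null has more params


class TestContrasts:
    def test_three_levels_three_rows_and_adjustment(self, playback_experiment):
        _, _, trials = playback_experiment
        full, _, _ = fit_model(1, trials, quadrature_order=12, restarts=1)
        for method in ("bonferroni", "tukey"):
            ct = pairwise_contrasts(full, "trigger_context", method=method)
            assert len(ct) == 3  # C(3,2)
            assert (ct["p_adjusted"] >= ct["p_raw"] - 1e-12).all()
        labels = set(pairwise_contrasts(full, "trigger_context")["contrast"])
        assert "high_social - low_social" in labels  # baseline named explicitly

    def test_equal_levels_give_z_zero(self):
        """A hand-built fit with two identical level effects."""
        beta = pd.Series({"intercept": 0.5, "f[a]": 0.3, "f[b]": 0.3})
        cov = pd.DataFrame(np.eye(3) * 0.04, index=beta.index, columns=beta.index)
        fit = mixed.MixedFit(
            spec=ModelSpec("hand", "y", "zip", ("f",), ()),
            beta=beta,
            zi_logit=0.0,
            sigma_b=0.1,
            loglik=-10.0,
            converged=True,
            n_obs=10,
            n_groups=2,
            quadrature_order=20,
            cov=cov,
            gradient_norm=0.0,
            baselines={"f": "base"},
        )
        ct = pairwise_contrasts(fit, "f").set_index("contrast")
        assert ct.loc["a - b", "z"] == pytest.approx(0.0)
        assert ct.loc["a - b", "p_adjusted"] == pytest.approx(1.0)


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(4)
        n = 400
        X = pd.DataFrame({"intercept": 1.0, "a": rng.normal(size=n), "b": rng.normal(size=n)})
        assert (vif(X) < 1.05).all()

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=100)
        X = pd.DataFrame({"intercept": 1.0, "a": a, "b": a})
        assert np.isinf(vif(X)).any()

    def test_balanced_playback_design_low_collinearity(self, playback_experiment):
        """The crossed factor design keeps all VIFs below 2.5, consistent
        with a well-conditioned playback protocol."""
        _, _, trials = playback_experiment
        data = response_differences(trials)
        data = data[data["trigger_context"] != "grunt"]
        X = build_design(data, model_spec(1).fixed_terms)
        assert (vif(X) < 2.5).all()


class TestModelPresets:
    def test_response_differences_columns(self, playback_experiment):
        _, _, trials = playback_experiment
        out = response_differences(trials)
        assert (out["gaze_diff"] == out["gazes_after"] - out["gazes_before"]).all()
        assert (out["sdb_diff"] == out["sdb_after"] - out["sdb_before"]).all()

    def test_model4_subset_is_grooming_high_vs_grunt(self, playback_experiment):
        _, _, trials = playback_experiment
        sub = mixed.filter_model4(trials)
        assert set(sub["trigger_context"]) == {"grunt", "high_social"}
        assert set(sub["receiver_context"]) == {"social"}
        assert len(sub) == 18  # 9 subjects x 2 grooming sessions

    def test_models_1_to_3_exclude_grunts(self, playback_experiment):
        _, _, trials = playback_experiment
        full, _, _ = fit_model(3, trials, quadrature_order=12, restarts=1)
        assert full.n_obs == 54  # 9 subjects x 6 yawn-stimulus sessions
        assert full.baselines["trigger_context"] == "high_social"
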
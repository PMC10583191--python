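"""AICc multimodel inference, model averaging, PCA and SMA regression."""

import math

import numpy as np
import pandas as pd
import pytest

from phenoseason import inference
from phenoseason.errors import DomainError, InsufficientDataError
from phenoseason.inference import CandidateModel, ModelSet


def make_data(n=60, p=4, seed=0, beta=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    names = [f"x{i}" for i in range(p)]
    beta = np.zeros(p) if beta is None else np.asarray(beta)
    y = X @ beta + rng.normal(size=n)
    df = pd.DataFrame(X, columns=names)
    df["y"] = y
    return df, names


class TestAICc:
    def test_small_sample_correction_value(self):
        # loglik -47, k=3, n=20: AIC = 100, correction = 24/16 = 1.5
        assert inference.aicc(-47.0, 3, 20) == pytest.approx(101.5)

    def test_denominator_guard(self):
        with pytest.raises(InsufficientDataError):
            inference.aicc(-1.0, 5, 6)


class TestAllSubsets:
    def test_four_predictors_give_sixteen_models(self):
        df, names = make_data(p=4)
        ms = inference.all_subsets("y", names, df)
        assert len(ms.models) == 16

    def test_weights_follow_delta_rule(self):
        df, names = make_data(p=3, beta=[0.5, 0, 0], seed=2)
        ms = inference.all_subsets("y", names, df)
        deltas = np.array([m.delta for m in ms.models])
        weights = np.array([m.weight for m in ms.models])
        expected = np.exp(-deltas / 2)
        expected /= expected.sum()
        assert np.allclose(weights, expected)
        assert weights.sum() == pytest.approx(1.0)
        assert deltas.min() == 0.0

    def test_two_model_weights_at_delta_two(self):
        # delta {0, 2} -> weights e^0 : e^-1 normalized = {0.731, 0.269}
        raw = np.exp(-np.array([0.0, 2.0]) / 2.0)
        w = raw / raw.sum()
        assert w[0] == pytest.approx(0.731, abs=5e-4)
        assert w[1] == pytest.approx(0.269, abs=5e-4)

    def test_weights_invariant_to_constant_aicc_shift(self):
        deltas = np.array([0.0, 1.2, 3.4])
        for shift in (0.0, 57.0):
            raw = np.exp(-(deltas + shift - (deltas + shift).min()) / 2.0)
            assert np.allclose(raw / raw.sum(),
                               np.exp(-deltas / 2) / np.exp(-deltas / 2).sum())

    def test_constant_column_rejected(self):
        df, names = make_data(p=2)
        df["x0"] = 1.0
        with pytest.raises(DomainError):
            inference.all_subsets("y", names, df)


def window_set(models):
    ms = ModelSet("y", sorted({p for m in models for p in m.predictors}),
                  models, n=100)
    return ms


class TestAverageEffects:
    def make_model(self, predictors, weight, coef=0.5, delta=0.0):
        return CandidateModel(
            predictors=tuple(predictors),
            coef={p: coef for p in predictors},
            ci={p: (coef - 0.2, coef + 0.2) for p in predictors},
            loglik=0.0, k=len(predictors) + 2, aicc=0.0,
            delta=delta, weight=weight,
        )

    def test_importance_definition(self):
        ms = window_set([
            self.make_model(["X"], 0.7),
            self.make_model(["X", "Y"], 0.3),
        ])
        out = inference.average_effects(ms).set_index("predictor")
        assert out.loc["X", "importance"] == pytest.approx(1.0)
        assert out.loc["Y", "importance"] == pytest.approx(0.3)

    def test_single_model_window_returns_its_coefficients(self):
        ms = window_set([self.make_model(["X"], 1.0, coef=0.42)])
        out = inference.average_effects(ms).set_index("predictor")
        assert out.loc["X", "estimate"] == pytest.approx(0.42)
        assert out.loc["X", "ci_low"] == pytest.approx(0.22)

    def test_absent_predictor_has_zero_importance(self):
        models = [
            self.make_model(["X"], 0.9),
            self.make_model(["Y"], 0.1, delta=5.0),  # outside the window
        ]
        out = inference.average_effects(window_set(models)).set_index(
            "predictor"
        )
        assert out.loc["Y", "importance"] == 0.0
        assert out.loc["Y", "estimate"] is None or np.isnan(
            out.loc["Y", "estimate"]
        )

    def test_true_predictor_beats_nulls_in_simulation(self):
        # mean importance over replicates: the true effect must dominate
        # every null predictor
        rows = []
        n_rep = 20
        for seed in range(n_rep):
            df, names = make_data(
                n=200, p=5, seed=1000 + seed, beta=[0.5, 0, 0, 0, 0]
            )
            ms = inference.all_subsets("y", names, df)
            out = inference.average_effects(ms).set_index("predictor")
            rows.append(out["importance"])
        mean_importance = pd.concat(rows, axis=1).mean(axis=1)
        assert (mean_importance["x0"] > mean_importance.drop("x0")).all()


class TestPCA:
    def test_perfectly_correlated_pair_loads_one_axis(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2.0 * x + 1.0})
        res = inference.pca_with_supplementary(df)
        assert res.explained[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(80, 5)),
                          columns=list("abcde"))
        res = inference.pca_with_supplementary(df)
        assert res.explained.sum() == pytest.approx(1.0, abs=1e-10)

    def test_scores_centred_with_eigenvalue_variance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        res = inference.pca_with_supplementary(df)
        assert np.allclose(res.scores.mean(), 0.0, atol=1e-10)
        z = (df - df.mean()) / df.std(ddof=1)
        eigval = np.sort(np.linalg.eigvalsh(np.corrcoef(z.T)))[::-1]
        assert np.allclose(res.scores.var(ddof=1), eigval, atol=1e-8)

    def test_supplementary_equal_to_active_variable(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        df["b"] += 0.6 * df["a"]
        res = inference.pca_with_supplementary(df, df[["a"]])
        # projection = corr(a, scores) must equal sqrt(lambda) * loading
        z = (df - df.mean()) / df.std(ddof=1)
        for j, axis in enumerate(res.scores.columns):
            lam = res.scores[axis].var(ddof=1)
            expected = res.loadings.loc["a", axis] * math.sqrt(lam)
            assert res.supplementary.loc["a", axis] == pytest.approx(
                expected, abs=1e-8
            )

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        with pytest.raises(DomainError):
            inference.pca_with_supplementary(df)


class TestSMA:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = inference.sma_regression(x, 2.0 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_axis_swap_inverts_slope(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = 0.7 * x + rng.normal(0, 0.5, 50)
        forward = inference.sma_regression(x, y)
        backward = inference.sma_regression(y, x)
        assert backward.slope == pytest.approx(1.0 / forward.slope)

    def test_bivariate_normal_slope_matches_sd_ratio(self):
        rng = np.random.default_rng(5)
        n = 10_000
        x = rng.normal(size=n)
        y = 3.0 * (0.6 * x + math.sqrt(1 - 0.36) * rng.normal(size=n))
        res = inference.sma_regression(x, y)
        assert res.slope == pytest.approx(3.0, rel=0.02)
        assert res.slope > 0

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            inference.sma_regression(np.ones(5), np.arange(5.0))


class TestNoiseDoesNotFakeCertainty:
    def test_pure_noise_importance_stays_moderate(self):
        means = []
        n_rep = 25
        for seed in range(n_rep):
            df, names = make_data(n=200, p=5, seed=5000 + seed)
            ms = inference.all_subsets("y", names, df)
            out = inference.average_effects(ms)
            means.append(out["importance"].to_numpy(dtype=float))
        mean_importance = np.mean(means, axis=0)
        assert (mean_importance < 0.8).all()


class TestPrepareCovariates:
    def test_imputation_and_log_transforms(self):
        df = pd.DataFrame(
            {
                "species_id": ["a", "b"],
                "moisture": [5.0, 6.0],
                "light": [7.0, 4.0],
                "height_cm": [40.0, 80.0],
                "lateral_spread_cm_yr": [np.nan, 4.0],
                "clonal": [False, True],
                "sla": [20.0, 25.0],
                "ldmc": [200.0, 180.0],
            }
        )
        out = inference.prepare_covariates(df)
        assert out.loc[0, "log_lateral_spread"] == pytest.approx(
            math.log(0.5)
        )
        assert out.loc[1, "log_lateral_spread"] == pytest.approx(math.log(4.0))
        assert out.loc[1, "log_height"] == pytest.approx(math.log(80.0))
        assert "height_cm" not in out.columns
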
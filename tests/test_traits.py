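"""Collinearity filter, AICc, all-subsets selection, and trait clamping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from monolignol.traits import (
    TRAITS,
    SelectionError,
    TraitModel,
    TraitModelSet,
    aicc,
    all_subsets_select,
    clamp_prediction,
    collinearity_filter,
    is_percentage,
    predict_traits,
    round_features,
)


def brute_force_collinearity(X: pd.DataFrame, threshold: float) -> list[str]:
    """Independent keep-first oracle using full pairwise correlations."""
    corr = X.corr().abs()
    retained = []
    for col in X.columns:
        if X[col].std(ddof=0) == 0:
            continue
        if all(corr.loc[col, r] <= threshold for r in retained):
            retained.append(col)
    return retained


def brute_force_select(X: pd.DataFrame, y: np.ndarray, max_terms: int):
    """Independent exhaustive search with per-subset lstsq fits."""
    n = len(X)
    best = None
    for k in range(0, max_terms + 1):
        for combo in itertools.combinations(X.columns, k):
            A = np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in combo])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(np.sum((y - A @ coef) ** 2))
            rss = max(rss, max(float(y @ y), 1.0) * 1e-16 + 1e-300)
            kk = k + 1
            if n <= kk + 1:
                continue
            score = n * np.log(rss / n) + 2 * kk + 2 * kk * (kk + 1) / (n - kk - 1)
            if best is None or score < best[0] - 1e-12:
                best = (score, combo, coef)
    return best


class TestCollinearityFilter:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=30)})
        assert collinearity_filter(X) == ["a", "c"]

    def test_below_threshold_both_retained(self):
        # construct a pair with |r| = 0.94 exactly
        n = 200
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        z -= z.mean() + 0.0
        z -= x * (x @ z) / (x @ x)  # orthogonalise
        z /= z.std()
        r = 0.94
        y = r * x + np.sqrt(1 - r * r) * z
        X = pd.DataFrame({"a": x, "b": y})
        assert collinearity_filter(X, threshold=0.95) == ["a", "b"]
        assert collinearity_filter(X, threshold=0.93) == ["a"]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(40, 4))
        cols = {}
        for j in range(10):
            i = j % 4
            cols[f"c{j}"] = base[:, i] + rng.normal(scale=0.1 * (j + 1), size=40)
        X = pd.DataFrame(cols)
        assert collinearity_filter(X, 0.95) == brute_force_collinearity(X, 0.95)

    def test_zero_variance_dropped_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            assert collinearity_filter(X) == ["a"]


class TestAICc:
    def test_direct_formula(self):
        n, k, rss = 20, 3, 10.0
        expect = n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert aicc(rss, n, k) == pytest.approx(expect)

    def test_approaches_aic_for_large_n(self):
        k, rss_per_n = 3, 0.5
        for n in (100, 10_000):
            a = aicc(rss_per_n * n, n, k)
            aic = n * np.log(rss_per_n) + 2 * k
            if n == 10_000:
                assert abs(a - aic) < 0.01
            else:
                assert abs(a - aic) < 0.3

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError, match="n=5"):
            aicc(1.0, n=5, k=4)


class TestAllSubsets:
    def test_noise_free_single_predictor(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(30, 5)),
                         columns=["x1", "x2", "x3", "x4", "x5"])
        y = 2.0 * X["x1"].to_numpy()
        model = all_subsets_select(X, y, max_terms=3)
        assert model.predictors == ("x1",)
        assert model.coefficients[0] == pytest.approx(2.0, abs=1e-8)
        assert model.intercept == pytest.approx(0.0, abs=1e-8)

    def test_single_candidate_column(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"only": rng.normal(size=20)})
        y = 1.5 * X["only"].to_numpy() + rng.normal(scale=0.1, size=20)
        model = all_subsets_select(X, y, max_terms=2)
        assert model.predictors == ("only",)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 25, 6
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{j}" for j in range(p)])
        k_true = rng.integers(1, 4)
        support = rng.choice(p, size=k_true, replace=False)
        y = X.iloc[:, support].to_numpy() @ rng.normal(size=k_true)
        y = y + rng.normal(scale=0.5, size=n)
        model = all_subsets_select(X, y, max_terms=4)
        score, combo, coef = brute_force_select(X, y, max_terms=4)
        assert model.predictors == combo
        assert model.aicc == pytest.approx(score, rel=1e-9)

    def test_selected_aicc_is_global_minimum(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(20, 4)),
                         columns=["a", "b", "c", "d"])
        y = X["b"].to_numpy() + rng.normal(scale=0.3, size=20)
        model = all_subsets_select(X, y, max_terms=3)
        for k in range(0, 4):
            for combo in itertools.combinations(X.columns, k):
                A = np.column_stack([np.ones(20)]
                                    + [X[c].to_numpy() for c in combo])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                rss = max(float(np.sum((y - A @ coef) ** 2)), 1e-12)
                assert model.aicc <= aicc(rss, 20, k + 1) + 1e-9

    def test_refuses_tiny_sample(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(SelectionError, match="rows"):
            all_subsets_select(X, np.array([1.0, 2.0, 3.0]), max_terms=2)


class TestClampedPrediction:
    def _model(self, trait, predictors=("V1",), coef=(1.0,), intercept=0.0):
        return TraitModel(
            trait=trait, predictors=predictors, intercept=intercept,
            coefficients=coef, aicc=0.0, adjusted_r_squared=1.0,
            max_terms=5, clamp_percentage=is_percentage(trait),
        )

    def test_negative_prediction_clamped_to_zero(self):
        m = self._model("lignin_content", intercept=-5.0, coef=(0.0,))
        X = pd.DataFrame({"V1": [1.0]})
        assert m.predict(X)[0] == 0.0

    def test_percentage_capped_at_100(self):
        m = self._model("beta_O_4", intercept=120.0, coef=(0.0,))
        X = pd.DataFrame({"V1": [1.0]})
        assert m.predict(X)[0] == 100.0

    def test_in_range_prediction_unchanged(self):
        m = self._model("glucose", intercept=45.3, coef=(0.0,))
        X = pd.DataFrame({"V1": [1.0]})
        assert m.predict(X)[0] == pytest.approx(45.3)

    def test_non_percentage_not_capped(self):
        m = self._model("moe", intercept=4000.0, coef=(0.0,))
        X = pd.DataFrame({"V1": [1.0]})
        assert m.predict(X)[0] == pytest.approx(4000.0)

    @settings(deadline=None, max_examples=50)
    @given(v=st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
           pct=st.booleans())
    def test_clamp_idempotent(self, v, pct):
        once = clamp_prediction(v, pct)
        assert clamp_prediction(once, pct) == once

    def test_missing_selected_column_named(self):
        m = self._model("glucose", predictors=("V9",))
        with pytest.raises(KeyError, match="V9"):
            m.predict(pd.DataFrame({"V1": [1.0]}))


class TestTraitRegistry:
    def test_25_traits_with_18_percentages(self):
        assert len(TRAITS) == 25
        assert sum(t.is_percentage for t in TRAITS) == 18

    def test_rounding_to_five_decimals(self):
        X = pd.DataFrame({"V1": [0.123456789, 1e-7]})
        out = round_features(X)
        assert out["V1"].iloc[0] == 0.12346
        assert out["V1"].iloc[1] == 0.0

    def test_model_set_json_round_trip(self, tmp_path):
        m = TraitModel("glucose", ("V1", "M2"), 1.0, (0.5, -2.0), -12.3, 0.9,
                       5, True)
        ms = TraitModelSet({"glucose": m})
        ms.to_json(tmp_path / "m.json")
        back = TraitModelSet.from_json(tmp_path / "m.json")
        assert back["glucose"] == m
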
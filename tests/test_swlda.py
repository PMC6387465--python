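"""Stepwise LDA: oracle equivalence, invariants, scoring semantics."""

import numpy as np
import pytest

from neuroproxy.swlda import (FeatureMatrix, SWLDAConfig, discriminant_scores,
                              fit_swlda)


def _fm(X, y, names=None):
    names = names or [f"f{j}" for j in range(X.shape[1])]
    return FeatureMatrix(X=X, y=y, feature_names=names)


def stepwise_oracle(X, y, alpha_enter=0.05, alpha_remove=0.1):
    """Brute-force stepwise selection: full OLS refit per candidate."""
    import statsmodels.api as sm

    n, m = X.shape
    selected = []
    while True:
        changed = False
        best = None
        for j in range(m):
            if j in selected:
                continue
            D = sm.add_constant(X[:, selected + [j]], has_constant="add")
            p = sm.OLS(y, D).fit().pvalues[-1]
            if best is None or p < best[1]:
                best = (j, p)
        if best is not None and best[1] < alpha_enter and len(selected) < n - 3:
            selected.append(best[0])
            changed = True
        while selected:
            D = sm.add_constant(X[:, selected], has_constant="add")
            pv = sm.OLS(y, D).fit().pvalues[1:]
            worst = int(np.argmax(pv))
            if pv[worst] > alpha_remove:
                selected.pop(worst)
                changed = True
            else:
                break
        if not changed:
            return selected


class TestSelection:
    def test_dominant_predictor_selected_first(self, rng):
        n = 60
        y = rng.integers(0, 2, n).astype(float)
        X = rng.standard_normal((n, 5))
        X[:, 3] = y + 1e-3 * rng.standard_normal(n)
        model = fit_swlda(_fm(X, y))
        assert model.feature_names[0] == "f3"
        scores = discriminant_scores(model, _fm(X, y))
        assert np.all(scores[y == 1] > scores[y == 0].max())

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_bruteforce_oracle_on_small_instances(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(16, 41))
        m = int(r.integers(2, 7))
        X = r.standard_normal((n, m))
        y = (r.standard_normal(n)
             + X[:, 0] * r.uniform(0, 1.5) > 0).astype(float)
        if y.sum() < 2 or y.sum() > n - 2:
            pytest.skip("degenerate label draw")
        model = fit_swlda(_fm(X, y))
        got = [int(nm[1:]) for nm in model.feature_names]
        assert got == stepwise_oracle(X, y)

    def test_null_features_family_wise_entry_rate(self):
        # 20 pure-noise candidates at alpha_enter=0.05: the chance that at
        # least one enters is approx 1 - 0.95^20 = 0.64 per replicate
        reps, hits = 200, 0
        for s in range(reps):
            r = np.random.default_rng(10_000 + s)
            X = r.standard_normal((500, 20))
            y = (r.standard_normal(500) > 0).astype(float)
            hits += fit_swlda(_fm(X, y)).n_features > 0
        assert 0.52 <= hits / reps <= 0.80

    def test_deterministic_same_input_same_model(self, rng):
        X = rng.standard_normal((50, 8))
        y = (X[:, 1] + 0.5 * rng.standard_normal(50) > 0).astype(float)
        m1 = fit_swlda(_fm(X, y))
        m2 = fit_swlda(_fm(X.copy(), y.copy()))
        assert m1.feature_names == m2.feature_names
        assert np.allclose(m1.weights, m2.weights)
        assert m1.intercept == pytest.approx(m2.intercept)

    def test_max_features_cap_respected(self, rng):
        X = rng.standard_normal((200, 30))
        beta = rng.uniform(0.5, 1.0, 30)
        y = (X @ beta + 0.1 * rng.standard_normal(200) > 0).astype(float)
        model = fit_swlda(_fm(X, y), SWLDAConfig(max_features=3))
        assert model.n_features <= 3

    def test_single_class_labels_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(ValueError, match="both classes"):
            fit_swlda(_fm(X, np.ones(20)))

    def test_duplicate_column_skipped_not_fatal(self, rng):
        X = rng.standard_normal((40, 3))
        X[:, 2] = X[:, 0]  # exact duplicate becomes rank-deficient once f0 in
        y = (X[:, 0] > 0).astype(float)
        model = fit_swlda(_fm(X, y))
        assert "f0" in model.feature_names
        assert "f2" not in model.feature_names


class TestScoring:
    def test_hand_set_weights(self):
        from neuroproxy.swlda import SWLDAModel
        model = SWLDAModel(feature_names=["a", "b"],
                           weights=np.array([2.0, -1.0]), intercept=1.0)
        fm = _fm(np.array([[1.0, 1.0], [0.0, 3.0]]),
                 np.array([1.0, 0.0]), names=["a", "b"])
        assert discriminant_scores(model, fm).tolist() == [2.0, -2.0]

    def test_empty_model_gives_constant_scores(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.array([0.0, 1.0] * 15)
        from neuroproxy.swlda import SWLDAModel
        model = SWLDAModel(feature_names=[], weights=np.empty(0),
                           intercept=0.5)
        assert np.ptp(discriminant_scores(model, _fm(X, y))) == 0.0

    def test_scores_align_features_by_name(self, rng):
        X = rng.standard_normal((80, 4))
        y = (X[:, 2] > 0).astype(float)
        model = fit_swlda(_fm(X, y))
        perm = [3, 1, 0, 2]
        fm_perm = _fm(X[:, perm], y, names=[f"f{j}" for j in perm])
        assert np.allclose(discriminant_scores(model, _fm(X, y)),
                           discriminant_scores(model, fm_perm))

    def test_missing_named_feature_raises(self, rng):
        X = rng.standard_normal((40, 3))
        y = (X[:, 0] > 0).astype(float)
        model = fit_swlda(_fm(X, y))
        bad = _fm(X[:, 1:], y, names=["g1", "g2"])
        with pytest.raises(KeyError):
            discriminant_scores(model, bad)


class TestConvergenceInvariant:
    @pytest.mark.parametrize("seed", [0, 7, 21, 99])
    def test_invariant_holds_after_fit(self, seed):
        # fit_swlda itself raises AssertionError if any included feature is
        # above alpha_remove or an excluded one is below alpha_enter
        r = np.random.default_rng(seed)
        X = r.standard_normal((120, 12))
        y = (X[:, 0] - X[:, 5] + r.standard_normal(120) > 0).astype(float)
        model = fit_swlda(_fm(X, y))
        assert model.stop_reason == "converged"
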
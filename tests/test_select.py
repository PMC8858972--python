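"""Hoeffding's D, the similarity matrix, RF importance and the elimination loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycofib.select import (
    EliminationConfig,
    RFConfig,
    SelectionTrace,
    dependence_dendrogram,
    hoeffding_d,
    iterative_elimination,
    most_correlated_pair,
    rf_importance,
    similarity_matrix,
)


def hoeffding_brute(x, y):
    """Independent O(n^2) evaluation of the scaled D from first principles:
    midranks and bivariate counts computed by explicit pairwise loops."""
    n = len(x)
    R = [1 + sum(1.0 if x[j] < x[i] else 0.5 if (j != i and x[j] == x[i]) else 0.0
                 for j in range(n)) for i in range(n)]
    S = [1 + sum(1.0 if y[j] < y[i] else 0.5 if (j != i and y[j] == y[i]) else 0.0
                 for j in range(n)) for i in range(n)]
    Q = []
    for i in range(n):
        q = 0.0
        for j in range(n):
            if j == i:
                continue
            if x[j] < x[i] and y[j] < y[i]:
                q += 1.0
            elif x[j] == x[i] and y[j] < y[i]:
                q += 0.5
            elif x[j] < x[i] and y[j] == y[i]:
                q += 0.5
            elif x[j] == x[i] and y[j] == y[i]:
                q += 0.25
        Q.append(q)
    D1 = sum(q * (q - 1) for q in Q)
    D2 = sum((r - 1) * (r - 2) * (s - 1) * (s - 2) for r, s in zip(R, S))
    D3 = sum((r - 2) * (s - 2) * q for r, s, q in zip(R, S, Q))
    return 30.0 * ((n - 2) * (n - 3) * D1 + D2 - 2 * (n - 2) * D3) / (
        n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    )


class TestHoeffdingD:
    def test_monotone_increasing_is_exactly_one(self):
        assert hoeffding_d([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == pytest.approx(1.0, abs=1e-15)

    def test_monotone_decreasing_is_exactly_one(self):
        assert hoeffding_d([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(1.0, abs=1e-15)

    def test_hand_computed_zero_case(self):
        assert hoeffding_d([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]) == pytest.approx(0.0, abs=1e-15)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert hoeffding_d(x, y) == pytest.approx(hoeffding_d(y, x), abs=1e-14)

    def test_matches_brute_force_with_and_without_ties(self, rng):
        for k in range(100):
            n = int(rng.integers(5, 31))
            if k % 2:  # discretized -> ties
                x = np.round(rng.normal(size=n), 0)
                y = np.round(rng.normal(size=n), 0)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
            else:
                x = rng.normal(size=n)
                y = rng.normal(size=n)
            assert hoeffding_d(x, y) == pytest.approx(
                hoeffding_brute(x.tolist(), y.tolist()), abs=1e-12
            )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = hoeffding_d(x, y)
        assert hoeffding_d(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert hoeffding_d(x, 3 * y + 1) == pytest.approx(base, abs=1e-12)

    def test_too_short_and_degenerate_errors(self):
        with pytest.raises(ValueError, match="at least 5"):
            hoeffding_d([1, 2, 3, 4], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="degenerate"):
            hoeffding_d([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


class TestSimilarityMatrix:
    def test_duplicate_column_gives_one(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=30)})
        sim = similarity_matrix(X)
        assert sim.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_with_unit_diagonal(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        sim = similarity_matrix(X)
        assert np.allclose(sim, sim.T)
        assert np.allclose(np.diag(sim), 1.0)

    def test_independent_features_near_zero(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(200, 6)), columns=list("abcdef"))
        sim = similarity_matrix(X).to_numpy()
        off = sim[~np.eye(6, dtype=bool)]
        assert abs(off.mean()) < 0.01

    def test_degenerate_feature_excluded(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10),
                          "c": rng.normal(size=10)})
        sim = similarity_matrix(X)
        assert list(sim.columns) == ["a", "c"]


class TestMostCorrelatedPair:
    def test_argmax(self):
        sim = pd.DataFrame(
            [[1.0, 0.1, 0.8], [0.1, 1.0, 0.2], [0.8, 0.2, 1.0]],
            index=list("fgh"), columns=list("fgh"),
        )
        assert most_correlated_pair(sim) == ("f", "h")

    def test_tie_broken_lexicographically(self):
        sim = pd.DataFrame(
            [[1.0, 0.5, 0.0, 0.0],
             [0.5, 1.0, 0.0, 0.0],
             [0.0, 0.0, 1.0, 0.5],
             [0.0, 0.0, 0.5, 1.0]],
            index=list("dcba"), columns=list("dcba"),
        )
        assert most_correlated_pair(sim) == ("a", "b")

    def test_decoy_twin_pair_found(self, default_cohort):
        table, truth = default_cohort
        decoy = truth.decoys[0]
        cols = [decoy.label, decoy.partner_label] + [
            c for c in table.feature_columns if c.startswith("IgG4.")
        ][:6]
        sim = similarity_matrix(table.features[cols])
        assert set(most_correlated_pair(sim)) == {decoy.label, decoy.partner_label}


class TestRFImportance:
    def test_separating_feature_dominates(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 30)
            X = pd.DataFrame(rng.normal(size=(60, 6)), columns=list("abcdef"))
            X["signal"] = y * 4.0 + rng.normal(0, 0.3, 60)
            imp = rf_importance(X, y, RFConfig(n_estimators=100, seed=seed))
            assert imp.idxmax() == "signal"

    def test_reproducible_given_seed(self, rng):
        y = np.repeat([0, 1, 2], 10)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        cfg = RFConfig(n_estimators=50, seed=11)
        pd.testing.assert_series_equal(rf_importance(X, y, cfg), rf_importance(X, y, cfg))

    def test_permutation_label_shuffle_kills_importance(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 25)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        X["signal"] = y * 3.0 + rng.normal(0, 0.3, 50)
        y_perm = rng.permutation(y)
        cfg = RFConfig(n_estimators=100, importance="permutation", seed=3)
        imp_true = rf_importance(X, y, cfg)
        imp_null = rf_importance(X, y_perm, cfg)
        assert imp_true["signal"] > imp_null.max()

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=list("ab"))
        with pytest.raises(ValueError, match="two classes"):
            rf_importance(X, np.zeros(10, dtype=int))


class TestIterativeElimination:
    def toy_data(self, seed=0, n=60):
        """Two informative features, one noisy twin of the first, three noise."""
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1, 2], n // 3)
        sig1 = y * 2.0 + rng.normal(0, 0.7, n)
        sig2 = -y * 2.0 + rng.normal(0, 0.7, n)
        twin = 0.6 * sig1 + rng.normal(0, 0.5, n)  # dependent but weaker
        X = pd.DataFrame(
            {
                "sig1": sig1,
                "sig2": sig2,
                "twin": twin,
                "n1": rng.normal(size=n),
                "n2": rng.normal(size=n),
                "n3": rng.normal(size=n),
            }
        )
        return X, y

    def cfg(self, seed=0, min_features=2):
        return EliminationConfig(
            rf=RFConfig(n_estimators=60, seed=seed),
            min_features=min_features,
            stop_cv_reps=3,
            seed=seed,
        )

    def test_twin_eliminated_first_and_never_the_stronger_member(self):
        X, y = self.toy_data(seed=1)
        trace = iterative_elimination(X, y, self.cfg(seed=1))
        assert trace.steps[0].eliminated == "twin"
        assert trace.steps[0].partner == "sig1"
        for step in trace.steps:
            assert step.eliminated_importance <= step.partner_importance

    def test_trace_bookkeeping(self):
        X, y = self.toy_data(seed=2)
        trace = iterative_elimination(X, y, self.cfg(seed=2))
        assert len(trace.steps) <= X.shape[1] - 2
        assert [s.iteration for s in trace.steps] == list(
            range(1, len(trace.steps) + 1)
        )
        # each iteration removes exactly one feature
        sizes = [s.n_features_after for s in trace.steps]
        assert sizes == list(range(X.shape[1] - 1, X.shape[1] - 1 - len(sizes), -1))
        assert set(trace.retained) <= set(trace.initial_features)

    def test_informative_features_survive_to_best_panel(self):
        X, y = self.toy_data(seed=3)
        trace = iterative_elimination(X, y, self.cfg(seed=3))
        assert "sig1" in trace.retained or "twin" in trace.retained
        assert "sig2" in trace.retained

    def test_trace_json_round_trip(self, tmp_path):
        X, y = self.toy_data(seed=4)
        trace = iterative_elimination(X, y, self.cfg(seed=4))
        path = tmp_path / "trace.json"
        trace.to_json(path)
        back = SelectionTrace.from_json(path)
        assert back.retained == trace.retained
        assert back.steps == trace.steps

    def test_deterministic_given_seed(self):
        X, y = self.toy_data(seed=5)
        t1 = iterative_elimination(X, y, self.cfg(seed=5))
        t2 = iterative_elimination(X, y, self.cfg(seed=5))
        assert t1.eliminated_order() == t2.eliminated_order()
        assert t1.retained == t2.retained


def test_dendrogram_shape(rng):
    X = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
    Z = dependence_dendrogram(similarity_matrix(X))
    assert Z.shape == (4, 4)
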
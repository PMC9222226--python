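import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from plasmoderf import (
    ForestParams,
    SelectionResult,
    StudySample,
    auroc,
    build_strategy_set,
    fit_lasso_comparator,
    fit_lasso_study,
    m5_pick_winner,
    train_probability_forest,
)
from plasmoderf.preceding import drop_degenerate


def _selection(names, method="lasso"):
    return SelectionResult(method, tuple(names), 0.0, {n: 1.0 for n in names})


def _current(columns=("A", "B", "C", "D"), n=40, seed=0, degenerate=()):
    rng = np.random.default_rng(seed)
    data = {}
    for c in columns:
        if c in degenerate:
            data[c] = np.zeros(n)
        else:
            data[c] = (rng.uniform(size=n) < 0.4).astype(float)
    y = rng.integers(0, 2, size=n)
    y[0], y[1] = 0, 1
    return StudySample(X=pd.DataFrame(data), y=y)


class TestStrategySets:
    def test_set_algebra(self):
        cur = _current()
        lasso, uni = _selection(["A", "B"]), _selection(["B", "C"], "univariate")
        m3 = build_strategy_set("M3", lasso, uni, cur)
        m4 = build_strategy_set("M4", lasso, uni, cur)
        assert set(m3.variables) == {"B"}
        assert set(m4.variables) == {"A", "B", "C"}
        assert m3.fallback_applied == "none" and m4.fallback_applied == "none"

    def test_m1_all_nondegenerate(self):
        cur = _current(degenerate=("D",))
        sset = build_strategy_set("M1", _selection([]), _selection([], "univariate"), cur)
        assert set(sset.variables) == {"A", "B", "C"}

    def test_m2_empty_falls_back_to_all(self):
        cur = _current()
        sset = build_strategy_set("M2", _selection([]), _selection(["C"], "univariate"), cur)
        assert set(sset.variables) == {"A", "B", "C", "D"}
        assert sset.fallback_applied == "all-variables"

    def test_m3_empty_intersection_uses_m4(self):
        cur = _current()
        lasso, uni = _selection(["A"]), _selection(["C"], "univariate")
        sset = build_strategy_set("M3", lasso, uni, cur)
        assert set(sset.variables) == {"A", "C"}
        assert sset.fallback_applied == "union-substitute"

    def test_m4_both_empty_falls_back_to_all(self):
        cur = _current()
        sset = build_strategy_set("M4", _selection([]), _selection([], "univariate"), cur)
        assert set(sset.variables) == {"A", "B", "C", "D"}
        assert sset.fallback_applied == "all-variables"

    def test_m5_one_empty_uses_other(self):
        cur = _current()
        sset = build_strategy_set("M5", _selection([]), _selection(["C"], "univariate"), cur)
        assert set(sset.variables) == {"C"}
        assert sset.fallback_applied == "other-model"
        assert sset.m5_winner == "univariate"

    def test_m5_both_empty_uses_all(self):
        cur = _current()
        sset = build_strategy_set("M5", _selection([]), _selection([], "univariate"), cur)
        assert set(sset.variables) == {"A", "B", "C", "D"}
        assert sset.fallback_applied == "both-empty-all"

    def test_degenerate_in_current_removed(self):
        cur = _current(degenerate=("B",))
        lasso, uni = _selection(["A", "B"]), _selection(["B", "C"], "univariate")
        m2 = build_strategy_set("M2", lasso, uni, cur)
        assert set(m2.variables) == {"A"}
        # intersection {B} is wiped out by degeneracy -> falls back to M4's set
        m3 = build_strategy_set("M3", lasso, uni, cur)
        assert set(m3.variables) == {"A", "C"}
        assert m3.fallback_applied == "union-substitute"

    def test_unknown_method_fails(self):
        cur = _current()
        with pytest.raises(ValueError):
            build_strategy_set("M9", _selection([]), _selection([]), cur)

    @given(st.integers(0, 500))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_set_algebra_invariants(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"V{i}" for i in range(8)]
        lasso = _selection([v for v in pool if rng.uniform() < 0.4])
        uni = _selection([v for v in pool if rng.uniform() < 0.4], "univariate")
        cur = _current(columns=tuple(pool), seed=seed)
        sets = {
            m: set(build_strategy_set(m, lasso, uni, cur).variables)
            for m in ("M1", "M2", "M3", "M4")
        }
        nondeg = set(cur.nondegenerate_names)
        assert sets["M2"] <= sets["M1"] == nondeg
        assert sets["M3"] <= sets["M4"]
        inter = set(lasso.selected) & set(uni.selected) & nondeg
        if inter:
            assert sets["M3"] <= sets["M2"]
            assert sets["M2"] | (set(uni.selected) & nondeg) == sets["M4"]


class TestM5Winner:
    def test_identical_models_tie_to_lasso(self):
        cur = _current()
        sel = _selection(["A"])
        sel_uni = SelectionResult("univariate", ("A",), 0.0, {"A": 1.0})
        assert m5_pick_winner(sel, sel_uni, cur) == "lasso"

    def test_true_model_wins(self):
        rng = np.random.default_rng(0)
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                {"S": (rng.uniform(size=1000) < 0.3).astype(float),
                 "N": (rng.uniform(size=1000) < 0.3).astype(float)}
            )
            y = (rng.uniform(size=1000) < expit(1.5 * X["S"].to_numpy() - 0.5)).astype(int)
            cur = StudySample(X=X, y=y)
            uni = SelectionResult("univariate", ("S",), -0.5, {"S": 1.5})
            lasso = SelectionResult("lasso", ("N",), 0.0, {"N": 1.0})
            wins += m5_pick_winner(lasso, uni, cur) == "univariate"
        assert wins >= 9

    def test_uses_shared_auroc(self):
        # the winner decision must agree with metrics.auroc on the same vectors
        cur = _current(n=200, seed=3)
        lasso = SelectionResult("lasso", ("A",), 0.0, {"A": 1.0})
        uni = SelectionResult("univariate", ("B",), 0.0, {"B": 1.0})
        from plasmoderf.preceding import predict_logistic

        auc_l = auroc(predict_logistic(lasso, cur.X), cur.y)
        auc_u = auroc(predict_logistic(uni, cur.X), cur.y)
        expected = "lasso" if auc_l >= auc_u else "univariate"
        assert m5_pick_winner(lasso, uni, cur) == expected


class TestProbabilityForest:
    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0]})
        with pytest.raises(ValueError):
            train_probability_forest(X, np.ones(4, dtype=int), ForestParams(n_trees=5))

    def test_determinism(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.uniform(size=(100, 5)), columns=list("abcde"))
        y = rng.integers(0, 2, size=100)
        params = ForestParams(n_trees=30, seed=4)
        p1 = train_probability_forest(X, y, params).predict_event_probability(X)
        p2 = train_probability_forest(X, y, params).predict_event_probability(X)
        assert np.array_equal(p1, p2)

    def test_probabilities_bounded_and_centered(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame((rng.uniform(size=(300, 10)) < 0.3).astype(float))
        X.columns = [f"v{i}" for i in range(10)]
        y = rng.integers(0, 2, size=300)
        p = train_probability_forest(X, y, ForestParams(n_trees=50, seed=0)).predict_event_probability(X)
        assert np.all((0 <= p) & (p <= 1))
        assert abs(p.mean() - y.mean()) < 0.1

    def test_binary_marker_auroc_matches_closed_form(self):
        # single binary predictor: any monotone scoring of it has concordance
        # a(1-b) + (ab + (1-a)(1-b))/2 with a = P(x=1|y=1), b = P(x=1|y=0)
        rng = np.random.default_rng(2)
        n = 4000
        y = rng.integers(0, 2, size=n)
        x = np.where(y == 1, rng.uniform(size=n) < 0.7, rng.uniform(size=n) < 0.2)
        X = pd.DataFrame({"x": x.astype(float)})
        half = n // 2
        forest = train_probability_forest(
            X.iloc[:half], y[:half], ForestParams(n_trees=50, seed=0)
        )
        p = forest.predict_event_probability(X.iloc[half:])
        a = x[half:][y[half:] == 1].mean()
        b = x[half:][y[half:] == 0].mean()
        closed_form = a * (1 - b) + 0.5 * (a * b + (1 - a) * (1 - b))
        assert auroc(p, y[half:]) == pytest.approx(closed_form, abs=1e-9)

    def test_mtry_resolution(self):
        assert ForestParams(mtry="sqrt").resolve_mtry(100) == 10
        assert ForestParams(mtry=0.5).resolve_mtry(9) == 5
        assert ForestParams(mtry=3).resolve_mtry(2) == 2
        with pytest.raises(ValueError):
            ForestParams(mtry="bad").resolve_mtry(10)


def test_strategy_audit_file_round_trip(tmp_path):
    from plasmoderf.strategies import StrategySet, write_strategy_audit

    sets = [
        StrategySet("M1", ("A", "B")),
        StrategySet("M5", ("C",), fallback_applied="other-model", m5_winner="univariate"),
    ]
    path = tmp_path / "audit.csv"
    write_strategy_audit(sets, path, replication=0)
    write_strategy_audit(sets, path, replication=1)  # appends
    table = pd.read_csv(path)
    assert len(table) == 4
    assert table.loc[1, "variables"] == "C"
    assert table.loc[1, "fallback_applied"] == "other-model"
    assert sorted(table["replication"].unique()) == [0, 1]


class TestLassoComparator:
    def test_shares_lasso_study_implementation(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame((rng.uniform(size=(200, 15)) < 0.3).astype(float))
        X.columns = [f"v{i}" for i in range(15)]
        y = (rng.uniform(size=200) < expit(1.2 * X["v0"].to_numpy() - 0.3)).astype(int)
        sample = StudySample(X=X, y=y)
        comp = fit_lasso_comparator(sample, seed=3)
        ref = fit_lasso_study(drop_degenerate(sample), seed=3)
        assert comp.selected == ref.selected
        assert comp.coefficients == ref.coefficients
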
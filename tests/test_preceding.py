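import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from plasmoderf import (
    LassoStudy,
    SelectionResult,
    StudySample,
    UnivariateStudy,
    drop_degenerate,
    fit_lasso_study,
    fit_univariate_study,
    predict_logistic,
)
from plasmoderf.preceding import univariate_wald_pvalues


def _sample(n=300, p=10, seed=0, signal=None, prevalence=0.3):
    """Binary-predictor sample; ``signal`` maps column index -> log odds."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        (rng.uniform(size=(n, p)) < prevalence).astype(float),
        columns=[f"v{i}" for i in range(p)],
    )
    eta = np.zeros(n)
    for j, beta in (signal or {}).items():
        eta += beta * X.iloc[:, j].to_numpy()
    y = (rng.uniform(size=n) < expit(eta)).astype(int)
    return StudySample(X=X, y=y)


class TestDropDegenerate:
    def test_all_zero_columns_removed(self):
        X = pd.DataFrame(
            {"a": [0, 0, 0, 0], "b": [0, 1, 0, 1], "c": [0, 0, 0, 0],
             "d": [1, 1, 1, 1], "e": [1, 0, 1, 1]}
        )
        out = drop_degenerate(StudySample(X=X, y=np.array([0, 1, 0, 1])))
        assert list(out.X.columns) == ["b", "e"]
        assert out.n_dropped_degenerate == 3

    def test_single_one_kept(self):
        X = pd.DataFrame({"a": [0] * 9 + [1]})
        out = drop_degenerate(StudySample(X=X, y=np.array([0, 1] * 5)))
        assert list(out.X.columns) == ["a"]

    def test_all_degenerate_fails(self):
        X = pd.DataFrame({"a": [1, 1], "b": [0, 0]})
        with pytest.raises(ValueError):
            drop_degenerate(StudySample(X=X, y=np.array([0, 1])))

    def test_sparse_column_survival_matches_closed_form(self):
        # a column with prevalence q survives an n-row subsample unless the
        # draw is all-zero or all-one: P = 1 - (1-q)^n - q^n
        q, n, reps = 1 / 150, 250, 400
        rng = np.random.default_rng(0)
        survived = 0
        for _ in range(reps):
            col = rng.uniform(size=n) < q
            survived += 0 < col.sum() < n
        expected = 1 - (1 - q) ** n - q**n
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(survived / reps - expected) < 4 * se


class TestWaldScreening:
    def test_binary_closed_form_matches_statsmodels(self):
        sample = _sample(n=400, p=4, seed=1, signal={0: 0.8})
        pvals = univariate_wald_pvalues(sample.X, sample.y)
        for col in sample.X.columns:
            design = sm.add_constant(sample.X[col].to_numpy())
            ref = sm.GLM(sample.y, design, family=sm.families.Binomial()).fit()
            assert pvals[col] == pytest.approx(ref.pvalues[1], abs=1e-6)

    def test_numeric_column_screened(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        y = (rng.uniform(size=500) < expit(1.0 * x)).astype(int)
        X = pd.DataFrame({"z": x})
        pvals = univariate_wald_pvalues(X, y)
        assert pvals["z"] < 0.001


class TestUnivariateStudy:
    def test_alpha_zero_gives_empty_selection(self):
        sample = _sample(seed=3)
        result = fit_univariate_study(sample, alpha=0.0)
        assert result.empty and result.selected == ()
        # empty model predicts the event rate everywhere
        p = predict_logistic(result, sample.X)
        assert np.allclose(p, sample.y.mean(), atol=1e-9)

    def test_strong_predictor_reliably_selected(self):
        # power check: log odds 1.0 at prevalence 0.3, n=1000
        hits = 0
        for seed in range(20):
            sample = _sample(n=1000, p=8, seed=seed, signal={0: 1.0})
            result = fit_univariate_study(sample)
            hits += "v0" in result.selected
        assert hits >= 19

    def test_mle_predictions_average_to_event_rate(self):
        # with every variable selected the multivariable fit is the plain
        # logistic MLE; its fitted probabilities average to the event rate
        sample = _sample(n=500, p=3, seed=4, signal={0: 1.0, 1: -0.5})
        result = UnivariateStudy(alpha=1.0).fit(sample.X, sample.y).result_
        assert set(result.selected) == set(sample.X.columns)
        p = predict_logistic(result, sample.X)
        assert p.mean() == pytest.approx(sample.y.mean(), abs=1e-6)

    def test_null_selection_rate_near_alpha(self):
        rates = []
        for seed in range(30):
            sample = _sample(n=400, p=40, seed=100 + seed)
            result = fit_univariate_study(sample, alpha=0.05)
            rates.append(len(result.selected) / 40)
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)


class TestLassoStudy:
    def test_vanishing_penalty_approaches_mle(self):
        sample = _sample(n=400, p=3, seed=5, signal={0: 1.0})
        est = LassoStudy(fixed_lambda=1e-9, random_state=0)
        est.fit(sample.X, sample.y)
        design = sm.add_constant(sample.X.to_numpy())
        ref = sm.GLM(sample.y, design, family=sm.families.Binomial()).fit()
        # at the near-zero end of the path the fit is essentially unpenalized
        coefs = np.array([est.coef_.get(c, 0.0) for c in sample.X.columns])
        assert np.allclose(coefs, ref.params[1:], atol=0.05)
        assert est.intercept_ == pytest.approx(ref.params[0], abs=0.05)

    def test_pure_noise_sometimes_selects_nothing(self):
        empties = 0
        for seed in range(12):
            sample = _sample(n=120, p=60, seed=200 + seed, prevalence=0.1)
            result = fit_lasso_study(sample, seed=seed, n_lambdas=12)
            empties += result.empty
        assert empties > 0

    def test_signal_selected_without_null_flood(self):
        sizes = []
        for seed in range(5):
            sample = _sample(n=400, p=80, seed=300 + seed, signal={0: 1.5, 1: 1.5})
            result = fit_lasso_study(sample, seed=seed)
            assert "v0" in result.selected or "v1" in result.selected
            sizes.append(len(result.selected))
        assert np.mean(sizes) < 40  # far below p

    def test_determinism(self):
        sample = _sample(n=200, p=20, seed=6, signal={0: 1.0})
        a = fit_lasso_study(sample, seed=9)
        b = fit_lasso_study(sample, seed=9)
        assert a.selected == b.selected and a.coefficients == b.coefficients

    def test_single_class_fails(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0]})
        with pytest.raises(ValueError):
            fit_lasso_study(StudySample(X=X, y=np.ones(4, dtype=int)))


class TestPredictLogistic:
    def test_intercept_only(self):
        result = SelectionResult("lasso", (), 0.0, {})
        X = pd.DataFrame({"a": [0.0, 1.0]})
        assert np.allclose(predict_logistic(result, X), 0.5)

    def test_single_coefficient_closed_form(self):
        result = SelectionResult("lasso", ("a",), 0.0, {"a": 1.0})
        X = pd.DataFrame({"a": [1.0]})
        assert predict_logistic(result, X)[0] == pytest.approx(expit(1.0))
        assert expit(1.0) == pytest.approx(0.7310585786, abs=1e-9)

    def test_missing_column_fails(self):
        result = SelectionResult("lasso", ("missing",), 0.0, {"missing": 1.0})
        with pytest.raises(KeyError):
            predict_logistic(result, pd.DataFrame({"a": [1.0]}))

    def test_degenerate_column_uses_constant_value(self):
        result = SelectionResult("lasso", ("a",), 0.0, {"a": 2.0})
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        assert np.allclose(predict_logistic(result, X), expit(2.0))


def test_selection_counts_grow_with_sample_size():
    # under signal, both selectors pick up more variables as n grows
    lasso_means, uni_means = [], []
    signal = {j: 0.8 for j in range(6)}
    for n in (150, 1200):
        nl, nu = [], []
        for seed in range(3):
            sample = _sample(n=n, p=30, seed=500 + seed, signal=signal)
            nl.append(len(fit_lasso_study(sample, seed=seed, n_lambdas=10).selected))
            nu.append(len(fit_univariate_study(sample).selected))
        lasso_means.append(np.mean(nl))
        uni_means.append(np.mean(nu))
    assert lasso_means[1] > lasso_means[0]
    assert uni_means[1] > uni_means[0]


def test_selection_result_invariants():
    with pytest.raises(ValueError):
        SelectionResult("lasso", ("a",), 0.0, {"b": 1.0})
    r = SelectionResult("lasso", (), 0.1, {})
    assert r.empty
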
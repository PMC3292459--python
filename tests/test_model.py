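"""Boosting loop: risk descent, oracles, determinism, serialization."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from qboost.learners import BaseLearnerSpec
from qboost.loss import empirical_risk
from qboost.model import QuantileBoost
from qboost.simstudy import simulate

from conftest import toy_frame


def test_zero_iterations_gives_quantile_offset(rng):
    y = rng.normal(size=200)
    X = toy_frame(200, rng)
    res = QuantileBoost(y, X, 0.8).fit(m_stop=0)
    pred = res.predict(toy_frame(10, rng))
    assert np.allclose(pred, np.quantile(y, 0.8))


def test_quantile_offset_calibration(rng):
    """Fraction of responses at or below the offset is within 1/n of tau."""
    y = rng.normal(size=500)
    X = toy_frame(500, rng)
    for tau in (0.1, 0.5, 0.9):
        res = QuantileBoost(y, X, tau).fit(m_stop=0)
        frac = float(np.mean(y <= res.offset))
        assert abs(frac - tau) <= 1.0 / len(y) + 1e-12


@pytest.mark.parametrize("tau", [0.025, 0.5, 0.975])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_training_risk_is_non_increasing(tau, seed):
    rng = np.random.default_rng(seed)
    X = toy_frame(150, rng, p=4)
    y = (1.0 + 2.0 * X["x1"] - X["x2"] + np.sin(5 * X["x3"])
         + 0.5 * rng.standard_normal(150)).to_numpy()
    specs = [BaseLearnerSpec(covariate="x1", kind="linear"),
             BaseLearnerSpec(covariate="x2", kind="linear"),
             BaseLearnerSpec(covariate="x3", kind="pspline", n_knots=10),
             BaseLearnerSpec(covariate="x4", kind="linear")]
    res = QuantileBoost(y, X, tau, specs=specs).fit(m_stop=400)
    # descent up to the fixed-step oscillation at the check-loss kink:
    # once converged, a full step can overshoot by O(step * gradient)
    r = res.risk_path
    assert np.all(np.diff(r) <= 1e-3 * r[:-1] + 1e-12)
    assert r[-1] < r[0]


def test_constant_predictor_minimizer_is_sample_quantile(rng):
    """Grid-search oracle: the best constant is the empirical quantile."""
    y = rng.gamma(2.0, 1.5, size=400)
    X = toy_frame(400, rng, p=1)
    tau = 0.7
    res = QuantileBoost(y, X, tau).fit(m_stop=3000)
    grid = np.linspace(y.min(), y.max(), 4001)
    risks = np.array([empirical_risk(y, np.full_like(y, c), tau)
                      for c in grid])
    # location-only data: the boosted fit cannot beat, and must approach,
    # the best constant
    assert res.risk_path[-1] <= risks.min() * 1.01 + 1e-9
    assert abs(np.median(res.predict()) - grid[risks.argmin()]) < 0.2


@pytest.mark.parametrize("tau", [0.025, 0.975])
def test_linear_programming_oracle_equivalence(tau):
    """Boosted risk within 1% of the LP quantile-regression optimum."""
    data = simulate("linear", 500, 4, np.random.default_rng(3))
    X = data.frame()
    res = QuantileBoost(data.y, X, tau).fit(m_stop=20000)
    lp = sm.QuantReg(data.y, sm.add_constant(X.values)).fit(q=tau)
    boost_risk = empirical_risk(data.y, res.predict(X), tau)
    lp_risk = empirical_risk(data.y, lp.predict(sm.add_constant(X.values)),
                             tau)
    assert boost_risk <= lp_risk * 1.01


def test_informative_coefficients_approach_lp_estimates():
    """With validation-chosen m, informative slopes track the LP fit and
    noise slopes stay near zero (shrinkage toward zero is allowed)."""
    rng = np.random.default_rng(8)
    train = simulate("linear", 2000, 10, rng)
    valid = simulate("linear", 2000, 10, rng)
    tau = 0.975
    model = QuantileBoost(train.y, train.frame(), tau)
    res = model.fit(m_stop=12000, eval_set=(valid.frame(), valid.y),
                    patience=1000)
    res = res.at_iteration(int(np.argmin(res.eval_risk_path)) + 1)
    slopes = np.array([res.states[g][1] for g in range(10)])
    lp = sm.QuantReg(train.y, sm.add_constant(train.X)).fit(q=tau)
    lp_slopes = lp.params[1:5]
    # informative effects track the LP estimates, shrunk toward zero
    assert np.allclose(slopes[:4], lp_slopes, atol=0.5)
    assert np.all(np.abs(slopes[:4]) <= np.abs(lp_slopes) + 0.05)
    # most noise coefficients are exactly zero (never selected)
    assert np.median(np.abs(slopes[4:])) < 0.1


def test_determinism_bit_identical(rng):
    y = rng.normal(size=120)
    X = toy_frame(120, rng)
    r1 = QuantileBoost(y, X, 0.3).fit(m_stop=100)
    r2 = QuantileBoost(y, X, 0.3).fit(m_stop=100)
    assert np.array_equal(r1.risk_path, r2.risk_path)
    for a, b in zip(r1.states, r2.states):
        assert np.array_equal(a, b)


def test_selection_counts_and_unselected_learners(rng):
    X = toy_frame(200, rng, p=5)
    y = (3.0 * X["x1"] + 0.1 * rng.standard_normal(200)).to_numpy()
    res = QuantileBoost(y, X, 0.5).fit(m_stop=60)
    assert res.selection_counts.sum() == 60
    for g in np.flatnonzero(res.selection_counts == 0):
        assert np.all(res.states[g] == 0.0)


def test_predict_on_training_matches_fittedvalues(rng):
    X = toy_frame(150, rng)
    y = (X["x1"] + rng.standard_normal(150)).to_numpy()
    res = QuantileBoost(y, X, 0.6).fit(m_stop=150)
    assert np.allclose(res.predict(X), res.predict(), atol=1e-10)


def test_predict_schema_mismatch_lists_missing_columns(rng):
    X = toy_frame(80, rng)
    res = QuantileBoost(rng.normal(size=80), X, 0.5).fit(m_stop=10)
    with pytest.raises(ValueError, match="x3"):
        res.predict(X[["x1", "x2"]])


def test_at_iteration_equals_fresh_fit(rng):
    X = toy_frame(150, rng, p=4)
    y = (X["x1"] - 2 * X["x2"] + rng.standard_normal(150)).to_numpy()
    full = QuantileBoost(y, X, 0.25).fit(m_stop=200)
    short = QuantileBoost(y, X, 0.25).fit(m_stop=80)
    trunc = full.at_iteration(80)
    for a, b in zip(trunc.states, short.states):
        assert np.array_equal(a, b)
    assert np.array_equal(trunc.selection_counts, short.selection_counts)


def test_subject_effect_decomposition(rng):
    """Within-sample prediction with vs. without subject effects differs by
    exactly the accumulated subject intercept plus slope times age."""
    n_subj, per = 30, 5
    subj = np.repeat([f"s{i}" for i in range(n_subj)], per)
    age = np.tile(np.linspace(2, 10, per), n_subj)
    b1 = rng.normal(0, 1.0, n_subj)
    y = 10 + 0.5 * age + np.repeat(b1, per) + 0.3 * rng.standard_normal(
        n_subj * per)
    X = pd.DataFrame({"cAge": age})
    specs = [BaseLearnerSpec(covariate="cAge", kind="linear"),
             BaseLearnerSpec(covariate=None, kind="subject_intercept"),
             BaseLearnerSpec(covariate="cAge", kind="subject_slope")]
    model = QuantileBoost(y, X, 0.5, specs=specs, subject=subj)
    res = model.fit(m_stop=400)
    with_fx = res.predict(X, subject=subj, include_subject_effects=True)
    without = res.predict(X, subject=subj, include_subject_effects=False)
    codes = np.array([int(s[1:]) for s in subj])
    expected = res.states[1][codes] + res.states[2][codes] * age
    assert np.allclose(with_fx - without, expected, atol=1e-10)


def test_json_round_trip_bit_exact(rng, tmp_path):
    from qboost.model import QuantileBoostResults
    X = toy_frame(150, rng, p=4)
    X["grp"] = np.array(["u", "v"])[rng.integers(0, 2, 150)]
    y = (X["x1"] + 0.5 * np.sin(4 * X["x2"])
         + rng.standard_normal(150)).to_numpy()
    specs = [BaseLearnerSpec(covariate="x1", kind="linear"),
             BaseLearnerSpec(covariate="x2", kind="pspline", n_knots=8),
             BaseLearnerSpec(covariate="grp", kind="linear")]
    res = QuantileBoost(y, X, 0.9, specs=specs).fit(m_stop=150)
    path = tmp_path / "model.json"
    res.save(path)
    loaded = QuantileBoostResults.load(path)
    X_new = toy_frame(40, rng, p=4)
    X_new["grp"] = np.array(["u", "v"])[rng.integers(0, 2, 40)]
    assert np.array_equal(res.predict(X_new), loaded.predict(X_new))
    assert loaded.m_stop == res.m_stop


def test_empty_spec_list_rejected(rng):
    with pytest.raises(ValueError, match="empty"):
        QuantileBoost(rng.normal(size=10), toy_frame(10, rng), 0.5,
                      specs=[])


def test_summary_mentions_selected_and_blank_terms(rng):
    X = toy_frame(300, rng, p=3)
    y = (5 * X["x1"] + 0.2 * rng.standard_normal(300)).to_numpy()
    res = QuantileBoost(y, X, 0.5).fit(m_stop=200)
    text = res.summary()
    assert "x1" in text and "m_stop = 200" in text
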
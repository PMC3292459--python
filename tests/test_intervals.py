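"""Interval construction, crossing repair, and the two coverage notions."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from qboost.intervals import (PredictionInterval, build_pi,
                              conditional_coverage, naive_pi,
                              sample_coverage)
from qboost.model import QuantileBoost
from qboost.simstudy import simulate


class _Stub:
    """Minimal quantile-predictor stand-in for interval plumbing tests."""

    def __init__(self, tau, fn):
        self.tau = tau
        self._fn = fn

    def predict(self, exog, subject=None, include_subject_effects=True):
        return self._fn(exog)


def test_two_constant_models_give_constant_interval():
    lo = _Stub(0.025, lambda X: np.full(len(X), 2.0))
    hi = _Stub(0.975, lambda X: np.full(len(X), 5.0))
    pi = build_pi(lo, hi, pd.DataFrame(index=range(7)))
    assert np.allclose(pi.lower, 2.0) and np.allclose(pi.upper, 5.0)
    assert pi.crossing_count == 0
    assert pi.nominal_level == pytest.approx(0.95)


def test_identical_models_give_zero_width_no_crossing():
    f = lambda X: np.arange(len(X), dtype=float)
    pi = build_pi(_Stub(0.1, f), _Stub(0.9, f), pd.DataFrame(index=range(5)))
    assert np.allclose(pi.length, 0.0)
    assert pi.crossing_count == 0


def test_crossing_is_swapped_and_counted():
    lo = _Stub(0.025, lambda X: np.array([0.0, 3.0, 1.0]))
    hi = _Stub(0.975, lambda X: np.array([1.0, 2.0, 1.5]))
    pi = build_pi(lo, hi, pd.DataFrame(index=range(3)))
    assert pi.crossing_count == 1
    assert np.all(pi.lower <= pi.upper)
    assert pi.lower[1] == 2.0 and pi.upper[1] == 3.0


def test_asymmetric_tau_pair_warns_not_errors():
    lo = _Stub(0.1, lambda X: np.zeros(len(X)))
    hi = _Stub(0.8, lambda X: np.ones(len(X)))
    with pytest.warns(UserWarning, match="symmetric"):
        pi = build_pi(lo, hi, pd.DataFrame(index=range(2)))
    assert pi.nominal_level == pytest.approx(0.7)


def test_nesting_of_intervals_from_a_monotone_family():
    qs = {0.025: -3.0, 0.1: -1.5, 0.9: 1.5, 0.975: 3.0}
    stubs = {t: _Stub(t, lambda X, v=v: np.full(len(X), v))
             for t, v in qs.items()}
    X = pd.DataFrame(index=range(4))
    wide = build_pi(stubs[0.025], stubs[0.975], X)    # 95%
    narrow = build_pi(stubs[0.1], stubs[0.9], X)      # 80%
    assert np.all(wide.lower <= narrow.lower)
    assert np.all(narrow.upper <= wide.upper)


def test_sample_coverage_extremes(rng):
    y = rng.normal(size=100)
    inf = PredictionInterval([-np.inf], [np.inf], 0.95)
    assert sample_coverage(inf, y).estimate == 1.0
    below = PredictionInterval([-10.0], [-9.0], 0.95)
    assert sample_coverage(below, y + 100).estimate == 0.0
    with pytest.raises(ValueError, match="empty"):
        sample_coverage(inf, [])


def test_conditional_coverage_zero_width_interval(rng):
    pi = PredictionInterval([1.0], [1.0], 0.95)
    rep = conditional_coverage(pi, rng.normal(size=1000), test_point=[0.5])
    assert rep.estimate == 0.0
    assert rep.mode == "conditional"
    assert rep.mc_se == 0.0


def test_coverage_report_binomial_standard_error(rng):
    pi = PredictionInterval([-1.96], [1.96], 0.95)
    rep = conditional_coverage(pi, rng.standard_normal(4000))
    assert rep.mc_se == pytest.approx(
        np.sqrt(rep.estimate * (1 - rep.estimate) / 4000))


def test_naive_interval_matches_quantile_convention():
    y = np.arange(1.0, 101.0)
    pi = naive_pi(y, alpha=0.1)
    lo, hi = np.quantile(y, [0.05, 0.95])  # type-7 linear interpolation
    assert pi.lower[0] == pytest.approx(lo) and pi.lower[0] == pytest.approx(5.95)
    assert pi.upper[0] == pytest.approx(hi) and pi.upper[0] == pytest.approx(95.05)


def test_naive_interval_permutation_invariant_and_degenerate(rng):
    y = rng.normal(size=200)
    p1 = naive_pi(y)
    p2 = naive_pi(rng.permutation(y))
    assert p1.lower[0] == p2.lower[0] and p1.upper[0] == p2.upper[0]
    flat = naive_pi(np.full(10, 3.0))
    assert flat.length[0] == 0.0
    with pytest.raises(ValueError, match="two"):
        naive_pi([1.0])


def test_fitted_interval_length_tracks_true_scale():
    """On the linear heteroscedastic setup, fitted PI length correlates
    strongly with the true conditional scale (Spearman > 0.9)."""
    rng = np.random.default_rng(6)
    train = simulate("linear", 2000, 4, rng)
    valid = simulate("linear", 2000, 4, rng)
    X = train.frame()
    borders = []
    for tau in (0.025, 0.975):
        res = QuantileBoost(train.y, X, tau).fit(
            m_stop=12000, eval_set=(valid.frame(), valid.y), patience=1000)
        borders.append(res.at_iteration(
            int(np.argmin(res.eval_risk_path)) + 1))
    test = simulate("linear", 800, 4, rng)
    pi = build_pi(borders[0], borders[1], test.frame())
    rho = spearmanr(pi.length, test.sigma).statistic
    assert rho > 0.9
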
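"""Cohort analysis pipelines: folds, loss comparison, goodness of fit."""

import numpy as np
import pandas as pd
import pytest

from qboost.cohort import CohortConfig, generate_cohort
from qboost.pipelines import (boost_method, cv_loss_compare,
                              fit_cross_sectional, fit_longitudinal,
                              gof_diagnostic, naive_method)


@pytest.fixture(scope="module")
def cross_result(small_cohort):
    return fit_cross_sectional(small_cohort, folds=3, bootstrap_reps=4,
                               m_max=300, seed=0)


def test_cross_sectional_held_out_pis(cross_result, small_cohort):
    pt = cross_result.pi_table
    # every child with an age-4 response gets exactly one held-out PI
    assert len(pt) == len(small_cohort.cross_sectional())
    assert pt["child_id"].is_unique
    assert (pt["upper"] >= pt["lower"]).all()
    assert cross_result.excluded_children == \
        small_cohort.n_children - len(pt)


def test_cross_sectional_effect_table_structure(cross_result):
    tab = cross_result.effect_table()
    assert tab["term"].iloc[0] == "Intercept"
    # report layout: blank (NaN) cells for covariates never selected
    assert {"tau=0.025", "tau=0.975"} <= set(tab.columns)
    assert "f(cBMI2)" in set(tab["term"])
    assert any(t.startswith("mEdu = ") for t in tab["term"])


def test_length_summary_is_positive(cross_result):
    s = cross_result.length_summary()
    assert 0 < s["min"] <= s["mean"] <= s["max"]


def test_no_child_level_leakage_in_folds(small_cohort):
    data = small_cohort.cross_sectional()
    comp = cv_loss_compare(data, {"naive": naive_method()}, folds=5, seed=3)
    fa = comp.fold_assignment
    assert fa["child_id"].is_unique            # a child sits in one fold only
    assert set(fa["child_id"]) == set(data["child_id"])


def test_method_compared_with_itself_gives_identical_losses(small_cohort):
    data = small_cohort.cross_sectional()
    comp = cv_loss_compare(data, {"a": naive_method(), "b": naive_method()},
                           folds=4, seed=1)
    piv = comp.records.pivot_table(index=["fold", "tau"], columns="method",
                                   values="loss")
    assert np.allclose(piv["a"], piv["b"])


def test_boosting_beats_naive_constant_quantiles(small_cohort):
    data = small_cohort.cross_sectional()
    comp = cv_loss_compare(
        data, {"boost": boost_method(m_max=400, bootstrap_reps=4),
               "naive": naive_method()}, folds=4, seed=2)
    piv = comp.records.pivot_table(index=["fold", "tau"], columns="method",
                                   values="loss")
    for tau in (0.025, 0.975):
        sub = piv.xs(tau, level="tau")
        assert sub["boost"].mean() < sub["naive"].mean()
        assert (sub["boost"] < sub["naive"]).mean() > 0.5   # sign check


def test_longitudinal_pipeline_new_children(small_cohort):
    res = fit_longitudinal(small_cohort, folds=2, bootstrap_reps=3,
                           m_max=300, seed=0)
    pt = res.pi_table
    meas = small_cohort.measurements
    assert len(pt) == len(meas)
    assert (pt["upper"] >= pt["lower"]).all()
    # held-out children are new: intervals at a fixed age are driven by
    # fixed effects only, so they are finite and well-behaved
    assert np.isfinite(pt[["lower", "upper"]]).all().all()


def test_longitudinal_degenerate_random_effects_runs():
    cfg = CohortConfig(sd_intercept=0.0, sd_slope=0.0)
    cohort = generate_cohort(120, seed=6, config=cfg)
    res = fit_longitudinal(cohort, folds=2, bootstrap_reps=2, m_max=150,
                           seed=1)
    assert np.isfinite(res.pi_table[["lower", "upper"]]).all().all()


# -- goodness-of-fit diagnostic ---------------------------------------------

def _true_grid(n, rng, shift=0.0):
    from scipy.stats import norm
    taus = np.round(np.arange(0.05, 0.951, 0.05), 2)
    mu = rng.uniform(-1, 1, n)
    sd = rng.uniform(0.5, 1.5, n)
    grid = mu[:, None] + shift + sd[:, None] * norm.ppf(taus)[None, :]
    y = mu + sd * rng.standard_normal(n)
    return y, grid, taus


def test_gof_self_consistency(rng):
    y, grid, taus = _true_grid(2000, rng)
    rep = gof_diagnostic(y, grid, taus, n_sim=30, seed=0)
    assert rep.discrepancy < 0.1
    assert rep.n_isotonized == 0


def test_gof_detects_location_misspecification(rng):
    y, grid0, taus = _true_grid(2000, rng, shift=0.0)
    discrepancies = []
    for shift in (0.0, 1.0, 2.0):
        rep = gof_diagnostic(y, grid0 + shift, taus, n_sim=30, seed=0)
        discrepancies.append(rep.discrepancy)
    assert discrepancies[0] < discrepancies[1] < discrepancies[2]
    # discrepancy tracks the size of the shift
    assert discrepancies[2] == pytest.approx(2.0, abs=0.3)


def test_gof_isotonizes_non_monotone_grids(rng):
    y, grid, taus = _true_grid(500, rng)
    grid[0, [3, 4]] = grid[0, [4, 3]]          # break monotonicity in row 0
    rep = gof_diagnostic(y, grid, taus, n_sim=5, seed=0)
    assert rep.n_isotonized == 1


def test_gof_reports_per_group(rng):
    y, grid, taus = _true_grid(900, rng)
    groups = np.repeat([4.0, 6.0, 10.0], 300)
    rep = gof_diagnostic(y, grid, taus, n_sim=10, seed=0, groups=groups)
    assert set(rep.by_group["group"]) == {4.0, 6.0, 10.0}


def test_gof_shape_mismatch_rejected(rng):
    with pytest.raises(ValueError, match="quantile_grid"):
        gof_diagnostic(np.zeros(10), np.zeros((10, 3)),
                       taus=[0.2, 0.5], n_sim=2)
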
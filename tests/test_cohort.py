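"""Synthetic cohort generator and its exact truth oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import skew

from qboost.cohort import CohortConfig, generate_cohort

POINT = {"cBMI0": 13.5, "cBMI2": 16.5, "mBMI": 24.0, "mDiffBMI": 4.0,
         "cSex": "female", "cArea": "urban", "cBreast": "yes",
         "mSmoke": "no", "mEdu": 2}


def test_same_seed_gives_identical_cohort():
    a = generate_cohort(120, seed=9)
    b = generate_cohort(120, seed=9)
    pd.testing.assert_frame_equal(a.children, b.children)
    pd.testing.assert_frame_equal(a.measurements, b.measurements)
    c = generate_cohort(120, seed=10)
    assert not a.measurements["cBMI"].equals(c.measurements["cBMI"])


def test_schema_and_visit_structure():
    cohort = generate_cohort(400, seed=1)
    assert set(cohort.children.columns) == {
        "child_id", "cBMI0", "cBMI2", "mBMI", "mDiffBMI", "cSex", "cArea",
        "cBreast", "mSmoke", "mEdu"}
    per_child = cohort.measurements.groupby("child_id").size()
    assert per_child.between(1, 3).all()
    jitter = (cohort.measurements["cAge"]
              - cohort.measurements["nominal_age"]).abs()
    assert (jitter <= 0.5).all()
    assert (cohort.children[["cBMI0", "cBMI2", "mBMI"]] > 0).all().all()
    assert cohort.children["mEdu"].isin([1, 2, 3, 4]).all()


def test_covariate_dependence_structure():
    cohort = generate_cohort(5000, seed=3)
    c = cohort.children
    assert c[["cBMI0", "cBMI2"]].corr().iloc[0, 1] > 0.1
    assert c[["mBMI", "cBMI2"]].corr().iloc[0, 1] > 0.1


def test_symmetric_family_when_skew_disabled():
    cfg = CohortConfig(skew_max=0.0)
    cohort = generate_cohort(50, seed=0, config=cfg)
    for age in (4.0, 8.0, 10.0):
        q_lo = cohort.truth_quantile(POINT, age, 0.025)
        q_med = cohort.truth_quantile(POINT, age, 0.5)
        q_hi = cohort.truth_quantile(POINT, age, 0.975)
        assert q_med - q_lo == pytest.approx(q_hi - q_med, abs=1e-9)


def test_age_specific_skewness_emerges_after_six():
    cohort = generate_cohort(50_000, seed=4)
    t = cohort.table()
    s4 = skew(t.loc[t.nominal_age == 4.0, "cBMI"])
    s10 = skew(t.loc[t.nominal_age == 10.0, "cBMI"])
    assert s10 > s4


def test_truth_quantile_monotone_in_tau():
    cohort = generate_cohort(10, seed=0)
    qs = [cohort.truth_quantile(POINT, 9.5, t)
          for t in (0.01, 0.1, 0.5, 0.9, 0.99)]
    assert np.all(np.diff(qs) > 0)


@pytest.mark.parametrize("age", [4.3, 9.7])
def test_truth_quantile_agrees_with_monte_carlo(age):
    cohort = generate_cohort(10, seed=0)
    rng = np.random.default_rng(21)
    draws = cohort.sample_response(POINT, age, 1_000_000, rng)
    for tau in (0.025, 0.5, 0.975):
        assert cohort.truth_quantile(POINT, age, tau) == pytest.approx(
            float(np.quantile(draws, tau)), abs=0.02)


def test_truth_intervals_close_the_coverage_loop():
    """Intervals from the truth oracle cover fresh draws at 95%."""
    cohort = generate_cohort(10, seed=0)
    rng = np.random.default_rng(5)
    se = 3 * np.sqrt(0.95 * 0.05 / 20000)
    for age in (4.0, 6.5, 10.0):
        lo = cohort.truth_quantile(POINT, age, 0.025)
        hi = cohort.truth_quantile(POINT, age, 0.975)
        y = cohort.sample_response(POINT, age, 20000, rng)
        cov = float(np.mean((lo <= y) & (y <= hi)))
        assert abs(cov - 0.95) < se + 0.003


def test_interval_length_grows_with_age_for_every_child():
    cohort = generate_cohort(150, seed=8)
    for _, child in cohort.children.iterrows():
        covs = child.to_dict()
        l4 = (cohort.truth_quantile(covs, 4.0, 0.975)
              - cohort.truth_quantile(covs, 4.0, 0.025))
        l10 = (cohort.truth_quantile(covs, 10.0, 0.975)
               - cohort.truth_quantile(covs, 10.0, 0.025))
        assert l10 > l4


def test_smoking_widens_the_true_interval():
    cohort = generate_cohort(10, seed=0)
    smoker = dict(POINT, mSmoke="yes")
    for age in (4.0, 10.0):
        w_ns = (cohort.truth_quantile(POINT, age, 0.975)
                - cohort.truth_quantile(POINT, age, 0.025))
        w_sm = (cohort.truth_quantile(smoker, age, 0.975)
                - cohort.truth_quantile(smoker, age, 0.025))
        assert w_sm > w_ns


def test_config_validation_errors():
    with pytest.raises(ValueError, match="skew"):
        CohortConfig(skew_max=1.5)
    with pytest.raises(ValueError, match="visit_prob"):
        CohortConfig(visit_prob=0.0)
    with pytest.raises(ValueError, match="n_children"):
        generate_cohort(0, seed=1)


def test_cohort_round_trip_to_disk(tmp_path):
    cohort = generate_cohort(50, seed=2)
    paths = (tmp_path / "children.csv", tmp_path / "meas.csv",
             tmp_path / "truth.json")
    cohort.save(*paths)
    children = pd.read_csv(paths[0])
    assert len(children) == 50
    meas = pd.read_csv(paths[1])
    assert set(meas["child_id"]) <= set(children["child_id"])
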
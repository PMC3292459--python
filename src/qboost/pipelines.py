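"""Cross-sectional and longitudinal BMI-prediction pipelines.

These re-express the two cohort analyses as reusable pipelines over any
table with the cohort schema (the synthetic generator by default):

* *cross-sectional*: 95% prediction intervals for the BMI around age four
  from everything known at age two — a non-linear effect for the BMI at
  two, linear effects for all other covariates; the stopping iteration is
  tuned by bootstrap on each training fold, held-out intervals come from
  10-fold cross-validation over children.
* *longitudinal*: intervals for the whole BMI pattern up to age ten,
  adding a non-linear age effect plus child-specific random intercepts
  and age slopes; tuning by subject-wise bootstrap; for held-out (new)
  children the subject effects are set to zero.

Also provided: a cross-validated empirical-loss comparison between
interval-fitting methods, and a simplified goodness-of-fit diagnostic
that simulates responses from the fitted conditional quantile function
and compares them to the observed distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import PredictionInterval, naive_pi
from .learners import BaseLearnerSpec
from .loss import check_loss
from .model import QuantileBoost, QuantileBoostResults

__all__ = ["cross_sectional_specs", "longitudinal_specs",
           "fit_cross_sectional", "fit_longitudinal", "cv_loss_compare",
           "gof_diagnostic", "fit_quantile_grid"]

BASE_COVARIATES = ["cBMI0", "cBMI2", "mBMI", "mDiffBMI", "cSex", "cArea",
                   "cBreast", "mSmoke", "mEdu"]


def cross_sectional_specs() -> list[BaseLearnerSpec]:
    """Non-linear cBMI2, linear everything else (incl. exact visit age)."""
    specs = [BaseLearnerSpec(covariate="cBMI2", kind="pspline")]
    for c in ["cBMI0", "cAge", "mBMI", "mDiffBMI", "cSex", "cArea",
              "cBreast", "mSmoke", "mEdu"]:
        specs.append(BaseLearnerSpec(covariate=c, kind="linear"))
    return specs


def longitudinal_specs(subject_df: float = 4.0) -> list[BaseLearnerSpec]:
    """Adds a smooth age effect and subject intercept/slope learners."""
    specs = [BaseLearnerSpec(covariate="cAge", kind="pspline"),
             BaseLearnerSpec(covariate="cBMI2", kind="pspline")]
    for c in ["cBMI0", "mBMI", "mDiffBMI", "cSex", "cArea", "cBreast",
              "mSmoke", "mEdu"]:
        specs.append(BaseLearnerSpec(covariate=c, kind="linear"))
    specs.append(BaseLearnerSpec(covariate=None, kind="subject_intercept",
                                 df=subject_df))
    specs.append(BaseLearnerSpec(covariate="cAge", kind="subject_slope",
                                 df=subject_df))
    return specs


def _prep(data: pd.DataFrame) -> pd.DataFrame:
    """Analysis-ready covariates: education as an unordered dummy block."""
    if "mEdu" in data.columns:
        data = data.assign(mEdu=data["mEdu"].astype(str))
    return data


def _child_folds(child_ids, folds, rng):
    """Partition children (never measurements) into CV folds."""
    ids = np.asarray(pd.unique(child_ids))
    perm = rng.permutation(len(ids))
    return [set(ids[perm[chunk]])
            for chunk in np.array_split(np.arange(len(ids)), folds)]


@dataclass
class PipelineResult:
    """Held-out prediction intervals plus the full-data reference fit."""

    pi_table: pd.DataFrame          # child_id, cAge, (nominal_age), lo, up
    models: dict                    # tau -> full-data QuantileBoostResults
    mstop: dict                     # tau -> tuned m on the full data
    excluded_children: int = 0
    crossing_count: int = 0

    def effect_table(self) -> pd.DataFrame:
        """Covariate-by-tau effect estimates; blank = not selected."""
        parts = []
        for tau, res in self.models.items():
            t = res.coefficient_table()[["term", "estimate"]]
            t = t.rename(columns={"estimate": f"tau={tau:g}"})
            parts.append(t.set_index("term"))
        return pd.concat(parts, axis=1).reset_index()

    def length_summary(self) -> pd.Series:
        lengths = self.pi_table["upper"] - self.pi_table["lower"]
        return pd.Series({"mean": lengths.mean(), "min": lengths.min(),
                          "max": lengths.max()})


def _tune_and_fit(y, X, tau, specs, subject, method, m_max, step_length,
                  reps, rng):
    model = QuantileBoost(y, X, tau, specs=specs, subject=subject)
    m_best = model.select_mstop(method=method, m_max=m_max,
                                step_length=step_length, reps=reps,
                                random_state=rng)
    return model.fit(m_stop=m_best, step_length=step_length)


def fit_cross_sectional(cohort, taus=(0.025, 0.975), folds: int = 10,
                        bootstrap_reps: int = 25, m_max: int = 1500,
                        step_length: float = 0.1, seed=None,
                        nominal_age: float = 4.0) -> PipelineResult:
    """Per-child 95% PIs for the BMI around one visit age, by child-level CV.

    The stopping iteration is selected by bootstrap (out-of-bag risk) on
    each training fold separately; children without the target response
    are excluded (counted in the result).
    """
    rng = np.random.default_rng(seed)
    data = _prep(cohort.cross_sectional(nominal_age=nominal_age))
    excluded = cohort.n_children - len(data)
    specs = cross_sectional_specs()
    covs = ["cAge"] + BASE_COVARIATES
    fold_sets = _child_folds(data["child_id"], folds, rng)
    pis = []
    crossings = 0
    for fold in fold_sets:
        test = data["child_id"].isin(fold)
        train = data.loc[~test]
        borders = {}
        for tau in taus:
            borders[tau] = _tune_and_fit(
                train["cBMI"].to_numpy(), train[covs], tau, specs, None,
                "bootstrap", m_max, step_length, bootstrap_reps, rng)
        te = data.loc[test]
        lo = borders[taus[0]].predict(te[covs])
        hi = borders[taus[1]].predict(te[covs])
        crossings += int(np.sum(lo > hi))
        pis.append(pd.DataFrame({
            "child_id": te["child_id"].to_numpy(), "cAge": te["cAge"],
            "lower": np.minimum(lo, hi), "upper": np.maximum(lo, hi)}))
    # full-data reference fit for the effect table
    models, mstop = {}, {}
    for tau in taus:
        model = QuantileBoost(data["cBMI"].to_numpy(), data[covs], tau,
                              specs=specs)
        m_best = model.select_mstop(method="bootstrap", m_max=m_max,
                                    step_length=step_length,
                                    reps=bootstrap_reps, random_state=rng)
        models[tau] = model.fit(m_stop=m_best, step_length=step_length)
        mstop[tau] = m_best
    return PipelineResult(pi_table=pd.concat(pis, ignore_index=True),
                          models=models, mstop=mstop,
                          excluded_children=excluded,
                          crossing_count=crossings)


def fit_longitudinal(cohort, taus=(0.025, 0.975), folds: int = 10,
                     bootstrap_reps: int = 25, m_max: int = 1500,
                     step_length: float = 0.1, seed=None,
                     subject_df: float = 4.0) -> PipelineResult:
    """PI trajectories over all visit ages, with child random effects.

    The stopping iteration is tuned by subject-wise bootstrap.  Held-out
    children are *new* children: their subject-specific intercepts and
    slopes are zero, their intervals rely on fixed effects only.
    """
    rng = np.random.default_rng(seed)
    data = _prep(cohort.table())
    specs = longitudinal_specs(subject_df=subject_df)
    covs = ["cAge"] + BASE_COVARIATES
    fold_sets = _child_folds(data["child_id"], folds, rng)
    pis = []
    crossings = 0
    for fold in fold_sets:
        test = data["child_id"].isin(fold)
        train = data.loc[~test]
        borders = {}
        for tau in taus:
            borders[tau] = _tune_and_fit(
                train["cBMI"].to_numpy(), train[covs], tau, specs,
                train["child_id"].to_numpy(), "subject_bootstrap", m_max,
                step_length, bootstrap_reps, rng)
        te = data.loc[test]
        lo = borders[taus[0]].predict(te[covs], include_subject_effects=False)
        hi = borders[taus[1]].predict(te[covs], include_subject_effects=False)
        crossings += int(np.sum(lo > hi))
        pis.append(pd.DataFrame({
            "child_id": te["child_id"].to_numpy(), "cAge": te["cAge"],
            "nominal_age": te["nominal_age"].to_numpy(),
            "lower": np.minimum(lo, hi), "upper": np.maximum(lo, hi)}))
    models, mstop = {}, {}
    for tau in taus:
        model = QuantileBoost(data["cBMI"].to_numpy(), data[covs], tau,
                              specs=specs,
                              subject=data["child_id"].to_numpy())
        m_best = model.select_mstop(method="subject_bootstrap", m_max=m_max,
                                    step_length=step_length,
                                    reps=bootstrap_reps, random_state=rng)
        models[tau] = model.fit(m_stop=m_best, step_length=step_length)
        mstop[tau] = m_best
    return PipelineResult(pi_table=pd.concat(pis, ignore_index=True),
                          models=models, mstop=mstop, crossing_count=crossings)


# ---------------------------------------------------------------------------
# cross-validated loss comparison
# ---------------------------------------------------------------------------

def boost_method(specs_factory=cross_sectional_specs, m_max: int = 1500,
                 bootstrap_reps: int = 25, step_length: float = 0.1):
    """Method plug-in: boosted additive quantile regression."""

    def fit_predict(train, test, tau, covs, rng):
        res = _tune_and_fit(train["cBMI"].to_numpy(), train[covs], tau,
                            specs_factory(), None, "bootstrap", m_max,
                            step_length, bootstrap_reps, rng)
        return res.predict(test[covs])

    return fit_predict


def naive_method():
    """Method plug-in: unconditional empirical quantile of the response."""

    def fit_predict(train, test, tau, covs, rng):
        q = float(np.quantile(train["cBMI"].to_numpy(), tau))
        return np.full(len(test), q)

    return fit_predict


@dataclass
class LossComparison:
    """Out-of-fold empirical check loss per fold, tau and method."""

    records: pd.DataFrame           # fold, tau, method, loss, n_test
    fold_assignment: pd.DataFrame   # child_id, fold

    def mean_table(self) -> pd.DataFrame:
        return (self.records.groupby(["method", "tau"])["loss"]
                .mean().reset_index())


def cv_loss_compare(data: pd.DataFrame, methods: dict,
                    taus=(0.025, 0.975), folds: int = 10, seed=None,
                    covs: Optional[Sequence[str]] = None) -> LossComparison:
    """Compare interval-fitting methods by out-of-fold mean check loss.

    ``methods`` maps a name to a plug-in ``fit_predict(train, test, tau,
    covs, rng)`` returning quantile predictions on the test rows.  Folds
    partition children, never single measurements.  The empirical loss is
    a measure to *compare* methods, not to validate coverage.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    data = _prep(data)
    covs = list(covs) if covs is not None else \
        ["cAge"] + [c for c in BASE_COVARIATES if c in data.columns]
    fold_sets = _child_folds(data["child_id"], folds, rng)
    assign = []
    for k, fold in enumerate(fold_sets):
        assign.extend((cid, k) for cid in sorted(fold))
    records = []
    for k, fold in enumerate(fold_sets):
        test_mask = data["child_id"].isin(fold)
        train, test = data.loc[~test_mask], data.loc[test_mask]
        for name, fit_predict in methods.items():
            for tau in taus:
                try:
                    pred = fit_predict(train, test, tau, covs,
                                       np.random.default_rng(rng.integers(2 ** 31)))
                except Exception as exc:
                    records.append({"fold": k, "tau": tau, "method": name,
                                    "loss": np.nan, "n_test": len(test),
                                    "error": repr(exc)})
                    continue
                loss = float(np.mean(check_loss(
                    test["cBMI"].to_numpy(), np.asarray(pred), tau)))
                records.append({"fold": k, "tau": tau, "method": name,
                                "loss": loss, "n_test": len(test),
                                "error": ""})
    return LossComparison(
        records=pd.DataFrame(records),
        fold_assignment=pd.DataFrame(assign, columns=["child_id", "fold"]))


# ---------------------------------------------------------------------------
# goodness of fit (simplified conditional-distribution diagnostic)
# ---------------------------------------------------------------------------

def fit_quantile_grid(y, X, specs, taus=None, m_stop: int = 300,
                      step_length: float = 0.1, subject=None) -> np.ndarray:
    """Fitted conditional quantiles on a tau grid, per observation.

    Refits one boosted model per grid level (19 levels by default).
    """
    if taus is None:
        taus = np.round(np.arange(0.05, 0.951, 0.05), 2)
    out = np.empty((len(X), len(taus)))
    for j, tau in enumerate(taus):
        res = QuantileBoost(y, X, float(tau), specs=specs,
                            subject=subject).fit(
            m_stop=m_stop, step_length=step_length)
        out[:, j] = res.predict()
    return out


@dataclass
class GofReport:
    """Discrepancy between simulated and observed response distributions."""

    discrepancy: float              # mean |QQ difference| on the probe grid
    qq: pd.DataFrame                # prob, observed, simulated
    n_isotonized: int
    by_group: Optional[pd.DataFrame] = None


def _sample_from_grid(qgrid, taus, n_sim, rng):
    """Draws from the piecewise-linear inverse of a fitted quantile grid.

    Tail draws beyond the grid extrapolate the first/last segment slope.
    """
    n, k = qgrid.shape
    u = rng.uniform(size=(n, n_sim))
    sims = np.empty((n, n_sim))
    for i in range(n):
        q = qgrid[i]
        sims[i] = np.interp(u[i], taus, q)
        lowmask = u[i] < taus[0]
        highmask = u[i] > taus[-1]
        slope_lo = (q[1] - q[0]) / (taus[1] - taus[0])
        slope_hi = (q[-1] - q[-2]) / (taus[-1] - taus[-2])
        sims[i, lowmask] = q[0] + slope_lo * (u[i, lowmask] - taus[0])
        sims[i, highmask] = q[-1] + slope_hi * (u[i, highmask] - taus[-1])
    return sims


def gof_diagnostic(y, quantile_grid, taus=None, n_sim: int = 20,
                   seed=None, groups=None) -> GofReport:
    """Compare responses simulated from the fitted conditional quantile
    function against the observed response distribution.

    Per observation, ``n_sim`` responses are drawn from the
    piecewise-linear inverse of its fitted quantile grid; the pooled
    simulated sample is compared to the observed one by the mean absolute
    difference of their quantiles over a central probability grid.
    Non-monotone fitted grids are isotonized (and counted).  With
    ``groups`` (e.g. nominal visit ages) the discrepancy is also reported
    per group.
    """
    y = np.asarray(y, dtype=float)
    qgrid = np.asarray(quantile_grid, dtype=float)
    if taus is None:
        taus = np.round(np.arange(0.05, 0.951, 0.05), 2)
    taus = np.asarray(taus, dtype=float)
    if qgrid.shape != (len(y), len(taus)):
        raise ValueError("quantile_grid must be (n_obs, n_taus)")
    rng = np.random.default_rng(seed)
    iso = np.maximum.accumulate(qgrid, axis=1)
    n_iso = int(np.sum(np.any(iso != qgrid, axis=1)))
    sims = _sample_from_grid(iso, taus, n_sim, rng)

    probe = np.arange(0.05, 0.951, 0.05)

    def qq(y_obs, y_sim):
        qo = np.quantile(y_obs, probe)
        qs = np.quantile(y_sim, probe)
        return qo, qs

    qo, qs = qq(y, sims.ravel())
    report = GofReport(
        discrepancy=float(np.mean(np.abs(qo - qs))),
        qq=pd.DataFrame({"prob": probe, "observed": qo, "simulated": qs}),
        n_isotonized=n_iso)
    if groups is not None:
        groups = np.asarray(groups)
        rows = []
        for g in pd.unique(groups):
            mask = groups == g
            qo, qs = qq(y[mask], sims[mask].ravel())
            rows.append({"group": g,
                         "discrepancy": float(np.mean(np.abs(qo - qs))),
                         "n": int(mask.sum())})
        report.by_group = pd.DataFrame(rows)
    return report
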
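"""Boosted additive quantile regression, statsmodels-style.

:class:`QuantileBoost` is the model: a continuous response, a covariate
table, a quantile level ``tau`` and a list of base-learner declarations.
``fit`` runs component-wise functional gradient boosting of the check
loss: in every iteration all base-learners are fitted to the negative
gradient of the empirical risk, only the best-fitting one (smallest
residual sum of squares; ties go to the lowest spec index) is updated by a
small step.  Early stopping — choosing the number of iterations ``m_stop``
by out-of-sample risk — supplies shrinkage and intrinsic variable
selection: a learner never selected contributes exactly zero.

:class:`QuantileBoostResults` carries the fitted additive predictor
(offset plus accumulated per-learner coefficient states), the risk
trajectory, selection counts, prediction, a summary table and JSON
serialization sufficient for bit-exact reload.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .learners import (BaseLearnerSpec, DummyEngine, LinearEngine,
                       PSplineEngine, SubjectEngine)
from .loss import _validate_tau, check_loss, negative_gradient

__all__ = ["QuantileBoost", "QuantileBoostResults", "default_specs"]


def default_specs(exog: pd.DataFrame) -> list[BaseLearnerSpec]:
    """One linear base-learner per column (dummy block if categorical)."""
    return [BaseLearnerSpec(covariate=c, kind="linear") for c in exog.columns]


def _is_numeric(col: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(col) and not \
        pd.api.types.is_bool_dtype(col)


class QuantileBoost:
    """Additive quantile regression model estimated by boosting.

    Parameters
    ----------
    endog : array_like
        Continuous response vector (no missing values).
    exog : pandas.DataFrame
        Covariate table; numeric columns and categorical (object /
        category) columns are both accepted.
    tau : float
        Quantile level in (0, 1).
    specs : list of BaseLearnerSpec, optional
        Candidate effects.  Defaults to one linear learner per column.
    subject : array_like, optional
        Subject labels (one per row); required by subject-specific
        base-learners.

    Examples
    --------
    >>> model = QuantileBoost(y, X, tau=0.975)
    >>> res = model.fit(m_stop=200, step_length=0.1)
    >>> res.predict(X_new)
    """

    def __init__(self, endog, exog: pd.DataFrame, tau: float,
                 specs: Optional[Sequence[BaseLearnerSpec]] = None,
                 subject=None):
        self.tau = _validate_tau(tau)
        y = np.asarray(endog, dtype=float)
        if y.ndim != 1:
            raise ValueError("endog must be one-dimensional")
        if not np.all(np.isfinite(y)):
            raise ValueError("endog contains missing or non-finite values")
        if not isinstance(exog, pd.DataFrame):
            exog = pd.DataFrame(np.asarray(exog),
                                columns=[f"x{j + 1}" for j in
                                         range(np.asarray(exog).shape[1])])
        if len(exog) != len(y):
            raise ValueError(
                f"length mismatch: {len(y)} responses, {len(exog)} rows")
        if exog.shape[1] < 1:
            raise ValueError("exog needs at least one covariate column")
        self.endog = y
        self.exog = exog
        self.nobs = len(y)
        if specs is None:
            specs = default_specs(exog)
        specs = list(specs)
        if not specs:
            raise ValueError("empty base-learner specification list")
        self.specs = specs
        if subject is not None:
            subject = np.asarray(subject).astype(str)
            if len(subject) != self.nobs:
                raise ValueError("subject must have one label per row")
        self.subject = subject
        self.engines, self._loc = self._build_engines()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, tau: float,
                       specs=None, covariates=None, subject_col=None):
        """Build a model from a single table holding response and covariates."""
        if response not in data.columns:
            raise ValueError(f"response column {response!r} not in table")
        subject = data[subject_col] if subject_col else None
        if covariates is None:
            drop = {response} | ({subject_col} if subject_col else set())
            covariates = [c for c in data.columns if c not in drop]
        return cls(data[response], data[covariates], tau, specs=specs,
                   subject=subject)

    def _build_engines(self):
        lin_names, lin_idx = [], []
        cat_names, cat_idx = [], []
        ps_specs, ps_names, ps_idx = [], [], []
        su_specs, su_idx, su_slopes = [], [], []
        for g, spec in enumerate(self.specs):
            if spec.kind in ("subject_intercept", "subject_slope"):
                if self.subject is None:
                    raise ValueError(
                        f"base-learner {spec.label!r} needs subject labels")
                su_specs.append(spec)
                su_idx.append(g)
                if spec.kind == "subject_slope":
                    self._require_column(spec.slope_covariate)
                    su_slopes.append(np.asarray(
                        self.exog[spec.slope_covariate], dtype=float))
                else:
                    su_slopes.append(None)
                continue
            self._require_column(spec.covariate)
            col = self.exog[spec.covariate]
            if spec.kind == "pspline":
                if not _is_numeric(col):
                    raise ValueError(f"pspline learner on non-numeric "
                                     f"covariate {spec.covariate!r}")
                ps_specs.append(spec)
                ps_names.append(spec.covariate)
                ps_idx.append(g)
            elif _is_numeric(col):
                lin_names.append(spec.covariate)
                lin_idx.append(g)
            else:
                cat_names.append(spec.covariate)
                cat_idx.append(g)
        engines = []
        if lin_names:
            engines.append(LinearEngine(
                lin_names, self.exog[lin_names].to_numpy(float), lin_idx))
        if cat_names:
            engines.append(DummyEngine(
                cat_names, [self.exog[c].to_numpy() for c in cat_names],
                cat_idx))
        if ps_specs:
            shapes = {(s.n_knots, s.degree, s.diff_order) for s in ps_specs}
            for shape in sorted(shapes):
                sel = [i for i, s in enumerate(ps_specs)
                       if (s.n_knots, s.degree, s.diff_order) == shape]
                engines.append(PSplineEngine(
                    [ps_names[i] for i in sel],
                    self.exog[[ps_names[i] for i in sel]].to_numpy(float),
                    [ps_specs[i] for i in sel],
                    [ps_idx[i] for i in sel]))
        if su_specs:
            codes, labels = pd.factorize(self.subject)
            engines.append(SubjectEngine(su_specs, codes, len(labels),
                                         list(labels), su_slopes, su_idx))
        loc = {}
        for eng in engines:
            for local_j, g in enumerate(eng.global_idx):
                loc[g] = (eng, local_j)
        return engines, loc

    def _require_column(self, name):
        if name not in self.exog.columns:
            raise ValueError(f"covariate column {name!r} missing from exog; "
                             f"available: {list(self.exog.columns)}")

    # -- estimation -------------------------------------------------------

    def fit(self, m_stop: int = 100, step_length: float = 0.1,
            eval_set=None, patience: Optional[int] = None
            ) -> "QuantileBoostResults":
        """Run ``m_stop`` boosting iterations.

        Parameters
        ----------
        m_stop : int
            Number of boosting iterations (0 gives the pure-offset model).
        step_length : float
            Shrinkage step in (0, 1] applied to every update.
        eval_set : tuple, optional
            ``(exog_eval, endog_eval)`` or ``(exog_eval, endog_eval,
            subject_eval)``; the empirical risk on this set is recorded
            after every iteration.
        patience : int, optional
            Stop early once the evaluation risk has not improved for this
            many consecutive iterations (requires ``eval_set``).
        """
        if m_stop < 0:
            raise ValueError("m_stop must be nonnegative")
        if not (0.0 < step_length <= 1.0):
            raise ValueError("step_length must lie in (0, 1]")
        tau = self.tau
        y = self.endog
        n = self.nobs
        p = len(self.specs)
        offset = float(np.quantile(y, tau))
        eta = np.full(n, offset)
        states = [self._loc[g][0].zero_state(self._loc[g][1])
                  for g in range(p)]
        counts = np.zeros(p, dtype=int)
        risk_path = []
        history = []

        eval_packs = eval_eta = y_eval = None
        eval_risk_path = None
        if eval_set is not None:
            X_ev, y_eval = eval_set[0], np.asarray(eval_set[1], dtype=float)
            subj_ev = eval_set[2] if len(eval_set) > 2 else None
            if subj_ev is not None:
                subj_ev = np.asarray(subj_ev).astype(str)
            if not isinstance(X_ev, pd.DataFrame):
                X_ev = pd.DataFrame(np.asarray(X_ev),
                                    columns=list(self.exog.columns))
            eval_packs = {id(e): e.eval_pack(X_ev, subj_ev)
                          for e in self.engines}
            eval_eta = np.full(len(y_eval), offset)
            eval_risk_path = []
        elif patience is not None:
            raise ValueError("patience requires an eval_set")

        rss_global = np.empty(p)
        best_eval = np.inf
        best_eval_m = 0
        for m in range(m_stop):
            u = negative_gradient(y, eta, tau)
            payloads = {}
            for eng in self.engines:
                rss, payload = eng.fit_all(u)
                rss_global[eng.global_idx] = rss
                payloads[id(eng)] = payload
            g = int(np.argmin(rss_global))  # first minimum: lowest index
            eng, lj = self._loc[g]
            coef = np.asarray(eng.coef_for(payloads[id(eng)], lj),
                              dtype=float)
            states[g] = states[g] + step_length * coef
            eta = eta + step_length * eng.fitted_for(payloads[id(eng)], lj)
            counts[g] += 1
            history.append((g, coef))
            r = y - eta
            risk_path.append(float(np.mean(
                np.where(r > 0, tau * r, (tau - 1.0) * r))))
            if eval_eta is not None:
                eval_eta = eval_eta + step_length * eng.eval_increment(
                    eval_packs[id(eng)], lj, coef)
                r = y_eval - eval_eta
                ev = float(np.mean(np.where(r > 0, tau * r, (tau - 1.0) * r)))
                eval_risk_path.append(ev)
                if ev < best_eval:
                    best_eval, best_eval_m = ev, m
                elif patience is not None and m - best_eval_m >= patience:
                    break

        return QuantileBoostResults(
            model=self, tau=tau, offset=offset, step_length=step_length,
            states=states, selection_counts=counts,
            risk_path=np.asarray(risk_path),
            eval_risk_path=(None if eval_risk_path is None
                            else np.asarray(eval_risk_path)),
            history=history, fittedvalues=eta)

    # -- tuning -----------------------------------------------------------

    def select_mstop(self, method: str = "validation_set", m_max: int = 1000,
                     step_length: float = 0.1, eval_set=None, folds: int = 10,
                     reps: int = 25, random_state=None,
                     patience: Optional[int] = None, return_path: bool = False):
        """Choose the stopping iteration by out-of-sample empirical risk.

        ``method`` is one of ``validation_set`` (held-out sample),
        ``kfold_cv``, ``bootstrap`` (row resampling, out-of-bag risk) or
        ``subject_bootstrap`` (whole-subject resampling).  Returns the
        arg-min over ``m in 1..m_max`` of the mean out-of-sample risk.
        """
        if m_max < 1:
            raise ValueError("m_max must be at least 1")
        rng = np.random.default_rng(random_state)
        if method == "validation_set":
            if eval_set is None:
                raise ValueError("validation_set selection needs eval_set")
            res = self.fit(m_stop=m_max, step_length=step_length,
                           eval_set=eval_set, patience=patience)
            path = res.eval_risk_path
        elif method == "kfold_cv":
            idx = rng.permutation(self.nobs)
            paths = []
            for chunk in np.array_split(idx, folds):
                mask = np.ones(self.nobs, dtype=bool)
                mask[chunk] = False
                paths.append(self._oos_path(mask, ~mask, m_max, step_length))
            path = np.mean(paths, axis=0)
        elif method == "bootstrap":
            paths = []
            for _ in range(reps):
                draw = rng.integers(0, self.nobs, self.nobs)
                oob = np.ones(self.nobs, dtype=bool)
                oob[draw] = False
                if not oob.any():
                    continue
                paths.append(self._oos_path(draw, oob, m_max, step_length))
            if not paths:
                raise RuntimeError("every bootstrap replicate had an empty "
                                   "out-of-bag set")
            path = np.mean(paths, axis=0)
        elif method == "subject_bootstrap":
            if self.subject is None:
                raise ValueError("subject_bootstrap requires subject labels")
            labels = pd.unique(self.subject)
            row_of = pd.Series(np.arange(self.nobs)).groupby(
                self.subject).groups
            paths = []
            for _ in range(reps):
                draw = rng.choice(labels, size=len(labels), replace=True)
                oob_labels = np.setdiff1d(labels, draw)
                if len(oob_labels) == 0:
                    continue
                tr_rows, tr_subj = [], []
                for copy, lab in enumerate(draw):
                    rows = np.asarray(row_of[lab])
                    tr_rows.append(rows)
                    tr_subj.extend([f"{lab}#{copy}"] * len(rows))
                tr_rows = np.concatenate(tr_rows)
                oob_rows = np.concatenate(
                    [np.asarray(row_of[lab]) for lab in oob_labels])
                sub = QuantileBoost(self.endog[tr_rows],
                                    self.exog.iloc[tr_rows], self.tau,
                                    specs=self.specs,
                                    subject=np.asarray(tr_subj))
                res = sub.fit(m_stop=m_max, step_length=step_length,
                              eval_set=(self.exog.iloc[oob_rows],
                                        self.endog[oob_rows],
                                        self.subject[oob_rows]))
                paths.append(res.eval_risk_path)
            if not paths:
                raise RuntimeError("every subject bootstrap replicate had an "
                                   "empty out-of-bag set")
            path = np.mean(paths, axis=0)
        else:
            raise ValueError(f"unknown selection method {method!r}")
        m_best = int(np.argmin(path)) + 1
        if return_path:
            return m_best, np.asarray(path)
        return m_best

    def _oos_path(self, train_rows, test_rows, m_max, step_length):
        train_rows = np.asarray(train_rows)
        if train_rows.dtype == bool:
            train_rows = np.flatnonzero(train_rows)
        test_rows = np.asarray(test_rows)
        if test_rows.dtype == bool:
            test_rows = np.flatnonzero(test_rows)
        subj = None if self.subject is None else self.subject[train_rows]
        sub = QuantileBoost(self.endog[train_rows],
                            self.exog.iloc[train_rows], self.tau,
                            specs=self.specs, subject=subj)
        ev_subj = None if self.subject is None else self.subject[test_rows]
        res = sub.fit(m_stop=m_max, step_length=step_length,
                      eval_set=(self.exog.iloc[test_rows],
                                self.endog[test_rows], ev_subj))
        return res.eval_risk_path


class QuantileBoostResults:
    """Fitted boosted additive quantile regression at one level tau."""

    def __init__(self, model, tau, offset, step_length, states,
                 selection_counts, risk_path, eval_risk_path, history,
                 fittedvalues=None, engines=None, specs=None):
        self.model = model
        self.tau = tau
        self.offset = offset
        self.step_length = step_length
        self.states = states
        self.selection_counts = np.asarray(selection_counts)
        self.risk_path = np.asarray(risk_path)
        self.eval_risk_path = eval_risk_path
        self.history = history
        self.fittedvalues = fittedvalues
        self._engines = engines if engines is not None else model.engines
        self._specs = specs if specs is not None else model.specs
        self._loc = (model._loc if model is not None else
                     {g: (e, j) for e in self._engines
                      for j, g in enumerate(e.global_idx)})

    @property
    def m_stop(self) -> int:
        return int(self.selection_counts.sum())

    # -- prediction -------------------------------------------------------

    def predict(self, exog=None, subject=None,
                include_subject_effects: bool = True):
        """Evaluate the fitted conditional quantile on new covariates.

        With ``include_subject_effects=False`` (or for subjects unseen in
        training) subject-specific intercepts and slopes contribute zero,
        which corresponds to their expected mean.
        """
        if exog is None:
            if self.fittedvalues is None:
                exog = self.model.exog
                subject = self.model.subject
            else:
                return self.fittedvalues.copy()
        if not isinstance(exog, pd.DataFrame):
            cols = (list(self.model.exog.columns) if self.model is not None
                    else None)
            exog = pd.DataFrame(np.asarray(exog), columns=cols)
        missing = sorted(self._required_columns() - set(exog.columns))
        if missing:
            raise ValueError(f"exog is missing required columns: {missing}")
        if subject is not None:
            subject = np.asarray(subject).astype(str)
        out = np.full(len(exog), self.offset)
        for eng in self._engines:
            for lj, g in enumerate(eng.global_idx):
                if self.selection_counts[g] == 0:
                    continue
                if isinstance(eng, SubjectEngine):
                    if not include_subject_effects:
                        continue
                    out = out + eng.contrib_new(lj, self.states[g], exog,
                                                subject=subject)
                else:
                    out = out + eng.contrib_new(lj, self.states[g], exog)
        return out

    def _required_columns(self):
        cols = set()
        for eng in self._engines:
            if isinstance(eng, SubjectEngine):
                cols.update(s.slope_covariate for s in eng.specs
                            if s.kind == "subject_slope")
            else:
                cols.update(eng.names)
        return cols

    # -- truncation (early stopping after the fact) -----------------------

    def at_iteration(self, m: int) -> "QuantileBoostResults":
        """Model state after the first ``m`` boosting iterations.

        Replays the stored update history, so the result is bit-identical
        to a fresh fit with ``m_stop=m``.
        """
        if self.history is None:
            raise ValueError("update history was not retained")
        if not (0 <= m <= len(self.history)):
            raise ValueError(f"m must lie in [0, {len(self.history)}]")
        p = len(self._specs)
        states = [self._loc[g][0].zero_state(self._loc[g][1])
                  for g in range(p)]
        counts = np.zeros(p, dtype=int)
        for g, coef in self.history[:m]:
            states[g] = states[g] + self.step_length * coef
            counts[g] += 1
        return QuantileBoostResults(
            model=self.model, tau=self.tau, offset=self.offset,
            step_length=self.step_length, states=states,
            selection_counts=counts, risk_path=self.risk_path[:m],
            eval_risk_path=(None if self.eval_risk_path is None
                            else self.eval_risk_path[:m]),
            history=self.history[:m], fittedvalues=None,
            engines=self._engines, specs=self._specs)

    # -- reporting --------------------------------------------------------

    def coefficient_table(self) -> pd.DataFrame:
        """Effect estimates in report layout: blank means never selected.

        Linear effects show their slope; dummy blocks one row per
        non-reference level; smooth and subject terms are flagged as
        ``f(.)`` / ``subject(.)`` without a single coefficient.  Learner
        intercept parts are folded into the reported intercept.
        """
        rows = []
        intercept = self.offset
        for eng in self._engines:
            for lj, g in enumerate(eng.global_idx):
                spec = self._specs[g]
                selected = self.selection_counts[g] > 0
                st = self.states[g]
                if isinstance(eng, LinearEngine):
                    if selected:
                        intercept += st[0] - st[1] * eng.center[lj]
                    rows.append((spec.label, "linear",
                                 int(self.selection_counts[g]),
                                 st[1] if selected else np.nan))
                elif isinstance(eng, DummyEngine):
                    if selected:
                        intercept += st[0]
                    for k, lev in enumerate(eng.levels[lj][1:], start=1):
                        rows.append((f"{spec.label} = {lev}", "linear",
                                     int(self.selection_counts[g]),
                                     st[k] if selected else np.nan))
                elif isinstance(eng, PSplineEngine):
                    rows.append((f"f({spec.label})", "pspline",
                                 int(self.selection_counts[g]), np.nan))
                else:
                    rows.append((spec.label, spec.kind,
                                 int(self.selection_counts[g]), np.nan))
        table = pd.DataFrame(rows, columns=["term", "kind", "selected",
                                            "estimate"])
        head = pd.DataFrame([("Intercept", "offset", -1, intercept)],
                            columns=table.columns)
        return pd.concat([head, table], ignore_index=True)

    def summary(self) -> str:
        tab = self.coefficient_table()
        lines = [
            "Boosted additive quantile regression",
            f"  tau = {self.tau:g}   m_stop = {self.m_stop}   "
            f"step length = {self.step_length:g}",
            f"  offset (empirical tau-quantile) = {self.offset:.6g}",
        ]
        if len(self.risk_path):
            lines.append(f"  final training risk = {self.risk_path[-1]:.6g}")
        lines.append("")
        lines.append(f"{'term':<24}{'kind':<18}{'updates':>8}  estimate")
        for _, r in tab.iterrows():
            sel = "" if r.selected < 0 else str(int(r.selected))
            est = "" if np.isnan(r.estimate) and r.kind != "offset" else (
                f"{r.estimate:.4f}")
            if r.kind in ("pspline",) and r.selected > 0:
                est = "f(.)"
            if r.kind in ("subject_intercept", "subject_slope") \
                    and r.selected > 0:
                est = "subject(.)"
            lines.append(f"{r.term:<24}{r.kind:<18}{sel:>8}  {est}")
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "offset": self.offset,
            "step_length": self.step_length,
            "selection_counts": self.selection_counts.tolist(),
            "risk_path": self.risk_path.tolist(),
            "eval_risk_path": (None if self.eval_risk_path is None
                               else np.asarray(self.eval_risk_path).tolist()),
            "specs": [{"covariate": s.covariate, "kind": s.kind,
                       "n_knots": s.n_knots, "degree": s.degree,
                       "diff_order": s.diff_order, "df": s.df,
                       "penalty": s.penalty,
                       "slope_covariate": s.slope_covariate}
                      for s in self._specs],
            "engines": [{"params": e.to_params(),
                         "global_idx": list(e.global_idx)}
                        for e in self._engines],
            "states": [np.asarray(s).tolist() for s in self.states],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "QuantileBoostResults":
        specs = [BaseLearnerSpec(**s) for s in d["specs"]]
        kinds = {"linear": LinearEngine, "dummy": DummyEngine,
                 "pspline": PSplineEngine, "subject": SubjectEngine}
        engines = []
        for e in d["engines"]:
            eng = kinds[e["params"]["type"]].from_params(e["params"])
            eng.global_idx = list(e["global_idx"])
            engines.append(eng)
        return cls(model=None, tau=d["tau"], offset=d["offset"],
                   step_length=d["step_length"],
                   states=[np.asarray(s, dtype=float) for s in d["states"]],
                   selection_counts=d["selection_counts"],
                   risk_path=d["risk_path"],
                   eval_risk_path=(None if d["eval_risk_path"] is None else
                                   np.asarray(d["eval_risk_path"])),
                   history=None, engines=engines, specs=specs)

    @classmethod
    def load(cls, path) -> "QuantileBoostResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # -- diagnostics -------------------------------------------------------

    def plot_risk_path(self, ax=None):
        """Training (and evaluation) empirical risk per iteration."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.risk_path) + 1), self.risk_path,
                label="training risk")
        if self.eval_risk_path is not None:
            ax.plot(np.arange(1, len(self.eval_risk_path) + 1),
                    self.eval_risk_path, label="evaluation risk")
        ax.set_xlabel("boosting iteration")
        ax.set_ylabel("empirical check-loss risk")
        ax.legend()
        return ax

    def empirical_risk(self, exog=None, endog=None, subject=None) -> float:
        """Mean check loss of the fitted predictor on a given sample."""
        if endog is None:
            endog = self.model.endog
        eta = self.predict(exog, subject=subject)
        return float(np.mean(check_loss(endog, eta, self.tau)))
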
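"""Base-learners for component-wise gradient boosting.

Each candidate covariate effect is represented by one *base-learner*: a
simple penalized univariate regression that is repeatedly fitted to the
current negative-gradient vector.  Four kinds are supported:

``linear``
    Ordinary least squares of the working response on the (mean-centered)
    covariate plus an intercept.  Categorical covariates are handled as one
    learner per dummy block (reference = first observed level).
``pspline``
    Penalized B-spline regression (P-spline): cubic B-spline basis over
    equidistant interior knots with a difference penalty on adjacent
    coefficients.  The penalty weight is calibrated once, from the basis
    alone, so that the smoother's effective degrees of freedom equal a
    configured target — this puts all learners on a comparable (weak)
    footing for the selection step.
``subject_intercept`` / ``subject_slope``
    Ridge-penalized per-subject constants / per-subject slopes in a given
    covariate (e.g. age), shrunk toward zero.  Together with the iterative
    shrinkage of boosting and early stopping these play the role of random
    intercepts and slopes in longitudinal data.

Engines below batch all learners of one kind so that each boosting
iteration costs a handful of BLAS calls instead of a Python loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import eigh
from scipy.optimize import brentq

_KINDS = ("linear", "pspline", "subject_intercept", "subject_slope")


@dataclass
class BaseLearnerSpec:
    """Declaration of one covariate's candidate effect.

    Parameters
    ----------
    covariate : str
        Column name in the covariate table.  Ignored (may be ``None``) for
        ``subject_intercept``.
    kind : str
        One of ``linear``, ``pspline``, ``subject_intercept``,
        ``subject_slope``.
    n_knots : int
        Number of equidistant interior knots (pspline only).
    degree : int
        B-spline degree (pspline only).
    diff_order : int
        Order of the difference penalty (pspline only).
    df : float
        Target effective degrees of freedom used to calibrate the penalty
        weight (pspline and subject kinds).
    penalty : float, optional
        Explicit penalty weight; overrides the df calibration.
    slope_covariate : str, optional
        Covariate multiplying the per-subject coefficient
        (``subject_slope`` only).
    """

    covariate: Optional[str]
    kind: str = "linear"
    n_knots: int = 20
    degree: int = 3
    diff_order: int = 2
    df: float = 4.0
    penalty: Optional[float] = None
    slope_covariate: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown base-learner kind {self.kind!r}; "
                             f"expected one of {_KINDS}")
        if self.kind == "subject_slope" and self.slope_covariate is None:
            self.slope_covariate = self.covariate
        if self.kind == "subject_slope" and self.slope_covariate is None:
            raise ValueError("subject_slope requires a slope_covariate")

    @property
    def label(self) -> str:
        if self.kind == "subject_intercept":
            return "subject(1)"
        if self.kind == "subject_slope":
            return f"subject({self.slope_covariate})"
        return str(self.covariate)


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------

class _Engine:
    """Common interface: batched fit of all member learners to u."""

    global_idx: list  # position of each member in the model's spec order

    def fit_all(self, u):  # -> (rss (k,), payload)
        raise NotImplementedError

    def coef_for(self, payload, j):
        raise NotImplementedError

    def fitted_for(self, payload, j):
        raise NotImplementedError

    def contrib_new(self, j, state_j, frame):
        """Contribution of learner j with accumulated state on new data."""
        raise NotImplementedError

    def zero_state(self, j):
        raise NotImplementedError

    def eval_pack(self, frame, subject=None):
        """Precompute whatever is needed to evaluate members on new data."""
        raise NotImplementedError

    def eval_increment(self, pack, j, coef):
        """Contribution of one coefficient vector on pre-packed data."""
        raise NotImplementedError


class LinearEngine(_Engine):
    """All plain linear learners, fitted jointly.

    Covariates are mean-centered before fitting so that the intercept part
    of every update accumulates cleanly; at prediction time the
    contribution is ``a + b * (x - center)``.
    """

    kind = "linear"

    def __init__(self, names, X, global_idx):
        self.names = list(names)
        self.global_idx = list(global_idx)
        X = np.asarray(X, dtype=float)
        self.center = X.mean(axis=0)
        self.xc = X - self.center
        self.ssq = np.einsum("ij,ij->j", self.xc, self.xc)
        self._const = self.ssq <= 1e-12 * max(1.0, float(np.max(np.abs(X))))
        self._safe_ssq = np.where(self._const, 1.0, self.ssq)
        self.n = X.shape[0]

    def fit_all(self, u):
        a = float(u.mean())
        b = (self.xc.T @ u) / self._safe_ssq
        b[self._const] = 0.0
        uu = float(u @ u)
        rss = uu - self.n * a * a - b * b * self.ssq
        return rss, (a, b)

    def coef_for(self, payload, j):
        a, b = payload
        return np.array([a, b[j]])

    def fitted_for(self, payload, j):
        a, b = payload
        return a + b[j] * self.xc[:, j]

    def zero_state(self, j):
        return np.zeros(2)

    def contrib_new(self, j, state_j, frame):
        x = np.asarray(frame[self.names[j]], dtype=float)
        return state_j[0] + state_j[1] * (x - self.center[j])

    def eval_pack(self, frame, subject=None):
        X = np.asarray(frame[self.names], dtype=float)
        return X - self.center

    def eval_increment(self, pack, j, coef):
        return coef[0] + coef[1] * pack[:, j]

    def to_params(self):
        return {"type": "linear", "names": self.names,
                "center": self.center.tolist()}

    @classmethod
    def from_params(cls, params):
        obj = cls.__new__(cls)
        obj.names = list(params["names"])
        obj.global_idx = []
        obj.center = np.asarray(params["center"], dtype=float)
        return obj


class DummyEngine(_Engine):
    """One linear learner per categorical covariate (dummy block).

    The first observed level is the reference; the block is fitted by OLS
    on ``[1, dummies]``.
    """

    kind = "linear"

    def __init__(self, names, columns, global_idx):
        self.names = list(names)
        self.global_idx = list(global_idx)
        self.levels = []
        self.designs = []
        self.solvers = []
        for col in columns:
            col = np.asarray(col)
            levels = list(dict.fromkeys(col.tolist()))  # observed order
            if len(levels) < 2:
                raise ValueError(
                    f"categorical covariate {self.names[len(self.levels)]!r} "
                    "has fewer than two observed levels")
            codes = np.array([levels.index(v) for v in col.tolist()])
            Z = np.zeros((len(col), len(levels)))
            Z[:, 0] = 1.0
            for k in range(1, len(levels)):
                Z[codes == k, k] = 1.0
            self.levels.append(levels)
            self.designs.append(Z)
            self.solvers.append(np.linalg.pinv(Z))

    def fit_all(self, u):
        rss = np.empty(len(self.designs))
        coefs = []
        fits = []
        for i, (Z, P) in enumerate(zip(self.designs, self.solvers)):
            c = P @ u
            f = Z @ c
            rss[i] = float(np.sum((u - f) ** 2))
            coefs.append(c)
            fits.append(f)
        return rss, (coefs, fits)

    def coef_for(self, payload, j):
        return payload[0][j]

    def fitted_for(self, payload, j):
        return payload[1][j]

    def zero_state(self, j):
        return np.zeros(len(self.levels[j]))

    def contrib_new(self, j, state_j, frame):
        col = np.asarray(frame[self.names[j]])
        levels = self.levels[j]
        unseen = sorted({str(v) for v in col.tolist() if v not in levels})
        if unseen:
            raise ValueError(
                f"unseen levels {unseen} for categorical covariate "
                f"{self.names[j]!r}; training levels were {levels}")
        codes = np.array([levels.index(v) for v in col.tolist()])
        return state_j[0] + np.where(codes > 0, state_j[codes], 0.0)

    def eval_pack(self, frame, subject=None):
        packs = []
        for j, name in enumerate(self.names):
            col = np.asarray(frame[name])
            levels = self.levels[j]
            unseen = sorted({str(v) for v in col.tolist() if v not in levels})
            if unseen:
                raise ValueError(
                    f"unseen levels {unseen} for categorical covariate "
                    f"{name!r}; training levels were {levels}")
            packs.append(np.array([levels.index(v) for v in col.tolist()]))
        return packs

    def eval_increment(self, pack, j, coef):
        codes = pack[j]
        return coef[0] + np.where(codes > 0, coef[codes], 0.0)

    def to_params(self):
        return {"type": "dummy", "names": self.names, "levels": self.levels}

    @classmethod
    def from_params(cls, params):
        obj = cls.__new__(cls)
        obj.names = list(params["names"])
        obj.global_idx = []
        obj.levels = [list(lv) for lv in params["levels"]]
        return obj


class PSplineEngine(_Engine):
    """All P-spline learners with a shared basis size, fitted jointly."""

    kind = "pspline"

    def __init__(self, names, X, specs, global_idx):
        self.names = list(names)
        self.global_idx = list(global_idx)
        X = np.asarray(X, dtype=float)
        n, k = X.shape
        spec0 = specs[0]
        self.degree = spec0.degree
        self.diff_order = spec0.diff_order
        self.K = spec0.n_knots + spec0.degree + 1
        self.knots = []
        self.bounds = []
        self.lambdas = np.empty(k)
        Bs = np.empty((k, n, self.K))
        Ms = np.empty((k, self.K, self.K))
        D = np.diff(np.eye(self.K), n=self.diff_order, axis=0)
        pen = D.T @ D
        for j, spec in enumerate(specs):
            x = X[:, j]
            lo, hi = float(x.min()), float(x.max())
            if hi <= lo:
                raise ValueError(
                    f"cannot build a spline basis for constant covariate "
                    f"{self.names[j]!r}")
            t = _knot_vector(lo, hi, spec.n_knots, spec.degree)
            B = BSpline.design_matrix(x, t, spec.degree).toarray()
            BtB = B.T @ B
            ridge = 1e-10 * max(1.0, float(np.trace(BtB)) / self.K)
            BtB_r = BtB + ridge * np.eye(self.K)
            if spec.penalty is not None:
                lam = float(spec.penalty)
            else:
                lam = _lambda_for_df(BtB_r, pen, spec.df)
            self.knots.append(t)
            self.bounds.append((lo, hi))
            self.lambdas[j] = lam
            Bs[j] = B
            Ms[j] = np.linalg.inv(BtB_r + lam * pen)
        self.B = Bs                      # (k, n, K)
        self.BT = np.ascontiguousarray(Bs.transpose(0, 2, 1))
        self.M = Ms
        self.BtBs = np.einsum("kji,kjl->kil", Bs, Bs)

    def fit_all(self, u):
        # RSS via quadratic forms; fitted values only materialized for the
        # single selected learner (fitted_for), which dominates runtime.
        btu = self.BT @ u[None, :, None]          # (k, K, 1)
        coefs = self.M @ btu                      # (k, K, 1)
        quad = self.BtBs @ coefs                  # (k, K, 1)
        uu = float(u @ u)
        rss = (uu - 2.0 * np.einsum("kij,kij->k", btu, coefs)
               + np.einsum("kij,kij->k", coefs, quad))
        return rss, coefs

    def coef_for(self, payload, j):
        return payload[j, :, 0].copy()

    def fitted_for(self, payload, j):
        return self.B[j] @ payload[j, :, 0]

    def zero_state(self, j):
        return np.zeros(self.K)

    def design_new(self, j, x):
        x = np.asarray(x, dtype=float)
        lo, hi = self.bounds[j]
        xc = np.clip(x, lo, hi)
        return BSpline.design_matrix(xc, self.knots[j], self.degree).toarray()

    def contrib_new(self, j, state_j, frame):
        return self.design_new(j, np.asarray(frame[self.names[j]],
                                             dtype=float)) @ state_j

    def eval_pack(self, frame, subject=None):
        return [self.design_new(j, np.asarray(frame[name], dtype=float))
                for j, name in enumerate(self.names)]

    def eval_increment(self, pack, j, coef):
        return pack[j] @ coef

    def to_params(self):
        return {"type": "pspline", "names": self.names, "degree": self.degree,
                "knots": [t.tolist() for t in self.knots],
                "bounds": [list(b) for b in self.bounds],
                "lambdas": self.lambdas.tolist()}

    @classmethod
    def from_params(cls, params):
        obj = cls.__new__(cls)
        obj.names = list(params["names"])
        obj.global_idx = []
        obj.degree = int(params["degree"])
        obj.knots = [np.asarray(t, dtype=float) for t in params["knots"]]
        obj.bounds = [tuple(b) for b in params["bounds"]]
        obj.lambdas = np.asarray(params["lambdas"], dtype=float)
        obj.K = len(obj.knots[0]) - obj.degree - 1
        return obj


class SubjectEngine(_Engine):
    """Ridge-penalized per-subject intercepts or slopes.

    Each learner fits one coefficient per subject (shrunk toward zero);
    subjects unseen in training contribute zero at prediction time, which
    corresponds to their expected mean.
    """

    kind = "subject"

    def __init__(self, specs, codes, n_subjects, subject_labels,
                 slope_values, global_idx):
        self.specs = list(specs)
        self.global_idx = list(global_idx)
        self.codes = np.asarray(codes)
        self.S = int(n_subjects)
        self.labels = list(subject_labels)
        self._label_pos = {lab: i for i, lab in enumerate(self.labels)}
        self.z = []         # multiplier column per learner (1s or slope cov)
        self.zz = []        # per-subject sum of squared multipliers
        self.lambdas = []
        for spec, zv in zip(self.specs, slope_values):
            if spec.kind == "subject_intercept":
                z = np.ones_like(self.codes, dtype=float)
            else:
                z = np.asarray(zv, dtype=float)
            zz = np.bincount(self.codes, weights=z * z, minlength=self.S)
            if spec.penalty is not None:
                lam = float(spec.penalty)
            else:
                lam = _ridge_lambda_for_df(zz, spec.df)
            self.z.append(z)
            self.zz.append(zz)
            self.lambdas.append(lam)

    def fit_all(self, u):
        k = len(self.specs)
        rss = np.empty(k)
        coefs = []
        fits = []
        uu = float(u @ u)
        for i in range(k):
            zu = np.bincount(self.codes, weights=self.z[i] * u,
                             minlength=self.S)
            denom = self.zz[i] + self.lambdas[i]
            c = np.where(denom > 0, zu / np.where(denom > 0, denom, 1.0), 0.0)
            f = c[self.codes] * self.z[i]
            coefs.append(c)
            fits.append(f)
            rss[i] = uu - 2.0 * float(f @ u) + float(f @ f)
        return rss, (coefs, fits)

    def coef_for(self, payload, j):
        return payload[0][j]

    def fitted_for(self, payload, j):
        return payload[1][j]

    def zero_state(self, j):
        return np.zeros(self.S)

    def contrib_new(self, j, state_j, frame, subject=None):
        if subject is None:
            raise ValueError("subject labels required to evaluate "
                             "subject-specific effects")
        subject = np.asarray(subject)
        idx = np.array([self._label_pos.get(lab, -1)
                        for lab in subject.tolist()])
        coef = np.where(idx >= 0, state_j[np.maximum(idx, 0)], 0.0)
        spec = self.specs[j]
        if spec.kind == "subject_slope":
            z = np.asarray(frame[spec.slope_covariate], dtype=float)
        else:
            z = 1.0
        return coef * z

    def eval_pack(self, frame, subject=None):
        n = len(frame)
        if subject is None:
            idx = np.full(n, -1)
        else:
            subject = np.asarray(subject)
            idx = np.array([self._label_pos.get(lab, -1)
                            for lab in subject.tolist()])
        packs = []
        for spec in self.specs:
            if spec.kind == "subject_slope":
                z = np.asarray(frame[spec.slope_covariate], dtype=float)
            else:
                z = np.ones(n)
            packs.append((idx, z))
        return packs

    def eval_increment(self, pack, j, coef):
        idx, z = pack[j]
        return np.where(idx >= 0, coef[np.maximum(idx, 0)], 0.0) * z

    def to_params(self):
        return {"type": "subject",
                "specs": [{"kind": s.kind,
                           "slope_covariate": s.slope_covariate}
                          for s in self.specs],
                "labels": [str(lab) for lab in self.labels],
                "lambdas": list(self.lambdas)}

    @classmethod
    def from_params(cls, params):
        obj = cls.__new__(cls)
        obj.specs = [BaseLearnerSpec(covariate=d["slope_covariate"],
                                     kind=d["kind"],
                                     slope_covariate=d["slope_covariate"])
                     for d in params["specs"]]
        obj.global_idx = []
        obj.labels = list(params["labels"])
        obj._label_pos = {lab: i for i, lab in enumerate(obj.labels)}
        obj.S = len(obj.labels)
        obj.lambdas = list(params["lambdas"])
        return obj


# ---------------------------------------------------------------------------
# penalty calibration
# ---------------------------------------------------------------------------

def _knot_vector(lo, hi, n_knots, degree):
    """Equidistant interior knots over [lo, hi] with repeated boundaries."""
    inner = np.linspace(lo, hi, n_knots + 2)
    h = inner[1] - inner[0]
    left = lo - h * np.arange(degree, 0, -1)
    right = hi + h * np.arange(1, degree + 1)
    return np.concatenate([left, inner, right])


def _lambda_for_df(BtB, pen, df):
    """Penalty weight lambda with trace of the smoother hat matrix == df.

    Uses the generalized eigenvalues s of (pen, BtB): the effective degrees
    of freedom are sum(1 / (1 + lambda * s)).
    """
    s = eigh(pen, BtB, eigvals_only=True)
    s = np.clip(s, 0.0, None)
    K = len(s)
    null_dim = int(np.sum(s < 1e-10))
    if not (null_dim < df < K):
        raise ValueError(
            f"target df {df} must lie in ({null_dim}, {K}) for this basis")

    def edf(loglam):
        return float(np.sum(1.0 / (1.0 + 10.0 ** loglam * s))) - df

    return 10.0 ** brentq(edf, -12.0, 16.0, xtol=1e-10)


def _ridge_lambda_for_df(zz, df):
    """Ridge weight so that sum(zz / (zz + lambda)) == df."""
    pos = zz[zz > 0]
    if df >= len(pos):
        return 0.0

    def edf(loglam):
        return float(np.sum(pos / (pos + 10.0 ** loglam))) - df

    lo, hi = -12.0, max(2.0, np.log10(pos.max()) + 8.0)
    return 10.0 ** brentq(edf, lo, hi, xtol=1e-10)
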
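"""Prediction intervals from paired quantile fits, and their validation.

A two-sided prediction interval at nominal level ``1 - alpha`` is the pair
of fitted conditional quantiles ``[q_hat_{alpha/2}(x), q_hat_{1-alpha/2}(x)]``.
Two distinct notions of coverage apply:

*sample coverage*
    the fraction of a whole fresh sample covered by its own intervals —
    necessary but not sufficient for a valid interval;
*conditional coverage*
    the fraction of fresh responses *at one fixed covariate combination*
    falling inside that combination's interval — the criterion a
    prediction interval must actually meet.

A "naive" interval built from the unconditional empirical quantiles of the
training response attains the sample coverage yet fails conditional
coverage whenever the data are heteroscedastic; :func:`naive_pi` provides
that baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class PredictionInterval:
    """Per-observation interval borders at nominal level ``1 - alpha``.

    ``crossing_count`` records how many fitted borders had to be swapped
    because the lower quantile fit exceeded the upper one (quantile
    crossing); crossings are repaired, never silent.
    """

    lower: np.ndarray
    upper: np.ndarray
    nominal_level: float
    crossing_count: int = 0

    def __post_init__(self):
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower and upper must have equal length")
        if not (0.0 < self.nominal_level < 1.0):
            raise ValueError("nominal_level must lie in (0, 1)")

    @property
    def length(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return (self.lower <= y) & (y <= self.upper)


@dataclass
class CoverageReport:
    """Estimated coverage probability with its binomial standard error."""

    estimate: float
    n_eval: int
    mode: str  # "sample" or "conditional"
    nominal_level: float
    test_point: Optional[np.ndarray] = None
    mc_se: float = field(init=False)

    def __post_init__(self):
        self.mc_se = float(np.sqrt(self.estimate * (1.0 - self.estimate)
                                   / self.n_eval))

    def to_row(self) -> dict:
        return {"mode": self.mode, "estimate": self.estimate,
                "mc_se": self.mc_se, "n_eval": self.n_eval,
                "nominal_level": self.nominal_level}


def build_pi(results_lo, results_hi, exog, subject=None,
             include_subject_effects: bool = True) -> PredictionInterval:
    """Interval from a lower- and an upper-quantile fit on new covariates.

    The nominal level is ``tau_hi - tau_lo``.  A non-symmetric tau pair is
    allowed but flagged with a warning.  Where the fitted borders cross
    they are swapped and counted.
    """
    if results_lo.tau >= results_hi.tau:
        raise ValueError("results_lo.tau must be below results_hi.tau")
    if not np.isclose(results_lo.tau + results_hi.tau, 1.0):
        warnings.warn("tau pair is not symmetric about 0.5; nominal level "
                      "is tau_hi - tau_lo", stacklevel=2)
    lo = np.atleast_1d(results_lo.predict(
        exog, subject=subject,
        include_subject_effects=include_subject_effects))
    hi = np.atleast_1d(results_hi.predict(
        exog, subject=subject,
        include_subject_effects=include_subject_effects))
    crossed = lo > hi
    n_cross = int(np.sum(crossed))
    lower = np.where(crossed, hi, lo)
    upper = np.where(crossed, lo, hi)
    return PredictionInterval(lower, upper,
                              nominal_level=results_hi.tau - results_lo.tau,
                              crossing_count=n_cross)


def naive_pi(y_train, alpha: float = 0.05) -> PredictionInterval:
    """Unconditional empirical-quantile interval — the naive baseline.

    Uses linear interpolation of order statistics (type-7 convention), and
    is by construction identical for every covariate combination.
    """
    y = np.asarray(y_train, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two training responses")
    lo, hi = np.quantile(y, [alpha / 2.0, 1.0 - alpha / 2.0])
    return PredictionInterval(np.array([lo]), np.array([hi]),
                              nominal_level=1.0 - alpha)


def sample_coverage(pi: PredictionInterval, y_new) -> CoverageReport:
    """Fraction of a fresh sample covered by its respective intervals.

    A scalar (length-1) interval is broadcast over the whole sample, which
    is exactly the naive baseline's use.
    """
    y = np.asarray(y_new, dtype=float)
    if y.size == 0:
        raise ValueError("empty evaluation sample")
    if len(pi.lower) not in (1, y.size):
        raise ValueError(f"interval count {len(pi.lower)} does not match "
                         f"sample size {y.size}")
    covered = (pi.lower <= y) & (y <= pi.upper)
    return CoverageReport(estimate=float(np.mean(covered)), n_eval=y.size,
                          mode="sample", nominal_level=pi.nominal_level)


def conditional_coverage(pi: PredictionInterval, y_test,
                         test_point=None) -> CoverageReport:
    """Fraction of fresh responses at one fixed x inside that x's interval."""
    y = np.asarray(y_test, dtype=float)
    if y.size == 0:
        raise ValueError("empty evaluation sample")
    if len(pi.lower) != 1:
        raise ValueError("conditional coverage needs the single interval "
                         "belonging to the fixed test point")
    covered = (pi.lower[0] <= y) & (y <= pi.upper[0])
    return CoverageReport(
        estimate=float(np.mean(covered)), n_eval=y.size, mode="conditional",
        nominal_level=pi.nominal_level,
        test_point=None if test_point is None
        else np.asarray(test_point, dtype=float))


def coverage_rows(reports, point_ids=None):
    """Coverage reports as tidy rows (for CSV emission)."""
    rows = []
    for i, rep in enumerate(reports):
        row = rep.to_row()
        row["test_point"] = (point_ids[i] if point_ids is not None else i)
        rows.append(row)
    return rows
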
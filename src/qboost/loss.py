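"""Check (pinball) loss and its functional gradient.

The check loss ``rho_tau(y, eta) = tau*(y-eta)`` for ``y > eta`` and
``(1-tau)*(eta-y)`` otherwise is the canonical loss for quantile
regression: the population minimizer of its expectation over constant
predictors is the tau-quantile of ``y``.  Boosting descends the empirical
risk (the mean check loss) by repeatedly fitting base-learners to the
negative gradient of the loss with respect to the predictor.
"""

from __future__ import annotations

import numpy as np


def _validate_tau(tau: float) -> float:
    tau = float(tau)
    if not (0.0 < tau < 1.0):
        raise ValueError(f"tau must lie in the open interval (0, 1), got {tau}")
    return tau


def check_loss(y, eta, tau: float):
    """Evaluate the check (pinball) loss elementwise.

    Parameters
    ----------
    y : array_like
        Observed responses.
    eta : array_like
        Predictor values (fitted conditional quantiles).
    tau : float
        Quantile level in (0, 1).

    Returns
    -------
    ndarray or float
        ``tau*(y-eta)`` where ``y > eta``, else ``(1-tau)*(eta-y)``.
    """
    tau = _validate_tau(tau)
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(eta))):
        raise ValueError("check_loss requires finite y and eta")
    r = y - eta
    out = np.where(r > 0, tau * r, (tau - 1.0) * r)
    if out.ndim == 0:
        return float(out)
    return out


def empirical_risk(y, eta, tau: float) -> float:
    """Mean check loss over a sample — the boosting objective."""
    return float(np.mean(check_loss(y, eta, tau)))


def negative_gradient(y, eta, tau: float):
    """Negative gradient of the check loss with respect to eta.

    Equals ``tau`` where ``y > eta`` and ``tau - 1`` where ``y <= eta``
    (the subgradient convention at ties assigns ``tau - 1``).
    """
    tau = _validate_tau(tau)
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if y.shape != eta.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs eta {eta.shape}")
    return np.where(y > eta, tau, tau - 1.0)
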
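"""Synthetic longitudinal birth-cohort generator with known truth.

Emulates the schema and the statistical signatures of a German birth
cohort used for childhood-BMI prediction: per child a set of early-life
covariates observed by age two (own BMI at birth and at two, maternal
BMI and pregnancy BMI gain, sex, area, breastfeeding, maternal smoking
and education) and up to three later BMI responses around the ages of
four, six and ten.  The generator is a documented construction of this
package — the real cohort is not public and no generative model for it is
published — but it reproduces the features the methodology needs to be
exercised against:

* a BMI distribution whose right skew sets in after about age six,
* response scale (hence prediction-interval length) increasing with age,
* within-child correlation through random intercepts and age slopes,
* a sparse ground truth (several covariates with exactly zero effect).

The response follows a location-scale two-piece (split) normal
distribution, so the true conditional quantile function is available
exactly: in closed form given the child's random effects, and by
Gauss-Hermite quadrature for a *new* child (random effects integrated
out).  That truth oracle is what makes conditional-coverage validation
possible at all on cohort-like data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = ["CohortConfig", "LongitudinalCohort", "generate_cohort"]

CHILD_COLUMNS = ["child_id", "cBMI0", "cBMI2", "mBMI", "mDiffBMI", "cSex",
                 "cArea", "cBreast", "mSmoke", "mEdu"]


# ---------------------------------------------------------------------------
# two-piece (split) normal error family: mode 0, left scale sL, right scale sR
# ---------------------------------------------------------------------------

def _tp_cdf(x, sL, sR):
    x = np.asarray(x, dtype=float)
    w = sL + sR
    left = 2.0 * sL / w * norm.cdf(x / sL)
    right = sL / w + 2.0 * sR / w * (norm.cdf(x / sR) - 0.5)
    return np.where(x < 0, left, right)


def _tp_quantile(tau, sL, sR):
    w = sL + sR
    p0 = sL / w
    if tau <= p0:
        return sL * norm.ppf(tau * w / (2.0 * sL))
    return sR * norm.ppf((tau * w - sL) / (2.0 * sR) + 0.5)


def _tp_rvs(sL, sR, size, rng):
    pick_left = rng.uniform(size=size) < sL / (sL + sR)
    mag = np.abs(rng.standard_normal(size))
    return np.where(pick_left, -sL * mag, sR * mag)


@dataclass
class CohortConfig:
    """Generator parameters (BMI units are kg/m^2, ages in years).

    The location is additive: a quadratic growth curve in age (dip and
    rebound around age six), a mildly non-linear effect of the BMI at age
    two, a linear maternal-BMI effect and small education effects.  Sex,
    area, breastfeeding, birth BMI and maternal BMI gain carry *zero*
    true effect, giving the variable-selection machinery something to
    reject.  Maternal smoking scales the response spread (wider intervals
    for smokers) rather than shifting its center.
    """

    # visit schedule
    nominal_ages: tuple = (4.0, 6.0, 10.0)
    age_jitter: float = 0.5
    visit_prob: float = 0.9
    # location model
    loc_intercept: float = 15.2
    loc_age_lin: float = -0.55
    loc_age_quad: float = 0.066
    bmi2_center: float = 16.3
    bmi2_lin: float = 0.7
    bmi2_quad: float = 0.04
    mbmi_effect: float = 0.05
    medu_effects: tuple = (0.2, 0.1, 0.0, -0.1)   # levels 1..4
    # scale model
    scale_base: float = 0.8
    scale_age: float = 0.11
    smoke_scale: float = 0.15
    # skewness: right-skew ramping up after skew_onset_age
    skew_max: float = 0.6
    skew_onset_age: float = 6.0
    skew_ramp_years: float = 4.0
    # random effects
    sd_intercept: float = 0.8
    sd_slope: float = 0.12
    # covariate marginals
    mbmi_mean: float = 23.0
    mbmi_sd: float = 3.5
    mdiff_mean: float = 4.5
    mdiff_sd: float = 1.5
    cbmi0_mean: float = 13.5
    cbmi0_sd: float = 1.2
    cbmi2_noise_sd: float = 1.0
    p_male: float = 0.5
    p_urban: float = 0.6
    p_breast: float = 0.55
    p_smoke: float = 0.18
    p_medu: tuple = (0.15, 0.30, 0.35, 0.20)

    def __post_init__(self):
        if not (0.0 <= self.skew_max < 1.0):
            raise ValueError("skew_max must lie in [0, 1)")
        if self.scale_base <= 0 or self.scale_age < 0:
            raise ValueError("scale parameters must keep sigma positive")
        if not np.isclose(sum(self.p_medu), 1.0):
            raise ValueError("p_medu must sum to 1")
        if not (0.0 < self.visit_prob <= 1.0):
            raise ValueError("visit_prob must lie in (0, 1]")

    # -- truth components -------------------------------------------------

    def location(self, covs, age):
        """Fixed-effect location (no random effects) at the given age."""
        a = np.asarray(age, dtype=float) - 2.0
        medu = np.asarray(covs["mEdu"], dtype=int)
        b2 = np.asarray(covs["cBMI2"], dtype=float) - self.bmi2_center
        return (self.loc_intercept + self.loc_age_lin * a
                + self.loc_age_quad * a ** 2
                + self.bmi2_lin * b2 + self.bmi2_quad * b2 ** 2
                + self.mbmi_effect * (np.asarray(covs["mBMI"], dtype=float)
                                      - self.mbmi_mean)
                + np.asarray(self.medu_effects)[medu - 1])

    def scale(self, covs, age):
        a = np.asarray(age, dtype=float) - 2.0
        smoke = np.asarray(covs["mSmoke"]) == "yes"
        return (self.scale_base + self.scale_age * a) \
            * (1.0 + self.smoke_scale * smoke)

    def skew(self, age):
        a = np.asarray(age, dtype=float)
        ramp = np.clip((a - self.skew_onset_age) / self.skew_ramp_years,
                       0.0, 1.0)
        return self.skew_max * ramp

    def re_sd(self, age):
        """SD of the combined random-effect contribution at a given age."""
        a = np.asarray(age, dtype=float) - 2.0
        return np.sqrt(self.sd_intercept ** 2 + (self.sd_slope * a) ** 2)


@dataclass
class LongitudinalCohort:
    """Synthetic cohort: children, repeated measurements, and exact truth."""

    children: pd.DataFrame
    measurements: pd.DataFrame
    truth: pd.DataFrame          # per measurement: mu, sigma, gamma, b...
    config: CohortConfig
    seed: Optional[int] = None

    @property
    def n_children(self) -> int:
        return len(self.children)

    def table(self) -> pd.DataFrame:
        """Measurements joined with child covariates (analysis layout)."""
        return self.measurements.merge(self.children, on="child_id",
                                       validate="many_to_one")

    def cross_sectional(self, nominal_age: float = 4.0) -> pd.DataFrame:
        """One row per child: covariates plus the response at one visit."""
        mask = self.measurements["nominal_age"] == nominal_age
        sub = self.measurements.loc[mask, ["child_id", "cAge", "cBMI"]]
        return sub.merge(self.children, on="child_id", validate="one_to_one")

    # -- truth oracle -----------------------------------------------------

    def truth_quantile(self, covs, age, tau, random_effects="marginal",
                       b_intercept=0.0, b_slope=0.0) -> float:
        """Exact conditional quantile of the generating distribution.

        ``random_effects='marginal'`` integrates the child-specific
        intercept and slope out (the distribution of a *new* child with
        these covariates); ``'conditional'`` conditions on the supplied
        random-effect values.
        """
        if not (0.0 < tau < 1.0):
            raise ValueError("tau must lie in (0, 1)")
        cfg = self.config
        mu = float(cfg.location(covs, age))
        sigma = float(cfg.scale(covs, age))
        gamma = float(cfg.skew(age))
        sL, sR = sigma, sigma * (1.0 + gamma)
        if random_effects == "conditional":
            mu = mu + float(b_intercept) + float(b_slope) * (float(age) - 2.0)
            return mu + _tp_quantile(tau, sL, sR)
        if random_effects != "marginal":
            raise ValueError("random_effects must be 'marginal' or "
                             "'conditional'")
        s = float(cfg.re_sd(age))
        if gamma == 0.0:
            return mu + np.sqrt(sigma ** 2 + s ** 2) * norm.ppf(tau)
        # Gauss-Hermite quadrature over the random-effect contribution
        g, w = np.polynomial.hermite.hermgauss(64)
        shift = np.sqrt(2.0) * s * g

        def cdf(yv):
            return float(np.sum(w * _tp_cdf(yv - mu - shift, sL, sR))
                         / np.sqrt(np.pi))

        span = 12.0 * (sigma + s) + 1.0
        return brentq(lambda yv: cdf(yv) - tau, mu - span, mu + span,
                      xtol=1e-10)

    def sample_response(self, covs, age, size, rng,
                        random_effects="marginal") -> np.ndarray:
        """Fresh responses at fixed covariates/age (new children)."""
        cfg = self.config
        mu = float(cfg.location(covs, age))
        sigma = float(cfg.scale(covs, age))
        gamma = float(cfg.skew(age))
        out = mu + _tp_rvs(sigma, sigma * (1.0 + gamma), size, rng)
        if random_effects == "marginal":
            out = out + cfg.sd_intercept * rng.standard_normal(size) \
                + cfg.sd_slope * rng.standard_normal(size) \
                * (float(age) - 2.0)
        return out

    # -- persistence ------------------------------------------------------

    def save(self, children_path, measurements_path, truth_path) -> None:
        self.children.to_csv(children_path, index=False)
        self.measurements.to_csv(measurements_path, index=False)
        with open(truth_path, "w") as fh:
            json.dump({"config": asdict(self.config), "seed": self.seed,
                       "truth": self.truth.to_dict(orient="list")}, fh)


def generate_cohort(n_children: int, seed=None,
                    config: Optional[CohortConfig] = None
                    ) -> LongitudinalCohort:
    """Simulate a cohort of ``n_children`` with full ground truth."""
    if n_children < 1:
        raise ValueError("n_children must be at least 1")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    n = n_children

    mBMI = np.clip(rng.normal(cfg.mbmi_mean, cfg.mbmi_sd, n), 16.0, 45.0)
    mDiff = np.clip(rng.normal(cfg.mdiff_mean, cfg.mdiff_sd, n), 0.0, 12.0)
    cBMI0 = np.clip(rng.normal(cfg.cbmi0_mean, cfg.cbmi0_sd, n), 9.0, 20.0)
    cBMI2 = np.clip(12.0 + 0.25 * cBMI0 + 0.09 * (mBMI - cfg.mbmi_mean)
                    + rng.normal(0.0, cfg.cbmi2_noise_sd, n), 11.0, 24.0)
    cSex = np.where(rng.uniform(size=n) < cfg.p_male, "male", "female")
    cArea = np.where(rng.uniform(size=n) < cfg.p_urban, "urban", "rural")
    cBreast = np.where(rng.uniform(size=n) < cfg.p_breast, "yes", "no")
    mSmoke = np.where(rng.uniform(size=n) < cfg.p_smoke, "yes", "no")
    mEdu = rng.choice([1, 2, 3, 4], size=n, p=list(cfg.p_medu))

    children = pd.DataFrame({
        "child_id": [f"c{i:06d}" for i in range(n)],
        "cBMI0": cBMI0, "cBMI2": cBMI2, "mBMI": mBMI, "mDiffBMI": mDiff,
        "cSex": cSex, "cArea": cArea, "cBreast": cBreast, "mSmoke": mSmoke,
        "mEdu": mEdu,
    })

    b1 = cfg.sd_intercept * rng.standard_normal(n)
    b2 = cfg.sd_slope * rng.standard_normal(n)

    n_visits = len(cfg.nominal_ages)
    attend = rng.uniform(size=(n, n_visits)) < cfg.visit_prob
    none = ~attend.any(axis=1)
    if none.any():  # every child keeps at least one visit
        forced = rng.integers(0, n_visits, size=int(none.sum()))
        attend[np.flatnonzero(none), forced] = True
    ages = (np.asarray(cfg.nominal_ages)[None, :]
            + rng.uniform(-cfg.age_jitter, cfg.age_jitter,
                          size=(n, n_visits)))

    rows = []
    truth_rows = []
    mid = 0
    for v, nominal in enumerate(cfg.nominal_ages):
        present = np.flatnonzero(attend[:, v])
        a = ages[present, v]
        covs = children.iloc[present]
        mu_fix = cfg.location(covs, a)
        sigma = cfg.scale(covs, a)
        gamma = cfg.skew(a)
        eps = np.empty(len(present))
        pick_left = rng.uniform(size=len(present)) < 1.0 / (2.0 + gamma)
        mag = np.abs(rng.standard_normal(len(present)))
        eps = np.where(pick_left, -sigma * mag, sigma * (1.0 + gamma) * mag)
        y = mu_fix + b1[present] + b2[present] * (a - 2.0) + eps
        for k, i in enumerate(present):
            rows.append((f"m{mid:07d}", children.at[i, "child_id"],
                         float(a[k]), nominal, float(y[k])))
            truth_rows.append((f"m{mid:07d}", float(mu_fix[k]),
                               float(sigma[k]), float(gamma[k]),
                               float(b1[i]), float(b2[i])))
            mid += 1

    measurements = pd.DataFrame(
        rows, columns=["measurement_id", "child_id", "cAge", "nominal_age",
                       "cBMI"]).sort_values(
        ["child_id", "cAge"]).reset_index(drop=True)
    truth = pd.DataFrame(
        truth_rows, columns=["measurement_id", "mu_fixed", "sigma", "gamma",
                             "b_intercept", "b_slope"])
    truth = truth.set_index("measurement_id").loc[
        measurements["measurement_id"]].reset_index()
    return LongitudinalCohort(children=children, measurements=measurements,
                              truth=truth, config=cfg, seed=seed)
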
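"""Synthetic cohort data emulating a health-claims observation window.

Generates per-subject doubly censored incidence records with the
structure of a claims-data study: birth cohorts 1900-1954, an observation
window opening 1/1/2004 and closing end-2012, prevalent (left-censored)
cases among subjects already diseased at entry, and right-censoring by
end of study or loss to follow-up.  Latent onset ages are drawn from the
Gompertz proportional-hazards model by quantile inversion, so the
generator is exactly the model the estimator assumes -- which is what
makes it usable as a recovery oracle.

Default parameter values give aggregate censoring shares of roughly
4-5% left-censored, 10-15% uncensored and 80-85% right-censored under
the default cohort mix, i.e. the regime of a large morbidity register;
mortality is deliberately absent here (death-driven selection is the
job of :mod:`gompcens.illness_death`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gompertz import GompertzPHParams, _gt, _BETA1_TINY
from .censoring import (
    DoubleCensoredDataset,
    classify_observation,
    cohort_dummies_from_birth_year,
    HCD_COLUMNS,
)

__all__ = ["SyntheticConfig", "generate_dataset", "discretize_times", "expected_censoring_shares"]

_COHORTS = ((1900, 1909), (1910, 1919), (1920, 1929), (1930, 1939), (1940, 1949), (1950, 1954))

# double-censoring point estimates of the motivating dementia study act as
# the default truth: a = 0.190e-3/yr at age 50, 18.3%/yr age slope
_DEFAULT_THETA = GompertzPHParams(
    float(np.log(0.190e-3)), 0.183, (-2.095, -1.177, -0.441, 0.525, 1.342), -0.039
)
# later cohorts dominate a 2004 cross-section of persons born 1900-1954
_DEFAULT_WEIGHTS = (0.01, 0.03, 0.08, 0.22, 0.36, 0.30)


@dataclass(frozen=True)
class SyntheticConfig:
    n: int = 10_000
    theta: GompertzPHParams = _DEFAULT_THETA
    birth_year_range: tuple = (1900, 1954)
    cohort_weights: tuple = _DEFAULT_WEIGHTS
    sex_prob: float = 0.5
    study_start: float = 2004.0
    study_end: float = 2013.0
    loss_to_followup_rate: float = 0.0
    discretize: str = "none"
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        w = np.asarray(self.cohort_weights, float)
        if w.shape != (6,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("cohort_weights must be 6 nonnegative values summing to 1")
        lo, hi = self.birth_year_range
        if not (1900 <= lo <= hi <= 1954):
            raise ValueError("birth_year_range must lie within 1900..1954")
        if not self.study_start < self.study_end:
            raise ValueError("study_start must precede study_end")
        if self.loss_to_followup_rate < 0:
            raise ValueError("loss_to_followup_rate must be >= 0")
        if self.discretize not in ("none", "monthly", "quarterly"):
            raise ValueError("discretize must be none, monthly or quarterly")


def _quantile_lp(theta: GompertzPHParams, u, lp):
    """Vectorized quantile inversion with a per-subject linear predictor."""
    target = -np.log1p(-u) / np.exp(theta.log_a + lp)
    if abs(theta.beta1) < _BETA1_TINY:
        return target
    return np.log1p(theta.beta1 * target) / theta.beta1


def generate_dataset(cfg: SyntheticConfig):
    """Draw a doubly censored dataset plus its latent truth table.

    Returns ``(dataset, truth)`` where ``truth`` is a DataFrame with the
    latent per-subject quantities (birth_time, birth_year, sex, y_star,
    l, r) retained for oracle tests.  Fully reproducible under
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.birth_year_range
    w = np.asarray(cfg.cohort_weights, float).copy()
    for j, (clo, chi) in enumerate(_COHORTS):
        if chi < lo or clo > hi:
            w[j] = 0.0
    if w.sum() == 0:
        raise ValueError("birth_year_range excludes every cohort with positive weight")
    w /= w.sum()

    cohort = rng.choice(6, size=cfg.n, p=w)
    year_lo = np.array([max(c[0], lo) for c in _COHORTS])
    year_hi = np.array([min(c[1], hi) for c in _COHORTS])
    birth_year = rng.integers(year_lo[cohort], year_hi[cohort] + 1)
    birth_time = birth_year + rng.uniform(0.0, 1.0, cfg.n)
    sex = (rng.uniform(size=cfg.n) < cfg.sex_prob).astype(int)

    Z = np.column_stack([cohort_dummies_from_birth_year(birth_year), sex.astype(float)])
    coef = np.array([*cfg.theta.beta2, cfg.theta.beta3])
    lp = Z @ coef
    y_star = _quantile_lp(cfg.theta, rng.uniform(size=cfg.n), lp)

    onset50 = birth_time + 50.0
    l = np.maximum(0.0, cfg.study_start - onset50)
    r = cfg.study_end - onset50
    if cfg.loss_to_followup_rate > 0:
        entry = np.maximum(cfg.study_start, onset50)
        loss = entry + rng.exponential(1.0 / cfg.loss_to_followup_rate, cfg.n)
        r = np.minimum(r, loss - onset50)
    y, delta = classify_observation(y_star, l, r)

    dataset = DoubleCensoredDataset(y, delta, Z, HCD_COLUMNS)
    truth = pd.DataFrame(
        {
            "birth_time": birth_time,
            "birth_year": birth_year,
            "sex": sex,
            "y_star": y_star,
            "l": l,
            "r": r,
        }
    )
    if cfg.discretize != "none":
        dataset = discretize_times(dataset, cfg.discretize, truth, cfg.study_start)
    return dataset, truth


def discretize_times(
    dataset: DoubleCensoredDataset,
    mode: str,
    truth: pd.DataFrame | None = None,
    study_start: float = 2004.0,
) -> DoubleCensoredDataset:
    """Snap continuous durations onto a claims-style reporting grid.

    ``monthly``: uncensored and right-censored durations to mid-month
    (1/12-year grid, offset 1/24).  ``quarterly``: diagnoses to
    mid-quarter, right-censoring times (loss/death/end) to the end of the
    quarter.  In either mode, if ``truth`` is supplied, an uncensored
    diagnosis whose calendar date falls in the first two quarters of the
    study start year is reclassified as prevalent: delta = -1 with y = l
    (a diagnosis that early is taken as pre-existing disease).
    ``none`` returns the dataset unchanged.
    """
    if mode == "none":
        return dataset
    if mode not in ("monthly", "quarterly"):
        raise ValueError("mode must be none, monthly or quarterly")
    y = dataset.y.copy()
    delta = dataset.delta.copy()
    unc = delta == 0
    rc = delta == 1
    if mode == "monthly":
        y[unc | rc] = np.floor(y[unc | rc] * 12.0) / 12.0 + 1.0 / 24.0
    else:
        y[unc] = np.floor(y[unc] * 4.0) / 4.0 + 0.125
        y[rc] = np.ceil(y[rc] * 4.0) / 4.0
    if truth is not None:
        diag_cal = truth["birth_time"].to_numpy() + 50.0 + y
        prevalent = unc & (diag_cal < study_start + 0.5)
        y[prevalent] = truth["l"].to_numpy()[prevalent]
        delta[prevalent] = -1
    return DoubleCensoredDataset(y, delta, dataset.Z, dataset.colnames)


def expected_censoring_shares(cfg: SyntheticConfig, points_per_year: int = 16):
    """Analytic (P_left, P_uncensored, P_right) under the generator.

    Averages F(l) and F(r) - F(l) of the latent onset distribution over
    the exact birth-year/cohort/sex mixture, integrating the uniform
    birth fraction on a midpoint grid.  Serves as the oracle for the
    empirical censoring shares (assumes no loss to follow-up).
    """
    lo, hi = cfg.birth_year_range
    w = np.asarray(cfg.cohort_weights, float).copy()
    for j, (clo, chi) in enumerate(_COHORTS):
        if chi < lo or clo > hi:
            w[j] = 0.0
    w /= w.sum()
    frac = (np.arange(points_per_year) + 0.5) / points_per_year
    coef = np.array([*cfg.theta.beta2, cfg.theta.beta3])
    p_left = p_unc = 0.0
    for j, (clo, chi) in enumerate(_COHORTS):
        ylo, yhi = max(clo, lo), min(chi, hi)
        if w[j] == 0.0:
            continue
        years = np.arange(ylo, yhi + 1)
        for sex, psex in ((0, 1 - cfg.sex_prob), (1, cfg.sex_prob)):
            for year in years:
                zz = np.append(cohort_dummies_from_birth_year(int(year)), float(sex))
                lp = float(zz @ coef)
                onset50 = year + frac + 50.0
                l = np.maximum(0.0, cfg.study_start - onset50)
                r = cfg.study_end - onset50
                scale = np.exp(cfg.theta.log_a + lp)
                Fl = -np.expm1(-scale * _gt(cfg.theta.beta1, l))
                Fr = -np.expm1(-scale * _gt(cfg.theta.beta1, r))
                wgt = w[j] * psex / len(years)
                p_left += wgt * Fl.mean()
                p_unc += wgt * (Fr - Fl).mean()
    return p_left, p_unc, 1.0 - p_left - p_unc
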
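"""Healthy-ill-dead Markov simulation of truncation and censoring.

A three-state continuous-time Markov process per individual: from
Healthy, illness onset occurs at rate ``a_HI`` (optionally multiplied by
exp(beta) for the late birth cohort) competing with death at rate
``c_HD``; once Ill, death follows at rate ``b_ID``.  The 50th birthday
(risk onset) is uniform on a calendar window, so cohorts age into an
observation period that opens at a fixed truncation year.

Individuals dead before the truncation year never enter the sample
(left-truncation).  Survivors contribute one record each: already ill at
the truncation year -> left-censored at the entry age; onset during the
collection period -> uncensored; otherwise right-censored at death or
end of collection.  Fitting the constant illness hazard to those records
-- with or without the left-censored ones -- is the experiment that
quantifies how much discarding prevalent cases biases incidence
estimation when truncation is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .censoring import DoubleCensoredDataset

__all__ = [
    "MarkovConfig",
    "IndividualPath",
    "IndividualPaths",
    "StudyOutcomes",
    "simulate_paths",
    "apply_truncation_and_censoring",
    "to_estimation_dataset",
    "truncation_probability",
]

STATUS_TRUNCATED = 0
STATUS_LEFT_CENSORED = 1
STATUS_UNCENSORED = 2
STATUS_RIGHT_CENSORED = 3
STATUS_LABELS = ("truncated", "left_censored", "uncensored", "right_censored")


@dataclass(frozen=True)
class MarkovConfig:
    """Rates per year; defaults follow the homogeneous benchmark scenario."""

    N: int = 1000
    a_HI: float = 1.0 / 35.0
    b_ID: float = 1.0 / 45.0
    c_HD: float = 1.0 / 45.0
    beta_cohort: float | None = None  # 0.7 in the cohort-effect scenario
    cohort_split_year: float = 1978.0
    birth_window: tuple = (1950.0, 2004.0)
    truncation_year: float = 2004.0
    end_of_collection: float = 2014.0
    seed: int = 0

    def __post_init__(self):
        if min(self.a_HI, self.b_ID, self.c_HD) < 0:
            raise ValueError("rates must be >= 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not self.birth_window[0] < self.birth_window[1]:
            raise ValueError("birth_window must be increasing")
        if self.truncation_year >= self.end_of_collection:
            raise ValueError("truncation_year must precede end_of_collection")


@dataclass(frozen=True)
class IndividualPath:
    """One latent trajectory: calendar 50th birthday, cohort flag, event ages."""

    onset50: float
    z: int
    illness_time: float | None  # years since 50; None if death strikes first
    death_time: float


class IndividualPaths:
    """Vectorized collection of latent trajectories."""

    def __init__(self, onset50, z, illness_time, death_time):
        self.onset50 = np.asarray(onset50, float)
        self.z = np.asarray(z, int)
        self.illness_time = np.asarray(illness_time, float)  # nan = never ill
        self.death_time = np.asarray(death_time, float)

    def __len__(self):
        return self.onset50.shape[0]

    def __getitem__(self, i) -> IndividualPath:
        it = self.illness_time[i]
        return IndividualPath(
            float(self.onset50[i]), int(self.z[i]),
            None if np.isnan(it) else float(it), float(self.death_time[i]),
        )


class StudyOutcomes:
    """Per-individual study status plus the observable (y, delta, z) triples."""

    def __init__(self, status, y, delta, z):
        self.status = np.asarray(status, int)
        self.y = np.asarray(y, float)      # nan where truncated
        self.delta = np.asarray(delta, int)
        self.z = np.asarray(z, int)

    def __len__(self):
        return self.status.shape[0]

    @property
    def n_truncated(self) -> int:
        return int((self.status == STATUS_TRUNCATED).sum())

    @property
    def n_left_censored(self) -> int:
        return int((self.status == STATUS_LEFT_CENSORED).sum())

    @property
    def n_sampled(self) -> int:
        return len(self) - self.n_truncated


def simulate_paths(cfg: MarkovConfig, rng: np.random.Generator | None = None) -> IndividualPaths:
    """Draw latent healthy-ill-dead trajectories.

    Exponential sojourns with multinomial target states: the Healthy
    sojourn has rate a*e^{beta z} + c and exits to Ill with probability
    a*e^{beta z} / (a*e^{beta z} + c); from Ill, death follows after an
    independent exponential with rate b.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.N
    onset50 = rng.uniform(*cfg.birth_window, size=n)
    if cfg.beta_cohort is None:
        z = np.zeros(n, int)
        rate_i = np.full(n, cfg.a_HI)
    else:
        z = (onset50 >= cfg.cohort_split_year).astype(int)
        rate_i = cfg.a_HI * np.exp(cfg.beta_cohort * z)
    exit_rate = rate_i + cfg.c_HD
    if np.any(exit_rate == 0):
        raise ValueError("a_HI and c_HD are both zero: infinite sojourn in Healthy")
    sojourn = rng.exponential(1.0, n) / exit_rate
    to_ill = rng.uniform(size=n) < rate_i / exit_rate
    illness_time = np.where(to_ill, sojourn, np.nan)
    if cfg.b_ID > 0:
        residual = rng.exponential(1.0 / cfg.b_ID, n)
    else:
        residual = np.full(n, np.inf)
    death_time = np.where(to_ill, sojourn + residual, sojourn)
    # for never-ill individuals the sojourn ends in death only if c_HD > 0
    if cfg.c_HD == 0:
        death_time = np.where(to_ill, death_time, np.inf)
    return IndividualPaths(onset50, z, illness_time, death_time)


def apply_truncation_and_censoring(paths: IndividualPaths, cfg: MarkovConfig) -> StudyOutcomes:
    """Select survivors of the truncation year and classify their records.

    Death strictly before ``truncation_year`` -> truncated (never
    sampled).  Among survivors: illness onset before the truncation year
    -> left-censored at y = truncation_year - onset50; onset during
    [truncation_year, min(death, end_of_collection)) -> uncensored at the
    onset age; otherwise right-censored at min(death, end) - onset50.
    """
    death_cal = paths.onset50 + paths.death_time
    ill_cal = paths.onset50 + paths.illness_time  # nan propagates
    truncated = death_cal < cfg.truncation_year

    ill = ~np.isnan(paths.illness_time)
    exit_cal = np.minimum(death_cal, cfg.end_of_collection)
    lc = ~truncated & ill & (ill_cal < cfg.truncation_year)
    unc = ~truncated & ill & (ill_cal >= cfg.truncation_year) & (ill_cal < cfg.end_of_collection)
    rc = ~truncated & ~lc & ~unc

    status = np.full(len(paths), STATUS_TRUNCATED)
    y = np.full(len(paths), np.nan)
    delta = np.zeros(len(paths), int)
    status[lc] = STATUS_LEFT_CENSORED
    y[lc] = cfg.truncation_year - paths.onset50[lc]
    delta[lc] = -1
    status[unc] = STATUS_UNCENSORED
    y[unc] = paths.illness_time[unc]
    delta[unc] = 0
    status[rc] = STATUS_RIGHT_CENSORED
    y[rc] = exit_cal[rc] - paths.onset50[rc]
    delta[rc] = 1
    return StudyOutcomes(status, y, delta, paths.z)


def to_estimation_dataset(outcomes: StudyOutcomes, mode: str = "consider_lc") -> DoubleCensoredDataset:
    """Observable records for fitting; optionally discard prevalent cases.

    ``consider_lc`` keeps every non-truncated record; ``ignore_lc`` drops
    the left-censored ones entirely (the deselection practice whose bias
    the simulation study measures).
    """
    if mode not in ("consider_lc", "ignore_lc"):
        raise ValueError("mode must be 'consider_lc' or 'ignore_lc'")
    keep = outcomes.status != STATUS_TRUNCATED
    if mode == "ignore_lc":
        keep &= outcomes.status != STATUS_LEFT_CENSORED
    if not keep.any():
        raise ValueError("no records remain after truncation/deselection")
    Z = outcomes.z[keep].astype(float)[:, None]
    return DoubleCensoredDataset(outcomes.y[keep], outcomes.delta[keep], Z, ("cohort_late",))


def _death_cdf(tau, rate_i, b, c):
    """P(death <= tau) for one individual: two-phase exponential algebra.

    Healthy exits at rate r = rate_i + c (to Ill w.p. rate_i/r, to Dead
    w.p. c/r); from Ill, death at rate b.  Closed form with a careful
    branch at b = r.
    """
    r = rate_i + c
    tau = np.asarray(tau, float)
    direct = c / r * -np.expm1(-r * tau)
    if b <= 0:
        via_ill = 0.0
    elif abs(b - r) < 1e-12:
        via_ill = rate_i / r * (-np.expm1(-r * tau)) - rate_i * tau * np.exp(-r * tau)
    else:
        via_ill = rate_i / r * (-np.expm1(-r * tau)) - rate_i * np.exp(-b * tau) * (
            -np.expm1(-(r - b) * tau)
        ) / (r - b)
    return direct + via_ill


def truncation_probability(cfg: MarkovConfig) -> float:
    """P(death before the truncation year), averaged over the birth window.

    Numerical integration of the closed-form two-phase death CDF over the
    uniform distribution of the 50th birthday; the oracle for E(n_LT)/N.
    """
    from scipy.integrate import quad

    lo, hi = cfg.birth_window

    def integrand(u):
        tau = cfg.truncation_year - u
        if tau <= 0:
            return 0.0
        if cfg.beta_cohort is None:
            rate_i = cfg.a_HI
        else:
            rate_i = cfg.a_HI * np.exp(cfg.beta_cohort * (u >= cfg.cohort_split_year))
        return float(_death_cdf(tau, rate_i, cfg.b_ID, cfg.c_HD))

    val, _ = quad(integrand, lo, hi, limit=200)
    return val / (hi - lo)
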
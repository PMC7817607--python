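"""Gompertz proportional-hazards model for age-at-disease-incidence.

The duration of interest is the time ``t`` (in years) between a person's
50th birthday -- the onset of disease risk -- and disease incidence.  Its
hazard, conditional on covariates ``z``, is

    a(t | z) = a * exp(b1 * t) * exp(beta2' z_cohort) * exp(beta3 * z_sex),

i.e. a Gompertz baseline ``a * exp(b1 * t)`` with multiplicative
(proportional-hazards) effects of birth cohort and sex.  ``a > 0`` is the
baseline hazard at age 50 for the reference group and ``b1 >= 0`` the
exponential age slope; ``b1 = 0`` recovers the exponential (constant
hazard) model, which this module treats as the continuous limit rather
than a special case that errors out.

All functions accept scalars or numpy arrays for the time argument and
are numerically careful for both tiny and huge cumulative hazards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GompertzPHParams",
    "CovariateVector",
    "hazard",
    "cum_hazard",
    "density",
    "cdf",
    "quantile",
    "interval_incidence_rate",
    "log_lr_exponential",
    "wald_dominance_bound",
]

# below this, the exponential-limit branch of the cumulative hazard is used
_BETA1_TINY = 1e-8


@dataclass(frozen=True)
class GompertzPHParams:
    """The eight-parameter vector theta = (log a, b1, beta2 (5,), beta3).

    ``log_a`` is the log baseline hazard at t=0 (age 50), ``beta1`` the age
    slope per year (must be >= 0), ``beta2`` the five cohort effects
    relative to the 1930s reference decade, and ``beta3`` the sex effect
    (female vs male).
    """

    log_a: float
    beta1: float = 0.0
    beta2: tuple = field(default=(0.0, 0.0, 0.0, 0.0, 0.0))
    beta3: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.log_a):
            raise ValueError("log_a must be finite")
        if self.beta1 < 0:
            raise ValueError("beta1 must be >= 0 (beta1=0 is the exponential model)")
        b2 = tuple(float(b) for b in np.atleast_1d(self.beta2))
        if len(b2) != 5:
            raise ValueError("beta2 must have length 5")
        object.__setattr__(self, "beta2", b2)

    @property
    def a(self) -> float:
        return float(np.exp(self.log_a))

    def to_vector(self) -> np.ndarray:
        return np.array([self.log_a, self.beta1, *self.beta2, self.beta3], float)

    @classmethod
    def from_vector(cls, theta) -> "GompertzPHParams":
        theta = np.asarray(theta, float)
        if theta.shape != (8,):
            raise ValueError("theta must be an 8-vector")
        return cls(theta[0], theta[1], tuple(theta[2:7]), theta[7])


@dataclass(frozen=True)
class CovariateVector:
    """Cohort dummies (z1..z5, at most one equal to 1) and sex (0=male, 1=female).

    All-zero cohort dummies encode the 1930s reference cohort.
    """

    cohort_dummies: tuple = field(default=(0, 0, 0, 0, 0))
    sex: int = 0

    def __post_init__(self):
        cd = tuple(int(c) for c in np.atleast_1d(self.cohort_dummies))
        if len(cd) != 5 or any(c not in (0, 1) for c in cd):
            raise ValueError("cohort_dummies must be five 0/1 indicators")
        if sum(cd) > 1:
            raise ValueError("at most one cohort dummy may be set")
        if self.sex not in (0, 1):
            raise ValueError("sex must be 0 (male) or 1 (female)")
        object.__setattr__(self, "cohort_dummies", cd)

    def linear_predictor(self, params: GompertzPHParams) -> float:
        return float(np.dot(params.beta2, self.cohort_dummies) + params.beta3 * self.sex)


_REF = CovariateVector()


def _check_t(t):
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (years since the 50th birthday)")
    return t


def _gt(beta1, t):
    """(exp(b1*t) - 1)/b1, continuous at b1 = 0 where it equals t."""
    if abs(beta1) < _BETA1_TINY:
        return np.asarray(t, float)
    with np.errstate(over="ignore"):  # inf at extreme ages is the right answer
        return np.expm1(beta1 * t) / beta1


def hazard(params: GompertzPHParams, t, z: CovariateVector = _REF):
    """Conditional hazard a * exp(b1 t + beta2'z + beta3 z_sex), per year."""
    t = _check_t(t)
    lp = z.linear_predictor(params)
    return np.exp(params.log_a + params.beta1 * t + lp)


def cum_hazard(params: GompertzPHParams, t, z: CovariateVector = _REF):
    """Integrated hazard A(t|z) = (a/b1) e^{lp} (e^{b1 t} - 1); a t e^{lp} at b1=0."""
    t = _check_t(t)
    lp = z.linear_predictor(params)
    return np.exp(params.log_a + lp) * _gt(params.beta1, t)


def density(params: GompertzPHParams, t, z: CovariateVector = _REF):
    """Conditional density f(t|z) = a(t|z) exp(-A(t|z)).

    Computed in log space: at old ages the hazard overflows while the
    survival factor underflows, and the naive product is nan.
    """
    t = _check_t(t)
    lp = z.linear_predictor(params)
    log_h = params.log_a + params.beta1 * t + lp
    return np.exp(log_h - cum_hazard(params, t, z))


def cdf(params: GompertzPHParams, t, z: CovariateVector = _REF):
    """Conditional CDF F(t|z) = 1 - exp(-A(t|z))."""
    return -np.expm1(-cum_hazard(params, t, z))


def quantile(params: GompertzPHParams, u, z: CovariateVector = _REF):
    """Inverse CDF in years since 50, for u in [0, 1).

    Closed form: t = (1/b1) log(1 + b1 * (-log(1-u)) / (a e^{lp})), with the
    exponential limit -log(1-u)/(a e^{lp}) at b1 = 0.
    """
    u = np.asarray(u, float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("u must lie in [0, 1)")
    lp = z.linear_predictor(params)
    # required cumulative hazard: A = -log(1-u)
    target = -np.log1p(-u) / np.exp(params.log_a + lp)
    if abs(params.beta1) < _BETA1_TINY:
        return target
    return np.log1p(params.beta1 * target) / params.beta1


def interval_incidence_rate(params: GompertzPHParams, t, d, z: CovariateVector = _REF):
    """P(incidence in [t, t+d) | still disease-free at t).

    Equals [F(t+d|z) - F(t|z)] / [1 - F(t|z)] = 1 - exp(-(A(t+d)-A(t))).
    With d = 5 these are the five-year incidence rates of a survivor aged
    50 + t.
    """
    t = _check_t(t)
    if np.any(np.asarray(d, float) <= 0):
        raise ValueError("d must be > 0")
    a1 = cum_hazard(params, t, z)
    if np.any(np.exp(-a1) == 0.0):
        raise ValueError("no survivors at t: F(t|z) = 1, conditional rate undefined")
    a2 = cum_hazard(params, np.asarray(t) + d, z)
    return -np.expm1(-(a2 - a1))


def log_lr_exponential(y, a, a0):
    """Log-likelihood ratio log f(y; a)/f(y; a0) for the exponential model.

    log LR(y, a, a0) = log(a/a0) - (a - a0) * y: linear in y, concave in a.
    """
    if a <= 0 or a0 <= 0:
        raise ValueError("rates must be positive")
    y = np.asarray(y, float)
    if np.any(y < 0):
        raise ValueError("y must be >= 0")
    return np.log(a / a0) - (a - a0) * y


def wald_dominance_bound(y, a0, eps=0.1):
    """Integrable envelope h(y) dominating |log LR(y, a, a0)| over a in [eps, 1/eps].

    The absolute log-likelihood ratio, concave in the rate ``a``, attains
    its maximum over the compact rate interval at one of only three
    candidates: the edges ``eps`` and ``1/eps``, or the interior stationary
    point ``1/y`` when that lies inside the interval.  The envelope is the
    pointwise maximum over those candidates; it is integrable against any
    exponential density, which is what makes the uniform (Wald-type)
    consistency argument work.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    lo, hi = eps, 1.0 / eps
    if not (lo < a0 < hi):
        raise ValueError("a0 must lie in the open interval (eps, 1/eps)")
    y = np.asarray(y, float)
    if np.any(y < 0):
        raise ValueError("y must be >= 0")
    cands = [np.abs(log_lr_exponential(y, lo, a0)), np.abs(log_lr_exponential(y, hi, a0))]
    with np.errstate(divide="ignore"):
        ainv = np.where(y > 0, 1.0 / np.where(y > 0, y, 1.0), np.inf)
    inside = (ainv >= lo) & (ainv <= hi)
    if np.any(inside):
        ac = np.clip(ainv, lo, hi)
        mid = np.abs(np.log(ac / a0) - (ac - a0) * y)
        cands.append(np.where(inside, mid, -np.inf))
    out = np.maximum.reduce(cands)
    return out if out.ndim else float(out)
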
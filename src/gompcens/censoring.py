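"""Observation scheme for doubly censored incidence durations.

A subject's latent age-at-incidence (in years since 50), ``y_star``, is
only partially observed through a study window: the subject enters at age
``50 + l`` and exits at ``50 + r``.  Incidence before entry is
left-censored (a prevalent case, the entry age is recorded), incidence
after exit is right-censored (the exit age is recorded), incidence inside
the window is observed exactly.  The censoring indicator is

    delta = -1  left-censored   (y = l,      y_star <  l)
    delta =  0  uncensored      (y = y_star, l <= y_star <= r)
    delta = +1  right-censored  (y = r,      y_star >  r)

and each record contributes to the estimation criterion

    Psi = 1{delta=0} log f(y|z) + 1{delta=-1} log F(y|z)
        + 1{delta=1} log(1 - F(y|z)),

the factor of the conditional likelihood that carries the duration
parameters.  The entry/exit distribution is left unspecified; it drops
out of the criterion, so the maximizer is unaffected by it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gompertz import GompertzPHParams, CovariateVector, _gt

__all__ = [
    "ObservationRecord",
    "DoubleCensoredDataset",
    "classify_observation",
    "criterion_term",
    "total_log_criterion",
    "cohort_dummies_from_birth_year",
    "read_dataset_csv",
    "write_dataset_csv",
    "HCD_COLUMNS",
]

# covariate column order used for datasets derived from birth year + sex
HCD_COLUMNS = ("z1", "z2", "z3", "z4", "z5", "sex")

# cohort decade boundaries (Table-style coding): z1=1900-09, z2=1910-19,
# z3=1920-29, reference=1930-39, z4=1940-49, z5=1950-54
_COHORT_EDGES = ((1900, 1909), (1910, 1919), (1920, 1929), (1940, 1949), (1950, 1954))
_DUMMY_SLOT = (0, 1, 2, 3, 4)  # z1, z2, z3, z4, z5


@dataclass(frozen=True)
class ObservationRecord:
    """One subject: observed duration y, censoring indicator delta, covariates."""

    y: float
    delta: int
    z: CovariateVector = field(default_factory=CovariateVector)

    def __post_init__(self):
        if self.delta not in (-1, 0, 1):
            raise ValueError("delta must be -1, 0 or 1")
        if self.y < 0:
            raise ValueError("y must be >= 0")


class DoubleCensoredDataset:
    """Array-backed collection of observation records.

    Parameters
    ----------
    y : (n,) durations in years since 50
    delta : (n,) ints in {-1, 0, 1}
    Z : (n, p) covariate matrix (may have p = 0 columns)
    colnames : names of the covariate columns
    """

    def __init__(self, y, delta, Z=None, colnames=()):
        self.y = np.ascontiguousarray(y, float)
        self.delta = np.ascontiguousarray(delta, int)
        n = self.y.shape[0]
        if Z is None:
            Z = np.empty((n, 0))
        self.Z = np.ascontiguousarray(Z, float)
        if self.Z.ndim == 1:
            self.Z = self.Z[:, None]
        self.colnames = tuple(colnames) if colnames else tuple(
            f"x{j}" for j in range(self.Z.shape[1])
        )
        if self.delta.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("y, delta and Z must have equal length")
        if len(self.colnames) != self.Z.shape[1]:
            raise ValueError("colnames must match the number of covariate columns")
        if not np.isin(self.delta, (-1, 0, 1)).all():
            raise ValueError("delta must be -1, 0 or 1")
        if np.any(self.y < 0):
            raise ValueError("durations must be >= 0")
        bad = (self.delta == -1) & (self.y == 0)
        if np.any(bad):
            warnings.warn(
                f"dropping {bad.sum()} degenerate prevalent record(s) with y=0 "
                "and delta=-1 (F(0)=0 makes the criterion -inf)",
                stacklevel=2,
            )
            keep = ~bad
            self.y, self.delta, self.Z = self.y[keep], self.delta[keep], self.Z[keep]

    def __len__(self):
        return self.y.shape[0]

    def __getitem__(self, i) -> ObservationRecord:
        z = CovariateVector()
        if self.colnames == HCD_COLUMNS:
            z = CovariateVector(tuple(int(v) for v in self.Z[i, :5]), int(self.Z[i, 5]))
        return ObservationRecord(float(self.y[i]), int(self.delta[i]), z)

    @property
    def counts(self):
        """(n_left, n_uncensored, n_right)."""
        return (
            int((self.delta == -1).sum()),
            int((self.delta == 0).sum()),
            int((self.delta == 1).sum()),
        )

    def subset(self, mask) -> "DoubleCensoredDataset":
        return DoubleCensoredDataset(self.y[mask], self.delta[mask], self.Z[mask], self.colnames)

    def drop_left_censored(self) -> "DoubleCensoredDataset":
        """The 'excluding left-censored persons' analysis path."""
        return self.subset(self.delta != -1)


def classify_observation(y_star, l, r):
    """Map latent durations onto (observed duration, censoring indicator).

    Ties ``y_star == l`` or ``y_star == r`` count as uncensored.  Accepts
    scalars or arrays; returns (y, delta) of the broadcast shape.
    """
    y_star = np.asarray(y_star, float)
    l = np.asarray(l, float)
    r = np.asarray(r, float)
    if np.any(l < 0):
        raise ValueError("entry age l must be >= 0")
    if np.any(l >= r):
        raise ValueError("need l < r (exit after entry)")
    y_star, l, r = np.broadcast_arrays(y_star, l, r)
    delta = np.where(y_star < l, -1, np.where(y_star > r, 1, 0))
    y = np.where(delta == -1, l, np.where(delta == 1, r, y_star))
    if y.ndim == 0:
        return float(y), int(delta)
    return y, delta.astype(int)


def _psi(y, delta, log_a, beta1, lp):
    """Vectorized criterion contributions Psi for each record.

    ``lp`` is the linear predictor beta' z per record (0-dim broadcasts).
    Uses log(1-exp(-A)) in the stable complementary form; A can be near 0
    or astronomically large without overflow in the left-censored branch.
    """
    y = np.asarray(y, float)
    u = np.exp(log_a + np.asarray(lp, float)) * _gt(beta1, y)  # cumulative hazard
    out = np.empty_like(u)
    unc = delta == 0
    rc = delta == 1
    lc = delta == -1
    out[unc] = log_a + beta1 * y[unc] + np.asarray(np.broadcast_to(lp, y.shape), float)[unc] - u[unc]
    out[rc] = -u[rc]
    with np.errstate(divide="ignore"):
        out[lc] = np.log(-np.expm1(-u[lc]))
    return out


def criterion_term(rec: ObservationRecord, params: GompertzPHParams) -> float:
    """Psi for a single record: exactly one of log f, log F, log(1-F)."""
    lp = rec.z.linear_predictor(params)
    val = float(_psi(np.array([rec.y]), np.array([rec.delta]), params.log_a, params.beta1, lp)[0])
    if not np.isfinite(val):
        warnings.warn(
            f"criterion term is {val} for record (y={rec.y}, delta={rec.delta}); "
            "F(y|z) hit 0 or 1 on a censored branch",
            stacklevel=2,
        )
    return val


def total_log_criterion(data: DoubleCensoredDataset, params: GompertzPHParams) -> float:
    """Sum of Psi over the dataset (log of the product criterion).

    With no censored records this is the ordinary log-likelihood.  A
    -inf contribution raises with the indices of the offending records.
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    if data.Z.shape[1] != len(HCD_COLUMNS):
        raise ValueError(
            "total_log_criterion expects the standard covariate layout "
            f"{HCD_COLUMNS}; use gompcens.estimate for generic designs"
        )
    coef = np.array([*params.beta2, params.beta3])
    lp = data.Z @ coef
    terms = _psi(data.y, data.delta, params.log_a, params.beta1, lp)
    if not np.all(np.isfinite(terms)):
        bad = np.flatnonzero(~np.isfinite(terms))
        raise FloatingPointError(
            f"criterion is non-finite for record indices {bad[:10].tolist()}"
            + ("..." if bad.size > 10 else "")
        )
    return float(terms.sum())


def cohort_dummies_from_birth_year(birth_year):
    """Five 0/1 cohort indicators from birth year (1930s decade = reference).

    Accepts scalars or arrays; returns an (n, 5) array (or (5,) for a
    scalar).  Years outside 1900-1954 are rejected.
    """
    by = np.atleast_1d(np.asarray(birth_year, int))
    if np.any((by < 1900) | (by > 1954)):
        raise ValueError("birth_year must lie in 1900..1954")
    Z = np.zeros((by.shape[0], 5))
    for (lo, hi), slot in zip(_COHORT_EDGES, _DUMMY_SLOT):
        Z[(by >= lo) & (by <= hi), slot] = 1.0
    return Z[0] if np.isscalar(birth_year) or np.asarray(birth_year).ndim == 0 else Z


def read_dataset_csv(path) -> DoubleCensoredDataset:
    """Read a dataset from the documented CSV dialect.

    Columns: id, y (decimal years since 50), delta in {-1,0,1},
    birth_year (1900-1954), sex (0/1).  Cohort dummies are derived from
    birth_year.
    """
    df = pd.read_csv(path)
    required = {"y", "delta", "birth_year", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    Z = np.column_stack(
        [cohort_dummies_from_birth_year(df["birth_year"].to_numpy()), df["sex"].to_numpy(float)]
    )
    return DoubleCensoredDataset(df["y"].to_numpy(float), df["delta"].to_numpy(int), Z, HCD_COLUMNS)


def write_dataset_csv(path, y, delta, birth_year, sex) -> None:
    """Write the CSV dialect read by :func:`read_dataset_csv`."""
    df = pd.DataFrame(
        {
            "id": np.arange(len(np.asarray(y))),
            "y": np.asarray(y, float),
            "delta": np.asarray(delta, int),
            "birth_year": np.asarray(birth_year, int),
            "sex": np.asarray(sex, int),
        }
    )
    df.to_csv(path, index=False)
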
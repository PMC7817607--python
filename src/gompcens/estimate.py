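"""Conditional maximum-likelihood estimation under double censoring.

The criterion maximized is the sum over records of

    Psi = 1{delta=0} log f(y|z) + 1{delta=-1} log F(y|z)
        + 1{delta=1} log(1-F(y|z))

with f, F from the Gompertz proportional-hazards model.  It is the factor
of the conditional likelihood that carries theta; entry/exit
distributions and covariate marginals drop out, so its maximizer is the
conditional MLE (an M-estimator).  Standard errors use the average
observed information J_hat = -(1/n) sum d2Psi/dtheta dtheta': for this
criterion a conditional information-matrix equality holds (the
outer-product information equals the negative-Hessian information), so
the sandwich collapses and se_k = sqrt([J_hat^{-1}]_kk / n).  The
``cime_diagnostic`` function exposes both matrices so the equality can be
checked empirically; a large relative difference flags misspecification.

Optimization is quasi-Newton (L-BFGS-B) with the analytic gradient and a
box bound beta1 >= 0, so the exponential submodel lies in the closure of
the parameter space.  Hessians are central differences of the analytic
gradient.  Convergence is verified ex post: gradient sup-norm below
1e-6 * n (projected at an active bound) and a positive-definite J_hat.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, stats

from .gompertz import GompertzPHParams, _gt, _BETA1_TINY
from .censoring import DoubleCensoredDataset, HCD_COLUMNS

__all__ = [
    "ModelSpec",
    "FitResult",
    "init_from_uncensored",
    "fit_cmle",
    "observed_information",
    "cime_diagnostic",
    "confidence_intervals",
]

logger = logging.getLogger(__name__)

_FALLBACK = (np.log(0.01), 0.1)  # (log_a, beta1) when no uncensored records exist


@dataclass(frozen=True)
class ModelSpec:
    """Which effects are estimated; the baseline log_a is always free.

    ``include_cohort`` activates every covariate column except ``sex``;
    ``include_sex`` activates the ``sex`` column if present.
    ``stratified_cohort`` requests the cohort-only model fitted as
    independent exponentials per stratum (equivalent to the joint fit with
    ``include_age=False, include_sex=False``).
    """

    include_age: bool = True
    include_cohort: bool = True
    include_sex: bool = True
    stratified_cohort: bool = False

    def active_columns(self, colnames):
        cols = []
        if self.include_cohort:
            cols += [c for c in colnames if c != "sex"]
        if self.include_sex and "sex" in colnames:
            cols.append("sex")
        return cols


@dataclass
class FitResult:
    """Estimates with inference metadata.

    ``theta`` holds only the free coordinates, in the order given by
    ``names`` (log_a, then beta1 if estimated, then covariate effects).
    ``info`` is the per-observation average observed information J_hat.
    """

    names: tuple
    theta: np.ndarray
    loglik: float
    info: np.ndarray
    se: np.ndarray
    ci95: np.ndarray
    converged: bool
    grad_sup: float
    n_used: dict
    message: str = ""

    @property
    def n(self) -> int:
        return sum(self.n_used.values())

    def as_params(self) -> GompertzPHParams:
        """Map back to the full 8-parameter vector (absent effects = 0)."""
        d = dict(zip(self.names, self.theta))
        return GompertzPHParams(
            d["log_a"],
            d.get("beta1", 0.0),
            tuple(d.get(c, 0.0) for c in ("z1", "z2", "z3", "z4", "z5")),
            d.get("sex", 0.0),
        )

    def to_json(self, path=None) -> str:
        payload = {
            "names": list(self.names),
            "theta": self.theta.tolist(),
            "loglik": self.loglik,
            "info": self.info.tolist(),
            "se": self.se.tolist(),
            "ci95": self.ci95.tolist(),
            "converged": bool(self.converged),
            "grad_sup": self.grad_sup,
            "n_used": self.n_used,
            "message": self.message,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FitResult":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            tuple(payload["names"]),
            np.array(payload["theta"]),
            payload["loglik"],
            np.array(payload["info"]),
            np.array(payload["se"]),
            np.array(payload["ci95"]),
            payload["converged"],
            payload["grad_sup"],
            {k: int(v) for k, v in payload["n_used"].items()},
            payload.get("message", ""),
        )

    def summary(self) -> str:
        lines = [
            f"n = {self.n} (left-censored {self.n_used.get('left', 0)}, "
            f"uncensored {self.n_used.get('uncensored', 0)}, "
            f"right-censored {self.n_used.get('right', 0)})",
            f"log-criterion = {self.loglik:.3f}   converged = {self.converged}",
            f"{'param':>8} {'estimate':>12} {'se':>10} {'95% CI':>24}",
        ]
        for k, name in enumerate(self.names):
            lo, hi = self.ci95[k]
            lines.append(
                f"{name:>8} {self.theta[k]:>12.5f} {self.se[k]:>10.5f} "
                f"[{lo:>10.5f}, {hi:>10.5f}]"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# criterion, gradient, per-record score matrix

def _unpack(theta, include_age):
    log_a = theta[0]
    if include_age:
        return log_a, theta[1], theta[2:]
    return log_a, 0.0, theta[1:]


def _log_g(beta1, y):
    """log[(exp(b1 y)-1)/b1], continuous at b1=0; -inf at y=0.

    Valid for negative b1 too (the finite-difference Hessian probes just
    below the beta1 >= 0 bound), where g = (1 - e^{b1 y})/(-b1) > 0.
    """
    with np.errstate(divide="ignore"):
        if abs(beta1) < _BETA1_TINY:
            return np.log(y)
        x = beta1 * y
        if beta1 > 0:
            return x + np.log(-np.expm1(-x)) - np.log(beta1)
        return np.log(-np.expm1(x)) - np.log(-beta1)


def _dg_over_g(beta1, y):
    """d log g / d b1 = y/(1-exp(-b1 y)) - 1/b1, with the limit y/2 at b1=0."""
    if abs(beta1) < _BETA1_TINY:
        return 0.5 * y
    x = beta1 * y
    small = x < 1e-4
    with np.errstate(divide="ignore", invalid="ignore"):
        exact = y / (-np.expm1(-x)) - 1.0 / beta1
    taylor = 0.5 * y + x * y / 12.0
    return np.where(small, taylor, exact)


def _score_matrix(theta, y, delta, X, include_age):
    """Per-record criterion contributions and their gradients.

    Returns (psi (n,), G (n,p)) where G[i] = dPsi_i/dtheta.
    """
    log_a, beta1, coef = _unpack(theta, include_age)
    lp = X @ coef if X.shape[1] else np.zeros_like(y)
    log_u = log_a + lp + _log_g(beta1, y)
    u = np.exp(np.minimum(log_u, 300.0))  # clip keeps gradients finite far afield
    unc = delta == 0
    rc = delta == 1
    lc = delta == -1

    psi = np.empty_like(y)
    psi[unc] = log_a + beta1 * y[unc] + lp[unc] - u[unc]
    psi[rc] = -u[rc]
    with np.errstate(divide="ignore"):
        psi[lc] = np.log(-np.expm1(-u[lc]))

    # multiplier on du/dtheta per branch: -1 for delta in {0,1},
    # exp(-u)/(1-exp(-u)) for delta=-1
    m = np.full_like(y, -1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-u[lc]) / (-np.expm1(-u[lc]))
    m[lc] = w

    s0 = unc.astype(float) + m * u  # dPsi/dlog_a (and per-unit-covariate)
    p = 1 + int(include_age) + X.shape[1]
    G = np.empty((y.shape[0], p))
    G[:, 0] = s0
    col = 1
    if include_age:
        G[:, 1] = unc * y + m * u * _dg_over_g(beta1, y)
        col = 2
    if X.shape[1]:
        G[:, col:] = X * s0[:, None]
    return psi, G


def _nll_grad(theta, y, delta, X, include_age):
    psi, G = _score_matrix(theta, y, delta, X, include_age)
    return -psi.sum(), -G.sum(axis=0)


def _fd_hessian(grad_fn, theta):
    """Central differences of a gradient function; symmetrized."""
    p = theta.shape[0]
    H = np.empty((p, p))
    h = np.cbrt(np.finfo(float).eps) * np.maximum(1.0, np.abs(theta))
    for k in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h[k]
        tm[k] -= h[k]
        H[:, k] = (grad_fn(tp) - grad_fn(tm)) / (2 * h[k])
    return 0.5 * (H + H.T)


def _design(data: DoubleCensoredDataset, spec: ModelSpec):
    cols = spec.active_columns(data.colnames)
    idx = [data.colnames.index(c) for c in cols]
    X = data.Z[:, idx]
    names = ["log_a"] + (["beta1"] if spec.include_age else []) + cols
    return X, tuple(names)


# ---------------------------------------------------------------------------
# public operations

def init_from_uncensored(data: DoubleCensoredDataset) -> GompertzPHParams:
    """Starting values from the uncensored records only, no covariates.

    For fixed beta1 the baseline MLE is closed form,
    a_hat(b1) = n / sum_i (exp(b1 y_i)-1)/b1; beta1 is found by a 1-D
    profile maximization over [0, 2] per year.  All covariate effects
    start at 0.  With fewer than two uncensored records a fixed default
    (a=0.01, beta1=0.1) is returned and logged.
    """
    y = data.y[data.delta == 0]
    n = y.shape[0]
    if n < 2:
        logger.warning("fewer than 2 uncensored records; using fallback init")
        return GompertzPHParams(_FALLBACK[0], _FALLBACK[1])
    sum_y = y.sum()

    def neg_profile(b1):
        s = _gt(b1, y).sum()
        return -(n * np.log(n / s) + b1 * sum_y - n)

    res = optimize.minimize_scalar(neg_profile, bounds=(0.0, 2.0), method="bounded")
    b1 = float(res.x) if res.success else 0.0
    if neg_profile(0.0) <= neg_profile(b1):  # boundary may beat the interior point
        b1 = 0.0
    a_hat = n / _gt(b1, y).sum()
    return GompertzPHParams(float(np.log(a_hat)), b1)


def fit_cmle(
    data: DoubleCensoredDataset,
    spec: ModelSpec = ModelSpec(),
    init: GompertzPHParams | None = None,
    options: dict | None = None,
) -> FitResult:
    """Maximize the double-censoring criterion; verify convergence ex post."""
    if len(data) == 0:
        raise ValueError("dataset is empty")
    if spec.stratified_cohort:
        return _fit_stratified(data)
    X, names = _design(data, spec)
    y, delta = data.y, data.delta
    include_age = spec.include_age

    if init is None:
        init = init_from_uncensored(data)
    theta0 = np.zeros(len(names))
    theta0[0] = init.log_a
    if include_age:
        theta0[1] = init.beta1
    nll0, _ = _nll_grad(theta0, y, delta, X, include_age)
    if not np.isfinite(nll0):
        logger.warning("criterion not finite at init; re-initializing at fallback")
        theta0 = np.zeros(len(names))
        theta0[0] = _FALLBACK[0]
        if include_age:
            theta0[1] = _FALLBACK[1]

    bounds = [(None, None)] * len(names)
    if include_age:
        bounds[1] = (0.0, None)
    opts = {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9}
    if options:
        opts.update(options)
    res = optimize.minimize(
        _nll_grad,
        theta0,
        args=(y, delta, X, include_age),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": opts["maxiter"], "ftol": opts["ftol"], "gtol": opts["gtol"]},
    )
    theta = res.x
    _, grad = _nll_grad(theta, y, delta, X, include_age)

    # polish with Newton steps on the FD Hessian: L-BFGS-B's ftol stop can
    # leave the score above the ex-post tolerance on ill-conditioned fits
    n = len(data)
    for _ in range(8):
        pg = grad.copy()
        if include_age and theta[1] <= 0.0:
            pg[1] = min(pg[1], 0.0)
        if np.abs(pg).max() < 1e-8 * n:
            break
        H = _fd_hessian(lambda th: _nll_grad(th, y, delta, X, include_age)[1], theta)
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            break
        cand = theta + step
        if include_age:
            cand[1] = max(cand[1], 0.0)
        nll_c, grad_c = _nll_grad(cand, y, delta, X, include_age)
        nll_t = _nll_grad(theta, y, delta, X, include_age)[0]
        if not np.isfinite(nll_c) or nll_c > nll_t + 1e-8 * max(1.0, abs(nll_t)):
            break
        theta, grad = cand, grad_c
    res.fun = _nll_grad(theta, y, delta, X, include_age)[0]
    # project the gradient at an active beta1 >= 0 bound
    pgrad = grad.copy()
    if include_age and theta[1] <= 0.0:
        pgrad[1] = min(pgrad[1], 0.0)
    grad_sup = float(np.abs(pgrad).max())

    J = observed_information(data, theta, spec)
    eigmin = float(np.linalg.eigvalsh(J).min())
    interior = not (include_age and theta[1] <= 0.0)
    if eigmin > 0:
        se = np.sqrt(np.diag(np.linalg.inv(J)) / n)
    else:
        warnings.warn("observed information not positive definite; SEs suppressed")
        se = np.full(len(names), np.nan)
    converged = bool(grad_sup < 1e-6 * n and (eigmin > 0 or not interior))
    ci95 = np.column_stack([theta - 1.96 * se, theta + 1.96 * se])
    nl, nu, nr = data.counts
    fit = FitResult(
        names,
        theta,
        -float(res.fun),
        J,
        se,
        ci95,
        converged,
        grad_sup,
        {"left": nl, "uncensored": nu, "right": nr},
        res.message if isinstance(res.message, str) else str(res.message),
    )
    if not converged:
        logger.warning("fit did not meet the ex-post convergence checks: %s", fit.message)
    return fit


def _fit_stratified(data: DoubleCensoredDataset) -> FitResult:
    """Cohort-only model as independent exponential fits per stratum.

    The joint criterion factorizes over cohorts, so per-stratum
    exponential fits reproduce the joint (log_a, beta2) estimates with a
    block-diagonal information matrix.
    """
    if data.colnames != HCD_COLUMNS:
        raise ValueError("stratified cohort fit requires the standard covariate layout")
    dummies = data.Z[:, :5]
    strata = {"ref": np.all(dummies == 0, axis=1)}
    for j, name in enumerate(("z1", "z2", "z3", "z4", "z5")):
        strata[name] = dummies[:, j] == 1
    spec0 = ModelSpec(include_age=False, include_cohort=False, include_sex=False)
    log_rates, ses, loglik = {}, {}, 0.0
    for name, mask in strata.items():
        if not mask.any():
            raise ValueError(f"empty cohort stratum {name!r}")
        sub = data.subset(mask)
        f = fit_cmle(sub, spec0)
        log_rates[name], ses[name] = float(f.theta[0]), float(f.se[0])
        loglik += f.loglik
    names = ("log_a", "z1", "z2", "z3", "z4", "z5")
    theta = np.array(
        [log_rates["ref"]] + [log_rates[c] - log_rates["ref"] for c in names[1:]]
    )
    se = np.array(
        [ses["ref"]] + [np.hypot(ses[c], ses["ref"]) for c in names[1:]]
    )
    info = np.diag(1.0 / np.maximum(se, 1e-300) ** 2 / len(data))  # block summary only
    ci95 = np.column_stack([theta - 1.96 * se, theta + 1.96 * se])
    nl, nu, nr = data.counts
    return FitResult(
        names, theta, loglik, info, se, ci95, True, 0.0,
        {"left": nl, "uncensored": nu, "right": nr}, "stratified per-cohort exponential fits",
    )


def _as_theta(theta_or_params, names):
    if isinstance(theta_or_params, GompertzPHParams):
        full = dict(zip(("log_a", "beta1", "z1", "z2", "z3", "z4", "z5", "sex"),
                        theta_or_params.to_vector()))
        return np.array([full[n] for n in names])
    return np.asarray(theta_or_params, float)


def observed_information(
    data: DoubleCensoredDataset,
    theta_hat,
    spec: ModelSpec = ModelSpec(),
) -> np.ndarray:
    """J_hat = -(1/n) sum d2Psi_i/dtheta dtheta' at theta_hat.

    The Hessian is computed by central differences of the analytic
    gradient with step h_k = eps^{1/3} max(1, |theta_k|).
    """
    X, names = _design(data, spec)
    theta = _as_theta(theta_hat, names)
    n = len(data)

    def grad(th):
        return _nll_grad(th, data.y, data.delta, X, spec.include_age)[1]

    return _fd_hessian(grad, theta) / n


def cime_diagnostic(
    data: DoubleCensoredDataset,
    theta,
    spec: ModelSpec = ModelSpec(),
):
    """Both information estimates and their relative Frobenius difference.

    Returns (J_hat, I_hat, rel_diff) where I_hat = (1/n) sum g_i g_i' is
    the outer-product (Gram) information and rel_diff = ||I-J||/||J||.
    Under a correctly specified model the two converge to the same matrix
    (the information-matrix equality); persistent discrepancy indicates
    misspecification, in which case a sandwich J^{-1} I J^{-1} would be
    needed.
    """
    X, names = _design(data, spec)
    th = _as_theta(theta, names)
    _, G = _score_matrix(th, data.y, data.delta, X, spec.include_age)
    I_hat = G.T @ G / len(data)
    J_hat = observed_information(data, th, spec)
    rel = float(np.linalg.norm(I_hat - J_hat) / np.linalg.norm(J_hat))
    return J_hat, I_hat, rel


def confidence_intervals(fit: FitResult, level: float = 0.95) -> np.ndarray:
    """Normal-theory intervals theta_k +/- z_{(1+level)/2} * se_k."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 * (1 + level))
    return np.column_stack([fit.theta - z * fit.se, fit.theta + z * fit.se])
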
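"""Point estimation for the GMO-EE parameters.

Five frequentist estimators are provided, all as constrained numerical
minimisations sharing one multi-start optimizer harness:

* ``fit_mle``  — maximum likelihood (analytic gradient);
* ``fit_lse``  — least squares against the plotting positions i/(n+1);
* ``fit_wlse`` — weighted least squares, weights = reciprocal variance of
  the empirical cdf at the order statistics;
* ``fit_ade``  — minimum Anderson-Darling distance;
* ``fit_cvme`` — minimum Cramer-von Mises distance.

Constraints are handled by optimizing over unconstrained coordinates
``(logit(alpha), logit(lambda), log(theta), log(beta))``; the upper
boundary alpha = lambda = 1 is reachable in the limit.  Multi-start
points are drawn from a seeded Latin hypercube over a box scaled to the
sample.  Standard errors (MLE only) come from the inverse observed
information, i.e. the negative inverse Hessian of the log-likelihood at
the optimum, with the Hessian obtained by central differences of the
analytic score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize, special
from scipy.stats import qmc

from .core import ParamVector, Sample, _log_w, gmoee_cdf

__all__ = [
    "FitResult",
    "loglik",
    "score",
    "fit_mle",
    "fit_lse",
    "fit_wlse",
    "fit_ade",
    "fit_cvme",
    "fit",
    "METHODS",
]

#: clamp for fitted cdf values inside log/distance objectives
_EPS = 1e-12

#: default optimizer settings (shared by all five estimators)
_DEFAULT_STARTS = 25
_GTOL = 1e-10
_XTOL = 1e-8
_MAXITER = 2000


@dataclass
class FitResult:
    """Outcome of one estimator on one sample.

    ``objective_value`` is the maximized log-likelihood for the MLE and
    the minimized distance objective for the other methods.  ``se`` is
    populated for the MLE only (observed-information Wald standard
    errors, NaN where the information matrix is not positive definite).
    """

    method: str
    eta_hat: ParamVector
    objective_value: float
    converged: bool
    n_starts_used: int
    se: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# log-likelihood and analytic score
# ---------------------------------------------------------------------------

def loglik(eta: ParamVector, sample: Sample) -> float:
    """Log-likelihood of the GMO-EE model.

    l(eta) = sum log A_i - 2 sum log D_i + n log(theta beta)
             - theta sum x_i + (beta - 1) sum log w_i,

    with w = 1 - e^{-theta x}, F = w^beta, A = (1-a)(1-l)F^2 + 2a(1-l)F + a l
    and D = a + (1-a)F.  Evaluated in log space so large theta*x or
    extreme beta do not underflow.
    """
    a, l, th, b = eta.alpha, eta.lambda_, eta.theta, eta.beta
    x = sample.values
    logw = _log_w(th * x)
    F = np.exp(b * logw)
    A = (1.0 - a) * (1.0 - l) * F * F + 2.0 * a * (1.0 - l) * F + a * l
    D = a + (1.0 - a) * F
    return float(
        np.sum(np.log(A)) - 2.0 * np.sum(np.log(D))
        + x.size * np.log(th * b) - th * np.sum(x) + (b - 1.0) * np.sum(logw)
    )


def score(eta: ParamVector, sample: Sample) -> np.ndarray:
    """Analytic gradient of the log-likelihood w.r.t. (alpha, lambda, theta, beta)."""
    a, l, th, b = eta.alpha, eta.lambda_, eta.theta, eta.beta
    x = sample.values
    n = x.size
    tx = th * x
    logw = _log_w(tx)
    w = -np.expm1(-tx)
    e = np.exp(-tx)
    F = np.exp(b * logw)
    A = (1.0 - a) * (1.0 - l) * F * F + 2.0 * a * (1.0 - l) * F + a * l
    D = a + (1.0 - a) * F

    dA_da = -(1.0 - l) * F * F + 2.0 * (1.0 - l) * F + l
    dA_dl = -(1.0 - a) * F * F - 2.0 * a * F + a
    dA_dF = 2.0 * (1.0 - a) * (1.0 - l) * F + 2.0 * a * (1.0 - l)
    dF_dth = b * np.exp((b - 1.0) * logw) * x * e
    dF_db = F * logw

    d_alpha = np.sum(dA_da / A) - 2.0 * np.sum((1.0 - F) / D)
    d_lambda = np.sum(dA_dl / A)
    d_theta = (
        np.sum(dA_dF * dF_dth / A)
        - 2.0 * (1.0 - a) * np.sum(dF_dth / D)
        + n / th - np.sum(x) + (b - 1.0) * np.sum(x * e / w)
    )
    d_beta = (
        np.sum(dA_dF * dF_db / A)
        - 2.0 * (1.0 - a) * np.sum(dF_db / D)
        + n / b + np.sum(logw)
    )
    return np.array([d_alpha, d_lambda, d_theta, d_beta])


# ---------------------------------------------------------------------------
# parameter transforms: eta <-> unconstrained z
# ---------------------------------------------------------------------------

def _to_z(eta: np.ndarray) -> np.ndarray:
    a, l, th, b = eta
    return np.array([special.logit(a), special.logit(l), np.log(th), np.log(b)])


def _from_z(z: np.ndarray) -> np.ndarray:
    return np.array([
        special.expit(z[0]), special.expit(z[1]), np.exp(z[2]), np.exp(z[3]),
    ])


def _jac_eta_z(eta: np.ndarray) -> np.ndarray:
    """d eta / d z (diagonal)."""
    a, l, th, b = eta
    return np.array([a * (1.0 - a), l * (1.0 - l), th, b])


def _eta_from_z_safe(z: np.ndarray) -> ParamVector:
    eta = _from_z(np.clip(z, -40.0, 40.0))
    # expit saturates to exactly 0/1 for |z| > ~37; pull back inside the box
    a = min(max(eta[0], 1e-12), 1.0)
    l = min(max(eta[1], 1e-12), 1.0)
    return ParamVector(a, l, float(eta[2]), float(eta[3]))


# ---------------------------------------------------------------------------
# multi-start harness
# ---------------------------------------------------------------------------

def _lhs_starts(sample: Sample, n_starts: int, seed) -> np.ndarray:
    """Latin-hypercube starting points over a sample-scaled box.

    alpha, lambda uniform on [0.05, 0.99]; theta log-uniform on
    [0.1/mean, 10/mean]; beta log-uniform on [0.2, 20].
    """
    mean = float(np.mean(sample.values))
    lhs = qmc.LatinHypercube(d=4, seed=np.random.default_rng(seed))
    u = lhs.random(n_starts)
    a = 0.05 + u[:, 0] * (0.99 - 0.05)
    l = 0.05 + u[:, 1] * (0.99 - 0.05)
    th = (0.1 / mean) * (100.0 ** u[:, 2])
    b = 0.2 * (100.0 ** u[:, 3])
    return np.column_stack([a, l, th, b])


def _multistart(
    objective: Callable[[ParamVector], float],
    sample: Sample,
    starts: int,
    seed,
    grad: Callable[[ParamVector], np.ndarray] | None = None,
    extra_starts: np.ndarray | None = None,
) -> tuple[ParamVector, float, bool, int, dict]:
    """Minimize ``objective`` over the parameter box from many starts."""

    def f(z: np.ndarray) -> float:
        try:
            v = objective(_eta_from_z_safe(z))
        except (ValueError, OverflowError, FloatingPointError):
            return np.inf
        return v if np.isfinite(v) else np.inf

    jac = None
    if grad is not None:
        def jac(z: np.ndarray) -> np.ndarray:
            eta = _eta_from_z_safe(z)
            g = grad(eta) * _jac_eta_z(eta.as_array())
            return np.where(np.isfinite(g), g, 0.0)

    init = _lhs_starts(sample, starts, seed) if starts > 0 else np.empty((0, 4))
    if extra_starts is not None and len(extra_starts):
        init = np.vstack([np.atleast_2d(extra_starts), init])

    best = None
    trace = []
    for eta0 in init:
        z0 = _to_z(np.asarray(eta0, dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = optimize.minimize(
                    f, z0, jac=jac, method="L-BFGS-B",
                    options={"maxiter": _MAXITER, "ftol": _GTOL, "gtol": 1e-8},
                )
                # polish gradient-free: L-BFGS-B can stall on ridges
                res2 = optimize.minimize(
                    f, res.x, method="Nelder-Mead",
                    options={"maxiter": _MAXITER, "xatol": _XTOL, "fatol": _GTOL},
                )
                if res2.fun < res.fun:
                    res = res2
            except Exception:  # pragma: no cover - defensive
                continue
        trace.append(float(res.fun))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    eta_hat = _eta_from_z_safe(best.x)
    converged = bool(np.isfinite(best.fun))
    return eta_hat, float(best.fun), converged, len(init), {"start_objectives": trace}


# ---------------------------------------------------------------------------
# the five estimators
# ---------------------------------------------------------------------------

def _check_n(sample: Sample) -> None:
    if sample.n < 5:
        raise ValueError("need at least 5 observations to fit four parameters")


def fit_mle(sample: Sample, starts: int = _DEFAULT_STARTS, seed=0,
            compute_se: bool = True, extra_starts=None) -> FitResult:
    """Maximum likelihood estimate via multi-start quasi-Newton."""
    _check_n(sample)
    eta_hat, negll, conv, used, diag = _multistart(
        lambda eta: -loglik(eta, sample), sample, starts, seed,
        grad=lambda eta: -score(eta, sample), extra_starts=extra_starts,
    )
    se = _wald_se(eta_hat, sample) if compute_se else None
    return FitResult("MLE", eta_hat, -negll, conv, used, se=se, diagnostics=diag)


def _plot_pos(n: int) -> np.ndarray:
    return np.arange(1, n + 1) / (n + 1.0)


def _ls_objective(sample: Sample, weights: np.ndarray | None) -> Callable:
    xs = sample.sorted_values
    pp = _plot_pos(sample.n)
    w = np.ones_like(pp) if weights is None else weights

    def obj(eta: ParamVector) -> float:
        G = np.asarray(gmoee_cdf(xs, eta))
        return float(np.sum(w * (G - pp) ** 2))

    return obj


def fit_lse(sample: Sample, starts: int = _DEFAULT_STARTS, seed=0,
            extra_starts=None) -> FitResult:
    """Least squares against the plotting positions i/(n+1)."""
    _check_n(sample)
    eta_hat, val, conv, used, diag = _multistart(
        _ls_objective(sample, None), sample, starts, seed, extra_starts=extra_starts
    )
    return FitResult("LSE", eta_hat, val, conv, used, diagnostics=diag)


def wlse_weights(n: int, printed_variant: bool = False) -> np.ndarray:
    """WLSE weights 1/Var[G(X_{i:n})] = (n+1)^2 (n+2) / (i (n-i+1)).

    ``printed_variant=True`` replaces the factor (n+2) by (n+1); this
    dimensionally odd variant appears in some presentations and is kept
    behind this flag for comparison only — it rescales the objective by a
    constant and therefore yields identical estimates.
    """
    i = np.arange(1, n + 1, dtype=float)
    last = (n + 1.0) if printed_variant else (n + 2.0)
    return (n + 1.0) ** 2 * last / (i * (n - i + 1.0))


def fit_wlse(sample: Sample, starts: int = _DEFAULT_STARTS, seed=0,
             printed_weights: bool = False, extra_starts=None) -> FitResult:
    """Weighted least squares with reciprocal-variance weights."""
    _check_n(sample)
    w = wlse_weights(sample.n, printed_variant=printed_weights)
    eta_hat, val, conv, used, diag = _multistart(
        _ls_objective(sample, w), sample, starts, seed, extra_starts=extra_starts
    )
    return FitResult("WLSE", eta_hat, val, conv, used, diagnostics=diag)


def ad_objective(sample: Sample, eta: ParamVector, literal_indexing: bool = False) -> float:
    """Anderson-Darling distance A^2 between the fitted cdf and the sample.

    Standard form:  A^2 = -n - (1/n) sum (2i-1) [log G(x_{(i)}) +
    log(1 - G(x_{(n+1-i)}))].  ``literal_indexing=True`` applies both logs
    to the same order statistic G(x_{(i)}); this is a genuinely different
    objective (re-indexing the second sum changes its weights to 2(n-i)+1)
    that appears in some presentations, and is exposed for comparison
    only — the standard form is the Anderson-Darling statistic.  Fitted
    cdf values are clamped into [eps, 1-eps], eps=1e-12, to keep the logs
    finite.
    """
    n = sample.n
    i = np.arange(1, n + 1, dtype=float)
    G = np.clip(np.asarray(gmoee_cdf(sample.sorted_values, eta)), _EPS, 1.0 - _EPS)
    if literal_indexing:
        s = np.sum((2.0 * i - 1.0) * (np.log(G) + np.log1p(-G)))
    else:
        s = np.sum((2.0 * i - 1.0) * (np.log(G) + np.log1p(-G[::-1])))
    return float(-n - s / n)


def cvm_objective(sample: Sample, eta: ParamVector) -> float:
    """Cramer-von Mises distance C = 1/(12n) + sum [G(x_{(i)}) - (2i-1)/(2n)]^2."""
    n = sample.n
    i = np.arange(1, n + 1, dtype=float)
    G = np.asarray(gmoee_cdf(sample.sorted_values, eta))
    return float(1.0 / (12.0 * n) + np.sum((G - (2.0 * i - 1.0) / (2.0 * n)) ** 2))


def fit_ade(sample: Sample, starts: int = _DEFAULT_STARTS, seed=0,
            literal_indexing: bool = False, extra_starts=None) -> FitResult:
    """Minimum Anderson-Darling distance estimate."""
    _check_n(sample)
    eta_hat, val, conv, used, diag = _multistart(
        lambda eta: ad_objective(sample, eta, literal_indexing),
        sample, starts, seed, extra_starts=extra_starts,
    )
    return FitResult("ADE", eta_hat, val, conv, used, diagnostics=diag)


def fit_cvme(sample: Sample, starts: int = _DEFAULT_STARTS, seed=0,
             extra_starts=None) -> FitResult:
    """Minimum Cramer-von Mises distance estimate."""
    _check_n(sample)
    eta_hat, val, conv, used, diag = _multistart(
        lambda eta: cvm_objective(sample, eta),
        sample, starts, seed, extra_starts=extra_starts,
    )
    return FitResult("CvME", eta_hat, val, conv, used, diagnostics=diag)


METHODS: dict[str, Callable[..., FitResult]] = {
    "MLE": fit_mle,
    "LSE": fit_lse,
    "WLSE": fit_wlse,
    "ADE": fit_ade,
    "CvME": fit_cvme,
}


def fit(sample: Sample, method: str = "MLE", **kwargs) -> FitResult:
    """Dispatch to one of the five estimators by name (case-insensitive)."""
    key = method.upper().replace("CVME", "CvME")
    if key not in METHODS:
        raise KeyError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    return METHODS[key](sample, **kwargs)


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

def _num_hessian_loglik(eta: ParamVector, sample: Sample, rel_step: float = 1e-5) -> np.ndarray:
    """Hessian of the log-likelihood by central differences of the analytic score."""
    eta0 = eta.as_array()
    H = np.zeros((4, 4))
    for j in range(4):
        h = rel_step * max(abs(eta0[j]), 1e-4)
        up, dn = eta0.copy(), eta0.copy()
        up[j] += h
        dn[j] -= h
        # stay inside the box for alpha, lambda
        if j < 2:
            up[j] = min(up[j], 1.0)
            dn[j] = max(dn[j], 1e-12)
        gu = score(ParamVector.from_array(up), sample)
        gd = score(ParamVector.from_array(dn), sample)
        H[:, j] = (gu - gd) / (up[j] - dn[j])
    return 0.5 * (H + H.T)


def _wald_se(eta: ParamVector, sample: Sample) -> np.ndarray:
    """Observed-information standard errors; NaN if the information is not PD."""
    try:
        info = -_num_hessian_loglik(eta, sample)
        cov = np.linalg.inv(info)
        var = np.diag(cov)
        if np.any(var <= 0):
            raise np.linalg.LinAlgError
        return np.sqrt(var)
    except np.linalg.LinAlgError:
        warnings.warn(
            "observed information not positive definite; standard errors set to NaN",
            RuntimeWarning,
        )
        return np.full(4, np.nan)
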
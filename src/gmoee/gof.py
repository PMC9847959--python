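"""Goodness-of-fit statistics, p-values and model-comparison reports.

For a fitted model on a sample this module computes -2*log-likelihood,
AIC, and the Kolmogorov-Smirnov, Anderson-Darling and Cramer-von Mises
statistics against the fitted cdf, together with approximate p-values.

The p-values use simple-hypothesis asymptotics (fitted parameters are
treated as known): K-S from the exact/asymptotic Kolmogorov distribution,
CvM from the asymptotic W^2 distribution, AD from the Marsaglia-Marsaglia
evaluation of the limiting A^2 distribution.  Because the parameters are
in fact estimated from the same data, these p-values are optimistic and
should be read as descriptive model-comparison indices, not calibrated
test levels.

``fit_baselines`` fits the nested/competing EE, Weibull and exponential
models by maximum likelihood so a sample can be scored across all four
models in one call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import ParamVector, Sample, _log_w, gmoee_cdf, ee_cdf
from .estimation import _EPS, fit_mle

__all__ = [
    "GofReport",
    "ks_stat",
    "ad_stat",
    "cvm_stat",
    "ad_pvalue",
    "gof_report",
    "fit_baselines",
    "compare_models",
    "report_table",
]


@dataclass(frozen=True)
class GofReport:
    """Model-comparison statistics for one fitted model on one sample."""

    model_name: str
    k: int
    neg2loglik: float
    aic: float
    ks: float
    ad: float
    cvm: float
    p_ks: float
    p_ad: float
    p_cvm: float


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def ks_stat(sample: Sample, cdf_at: Callable[[np.ndarray], np.ndarray]) -> float:
    """Two-sided Kolmogorov-Smirnov sup-norm statistic.

    D = max_i max( i/n - G(x_(i)), G(x_(i)) - (i-1)/n ).
    """
    n = sample.n
    G = np.asarray(cdf_at(sample.sorted_values))
    i = np.arange(1, n + 1, dtype=float)
    d_plus = np.max(i / n - G)
    d_minus = np.max(G - (i - 1.0) / n)
    return float(max(d_plus, d_minus))


def _as_eta_cdf(cdf_at) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(cdf_at, ParamVector):
        eta = cdf_at
        return lambda x: np.asarray(gmoee_cdf(x, eta))
    return cdf_at


def ad_stat(sample: Sample, cdf_at) -> float:
    """Anderson-Darling statistic A^2 of the fitted cdf (eps-clamped)."""
    cdf = _as_eta_cdf(cdf_at)
    n = sample.n
    i = np.arange(1, n + 1, dtype=float)
    G = np.clip(np.asarray(cdf(sample.sorted_values)), _EPS, 1.0 - _EPS)
    s = np.sum((2.0 * i - 1.0) * (np.log(G) + np.log1p(-G[::-1])))
    return float(-n - s / n)


def cvm_stat(sample: Sample, cdf_at) -> float:
    """Cramer-von Mises statistic W^2 = 1/(12n) + sum (G(x_(i)) - (2i-1)/(2n))^2."""
    cdf = _as_eta_cdf(cdf_at)
    n = sample.n
    i = np.arange(1, n + 1, dtype=float)
    G = np.asarray(cdf(sample.sorted_values))
    return float(1.0 / (12.0 * n) + np.sum((G - (2.0 * i - 1.0) / (2.0 * n)) ** 2))


# ---------------------------------------------------------------------------
# p-values (simple-hypothesis asymptotics)
# ---------------------------------------------------------------------------

def ad_pvalue(a2: float) -> float:
    """P(A^2 > a2) under the limiting Anderson-Darling distribution.

    Marsaglia & Marsaglia's rational approximations to the asymptotic cdf
    (accurate to ~1e-5 over the practical range).
    """
    z = float(a2)
    if z <= 0.0:
        return 1.0
    if z < 2.0:
        cdf = (
            np.exp(-1.2337141 / z) / np.sqrt(z)
            * (2.00012 + (0.247105 - (0.0649821 - (0.0347962
               - (0.011672 - 0.00168691 * z) * z) * z) * z) * z)
        )
    else:
        cdf = np.exp(
            -np.exp(1.0776 - (2.30695 - (0.43424 - (0.082433
                    - (0.008056 - 0.0003146 * z) * z) * z) * z) * z)
        )
    return float(np.clip(1.0 - cdf, 0.0, 1.0))


def _ks_pvalue(d: float, n: int) -> float:
    return float(stats.kstwo.sf(d, n))


def _cvm_pvalue(w2: float) -> float:
    # asymptotic distribution of W^2, as used by scipy.stats.cramervonmises
    from scipy.stats._hypotests import _cdf_cvm

    return float(np.clip(1.0 - _cdf_cvm(w2), 0.0, 1.0))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def gof_report(sample: Sample, cdf_at, model_name: str, k: int,
               loglik_value: float) -> GofReport:
    """Assemble a goodness-of-fit report for one fitted model.

    ``cdf_at`` is the fitted cdf evaluator (or a ParamVector, interpreted
    as a fitted GMO-EE); ``k`` is the number of free parameters;
    ``loglik_value`` the maximized log-likelihood.
    """
    cdf = _as_eta_cdf(cdf_at)
    neg2 = -2.0 * loglik_value
    ks = ks_stat(sample, cdf)
    ad = ad_stat(sample, cdf)
    cvm = cvm_stat(sample, cdf)
    return GofReport(
        model_name=model_name,
        k=k,
        neg2loglik=neg2,
        aic=neg2 + 2.0 * k,
        ks=ks,
        ad=ad,
        cvm=cvm,
        p_ks=_ks_pvalue(ks, sample.n),
        p_ad=ad_pvalue(ad),
        p_cvm=_cvm_pvalue(cvm),
    )


# ---------------------------------------------------------------------------
# baseline models: EE, Weibull, exponential
# ---------------------------------------------------------------------------

def _ee_loglik(theta: float, beta: float, x: np.ndarray) -> float:
    return float(
        x.size * np.log(theta * beta) - theta * np.sum(x)
        + (beta - 1.0) * np.sum(_log_w(theta * x))
    )


def fit_ee(sample: Sample) -> tuple[np.ndarray, np.ndarray, float]:
    """Two-parameter EE maximum likelihood: returns (est, se, loglik)."""
    x = sample.values

    def nll(z):
        th, b = np.exp(z)
        return -_ee_loglik(th, b, x)

    z0 = np.log([1.0 / np.mean(x), 1.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(nll, z0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    th, b = np.exp(res.x)
    se = _se_from_nll_2d(lambda p: -_ee_loglik(p[0], p[1], x), np.array([th, b]))
    return np.array([th, b]), se, -float(res.fun)


def fit_weibull(sample: Sample) -> tuple[np.ndarray, np.ndarray, float]:
    """Weibull (shape k, scale lam) MLE, cdf 1 - exp(-(x/lam)^k)."""
    x = sample.values
    shape, _, scale = stats.weibull_min.fit(x, floc=0)
    ll = float(np.sum(stats.weibull_min.logpdf(x, shape, scale=scale)))
    se = _se_from_nll_2d(
        lambda p: -float(np.sum(stats.weibull_min.logpdf(x, p[0], scale=p[1]))),
        np.array([shape, scale]),
    )
    return np.array([shape, scale]), se, ll


def fit_exponential(sample: Sample) -> tuple[np.ndarray, np.ndarray, float]:
    """Exponential rate MLE = 1/mean; SE = rate/sqrt(n) (exact Fisher)."""
    x = sample.values
    rate = 1.0 / float(np.mean(x))
    ll = x.size * np.log(rate) - rate * float(np.sum(x))
    return np.array([rate]), np.array([rate / np.sqrt(x.size)]), float(ll)


def _se_from_nll_2d(nll, p_hat: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Observed-information SEs from a central-difference Hessian of the nll."""
    m = p_hat.size
    H = np.zeros((m, m))
    h = rel_step * np.abs(p_hat)
    for i in range(m):
        for j in range(i, m):
            pp = p_hat.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = p_hat.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = p_hat.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = p_hat.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            H[i, j] = H[j, i] = (nll(pp) - nll(pm) - nll(mp) + nll(mm)) / (4 * h[i] * h[j])
    try:
        var = np.diag(np.linalg.inv(H))
        if np.any(var <= 0):
            raise np.linalg.LinAlgError
        return np.sqrt(var)
    except np.linalg.LinAlgError:
        return np.full(m, np.nan)


def fit_baselines(sample: Sample) -> list[tuple[str, np.ndarray, np.ndarray, GofReport]]:
    """Fit EE, Weibull and exponential; return (name, est, se, report) rows."""
    out = []
    ee_est, ee_se, ee_ll = fit_ee(sample)
    out.append((
        "EE", ee_est, ee_se,
        gof_report(sample, lambda x: np.asarray(ee_cdf(x, *ee_est)), "EE", 2, ee_ll),
    ))
    w_est, w_se, w_ll = fit_weibull(sample)
    out.append((
        "Weibull", w_est, w_se,
        gof_report(
            sample,
            lambda x: stats.weibull_min.cdf(x, w_est[0], scale=w_est[1]),
            "Weibull", 2, w_ll,
        ),
    ))
    e_est, e_se, e_ll = fit_exponential(sample)
    out.append((
        "Exponential", e_est, e_se,
        gof_report(sample, lambda x: -np.expm1(-e_est[0] * np.asarray(x)),
                   "Exponential", 1, e_ll),
    ))
    return out


def compare_models(sample: Sample, starts: int = 25, seed: int = 0) -> pd.DataFrame:
    """Fit GMO-EE (MLE) plus the three baselines and tabulate the reports."""
    fr = fit_mle(sample, starts=starts, seed=seed, compute_se=False)
    reports = [gof_report(sample, fr.eta_hat, "GMO-EE", 4, fr.objective_value)]
    reports += [row[3] for row in fit_baselines(sample)]
    return report_table(reports)


def report_table(reports: list[GofReport]) -> pd.DataFrame:
    """One row per model, columns matching the standard comparison layout."""
    return pd.DataFrame(
        [
            {
                "model": r.model_name,
                "-2log": r.neg2loglik,
                "AIC": r.aic,
                "AD": r.ad,
                "CvM": r.cvm,
                "K-S": r.ks,
                "p(AD)": r.p_ad,
                "p(CvM)": r.p_cvm,
                "p(K-S)": r.p_ks,
            }
            for r in reports
        ]
    )
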
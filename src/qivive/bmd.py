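"""Benchmark-dose analysis of continuous dose-response data.

Fits the three-parameter increasing exponential model for continuous
endpoints,

    y(x) = a * exp(b * x**d),        a > 0, b >= 0, 1 <= d <= 4,

by maximum likelihood (lognormal errors by default, which is standard for
positive-valued endpoints such as uterus weight; normal errors optional),
and reports the benchmark dose for a benchmark response (BMR) defined as a
relative change over the control:

    a * exp(b * BMD**d) = a * (1 + BMR)   =>   BMD = (ln(1 + BMR) / b)**(1/d).

Confidence bounds (BMDL/BMDU) come from the profile likelihood after
reparameterizing so the BMD itself is a model parameter, with a chi-square
cutoff at the configured level (default: 90% two-sided profile interval,
i.e. a one-sided 95% BMDL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .errors import DataError, DomainError, FitError
from .reverse_dosimetry import DoseResponse

__all__ = [
    "ExponentialFit",
    "BMDResult",
    "fit_exponential",
    "bmd_at_bmr",
    "bmd_confidence_bounds",
    "bmd_analysis",
]

_D_BOUNDS = (1.0, 4.0)


@dataclass
class ExponentialFit:
    """ML fit of y = a*exp(b*x^d)."""

    a: float
    b: float
    d: float
    sigma: float  # residual sd on the fitting scale
    loglik: float
    error_model: str
    converged: bool
    flat: bool  # True when the data show no dose-related increase (b ~ 0)


@dataclass
class BMDResult:
    """Benchmark dose and its profile-likelihood confidence bounds (mg/kg bw)."""

    bmd10: Optional[float]
    bmdl10: Optional[float]
    bmdu10: Optional[float]
    fit: ExponentialFit
    bmr: float = 0.10
    level: float = 0.90  # two-sided profile level

    @property
    def accepted(self) -> bool:
        return self.fit.converged and not self.fit.flat and self.bmd10 is not None


def _prepare(data: DoseResponse, error_model: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(data.doses, float)
    y = np.asarray(data.responses, float)
    if np.unique(x).size < 4:
        raise DataError("BMD fitting requires at least 4 dose groups")
    if not np.any(x == 0):
        raise DataError("BMD fitting requires a control (dose 0) group")
    if error_model == "lognormal" and np.any(y <= 0):
        raise DataError("lognormal errors require strictly positive responses")
    return x, y


def _neg_loglik_factory(x: np.ndarray, y: np.ndarray, error_model: str):
    """Negative log-likelihood in (ln a, b, d), profiled over sigma."""
    n = y.size
    log_y = np.log(y) if error_model == "lognormal" else None

    def nll(theta: np.ndarray) -> float:
        ln_a, b, d = theta
        mean_log = ln_a + b * np.power(x, d)
        if error_model == "lognormal":
            resid = log_y - mean_log
            jacobian = log_y.sum()  # d(log y)/dy terms of the lognormal density
        else:
            # clip to keep intermediate overflow out of the line search
            resid = y - np.exp(np.clip(mean_log, None, 50.0))
            jacobian = 0.0
        sse = float(resid @ resid)
        sigma2 = max(sse / n, 1e-300)
        return 0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0) + jacobian

    return nll


def fit_exponential(data: DoseResponse, error_model: str = "lognormal") -> ExponentialFit:
    """Maximum-likelihood fit of the exponential model to a dose-response set.

    Flat data (no dose-related increase) yield a converged fit flagged
    ``flat``; no BMD is reported for such a fit.
    """
    if error_model not in ("lognormal", "normal"):
        raise DomainError(f"error_model must be 'lognormal' or 'normal', got {error_model!r}")
    x, y = _prepare(data, error_model)
    # fit on the unit dose axis u = x/x_ref so the optimizer sees O(1)
    # parameters regardless of the dose units; results are exactly
    # equivariant under rescaling of the dose axis
    x_ref = float(x.max())
    u = x / x_ref
    nll = _neg_loglik_factory(u, y, error_model)

    # starting values: control mean for a; b from the endpoint response at d=1
    ctrl = float(np.mean(y[x == 0]))
    top_y = float(np.mean(y[x == x.max()]))
    b0 = max(math.log(max(top_y / max(ctrl, 1e-12), 1.0 + 1e-9)), 1e-9)
    best = None
    for d0 in (1.0, 2.0):
        res = optimize.minimize(
            nll,
            x0=np.array([math.log(max(ctrl, 1e-12)), b0, d0]),
            method="L-BFGS-B",
            bounds=[(None, None), (0.0, None), _D_BOUNDS],
        )
        # simplex polish: escapes gradient-tolerance stalls near the bounds
        res = optimize.minimize(
            nll, res.x, method="Nelder-Mead",
            bounds=[(None, None), (0.0, None), _D_BOUNDS],
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    ln_a, b_u, d = best.x
    b = b_u / x_ref**d
    mean_log = ln_a + b_u * np.power(u, d)
    if error_model == "lognormal":
        resid = np.log(y) - mean_log
    else:
        resid = y - np.exp(mean_log)
    sigma = float(np.sqrt(np.mean(resid**2)))
    flat = b_u < 1e-8  # response change over the tested dose range ~ b_u
    return ExponentialFit(
        a=float(math.exp(ln_a)),
        b=float(b),
        d=float(d),
        sigma=sigma,
        loglik=float(-best.fun),
        error_model=error_model,
        converged=bool(best.success),
        flat=bool(flat),
    )


def bmd_at_bmr(fit_or_params, bmr: float = 0.10) -> float:
    """Closed-form BMD: (ln(1 + BMR) / b) ** (1/d).

    Accepts an :class:`ExponentialFit` or an (a, b, d) tuple. BMR 0 gives 0;
    b <= 0 leaves the BMD undefined.
    """
    if isinstance(fit_or_params, ExponentialFit):
        b, d = fit_or_params.b, fit_or_params.d
    else:
        _, b, d = fit_or_params
    if bmr < 0:
        raise DomainError(f"bmr must be >= 0, got {bmr}")
    if bmr == 0:
        return 0.0
    if b <= 0:
        raise DomainError("BMD is undefined for b <= 0 (no dose-related increase)")
    return (math.log1p(bmr) / b) ** (1.0 / d)


def _profile_nll(bmd: float, x, y, error_model: str, bmr: float) -> float:
    """Profile negative log-likelihood with BMD as a model parameter.

    For fixed BMD, b = ln(1+BMR)/BMD^d, and (ln a, d) are re-optimized.
    """
    x_ref = float(x.max())
    u = x / x_ref
    bmd_u = bmd / x_ref
    nll = _neg_loglik_factory(u, y, error_model)
    lbmr = math.log1p(bmr)

    def constrained(theta2: np.ndarray) -> float:
        ln_a, d = theta2
        b_u = lbmr / bmd_u**d
        return nll(np.array([ln_a, b_u, d]))

    ctrl = float(np.mean(y[x == 0]))
    best = None
    for d0 in (1.0, 2.0):
        res = optimize.minimize(
            constrained,
            x0=np.array([math.log(max(ctrl, 1e-12)), d0]),
            method="L-BFGS-B",
            bounds=[(None, None), _D_BOUNDS],
        )
        res = optimize.minimize(
            constrained, res.x, method="Nelder-Mead",
            bounds=[(None, None), _D_BOUNDS],
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(best.fun)


def bmd_confidence_bounds(
    data: DoseResponse,
    fit: ExponentialFit,
    bmr: float = 0.10,
    level: float = 0.90,
) -> tuple[Optional[float], Optional[float]]:
    """Profile-likelihood BMDL/BMDU at the given two-sided level.

    An unbounded profile (the likelihood never crosses the cutoff within a
    wide search range) is reported as an explicit open end (None).
    """
    if not fit.converged or fit.flat:
        raise FitError("confidence bounds require a converged, non-flat fit")
    x, y = _prepare(data, fit.error_model)
    bmd = bmd_at_bmr(fit, bmr)
    cutoff = stats.chi2.ppf(level, df=1)
    nll_hat = -fit.loglik

    def deviance(candidate: float) -> float:
        return 2.0 * (_profile_nll(candidate, x, y, fit.error_model, bmr) - nll_hat) - cutoff

    def search(direction: int) -> Optional[float]:
        factor = 1.5
        inner = bmd
        for _ in range(60):
            outer = inner * factor if direction > 0 else inner / factor
            if deviance(outer) > 0:
                lo, hi = (inner, outer) if direction > 0 else (outer, inner)
                return float(optimize.brentq(deviance, lo, hi, rtol=1e-6))
            inner = outer
            if direction > 0 and inner > bmd * 1e6:
                return None
            if direction < 0 and inner < bmd * 1e-6:
                return None
        return None  # pragma: no cover

    bmdl = search(-1)
    bmdu = search(+1)
    if bmdl is not None and bmdl > bmd:  # numerical guard
        bmdl = bmd
    if bmdu is not None and bmdu < bmd:
        bmdu = bmd
    return bmdl, bmdu


def bmd_analysis(
    data: DoseResponse,
    error_model: str = "lognormal",
    bmr: float = 0.10,
    level: float = 0.90,
) -> BMDResult:
    """Fit the exponential model and report BMD10/BMDL10/BMDU10.

    Mirrors the reporting convention of continuous-endpoint BMD software:
    values are only reported when the model fit is accepted (converged and
    showing a dose-related increase).
    """
    fit = fit_exponential(data, error_model)
    if not fit.converged or fit.flat:
        return BMDResult(bmd10=None, bmdl10=None, bmdu10=None, fit=fit, bmr=bmr, level=level)
    bmd = bmd_at_bmr(fit, bmr)
    bmdl, bmdu = bmd_confidence_bounds(data, fit, bmr, level)
    return BMDResult(bmd10=bmd, bmdl10=bmdl, bmdu10=bmdu, fit=fit, bmr=bmr, level=level)
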
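"""In vitro concentration-response curves: normalization and Hill fitting.

Raw assay responses (proliferation, luciferase or beta-galactosidase
induction) are expressed as a percentage of the maximum response the
compound itself induced in that assay, and the normalized curve is fitted
with a symmetrical sigmoid (Hill model) on log concentration:

    y(c) = bottom + (top - bottom) / (1 + (EC50 / c)**slope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError, FitError

__all__ = ["HillFit", "ConcResponse", "normalize_to_percent_max", "fit_hill", "hill"]


def hill(c: np.ndarray, bottom: float, top: float, log10_ec50: float, slope: float) -> np.ndarray:
    """Symmetrical sigmoid on log concentration; EC50 parameterized as log10."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (log10_ec50 - np.log10(c))))


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters (responses in %, EC50 in M)."""

    bottom: float
    top: float
    ec50: float
    slope: float
    residual_ss: float

    def predict(self, c: np.ndarray) -> np.ndarray:
        return hill(c, self.bottom, self.top, np.log10(self.ec50), self.slope)


@dataclass
class ConcResponse:
    """A concentration-response curve (concentrations in M)."""

    concentrations: np.ndarray
    response_pct: np.ndarray
    raw_response: Optional[np.ndarray] = None
    source: str = ""
    hill_fit: Optional[HillFit] = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.response_pct = np.asarray(self.response_pct, dtype=float)
        if self.concentrations.shape != self.response_pct.shape:
            raise DataError("concentrations and responses must have matching shapes")
        if np.any(self.concentrations <= 0):
            raise DataError("concentrations must be > 0")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, source: str = "") -> "ConcResponse":
        """Normalize a raw table with columns conc_M, response."""
        missing = {"conc_M", "response"} - set(frame.columns)
        if missing:
            raise DataError(f"concentration-response table is missing columns: {sorted(missing)}")
        return normalize_to_percent_max(
            frame["conc_M"].to_numpy(float), frame["response"].to_numpy(float), source=source
        )


def normalize_to_percent_max(
    concentrations: np.ndarray, raw_response: np.ndarray, source: str = ""
) -> ConcResponse:
    """Scale responses so the maximum observed response is exactly 100%."""
    concentrations = np.asarray(concentrations, dtype=float)
    raw = np.asarray(raw_response, dtype=float)
    peak = raw.max() if raw.size else 0.0
    if not peak > 0:
        raise DataError("normalization requires at least one positive response")
    return ConcResponse(
        concentrations=concentrations,
        response_pct=100.0 * raw / peak,
        raw_response=raw,
        source=source,
    )


def fit_hill(curve: ConcResponse, maxfev: int = 20000) -> HillFit:
    """Least-squares Hill fit of a normalized curve.

    Starting values: bottom = min response, top = max response, EC50 at the
    geometric mid-concentration, slope 1; EC50 is fitted on the log10 scale
    for stability. The fit is stored on the curve and returned.
    """
    c = curve.concentrations
    y = curve.response_pct
    if c.size < 4:
        raise DataError("Hill fitting requires at least 4 concentration points")
    logc = np.log10(c)
    p0 = [float(y.min()), float(y.max()), float(logc.mean()), 1.0]
    try:
        popt, _ = curve_fit(hill, c, y, p0=p0, maxfev=maxfev)
    except RuntimeError as exc:  # pragma: no cover - rare non-convergence path
        raise FitError(
            f"Hill fit did not converge (starting values bottom={p0[0]:.3g}, "
            f"top={p0[1]:.3g}, log10 EC50={p0[2]:.3g}, slope=1): {exc}"
        ) from exc
    bottom, top, log_ec50, slope = popt
    residual_ss = float(np.sum((hill(c, *popt) - y) ** 2))
    fit = HillFit(
        bottom=float(bottom),
        top=float(top),
        ec50=float(10.0**log_ec50),
        slope=float(slope),
        residual_ss=residual_ss,
    )
    curve.hill_fit = fit
    return fit
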
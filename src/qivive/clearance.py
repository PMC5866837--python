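"""Intrinsic clearance from substrate-depletion time courses.

In the substrate-depletion approach the parent compound is incubated with
liver S9 fraction and co-factors at a concentration well below Km, so its
disappearance is first order. The log concentration ratio against the
co-factor-free control, ln(C_compound/C_control), declines linearly with
time; the negative slope of the linear part is the elimination rate constant
k (1/min), and

    CLint,in vitro (uL/min/mg protein) = V (uL) / P (mg) * k

with V the incubation volume and P the protein amount. CLint is scaled to
the whole liver through the S9 protein content per kg liver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DomainError
from .units import clint_to_liver_clearance_l_per_h

__all__ = [
    "DEPLETION_TIME_GRID_MIN",
    "DepletionSeries",
    "ClintResult",
    "fit_depletion",
    "clint_invitro",
    "sum_pathway_clints",
    "scale_clint_to_liver",
    "check_substrate_below_km",
]

#: Incubation sampling grid (minutes) used throughout: termination points at
#: 0, 1, 2, 3, 4, 5, 7, 8.5, 10, 15, 20, 25, 30 and 45 min.
DEPLETION_TIME_GRID_MIN: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 7, 8.5, 10, 15, 20, 25, 30, 45)

#: Minimum window length and r^2 for the "linear part" search.
_MIN_WINDOW = 5
_MIN_R2 = 0.9


@dataclass
class DepletionSeries:
    """A substrate-depletion experiment: concentration ratios over time.

    ``ratios`` has shape (n_replicates, n_times); each entry is
    C_compound/C_control at that time, so the series starts near 1.
    """

    times: np.ndarray
    ratios: np.ndarray
    incubation_volume_ul: float = 200.0
    protein_mg: float = 0.1
    substrate_conc_um: float = 3.0
    km_lower_bound_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratios = np.atleast_2d(np.asarray(self.ratios, dtype=float))
        if self.times.ndim != 1 or self.times.size < 2:
            raise DataError("times must be a 1-D grid with at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        if self.times[0] != 0:
            raise DataError("the first sampling time must be 0")
        if self.ratios.shape[1] != self.times.size:
            raise DataError(
                f"ratios has {self.ratios.shape[1]} time columns, expected {self.times.size}"
            )
        if np.any(~np.isfinite(self.ratios)) or np.any(self.ratios <= 0):
            raise DataError("all concentration ratios must be finite and > 0")
        if not self.incubation_volume_ul > 0 or not self.protein_mg > 0:
            raise DomainError("incubation volume and protein amount must be > 0")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **metadata) -> "DepletionSeries":
        """Build from a long-form table with columns time_min, replicate, ratio."""
        required = {"time_min", "replicate", "ratio"}
        missing = required - set(frame.columns)
        if missing:
            raise DataError(f"depletion table is missing columns: {sorted(missing)}")
        wide = frame.pivot_table(index="replicate", columns="time_min", values="ratio")
        if wide.isna().any().any():
            raise DataError("depletion table has missing time points for some replicates")
        return cls(times=wide.columns.to_numpy(float), ratios=wide.to_numpy(float), **metadata)


@dataclass
class ClintResult:
    """Fitted elimination rate and the intrinsic clearance it implies."""

    k: float  # 1/min
    clint_invitro: float  # uL/min/mg protein
    window: tuple[int, int]  # [start, stop) indices of the fitted points
    fit_r2: float
    no_depletion: bool = False
    log_intercept: float = 0.0


def _linfit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(t, y)
    return res.slope, res.intercept, res.rvalue**2


def fit_depletion(series: DepletionSeries) -> ClintResult:
    """Elimination rate constant k and CLint from a depletion series.

    Replicates are pooled by averaging ln(ratio) per time point. The linear
    part is found by scanning contiguous windows anchored at t=0: the longest
    window of at least 5 points with r^2 >= 0.9 is used; if none qualifies the
    whole series is fitted. k is the negative slope, floored at 0 (a flat or
    rising series is flagged as showing no depletion).
    """
    if series.times.size < 4:
        raise DataError("fit_depletion requires at least 4 time points")
    log_mean = np.log(series.ratios).mean(axis=0)
    t = series.times
    n = t.size

    best: Optional[tuple[int, float, float, float]] = None  # (stop, slope, intercept, r2)
    for stop in range(n, _MIN_WINDOW - 1, -1):
        slope, intercept, r2 = _linfit(t[:stop], log_mean[:stop])
        if r2 >= _MIN_R2:
            best = (stop, slope, intercept, r2)
            break
    if best is None:
        stop = n
        slope, intercept, r2 = _linfit(t, log_mean)
    else:
        stop, slope, intercept, r2 = best

    k = float(-slope)
    no_depletion = k <= 0
    k = max(k, 0.0)
    return ClintResult(
        k=k,
        clint_invitro=clint_invitro(k, series.incubation_volume_ul, series.protein_mg),
        window=(0, int(stop)),
        fit_r2=float(r2),
        no_depletion=bool(no_depletion),
        log_intercept=float(intercept),
    )


def clint_invitro(k: float, volume_ul: float, protein_mg: float) -> float:
    """CLint,in vitro (uL/min/mg protein) = V/P * k."""
    if not volume_ul > 0 or not protein_mg > 0:
        raise DomainError("volume and protein must be > 0")
    if k < 0:
        raise DomainError(f"k must be >= 0, got {k}")
    return volume_ul / protein_mg * k


def sum_pathway_clints(pathway_values: Iterable[Optional[float]]) -> float:
    """Total CLint as the sum over metabolic pathways.

    Pathways for which no clearance could be derived (e.g. an incubation
    showing no depletion) are passed as None and contribute 0.
    """
    total = 0.0
    for value in pathway_values:
        if value is None:
            continue
        if value < 0:
            raise DataError(f"pathway CLint must be >= 0, got {value}")
        total += value
    return total


def scale_clint_to_liver(
    clint_invitro_ul_min_mg: float,
    s9_protein_g_per_kg: float = 87.0,
    liver_mass_kg: float = 0.0085,
) -> float:
    """Whole-liver clearance (L/h) from CLint per mg S9 protein.

    Default S9 protein content: 87 g per kg liver.
    """
    if clint_invitro_ul_min_mg < 0:
        raise DomainError(f"clint must be >= 0, got {clint_invitro_ul_min_mg}")
    if not s9_protein_g_per_kg > 0 or not liver_mass_kg > 0:
        raise DomainError("S9 protein content and liver mass must be > 0")
    return clint_to_liver_clearance_l_per_h(
        clint_invitro_ul_min_mg, s9_protein_g_per_kg, liver_mass_kg
    )


def check_substrate_below_km(series: DepletionSeries) -> Optional[bool]:
    """Whether the incubation concentration is below the lowest reported Km.

    First-order depletion requires substrate << Km. Returns True/False when a
    Km lower bound is available, None when it is not (undetermined).
    """
    if series.km_lower_bound_um is None:
        return None
    return bool(series.substrate_conc_um < series.km_lower_bound_um)
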
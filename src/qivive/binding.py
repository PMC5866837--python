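"""Fraction unbound from rapid-equilibrium-dialysis (RED) data.

The RED device has a plasma chamber (serum or assay medium spiked with the
compound) and a buffer chamber separated by a dialysis membrane. At
equilibrium only the unbound compound has equilibrated across the membrane,
so

    fub = C_buffer / C_plasma.

Only the unbound compound is assumed to drive the effect, so a nominal
in vitro concentration maps onto the nominal blood concentration giving the
same unbound level:

    C_in vivo = C_in vitro * fub,in vitro / fub,in vivo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

__all__ = ["RedMeasurement", "fub_from_red", "correct_concentration", "summarize_fub"]

#: Blood:plasma concentration ratio. The serum fraction unbound is used
#: directly as the blood free fraction, i.e. this ratio is assumed 1;
#: override here if a compound partitions appreciably into blood cells.
BLOOD_PLASMA_RATIO = 1.0


@dataclass(frozen=True)
class RedMeasurement:
    """One RED replicate: post-dialysis chamber concentrations (uM)."""

    conc_buffer: float
    conc_plasma: float
    matrix: str = "serum"

    def __post_init__(self) -> None:
        if self.conc_buffer < 0:
            raise DataError(f"buffer concentration must be >= 0, got {self.conc_buffer}")


def fub_from_red(measurement: RedMeasurement) -> float:
    """Fraction unbound = buffer / plasma chamber concentration, in (0, 1].

    Ratios slightly above 1 (measurement noise in a protein-poor matrix) are
    clipped to 1 with a warning. A zero buffer concentration is reported as an
    error rather than silently returned as fub = 0, since it indicates the
    compound was not recovered.
    """
    if not measurement.conc_plasma > 0:
        raise DataError("plasma-chamber concentration must be > 0")
    if measurement.conc_buffer <= 0:
        raise DataError(
            "buffer-chamber concentration is 0: compound not detected, fub undetermined"
        )
    ratio = measurement.conc_buffer / measurement.conc_plasma
    if ratio > 1:
        warnings.warn(
            f"raw fub {ratio:.3f} > 1 in matrix {measurement.matrix!r}; clipped to 1",
            stacklevel=2,
        )
        ratio = 1.0
    return ratio


def correct_concentration(c_invitro: float, fub_invitro: float, fub_invivo: float) -> float:
    """Nominal blood concentration with the same unbound level as the assay.

    C_in vivo = C_in vitro * fub,in vitro / fub,in vivo; linear in the
    concentration. Units are preserved (uM in, uM out).
    """
    for label, frac in [("fub_invitro", fub_invitro), ("fub_invivo", fub_invivo)]:
        if not (0 < frac <= 1):
            raise DomainError(f"{label} must be in (0, 1], got {frac}")
    if c_invitro < 0:
        raise DomainError(f"c_invitro must be >= 0, got {c_invitro}")
    return c_invitro * fub_invitro / fub_invivo


def summarize_fub(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd fraction unbound per matrix from a replicate table.

    Expects columns matrix, replicate, conc_buffer, conc_plasma; returns one
    row per matrix with fub_mean, fub_sd and n.
    """
    required = {"matrix", "replicate", "conc_buffer", "conc_plasma"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"RED table is missing columns: {sorted(missing)}")
    rows = []
    for matrix, group in frame.groupby("matrix", sort=False):
        fubs = [
            fub_from_red(RedMeasurement(row.conc_buffer, row.conc_plasma, str(matrix)))
            for row in group.itertuples()
        ]
        rows.append(
            {
                "matrix": matrix,
                "fub_mean": float(np.mean(fubs)),
                "fub_sd": float(np.std(fubs, ddof=1)) if len(fubs) > 1 else 0.0,
                "n": len(fubs),
            }
        )
    return pd.DataFrame(rows)
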
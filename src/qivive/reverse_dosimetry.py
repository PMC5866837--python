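"""Reverse dosimetry: from target blood concentrations back to oral doses.

The uterotrophic response is assumed to track the peak blood concentration
(Cmax) of the parent compound. Reverse dosimetry therefore finds the oral
dose whose simulated Cmax equals a target nominal blood concentration, and
applies this per concentration of an in vitro concentration-response curve
(after the free-fraction correction) to obtain a predicted in vivo
dose-response curve. Because every process in the kinetic model is first
order, Cmax is proportional to dose and the search reduces to one division;
a bracketed root find is kept as a fallback for non-linear model variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .binding import correct_concentration
from .chem_params import ChemicalParams, PartitionCoefficients
from .errors import DomainError, SimulationError
from .pbk_core import ExposureScenario, PhysiologyParams, SolverSettings, simulate
from .response_curves import ConcResponse
from .units import molar_to_umolar

__all__ = ["DoseResponse", "DoseFinder", "find_oral_dose", "translate_curve"]

_LINEARITY_RTOL = 1e-3  # the two probe doses must agree on cmax/dose to 0.1%


@dataclass
class DoseResponse:
    """Dose-response data: doses in mg/kg bw, responses in the stated units."""

    doses: np.ndarray
    responses: np.ndarray
    source: str = ""
    response_units: str = "% of maximum"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise DomainError("doses and responses must have matching shapes")
        if np.any(self.doses < 0):
            raise DomainError("doses must be >= 0")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"dose_mg_per_kg": self.doses, "response": self.responses, "source": self.source}
        )


class DoseFinder:
    """Inverts the Cmax(dose) relation for one chemical/physiology setting.

    Runs the kinetic model at two probe doses, verifies dose-proportionality
    (all-first-order model), and then maps target concentrations to doses by
    scaling. If the proportionality check fails the finder falls back to a
    bracketed root search per target.
    """

    def __init__(
        self,
        chem: ChemicalParams,
        pc: Optional[PartitionCoefficients],
        phys: PhysiologyParams,
        duration_h: float = 24.0,
        solver: SolverSettings = SolverSettings(),
        probe_doses: tuple[float, float] = (1.0, 10.0),
    ) -> None:
        self._chem, self._pc, self._phys = chem, pc, phys
        self._duration, self._solver = duration_h, solver
        lo, hi = probe_doses
        cmax_lo = self._cmax(lo)
        cmax_hi = self._cmax(hi)
        if cmax_lo <= 0 or cmax_hi <= 0:
            raise SimulationError("probe simulations produced non-positive Cmax")
        self.cmax_per_dose = cmax_lo / lo
        self.is_linear = abs(cmax_hi / hi / self.cmax_per_dose - 1.0) < _LINEARITY_RTOL

    def _cmax(self, dose: float) -> float:
        scenario = ExposureScenario(route="oral", dose_mg_per_kg=dose, duration_h=self._duration)
        return simulate(self._chem, self._pc, self._phys, scenario, self._solver).cmax

    def find(self, target_conc_um: float) -> float:
        """Oral dose (mg/kg bw) whose simulated blood Cmax equals the target (uM)."""
        if target_conc_um < 0:
            raise DomainError(f"target concentration must be >= 0, got {target_conc_um}")
        if target_conc_um == 0:
            return 0.0
        if self.is_linear:
            return target_conc_um / self.cmax_per_dose
        return self._bracketed(target_conc_um)

    def _bracketed(self, target: float) -> float:
        from scipy.optimize import brentq

        guess = target / self.cmax_per_dose
        lo, hi = guess / 100.0, guess * 100.0
        f = lambda d: self._cmax(d) - target
        f_lo, f_hi = f(lo), f(hi)
        if f_lo * f_hi > 0:
            raise SimulationError(
                f"target Cmax {target} uM not bracketed in [{lo}, {hi}] mg/kg "
                f"(f(lo)={f_lo:.3g}, f(hi)={f_hi:.3g})"
            )
        return float(brentq(f, lo, hi, rtol=1e-6))


def find_oral_dose(
    target_conc_um: float,
    chem: ChemicalParams,
    pc: Optional[PartitionCoefficients],
    phys: PhysiologyParams,
    duration_h: float = 24.0,
    solver: SolverSettings = SolverSettings(),
) -> float:
    """One-shot wrapper around :class:`DoseFinder` for a single target."""
    return DoseFinder(chem, pc, phys, duration_h, solver).find(target_conc_um)


def translate_curve(
    curve: ConcResponse,
    assay_fub: float,
    fub_serum: float,
    chem: ChemicalParams,
    pc: Optional[PartitionCoefficients],
    phys: PhysiologyParams,
    duration_h: float = 24.0,
    solver: SolverSettings = SolverSettings(),
    source: Optional[str] = None,
) -> DoseResponse:
    """Translate an in vitro concentration-response curve into doses.

    Per concentration: the free-fraction-corrected nominal blood target is
    C_in vitro * fub,assay / fub,serum, and the dose is the one whose
    simulated Cmax reaches that target. Responses (already in % of the
    compound's maximum) are carried over unchanged.
    """
    finder = DoseFinder(chem, pc, phys, duration_h, solver)
    targets = np.array(
        [
            correct_concentration(molar_to_umolar(c), assay_fub, fub_serum)
            for c in curve.concentrations
        ]
    )
    doses = np.array([finder.find(t) for t in targets])
    return DoseResponse(
        doses=doses,
        responses=curve.response_pct.copy(),
        source=source if source is not None else curve.source,
    )
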
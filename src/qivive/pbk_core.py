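"""Minimal physiologically based kinetic (PBK) model of a chemical in the rat.

Compartments: blood, liver, fat, richly perfused and slowly perfused tissue,
plus a stomach and a small intestine divided into 7 sub-compartments that
carry the oral dose down the gut. All tissue exchange is flow-limited,

    dA_T/dt = Q_T * (C_blood - C_T / P_T),

with Q_T the tissue blood flow, C_T = A_T/V_T and P_T the tissue:blood
partition coefficient. An oral dose enters the stomach and empties first
order into intestinal sub-compartment 1; lumen contents move between
sub-compartments at the transfer rate kin, and whatever leaves sub-compartment
7 is counted as unabsorbed. Absorption from each sub-compartment goes to the
liver (portal delivery) at rate Papp,in vivo * SAin * C_lumen. Hepatic
metabolism is the only clearance process, at rate CL_liver * C_liver/P_liver
(venous-equilibration convention on the total liver concentration, isolated
in :func:`_hepatic_elimination_rate` so the convention can be switched). An
IV dose is a bolus into blood.

Every process is first order, so the whole system is linear in the dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .chem_params import ChemicalParams, PartitionCoefficients
from .errors import ConfigurationError, DomainError, SimulationError
from .units import mg_per_kg_to_umol

__all__ = [
    "PhysiologyParams",
    "ExposureScenario",
    "SolverSettings",
    "SimulationResult",
    "simulate",
    "cmax_auc",
]

N_GUT = 7
_COMPARTMENTS = (
    "blood",
    "liver",
    "fat",
    "richly_perfused",
    "slowly_perfused",
    "stomach",
    *[f"lumen_{i + 1}" for i in range(N_GUT)],
    "unabsorbed",
    "metabolized",
)
_IDX = {name: i for i, name in enumerate(_COMPARTMENTS)}
_N_STATE = len(_COMPARTMENTS)

MASS_BALANCE_TOL = 1e-6


@dataclass
class PhysiologyParams:
    """Anatomical and physiological constants of the adult rat.

    Volume fractions are fractions of body weight (tissue density taken as
    1 kg/L); the slowly perfused fraction is the remainder of the perfused
    body, and the slowly perfused flow fraction the remainder of cardiac
    output, so the sum constraints hold by construction.
    """

    body_weight: float = 0.25  # kg
    vlc: float = 0.034  # liver, fraction of bw
    vfc: float = 0.07  # fat
    vbc: float = 0.074  # blood
    vrc: float = 0.05  # richly perfused tissue
    perfused_fraction: float = 0.91  # perfused share of bw; remainder unperfused
    cardiac_output_coeff: float = 15.0  # L/h/kg^0.74
    qlc: float = 0.25  # liver share of cardiac output
    qfc: float = 0.07  # fat share
    qrc: float = 0.51  # richly perfused share
    n_gut: int = N_GUT
    vin_ml: float = 1.5  # lumen fluid volume per intestinal sub-compartment, mL
    sain_cm2: float = 16.1  # absorptive surface area per sub-compartment, cm^2
    kin_per_h: float = 4.667  # lumen-to-lumen transfer rate, 1/h (~1.5 h transit)
    gastric_emptying_per_h: float = 5.5  # 1/h (~7.5 min half-time, aqueous gavage)
    s9_protein_g_per_kg: float = 87.0  # g S9 protein per kg liver

    def __post_init__(self) -> None:
        if self.n_gut != N_GUT:
            raise ConfigurationError(f"the intestine model is fixed at {N_GUT} sub-compartments")
        positives = {
            "body_weight": self.body_weight,
            "vlc": self.vlc,
            "vfc": self.vfc,
            "vbc": self.vbc,
            "vrc": self.vrc,
            "qlc": self.qlc,
            "qfc": self.qfc,
            "qrc": self.qrc,
            "vin_ml": self.vin_ml,
            "sain_cm2": self.sain_cm2,
            "s9_protein_g_per_kg": self.s9_protein_g_per_kg,
            "cardiac_output_coeff": self.cardiac_output_coeff,
        }
        for name, value in positives.items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be > 0, got {value}")
        for name, value in [
            ("kin_per_h", self.kin_per_h),
            ("gastric_emptying_per_h", self.gastric_emptying_per_h),
        ]:
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        if not self.vsc > 0:
            raise ConfigurationError(
                "tissue volume fractions exceed the perfused fraction of the body"
            )
        if not self.qsc > 0:
            raise ConfigurationError("tissue flow fractions exceed the cardiac output")

    @property
    def vsc(self) -> float:
        """Slowly perfused volume fraction (remainder of the perfused body)."""
        return self.perfused_fraction - self.vlc - self.vfc - self.vbc - self.vrc

    @property
    def qsc(self) -> float:
        """Slowly perfused flow fraction (remainder of cardiac output)."""
        return 1.0 - self.qlc - self.qfc - self.qrc

    @property
    def cardiac_output(self) -> float:
        """Cardiac output, L/h (allometric in body weight)."""
        return self.cardiac_output_coeff * self.body_weight**0.74

    @property
    def liver_mass_kg(self) -> float:
        return self.vlc * self.body_weight


@dataclass
class ExposureScenario:
    """A single-dose exposure: route, dose (mg/kg bw) and output grid (h)."""

    route: str = "oral"
    dose_mg_per_kg: float = 0.0
    duration_h: float = 24.0
    n_output: int = 481

    def __post_init__(self) -> None:
        if self.route not in ("oral", "iv"):
            raise ConfigurationError(f"route must be 'oral' or 'iv', got {self.route!r}")
        if self.dose_mg_per_kg < 0:
            raise DomainError(f"dose must be >= 0, got {self.dose_mg_per_kg}")
        if not self.duration_h > 0:
            raise DomainError("duration must be > 0")

    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.duration_h, self.n_output)


@dataclass(frozen=True)
class SolverSettings:
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-12


@dataclass
class SimulationResult:
    """Time-resolved output of one kinetic simulation."""

    times: np.ndarray  # h
    amounts: pd.DataFrame  # umol, one column per compartment
    conc_blood: np.ndarray  # uM
    dose_umol: float
    cmax: float  # uM
    tmax: float  # h
    auc: float  # uM*h
    mass_balance_error: float  # max relative deviation from the dose

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (time_h, compartment, amount_umol) plus blood conc."""
        frame = self.amounts.copy()
        frame.insert(0, "time_h", self.times)
        frame["conc_blood_um"] = self.conc_blood
        return frame


def _hepatic_elimination_rate(cl_liver: float, a_liver: float, v_liver: float, p_liver: float) -> float:
    """Metabolic elimination rate (umol/h): CL_liver * C_liver / P_liver.

    Venous-equilibration convention on the total (not unbound) liver
    concentration; switch here to change the clearance convention model-wide.
    """
    return cl_liver * (a_liver / v_liver) / p_liver


def simulate(
    chem: ChemicalParams,
    pc: Optional[PartitionCoefficients],
    phys: PhysiologyParams,
    scenario: ExposureScenario,
    solver: SolverSettings = SolverSettings(),
) -> SimulationResult:
    """Integrate the PBK model for one exposure scenario.

    ``pc`` may be None, in which case the chemical's explicit PCs (or its QPPR
    estimate) are used. Amounts are in umol, blood concentration in uM.
    """
    from .clearance import scale_clint_to_liver

    if pc is None:
        pc = chem.resolve_pc()

    bw = phys.body_weight
    vb = phys.vbc * bw
    vl = phys.vlc * bw
    vf = phys.vfc * bw
    vr = phys.vrc * bw
    vs = phys.vsc * bw
    qc = phys.cardiac_output
    ql, qf, qr, qs = (phys.qlc * qc, phys.qfc * qc, phys.qrc * qc, phys.qsc * qc)
    cl_liver = scale_clint_to_liver(
        chem.clint_invitro, phys.s9_protein_g_per_kg, phys.liver_mass_kg
    )
    papp = chem.papp_invivo_cm_per_h()
    abs_coeff = papp * phys.sain_cm2 / phys.vin_ml  # 1/h on each lumen amount
    kin = phys.kin_per_h
    ks = phys.gastric_emptying_per_h

    dose_umol = mg_per_kg_to_umol(scenario.dose_mg_per_kg, bw, chem.mw)
    y0 = np.zeros(_N_STATE)
    if scenario.route == "iv":
        y0[_IDX["blood"]] = dose_umol
    else:
        y0[_IDX["stomach"]] = dose_umol

    i_bl, i_li, i_fa, i_ri, i_sl, i_st = (
        _IDX["blood"], _IDX["liver"], _IDX["fat"],
        _IDX["richly_perfused"], _IDX["slowly_perfused"], _IDX["stomach"],
    )
    i_l1 = _IDX["lumen_1"]
    i_un, i_me = _IDX["unabsorbed"], _IDX["metabolized"]

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        cb = y[i_bl] / vb
        cv_li = y[i_li] / vl / pc.liver
        cv_fa = y[i_fa] / vf / pc.fat
        cv_ri = y[i_ri] / vr / pc.richly_perfused
        cv_sl = y[i_sl] / vs / pc.slowly_perfused

        lumen = y[i_l1 : i_l1 + N_GUT]
        absorbed = abs_coeff * lumen  # umol/h per sub-compartment

        dy[i_fa] = qf * (cb - cv_fa)
        dy[i_ri] = qr * (cb - cv_ri)
        dy[i_sl] = qs * (cb - cv_sl)
        dy[i_li] = (
            ql * (cb - cv_li)
            + absorbed.sum()
            - _hepatic_elimination_rate(cl_liver, y[i_li], vl, pc.liver)
        )
        dy[i_bl] = ql * cv_li + qf * cv_fa + qr * cv_ri + qs * cv_sl - qc * cb
        dy[i_st] = -ks * y[i_st]
        dy[i_l1 : i_l1 + N_GUT] = -kin * lumen - absorbed
        dy[i_l1] += ks * y[i_st]
        dy[i_l1 + 1 : i_l1 + N_GUT] += kin * lumen[:-1]
        dy[i_un] = kin * lumen[-1]
        dy[i_me] = _hepatic_elimination_rate(cl_liver, y[i_li], vl, pc.liver)
        return dy

    times = scenario.times()
    if dose_umol == 0.0:
        amounts = pd.DataFrame(np.zeros((times.size, _N_STATE)), columns=_COMPARTMENTS)
        return SimulationResult(
            times=times, amounts=amounts, conc_blood=np.zeros_like(times),
            dose_umol=0.0, cmax=0.0, tmax=0.0, auc=0.0, mass_balance_error=0.0,
        )

    sol = solve_ivp(
        rhs,
        (0.0, scenario.duration_h),
        y0,
        method=solver.method,
        t_eval=times,
        dense_output=True,
        rtol=solver.rtol,
        atol=solver.atol * max(dose_umol, 1.0),
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    y = sol.y
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite state encountered during integration")

    balance = np.abs(y.sum(axis=0) - dose_umol) / dose_umol
    mass_balance_error = float(balance.max())
    if mass_balance_error > MASS_BALANCE_TOL:
        raise SimulationError(
            f"mass-balance error {mass_balance_error:.3e} exceeds {MASS_BALANCE_TOL:.0e}"
        )

    conc_blood = y[_IDX["blood"]] / vb
    cmax, tmax, auc = cmax_auc(times, conc_blood)
    # refine the peak on the dense solution between the grid neighbours
    j = int(np.argmax(conc_blood))
    lo = times[max(j - 1, 0)]
    hi = times[min(j + 1, times.size - 1)]
    if hi > lo:
        opt = minimize_scalar(
            lambda t: -sol.sol(t)[_IDX["blood"]] / vb,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8 * max(hi, 1.0)},
        )
        if -opt.fun > cmax:
            cmax, tmax = float(-opt.fun), float(opt.x)

    amounts = pd.DataFrame(y.T, columns=_COMPARTMENTS)
    return SimulationResult(
        times=times,
        amounts=amounts,
        conc_blood=conc_blood,
        dose_umol=dose_umol,
        cmax=cmax,
        tmax=tmax,
        auc=auc,
        mass_balance_error=mass_balance_error,
    )


def cmax_auc(times: np.ndarray, conc: np.ndarray) -> tuple[float, float, float]:
    """Peak concentration, its time, and the trapezoid AUC on the grid."""
    times = np.asarray(times, float)
    conc = np.asarray(conc, float)
    if times.size == 0 or conc.size != times.size:
        raise DomainError("cmax_auc requires matching, non-empty time and concentration grids")
    j = int(np.argmax(conc))
    return float(conc[j]), float(times[j]), float(np.trapezoid(conc, times))
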
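"""Local sensitivity analysis of kinetic-model outputs.

Normalized sensitivity coefficients by one-at-a-time forward perturbation:

    SC = (C' - C) / (P' - P) * (P / C),

where C is the model output at the baseline parameter value P and C' the
output after increasing that one parameter to P' (default +5%), all other
parameters held fixed. Forward (not central) differences are used to match
the published procedure. When a perturbed fraction would break a sum
constraint, the slowly perfused remainder compartment absorbs the
difference — that is how :class:`~qivive.pbk_core.PhysiologyParams` derives
its remainder fractions, so the physiological invariants hold for every
perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem_params import ChemicalParams, PartitionCoefficients
from .errors import DomainError
from .pbk_core import ExposureScenario, PhysiologyParams, SolverSettings, simulate

__all__ = ["SensitivityResult", "normalized_sc", "sensitivity_screen", "cmax_model"]

DEFAULT_DELTA = 0.05
DEFAULT_THRESHOLD = 0.1


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    sc: float
    perturbation: float = DEFAULT_DELTA
    output_metric: str = "cmax"


def normalized_sc(
    model: Callable[[Mapping[str, float]], float],
    params: Mapping[str, float],
    parameter: str,
    delta: float = DEFAULT_DELTA,
    output_metric: str = "cmax",
) -> SensitivityResult:
    """Normalized SC of one parameter by a forward +delta perturbation."""
    if not delta > 0:
        raise DomainError(f"delta must be > 0, got {delta}")
    if parameter not in params:
        raise DomainError(f"unknown parameter {parameter!r}")
    baseline = model(params)
    if baseline == 0 or not np.isfinite(baseline):
        raise DomainError(
            f"baseline output is {baseline}; the normalized SC is undefined"
        )
    perturbed = dict(params)
    perturbed[parameter] = params[parameter] * (1.0 + delta)
    shifted = model(perturbed)
    sc = (shifted - baseline) / baseline / delta
    return SensitivityResult(parameter=parameter, sc=float(sc), perturbation=delta, output_metric=output_metric)


def sensitivity_screen(
    model: Callable[[Mapping[str, float]], float],
    params: Mapping[str, float],
    parameters: Optional[Sequence[str]] = None,
    delta: float = DEFAULT_DELTA,
    threshold: float = DEFAULT_THRESHOLD,
    output_metric: str = "cmax",
) -> pd.DataFrame:
    """SCs for a list of parameters, ranked by |SC| and flagged vs threshold."""
    names = list(parameters) if parameters is not None else list(params)
    rows = []
    for name in names:
        result = normalized_sc(model, params, name, delta, output_metric)
        rows.append(
            {
                "parameter": name,
                "sc": result.sc,
                "abs_sc": abs(result.sc),
                "above_threshold": abs(result.sc) > threshold,
            }
        )
    frame = pd.DataFrame(rows, columns=["parameter", "sc", "abs_sc", "above_threshold"])
    return frame.sort_values("abs_sc", ascending=False, ignore_index=True)


def cmax_model(
    chem: ChemicalParams,
    phys: PhysiologyParams,
    scenario: ExposureScenario,
    pc: Optional[PartitionCoefficients] = None,
    solver: SolverSettings = SolverSettings(),
) -> tuple[Callable[[Mapping[str, float]], float], dict[str, float]]:
    """Blood-Cmax closure over the standard kinetic-model parameters.

    Returns (model, baseline) where baseline maps parameter names to their
    current values and model re-simulates Cmax for any override of them.
    Volume/flow remainders (slowly perfused tissue) are re-derived inside
    PhysiologyParams, so perturbing one fraction keeps the sums consistent.
    """
    if pc is None:
        pc = chem.resolve_pc()
    baseline = {
        "dose": scenario.dose_mg_per_kg,
        "body_weight": phys.body_weight,
        "clint": chem.clint_invitro,
        "papp_caco2": chem.papp_caco2,
        "s9_protein": phys.s9_protein_g_per_kg,
        "vlc": phys.vlc,
        "vfc": phys.vfc,
        "vbc": phys.vbc,
        "vrc": phys.vrc,
        "qc_coeff": phys.cardiac_output_coeff,
        "qlc": phys.qlc,
        "qfc": phys.qfc,
        "qrc": phys.qrc,
        "vin": phys.vin_ml,
        "sain": phys.sain_cm2,
        "kin": phys.kin_per_h,
        "gastric_emptying": phys.gastric_emptying_per_h,
        "pc_liver": pc.liver,
        "pc_fat": pc.fat,
        "pc_richly": pc.richly_perfused,
        "pc_slowly": pc.slowly_perfused,
    }

    def model(p: Mapping[str, float]) -> float:
        chem_p = replace(
            chem, clint_invitro=p["clint"], papp_caco2=p["papp_caco2"], partition_coefficients=None
        )
        pc_p = PartitionCoefficients(
            liver=p["pc_liver"],
            fat=p["pc_fat"],
            richly_perfused=p["pc_richly"],
            slowly_perfused=p["pc_slowly"],
        )
        phys_p = replace(
            phys,
            body_weight=p["body_weight"],
            s9_protein_g_per_kg=p["s9_protein"],
            vlc=p["vlc"],
            vfc=p["vfc"],
            vbc=p["vbc"],
            vrc=p["vrc"],
            cardiac_output_coeff=p["qc_coeff"],
            qlc=p["qlc"],
            qfc=p["qfc"],
            qrc=p["qrc"],
            vin_ml=p["vin"],
            sain_cm2=p["sain"],
            kin_per_h=p["kin"],
            gastric_emptying_per_h=p["gastric_emptying"],
        )
        scen_p = replace(scenario, dose_mg_per_kg=p["dose"])
        return simulate(chem_p, pc_p, phys_p, scen_p, solver).cmax

    return model, baseline
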
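"""Chemical-specific kinetic model inputs.

Derives the chemical-dependent parameters of the kinetic model from simple
physicochemical measurements:

* in vivo intestinal permeability from a Caco-2 apparent-permeability value,
  through the published log-log regression
  ``log Papp,in vivo = 0.6836 * log Papp,Caco-2 - 0.5579``;
* tissue:blood partition coefficients from the octanol-water partition
  coefficient (log Pow) through a quantitative property-property relationship
  (QPPR) on tissue lipid/water composition;
* the intestinal absorption-rate relation
  ``rate (umol/h) = Papp,in vivo (cm/h) * surface area (cm^2) * C_lumen (mM)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

from .errors import ConfigurationError, DomainError
from .units import SECONDS_PER_HOUR

__all__ = [
    "ChemicalParams",
    "PartitionCoefficients",
    "PappUnitConvention",
    "TISSUE_COMPOSITION",
    "papp_regression",
    "papp_invivo_from_caco2",
    "partition_coefficients_qppr",
    "absorption_rate",
]

PAPP_REGRESSION_SLOPE = 0.6836
PAPP_REGRESSION_INTERCEPT = -0.5579


class PappUnitConvention(str, Enum):
    """Unit reading of the Caco-2 -> in vivo permeability regression.

    CACO2_1E6_TO_INVIVO_1E4
        Input interpreted in 1e-6 cm/s, regression output in 1e-4 cm/s
        (the units in which the source regression was published). Default.
    SAME_UNITS
        Input and output both in 1e-6 cm/s (a literal same-scale reading).
    """

    CACO2_1E6_TO_INVIVO_1E4 = "caco2-1e-6-to-invivo-1e-4"
    SAME_UNITS = "same-units"


#: Tissue composition used by the QPPR: volume fractions of total lipid and
#: water per tissue group, plus the exponent applied to Pow for that tissue
#: (adipose lipids are less lipophilic than octanol, hence the reduced
#: exponent for fat). Compiled reference values for the adult rat; any
#: user-supplied table with the same keys can be passed instead.
TISSUE_COMPOSITION: dict[str, dict[str, float]] = {
    "blood": {"lipid": 0.0033, "water": 0.83},
    "liver": {"lipid": 0.042, "water": 0.72},
    "fat": {"lipid": 0.853, "water": 0.12, "pow_exponent": 0.7},
    "richly_perfused": {"lipid": 0.040, "water": 0.75},
    "slowly_perfused": {"lipid": 0.021, "water": 0.76},
}


@dataclass(frozen=True)
class PartitionCoefficients:
    """Tissue:blood concentration ratios at equilibrium (dimensionless)."""

    liver: float
    fat: float
    richly_perfused: float
    slowly_perfused: float

    def __post_init__(self) -> None:
        for name in ("liver", "fat", "richly_perfused", "slowly_perfused"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise DomainError(f"partition coefficient {name!r} must be > 0, got {value}")


@dataclass
class ChemicalParams:
    """Per-compound inputs of the kinetic model.

    Parameters
    ----------
    name : compound label.
    mw : molar mass, g/mol.
    log_pow : log10 octanol-water partition coefficient.
    papp_caco2 : Caco-2 apparent permeability, in 1e-6 cm/s.
    clint_invitro : intrinsic clearance, uL/min/mg S9 protein.
    fub_serum : fraction unbound in rat serum, in (0, 1].
    fub_medium : map of assay name -> fraction unbound in that assay medium.
    partition_coefficients : explicit tissue:blood PCs; when given they bypass
        the QPPR estimate entirely.
    papp_unit_convention : unit reading of the permeability regression.
    """

    name: str
    mw: float
    log_pow: float
    papp_caco2: float
    clint_invitro: float
    fub_serum: float
    fub_medium: Mapping[str, float] = field(default_factory=dict)
    partition_coefficients: Optional[PartitionCoefficients] = None
    papp_unit_convention: PappUnitConvention = PappUnitConvention.CACO2_1E6_TO_INVIVO_1E4

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise DomainError(f"mw must be > 0, got {self.mw}")
        if not self.papp_caco2 > 0:
            raise DomainError(f"papp_caco2 must be > 0, got {self.papp_caco2}")
        if self.clint_invitro < 0:
            raise DomainError(f"clint_invitro must be >= 0, got {self.clint_invitro}")
        for label, frac in [("fub_serum", self.fub_serum), *self.fub_medium.items()]:
            if not (0 < frac <= 1):
                raise DomainError(f"fraction unbound {label!r} must be in (0, 1], got {frac}")

    def resolve_pc(self, composition: Optional[Mapping[str, Mapping[str, float]]] = None) -> PartitionCoefficients:
        """Explicit PCs when provided, otherwise the QPPR estimate from log Pow."""
        if self.partition_coefficients is not None:
            return self.partition_coefficients
        return partition_coefficients_qppr(self.log_pow, composition)

    def papp_invivo_cm_per_h(self) -> float:
        return papp_invivo_from_caco2(self.papp_caco2, self.papp_unit_convention)


def papp_regression(papp_caco2: float) -> float:
    """Evaluate the permeability regression in its native (unitless log) form.

    Returns 10**(0.6836 * log10(papp_caco2) - 0.5579) without any unit
    conversion: the caller decides what scale both sides live on.
    """
    if not papp_caco2 > 0:
        raise DomainError(f"papp_caco2 must be > 0, got {papp_caco2}")
    return 10.0 ** (PAPP_REGRESSION_SLOPE * math.log10(papp_caco2) + PAPP_REGRESSION_INTERCEPT)


def papp_invivo_from_caco2(
    papp_caco2: float,
    unit_convention: PappUnitConvention = PappUnitConvention.CACO2_1E6_TO_INVIVO_1E4,
) -> float:
    """In vivo intestinal permeability (cm/h) from a Caco-2 Papp value.

    ``papp_caco2`` is given in 1e-6 cm/s (e.g. 17 for 17e-6 cm/s). The
    regression output is interpreted according to ``unit_convention`` and
    converted to cm/h.
    """
    raw = papp_regression(papp_caco2)
    convention = PappUnitConvention(unit_convention)
    if convention is PappUnitConvention.CACO2_1E6_TO_INVIVO_1E4:
        scale = 1e-4
    else:
        scale = 1e-6
    return raw * scale * SECONDS_PER_HOUR


def partition_coefficients_qppr(
    log_pow: float,
    composition: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> PartitionCoefficients:
    """Tissue:blood partition coefficients from log Pow via the QPPR.

    For each tissue group T,

        P_T = (f_lip,T * Pow**n + f_wat,T) / (f_lip,blood * Pow**n + f_wat,blood)

    where f_lip / f_wat are the lipid and water volume fractions and n is the
    tissue's Pow exponent (1 except for fat). A tissue whose composition equals
    blood's therefore has P = 1 for every log Pow.
    """
    table = TISSUE_COMPOSITION if composition is None else composition
    required = ("blood", "liver", "fat", "richly_perfused", "slowly_perfused")
    for key in required:
        if key not in table:
            raise ConfigurationError(f"tissue composition table is missing {key!r}")
    blood = table["blood"]
    _check_fractions("blood", blood)

    def one(tissue: str) -> float:
        comp = table[tissue]
        _check_fractions(tissue, comp)
        n = comp.get("pow_exponent", 1.0)
        pow_n = 10.0 ** (log_pow * n)
        num = comp["lipid"] * pow_n + comp["water"]
        den = blood["lipid"] * pow_n + blood["water"]
        return num / den

    return PartitionCoefficients(
        liver=one("liver"),
        fat=one("fat"),
        richly_perfused=one("richly_perfused"),
        slowly_perfused=one("slowly_perfused"),
    )


def _check_fractions(tissue: str, comp: Mapping[str, float]) -> None:
    for phase in ("lipid", "water"):
        if phase not in comp:
            raise ConfigurationError(f"composition of {tissue!r} lacks a {phase!r} fraction")
        if not (0 <= comp[phase] <= 1):
            raise ConfigurationError(
                f"{phase} fraction of {tissue!r} must be in [0, 1], got {comp[phase]}"
            )


def absorption_rate(papp_invivo: float, surface_area: float, lumen_conc: float) -> float:
    """Intestinal absorption rate (umol/h).

    cm/h * cm^2 * mM (= umol/cm^3) = umol/h; bilinear and exactly zero when
    any factor is zero.
    """
    for label, value in [("papp_invivo", papp_invivo), ("surface_area", surface_area), ("lumen_conc", lumen_conc)]:
        if value < 0:
            raise DomainError(f"{label} must be >= 0, got {value}")
    return papp_invivo * surface_area * lumen_conc
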
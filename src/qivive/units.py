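"""Centralized unit conversions.

Public interfaces use the conventions of the kinetic-modelling literature:
blood concentrations in uM (umol/L), external doses in mg/kg body weight,
intrinsic clearance in uL/min/mg S9 protein, whole-organ clearance in L/h,
permeability in cm/h, gut-lumen concentrations in mM (umol/cm^3).
"""

SECONDS_PER_HOUR = 3600.0
MINUTES_PER_HOUR = 60.0
UL_PER_L = 1e6
MG_PER_G = 1000.0
G_PER_KG = 1000.0


def mg_per_kg_to_umol(dose_mg_per_kg: float, body_weight_kg: float, mw_g_per_mol: float) -> float:
    """Convert an external dose (mg/kg bw) to an absolute molar amount (umol).

    mg/kg * kg = mg; mg / (g/mol) = mmol; * 1000 = umol.
    """
    return dose_mg_per_kg * body_weight_kg / mw_g_per_mol * 1000.0


def umol_to_mg(amount_umol: float, mw_g_per_mol: float) -> float:
    return amount_umol * mw_g_per_mol / 1000.0


def clint_to_liver_clearance_l_per_h(
    clint_ul_per_min_per_mg: float, s9_protein_g_per_kg: float, liver_mass_kg: float
) -> float:
    """Scale in vitro intrinsic clearance to whole-liver clearance (L/h).

    uL/min/mg * 60 min/h = uL/h/mg; / 1e6 uL/L = L/h/mg protein.
    Protein amount: (g protein / kg liver) * kg liver * 1000 mg/g = mg protein.
    """
    l_per_h_per_mg = clint_ul_per_min_per_mg * MINUTES_PER_HOUR / UL_PER_L
    protein_mg = s9_protein_g_per_kg * liver_mass_kg * MG_PER_G
    return l_per_h_per_mg * protein_mg


def molar_to_umolar(conc_m: float) -> float:
    """M -> uM."""
    return conc_m * 1e6
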
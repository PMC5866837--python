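"""Synthetic-data generators with known ground truth.

Every stage of the pipeline fits data of a known parametric family:
first-order substrate depletion, sigmoidal (Hill) concentration-response,
and exponentially increasing uterotrophic dose-response. These generators
draw from exactly those families with realistic noise, and return the data
together with the generating parameters, so estimator-recovery tests and
end-to-end demonstrations run without any external dataset.

Noise models: multiplicative lognormal for positive-valued measurements
(depletion ratios, uterus weights), additive Gaussian on the percent scale
for normalized assay responses. A fixed seed gives bit-identical output.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .clearance import DEPLETION_TIME_GRID_MIN, DepletionSeries
from .errors import DomainError
from .response_curves import ConcResponse, hill
from .reverse_dosimetry import DoseResponse

__all__ = [
    "E2_UTEROTROPHIC_DOSES",
    "make_depletion",
    "make_hill_curve",
    "make_uterotrophic",
]

#: Dose grid (mg/kg bw) of a typical oral uterotrophic study design for a
#: potent estrogen; the default design the uterotrophic generator emulates.
E2_UTEROTROPHIC_DOSES: tuple[float, ...] = (0.0, 0.01, 0.02, 0.04, 0.1, 0.2, 0.4)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv < 0:
        raise DomainError(f"noise_cv must be >= 0, got {cv}")
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def make_depletion(
    k_true: float,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    times: Sequence[float] = DEPLETION_TIME_GRID_MIN,
    seed: int = 0,
    incubation_volume_ul: float = 200.0,
    protein_mg: float = 0.1,
    substrate_conc_um: float = 3.0,
    km_lower_bound_um: Optional[float] = None,
) -> tuple[DepletionSeries, dict]:
    """First-order depletion series: ratio = exp(-k*t) with lognormal noise.

    The t=0 ratio is forced to 1 (each time point is normalized to its own
    co-factor-free control). Returns (series, truth).
    """
    if k_true < 0:
        raise DomainError(f"k_true must be >= 0, got {k_true}")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, float)
    clean = np.exp(-k_true * t)
    ratios = clean[None, :] * _lognormal_factors(rng, noise_cv, (n_replicates, t.size))
    ratios[:, t == 0] = 1.0
    series = DepletionSeries(
        times=t,
        ratios=ratios,
        incubation_volume_ul=incubation_volume_ul,
        protein_mg=protein_mg,
        substrate_conc_um=substrate_conc_um,
        km_lower_bound_um=km_lower_bound_um,
    )
    truth = {
        "k_true": k_true,
        "clint_true": incubation_volume_ul / protein_mg * k_true,
        "noise_cv": noise_cv,
        "n_replicates": n_replicates,
        "seed": seed,
    }
    return series, truth


def make_hill_curve(
    bottom: float = 0.0,
    top: float = 100.0,
    ec50_m: float = 1e-9,
    slope: float = 1.0,
    noise_sd_pct: float = 2.0,
    concentrations_m: Optional[Sequence[float]] = None,
    seed: int = 0,
    source: str = "synthetic-assay",
) -> tuple[ConcResponse, dict]:
    """Sigmoidal concentration-response curve with additive % noise.

    The default concentration grid spans 3 decades either side of the EC50,
    the range a well-designed assay covers. Returns (curve, truth); the
    curve's responses are the noisy values, not re-normalized, so zero-noise
    fixtures are exactly recovered by the Hill fitter.
    """
    if ec50_m <= 0:
        raise DomainError(f"ec50_m must be > 0, got {ec50_m}")
    if noise_sd_pct < 0:
        raise DomainError(f"noise_sd_pct must be >= 0, got {noise_sd_pct}")
    rng = np.random.default_rng(seed)
    if concentrations_m is None:
        concentrations_m = ec50_m * np.logspace(-3, 3, 13)
    c = np.asarray(concentrations_m, float)
    clean = hill(c, bottom, top, np.log10(ec50_m), slope)
    noisy = clean + rng.normal(0.0, noise_sd_pct, size=c.size)
    curve = ConcResponse(concentrations=c, response_pct=noisy, source=source)
    truth = {
        "bottom": bottom,
        "top": top,
        "ec50_m": ec50_m,
        "slope": slope,
        "noise_sd_pct": noise_sd_pct,
        "seed": seed,
    }
    return curve, truth


def make_uterotrophic(
    a: float = 100.0,
    b: float = 2.5,
    d: float = 1.0,
    noise_cv: float = 0.05,
    doses: Sequence[float] = E2_UTEROTROPHIC_DOSES,
    n_per_group: int = 5,
    seed: int = 0,
    source: str = "synthetic-uterotrophic",
) -> tuple[DoseResponse, dict]:
    """Uterotrophic dose-response data: y = a*exp(b*x^d) with lognormal noise.

    ``a`` is the control uterus weight (mg); the default potency ``b`` makes
    the top dose of the default design roughly double the control weight.
    Returns (data, truth) with the true BMD10 included in the manifest.
    """
    if a <= 0:
        raise DomainError(f"control response a must be > 0, got {a}")
    if b < 0 or d <= 0:
        raise DomainError("b must be >= 0 and d > 0")
    rng = np.random.default_rng(seed)
    x = np.repeat(np.asarray(doses, float), n_per_group)
    clean = a * np.exp(b * x**d)
    y = clean * _lognormal_factors(rng, noise_cv, x.size)
    data = DoseResponse(doses=x, responses=y, source=source, response_units="mg uterus weight")
    truth = {
        "a": a,
        "b": b,
        "d": d,
        "noise_cv": noise_cv,
        "n_per_group": n_per_group,
        "seed": seed,
        "bmd10_true": (np.log(1.1) / b) ** (1.0 / d) if b > 0 else None,
    }
    return data, truth
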
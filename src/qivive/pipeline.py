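"""The five-step workflow chained end to end.

(1) parameterize the kinetic model from chemical inputs, (2) evaluate it by
simulating the exposure scenarios, (3) determine in vitro effect
concentrations (here: synthetic assay curves with known truth), (4)
translate the curves into predicted in vivo dose-response data by reverse
dosimetry, and (5) evaluate the predictions with benchmark-dose analysis.
A sensitivity screen of blood Cmax completes the run.

Outputs are machine-readable tables/JSON under the configured output
directory; a provenance record (config hash, seed, package version) is
attached to every report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .bmd import bmd_analysis
from .clearance import fit_depletion
from .errors import ConfigurationError
from .fixtures import make_depletion, make_hill_curve, make_uterotrophic
from .io import RunConfig, config_hash
from .pbk_core import simulate
from .reverse_dosimetry import DoseResponse, translate_curve
from .sensitivity import cmax_model, sensitivity_screen

logger = logging.getLogger("qivive")

STAGES = ("clint", "simulate", "reverse-dosimetry", "bmd", "sensitivity")

__all__ = ["STAGES", "run_pipeline"]


def _provenance(config: RunConfig) -> dict:
    return {"config_hash": config_hash(config), "seed": config.seed, "version": __version__}


def run_pipeline(
    config: RunConfig,
    stages: Optional[Iterable[str]] = None,
    write: bool = True,
) -> dict:
    """Execute the requested stages; an empty stage list validates only.

    Returns a dict of stage reports; with ``write`` the reports and tables
    are also written under ``config.output_dir``.
    """
    stages = list(STAGES if stages is None else stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")
    reports: dict = {"provenance": _provenance(config)}
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    predicted: dict[str, DoseResponse] = {}

    if "clint" in stages:
        rows = []
        for i, (name, chem) in enumerate(config.chemicals.items()):
            k_true = chem.clint_invitro * 0.1 / 200.0  # default V=200 uL, P=0.1 mg
            series, truth = make_depletion(k_true=k_true, seed=config.seed + i)
            fit = fit_depletion(series)
            rows.append(
                {
                    "chemical": name,
                    "k_per_min": fit.k,
                    "clint_ul_min_mg": fit.clint_invitro,
                    "clint_config": chem.clint_invitro,
                    "fit_r2": fit.fit_r2,
                    "no_depletion": fit.no_depletion,
                }
            )
        frame = pd.DataFrame(rows)
        reports["clint"] = frame
        if write:
            frame.to_csv(outdir / "clint.csv", index=False)
        logger.info("clint stage: fitted %d depletion series", len(rows))

    if "simulate" in stages:
        rows = []
        for name, scenario in config.scenarios:
            chem = config.chemicals[name]
            result = simulate(chem, None, config.physiology, scenario, config.solver)
            rows.append(
                {
                    "chemical": name,
                    "route": scenario.route,
                    "dose_mg_per_kg": scenario.dose_mg_per_kg,
                    "cmax_um": result.cmax,
                    "tmax_h": result.tmax,
                    "auc_um_h": result.auc,
                    "mass_balance_error": result.mass_balance_error,
                }
            )
            if write:
                tag = f"{name}_{scenario.route}_{scenario.dose_mg_per_kg:g}"
                result.to_frame().to_csv(outdir / f"timecourse_{tag}.csv", index=False)
        frame = pd.DataFrame(rows)
        reports["simulate"] = frame
        if write:
            frame.to_csv(outdir / "simulate.csv", index=False)
        logger.info("simulate stage: %d scenarios", len(rows))

    if "reverse-dosimetry" in stages:
        hill_specs = config.fixtures.get("hill", {})
        frames = []
        for i, (name, spec) in enumerate(hill_specs.items()):
            chem = config.chemicals[name]
            spec = dict(spec)
            assay = spec.pop("assay", None)
            fub_assay = chem.fub_medium.get(assay, 1.0) if assay else 1.0
            curve, truth = make_hill_curve(
                seed=config.seed + 100 + i,
                source=f"{assay or 'assay'}:{name}",
                **spec,
            )
            dr = translate_curve(
                curve, fub_assay, chem.fub_serum, chem, None, config.physiology
            )
            frame = dr.to_frame()
            frame["chemical"] = name
            frames.append(frame)
            predicted[name] = dr
        if frames:
            frame = pd.concat(frames, ignore_index=True)
            reports["reverse-dosimetry"] = frame
            if write:
                frame.to_csv(outdir / "predicted_dose_response.csv", index=False)
        logger.info("reverse-dosimetry stage: %d curves translated", len(frames))

    if "bmd" in stages:
        rows = []
        utero_specs = config.fixtures.get("uterotrophic", {})
        for i, (name, spec) in enumerate(utero_specs.items()):
            data, truth = make_uterotrophic(seed=config.seed + 200 + i, **dict(spec))
            res = bmd_analysis(data, error_model="lognormal")
            rows.append(
                {
                    "chemical": name,
                    "dataset": "observed-uterotrophic",
                    "bmd10": res.bmd10,
                    "bmdl10": res.bmdl10,
                    "bmdu10": res.bmdu10,
                    "accepted": res.accepted,
                    "loglik": res.fit.loglik,
                }
            )
        for name, dr in predicted.items():
            fitted = _with_background(dr)
            res = bmd_analysis(fitted, error_model="normal")
            rows.append(
                {
                    "chemical": name,
                    "dataset": f"predicted:{dr.source}",
                    "bmd10": res.bmd10,
                    "bmdl10": res.bmdl10,
                    "bmdu10": res.bmdu10,
                    "accepted": res.accepted,
                    "loglik": res.fit.loglik,
                }
            )
        frame = pd.DataFrame(rows)
        reports["bmd"] = frame
        if write:
            frame.to_csv(outdir / "bmd.csv", index=False)
        logger.info("bmd stage: %d datasets analysed", len(rows))

    if "sensitivity" in stages:
        frames = []
        for name, scenario in config.scenarios:
            chem = config.chemicals[name]
            model, baseline = cmax_model(chem, config.physiology, scenario, solver=config.solver)
            screen = sensitivity_screen(model, baseline)
            screen.insert(0, "chemical", name)
            screen.insert(1, "dose_mg_per_kg", scenario.dose_mg_per_kg)
            frames.append(screen)
        if frames:
            frame = pd.concat(frames, ignore_index=True)
            reports["sensitivity"] = frame
            if write:
                frame.to_csv(outdir / "sensitivity.csv", index=False)
        logger.info("sensitivity stage: %d scenarios screened", len(frames))

    if write:
        summary = {
            k: (v.to_dict(orient="records") if isinstance(v, pd.DataFrame) else v)
            for k, v in reports.items()
        }
        (outdir / "report.json").write_text(json.dumps(summary, indent=2, default=_json_default))
    return reports


def _with_background(dr: DoseResponse) -> DoseResponse:
    """Prepend a dose-0 control with the low-dose asymptote of the curve.

    Predicted curves from reverse dosimetry have no dose-0 group; the
    exponential BMD model needs a background anchor, so the smallest
    predicted response is carried to dose 0 (at the bottom of a sigmoid the
    response is flat, making this a faithful background estimate).
    """
    j = int(np.argmin(dr.doses))
    doses = np.concatenate([[0.0], dr.doses])
    responses = np.concatenate([[max(dr.responses[j], 1e-6)], dr.responses])
    return DoseResponse(doses, responses, source=dr.source, response_units=dr.response_units)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
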
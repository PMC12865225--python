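"""End-to-end orchestration: assay data -> fits -> static risk -> PBPK DDI.

A :class:`PipelineConfig` describes where the assay data come from (CSV
files or seeded synthetic specifications), the precipitant exposure
parameters, and an optional PBPK DDI scenario. :func:`run_pipeline` executes
the stages in order, writes a fitted-parameter table, the static risk
report, a PBPK summary and a run manifest (seed, config hash, package
version) into the output directory, and fails with a stage-tagged error if
any stage does. Identical config + seed produces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .fitting import fit_ic50, percent_activity, vesicle_net_transport
from .io import read_assay_csv
from .pbpk import ddi_ratios, ddi_scenario, load_drug, load_drug_file
from .static_risk import PrecipitantProfile, build_report
from .synth import NoiseModel, TrueParams, generate_inhibition_dataset, generate_vesicle_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


class AssaySpec(BaseModel):
    """One transporter's inhibition assay: a CSV path or a synthetic spec."""

    transporter: str
    kind: Literal["inhibition", "vesicle"] = "inhibition"
    csv: Optional[str] = None
    # synthetic generation (used when csv is None)
    true_ic50: Optional[float] = None
    concs: list[float] = Field(
        default_factory=lambda: [0.41, 1.23, 3.7, 11.1, 33.3, 100.0, 300.0]
    )
    n_replicates: int = 3
    n_experiments: int = 2
    cv: float = 0.1
    background_fraction: float = 0.1


class PrecipitantConfig(BaseModel):
    name: str
    fu_p: float
    cmax_total: float
    dose_mg: float = 1000.0
    mw: float
    fa: float = 1.0
    fg: float = 1.0
    ka: float = 0.1
    qh: float = 1.62
    rb: float = 0.65

    def profile(self) -> PrecipitantProfile:
        return PrecipitantProfile(**self.model_dump())


class PBPKConfig(BaseModel):
    victim: str = "rosuvastatin_surrogate"
    precipitant: str = "dicloxacillin"
    victim_dose_mg: float = 20.0
    precipitant_dose_mg: float = 1000.0
    precipitant_interval_h: float = 8.0
    precipitant_n_doses: int = 6
    t_end_h: float = 48.0


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: str = "pipeline_out"
    precipitant: PrecipitantConfig
    assays: list[AssaySpec] = Field(default_factory=list)
    ic50_source: Literal["fitted", "literal"] = "fitted"
    literal_ic50s: dict[str, float] = Field(default_factory=dict)
    pbpk: Optional[PBPKConfig] = None


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _fit_stage(config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for i, spec in enumerate(config.assays):
        if spec.csv is not None:
            data = read_assay_csv(spec.csv)
        elif spec.kind == "inhibition":
            data = generate_inhibition_dataset(
                TrueParams(ic50=spec.true_ic50),
                spec.concs,
                n_replicates=spec.n_replicates,
                n_experiments=spec.n_experiments,
                noise=NoiseModel(cv=spec.cv, background_fraction=spec.background_fraction,
                                 seed=config.seed + i),
            )
        else:
            data = generate_vesicle_dataset(
                net_transport=100.0, amp_background=20.0,
                inhibition_curve=TrueParams(ic50=spec.true_ic50),
                concs=spec.concs, n_replicates=spec.n_replicates,
                noise=NoiseModel(cv=spec.cv, background_fraction=0.0,
                                 seed=config.seed + i),
            )
        reduce = vesicle_net_transport if spec.kind == "vesicle" or (
            spec.csv and "energy_source" in data.columns
        ) else percent_activity
        activity = reduce(data)
        fit = fit_ic50(activity)
        low, high = fit.ci95["ic50"]
        rows.append({
            "transporter": spec.transporter,
            "ic50_uM": fit.params["ic50"],
            "ci95_low": low,
            "ci95_high": high,
            "n_points": fit.n_points,
            "converged": fit.converged,
            "n_rows_in": len(data),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, verbose: bool = True) -> dict[str, Path]:
    """Run all configured stages; return paths of the written outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    log = print if verbose else (lambda *a, **k: None)

    # stage: fit
    fitted = pd.DataFrame()
    try:
        if config.assays:
            fitted = _fit_stage(config)
            outputs["fitted_parameters"] = out / "fitted_parameters.csv"
            fitted.to_csv(outputs["fitted_parameters"], index=False)
            log(f"[fit] {len(config.assays)} assays -> {len(fitted)} IC50 fits")
    except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
        raise PipelineError("fit", exc) from exc

    # stage: static risk
    try:
        if config.ic50_source == "literal":
            ic50s = dict(config.literal_ic50s)
        else:
            ic50s = dict(zip(fitted["transporter"], fitted["ic50_uM"]))
        if not ic50s:
            raise ValueError("no IC50 values: configure assays or literal_ic50s")
        report = build_report(config.precipitant.profile(), ic50s)
        outputs["static_risk"] = out / "static_risk.csv"
        report.table.to_csv(outputs["static_risk"], index=False)
        log(f"[static] {len(ic50s)} IC50s -> {len(report.table)} R-value rows")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("static", exc) from exc

    # stage: pbpk
    if config.pbpk is not None:
        try:
            cfg = config.pbpk
            def _drug(name: str):
                return load_drug_file(name) if name.endswith(".yaml") else load_drug(name)
            scenario = ddi_scenario(
                _drug(cfg.victim), _drug(cfg.precipitant),
                victim_dose_mg=cfg.victim_dose_mg,
                precipitant_dose_mg=cfg.precipitant_dose_mg,
                precipitant_interval_h=cfg.precipitant_interval_h,
                precipitant_n_doses=cfg.precipitant_n_doses,
            )
            ddi = ddi_ratios(scenario, t_end=cfg.t_end_h)
            summary = {
                "victim": cfg.victim,
                "precipitant": cfg.precipitant,
                "auc_ratio": ddi.auc_ratio,
                "cmax_ratio": ddi.cmax_ratio,
                "baseline": ddi.baseline.summary(),
                "with_precipitant": ddi.combined.summary(),
                "max_percent_inhibition": ddi.max_inhibition(),
            }
            outputs["pbpk_summary"] = out / "pbpk_summary.json"
            outputs["pbpk_summary"].write_text(json.dumps(summary, indent=2))
            log(f"[pbpk] AUC ratio {ddi.auc_ratio:.3f}, Cmax ratio {ddi.cmax_ratio:.3f}")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("pbpk", exc) from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    outputs["manifest"] = out / "manifest.json"
    outputs["manifest"].write_text(json.dumps(manifest, indent=2))
    return outputs
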
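"""End-to-end orchestration: ingest/generate -> NCA -> dose proportionality
-> PBPK calibration and dose scan -> fold-error validation, emitting a report
bundle of CSV/JSON tables plus a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .cohort import CohortSpec, generate_cohort, truth_to_frame
from .dose_proportionality import (acceptance_range, assess_proportionality,
                                   fit_power_model)
from .errors import PKError
from .nca import analyze_groups, results_to_frame, summarize_group, summaries_to_frame
from .pbpk import build_model, calibrate, default_grid, dose_scan, simulate
from .pk_dataset import DoseGroup, read_profiles, write_profiles
from .reference import (absorption_model, calibration_reference, drug_parameters,
                        elimination_model, load_drug_config, load_physiology)
from .validation import validate_predictions

log = logging.getLogger("pbpkfih")


class DosePropOptions(BaseModel):
    theta_l: float = 0.8
    theta_h: float = 1.25
    ci_level: float = 0.90
    parameters: tuple[str, ...] = ("cmax", "auc_0t", "auc_0inf")


class NCAOptions(BaseModel):
    method: str = "linuplogdown"


class PBPKOptions(BaseModel):
    enabled: bool = True
    drug_config: str | None = None      # path; packaged NH130 config when None
    physiology: str | None = None       # path; packaged 70-kg adult when None


class PipelineConfig(BaseModel):
    """One input source (CSV path or synthetic cohort spec), stage options,
    output directory and the global seed."""

    input_csv: str | None = None
    synthetic: CohortSpec | None = None
    nca: NCAOptions = Field(default_factory=NCAOptions)
    doseprop: DosePropOptions = Field(default_factory=DosePropOptions)
    pbpk: PBPKOptions = Field(default_factory=PBPKOptions)
    output_dir: str = "pbpkfih_out"
    seed: int | None = None
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_source(self):
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_csv / synthetic must be set")
        return self

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.model_validate(raw)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


@dataclass
class ReportBundle:
    nca_results: pd.DataFrame
    group_summary: pd.DataFrame
    proportionality: pd.DataFrame
    predictions: pd.DataFrame | None
    fold_errors: pd.DataFrame | None
    manifest: dict
    output_dir: Path


def _write_atomic(frame: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    frame.to_csv(tmp, index=False)
    tmp.replace(path)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str, manifest: dict):
    class _Timer:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest["stages"][name] = round(dt, 3)
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s failed: %s", name, exc)
            return False
    return _Timer()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all configured stages in order; any stage failure aborts with a
    stage-tagged error. Outputs are written atomically under ``output_dir``."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    with _stage("ingest", manifest):
        if config.synthetic is not None:
            spec = config.synthetic
            if config.seed is not None:
                spec = spec.model_copy(update={"seed": config.seed})
            groups, subjects = generate_cohort(spec)
            write_profiles(groups, out / "cohort.csv")
            _write_atomic(truth_to_frame(subjects), out / "cohort_truth.csv")
        else:
            groups = read_profiles(config.input_csv)
        log.info("ingested %d dose groups, %d subjects",
                 len(groups), sum(g.n for g in groups))

    with _stage("nca", manifest):
        results = analyze_groups(groups, method=config.nca.method)
        by_dose: dict[float, list] = {}
        for r in results:
            by_dose.setdefault(r.dose_mg, []).append(r)
        summaries = [summarize_group(rs) for _, rs in sorted(by_dose.items())]
        nca_frame = results_to_frame(results)
        summary_frame = summaries_to_frame(summaries)
        _write_atomic(nca_frame, out / "nca_results.csv")
        _write_atomic(summary_frame, out / "group_summary.csv")

    with _stage("doseprop", manifest):
        dp = config.doseprop
        doses = sorted(by_dose)
        rng = acceptance_range(dp.theta_l, dp.theta_h, max(doses) / min(doses))
        rows = []
        for param in dp.parameters:
            pairs = [(r.dose_mg, getattr(r, param)) for r in results
                     if getattr(r, param) is not None and getattr(r, param) > 0]
            fit = fit_power_model(pairs, param, ci_level=dp.ci_level)
            verdict = assess_proportionality(fit, rng)
            rows.append({"parameter": param, "beta": fit.beta,
                         "ci_low": fit.ci90[0], "ci_high": fit.ci90[1],
                         "range_low": rng.low, "range_high": rng.high,
                         "verdict": verdict.verdict, "rationale": verdict.rationale})
        prop_frame = pd.DataFrame(rows)
        _write_atomic(prop_frame, out / "dose_proportionality.csv")
        (out / "dose_proportionality.json").write_text(
            prop_frame.to_json(orient="records", indent=2))

    predictions = fe_frame = None
    if config.pbpk.enabled:
        with _stage("pbpk", manifest):
            drug_cfg = load_drug_config(config.pbpk.drug_config)
            model = build_model(drug_parameters(drug_cfg),
                                load_physiology(config.pbpk.physiology),
                                absorption_model(drug_cfg),
                                elimination_model(drug_cfg))
            ref_dose, targets = calibration_reference(drug_cfg)
            model = calibrate(model, ref_dose, targets)
            manifest["calibrated"] = {"cl_hepatic": model.elimination.cl_hepatic,
                                      "ka": model.absorption.ka}
            predictions = dose_scan(model, sorted(by_dose))
            _write_atomic(predictions, out / "predictions.csv")

        with _stage("validate", manifest):
            observed = summary_frame.rename(columns={
                "cmax_geomean": "cmax", "auc_0inf_geomean": "auc_0inf"})
            obs_means = _observed_mean_profiles(groups)
            grid = default_grid()
            pred_profiles = pd.concat([
                pd.DataFrame({"dose_mg": d, "time_h": grid,
                              "conc_ng_ml": simulate(model, d, grid).plasma_conc})
                for d in sorted(by_dose)], ignore_index=True)
            report = validate_predictions(
                predictions, observed[["dose_mg", "cmax", "auc_0inf"]],
                pred_profiles, obs_means)
            fe_frame = report.parameters
            _write_atomic(fe_frame, out / "fold_errors.csv")
            _write_atomic(report.timepoints, out / "fold_errors_timepoints.csv")
            manifest["validation_success"] = report.success

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ReportBundle(nca_frame, summary_frame, prop_frame, predictions,
                        fe_frame, manifest, out)


def _observed_mean_profiles(groups: list[DoseGroup]) -> pd.DataFrame:
    """Per-dose arithmetic mean of quantified concentrations at each time."""
    rows = []
    for g in groups:
        times = np.unique(np.concatenate([p.times for p in g.profiles]))
        for t in times:
            vals = []
            for p in g.profiles:
                idx = np.flatnonzero(p.times == t)
                if idx.size and not p.blq[idx[0]]:
                    vals.append(p.concentrations[idx[0]])
            if vals:
                rows.append({"dose_mg": g.dose_mg, "time_h": float(t),
                             "conc_ng_ml": float(np.mean(vals))})
    return pd.DataFrame(rows)
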
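"""Packaged reference inputs: NH130 drug parameters, a 70-kg adult
physiology, the clinical group-level PK summary, and the reference PBPK
prediction table used for calibration and fold-error validation."""

from __future__ import annotations

import tomllib
from importlib import resources
from io import StringIO
from pathlib import Path

import pandas as pd

from .pbpk import AbsorptionModel, DrugParameters, EliminationModel, Physiology


def _read_data_text(name: str) -> str:
    return (resources.files("pbpkfih") / "data" / name).read_text(encoding="utf-8")


def _read_toml(name_or_path: str | Path, packaged: bool) -> dict:
    if packaged:
        return tomllib.loads(_read_data_text(str(name_or_path)))
    with open(name_or_path, "rb") as fh:
        return tomllib.load(fh)


def observed_pk_summary() -> pd.DataFrame:
    """Group-level observed PK summary of the single-ascending-dose trial:
    geometric mean and geometric CV% per parameter, median (range) for Tmax."""
    return pd.read_csv(StringIO(_read_data_text("observed_pk_summary.csv")))


def reference_predictions() -> pd.DataFrame:
    """Reference predicted/observed Cmax and AUC0-inf per dose with their
    published fold errors (columns ``*_pred``, ``*_obs``, ``*_fe``)."""
    return pd.read_csv(StringIO(_read_data_text("pbpk_reference_predictions.csv")))


def load_drug_config(path: str | Path | None = None) -> dict:
    """Raw drug config (drug / absorption / elimination / calibration sections)."""
    if path is None:
        return _read_toml("nh130.toml", packaged=True)
    return _read_toml(path, packaged=False)


def drug_parameters(config: dict | None = None) -> DrugParameters:
    cfg = (config or load_drug_config())["drug"]
    return DrugParameters(
        molecular_weight=cfg["molecular_weight"],
        logp=cfg["logp"],
        pka_list=tuple(cfg["pka"]),
        solubility_mg_ml=cfg["solubility_mg_ml"],
        papp_cm_s=cfg["papp_cm_s"],
        kp=dict(cfg["kp"]),
        blood_to_plasma=cfg.get("blood_to_plasma", 1.0),
    )


def absorption_model(config: dict | None = None) -> AbsorptionModel:
    cfg = (config or load_drug_config())["absorption"]
    return AbsorptionModel(ka=cfg["ka"], f_abs=cfg.get("f_abs", 1.0),
                           tlag=cfg.get("tlag", 0.0))


def elimination_model(config: dict | None = None) -> EliminationModel:
    cfg = (config or load_drug_config())["elimination"]
    return EliminationModel(cl_hepatic=cfg["cl_hepatic"])


def calibration_reference(config: dict | None = None) -> tuple[float, tuple[float, float]]:
    """(reference dose mg, (target Cmax ng/mL, target AUC0-inf h*ng/mL))."""
    cfg = (config or load_drug_config())["calibration"]
    return cfg["reference_dose_mg"], (cfg["target_cmax_ng_ml"],
                                      cfg["target_auc_0inf_h_ng_ml"])


def load_physiology(path: str | Path | None = None) -> Physiology:
    """Physiology from a TOML table (packaged 70-kg reference by default)."""
    cfg = _read_toml(path or "physiology_adult_70kg.toml", packaged=path is None)
    return Physiology(
        volumes=dict(cfg["volumes_l"]),
        flows=dict(cfg["flows_l_h"]),
        arterial_volume=cfg["arterial_volume_l"],
        venous_volume=cfg["venous_volume_l"],
        cardiac_output=cfg["cardiac_output_l_h"],
        body_weight_kg=cfg.get("body_weight_kg", 70.0),
    )
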
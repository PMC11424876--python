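"""Predicted-vs-observed model validation by fold error.

Fold error (FE) is predicted/observed. A simulation is conventionally judged
successful when every parameter-level FE lies in [0.3, 3]; entries are
additionally banded as within 2-fold ([0.5, 2]), within 3-fold
([1/3, 3] outside the 2-fold band) or beyond 3-fold. Band edges are closed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

Band = Literal["within_2x", "within_3x", "beyond_3x"]

SUCCESS_LOW, SUCCESS_HIGH = 0.3, 3.0


def fold_error(predicted: float, observed: float) -> float:
    if predicted <= 0 or observed <= 0:
        raise DomainError("fold error needs positive predicted and observed values")
    return predicted / observed


def classify_fe(fe: float) -> tuple[Band, bool]:
    """(band, contributes-to-success). Success uses the [0.3, 3] rule."""
    if fe <= 0:
        raise DomainError("fold error must be positive")
    if 0.5 <= fe <= 2.0:
        band: Band = "within_2x"
    elif 1.0 / 3.0 <= fe <= 3.0:
        band = "within_3x"
    else:
        band = "beyond_3x"
    return band, SUCCESS_LOW <= fe <= SUCCESS_HIGH


@dataclass(frozen=True)
class FoldErrorReport:
    """Parameter-level and per-timepoint FE tables with banding."""

    parameters: pd.DataFrame   # dose_mg, parameter, predicted, observed, fe, band, success
    timepoints: pd.DataFrame   # dose_mg, time_h, predicted, observed, fe, band
    success: bool              # all parameter-level FE within [0.3, 3]

    def band_counts(self) -> pd.DataFrame:
        """Per-dose counts of timepoint FEs per band (banded-summary export)."""
        if self.timepoints.empty:
            return pd.DataFrame(columns=["dose_mg", "within_2x", "within_3x", "beyond_3x"])
        counts = (self.timepoints.groupby("dose_mg")["band"]
                  .value_counts().unstack(fill_value=0))
        for b in ("within_2x", "within_3x", "beyond_3x"):
            if b not in counts:
                counts[b] = 0
        return counts[["within_2x", "within_3x", "beyond_3x"]].reset_index()


def _param_table(predictions: pd.DataFrame, observed: pd.DataFrame) -> pd.DataFrame:
    pred_doses = set(predictions["dose_mg"])
    obs_doses = set(observed["dose_mg"])
    if pred_doses != obs_doses:
        raise ValidationError(
            f"dose sets differ: only-predicted {sorted(pred_doses - obs_doses)}, "
            f"only-observed {sorted(obs_doses - pred_doses)}"
        )
    merged = predictions.merge(observed, on="dose_mg", suffixes=("_pred", "_obs"))
    rows = []
    for param in ("cmax", "auc_0inf"):
        pc, oc = f"{param}_pred", f"{param}_obs"
        if pc not in merged or oc not in merged:
            continue
        for _, row in merged.iterrows():
            fe = fold_error(row[pc], row[oc])
            band, ok = classify_fe(fe)
            rows.append({"dose_mg": row["dose_mg"], "parameter": param,
                         "predicted": row[pc], "observed": row[oc],
                         "fe": fe, "band": band, "success": ok})
    return pd.DataFrame(rows)


def _timepoint_table(pred_profiles: pd.DataFrame | None,
                     obs_profiles: pd.DataFrame | None) -> pd.DataFrame:
    cols = ["dose_mg", "time_h", "predicted", "observed", "fe", "band"]
    if pred_profiles is None or obs_profiles is None or obs_profiles.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    for dose, obs in obs_profiles.groupby("dose_mg"):
        pred = pred_profiles[pred_profiles["dose_mg"] == dose]
        if pred.empty:
            raise ValidationError(f"no predicted profile for {dose} mg")
        pt = pred["time_h"].to_numpy()
        pc = pred["conc_ng_ml"].to_numpy()
        for _, row in obs.iterrows():
            t = row["time_h"]
            i = int(np.argmin(np.abs(pt - t)))
            # nearest grid time must sit within 1% of the observation time
            if abs(pt[i] - t) > 0.01 * max(t, 1e-9):
                raise ValidationError(
                    f"{dose} mg: no predicted grid time within 1% of t={t} h"
                )
            if row["conc_ng_ml"] <= 0 or pc[i] <= 0:
                continue  # zero/BLQ-level points carry no fold error
            fe = fold_error(pc[i], row["conc_ng_ml"])
            band, _ = classify_fe(fe)
            rows.append({"dose_mg": dose, "time_h": t, "predicted": pc[i],
                         "observed": row["conc_ng_ml"], "fe": fe, "band": band})
    return pd.DataFrame(rows, columns=cols)


def validate_predictions(
    predictions: pd.DataFrame,
    observed_summary: pd.DataFrame,
    pred_profiles: pd.DataFrame | None = None,
    obs_mean_profiles: pd.DataFrame | None = None,
) -> FoldErrorReport:
    """Full fold-error report.

    ``predictions`` and ``observed_summary`` carry one row per dose with
    ``dose_mg`` plus ``cmax``/``auc_0inf`` columns. Optional per-timepoint
    tables (``dose_mg, time_h, conc_ng_ml``) feed the banded concentration
    comparison; observed per-timepoint values are group means of quantified
    concentrations (configurably geometric means upstream), matched to the
    nearest predicted grid time within 1%.
    """
    params = _param_table(predictions, observed_summary)
    times = _timepoint_table(pred_profiles, obs_mean_profiles)
    success = bool(params["success"].all()) if not params.empty else False
    return FoldErrorReport(params, times, success)
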
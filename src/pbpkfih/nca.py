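"""Non-compartmental analysis of single-dose plasma profiles.

Implements the standard parameter set (Cmax, Tmax, AUC0-t, AUC0-inf, lambda_z,
T1/2, CL/F) with the linear-up/log-down trapezoid rule and an automated
best-fit terminal window selected by adjusted R-squared, plus group summaries
as geometric mean / geometric CV% (median and range for Tmax).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientData, NoQuantifiableData
from .pk_dataset import ConcentrationProfile, DoseGroup, PreparedProfile, blq_policy
from .units import clearance_l_per_h

LN2 = math.log(2.0)


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression result."""

    lambda_z: float
    intercept: float        # ln-concentration intercept at t=0
    r2_adj: float
    n_points: int
    window: tuple[float, float]  # (first, last) time in the fit


@dataclass(frozen=True)
class NCAResult:
    subject_id: str
    dose_mg: float
    cmax: float
    tmax: float
    auc_0t: float
    auc_0inf: float | None
    lambda_z: float | None
    t_half: float | None
    cl_f: float | None
    lambda_z_n_points: int
    lambda_z_r2_adj: float | None
    pct_extrapolated: float | None


def compute_cmax_tmax(prep: PreparedProfile) -> tuple[float, float]:
    """Maximum observed concentration and its sampling time (ties -> earliest)."""
    c = prep.analysis_concs
    if c.size == 0:
        raise NoQuantifiableData(f"subject {prep.subject_id}: no quantified points")
    i = int(np.argmax(c))  # argmax returns the first index on ties
    return float(c[i]), float(prep.analysis_times[i])


def auc_linuplogdown(
    prep: PreparedProfile, t_end: float | None = None, method: str = "linuplogdown"
) -> float:
    """AUC by per-segment trapezoids up to ``t_end`` (default: last point).

    Each segment uses the linear rule when the concentration is non-decreasing
    or either endpoint is zero, and the logarithmic rule
    (C1-C2)/ln(C1/C2)*dt when strictly decreasing with positive endpoints.
    ``method="linear"`` forces the linear rule throughout.
    """
    return auc_from_arrays(prep.analysis_times, prep.analysis_concs, t_end, method,
                           label=f"subject {prep.subject_id}")


def auc_from_arrays(
    t: np.ndarray, c: np.ndarray, t_end: float | None = None,
    method: str = "linuplogdown", label: str = "profile",
) -> float:
    """Trapezoid AUC on raw time/concentration arrays (see auc_linuplogdown)."""
    if t.size < 2:
        raise InsufficientData(f"{label}: need >=2 points for AUC")
    if t_end is None:
        t_end = float(t[-1])
    if t_end > t[-1] + 1e-12:
        raise DomainError(f"t_end={t_end} beyond last quantified time {t[-1]}")
    total = 0.0
    for i in range(t.size - 1):
        if t[i] >= t_end:
            break
        t1, t2 = t[i], min(t[i + 1], t_end)
        c1, c2 = c[i], c[i + 1]
        if t2 < t[i + 1]:  # partial segment: interpolate the endpoint
            frac = (t2 - t1) / (t[i + 1] - t1)
            if method != "linear" and c1 > c2 > 0 and c1 != c2:
                c2 = c1 * (c2 / c1) ** frac
            else:
                c2 = c1 + (c2 - c1) * frac
        dt = t2 - t1
        if method != "linear" and c1 > c2 > 0:
            total += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            total += dt * 0.5 * (c1 + c2)
    return total


def _loglin_fit(t: np.ndarray, lnc: np.ndarray) -> tuple[float, float, float]:
    """Least squares of ln(C) on t; returns (slope, intercept, adjusted R2)."""
    n = t.size
    slope, intercept = np.polyfit(t, lnc, 1)
    resid = lnc - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((lnc - lnc.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-24 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(slope), float(intercept), r2_adj


def fit_lambda_z(prep: PreparedProfile) -> LambdaZFit | None:
    """Best-fit terminal slope over candidate windows.

    Candidates are the suffixes (>=3 points, ending at the last quantified
    positive point) of the post-peak samples. The Cmax point itself is
    eligible only when it is the first quantified sample (no absorption phase
    observed); otherwise it is excluded, the usual convention for oral data.
    The window maximising adjusted R-squared wins; ties go to more points.
    Returns None when no window yields a positive terminal rate.
    """
    _, tmax = compute_cmax_tmax(prep)
    t, c = prep.analysis_times, prep.analysis_concs
    pos = c > 0
    if not pos.any():
        return None
    # the peak itself enters only for bolus-like profiles that decline from
    # the first positive sample onward
    peak_is_first = tmax <= float(t[pos][0])
    eligible = pos & ((t >= tmax) if peak_is_first else (t > tmax))
    te, ce = t[eligible], c[eligible]
    if te.size < 3:
        return None
    lnc = np.log(ce)
    best: LambdaZFit | None = None
    for start in range(te.size - 2):
        slope, intercept, r2_adj = _loglin_fit(te[start:], lnc[start:])
        if slope >= 0:
            continue
        cand = LambdaZFit(-slope, intercept, r2_adj, te.size - start,
                          (float(te[start]), float(te[-1])))
        if best is None or cand.r2_adj > best.r2_adj + 1e-12 or (
            abs(cand.r2_adj - best.r2_adj) <= 1e-12 and cand.n_points > best.n_points
        ):
            best = cand
    return best


def extrapolate_auc_inf(auc_0t: float, c_last: float, lambda_z: float) -> tuple[float, float]:
    """AUC0-inf = AUC0-t + Clast/lambda_z, with the extrapolated percentage."""
    if lambda_z <= 0 or c_last <= 0 or auc_0t <= 0:
        raise DomainError("extrapolation needs positive AUC0-t, Clast and lambda_z")
    auc_inf = auc_0t + c_last / lambda_z
    pct = 100.0 * (auc_inf - auc_0t) / auc_inf
    return auc_inf, pct


def derive_secondary(dose_mg: float, auc_0inf: float, lambda_z: float) -> tuple[float, float]:
    """Terminal half-life and apparent clearance CL/F (L/h)."""
    if dose_mg <= 0 or auc_0inf <= 0 or lambda_z <= 0:
        raise DomainError("dose, AUC0-inf and lambda_z must be positive")
    return LN2 / lambda_z, clearance_l_per_h(dose_mg, auc_0inf)


def analyze_profile(
    profile: ConcentrationProfile, method: str = "linuplogdown",
    lambda_z_fit: LambdaZFit | None = None,
) -> NCAResult:
    """Full single-subject NCA; terminal-phase parameters are None when
    lambda_z cannot be estimated. ``lambda_z_fit`` overrides the automatic
    window selection (manual mode)."""
    prep = blq_policy(profile)
    cmax, tmax = compute_cmax_tmax(prep)
    auc_0t = auc_linuplogdown(prep, method=method)
    fit = lambda_z_fit if lambda_z_fit is not None else fit_lambda_z(prep)
    if fit is None:
        return NCAResult(profile.subject_id, profile.dose_mg, cmax, tmax, auc_0t,
                         None, None, None, None, 0, None, None)
    pos = prep.analysis_concs > 0
    c_last = float(prep.analysis_concs[pos][-1])
    auc_inf, pct = extrapolate_auc_inf(auc_0t, c_last, fit.lambda_z)
    t_half, cl_f = derive_secondary(profile.dose_mg, auc_inf, fit.lambda_z)
    return NCAResult(profile.subject_id, profile.dose_mg, cmax, tmax, auc_0t,
                     auc_inf, fit.lambda_z, t_half, cl_f, fit.n_points,
                     fit.r2_adj, pct)


def analyze_groups(groups: list[DoseGroup], method: str = "linuplogdown") -> list[NCAResult]:
    return [analyze_profile(p, method=method) for g in groups for p in g.profiles]


# ---------------------------------------------------------------------------
# group summaries (geometric mean / geometric CV%)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    dose_mg: float
    n: int
    geomean: dict[str, float]     # parameter -> geometric mean
    geocv_pct: dict[str, float]   # parameter -> geometric CV%
    tmax_median: float
    tmax_range: tuple[float, float]


def geometric_stats(values: np.ndarray) -> tuple[float, float]:
    """Geometric mean and geometric CV% (100*sqrt(exp(s^2)-1), s = SD of logs,
    n-1 denominator; 0% for a single value)."""
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise DomainError("geometric statistics need strictly positive values")
    logs = np.log(x)
    gm = float(np.exp(logs.mean()))
    s = float(logs.std(ddof=1)) if x.size > 1 else 0.0
    return gm, 100.0 * math.sqrt(math.expm1(s * s))


_SUMMARY_PARAMS = ("cmax", "auc_0t", "auc_0inf", "t_half", "cl_f")


def summarize_group(results: list[NCAResult]) -> GroupSummary:
    """Table-style group summary: geometric mean (geometric CV%) per
    parameter, median (min, max) for Tmax. Subjects with undefined or
    non-positive values are excluded per parameter, with a warning."""
    if not results:
        raise InsufficientData("no results to summarize")
    dose = results[0].dose_mg
    geomean, geocv = {}, {}
    for param in _SUMMARY_PARAMS:
        vals = [getattr(r, param) for r in results]
        ok = [v for v in vals if v is not None and v > 0]
        if len(ok) < len(vals):
            warnings.warn(
                f"{dose} mg group: {len(vals) - len(ok)} subject(s) excluded "
                f"from {param} summary (undefined or non-positive)",
                stacklevel=2,
            )
        if ok:
            geomean[param], geocv[param] = geometric_stats(np.array(ok))
    tmaxes = np.array([r.tmax for r in results])
    return GroupSummary(dose, len(results), geomean, geocv,
                        float(np.median(tmaxes)),
                        (float(tmaxes.min()), float(tmaxes.max())))


def results_to_frame(results: list[NCAResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"dose_mg": s.dose_mg, "n": s.n,
               "tmax_median": s.tmax_median,
               "tmax_min": s.tmax_range[0], "tmax_max": s.tmax_range[1]}
        for p in _SUMMARY_PARAMS:
            row[f"{p}_geomean"] = s.geomean.get(p)
            row[f"{p}_geocv_pct"] = s.geocv_pct.get(p)
        rows.append(row)
    return pd.DataFrame(rows)
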
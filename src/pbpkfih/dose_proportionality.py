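"""Power-model dose-proportionality assessment.

The exposure parameter Y (Cmax, AUC0-t or AUC0-inf) is regressed on dose on
the log-log scale, ln(Y) = alpha + beta * ln(dose). Proportionality holds
when the 90% confidence interval for the slope beta lies inside the
acceptance range

    (1 + ln(theta_L)/ln(R), 1 + ln(theta_H)/ln(R)),

the bioequivalence limits theta_L = 0.8 and theta_H = 1.25 rescaled by the
log of the highest/lowest dose ratio R (the Smith criterion). With a wide
escalation range (R = 45 here) the acceptance range is narrow, so a CI can
cover the whole range without being contained in it — reported as
"inconclusive" rather than "nonproportional".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError, InsufficientData, ValidationError

Verdict = Literal["proportional", "inconclusive", "nonproportional"]


@dataclass(frozen=True)
class PowerModelFit:
    parameter_name: str
    alpha: float
    beta: float
    beta_se: float | None
    ci90: tuple[float, float] | None
    n_obs: int
    dose_range: tuple[float, float]


@dataclass(frozen=True)
class AcceptanceRange:
    theta_l: float
    theta_h: float
    r: float
    low: float
    high: float


@dataclass(frozen=True)
class ProportionalityVerdict:
    verdict: Verdict
    rationale: str


def fit_power_model(
    pairs: Sequence[tuple[float, float]], parameter_name: str, ci_level: float = 0.90
) -> PowerModelFit:
    """OLS of ln(Y) on ln(dose) over per-subject (dose, Y) pairs.

    The CI uses the t distribution with n-2 degrees of freedom.
    """
    if len(pairs) < 3:
        raise InsufficientData("power model needs at least 3 (dose, Y) pairs")
    doses = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.any(doses <= 0) or np.any(y <= 0):
        raise DomainError("doses and Y must be strictly positive for log transform")
    if np.unique(doses).size < 2:
        raise DomainError("at least two distinct dose levels are required")
    x = sm.add_constant(np.log(doses))
    fit = sm.OLS(np.log(y), x).fit()
    alpha, beta = fit.params
    se = float(fit.bse[1])
    tcrit = stats.t.ppf(0.5 + ci_level / 2, len(pairs) - 2)
    return PowerModelFit(
        parameter_name, float(alpha), float(beta), se,
        (float(beta - tcrit * se), float(beta + tcrit * se)),
        len(pairs), (float(doses.min()), float(doses.max())),
    )


def fit_power_model_from_summaries(
    doses: Sequence[float], geomeans: Sequence[float],
    group_ns: Sequence[int], parameter_name: str,
) -> PowerModelFit:
    """Group-level power-model slope from geometric means.

    Weighted least squares of ln(geomean) on ln(dose) with the group sizes as
    weights. Because dose is constant within a group, the point estimate
    equals the individual-level OLS slope; the CI is unavailable (it needs
    individual residuals) and is returned as None.
    """
    if not (len(doses) == len(geomeans) == len(group_ns)):
        raise ValidationError("doses, geomeans and group_ns must have equal length")
    if len(doses) < 3:
        raise InsufficientData("need at least 3 groups")
    d = np.asarray(doses, dtype=float)
    g = np.asarray(geomeans, dtype=float)
    if np.any(d <= 0) or np.any(g <= 0):
        raise DomainError("doses and geomeans must be strictly positive")
    x = sm.add_constant(np.log(d))
    fit = sm.WLS(np.log(g), x, weights=np.asarray(group_ns, dtype=float)).fit()
    alpha, beta = fit.params
    return PowerModelFit(parameter_name, float(alpha), float(beta), None, None,
                         int(np.sum(group_ns)), (float(d.min()), float(d.max())))


def acceptance_range(theta_l: float = 0.8, theta_h: float = 1.25, r: float = 45.0) -> AcceptanceRange:
    """Slope acceptance limits 1 + ln(theta)/ln(R)."""
    if not (0 < theta_l < 1 < theta_h):
        raise DomainError("need 0 < theta_l < 1 < theta_h")
    if r <= 1:
        raise DomainError("dose ratio R must exceed 1")
    return AcceptanceRange(
        theta_l, theta_h, r,
        1.0 + math.log(theta_l) / math.log(r),
        1.0 + math.log(theta_h) / math.log(r),
    )


def assess_proportionality(fit: PowerModelFit, rng: AcceptanceRange) -> ProportionalityVerdict:
    """Three-way verdict from the CI vs acceptance-range set relation."""
    if fit.ci90 is None:
        raise DomainError("fit has no confidence interval; use individual-level data")
    lo, hi = fit.ci90
    if rng.low <= lo and hi <= rng.high:
        return ProportionalityVerdict(
            "proportional",
            f"90% CI ({lo:.2f}, {hi:.2f}) contained in acceptance range "
            f"({rng.low:.2f}, {rng.high:.2f})",
        )
    if hi < rng.low or lo > rng.high:
        return ProportionalityVerdict(
            "nonproportional",
            f"90% CI ({lo:.2f}, {hi:.2f}) disjoint from acceptance range "
            f"({rng.low:.2f}, {rng.high:.2f})",
        )
    covers = lo <= rng.low and rng.high <= hi
    note = "CI wider than and covering the acceptance range" if covers else \
        "CI partially overlaps the acceptance range"
    return ProportionalityVerdict(
        "inconclusive",
        f"{note}: CI ({lo:.2f}, {hi:.2f}) vs ({rng.low:.2f}, {rng.high:.2f})",
    )


def fold_range_ratio(geomeans_by_dose: dict[float, float]) -> tuple[float, float]:
    """(parameter fold-change, dose fold-change) between highest and lowest dose."""
    if len(geomeans_by_dose) < 2:
        raise InsufficientData("need at least two dose levels")
    d_lo, d_hi = min(geomeans_by_dose), max(geomeans_by_dose)
    g_lo, g_hi = geomeans_by_dose[d_lo], geomeans_by_dose[d_hi]
    if g_lo <= 0 or g_hi <= 0:
        raise DomainError("geometric means must be positive")
    return g_hi / g_lo, d_hi / d_lo
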
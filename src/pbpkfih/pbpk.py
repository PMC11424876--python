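"""Whole-body perfusion-limited PBPK simulator.

The body is 14 well-stirred tissue compartments — lung plus 13 systemic
tissues (adipose, muscle, liver, gut, spleen, heart, brain, kidney, skin,
reproductive organs, red marrow, yellow marrow, rest of body) — linked by
arterial and venous blood. Distribution is perfusion-limited: each tissue
exchanges with plasma at its blood flow Q_T, equilibrating toward
C_T = Kp_T * C_plasma. Oral input is a first-order depot emptying into the
portal inflow of the liver (gut and spleen venous outflow also perfuse the
liver); elimination is a lumped first-order hepatic clearance acting on the
liver outflow concentration. The whole system is linear in dose.

For a non-eliminating tissue:   V_T dC_T/dt = Q_T (C_art - C_T BP / Kp_T)
Lung sits in series at cardiac output between the venous and arterial pools.
Plasma concentration is reported as venous concentration / blood:plasma.

A useful exact identity of this formulation (used by the calibrator):
integrating the system gives AUC_plasma = f_abs * dose / cl_hepatic,
independent of flows, volumes, Kp and ka.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import CalibrationError, DomainError, SolverError, ValidationError
from .units import dose_mg_to_ug

#: systemic (non-lung) tissue names, in state-vector order
SYSTEMIC_TISSUES: tuple[str, ...] = (
    "adipose", "muscle", "liver", "gut", "spleen", "heart", "brain",
    "kidney", "skin", "reproductive", "red_marrow", "yellow_marrow",
    "rest_of_body",
)
ALL_TISSUES: tuple[str, ...] = ("lung",) + SYSTEMIC_TISSUES
PORTAL_TISSUES = ("gut", "spleen")

_FLOW_TOL = 1e-6


@dataclass(frozen=True)
class DrugParameters:
    """Compound-specific inputs.

    Molecular weight, LogP, pKa list, solubility and apparent permeability are
    carried as compound metadata (they justify the rapid-permeation,
    perfusion-limited treatment but do not enter the dynamics); the Kp map and
    blood:plasma ratio do.
    """

    molecular_weight: float
    logp: float
    pka_list: tuple[float, ...]
    solubility_mg_ml: float
    papp_cm_s: float
    kp: dict[str, float]
    blood_to_plasma: float = 1.0

    def __post_init__(self) -> None:
        for name, val in (("molecular_weight", self.molecular_weight),
                          ("solubility_mg_ml", self.solubility_mg_ml),
                          ("papp_cm_s", self.papp_cm_s),
                          ("blood_to_plasma", self.blood_to_plasma)):
            if val <= 0:
                raise ValidationError(f"{name} must be positive")
        unknown = set(self.kp) - set(ALL_TISSUES)
        missing = set(ALL_TISSUES) - set(self.kp)
        if unknown or missing:
            raise ValidationError(
                f"Kp map must cover exactly the model tissues; unknown={sorted(unknown)}, "
                f"missing={sorted(missing)}"
            )
        if any(v <= 0 for v in self.kp.values()):
            raise ValidationError("all Kp values must be positive")


@dataclass(frozen=True)
class Physiology:
    """Reference-human tissue volumes (L) and blood flows (L/h).

    ``flows['liver']`` is the hepatic-artery flow; total liver inflow is
    hepatic artery + gut + spleen. Lung flow equals cardiac output.
    """

    volumes: dict[str, float]          # per tissue, incl. lung
    flows: dict[str, float]            # per systemic tissue
    arterial_volume: float
    venous_volume: float
    cardiac_output: float
    body_weight_kg: float = 70.0

    def __post_init__(self) -> None:
        if set(self.volumes) != set(ALL_TISSUES):
            raise ValidationError("volumes must cover exactly the 14 model tissues")
        if set(self.flows) != set(SYSTEMIC_TISSUES):
            raise ValidationError("flows must cover exactly the 13 systemic tissues")
        vals = list(self.volumes.values()) + list(self.flows.values()) + [
            self.arterial_volume, self.venous_volume, self.cardiac_output]
        if any(v <= 0 for v in vals):
            raise ValidationError("all volumes and flows must be positive")
        imbalance = sum(self.flows.values()) - self.cardiac_output
        if abs(imbalance) > _FLOW_TOL * self.cardiac_output:
            raise ValidationError(
                f"systemic flows do not balance cardiac output (imbalance {imbalance:+.4g} L/h)"
            )

    @property
    def liver_inflow(self) -> float:
        return self.flows["liver"] + sum(self.flows[t] for t in PORTAL_TISSUES)


def default_physiology() -> Physiology:
    """The packaged 70-kg reference adult (cardiac output 390 L/h)."""
    from .reference import load_physiology  # deferred: reference imports this module

    return load_physiology()


@dataclass(frozen=True)
class AbsorptionModel:
    """First-order depot -> portal absorption with optional lag."""

    ka: float
    f_abs: float = 1.0
    tlag: float = 0.0

    def __post_init__(self) -> None:
        if self.ka <= 0 or not (0 < self.f_abs <= 1) or self.tlag < 0:
            raise ValidationError("need ka > 0, 0 < f_abs <= 1, tlag >= 0")


@dataclass(frozen=True)
class EliminationModel:
    """Lumped first-order hepatic clearance (L/h) on liver outflow concentration."""

    cl_hepatic: float

    def __post_init__(self) -> None:
        if self.cl_hepatic < 0:
            raise ValidationError("cl_hepatic must be >= 0")


# state vector: [depot, arterial, venous, lung, 13 systemic tissues, eliminated]
_IDX_DEPOT, _IDX_ART, _IDX_VEN, _IDX_LUNG = 0, 1, 2, 3
_IDX_TISSUE0 = 3  # lung occupies tissue slot 0
N_STATES = 4 + len(SYSTEMIC_TISSUES) + 1
_IDX_ELIM = N_STATES - 1


@dataclass(frozen=True)
class PBPKModel:
    drug: DrugParameters
    physiology: Physiology
    absorption: AbsorptionModel
    elimination: EliminationModel
    matrix: np.ndarray = field(repr=False, compare=False, default=None)

    def with_params(self, cl_hepatic: float | None = None, ka: float | None = None) -> "PBPKModel":
        absorption = self.absorption if ka is None else replace(self.absorption, ka=ka)
        elimination = (self.elimination if cl_hepatic is None
                       else EliminationModel(cl_hepatic))
        return build_model(self.drug, self.physiology, absorption, elimination)


def build_model(drug: DrugParameters, phys: Physiology,
                absorption: AbsorptionModel, elimination: EliminationModel) -> PBPKModel:
    """Assemble the (constant) rate matrix of the linear ODE system."""
    bp = drug.blood_to_plasma
    co = phys.cardiac_output
    m = np.zeros((N_STATES, N_STATES))
    tissue_index = {name: _IDX_TISSUE0 + i for i, name in enumerate(ALL_TISSUES)}

    # depot -> liver (portal) absorption
    i_liv = tissue_index["liver"]
    m[_IDX_DEPOT, _IDX_DEPOT] = -absorption.ka
    m[i_liv, _IDX_DEPOT] = absorption.ka

    # venous -> lung -> arterial, at cardiac output
    i_lung = tissue_index["lung"]
    k_lung_out = co * bp / (drug.kp["lung"] * phys.volumes["lung"])
    m[i_lung, _IDX_VEN] += co / phys.venous_volume
    m[_IDX_VEN, _IDX_VEN] += -co / phys.venous_volume
    m[_IDX_ART, i_lung] += k_lung_out
    m[i_lung, i_lung] += -k_lung_out

    liver_inflow = phys.liver_inflow
    for name in SYSTEMIC_TISSUES:
        i = tissue_index[name]
        q = phys.flows[name]
        # arterial supply (hepatic artery only, for liver)
        m[i, _IDX_ART] += q / phys.arterial_volume
        m[_IDX_ART, _IDX_ART] += -q / phys.arterial_volume
        k_out_conc = bp / (drug.kp[name] * phys.volumes[name])  # outflow conc per amount
        if name in PORTAL_TISSUES:
            m[i_liv, i] += q * k_out_conc
            m[i, i] += -q * k_out_conc
        elif name == "liver":
            m[_IDX_VEN, i] += liver_inflow * k_out_conc
            m[i, i] += -(liver_inflow + elimination.cl_hepatic) * k_out_conc
            m[_IDX_ELIM, i] += elimination.cl_hepatic * k_out_conc
        else:
            m[_IDX_VEN, i] += q * k_out_conc
            m[i, i] += -q * k_out_conc
    return PBPKModel(drug, phys, absorption, elimination, m)


@dataclass(frozen=True)
class SimulatedProfile:
    """Dense simulation output; amounts in ug, concentration in ng/mL."""

    times: np.ndarray
    plasma_conc: np.ndarray
    amounts: np.ndarray            # (n_times, n_tissues + 2 blood pools)
    amount_labels: tuple[str, ...]
    depot: np.ndarray
    eliminated: np.ndarray
    dose_mg: float
    f_abs: float

    def mass_balance_residual(self) -> float:
        """Max |depot + body + eliminated - f_abs*dose| over the grid, in ug."""
        total = self.depot + self.amounts.sum(axis=1) + self.eliminated
        return float(np.max(np.abs(total - self.f_abs * dose_mg_to_ug(self.dose_mg))))


def default_grid(t_end: float = 96.0) -> np.ndarray:
    """Reporting grid: 0.02 h steps through absorption, coarser after 12 h."""
    fine = np.arange(0.0, min(12.0, t_end), 0.02)
    coarse = np.arange(12.0, t_end + 1e-9, 0.25)
    return np.unique(np.concatenate([fine, coarse, [t_end]]))


def simulate(model: PBPKModel, dose_mg: float, t_grid: np.ndarray | None = None,
             rtol: float = 1e-8, atol: float = 1e-10) -> SimulatedProfile:
    """Integrate the model for a single oral dose.

    Stiff-capable adaptive integration (LSODA) with an analytic Jacobian;
    the absorption lag, if any, is handled by starting the depot at t = tlag.
    """
    if dose_mg < 0:
        raise DomainError("dose must be >= 0")
    if t_grid is None:
        t_grid = default_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 2 or t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must increase from 0")

    n_amount = len(ALL_TISSUES) + 2
    labels = ("arterial", "venous") + ALL_TISSUES
    if dose_mg == 0.0:
        z = np.zeros((t_grid.size, n_amount))
        return SimulatedProfile(t_grid, np.zeros(t_grid.size), z, labels,
                                np.zeros(t_grid.size), np.zeros(t_grid.size),
                                0.0, model.absorption.f_abs)

    m = model.matrix
    a0 = np.zeros(N_STATES)
    a0[_IDX_DEPOT] = model.absorption.f_abs * dose_mg_to_ug(dose_mg)
    tlag = model.absorption.tlag

    sol_y = np.zeros((N_STATES, t_grid.size))
    if tlag > 0:
        active = t_grid > tlag
        sol_y[:, ~active] = a0[:, None]  # nothing moves before the lag
        eval_times = t_grid[active] - tlag
    else:
        active = np.ones(t_grid.size, dtype=bool)
        eval_times = t_grid
    if eval_times.size:
        t_span = (0.0, float(eval_times[-1]) if eval_times[-1] > 0 else 1e-9)
        res = solve_ivp(
            lambda t, y: m @ y, t_span, a0, method="LSODA",
            t_eval=eval_times, jac=lambda t, y: m, rtol=rtol, atol=atol,
        )
        if not res.success:
            raise SolverError(f"integration failed at t={res.t[-1] if res.t.size else 0}: "
                              f"{res.message}")
        sol_y[:, active] = res.y
        if tlag == 0 and t_grid[0] == 0.0:
            sol_y[:, 0] = a0

    amounts = np.vstack([sol_y[_IDX_ART], sol_y[_IDX_VEN],
                         sol_y[_IDX_TISSUE0:_IDX_ELIM]]).T
    conc_ven = sol_y[_IDX_VEN] / model.physiology.venous_volume  # ug/L over blood? ug/L
    plasma = conc_ven / model.drug.blood_to_plasma               # ng/mL == ug/L
    return SimulatedProfile(t_grid, plasma, amounts, labels,
                            sol_y[_IDX_DEPOT], sol_y[_IDX_ELIM],
                            dose_mg, model.absorption.f_abs)


def auc_inf_exact(model: PBPKModel, dose_mg: float) -> float:
    """Exact AUC0-inf (h*ng/mL) of the linear system via a linear solve.

    Integrating dA/dt = M A from 0 to infinity gives M x = -A(0) for
    x = integral of A; the plasma AUC is x_venous / (V_ven * BP). Requires
    cl_hepatic > 0 (otherwise the AUC diverges).
    """
    if model.elimination.cl_hepatic <= 0:
        raise DomainError("AUC0-inf diverges with zero clearance")
    a0 = np.zeros(N_STATES - 1)
    a0[_IDX_DEPOT] = model.absorption.f_abs * dose_mg_to_ug(dose_mg)
    m = model.matrix[: N_STATES - 1, : N_STATES - 1]  # drop the eliminated row
    x = np.linalg.solve(m, -a0)
    return float(x[_IDX_VEN] / (model.physiology.venous_volume * model.drug.blood_to_plasma))


def vss(model: PBPKModel) -> float:
    """Steady-state distribution volume V_blood + sum V_T Kp_T / BP (L)."""
    phys, drug = model.physiology, model.drug
    return (phys.arterial_volume + phys.venous_volume
            + sum(phys.volumes[t] * drug.kp[t] for t in ALL_TISSUES) / drug.blood_to_plasma)


@dataclass(frozen=True)
class PredictedPK:
    cmax: float
    tmax: float
    auc_0inf: float


def predicted_pk(sim: SimulatedProfile, terminal_window: float = 24.0) -> PredictedPK:
    """Cmax/Tmax from the dense curve; AUC0-inf by trapezoid plus
    terminal-slope extrapolation (log-linear fit over the last
    ``terminal_window`` hours of the grid)."""
    from . import nca  # local import: nca is a sibling, not a dependency cycle

    c = sim.plasma_conc
    if not np.any(c > 0):
        raise DomainError("degenerate (all-zero) profile")
    i = int(np.argmax(c))
    cmax, tmax = float(c[i]), float(sim.times[i])
    auc_0t = nca.auc_from_arrays(sim.times, c, label="simulated profile")
    tail = (sim.times >= sim.times[-1] - terminal_window) & (c > 0)
    slope, _, _ = nca._loglin_fit(sim.times[tail], np.log(c[tail]))
    if slope >= 0:
        raise DomainError("no terminal decline on the simulation grid")
    auc_inf, _ = nca.extrapolate_auc_inf(auc_0t, float(c[-1]), -slope)
    return PredictedPK(cmax, tmax, auc_inf)


def terminal_slope(sim: SimulatedProfile, window: float = 24.0) -> float:
    """First-order terminal rate (1/h) fitted on the last ``window`` hours."""
    from . import nca

    mask = (sim.times >= sim.times[-1] - window) & (sim.plasma_conc > 0)
    slope, _, _ = nca._loglin_fit(sim.times[mask], np.log(sim.plasma_conc[mask]))
    return -slope


def calibrate(
    model: PBPKModel,
    reference_dose_mg: float,
    targets: tuple[float, float],
    cl_bracket: tuple[float, float] = (1e-2, 1e5),
    ka_bracket: tuple[float, float] = (1e-4, 1e3),
    rel_tol: float = 5e-3,
    t_grid: np.ndarray | None = None,
) -> PBPKModel:
    """Fit (cl_hepatic, ka) to a reference dose's (Cmax, AUC0-inf).

    Nested bracketed root finding: the outer loop adjusts cl_hepatic to match
    AUC0-inf (AUC is monotone decreasing in clearance and independent of ka in
    this formulation, so it converges immediately), the inner loop adjusts ka
    to match Cmax (monotone increasing in ka at fixed AUC). Converged when
    both targets are met within ``rel_tol`` relative.
    """
    cmax_target, auc_target = targets
    if cmax_target <= 0 or auc_target <= 0:
        raise CalibrationError("calibration targets must be positive")
    if t_grid is None:
        t_grid = default_grid()

    def auc_err(log_cl: float) -> float:
        return auc_inf_exact(model.with_params(cl_hepatic=10 ** log_cl),
                             reference_dose_mg) - auc_target

    lo, hi = math.log10(cl_bracket[0]), math.log10(cl_bracket[1])
    e_lo, e_hi = auc_err(lo), auc_err(hi)
    if e_lo * e_hi > 0:
        lim = sorted([e_lo + auc_target, e_hi + auc_target])
        raise CalibrationError(
            f"AUC target {auc_target} outside achievable range [{lim[0]:.4g}, {lim[1]:.4g}] "
            f"for cl bracket {cl_bracket}"
        )
    cl = 10 ** brentq(auc_err, lo, hi, xtol=1e-10)

    def cmax_of(ka: float) -> float:
        trial = model.with_params(cl_hepatic=cl, ka=ka)
        return float(np.max(simulate(trial, reference_dose_mg, t_grid).plasma_conc))

    klo, khi = math.log10(ka_bracket[0]), math.log10(ka_bracket[1])
    f_lo = cmax_of(10 ** klo) - cmax_target
    f_hi = cmax_of(10 ** khi) - cmax_target
    if f_lo * f_hi > 0:
        lim = sorted([f_lo + cmax_target, f_hi + cmax_target])
        raise CalibrationError(
            f"Cmax target {cmax_target} outside achievable range [{lim[0]:.4g}, {lim[1]:.4g}] "
            f"for ka bracket {ka_bracket}"
        )
    log_ka = brentq(lambda lk: cmax_of(10 ** lk) - cmax_target, klo, khi, xtol=1e-8)
    ka = 10 ** log_ka

    calibrated = model.with_params(cl_hepatic=cl, ka=ka)
    sim = simulate(calibrated, reference_dose_mg, t_grid)
    got_cmax = float(np.max(sim.plasma_conc))
    got_auc = auc_inf_exact(calibrated, reference_dose_mg)
    if (abs(got_cmax - cmax_target) > rel_tol * cmax_target
            or abs(got_auc - auc_target) > rel_tol * auc_target):
        raise CalibrationError(
            f"calibration did not converge: Cmax {got_cmax:.4g} vs {cmax_target}, "
            f"AUC {got_auc:.4g} vs {auc_target}"
        )
    return calibrated


def dose_scan(model: PBPKModel, doses_mg: list[float],
              t_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Predicted (Cmax, Tmax, AUC0-inf) per dose, one simulation each."""
    if t_grid is None:
        t_grid = default_grid()
    rows, errors = [], []
    for d in doses_mg:
        try:
            pk = predicted_pk(simulate(model, d, t_grid))
            rows.append({"dose_mg": d, "cmax": pk.cmax, "tmax": pk.tmax,
                         "auc_0inf": pk.auc_0inf})
        except (SolverError, DomainError) as exc:  # continue with other doses
            errors.append((d, str(exc)))
            rows.append({"dose_mg": d, "cmax": np.nan, "tmax": np.nan,
                         "auc_0inf": np.nan})
    frame = pd.DataFrame(rows)
    frame.attrs["errors"] = errors
    return frame
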
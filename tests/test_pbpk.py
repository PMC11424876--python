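"""Whole-body PBPK simulator: structure, conservation laws, calibration."""

import dataclasses

import numpy as np
import pytest

from pbpkfih import pbpk, reference
from pbpkfih.cohort import bateman_cmax_auc
from pbpkfih.errors import CalibrationError, DomainError, ValidationError

DOSES = [2.0, 6.0, 12.0, 24.0, 40.0, 60.0, 90.0]


def scaled_flows(phys, factor):
    return pbpk.Physiology(
        volumes=phys.volumes, flows={k: v * factor for k, v in phys.flows.items()},
        arterial_volume=phys.arterial_volume, venous_volume=phys.venous_volume,
        cardiac_output=phys.cardiac_output * factor,
        body_weight_kg=phys.body_weight_kg)


class TestStructure:
    def test_default_model_states(self, base_model):
        # 14 tissues + arterial + venous + depot + eliminated accumulator
        assert base_model.matrix.shape == (18, 18)
        assert len(pbpk.ALL_TISSUES) == 14

    def test_kp_map_must_cover_tissues(self, drug_config):
        drug = reference.drug_parameters(drug_config)
        bad = dict(drug.kp)
        bad["pancreas"] = bad.pop("gut")
        with pytest.raises(ValidationError, match="pancreas"):
            dataclasses.replace(drug, kp=bad)

    def test_flow_imbalance_rejected(self):
        phys = reference.load_physiology()
        flows = dict(phys.flows)
        flows["gut"] *= 1.5  # breaks the cardiac-output (and liver inflow) balance
        with pytest.raises(ValidationError, match="imbalance"):
            pbpk.Physiology(volumes=phys.volumes, flows=flows,
                            arterial_volume=phys.arterial_volume,
                            venous_volume=phys.venous_volume,
                            cardiac_output=phys.cardiac_output)

    def test_uniform_steady_state_with_unit_kp_and_no_clearance(self, unit_kp_drug):
        phys = reference.load_physiology()
        model = pbpk.build_model(unit_kp_drug, phys,
                                 pbpk.AbsorptionModel(ka=0.5),
                                 pbpk.EliminationModel(0.0))
        grid = np.linspace(0.0, 500.0, 1001)
        sim = pbpk.simulate(model, 60.0, grid)
        vols = np.array([phys.arterial_volume, phys.venous_volume]
                        + [phys.volumes[t] for t in pbpk.ALL_TISSUES])
        concs = sim.amounts[-1] / vols
        assert concs == pytest.approx(np.full_like(concs, 60000.0 / pbpk.vss(model)),
                                      rel=1e-6)


class TestSimulate:
    def test_zero_dose_zero_profile(self, base_model):
        sim = pbpk.simulate(base_model, 0.0)
        assert not np.any(sim.plasma_conc)
        assert sim.mass_balance_residual() == 0.0

    @pytest.mark.parametrize("dose", DOSES)
    def test_mass_balance(self, calibrated_model, dose):
        sim = pbpk.simulate(calibrated_model, dose)
        assert sim.mass_balance_residual() <= 1e-6 * dose * 1000.0

    def test_linearity_in_dose(self, calibrated_model):
        grid = pbpk.default_grid()
        c1 = pbpk.simulate(calibrated_model, 6.0, grid).plasma_conc
        c5 = pbpk.simulate(calibrated_model, 30.0, grid).plasma_conc
        assert c5 == pytest.approx(5.0 * c1, rel=1e-6, abs=1e-12)

    def test_no_clearance_distribution_equilibrium(self, base_model):
        model = base_model.with_params(cl_hepatic=0.0)
        grid = np.linspace(0.0, 3000.0, 1501)
        sim = pbpk.simulate(model, 12.0, grid)
        assert sim.amounts[-1].sum() == pytest.approx(12000.0, rel=1e-6)
        assert sim.plasma_conc[-1] == pytest.approx(12000.0 / pbpk.vss(model), rel=1e-5)

    def test_auc_diverges_without_clearance(self, base_model):
        with pytest.raises(DomainError):
            pbpk.auc_inf_exact(base_model.with_params(cl_hepatic=0.0), 10.0)

    def test_refinement_convergence(self, calibrated_model):
        grid = pbpk.default_grid()
        a = pbpk.predicted_pk(pbpk.simulate(calibrated_model, 60.0, grid))
        b = pbpk.predicted_pk(pbpk.simulate(calibrated_model, 60.0, grid,
                                            rtol=5e-9, atol=5e-11))
        assert b.cmax == pytest.approx(a.cmax, rel=1e-4)
        assert b.auc_0inf == pytest.approx(a.auc_0inf, rel=1e-4)

    def test_simulated_auc_matches_linear_solve(self, calibrated_model):
        pk = pbpk.predicted_pk(pbpk.simulate(calibrated_model, 24.0))
        assert pk.auc_0inf == pytest.approx(
            pbpk.auc_inf_exact(calibrated_model, 24.0), rel=1e-3)

    def test_one_compartment_limit(self, unit_kp_drug):
        # with uniform Kp and flows much faster than absorption/elimination
        # the body collapses to one well-mixed compartment: the plasma curve
        # approaches the closed-form one-compartment oral solution
        phys = scaled_flows(reference.load_physiology(), 10.0)
        model = pbpk.build_model(unit_kp_drug, phys,
                                 pbpk.AbsorptionModel(ka=0.05),
                                 pbpk.EliminationModel(5.0))
        v = pbpk.vss(model)
        pk = pbpk.predicted_pk(pbpk.simulate(model, 60.0))
        cmax_ref, auc_ref = bateman_cmax_auc(60.0, v, 0.05, 5.0 / v)
        assert pk.cmax == pytest.approx(cmax_ref, rel=5e-3)
        assert pk.auc_0inf == pytest.approx(auc_ref, rel=2e-3)


class TestTerminalPhase:
    def test_terminal_slope_dose_independent(self, calibrated_model):
        slopes = [pbpk.terminal_slope(pbpk.simulate(calibrated_model, d)) for d in (2.0, 90.0)]
        assert slopes[0] == pytest.approx(slopes[1], rel=1e-6)

    def test_terminal_slope_ka_independent_when_absorption_fast(self, base_model):
        # outside the flip-flop regime (ka far above the disposition rates)
        # the terminal slope is a disposition property, not an absorption one
        m_lo = base_model.with_params(cl_hepatic=20.0, ka=20.0)
        m_hi = base_model.with_params(cl_hepatic=20.0, ka=100.0)
        grid = pbpk.default_grid(200.0)
        s_lo = pbpk.terminal_slope(pbpk.simulate(m_lo, 60.0, grid), window=50.0)
        s_hi = pbpk.terminal_slope(pbpk.simulate(m_hi, 60.0, grid), window=50.0)
        assert s_lo == pytest.approx(s_hi, rel=1e-3)

    def test_cmax_monotone_in_ka(self, calibrated_model):
        cmaxes = [
            float(np.max(pbpk.simulate(calibrated_model.with_params(ka=ka), 60.0).plasma_conc))
            for ka in (0.05, 0.2, 1.0, 10.0)]
        assert np.all(np.diff(cmaxes) > 0)


class TestCalibration:
    def test_reference_targets_reproduced(self, calibrated_model, drug_config):
        ref_dose, (cmax_t, auc_t) = reference.calibration_reference(drug_config)
        sim = pbpk.simulate(calibrated_model, ref_dose)
        assert float(np.max(sim.plasma_conc)) == pytest.approx(cmax_t, rel=5e-3)
        assert pbpk.auc_inf_exact(calibrated_model, ref_dose) == pytest.approx(auc_t, rel=5e-3)

    def test_parameter_recovery(self, base_model):
        truth = base_model.with_params(cl_hepatic=300.0, ka=0.12)
        sim = pbpk.simulate(truth, 60.0)
        targets = (float(np.max(sim.plasma_conc)), pbpk.auc_inf_exact(truth, 60.0))
        recovered = pbpk.calibrate(base_model, 60.0, targets)
        assert recovered.elimination.cl_hepatic == pytest.approx(300.0, rel=0.01)
        assert recovered.absorption.ka == pytest.approx(0.12, rel=0.01)

    def test_unreachable_target_fails(self, base_model):
        with pytest.raises(CalibrationError):
            pbpk.calibrate(base_model, 60.0, (12.26, 0.0))

    def test_flow_perturbation_robustness(self, drug_config):
        # +/-20% on all flows, recalibrated: dose-scan AUCs are unchanged
        # (AUC depends only on f_abs*D/cl after calibration)
        ref_dose, targets = reference.calibration_reference(drug_config)
        drug = reference.drug_parameters(drug_config)
        absn = reference.absorption_model(drug_config)
        elim = reference.elimination_model(drug_config)
        aucs = []
        for factor in (0.8, 1.2):
            phys = scaled_flows(reference.load_physiology(), factor)
            model = pbpk.calibrate(pbpk.build_model(drug, phys, absn, elim),
                                   ref_dose, targets)
            aucs.append([pbpk.auc_inf_exact(model, d) for d in DOSES])
        assert aucs[0] == pytest.approx(aucs[1], rel=5e-3)


class TestDoseScan:
    def test_auc_strictly_dose_proportional(self, calibrated_model):
        table = pbpk.dose_scan(calibrated_model, DOSES)
        per_mg = table["auc_0inf"] / table["dose_mg"]
        assert per_mg.max() / per_mg.min() == pytest.approx(1.0, rel=1e-3)
        ratio = (table.set_index("dose_mg").loc[90.0, "auc_0inf"]
                 / table.set_index("dose_mg").loc[60.0, "auc_0inf"])
        assert ratio == pytest.approx(1.5, rel=1e-3)

    def test_single_dose(self, calibrated_model):
        table = pbpk.dose_scan(calibrated_model, [24.0])
        assert len(table) == 1 and table.loc[0, "dose_mg"] == 24.0
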
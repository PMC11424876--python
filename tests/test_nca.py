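"""Non-compartmental analysis against closed-form and enumeration oracles."""

import math

import numpy as np
import pytest

from pbpkfih import nca
from pbpkfih.cohort import bateman, bateman_cmax_auc
from pbpkfih.errors import DomainError, InsufficientData
from pbpkfih.pk_dataset import DEFAULT_SCHEDULE

from conftest import make_profile, prepared

SCHEDULE = np.array(DEFAULT_SCHEDULE)
KA, KE = 0.8, 0.0442  # 1/h; absorption and elimination of the oracle curve


def bateman_profile(dose=24.0, v_f=5300.0, ka=KA, ke=KE, times=SCHEDULE):
    return prepared(times, bateman(times, dose, v_f, ka, ke), dose=dose)


class TestCmaxTmax:
    def test_direct_maximum(self):
        assert nca.compute_cmax_tmax(prepared([0, 1, 2], [0, 5, 3])) == (5.0, 1.0)

    def test_tie_breaks_to_earliest(self):
        assert nca.compute_cmax_tmax(prepared([1, 2], [4, 4])) == (4.0, 1.0)

    def test_bateman_on_schedule_matches_closed_form(self):
        # the sampled Tmax is the schedule point where the closed form is
        # largest; Cmax is bounded by the analytic peak value
        prep = bateman_profile()
        cmax, tmax = nca.compute_cmax_tmax(prep)
        curve = bateman(SCHEDULE, 24.0, 5300.0, KA, KE)
        assert tmax == SCHEDULE[int(np.argmax(curve))] == 4.0
        tstar = math.log(KA / KE) / (KA - KE)
        analytic_peak = float(bateman(np.array([tstar]), 24.0, 5300.0, KA, KE)[0])
        assert cmax <= analytic_peak
        assert cmax == pytest.approx(analytic_peak, rel=0.01)


class TestAuc:
    def test_triangle(self):
        assert nca.auc_linuplogdown(prepared([0, 1], [0, 2])) == pytest.approx(1.0)

    def test_log_trapezoid_closed_form(self):
        # (10-5)/ln(10/5) * 1 h
        assert nca.auc_linuplogdown(prepared([0, 1], [10, 5])) == pytest.approx(
            5.0 / math.log(2.0))

    def test_piecewise_segment_sum(self):
        # linear rise + flat (linear) + log-down: 1 + 2 + 1/ln 2
        prep = prepared([0, 1, 2, 3], [0, 2, 2, 1])
        assert nca.auc_linuplogdown(prep) == pytest.approx(3.0 + 1.0 / math.log(2.0))

    def test_pure_linear_method(self):
        prep = prepared([0, 1, 2], [0, 10, 5])
        assert nca.auc_linuplogdown(prep, method="linear") == pytest.approx(5.0 + 7.5)

    def test_needs_two_points(self):
        with pytest.raises(InsufficientData):
            nca.auc_linuplogdown(prepared([1.0], [5.0]))

    def test_t_end_beyond_data_rejected(self):
        with pytest.raises(DomainError):
            nca.auc_linuplogdown(prepared([0, 1], [0, 1]), t_end=2.0)

    @pytest.mark.parametrize("split", list(SCHEDULE[1:-1]))
    def test_additivity_at_interior_points(self, split):
        prep = bateman_profile()
        total = nca.auc_linuplogdown(prep)
        left = nca.auc_linuplogdown(prep, t_end=split)
        right = nca.auc_from_arrays(
            prep.analysis_times[prep.analysis_times >= split],
            prep.analysis_concs[prep.analysis_times >= split])
        assert left + right == pytest.approx(total, rel=1e-12)


class TestLambdaZ:
    def test_exact_exponential_uses_all_points(self):
        t = np.array([24.0, 36.0, 48.0, 72.0])
        prep = prepared(t, 10 * np.exp(-0.1 * t))
        fit = nca.fit_lambda_z(prep)
        assert fit.lambda_z == pytest.approx(0.1, rel=1e-12)
        assert fit.r2_adj == pytest.approx(1.0)
        assert fit.n_points == 4

    def test_distribution_outlier_excluded_by_best_fit(self):
        # an early distribution-phase point far above the terminal line
        t = np.array([8.0, 24.0, 36.0, 48.0, 72.0])
        c = 10 * np.exp(-0.1 * t)
        c[0] *= 4.0
        prep = prepared(t, c)
        fit = nca.fit_lambda_z(prep)
        assert fit.window[0] == 24.0 and fit.n_points == 4
        # independent enumeration of every candidate suffix window
        best = max(
            (nca._loglin_fit(t[s:], np.log(c[s:]))[2], len(t) - s, -s)
            for s in range(len(t) - 2))
        assert fit.r2_adj == pytest.approx(best[0])
        assert fit.n_points == best[1]

    def test_too_few_post_peak_points(self):
        # rising first point: the peak is not bolus-like, so Cmax itself is
        # ineligible and only two post-peak points remain
        prep = prepared([0, 1, 2, 3], [1, 10, 6, 4])
        assert nca.fit_lambda_z(prep) is None

    def test_no_terminal_decline(self):
        prep = prepared([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        assert nca.fit_lambda_z(prep) is None


class TestExtrapolation:
    def test_formula(self):
        auc, pct = nca.extrapolate_auc_inf(100.0, 1.0, 0.05)
        assert auc == pytest.approx(120.0)
        assert pct == pytest.approx(100 * 20 / 120)

    def test_vanishing_tail(self):
        auc, pct = nca.extrapolate_auc_inf(100.0, 1e-4, 1.0)
        assert auc == pytest.approx(100.0001)
        assert pct == pytest.approx(1e-4, rel=1e-2)

    def test_bateman_extrapolation_within_1pct(self):
        res = nca.analyze_profile(
            make_profile(SCHEDULE, bateman(SCHEDULE, 24.0, 5300.0, KA, KE), dose=24.0))
        _, auc_ref = bateman_cmax_auc(24.0, 5300.0, KA, KE)
        assert res.auc_0inf == pytest.approx(auc_ref, rel=0.01)

    def test_noise_free_bateman_recovers_ke_to_4sf(self):
        res = nca.analyze_profile(
            make_profile(SCHEDULE, bateman(SCHEDULE, 24.0, 5300.0, KA, KE), dose=24.0))
        assert res.lambda_z == pytest.approx(KE, rel=5e-4)
        assert res.auc_0inf >= res.auc_0t


class TestSecondary:
    @pytest.mark.parametrize("dose,auc,expected", [(2.0, 11.9, 168.07), (6.0, 24.7, 242.91)])
    def test_clearance_from_dose_and_auc(self, dose, auc, expected):
        _, cl_f = nca.derive_secondary(dose, auc, 0.05)
        assert cl_f == pytest.approx(expected, abs=0.005)

    def test_half_life_identity(self):
        t_half, _ = nca.derive_secondary(1.0, 1.0, math.log(2.0))
        assert t_half == pytest.approx(1.0)

    def test_positive_inputs_required(self):
        with pytest.raises(DomainError):
            nca.derive_secondary(0.0, 1.0, 1.0)


class TestGroupSummary:
    def _results(self, cl_values, dose=24.0):
        return [
            nca.NCAResult(f"S{i}", dose, 1.0, 3.0, 10.0, 12.0, 0.05, 14.0, v, 3, 0.99, 10.0)
            for i, v in enumerate(cl_values)
        ]

    def test_zero_variance(self):
        s = nca.summarize_group(self._results([5.0, 5.0, 5.0]))
        assert s.geomean["cl_f"] == pytest.approx(5.0)
        assert s.geocv_pct["cl_f"] == pytest.approx(0.0)

    def test_two_point_hand_computation(self):
        s = nca.summarize_group(self._results([1.0, math.e ** 2]))
        assert s.geomean["cl_f"] == pytest.approx(math.e)
        # s = sqrt(2) for logs {0, 2}; geoCV = 100*sqrt(exp(2)-1)
        assert s.geocv_pct["cl_f"] == pytest.approx(100 * math.sqrt(math.e ** 2 - 1))

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(11)
        sigma = math.sqrt(math.log(1 + 0.45 ** 2))
        vals = rng.lognormal(math.log(234.0), sigma, size=1000)
        gm, cv = nca.geometric_stats(vals)
        assert gm == pytest.approx(234.0, rel=0.03)
        assert cv == pytest.approx(45.0, rel=0.05)

    def test_undefined_parameters_excluded_with_warning(self):
        results = self._results([5.0, 5.0])
        results.append(nca.NCAResult("S9", 24.0, 1.0, 3.0, 10.0, None, None,
                                     None, None, 0, None, None))
        with pytest.warns(UserWarning, match="excluded"):
            s = nca.summarize_group(results)
        assert s.n == 3 and s.geomean["cl_f"] == pytest.approx(5.0)
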
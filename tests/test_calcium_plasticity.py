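import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.interpolate import CubicSpline

import ioniccable as ic
from ioniccable.calcium_plasticity import (
    CalciumSystem,
    CalciumTransient,
    PlasticityRule,
    calcium_influx_series,
    drive_variable,
    eta,
    omega,
    rba_reduce,
    solve_calcium,
    weight_change_single_pairing,
    weight_evolve_train,
)
from ioniccable.model_core import StimulusEvents, ValidationError, derive_constants


class TestRBA:
    def test_no_buffer_recovers_free_diffusion(self):
        sys0 = CalciumSystem(B_total_uM=0.0)
        rba = rba_reduce(sys0, diameter_um=1.0)
        assert rba.D_eff_um2_ms == pytest.approx(sys0.D_Ca_um2_ms)
        assert rba.source_scale == 1.0

    def test_buffering_reshapes_the_chemical_constants(self):
        # buffering slows the effective decay (tau_c grows with B_T); an
        # immobile buffer leaves lambda_c = sqrt(D_eff/k) unchanged while a
        # mobile one adds transport and lengthens it
        taus, lam_mobile, lam_fixed = [], [], []
        for bt in (0.0, 20.0, 100.0, 400.0):
            taus.append(rba_reduce(CalciumSystem(B_total_uM=bt), 1.0).tau_c_ms)
            lam_mobile.append(rba_reduce(CalciumSystem(B_total_uM=bt), 1.0).lambda_c_um)
            lam_fixed.append(
                rba_reduce(CalciumSystem(B_total_uM=bt, D_B_um2_ms=0.0), 1.0).lambda_c_um
            )
        assert np.all(np.diff(taus) > 0)
        assert np.all(np.diff(lam_mobile) > 0)
        np.testing.assert_allclose(lam_fixed, lam_fixed[0], rtol=1e-12)

    def test_pump_linearity(self):
        r1 = rba_reduce(CalciumSystem(pump_Pm_um_ms=1.0), 1.0)
        r2 = rba_reduce(CalciumSystem(pump_Pm_um_ms=2.0), 1.0)
        assert r2.decay_per_ms == pytest.approx(2.0 * r1.decay_per_ms)

    def test_internal_consistency(self):
        rba = rba_reduce(CalciumSystem(), 1.0)
        assert rba.lambda_c_um == pytest.approx(
            np.sqrt(rba.D_eff_um2_ms / rba.decay_per_ms)
        )
        assert rba.tau_c_ms == pytest.approx(1.0 / rba.decay_per_ms)

    def test_geometry_receives_chemical_constants(self):
        sys0 = CalciumSystem()
        geom = derive_constants(calcium=sys0)
        rba = rba_reduce(sys0, geom.diameter_um)
        assert geom.lambda_c_um == pytest.approx(rba.lambda_c_um)
        assert geom.tau_c_ms == pytest.approx(rba.tau_c_ms)


class TestChemicalCable:
    def test_zero_sources_stay_at_rest(self):
        sys0 = CalciumSystem()
        geom = derive_constants(calcium=sys0)
        t = np.arange(0.0, 50.0, 0.1)
        [tr] = solve_calcium({}, sys0, geom, [10.0], t)
        np.testing.assert_array_equal(tr.conc_uM, 0.0)

    def test_point_source_matches_independent_quadrature(self):
        # unit-rate source at depth 5 in a system engineered so the
        # effective constants are D = 1 um^2/ms, k = 1/ms (buffer absent)
        sys0 = CalciumSystem(D_Ca_um2_ms=1.0, B_total_uM=0.0, pump_Pm_um_ms=0.25)
        geom = derive_constants(calcium=sys0)
        rba = rba_reduce(sys0, 1.0)
        assert rba.D_eff_um2_ms == pytest.approx(1.0)
        assert rba.decay_per_ms == pytest.approx(1.0)
        dt = 0.002
        t = np.arange(0.0, 8.0 + dt / 2, dt)
        src = {("J", 0, 5.0): np.ones_like(t)}
        [tr] = solve_calcium(src, sys0, geom, [5.0], t)

        def kern(u):
            pref = np.exp(-u) / np.sqrt(4 * np.pi * u)
            return pref * (1.0 - np.exp(-100.0 / (4.0 * u)))

        for tq in (0.5, 2.0, 8.0):
            exact = quad(kern, 0, tq, points=[1e-6], limit=400)[0]
            i = int(round(tq / dt))
            assert tr.conc_uM[i] == pytest.approx(exact, abs=1e-6)
        # and the self term alone has the closed form erf(sqrt(t))/2
        assert quad(lambda u: np.exp(-u) / np.sqrt(4 * np.pi * u), 0, 4.0)[0] == (
            pytest.approx(0.5 * __import__('math').erf(2.0), abs=1e-10)
        )

    def test_peak_decays_with_distance_from_source(self):
        sys0 = CalciumSystem()
        geom = derive_constants(calcium=sys0)
        dt = 0.05
        t = np.arange(0.0, 60.0, dt)
        src = {("J", 0, 50.0): np.where(t < 5.0, 1.0, 0.0)}
        probes = [50.0, 51.0, 52.5, 55.0]
        trs = solve_calcium(src, sys0, geom, probes, t)
        peaks = [tr.peak for tr in trs]
        assert np.all(np.diff(peaks) < 0)

    def test_negative_probe_rejected(self):
        sys0 = CalciumSystem()
        geom = derive_constants(calcium=sys0)
        with pytest.raises(ValidationError):
            solve_calcium({}, sys0, geom, [-1.0], np.arange(0.0, 1.0, 0.1))


class TestInflux:
    def test_no_calcium_hotspots_no_sources(self, passive_model):
        t = np.arange(0.0, 30.0, 0.1)
        ev = StimulusEvents(post_onsets_ms=(5.0,))
        sol = ic.solve_voltage(passive_model, ev, outputs_um=[50.0], t_max_ms=30.0)
        out = calcium_influx_series(sol, passive_model, sol.t_ms, ev)
        assert all(not np.any(series) for series in out.values())

    def test_rest_voltage_gives_negligible_influx(self, model):
        ev = StimulusEvents()  # no AP, no presynaptic event
        sol = ic.solve_voltage(model, ev, outputs_um=[model.nmda.x_um], t_max_ms=30.0)
        out = calcium_influx_series(sol, model, sol.t_ms, ev,
                                    sites_um=[model.nmda.x_um])
        for series in out.values():
            assert np.max(np.abs(series)) < 1e-4

    def test_linearity_in_channel_counts(self, model):
        import dataclasses

        ev = StimulusEvents(post_onsets_ms=(5.0,))
        sol = ic.solve_voltage(model, ev, outputs_um=[model.nmda.x_um], t_max_ms=40.0)
        base = calcium_influx_series(sol, model, sol.t_ms, ev,
                                     sites_um=[model.nmda.x_um])
        m2 = dataclasses.replace(model)
        m2.channels = {
            k: (v.scaled(2.0) if v.carries_calcium else v)
            for k, v in model.channels.items()
        }
        doubled = calcium_influx_series(sol, m2, sol.t_ms, ev,
                                        sites_um=[model.nmda.x_um])
        for key in base:
            np.testing.assert_allclose(doubled[key], 2.0 * base[key], rtol=1e-12)


class TestRule:
    rule = PlasticityRule()

    def test_omega_baseline_and_saturation(self):
        assert omega(0.0, self.rule) == pytest.approx(self.rule.baseline, abs=1e-9)
        assert omega(5.0, self.rule) == pytest.approx(1.0, abs=1e-6)
        mid = 0.5 * (self.rule.theta_d + self.rule.theta_p)
        assert omega(mid, self.rule) < self.rule.baseline

    def test_omega_continuous(self):
        ca = np.linspace(0, 1.5, 20001)
        om = omega(ca, self.rule)
        assert np.max(np.abs(np.diff(om))) < 2e-3

    def test_eta_rest_and_monotone(self):
        assert eta(0.0, self.rule) < 2e-4
        ca = np.linspace(0.0, 2.0, 500)
        assert np.all(np.diff(eta(ca, self.rule)) >= 0)

    def test_eta_dual_path_evaluation(self):
        grid = np.linspace(0.0, 2.0, 40001)
        spline = CubicSpline(grid, eta(grid, self.rule))
        probe = np.linspace(0.05, 1.95, 137)
        np.testing.assert_allclose(spline(probe), eta(probe, self.rule), atol=1e-10)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValidationError, match="theta"):
            PlasticityRule(theta_d=0.6, theta_p=0.5)

    @given(
        theta_d=st.floats(0.2, 0.6),
        gap=st.floats(0.1, 0.5),
        beta=st.floats(40.0, 200.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_sign_structure_property(self, theta_d, gap, beta):
        """Calcium-control hypothesis: no change below theta_d, depression
        between the thresholds, potentiation above (sampled away from the
        sigmoid transition widths)."""
        rule = PlasticityRule(theta_d=theta_d, theta_p=theta_d + gap,
                              beta1=beta, beta2=beta)
        margin = 6.0 / beta
        below = max(theta_d - 2 * margin, 0.0)
        mid = 0.5 * (rule.theta_d + rule.theta_p)
        above = rule.theta_p + 2 * margin
        assert abs(weight_change_single_pairing(below, rule)) < 0.02
        if gap > 2 * margin:
            assert weight_change_single_pairing(mid, rule) < 0.0
        assert weight_change_single_pairing(above, rule) > 0.0


class TestDriveVariable:
    def test_flat_transient_zero_drive(self):
        t = np.arange(0.0, 10.0, 0.1)
        tr = CalciumTransient(t, np.zeros_like(t), rest_uM=0.05)
        assert drive_variable(tr, "peak") == 0.0
        assert drive_variable(tr, "ratio") == 0.0

    def test_rectangle_ratio_hand_value(self):
        tr = ic.make_fixture("transient", {"height_uM": 2.0, "duration_ms": 20.0,
                                           "dt_ms": 0.01})
        # peak h over integral h*d: 1/d  (within one grid step of the edge)
        assert drive_variable(tr, "ratio") == pytest.approx(1.0 / 20.0, rel=1e-3)
        assert drive_variable(tr, "peak", normalizer=4.0) == pytest.approx(0.5)

    def test_scaling_homogeneity(self):
        tr = ic.make_fixture("transient", {"height_uM": 1.0})
        tr2 = CalciumTransient(tr.t_ms, 2.0 * tr.conc_uM, tr.rest_uM)
        assert drive_variable(tr2, "peak") == pytest.approx(2 * drive_variable(tr, "peak"))
        assert drive_variable(tr2, "ratio") == pytest.approx(drive_variable(tr, "ratio"))

    def test_unknown_mode_rejected(self):
        tr = ic.make_fixture("transient")
        with pytest.raises(ValidationError):
            drive_variable(tr, "median")


class TestWeightEvolution:
    def test_zero_drive_no_change(self):
        assert weight_evolve_train(np.zeros(100)) == pytest.approx(0.0, abs=1e-3)

    def test_two_separated_pairings_accumulate(self):
        rule = PlasticityRule()
        single = weight_change_single_pairing(0.8, rule)
        train = weight_evolve_train(np.array([0.8, 0.8]), rule, dt_s=1.0)
        assert train == pytest.approx(2.0 * single, rel=0.05)

    def test_no_decay_reduces_to_running_integral(self):
        rule = PlasticityRule(lambda_w=0.0)
        D = np.array([0.3, 0.45, 0.7, 0.9])
        expected = np.sum(eta(D, rule) * (omega(D, rule) - rule.baseline)) * 0.5
        assert weight_evolve_train(D, rule, dt_s=0.5) == pytest.approx(expected)

    def test_decay_variant_matches_closed_form(self):
        # constant drive: W(t) = W_inf (1 - exp(-eta lambda t))
        rule = PlasticityRule(lambda_w=0.8)
        D = 0.9
        n, dt_s = 50, 0.2
        e, om = float(eta(D, rule)), float(omega(D, rule) - rule.baseline)
        expected = om / 0.8 * (1.0 - np.exp(-e * 0.8 * n * dt_s))
        assert weight_evolve_train(np.full(n, D), rule, dt_s=dt_s) == pytest.approx(
            expected, rel=1e-9
        )
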
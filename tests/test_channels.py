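import numpy as np
import pytest
from scipy.integrate import trapezoid

from ioniccable.channels import (
    GatingVariable,
    Hotspot,
    NMDASpec,
    channel_current_density,
    gate_evolve,
    gate_steady_state,
    mg_block,
    nmda_conductance,
    nmda_currents,
    nmda_pool_saturate,
    standard_channel_set,
)
from ioniccable.model_core import ValidationError

VGRID = np.linspace(-90.0, 40.0, 27)


@pytest.fixture(scope="module")
def channels():
    return standard_channel_set()


class TestGates:
    def test_steady_state_identity_and_bounds(self, channels):
        # x_inf (alpha+beta) == alpha holds identically for rate-form gates
        for gate, _p in channels["Na"].gates + channels["K_DR"].gates:
            if gate.alpha is None:
                continue
            xi, tx = gate_steady_state(gate, VGRID)
            a, b = gate.alpha(VGRID), gate.beta(VGRID)
            np.testing.assert_allclose(xi * (a + b), a, rtol=1e-12)
            assert np.all((xi >= 0) & (xi <= 1))
            assert np.all(tx > 0)

    def test_activation_saturates_with_depolarization(self, channels):
        m = channels["Na"].gates[0][0]
        xi, _ = gate_steady_state(m, np.array([-80.0, -40.0, 0.0, 60.0, 120.0]))
        assert np.all(np.diff(xi) > 0)
        assert xi[-1] > 0.999

    def test_exponential_rates_match_closed_form_sigmoid(self):
        # alpha = a e^{V/k}, beta = a e^{-V/k}  =>  x_inf = 1/(1+e^{-2V/k})
        a, k = 0.2, 9.0
        gate = GatingVariable(
            "sig",
            alpha=lambda V: a * np.exp(np.asarray(V, float) / k),
            beta=lambda V: a * np.exp(-np.asarray(V, float) / k),
        )
        xi, _ = gate_steady_state(gate, VGRID)
        closed = 1.0 / (1.0 + np.exp(-2.0 * VGRID / k))
        np.testing.assert_allclose(xi, closed, rtol=1e-12)

    def test_fixed_point(self, channels):
        h = channels["Na"].gates[1][0]
        V = np.full(200, -55.0)
        xi0, _ = gate_steady_state(h, -55.0)
        x = gate_evolve(h, V, dt_ms=0.1, x0=float(xi0))
        np.testing.assert_allclose(x, xi0, rtol=1e-12)

    def test_exponential_relaxation(self, channels):
        m = channels["Na"].gates[0][0]
        xi, tx = gate_steady_state(m, -30.0)
        dt = float(tx) / 400.0
        n = int(round(float(tx) / dt)) + 1
        x = gate_evolve(m, np.full(n, -30.0), dt_ms=dt, x0=0.0)
        assert x[-1] == pytest.approx(float(xi) * (1 - np.e**-1), rel=1e-3)

    def test_piecewise_constant_voltage_matches_analytic_chaining(self, channels):
        m = channels["Na"].gates[0][0]
        dt = 0.05
        segs = [(-70.0, 40), (-20.0, 60), (-50.0, 50)]
        V = np.concatenate([np.full(n, v) for v, n in segs])
        x = gate_evolve(m, V, dt_ms=dt, x0=0.3)
        # closed-form exponential per segment, chained (voltage held on
        # [t_i, t_{i+1}), matching the solver convention)
        expect = np.empty_like(V)
        xc = 0.3
        i = 0
        for v, n in segs:
            xi, tx = gate_steady_state(m, v)
            for j in range(n):
                expect[i] = xc
                xc = float(xi + (xc - xi) * np.exp(-dt / tx))
                i += 1
        np.testing.assert_allclose(x, expect, atol=1e-8)

    def test_gates_stay_in_unit_interval_for_wild_voltage(self, channels):
        rng = np.random.default_rng(7)
        V = rng.uniform(-120.0, 80.0, 5000)
        for name, spec in channels.items():
            for gate, _p in spec.gates:
                x = gate_evolve(gate, V, dt_ms=0.1)
                assert np.all((x >= 0.0) & (x <= 1.0)), (name, gate.name)

    def test_euler_rejects_unstable_step(self, channels):
        m = channels["Na"].gates[0][0]
        with pytest.raises(ValidationError, match="stability"):
            gate_evolve(m, np.full(10, 0.0), dt_ms=5.0, method="euler")


class TestChannelCurrents:
    def test_zero_count_zero_current(self, channels):
        spec = channels["Na"]
        assert channel_current_density(spec, 0.0, -20.0, [0.5, 0.5]) == 0.0

    def test_reversal_potential(self, channels):
        spec = channels["Na"]
        assert channel_current_density(spec, 100.0, spec.E_mV, [1.0, 1.0]) == 0.0

    def test_linearity_in_epsilon_and_count(self, channels):
        spec = channels["Ca_T"]
        base = channel_current_density(spec, 50.0, -30.0, [0.4, 0.2])
        doubled = channel_current_density(spec.scaled(2.0), 50.0, -30.0, [0.4, 0.2])
        assert doubled == pytest.approx(2.0 * base, rel=1e-12)
        assert channel_current_density(spec, 100.0, -30.0, [0.4, 0.2]) == pytest.approx(
            2.0 * base, rel=1e-12
        )

    def test_gate_value_outside_unit_interval_rejected(self, channels):
        with pytest.raises(ValidationError):
            channel_current_density(channels["Na"], 1.0, 0.0, [1.5, 0.5])

    def test_unknown_channel_id_rejected(self):
        with pytest.raises(ValidationError, match="Kv7"):
            standard_channel_set(Kv7={})

    def test_hotspot_validation(self):
        with pytest.raises(ValidationError):
            Hotspot(x_um=-1.0, count=5)
        with pytest.raises(ValidationError):
            Hotspot(x_um=1.0, count=-5)


class TestMgBlock:
    def test_no_magnesium_means_no_block(self):
        np.testing.assert_allclose(mg_block(VGRID, 0.0), 1.0)

    def test_monotone_in_voltage(self):
        B = mg_block(VGRID, 1.0)
        assert np.all(np.diff(B) > 0)
        assert mg_block(200.0, 1.0) > 0.999

    def test_hand_evaluation_at_zero_mV(self):
        # independent transcription: 1/(1 + ([Mg]/3.57) e^{-0.062 V}) at V=0
        expected = 1.0 / (1.0 + 1.0 / 3.57)
        assert mg_block(0.0, 1.0) == pytest.approx(expected, abs=1e-12)


class TestNMDA:
    spec = NMDASpec(x_um=50.0)

    def test_zero_before_presynaptic_event(self):
        tot, ca = nmda_currents(self.spec, -20.0, -5.0)
        assert tot == 0.0 and ca == 0.0

    def test_distinct_reversals(self):
        tot, ca = nmda_currents(self.spec, self.spec.E_mV, 10.0)
        assert tot == 0.0
        assert ca != 0.0

    def test_total_to_calcium_ratio_constant_in_time(self):
        ratios = []
        for t in (5.0, 20.0, 60.0):
            tot, ca = nmda_currents(self.spec, -20.0, t)
            ratios.append(tot / ca)
        assert np.ptp(ratios) < 1e-12 * abs(ratios[0])

    def test_conductance_normalized_and_causal(self):
        t = np.linspace(-10.0, 400.0, 8000)
        g = nmda_conductance(self.spec, t)
        assert np.all(g[t < 0] == 0.0)
        assert np.max(g) == pytest.approx(1.0, abs=1e-3)
        assert g[-1] < 1e-3

    def test_pool_saturation_identity_and_compression(self):
        g = np.linspace(0.0, 4.0, 50)
        np.testing.assert_array_equal(nmda_pool_saturate(self.spec, g), g)
        capped = NMDASpec(x_um=0.0, pool_capacity=1.5)
        gs = nmda_pool_saturate(capped, g)
        assert np.all(gs <= 1.5) and np.all(np.diff(gs) > 0)
        assert nmda_pool_saturate(capped, 0.05) == pytest.approx(0.05, rel=0.02)

    def test_coincidence_detection(self):
        """Pairing a depolarization with the conductance admits more calcium
        than the presynaptic event alone (magnesium-block relief)."""
        t = np.arange(0.0, 200.0, 0.1)
        V_rest = np.full_like(t, -65.0)
        V_pair = V_rest + 80.0 * np.exp(-((t - 12.0) ** 2) / 18.0)  # transient
        flux = {}
        for name, V in (("alone", V_rest), ("paired", V_pair)):
            _tot, ca = nmda_currents(self.spec, V, t - 10.0)
            flux[name] = -trapezoid(ca, t)  # inward calcium charge
        assert flux["paired"] > 2.0 * flux["alone"]

    def test_validation(self):
        with pytest.raises(ValidationError):
            NMDASpec(x_um=0.0, ca_fraction=0.0)
        with pytest.raises(ValidationError):
            NMDASpec(x_um=0.0, Mg_mM=-1.0)
        with pytest.raises(ValidationError):
            NMDASpec(x_um=0.0, tau_slow_ms=5.0)  # must exceed the fast decay
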
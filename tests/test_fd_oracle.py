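import dataclasses

import numpy as np
import pytest

import ioniccable as ic
from ioniccable.calcium_plasticity import CalciumSystem, rba_reduce, solve_calcium
from ioniccable.fd_oracle import FDConfig, FieldSolution, compare_solutions, fd_solve
from ioniccable.model_core import StimulusEvents, ValidationError
from ioniccable.analytic_solver import solve_voltage

from test_analytic_solver import passive_step_response


@pytest.fixture(scope="module")
def quiet_events():
    return StimulusEvents()


class TestEquilibrium:
    def test_rest_stays_at_rest(self, model):
        """Zero clamp, no events: every field constant at rest."""
        m = dataclasses.replace(
            model,
            waveform=ic.BoundaryWaveform(kind="custom", custom_t_ms=(0.0, 1.0),
                                         custom_mV=(0.0, 0.0)),
        )
        fd = fd_solve(m, StimulusEvents(), FDConfig(dx_um=10.0, dt_ms=0.05),
                      t_max_ms=10.0)
        assert np.max(np.abs(fd.u)) < 1e-12
        assert np.max(np.abs(fd.ca_uM)) < 1e-12
        assert fd.buffer_conservation_error() < 1e-10


class TestPassiveVoltage:
    def test_step_response_matches_closed_form_after_richardson(self, passive_model):
        geom = passive_model.geometry
        step = ic.BoundaryWaveform(kind="custom", custom_t_ms=(0.0, 1e9),
                                   custom_mV=(geom.Vmax_mV, geom.Vmax_mV))
        m = dataclasses.replace(passive_model, waveform=step)
        ev = StimulusEvents(post_onsets_ms=(0.0,))
        sols = {}
        for dt in (0.04, 0.02):
            fd = fd_solve(m, ev, FDConfig(dx_um=2.5, dt_ms=dt, store_every=int(0.4 / dt)),
                          t_max_ms=40.0, with_calcium=False)
            sols[dt] = fd
        p = geom.lambda_um
        t = sols[0.04].t_ms
        u_fine = np.interp(t, sols[0.02].t_ms, sols[0.02].u_at(p))
        u_rich = 2.0 * u_fine - sols[0.04].u_at(p)
        exact = passive_step_response(1.0, t / geom.tau_ms)
        assert np.max(np.abs(u_rich - exact)) < 1e-3

    def test_second_order_convergence_in_space(self, passive_model):
        # smooth AP clamp; tiny dt so the spatial error dominates
        ev = StimulusEvents(post_onsets_ms=(2.0,))
        geom = passive_model.geometry
        p = 0.5 * geom.lambda_um  # node-aligned on every grid below
        ref = solve_voltage(passive_model, ev, outputs_um=[p], t_max_ms=25.0, dt_ms=0.02)
        errs = []
        for dx in (50.0, 25.0, 12.5):
            fd = fd_solve(passive_model, ev, FDConfig(dx_um=dx, dt_ms=0.005),
                          t_max_ms=25.0, with_calcium=False)
            ui = np.interp(ref.t_ms, fd.t_ms, fd.u_at(p))
            errs.append(np.max(np.abs(ui - ref.u_at(p))))
        # halving dx should cut the error by about 4; demand > 2.8
        assert errs[0] / errs[1] > 2.8
        assert errs[1] / errs[2] > 2.8


class TestBufferAndCalcium:
    def test_buffer_conservation_with_stimulation(self, model):
        ev = StimulusEvents(post_onsets_ms=(10.0,), pre_times_ms=(5.0,))
        fd = fd_solve(model, ev, FDConfig(dx_um=5.0, dt_ms=0.02), t_max_ms=60.0)
        assert fd.buffer_conservation_error() < 1e-10
        # calcium stays physical (never below zero absolute concentration)
        assert np.min(fd.ca_uM) >= -model.calcium.rest_uM - 1e-9

    def test_rba_validity_improves_with_faster_buffer(self):
        """FD (explicit buffer) and the rapid-buffer reduction agree when the
        buffer kinetics are fast and the transient stays in the linear range;
        slowing the kinetics monotonically widens the gap.

        Uses a resolvable configuration: weak point source, chemical length
        large compared to the grid spacing.
        """
        cal = CalciumSystem(D_Ca_um2_ms=2.2, D_B_um2_ms=0.5, B_total_uM=20.0,
                            K_d_uM=5.0, pump_Pm_um_ms=0.02, pump_Kp_uM=10.0,
                            rest_uM=0.05, k_on_per_uM_ms=1.0)
        cfg = {
            "calcium": {"DCa_um2_ms": 2.2, "DB_um2_ms": 0.5, "BT_uM": 20.0,
                         "Kd_uM": 5.0, "Pm_um_ms": 0.02, "Kp_uM": 10.0,
                         "k_on_per_uM_ms": 1.0},
            "channels": {k: {"density_pS_um2": 0.0} for k in
                          ("Na", "K_DR", "K_A", "Ca_T", "Ca_L")},
            "synapse": {"ca_t_count": 0.0, "ca_l_count": 0.0,
                         "nmda": {"count": 1.0, "ca_fraction": 0.02}},
        }
        m = ic.build_model(cfg)
        rba = rba_reduce(m.calcium, m.geometry.diameter_um)
        assert rba.lambda_c_um > 15.0  # resolvable on the FD grid below
        ev = StimulusEvents(post_onsets_ms=(10.0,), pre_times_ms=(5.0,))

        # analytic rapid-buffer transient at the synapse
        from ioniccable.calcium_plasticity import calcium_influx_series

        sol = solve_voltage(m, ev, outputs_um=[m.nmda.x_um], t_max_ms=200.0)
        sources = calcium_influx_series(sol, m, sol.t_ms, ev, sites_um=[m.nmda.x_um])
        [tr] = solve_calcium(sources, m.calcium, m.geometry, [m.nmda.x_um], sol.t_ms)
        assert tr.peak < 0.3 * m.calcium.K_d_uM  # linear-range check

        gaps = []
        for k_on in (1.0, 0.01):
            mm = dataclasses.replace(
                m, calcium=dataclasses.replace(m.calcium, k_on_per_uM_ms=k_on)
            )
            fd = fd_solve(mm, ev,
                          FDConfig(dx_um=1.25, dt_ms=0.02, L_over_lambda=8.0),
                          t_max_ms=200.0)
            gaps.append(abs(fd.ca_at(m.nmda.x_um).max() - tr.peak) / tr.peak)
        assert gaps[0] < 0.10  # fast buffer: reduction holds within 10%
        assert gaps[1] > gaps[0]  # slow buffer: reduction degrades


class TestCompare:
    def test_self_comparison_is_zero(self, passive_model):
        ev = StimulusEvents(post_onsets_ms=(5.0,))
        fd = fd_solve(passive_model, ev, FDConfig(dx_um=10.0, dt_ms=0.05),
                      t_max_ms=30.0, with_calcium=False)
        sol_like = type("S", (), {"t_ms": fd.t_ms, "u_at": fd.u_at})()
        rep = compare_solutions(sol_like, fd, [100.0, 250.0])
        assert all(v["sup"] == 0.0 for v in rep.voltage.values())
        assert rep.within_tolerance

    def test_passive_equivalence_and_perturbation_scaling(self, model):
        """Analytic-vs-FD voltage discrepancy: passive within 1e-3, and the
        active discrepancy shrinks when hotspot strengths shrink."""
        geom = model.geometry
        ev = StimulusEvents(post_onsets_ms=(5.0,))
        probes = [0.25 * geom.lambda_um, 0.5 * geom.lambda_um]
        discrepancies = {}
        for s in (0.0, 1.0, 0.1):
            m = dataclasses.replace(model)
            m.channels = {k: v.scaled(s) for k, v in model.channels.items()}
            m.nmda = dataclasses.replace(model.nmda, count=0.0)
            sol = solve_voltage(m, ev, outputs_um=probes, t_max_ms=60.0, dt_ms=0.05)
            fd = fd_solve(m, ev, FDConfig(dx_um=2.5, dt_ms=0.02), t_max_ms=60.0,
                          with_calcium=False)
            rep = compare_solutions(sol, fd, probes, tolerance=1e-3)
            discrepancies[s] = max(v["sup"] for v in rep.voltage.values())
        assert discrepancies[0.0] < 1e-3
        assert discrepancies[0.1] < 0.12 * discrepancies[1.0]

    def test_disjoint_windows_rejected(self, passive_model):
        ev = StimulusEvents(post_onsets_ms=(5.0,))
        fd = fd_solve(passive_model, ev, FDConfig(dx_um=10.0, dt_ms=0.05),
                      t_max_ms=20.0, with_calcium=False)
        late = type("S", (), {"t_ms": fd.t_ms + 100.0, "u_at": fd.u_at})()
        with pytest.raises(ValidationError):
            compare_solutions(late, fd, [100.0])


def test_fd_config_validation():
    with pytest.raises(ValidationError):
        FDConfig(L_over_lambda=4.0)
    with pytest.raises(ValidationError):
        FDConfig(dx_um=-1.0)
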
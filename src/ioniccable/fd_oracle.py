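"""Finite-difference reference solver for the full reaction-diffusion system.

This is the verification oracle for the Green's-function perturbation solver
and the rapid-buffer calcium cable: it discretizes the *untransformed* system
— nonlinear hotspot currents with gates driven by the local voltage, an
explicit buffer species with mass-action binding kinetics, and a saturating
membrane pump — on a truncated domain with the far boundary clamped to rest.

Scheme: Crank-Nicolson in the diffusion (and linear leak/decay) operators,
explicit in the reaction and channel terms (IMEX), with the stiff buffer
binding subcycled so its explicit step stays well inside the stability
bound.  Hotspot Dirac sources are deposited into a single cell scaled by
1/dx (consistent-mass discretization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .calcium_plasticity import CURRENT_TO_FLUX, CalciumSystem, rest_current
from .channels import mg_block, nmda_conductance
from .model_core import Model, StimulusEvents, ValidationError, clamp_train

__all__ = ["FDConfig", "FieldSolution", "fd_solve", "compare_solutions"]


@dataclass(frozen=True)
class FDConfig:
    """Grid and domain parameters of the finite-difference oracle."""

    L_over_lambda: float = 10.0
    dx_um: float = 5.0
    dt_ms: float = 0.01
    store_every: int | None = None  # default: keep ~2000 frames
    max_buffer_substep: float = 0.2  # explicit binding step as a rate fraction

    def __post_init__(self) -> None:
        if self.L_over_lambda < 8.0:
            raise ValidationError(
                "domain must span >= 8 space constants to keep truncation error small"
            )
        if self.dx_um <= 0 or self.dt_ms <= 0:
            raise ValidationError("dx_um and dt_ms must be positive")


@dataclass
class FieldSolution:
    """Stored fields of an FD run (subsampled in time)."""

    x_um: np.ndarray
    t_ms: np.ndarray
    u: np.ndarray          # dimensionless voltage, (n_t, n_x)
    ca_uM: np.ndarray      # free calcium above rest
    buffer_free_uM: np.ndarray
    buffer_bound_uM: np.ndarray
    rest_ca_uM: float
    buffer_total_uM: float

    def u_at(self, x_um: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.x_um - x_um)))
        return self.u[:, i]

    def ca_at(self, x_um: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.x_um - x_um)))
        return self.ca_uM[:, i]

    def buffer_conservation_error(self) -> float:
        """Max deviation of free+bound buffer from the total, in uM."""
        tot = self.buffer_free_uM + self.buffer_bound_uM
        return float(np.max(np.abs(tot - self.buffer_total_uM)))


def _cn_operators(n: int, r: float, decay: float, dt: float):
    """Banded LHS/RHS for (1 -+ dt/2(r*Lap - decay)) with Dirichlet ends."""
    lhs = np.zeros((3, n))
    main_l = 1.0 + dt * (r + decay / 2.0)
    off_l = -dt * r / 2.0
    main_r = 1.0 - dt * (r + decay / 2.0)
    off_r = dt * r / 2.0
    lhs[0, 1:] = off_l
    lhs[1, :] = main_l
    lhs[2, :-1] = off_l
    # Dirichlet rows
    for j in (0, n - 1):
        lhs[1, j] = 1.0
    lhs[0, 1] = 0.0
    lhs[2, n - 2] = 0.0
    return lhs, (main_r, off_r)


def _cn_rhs(field: np.ndarray, main_r: float, off_r: float, bc0: float, bcN: float):
    rhs = main_r * field
    rhs[1:-1] += off_r * (field[:-2] + field[2:])
    rhs[0] = bc0
    rhs[-1] = bcN
    return rhs


def fd_solve(
    model: Model,
    events: StimulusEvents,
    config: FDConfig = FDConfig(),
    t_max_ms: float | None = None,
    with_calcium: bool = True,
    source_scale: float = 1.0,
) -> FieldSolution:
    """Integrate the full system; Dirichlet AP clamp at x=0, rest at the far end.

    ``source_scale`` uniformly scales all hotspot strengths (used for the
    perturbation-order verification).  Raises on field blow-up with the
    violated bound named.
    """
    geom = model.geometry
    lam, tau = geom.lambda_um, geom.tau_ms
    L = config.L_over_lambda * lam
    n = int(round(L / config.dx_um)) + 1
    x = config.dx_um * np.arange(n)
    dt = config.dt_ms
    if t_max_ms is None:
        horizon = max(list(events.post_onsets_ms or [0.0]) + list(events.pre_times_ms or [0.0]))
        t_max_ms = horizon + 20.0 * tau
    n_t = int(round(t_max_ms / dt)) + 1
    store_every = config.store_every or max(1, n_t // 2000)

    # voltage operator (dimensionless u, physical t): u_t = (lam^2/tau) u_xx - u/tau
    r_u = (lam**2 / tau) / config.dx_um**2
    lhs_u, rhs_u = _cn_operators(n, r_u, 1.0 / tau, dt)

    sys: CalciumSystem = model.calcium
    if with_calcium and sys is None:
        raise ValidationError("model has no calcium system; pass with_calcium=False")
    if with_calcium:
        r_c = sys.D_Ca_um2_ms / config.dx_um**2
        r_b = sys.D_B_um2_ms / config.dx_um**2
        lhs_c, rhs_c = _cn_operators(n, r_c, 0.0, dt)
        lhs_b, rhs_b = _cn_operators(n, r_b, 0.0, dt)
        k_on = sys.k_on_per_uM_ms
        k_off = k_on * sys.K_d_uM
        c_rest = sys.rest_uM
        b_rest = sys.B_total_uM * sys.K_d_uM / (sys.K_d_uM + c_rest)
        bound_rest = sys.B_total_uM - b_rest
        pump_pref = 4.0 * sys.pump_Pm_um_ms / geom.diameter_um
        pump_rest = pump_pref * c_rest / (sys.pump_Kp_uM + c_rest)
        # explicit binding stability: subcycle so rate*substep <= bound
        binding_rate = k_on * (sys.B_total_uM + sys.K_d_uM + c_rest)
        n_sub = max(1, int(np.ceil(binding_rate * dt / config.max_buffer_substep)))
        flux_conv = CURRENT_TO_FLUX / geom.cross_section_um2

    # hotspot bookkeeping: node index, channel spec, gates state
    from .analytic_solver import source_scale_per_nA

    w_scale = source_scale_per_nA(geom)  # per nA; source_scale enters the currents
    spots = []
    for name, spec in model.channels.items():
        for spot in spec.hotspots:
            idx = int(round(spot.x_um / config.dx_um))
            if not (0 <= idx < n):
                raise ValidationError(f"hotspot at {spot.x_um} um outside the domain")
            spots.append({"spec": spec, "count": spot.count, "idx": idx, "gates": None})
    nmda_idx = None
    if model.nmda is not None and len(events.pre_times_ms) > 0:
        nmda_idx = int(round(model.nmda.x_um / config.dx_um))

    t_grid = dt * np.arange(n_t)
    clamp = clamp_train(model.waveform, events.post_onsets_ms, t_grid) / geom.Vmax_mV
    g_nmda = np.zeros(n_t)
    if nmda_idx is not None:
        for tp in events.pre_times_ms:
            g_nmda += nmda_conductance(model.nmda, t_grid - tp)

    u = np.zeros(n)
    if with_calcium:
        c = np.zeros(n)  # above rest
        b = np.full(n, b_rest)
        bound = np.full(n, bound_rest)

    frames_t, frames_u, frames_c, frames_bf, frames_bb = [], [], [], [], []

    def snapshot(it):
        frames_t.append(t_grid[it])
        frames_u.append(u.copy())
        if with_calcium:
            frames_c.append(c.copy())
            frames_bf.append(b.copy())
            frames_bb.append(bound.copy())
        else:
            frames_c.append(np.zeros(n))
            frames_bf.append(np.zeros(n))
            frames_bb.append(np.zeros(n))

    snapshot(0)
    for it in range(n_t - 1):
        V = geom.Er_mV + geom.Vmax_mV * u
        # --- hotspot currents (explicit) ---
        src_u = np.zeros(n)
        ca_flux = np.zeros(n) if with_calcium else None
        for s in spots:
            spec = s["spec"]
            Vn = V[s["idx"]]
            if s["gates"] is None:
                s["gates"] = [g.steady_state(Vn)[0] for g, _p in spec.gates]
            open_frac = 1.0
            for gi, (g, p) in enumerate(spec.gates):
                xi, tx = g.steady_state(Vn)
                s["gates"][gi] = xi + (s["gates"][gi] - xi) * np.exp(-dt / tx)
                open_frac *= s["gates"][gi] ** p
            i_nA = (
                1.0e-6
                * spec.cluster_conductance_pS
                * s["count"]
                * source_scale
                * open_frac
                * spec.driving_force(Vn, spec.E_mV)
            )
            i_dev_u = i_nA - rest_current(spec, s["count"], geom) * source_scale
            src_u[s["idx"]] -= w_scale * i_dev_u * (geom.lambda_um / config.dx_um) / tau
            if with_calcium and spec.carries_calcium:
                i_dev = i_nA - rest_current(spec, s["count"], geom) * source_scale
                ca_flux[s["idx"]] -= flux_conv * i_dev / config.dx_um
        if nmda_idx is not None:
            spec = model.nmda
            Vn = V[nmda_idx]
            gB = g_nmda[it] * spec.conductance_pS * mg_block(Vn, spec.Mg_mM) * 1.0e-6
            i_tot = gB * (Vn - spec.E_mV) * source_scale
            i_ca = spec.ca_fraction * gB * (Vn - spec.ECa_mV) * source_scale
            src_u[nmda_idx] -= w_scale * i_tot * (geom.lambda_um / config.dx_um) / tau
            if with_calcium:
                ca_flux[nmda_idx] -= flux_conv * i_ca / config.dx_um

        # --- voltage CN step ---
        rhs = _cn_rhs(u, *rhs_u, bc0=clamp[it + 1], bcN=0.0) + dt * src_u
        rhs[0], rhs[-1] = clamp[it + 1], 0.0
        u = solve_banded((1, 1), lhs_u, rhs)
        if np.max(np.abs(u)) > 50.0:
            raise ValidationError(
                "voltage field blow-up: explicit source step violated its "
                "stability bound; reduce dt_ms"
            )

        if with_calcium:
            # --- reaction (binding + pump + influx), subcycled explicit ---
            h = dt / n_sub
            for _ in range(n_sub):
                R = k_on * (c + c_rest) * b - k_off * bound
                pump = pump_pref * (c + c_rest) / (sys.pump_Kp_uM + c + c_rest) - pump_rest
                c = c + h * (-R - pump + ca_flux)
                b = b + h * (-R)
                bound = bound + h * R
            # --- diffusion CN steps ---
            c = solve_banded((1, 1), lhs_c, _cn_rhs(c, *rhs_c, bc0=0.0, bcN=0.0))
            b = solve_banded((1, 1), lhs_b, _cn_rhs(b, *rhs_b, bc0=b_rest, bcN=b_rest))
            bound = solve_banded(
                (1, 1), lhs_b, _cn_rhs(bound, *rhs_b, bc0=bound_rest, bcN=bound_rest)
            )
            if np.min(c) < -c_rest - 1e-6:
                raise ValidationError("calcium went negative: reduce dt_ms")

        if (it + 1) % store_every == 0 or it == n_t - 2:
            snapshot(it + 1)

    return FieldSolution(
        x_um=x,
        t_ms=np.asarray(frames_t),
        u=np.asarray(frames_u),
        ca_uM=np.asarray(frames_c),
        buffer_free_uM=np.asarray(frames_bf),
        buffer_bound_uM=np.asarray(frames_bb),
        rest_ca_uM=0.0 if not with_calcium else c_rest,
        buffer_total_uM=0.0 if not with_calcium else sys.B_total_uM,
    )


@dataclass
class DiscrepancyReport:
    """Relative sup/L2 discrepancies per probe between two solutions."""

    voltage: dict
    calcium: dict
    tolerance: float

    @property
    def within_tolerance(self) -> bool:
        vals = [v["sup"] for v in self.voltage.values()]
        vals += [v["sup"] for v in self.calcium.values()]
        return all(v <= self.tolerance for v in vals)


def _discrepancy(t_ref, y_ref, t_other, y_other):
    lo, hi = max(t_ref[0], t_other[0]), min(t_ref[-1], t_other[-1])
    if hi <= lo:
        raise ValidationError("solutions share no overlapping time window")
    mask = (t_ref >= lo) & (t_ref <= hi)
    a = y_ref[mask]
    b = np.interp(t_ref[mask], t_other, y_other)
    scale = np.max(np.abs(a))
    if scale == 0:
        scale = 1.0
    return {
        "sup": float(np.max(np.abs(a - b)) / scale),
        "l2": float(np.linalg.norm(a - b) / (np.linalg.norm(a) + 1e-300)),
    }


def compare_solutions(
    analytic,
    fd: FieldSolution,
    probes_um,
    calcium_transients=None,
    tolerance: float = 1e-3,
) -> DiscrepancyReport:
    """Sup/L2 relative discrepancies at shared probes (FD grid as reference).

    ``analytic`` is a PerturbationSolution; optional ``calcium_transients``
    maps probe position to a CalciumTransient for the chemical comparison.
    Grids are resampled by linear interpolation.
    """
    voltage, calcium = {}, {}
    for p in probes_um:
        voltage[p] = _discrepancy(fd.t_ms, fd.u_at(p), analytic.t_ms, analytic.u_at(p))
        if calcium_transients is not None and p in calcium_transients:
            tr = calcium_transients[p]
            calcium[p] = _discrepancy(fd.t_ms, fd.ca_at(p), tr.t_ms, tr.conc_uM)
    return DiscrepancyReport(voltage=voltage, calcium=calcium, tolerance=tolerance)
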
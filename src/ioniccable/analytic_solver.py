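"""Green's-function perturbation solver for the dimensionless voltage cable.

The dimensionless membrane potential ``u(X, T)`` on the semi-infinite cable
obeys

    du/dT = d^2u/dX^2 - u - sum_{j,k} w_jk(T) delta(X - X_jk),

with a nonhomogeneous Dirichlet condition ``u(0, T) = f(T)`` (the action
potential clamp) and rest initial data.  The problem is recast as Volterra
convolutions against the killed-end (homogeneous Dirichlet) Green's function

    G(X, Y, T) = e^{-T}/sqrt(4 pi T) [e^{-(X-Y)^2/4T} - e^{-(X+Y)^2/4T}]

and solved by a regular perturbation expansion truncated at first order:

* order 0 (passive): the clamp propagated inward through the boundary-flux
  kernel ``-dG/dY|_{Y=0}``;
* order 1: each hotspot current, computed from gating variables driven by the
  order-0 voltage at that hotspot, convolved with ``G``.

Hotspot source strengths ``w_jk`` are the physical hotspot currents (nA)
scaled by ``R_m / (pi d lambda V_max)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._conv import panel_kernel, volterra_convolve
from .channels import NMDASpec, gate_evolve, mg_block, nmda_conductance
from .calcium_plasticity import rest_current
from .model_core import CableGeometry, Model, StimulusEvents, ValidationError, clamp_train

__all__ = [
    "greens_semi_infinite",
    "boundary_flux_kernel",
    "boundary_term",
    "hotspot_source_series",
    "solve_voltage",
    "PerturbationSolution",
    "KernelCache",
    "source_scale_per_nA",
]


def greens_semi_infinite(X, Y, T):
    """Killed-end Green's function of the dimensionless leaky cable.

    Symmetric in (X, Y), nonnegative, zero at the boundary X = 0, and decaying
    like exp(-T).  ``T`` must be strictly positive.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValidationError("greens_semi_infinite requires T > 0")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.any(X < 0) or np.any(Y < 0):
        raise ValidationError("positions must be >= 0 on the semi-infinite cable")
    pref = np.exp(-T) / np.sqrt(4.0 * np.pi * T)
    return pref * (np.exp(-((X - Y) ** 2) / (4.0 * T)) - np.exp(-((X + Y) ** 2) / (4.0 * T)))


def boundary_flux_kernel(X, T):
    """Normal derivative of G at the boundary: the Dirichlet data propagator.

    K(X, T) = X e^{-T - X^2/(4T)} / (2 sqrt(pi) T^{3/2}); its time integral
    is e^{-X}, the steady-state attenuation of the passive cable.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValidationError("boundary_flux_kernel requires T > 0")
    X = np.asarray(X, dtype=float)
    return X * np.exp(-T - X**2 / (4.0 * T)) / (2.0 * np.sqrt(np.pi) * T**1.5)


def source_scale_per_nA(geometry: CableGeometry) -> float:
    """Dimensionless source strength contributed by 1 nA of hotspot current.

    From nondimensionalizing the point-source term: w = R_m I/(pi d lambda
    V_max), evaluated here with R_m in Ohm cm^2, d and lambda in um, V_max in
    mV and I in nA.
    """
    return (
        100.0
        * geometry.Rm_ohm_cm2
        / (np.pi * geometry.diameter_um * geometry.lambda_um * geometry.Vmax_mV)
    )


class KernelCache:
    """Panel-moment cache for the convolution kernels of one grid spacing.

    Kernels depend only on the spatial pair and the time step, not on the run
    length, so cached arrays are extended on demand and sliced otherwise.
    """

    def __init__(self, geometry: CableGeometry, dt_ms: float):
        self.geometry = geometry
        self.dt_ms = float(dt_ms)
        self._store: dict = {}

    def _get(self, key, kern, n_max, decay_ms):
        hit = self._store.get(key)
        if hit is not None:
            K0, K1, complete = hit
            if complete or len(K0) >= n_max:
                return K0, K1
        K0, K1 = panel_kernel(kern, self.dt_ms, n_max, decay_ms=decay_ms)
        # shorter than requested means the decaying tail was truncated, so the
        # cached kernel is complete for any future (longer) request
        self._store[key] = (K0, K1, len(K0) < n_max)
        return K0, K1

    def boundary(self, X: float, n_max: int):
        tau = self.geometry.tau_ms
        kern = lambda t: boundary_flux_kernel(X, t / tau) / tau
        return self._get(("b", round(X, 12)), kern, n_max, decay_ms=tau * 1.05)

    def source(self, X: float, Y: float, n_max: int):
        tau = self.geometry.tau_ms
        kern = lambda t: greens_semi_infinite(X, Y, t / tau) / tau
        key = ("s",) + tuple(sorted((round(X, 12), round(Y, 12))))
        return self._get(key, kern, n_max, decay_ms=tau * 1.05)

    def chemical(self, x_um: float, y_um: float, D_um2_ms: float, k_per_ms: float, n_max: int):
        def kern(t):
            pref = np.exp(-k_per_ms * t) / np.sqrt(4.0 * np.pi * D_um2_ms * t)
            return pref * (
                np.exp(-((x_um - y_um) ** 2) / (4.0 * D_um2_ms * t))
                - np.exp(-((x_um + y_um) ** 2) / (4.0 * D_um2_ms * t))
            )

        key = ("c", round(D_um2_ms, 12), round(k_per_ms, 12)) + tuple(
            sorted((round(x_um, 9), round(y_um, 9)))
        )
        return self._get(key, kern, n_max, decay_ms=1.05 / k_per_ms)


@dataclass
class PerturbationSolution:
    """Voltage field of a perturbation solve, sampled at chosen positions."""

    order: int
    t_ms: np.ndarray
    x_um: np.ndarray
    u0: np.ndarray  # (n_x, n_t) dimensionless, order-0 (passive)
    u1: np.ndarray  # (n_x, n_t) first-order hotspot correction
    clamp: np.ndarray  # boundary waveform samples, dimensionless
    geometry: CableGeometry
    sources: dict = field(default_factory=dict)  # (channel, k) -> w_jk series
    gate_states: dict = field(default_factory=dict)

    @property
    def u(self) -> np.ndarray:
        return self.u0 + self.u1

    def _row(self, x_um: float) -> int:
        idx = np.nonzero(np.isclose(self.x_um, x_um, rtol=0, atol=1e-9))[0]
        if len(idx) == 0:
            raise ValidationError(f"position {x_um} um was not sampled in this solve")
        return int(idx[0])

    def u_at(self, x_um: float) -> np.ndarray:
        return self.u[self._row(x_um)]

    def V_at(self, x_um: float) -> np.ndarray:
        """Absolute membrane potential (mV) at a sampled position."""
        return self.geometry.Er_mV + self.geometry.Vmax_mV * self.u_at(x_um)

    def order_norms(self) -> dict:
        return {
            "u0_sup": float(np.max(np.abs(self.u0))),
            "u1_sup": float(np.max(np.abs(self.u1))),
        }


def boundary_term(clamp_samples: np.ndarray, X: float, t_ms: np.ndarray,
                  geometry: CableGeometry, cache: KernelCache | None = None) -> np.ndarray:
    """Order-0 (passive) solution: the Dirichlet clamp propagated to depth X.

    ``clamp_samples`` is the dimensionless boundary voltage on the grid
    ``t_ms``.  At X = 0 the clamp is returned exactly.
    """
    if X == 0.0:
        return np.array(clamp_samples, dtype=float, copy=True)
    dt = float(t_ms[1] - t_ms[0])
    cache = cache or KernelCache(geometry, dt)
    K0, K1 = cache.boundary(X, len(t_ms))
    return volterra_convolve(K0, K1, np.asarray(clamp_samples, float), len(t_ms))


def _nmda_current_series(spec: NMDASpec, V_mV: np.ndarray, t_ms: np.ndarray, pre_times_ms):
    """Total and calcium NMDA currents (nA) for a train of presynaptic events."""
    g = np.zeros_like(t_ms)
    for tp in pre_times_ms:
        g = g + nmda_conductance(spec, t_ms - tp)
    B = mg_block(V_mV, spec.Mg_mM)
    gB = g * spec.conductance_pS * B * 1.0e-6
    return gB * (V_mV - spec.E_mV), spec.ca_fraction * gB * (V_mV - spec.ECa_mV)


def hotspot_source_series(model: Model, u_prev: dict, t_ms: np.ndarray,
                          events: StimulusEvents) -> dict:
    """Per-hotspot dimensionless source strengths driven by the previous-order
    voltage.

    ``u_prev`` maps hotspot position (um) to the dimensionless voltage there.
    Gating variables start from rest steady state and are integrated with the
    exponential (Rush-Larsen) update.  Returns {(channel_name, k): w series};
    the NMDA receptor appears under ("NMDA", 0).
    """
    geom = model.geometry
    dt = float(t_ms[1] - t_ms[0])
    scale = source_scale_per_nA(geom)
    out: dict = {}
    gate_states: dict = {}
    for name, spec in model.channels.items():
        for k, spot in enumerate(spec.hotspots):
            if spot.x_um not in u_prev:
                raise ValidationError(
                    f"no previous-order voltage sampled at hotspot x={spot.x_um} um"
                )
            V = geom.Er_mV + geom.Vmax_mV * u_prev[spot.x_um]
            gates = [gate_evolve(g, V, dt) for g, _p in spec.gates]
            open_frac = np.ones_like(V)
            for (g, p), x in zip(spec.gates, gates):
                open_frac = open_frac * x**p
            i_nA = 1.0e-6 * spec.cluster_conductance_pS * spot.count * open_frac * (
                spec.driving_force(V, spec.E_mV)
            )
            # channel currents are measured from their resting values: the
            # leak equilibrium is defined to absorb the standing currents so
            # that E_r is the true rest state of the full model
            out[(name, k)] = scale * (i_nA - rest_current(spec, spot.count, geom))
            gate_states[(name, k)] = gates
    if model.nmda is not None and len(events.pre_times_ms) > 0:
        spec = model.nmda
        if spec.x_um not in u_prev:
            raise ValidationError(
                f"no previous-order voltage sampled at the NMDA hotspot x={spec.x_um} um"
            )
        V = geom.Er_mV + geom.Vmax_mV * u_prev[spec.x_um]
        i_total, _i_ca = _nmda_current_series(spec, V, t_ms, events.pre_times_ms)
        out[("NMDA", 0)] = scale * i_total
    return out, gate_states


def solve_voltage(
    model: Model,
    events: StimulusEvents,
    order: int = 1,
    outputs_um=(),
    t_max_ms: float | None = None,
    dt_ms: float | None = None,
    cache: KernelCache | None = None,
) -> PerturbationSolution:
    """Solve the voltage cable to the requested perturbation order.

    The sampled positions are the union of ``outputs_um``, every hotspot
    position and the NMDA site.  The boundary condition is honored exactly on
    grid nodes at X = 0.
    """
    if order not in (0, 1):
        raise ValidationError("order must be 0 or 1 (higher orders are a hook)")
    geom = model.geometry
    dt = float(dt_ms if dt_ms is not None else model.dt_ms)
    if t_max_ms is None:
        horizon = max(
            list(events.post_onsets_ms or [0.0]) + list(events.pre_times_ms or [0.0])
        )
        t_max_ms = horizon + 20.0 * geom.tau_ms
    n = int(round(t_max_ms / dt)) + 1
    t_ms = dt * np.arange(n)

    positions = set(float(x) for x in outputs_um)
    for spec in model.channels.values():
        positions.update(h.x_um for h in spec.hotspots)
    if model.nmda is not None:
        positions.add(model.nmda.x_um)
    x_um = np.asarray(sorted(positions), dtype=float)

    clamp = clamp_train(model.waveform, events.post_onsets_ms, t_ms) / geom.Vmax_mV
    cache = cache or KernelCache(geom, dt)

    u0 = np.empty((len(x_um), n))
    for i, x in enumerate(x_um):
        u0[i] = boundary_term(clamp, x / geom.lambda_um, t_ms, geom, cache)

    u1 = np.zeros_like(u0)
    sources: dict = {}
    gate_states: dict = {}
    if order >= 1:
        u_prev = {x: u0[i] for i, x in enumerate(x_um)}
        sources, gate_states = hotspot_source_series(model, u_prev, t_ms, events)
        tau = geom.tau_ms
        pos_of = {("NMDA", 0): model.nmda.x_um if model.nmda is not None else None}
        for name, spec in model.channels.items():
            for k, spot in enumerate(spec.hotspots):
                pos_of[(name, k)] = spot.x_um
        for key, w in sources.items():
            if not np.any(w):
                continue
            y = pos_of[key]
            for i, x in enumerate(x_um):
                X, Y = x / geom.lambda_um, y / geom.lambda_um
                if X == 0.0:
                    continue  # killed-end kernel vanishes at the boundary
                K0, K1 = cache.source(X, Y, n)
                u1[i] -= volterra_convolve(K0, K1, w, n)

    return PerturbationSolution(
        order=order,
        t_ms=t_ms,
        x_um=x_um,
        u0=u0,
        u1=u1,
        clamp=clamp,
        geometry=geom,
        sources=sources,
        gate_states=gate_states,
    )
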
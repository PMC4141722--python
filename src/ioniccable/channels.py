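"""Hodgkin-Huxley style channel kinetics, hotspot currents, and the NMDA receptor.

Ion channels sit in discrete clusters ("hotspots") on the cable and act as
point current sources.  A hotspot of channel type ``j`` at position ``x_jk``
carries the current

    I_jk = eps_j * gamma_j * Nbar_j * N_jk * m^p * h^q * Phi_j(V)

with ``Phi_j(V) = V - E_j`` (ohmic Hodgkin-Huxley driving force) by default;
``Phi`` is a pluggable hook so a Goldman-Hodgkin-Katz driving force can be
substituted without touching the solver.  ``gamma`` is the single-channel
conductance (pS), ``N_jk`` the channel count of hotspot ``k``, and ``eps`` and
``Nbar`` dimensionless scaling factors; their product is the effective
cluster conductance in pS.  Currents are returned in nA (outward positive).

The NMDA receptor contributes a glutamate-gated conductance with the
Jahr-Stevens voltage-dependent magnesium block; its calcium component uses
the calcium reversal potential and a fixed fractional scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from ._kinetics import rush_larsen_scan
from .model_core import ValidationError

__all__ = [
    "GatingVariable",
    "ChannelSpec",
    "Hotspot",
    "HotspotSet",
    "NMDASpec",
    "gate_steady_state",
    "gate_evolve",
    "channel_current_density",
    "mg_block",
    "nmda_conductance",
    "nmda_currents",
    "standard_channel_set",
]

_PS_MV_TO_NA = 1.0e-6  # pS * mV = 1e-15 A = 1e-6 nA


def _linoid(a: float, vhalf: float, k: float) -> Callable[[np.ndarray], np.ndarray]:
    """Rate a*(vhalf - V)/(exp((vhalf - V)/k) - 1) with the removable
    singularity at V = vhalf handled analytically (limit a*k)."""

    def rate(V):
        V = np.asarray(V, dtype=float)
        z = (vhalf - V) / k
        small = np.abs(z) < 1e-7
        zsafe = np.where(small, 1.0, z)
        out = a * k * np.where(small, 1.0 - z / 2.0, zsafe / np.expm1(zsafe))
        return out

    return rate


def _expr(a: float, vhalf: float, k: float) -> Callable[[np.ndarray], np.ndarray]:
    """Exponential rate a*exp((vhalf - V)/k)."""

    def rate(V):
        return a * np.exp((vhalf - np.asarray(V, dtype=float)) / k)

    return rate


def _sigr(a: float, vhalf: float, k: float) -> Callable[[np.ndarray], np.ndarray]:
    """Sigmoidal rate a/(1 + exp((vhalf - V)/k))."""

    def rate(V):
        return a / (1.0 + np.exp((vhalf - np.asarray(V, dtype=float)) / k))

    return rate


@dataclass(frozen=True)
class GatingVariable:
    """One first-order gate, defined by rates alpha/beta or by (xinf, tau)."""

    name: str
    alpha: Callable | None = None
    beta: Callable | None = None
    xinf: Callable | None = None
    tau: Callable | None = None

    def __post_init__(self) -> None:
        has_rates = self.alpha is not None and self.beta is not None
        has_ss = self.xinf is not None and self.tau is not None
        if not (has_rates or has_ss):
            raise ValidationError(
                f"gate {self.name!r} needs (alpha, beta) or (xinf, tau)"
            )

    def steady_state(self, V):
        """Return (x_inf(V), tau_x(V)); raises if alpha+beta is nonpositive."""
        if self.xinf is not None and self.tau is not None:
            xi = np.asarray(self.xinf(V), dtype=float)
            tx = np.asarray(self.tau(V), dtype=float)
        else:
            a = np.asarray(self.alpha(V), dtype=float)
            b = np.asarray(self.beta(V), dtype=float)
            s = a + b
            if np.any(s <= 0):
                raise ValidationError(
                    f"gate {self.name!r}: alpha+beta <= 0 in the requested range"
                )
            xi, tx = a / s, 1.0 / s
        if np.any(tx <= 0):
            raise ValidationError(f"gate {self.name!r}: tau must be positive")
        return xi, tx


def gate_steady_state(gate: GatingVariable, V):
    """Steady-state open fraction and relaxation time constant at voltage V."""
    return gate.steady_state(V)


def gate_evolve(
    gate: GatingVariable,
    V_traj: np.ndarray,
    dt_ms: float,
    x0: float | None = None,
    method: str = "exponential",
) -> np.ndarray:
    """Integrate dx/dt = (x_inf(V) - x)/tau_x(V) along a sampled voltage path.

    The voltage is held constant on each step ``[t_i, t_{i+1})``.  The default
    exponential (Rush-Larsen) update is exact for piecewise-constant voltage
    and unconditionally stable; ``method="euler"`` is provided for reference
    and rejects time steps beyond its stability bound ``dt < 2*min(tau)``.
    """
    if dt_ms <= 0:
        raise ValidationError("dt_ms must be positive")
    V_traj = np.asarray(V_traj, dtype=float)
    xinf, tau = gate.steady_state(V_traj)
    if x0 is None:
        x0 = float(xinf[0])
    if method == "exponential":
        efac = np.exp(-dt_ms / tau)
        return rush_larsen_scan(xinf, efac, x0)
    if method == "euler":
        if dt_ms >= 2.0 * float(np.min(tau)):
            raise ValidationError(
                f"dt={dt_ms} ms exceeds the forward-Euler stability bound "
                f"(2*min tau = {2 * float(np.min(tau)):.4g} ms); "
                "use method='exponential'"
            )
        x = np.empty_like(V_traj)
        x[0] = x0
        for i in range(len(x) - 1):
            x[i + 1] = x[i] + dt_ms * (xinf[i] - x[i]) / tau[i]
        return x
    raise ValidationError(f"unknown integration method {method!r}")


def ohmic_driving_force(V, E_mV):
    return np.asarray(V, dtype=float) - E_mV


@dataclass(frozen=True)
class Hotspot:
    x_um: float
    count: float  # number of channels in the cluster

    def __post_init__(self) -> None:
        if self.x_um < 0:
            raise ValidationError("hotspot position must be >= 0")
        if self.count < 0:
            raise ValidationError("hotspot channel count must be >= 0")


@dataclass(frozen=True)
class ChannelSpec:
    """A channel type: gates, single-channel conductance, and its hotspots."""

    name: str
    gamma_pS: float
    E_mV: float
    gates: tuple = ()  # tuple of (GatingVariable, integer exponent)
    epsilon: float = 1.0
    Nbar: float = 1.0
    carries_calcium: bool = False
    hotspots: tuple = ()
    driving_force: Callable = ohmic_driving_force

    def __post_init__(self) -> None:
        if self.gamma_pS < 0 or self.Nbar < 0:
            raise ValidationError(f"channel {self.name!r}: gamma and Nbar must be >= 0")

    @property
    def cluster_conductance_pS(self) -> float:
        """Effective conductance of a single-channel hotspot (count 1)."""
        return self.epsilon * self.gamma_pS * self.Nbar

    def scaled(self, factor: float) -> "ChannelSpec":
        """Uniformly scale the channel density (all hotspot strengths)."""
        return replace(self, epsilon=self.epsilon * factor)

    def with_hotspots(self, spots: Sequence[Hotspot]) -> "ChannelSpec":
        return replace(self, hotspots=tuple(spots))


def channel_current_density(
    spec: ChannelSpec, count: float, V, gate_values: Sequence
) -> np.ndarray:
    """Hotspot current in nA (outward positive) at voltage V (mV).

    ``gate_values`` supplies the open fraction of each gate in ``spec.gates``
    order; each must lie in [0, 1].
    """
    open_frac = 1.0
    for (gate, power), x in zip(spec.gates, gate_values):
        x = np.asarray(x, dtype=float)
        if np.any((x < -1e-12) | (x > 1 + 1e-12)):
            raise ValidationError(f"gate {gate.name!r} state outside [0, 1]")
        open_frac = open_frac * x**power
    g_pS = spec.cluster_conductance_pS * count
    return _PS_MV_TO_NA * g_pS * open_frac * spec.driving_force(V, spec.E_mV)


class HotspotSet:
    """All hotspot positions of a model, with coordinates in every frame."""

    def __init__(self, channels: Sequence[ChannelSpec]):
        self.channels = tuple(channels)

    def positions_um(self) -> np.ndarray:
        xs = sorted({h.x_um for ch in self.channels for h in ch.hotspots})
        return np.asarray(xs, dtype=float)

    def electrotonic(self, geometry) -> np.ndarray:
        return self.positions_um() / geometry.lambda_um

    def chemicotonic(self, geometry) -> np.ndarray:
        return self.positions_um() / geometry.lambda_c_um

    def __iter__(self):
        for ch in self.channels:
            for spot in ch.hotspots:
                yield ch, spot


def mg_block(V, Mg_mM: float = 1.0):
    """Jahr-Stevens voltage-dependent magnesium block of the NMDA receptor.

    B(V) = 1 / (1 + ([Mg]o / 3.57 mM) * exp(-0.062 V)); equals 1 for Mg = 0
    and approaches 1 with depolarization.
    """
    if Mg_mM < 0:
        raise ValidationError("Mg_mM must be >= 0")
    return 1.0 / (1.0 + (Mg_mM / 3.57) * np.exp(-0.062 * np.asarray(V, dtype=float)))


@dataclass(frozen=True)
class NMDASpec:
    """A single NMDA receptor hotspot (the synapse under study)."""

    x_um: float
    gamma_pS: float = 50.0
    count: float = 10.0
    Nbar: float = 1.0
    E_mV: float = 0.0
    ECa_mV: float = 120.0
    tau_rise_ms: float = 2.0
    tau_decay_ms: float = 30.0
    tau_slow_ms: float | None = None  # optional slow decay component
    fraction_fast: float = 1.0        # weight of the fast decay component
    ca_fraction: float = 0.1
    Mg_mM: float = 1.0
    pool_capacity: float | None = None  # saturation of the summed conductance

    def __post_init__(self) -> None:
        if not (0.0 < self.ca_fraction <= 1.0):
            raise ValidationError("ca_fraction must lie in (0, 1]")
        if self.Mg_mM < 0:
            raise ValidationError("Mg_mM must be >= 0")
        if self.tau_decay_ms <= 0 or self.tau_rise_ms <= 0:
            raise ValidationError("tau_decay_ms and tau_rise_ms must be positive")
        if not (0.0 < self.fraction_fast <= 1.0):
            raise ValidationError("fraction_fast must lie in (0, 1]")
        if self.tau_slow_ms is not None and self.tau_slow_ms <= self.tau_decay_ms:
            raise ValidationError("tau_slow_ms must exceed tau_decay_ms")

    @property
    def conductance_pS(self) -> float:
        return self.gamma_pS * self.Nbar * self.count

    def scaled(self, factor: float) -> "NMDASpec":
        return replace(self, count=self.count * factor)


def _nmda_shape(spec: NMDASpec, t: np.ndarray) -> np.ndarray:
    decay = spec.fraction_fast * np.exp(-t / spec.tau_decay_ms)
    if spec.tau_slow_ms is not None and spec.fraction_fast < 1.0:
        decay = decay + (1.0 - spec.fraction_fast) * np.exp(-t / spec.tau_slow_ms)
    return (1.0 - np.exp(-t / spec.tau_rise_ms)) * decay


def nmda_conductance(spec: NMDASpec, t_since_pre):
    """Normalized (peak 1) conductance time course; zero before the event.

    A rising exponential gates a single- or double-exponential decay (the
    receptor's fast and slow deactivation components).
    """
    t = np.asarray(t_since_pre, dtype=float)
    # normalize to unit peak (dense sampling over the rise/fast-decay span)
    tp = np.linspace(0.0, 8.0 * spec.tau_decay_ms, 2049)
    norm = float(np.max(_nmda_shape(spec, tp)))
    g = _nmda_shape(spec, np.clip(t, 0.0, None)) / norm
    return np.where(t >= 0.0, g, 0.0)


def nmda_pool_saturate(spec: NMDASpec, g_sum):
    """Saturate a summed (train) conductance by the finite receptor pool.

    g_eff = C (1 - exp(-g/C)) with C = pool_capacity (in units of the
    single-event peak); the identity map when no capacity is configured.
    """
    if spec.pool_capacity is None:
        return g_sum
    C = spec.pool_capacity
    return C * (1.0 - np.exp(-np.asarray(g_sum, dtype=float) / C))


def nmda_currents(spec: NMDASpec, V, t_since_pre):
    """(total current, calcium component) in nA, outward positive.

    Both share the conductance time course and the Jahr-Stevens block; the
    calcium component replaces the reversal potential with E_Ca and is scaled
    by the fixed calcium fraction.
    """
    g = nmda_conductance(spec, t_since_pre) * spec.conductance_pS
    B = mg_block(V, spec.Mg_mM)
    V = np.asarray(V, dtype=float)
    i_total = _PS_MV_TO_NA * g * B * (V - spec.E_mV)
    i_ca = spec.ca_fraction * _PS_MV_TO_NA * g * B * (V - spec.ECa_mV)
    return i_total, i_ca


# ---------------------------------------------------------------------------
# Default channel kinetics (Traub-style rate functions, voltages in absolute
# mV with rest near -65 mV).  All of these are configurable; the constants
# below are the package defaults.
# ---------------------------------------------------------------------------

_SHIFT = 65.0  # rate functions below are written for v = V + 65 (rest at 0)


def _shifted(rate):
    def wrapped(V):
        return rate(np.asarray(V, dtype=float) + _SHIFT)

    return wrapped


def na_channel(gamma_pS: float = 20.0, E_mV: float = 55.0) -> ChannelSpec:
    """Transient sodium channel, m^2 h, Traub-style rates."""
    m = GatingVariable(
        "Na_m",
        alpha=_shifted(_linoid(0.32, 13.1, 4.0)),
        beta=_shifted(_linoid(-0.28, 40.1, -5.0)),
    )
    h = GatingVariable(
        "Na_h",
        alpha=_shifted(_expr(0.128, 17.0, 18.0)),
        beta=_shifted(_sigr(4.0, 40.0, 5.0)),
    )
    return ChannelSpec("Na", gamma_pS, E_mV, gates=((m, 2), (h, 1)))


def kdr_channel(gamma_pS: float = 20.0, E_mV: float = -85.0) -> ChannelSpec:
    """Delayed-rectifier potassium channel, single n gate, Traub-style."""
    n = GatingVariable(
        "K_n",
        alpha=_shifted(_linoid(0.016, 35.1, 5.0)),
        beta=_shifted(_expr(0.25, 20.0, 40.0)),
    )
    return ChannelSpec("K_DR", gamma_pS, E_mV, gates=((n, 1),))


def ka_channel(gamma_pS: float = 20.0, E_mV: float = -85.0) -> ChannelSpec:
    """A-type (transient) potassium channel, a*b, Traub-style."""
    a = GatingVariable(
        "A_a",
        alpha=_shifted(_linoid(0.02, 13.1, 10.0)),
        beta=_shifted(_linoid(-0.0175, 40.1, -10.0)),
    )
    b = GatingVariable(
        "A_b",
        alpha=_shifted(_expr(0.0016, -13.0, 18.0)),
        beta=_shifted(_sigr(0.05, 10.1, 5.0)),
    )
    return ChannelSpec("K_A", gamma_pS, E_mV, gates=((a, 1), (b, 1)))


def cat_channel(gamma_pS: float = 10.0, E_mV: float = 120.0) -> ChannelSpec:
    """Low-voltage-activated (T-type) calcium channel, m^2 h."""
    m = GatingVariable(
        "CaT_m",
        xinf=lambda V: 1.0 / (1.0 + np.exp(-(np.asarray(V, float) + 57.0) / 6.2)),
        tau=lambda V: 0.612
        + 1.0
        / (
            np.exp(-(np.asarray(V, float) + 132.0) / 16.7)
            + np.exp((np.asarray(V, float) + 16.8) / 18.2)
        ),
    )
    h = GatingVariable(
        "CaT_h",
        xinf=lambda V: 1.0 / (1.0 + np.exp((np.asarray(V, float) + 72.0) / 5.0)),
        tau=lambda V: 20.0 + 45.0 / (1.0 + np.exp((np.asarray(V, float) + 78.0) / 7.0)),
    )
    return ChannelSpec("Ca_T", gamma_pS, E_mV, gates=((m, 2), (h, 1)), carries_calcium=True)


def cal_channel(gamma_pS: float = 10.0, E_mV: float = 120.0) -> ChannelSpec:
    """High-voltage-activated (L-type) calcium channel, m^2, no inactivation."""
    m = GatingVariable(
        "CaL_m",
        xinf=lambda V: 1.0 / (1.0 + np.exp(-(np.asarray(V, float) + 15.0) / 6.0)),
        tau=lambda V: np.full_like(np.asarray(V, dtype=float), 2.0),
    )
    return ChannelSpec("Ca_L", gamma_pS, E_mV, gates=((m, 2),), carries_calcium=True)


_CHANNEL_FACTORIES = {
    "Na": na_channel,
    "K_DR": kdr_channel,
    "K_A": ka_channel,
    "Ca_T": cat_channel,
    "Ca_L": cal_channel,
}


def standard_channel_set(**overrides) -> dict:
    """The five default channel types keyed by name.

    ``overrides`` may map a channel name to a dict of factory keyword
    arguments (e.g. ``Na={"gamma_pS": 30.0}``).
    """
    out = {}
    for name, factory in _CHANNEL_FACTORIES.items():
        kwargs = overrides.get(name, {})
        out[name] = factory(**kwargs)
    unknown = set(overrides) - set(_CHANNEL_FACTORIES)
    if unknown:
        raise ValidationError(
            f"unknown channel id(s) {sorted(unknown)}; valid: {sorted(_CHANNEL_FACTORIES)}"
        )
    return out
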
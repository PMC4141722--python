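"""Calcium reaction-diffusion cable (rapid-buffer reduction) and the CaDP rule.

Free calcium in the cable diffuses, binds a single fast buffer, and is
extruded by a high-affinity membrane pump.  In the rapid-buffer approximation
(RBA) the buffer equilibrates instantly, which linearizes the system into an
effective diffusion-decay cable

    dC/dt = D_eff d2C/dx2 - k_eff C + (1/(1+theta)) * sum_sites J(t) delta(x - x_s)

with the buffering factor ``theta = B_T K_d / (K_d + C_rest)^2``,

    D_eff = (D_Ca + D_B * theta) / (1 + theta),
    k_eff = (4 P_m / (d K_p)) / (1 + theta)      (linearized pump),

and hence chemical cable constants ``lambda_c = sqrt(D_eff/k_eff)`` and
``tau_c = 1/k_eff``.  Hotspot calcium currents are converted to concentration
flux by ``1/(2 F A)`` (two charges per ion, cross-section ``A``).

Synaptic weights follow the calcium-control hypothesis: the sign function
``Omega(Ca)`` (no change below theta_d, depression between theta_d and
theta_p, potentiation above) and the calcium-dependent learning rate
``eta(Ca)`` drive dW/dt = eta * (Omega - baseline - lambda_w W).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import CableGeometry, ValidationError

__all__ = [
    "CalciumSystem",
    "RBAConstants",
    "CalciumTransient",
    "PlasticityRule",
    "rba_reduce",
    "calcium_influx_series",
    "solve_calcium",
    "omega",
    "eta",
    "drive_variable",
    "weight_change_single_pairing",
    "weight_evolve_train",
]

FARADAY_C_PER_MOL = 96485.33212
# nA of calcium current -> uM * um / ms of line-source concentration flux,
# per um^2 of cross-section: 1e-12 C/ms / (2F) -> mol/ms, to umol and per
# (um^2 * um) volume in litres.
CURRENT_TO_FLUX = 1.0e9 / (2.0 * FARADAY_C_PER_MOL)  # = 5182.1 / A_um2


@dataclass(frozen=True)
class CalciumSystem:
    """Physical constants of the calcium/buffer/pump subsystem."""

    D_Ca_um2_ms: float = 0.22
    D_B_um2_ms: float = 0.05
    B_total_uM: float = 100.0
    K_d_uM: float = 1.0
    pump_Pm_um_ms: float = 1.0
    pump_Kp_uM: float = 1.0
    rest_uM: float = 0.05
    k_on_per_uM_ms: float = 0.5  # buffer forward rate (used by the FD oracle)

    def __post_init__(self) -> None:
        for name in (
            "D_Ca_um2_ms",
            "K_d_uM",
            "pump_Pm_um_ms",
            "pump_Kp_uM",
            "rest_uM",
            "k_on_per_uM_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.D_B_um2_ms < 0 or self.B_total_uM < 0:
            raise ValidationError("D_B and B_total must be >= 0")


@dataclass(frozen=True)
class RBAConstants:
    """Effective constants of the linearized (rapid-buffer) calcium cable."""

    D_eff_um2_ms: float
    decay_per_ms: float
    source_scale: float  # 1/(1+theta), applied to every influx term
    theta: float
    lambda_c_um: float
    tau_c_ms: float
    buffer_speed_ratio: float  # buffer relaxation rate vs calcium decay rate


def rba_reduce(system: CalciumSystem, diameter_um: float) -> RBAConstants:
    """Reduce the calcium/buffer/pump system to effective diffusion-decay.

    The returned ``buffer_speed_ratio`` reports how much faster the buffer
    equilibrates than the calcium decay time; the approximation is trustworthy
    when it is large (>= ~100).
    """
    if diameter_um <= 0:
        raise ValidationError("diameter_um must be strictly positive")
    s = system
    theta = s.B_total_uM * s.K_d_uM / (s.K_d_uM + s.rest_uM) ** 2
    D_eff = (s.D_Ca_um2_ms + s.D_B_um2_ms * theta) / (1.0 + theta)
    decay = (4.0 * s.pump_Pm_um_ms / (diameter_um * s.pump_Kp_uM)) / (1.0 + theta)
    if D_eff <= 0 or decay <= 0:
        raise ValidationError("effective diffusion and decay must be positive")
    # buffer relaxation rate: k_on*(K_d + C_rest) in 1/ms
    buffer_rate = s.k_on_per_uM_ms * (s.K_d_uM + s.rest_uM)
    return RBAConstants(
        D_eff_um2_ms=D_eff,
        decay_per_ms=decay,
        source_scale=1.0 / (1.0 + theta),
        theta=theta,
        lambda_c_um=float(np.sqrt(D_eff / decay)),
        tau_c_ms=1.0 / decay,
        buffer_speed_ratio=buffer_rate / decay,
    )


# ---------------------------------------------------------------------------
# Influx and the chemical cable solve
# ---------------------------------------------------------------------------


def rest_current(spec, count: float, geometry: CableGeometry) -> float:
    """Steady channel current (nA) at the resting potential."""
    open_frac = 1.0
    for gate, p in spec.gates:
        xi, _tx = gate.steady_state(geometry.Er_mV)
        open_frac *= float(xi) ** p
    return (
        1.0e-6
        * spec.cluster_conductance_pS
        * count
        * open_frac
        * float(spec.driving_force(geometry.Er_mV, spec.E_mV))
    )


def calcium_influx_series(solution, model, t_ms: np.ndarray, events,
                          sites_um=None) -> dict:
    """Concentration flux series (uM um/ms) at every calcium-carrying site.

    Sources are the T- and L-type channel hotspots and the NMDA receptor's
    calcium component, each evaluated with the *full* (order-0 + order-1)
    voltage at its site; inward calcium current (negative in the outward-
    positive convention) becomes positive flux.  ``sites_um`` optionally
    restricts evaluation to sites near the probes (distant sources are
    exponentially negligible on the chemical cable).
    """
    from .analytic_solver import _nmda_current_series  # local: avoid cycle
    from .channels import gate_evolve

    geom: CableGeometry = model.geometry
    rba = rba_reduce(model.calcium, geom.diameter_um)
    conv = CURRENT_TO_FLUX / geom.cross_section_um2 * rba.source_scale
    dt = float(t_ms[1] - t_ms[0])
    out: dict = {}
    for name, spec in model.channels.items():
        if not spec.carries_calcium:
            continue
        for k, spot in enumerate(spec.hotspots):
            if sites_um is not None and not any(
                abs(spot.x_um - s) < 1e-9 for s in sites_um
            ):
                continue
            V = geom.Er_mV + geom.Vmax_mV * solution.u_at(spot.x_um)
            gates = [gate_evolve(g, V, dt) for g, _p in spec.gates]
            open_frac = np.ones_like(V)
            for (g, p), x in zip(spec.gates, gates):
                open_frac = open_frac * x**p
            i_nA = (
                1.0e-6
                * spec.cluster_conductance_pS
                * spot.count
                * open_frac
                * spec.driving_force(V, spec.E_mV)
            )
            # the resting window current is part of the balance that defines
            # the resting concentration; only deviations drive the cable
            out[(name, k, spot.x_um)] = -conv * (i_nA - rest_current(spec, spot.count, geom))
    if model.nmda is not None and len(events.pre_times_ms) > 0:
        spec = model.nmda
        if sites_um is None or any(abs(spec.x_um - s) < 1e-9 for s in sites_um):
            V = geom.Er_mV + geom.Vmax_mV * solution.u_at(spec.x_um)
            _tot, i_ca = _nmda_current_series(spec, V, t_ms, events.pre_times_ms)
            out[("NMDA", 0, spec.x_um)] = -conv * i_ca
    return out


@dataclass
class CalciumTransient:
    """Free-calcium time series at one probe, above the resting level."""

    t_ms: np.ndarray
    conc_uM: np.ndarray  # above rest
    rest_uM: float
    x_um: float = 0.0

    @property
    def peak(self) -> float:
        return float(np.max(self.conc_uM, initial=0.0))

    def running_integral(self) -> np.ndarray:
        dt = float(self.t_ms[1] - self.t_ms[0])
        return np.cumsum(self.conc_uM) * dt

    @property
    def max_integral(self) -> float:
        return float(np.max(self.running_integral(), initial=0.0))

    @property
    def peak_over_max_integral(self) -> float:
        mi = self.max_integral
        return self.peak / mi if mi > 0 else 0.0


def solve_calcium(
    sources: dict,
    system: CalciumSystem,
    geometry: CableGeometry,
    probes_um,
    t_ms: np.ndarray,
    cache=None,
) -> list[CalciumTransient]:
    """Convolve point-source flux series with the chemical cable kernel.

    ``sources`` maps ``(..., x_um)`` keys (last element the site position) to
    flux series in uM um/ms.  The kernel is the same killed-end image form as
    the electrical cable, in physical variables:

        G_c(x, y, t) = e^{-k t}/sqrt(4 pi D t)
                       [e^{-(x-y)^2/4Dt} - e^{-(x+y)^2/4Dt}].
    """
    from ._conv import volterra_convolve
    from .analytic_solver import KernelCache

    rba = rba_reduce(system, geometry.diameter_um)
    dt = float(t_ms[1] - t_ms[0])
    n = len(t_ms)
    cache = cache or KernelCache(geometry, dt)
    out = []
    for probe in np.atleast_1d(np.asarray(probes_um, dtype=float)):
        if probe < 0:
            raise ValidationError("probe position must be >= 0")
        c = np.zeros(n)
        for key, series in sources.items():
            y = float(key[-1])
            if not np.any(series):
                continue
            K0, K1 = cache.chemical(probe, y, rba.D_eff_um2_ms, rba.decay_per_ms, n)
            c += volterra_convolve(K0, K1, np.asarray(series, float), n)
        out.append(CalciumTransient(t_ms=t_ms, conc_uM=c, rest_uM=system.rest_uM, x_um=float(probe)))
    return out


# ---------------------------------------------------------------------------
# The calcium-dependent plasticity rule
# ---------------------------------------------------------------------------


def _sig(x, beta):
    return 1.0 / (1.0 + np.exp(-beta * np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class PlasticityRule:
    """Omega/eta parameterization of calcium-dependent plasticity.

    Omega is the canonical difference of sigmoids with midpoints at the
    depression threshold ``theta_d`` and potentiation threshold ``theta_p``;
    eta is the reciprocal of a calcium-dependent time constant,
    ``eta = 1 / (p1/(p2 + Ca^p3) + p4)`` (in 1/s).  ``drive_mode`` selects
    the scalar summary of a calcium transient that drives the rule:
    ``"peak"`` (normalized peak) or ``"ratio"`` (peak over the maximum of the
    running time-integral, then normalized).
    """

    theta_d: float = 0.35
    theta_p: float = 0.55
    beta1: float = 80.0
    beta2: float = 80.0
    baseline: float = 0.25
    eta_p1: float = 0.1
    eta_p2: float = 1.0e-5
    eta_p3: float = 3.0
    eta_p4: float = 1.0
    lambda_w: float = 0.0
    drive_mode: str = "peak"
    pairing_gain_s: float = 1.0  # effective per-pairing integration time
    # frequency-protocol ratio normalization: the causal (+delta_t) pairing at
    # the lowest repetition frequency is anchored to this drive, just above
    # the potentiation threshold (causal pairings potentiate at every
    # frequency in the reference experiments)
    ratio_anchor: float = 0.57
    ratio_anchor_freq_Hz: float = 2.0

    def __post_init__(self) -> None:
        if not self.theta_d < self.theta_p:
            raise ValidationError(
                f"thresholds must be ordered theta_d < theta_p "
                f"(got {self.theta_d} >= {self.theta_p})"
            )
        if self.drive_mode not in ("peak", "ratio"):
            raise ValidationError("drive_mode must be 'peak' or 'ratio'")
        if min(self.beta1, self.beta2, self.eta_p1, self.eta_p4) <= 0:
            raise ValidationError("slopes and eta parameters must be positive")


def omega(drive, rule: PlasticityRule = PlasticityRule()):
    """Sign function of the calcium-control hypothesis.

    Continuous; at the baseline for drive well below theta_d, below baseline
    (depression) between the thresholds, saturating above baseline
    (potentiation) for large drive.
    """
    ca = np.asarray(drive, dtype=float)
    return (
        rule.baseline
        + _sig(ca - rule.theta_p, rule.beta2)
        - rule.baseline * _sig(ca - rule.theta_d, rule.beta1)
    )


def eta(drive, rule: PlasticityRule = PlasticityRule()):
    """Calcium-dependent learning rate in 1/s; ~0 at rest, nondecreasing."""
    ca = np.clip(np.asarray(drive, dtype=float), 0.0, None)
    tau_s = rule.eta_p1 / (rule.eta_p2 + ca**rule.eta_p3) + rule.eta_p4
    return 1.0 / tau_s


def drive_variable(
    transient: CalciumTransient,
    mode: str = "peak",
    normalizer: float = 1.0,
) -> float:
    """Scalar calcium drive of a transient.

    ``peak``: peak concentration / normalizer (homogeneous of degree 1).
    ``ratio``: peak / max running time-integral, then / normalizer
    (invariant under uniform scaling of the transient); an all-rest
    transient yields drive 0 by convention.
    """
    if mode == "peak":
        return transient.peak / normalizer
    if mode == "ratio":
        return transient.peak_over_max_integral / normalizer
    raise ValidationError("mode must be 'peak' or 'ratio'")


def weight_change_single_pairing(drive: float, rule: PlasticityRule = PlasticityRule()) -> float:
    """Weight change of one pre/post pairing: eta(D) * (Omega(D) - baseline).

    The sign is set entirely by which side of the thresholds the drive falls:
    zero below theta_d, negative (LTD) between theta_d and theta_p, positive
    (LTP) above theta_p.
    """
    return float(eta(drive, rule) * (omega(drive, rule) - rule.baseline))


def weight_evolve_train(
    drive_series: np.ndarray,
    rule: PlasticityRule = PlasticityRule(),
    dt_s: float = 1.0,
) -> float:
    """Integrate dW/dt = eta(D) (Omega(D) - baseline - lambda_w W), W(0)=0.

    ``drive_series`` samples the drive on a uniform grid of spacing ``dt_s``
    seconds (eta is in 1/s).  With ``lambda_w = 0`` this is exactly the
    running integral of eta * (Omega - baseline), i.e. per-pairing
    accumulation for well-separated pairings.
    """
    D = np.asarray(drive_series, dtype=float)
    e = eta(D, rule)
    om = omega(D, rule) - rule.baseline
    if rule.lambda_w == 0.0:
        return float(np.sum(e * om) * dt_s)
    W = 0.0
    lam = rule.lambda_w
    for i in range(len(D)):
        # exact step for piecewise-constant drive
        Winf = om[i] / lam
        W = Winf + (W - Winf) * np.exp(-e[i] * lam * dt_s)
    return float(W)
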
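"""Experiment drivers: STDP windows, density/diameter sweeps, pairing frequency.

Sign convention (stated once, used everywhere): ``delta_t = t_post - t_pre``,
so *positive* delta_t means the presynaptic event precedes the postsynaptic
action potential (the classically potentiating order).

A pairing consists of one presynaptic event at the NMDA hotspot and one
action-potential clamp at the cable origin.  The drivers solve the voltage
cable to first order, convert the calcium-carrying currents at the synapse
into a calcium transient on the chemical cable, summarize the transient into
a scalar drive (normalized peak, or peak over the maximum running integral),
and apply the calcium-dependent plasticity rule.

Peak normalization follows the reference-location convention: drives are
divided by the maximum raw drive observed in the scan at the *proximal
reference* location, so windows taken at different distances share one scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .analytic_solver import (
    KernelCache,
    boundary_term,
    hotspot_source_series,
    source_scale_per_nA,
    volterra_convolve,
)
from .calcium_plasticity import (
    CURRENT_TO_FLUX,
    CalciumTransient,
    rba_reduce,
    rest_current,
    solve_calcium,
    weight_evolve_train,
)
from .channels import gate_evolve
from .model_core import Model, StimulusEvents, ValidationError, clamp_train

__all__ = [
    "PairingProtocol",
    "STDPWindowResult",
    "FrequencyCurveResult",
    "PairingEngine",
    "run_stdp_window",
    "fit_ltd_time_constant",
    "run_frequency_protocol",
    "find_crossover",
    "run_sweep",
    "depression_lobe_area",
    "positive_lobe_bounds",
]


@dataclass(frozen=True)
class PairingProtocol:
    """One repeated pre/post pairing pattern."""

    delta_t_ms: float
    n_pairings: int = 1
    frequency_Hz: float = 1.0
    location_um: float = 50.0

    def __post_init__(self) -> None:
        if self.n_pairings < 1:
            raise ValidationError("n_pairings must be >= 1")
        if self.frequency_Hz <= 0:
            raise ValidationError("frequency must be positive")
        if self.n_pairings > 1 and 1000.0 / self.frequency_Hz <= abs(self.delta_t_ms):
            raise ValidationError(
                f"inter-pairing interval {1000.0 / self.frequency_Hz:.1f} ms must "
                f"exceed |delta_t| = {abs(self.delta_t_ms)} ms"
            )


@dataclass
class STDPWindowResult:
    """Weight change versus pre/post timing difference at one location."""

    delta_t_ms: np.ndarray
    dw: np.ndarray
    location_um: float
    drive_mode: str
    drives: np.ndarray
    peaks_uM: np.ndarray
    normalizer: float
    tau_ltd_ms: float | None = None


@dataclass
class FrequencyCurveResult:
    """Weight change versus pairing repetition frequency for +/- delta_t."""

    frequency_Hz: np.ndarray
    dw_by_delta_t: dict      # delta_t -> dw array
    drives_by_delta_t: dict  # delta_t -> normalized drive array
    location_um: float
    drive_mode: str
    normalizer: float
    crossover_Hz: float | None = None
    all_crossovers_Hz: tuple = ()
    degenerate: bool = False


# ---------------------------------------------------------------------------
# The pairing engine
# ---------------------------------------------------------------------------


class PairingEngine:
    """Shared-state runner for pairing protocols at one synapse location.

    The boundary action potential is always clamped at the same times across
    a delta_t scan (only the presynaptic times move), so the passive field,
    the non-NMDA hotspot sources, and every convolution kernel are computed
    once and reused.  Calcium is evaluated at the synapse from the co-located
    calcium-carrying hotspots and the NMDA receptor; sites farther than
    ``chem_cutoff`` chemical space constants contribute exponentially little
    and are skipped.
    """

    def __init__(
        self,
        model: Model,
        post_onsets_ms,
        t_max_ms: float,
        cache: KernelCache | None = None,
        chem_cutoff_lambda_c: float = 12.0,
    ):
        if model.nmda is None:
            raise ValidationError("pairing protocols need an NMDA hotspot on the model")
        self.model = model
        geom = model.geometry
        self.geom = geom
        self.dt = float(model.dt_ms)
        n = int(round(t_max_ms / self.dt)) + 1
        self.t_ms = self.dt * np.arange(n)
        self.cache = cache if cache is not None else KernelCache(geom, self.dt)
        self.post_onsets = tuple(post_onsets_ms)
        self.probe_um = model.nmda.x_um
        self.rba = rba_reduce(model.calcium, geom.diameter_um)
        self.chem_cutoff_um = chem_cutoff_lambda_c * self.rba.lambda_c_um

        clamp = clamp_train(model.waveform, self.post_onsets, self.t_ms) / geom.Vmax_mV
        self.clamp = clamp

        positions = {self.probe_um}
        for spec in model.channels.values():
            positions.update(h.x_um for h in spec.hotspots)
        self.positions = sorted(positions)
        self.u0 = {
            x: boundary_term(clamp, x / geom.lambda_um, self.t_ms, geom, self.cache)
            for x in self.positions
        }

        # non-NMDA hotspot sources driven by the passive field, once
        quiet = StimulusEvents(post_onsets_ms=self.post_onsets, pre_times_ms=())
        sources, _ = hotspot_source_series(model, self.u0, self.t_ms, quiet)
        Xp = self.probe_um / geom.lambda_um
        self.u1_base = np.zeros(n)
        pos_of = {}
        for name, spec in model.channels.items():
            for k, spot in enumerate(spec.hotspots):
                pos_of[(name, k)] = spot.x_um
        for key, w in sources.items():
            if not np.any(w):
                continue
            K0, K1 = self.cache.source(Xp, pos_of[key] / geom.lambda_um, n)
            self.u1_base -= volterra_convolve(K0, K1, w, n)
        self._scale = source_scale_per_nA(geom)
        self._flux_conv = CURRENT_TO_FLUX / geom.cross_section_um2 * self.rba.source_scale

    def _g_train(self, pre_times_ms) -> np.ndarray:
        """Summed normalized NMDA conductance for a train of events.

        The single-event time course is sampled once and added at each event
        offset (rounded to the grid), which keeps long trains cheap.
        """
        from .channels import nmda_conductance

        if not hasattr(self, "_g_single"):
            self._g_single = nmda_conductance(self.model.nmda, self.t_ms)
        n = len(self.t_ms)
        g = np.zeros(n)
        for tp in pre_times_ms:
            i = int(round(tp / self.dt))
            if i >= n:
                continue
            if i >= 0:
                g[i:] += self._g_single[: n - i]
            else:
                g += self._g_single[-i:][:n]
        from .channels import nmda_pool_saturate

        return nmda_pool_saturate(self.model.nmda, g)

    def _voltage_from_g(self, g: np.ndarray) -> np.ndarray:
        from .channels import mg_block

        u = self.u0[self.probe_um] + self.u1_base
        if np.any(g):
            spec = self.model.nmda
            V0 = self.geom.Er_mV + self.geom.Vmax_mV * self.u0[self.probe_um]
            gB = g * spec.conductance_pS * mg_block(V0, spec.Mg_mM) * 1.0e-6
            w = self._scale * gB * (V0 - spec.E_mV)
            Xp = self.probe_um / self.geom.lambda_um
            K0, K1 = self.cache.source(Xp, Xp, len(self.t_ms))
            u = u - volterra_convolve(K0, K1, w, len(self.t_ms))
        return u

    def voltage_at_probe(self, pre_times_ms) -> np.ndarray:
        """Full first-order dimensionless voltage at the synapse."""
        return self._voltage_from_g(self._g_train(pre_times_ms))

    def calcium_transient(self, pre_times_ms) -> CalciumTransient:
        """Calcium at the synapse for presynaptic events at ``pre_times_ms``."""
        geom = self.geom
        g_syn = self._g_train(pre_times_ms)
        u_full = self._voltage_from_g(g_syn)
        V = geom.Er_mV + geom.Vmax_mV * u_full
        sources = {}
        for name, spec in self.model.channels.items():
            if not spec.carries_calcium:
                continue
            for k, spot in enumerate(spec.hotspots):
                if abs(spot.x_um - self.probe_um) > self.chem_cutoff_um:
                    continue
                gates = [gate_evolve(g, V, self.dt) for g, _p in spec.gates]
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
                i_nA = i_nA - rest_current(spec, spot.count, geom)
                sources[(name, k, spot.x_um)] = -self._flux_conv * i_nA
        if np.any(g_syn):
            from .channels import mg_block

            spec = self.model.nmda
            gB = g_syn * spec.conductance_pS * mg_block(V, spec.Mg_mM) * 1.0e-6
            i_ca = spec.ca_fraction * gB * (V - spec.ECa_mV)
            sources[("NMDA", 0, spec.x_um)] = -self._flux_conv * i_ca
        [tr] = solve_calcium(
            sources, self.model.calcium, geom, [self.probe_um], self.t_ms, cache=self.cache
        )
        return tr


_PAIR_T_POST = 150.0     # ms; fixed boundary AP time within a single-pairing run
_PAIR_T_MAX = 650.0      # ms; run length covering delta_t in [-150, 150] + tails
_TRAIN_LEAD = 60.0       # ms before the first pairing of a train
_TRAIN_TAIL = 400.0      # ms after the last pairing


def _raw_drive(tr: CalciumTransient, mode: str) -> float:
    return tr.peak if mode == "peak" else tr.peak_over_max_integral


def _window_raw(model: Model, location_um: float, delta_ts, cache=None):
    from .io_fixtures import relocate_synapse

    m = relocate_synapse(model, location_um)
    engine = PairingEngine(m, (_PAIR_T_POST,), _PAIR_T_MAX, cache=cache)
    peaks, ratios = [], []
    for dt_pair in delta_ts:
        tr = engine.calcium_transient((_PAIR_T_POST - dt_pair,))
        peaks.append(tr.peak)
        ratios.append(tr.peak_over_max_integral)
    return np.asarray(peaks), np.asarray(ratios)


def run_stdp_window(
    model: Model,
    location_um: float,
    delta_ts=None,
    drive_mode: str | None = None,
    normalizer: float | None = None,
    reference_location_um: float | None = None,
    cache: KernelCache | None = None,
) -> STDPWindowResult:
    """Single-pairing STDP window: weight change per pre/post lag.

    For each delta_t one presynaptic event and one boundary AP are scheduled,
    the voltage and calcium cables solved, the scalar drive extracted and the
    plasticity rule applied.  ``normalizer`` defaults to the maximum raw
    drive over the scan at ``reference_location_um`` (itself defaulting to
    this location).
    """
    from .calcium_plasticity import weight_change_single_pairing

    delta_ts = np.asarray(
        delta_ts if delta_ts is not None else np.arange(-100.0, 121.0, 5.0), dtype=float
    )
    if len(delta_ts) == 0:
        raise ValidationError("delta_t grid is empty")
    if np.any(np.diff(delta_ts) <= 0):
        raise ValidationError("delta_t grid must be strictly increasing")
    if np.all(delta_ts > 0) or np.all(delta_ts < 0):
        import warnings

        warnings.warn("delta_t grid is entirely one-signed; window will be partial")
    rule = model.rule
    mode = drive_mode or rule.drive_mode

    peaks, ratios = _window_raw(model, location_um, delta_ts, cache=cache)
    raw = peaks if mode == "peak" else ratios
    if normalizer is None:
        ref = reference_location_um if reference_location_um is not None else location_um
        if abs(ref - location_um) < 1e-9:
            normalizer = float(np.max(raw))
        else:
            ref_peaks, ref_ratios = _window_raw(model, ref, delta_ts, cache=cache)
            normalizer = float(np.max(ref_peaks if mode == "peak" else ref_ratios))
    drives = raw / normalizer
    dw = np.array([weight_change_single_pairing(d, rule) for d in drives])
    result = STDPWindowResult(
        delta_t_ms=delta_ts,
        dw=dw,
        location_um=location_um,
        drive_mode=mode,
        drives=drives,
        peaks_uM=peaks,
        normalizer=normalizer,
    )
    result.tau_ltd_ms = fit_ltd_time_constant(result)
    return result


def fit_ltd_time_constant(window: STDPWindowResult) -> float | None:
    """Decay constant (ms) of the post-pre (negative delta_t) depression lobe.

    Nonlinear least-squares single-exponential fit of |dw| ~ A exp(delta_t /
    tau) over the decaying flank of the contiguous depression lobe (from the
    depression maximum toward more negative lags); the nonlinear residual
    weights large depressions naturally, so near-threshold edge points cannot
    dominate the slope, and the fitted tau is exactly invariant under uniform
    rescaling of dw.  Returns None when there is no negative-lag depression
    lobe with enough points.
    """
    from scipy.optimize import curve_fit

    dts, dw = window.delta_t_ms, window.dw
    floor = 0.01 * max(np.max(np.abs(dw)), 1e-300)
    neg = np.nonzero((dts < 0) & (dw < -floor))[0]
    if len(neg) < 2:
        return None
    runs = np.split(neg, np.nonzero(np.diff(neg) > 1)[0] + 1)
    lobe = max(runs, key=len)
    depth = np.abs(dw[lobe])
    i_max = int(np.argmax(depth))
    flank = lobe[: i_max + 1]
    if len(flank) < 2:
        return None
    x, y = dts[flank], np.abs(dw[flank])
    x0 = x[-1]
    if len(flank) == 2:
        if y[0] >= y[1]:
            return None
        return float((x[1] - x[0]) / np.log(y[1] / y[0]))
    try:
        popt, _ = curve_fit(
            lambda t, A, tau: A * np.exp((t - x0) / tau), x, y,
            p0=(float(y.max()), 20.0), maxfev=5000,
        )
    except Exception:
        return None
    tau = float(popt[1])
    return tau if tau > 0 else None


def positive_lobe_bounds(window: STDPWindowResult) -> tuple[float, float] | None:
    """(lower, upper) delta_t of the contiguous pre-post depression region."""
    dts, dw = window.delta_t_ms, window.dw
    floor = 0.01 * max(np.max(np.abs(dw)), 1e-300)
    pos = np.nonzero((dts > 0) & (dw < -floor))[0]
    if len(pos) == 0:
        return None
    runs = np.split(pos, np.nonzero(np.diff(pos) > 1)[0] + 1)
    lobe = max(runs, key=len)
    return float(dts[lobe[0]]), float(dts[lobe[-1]])


def depression_lobe_area(window: STDPWindowResult, side: str = "positive") -> float:
    """Integrated |dw| of the depression lobe on one side of zero lag."""
    dts, dw = window.delta_t_ms, window.dw
    mask = (dts > 0) if side == "positive" else (dts < 0)
    mask &= dw < 0
    if not np.any(mask):
        return 0.0
    step = float(np.median(np.diff(dts)))
    return float(np.sum(np.abs(dw[mask])) * step)


# ---------------------------------------------------------------------------
# Pairing-frequency protocol
# ---------------------------------------------------------------------------


def _train_drive(model, location_um, delta_t, f_Hz, n_pairings, cache):
    """Raw calcium drives of one pairing train.

    Returns ``(train_peak, per_pairing_ratios)``: the whole-train peak (the
    scalar drive of peak mode) and the per-pairing ratio series — for every
    pairing cycle, the calcium peak within that cycle divided by the running
    time-integral of calcium accumulated so far.  The ratio series embodies
    the temporal-integration reading of the ratio drive: the same event-locked
    peak counts for less as integrated calcium activity builds up over the
    train.
    """
    from .io_fixtures import relocate_synapse

    period = 1000.0 / f_Hz
    if period <= abs(delta_t):
        raise ValidationError(
            f"frequency {f_Hz} Hz infeasible: period {period:.2f} ms <= |delta_t|"
        )
    posts = _TRAIN_LEAD + period * np.arange(n_pairings)
    posts = np.round(posts / model.dt_ms) * model.dt_ms  # grid-aligned onsets
    t_max = posts[-1] + _TRAIN_TAIL
    m = relocate_synapse(model, location_um)
    engine = PairingEngine(m, tuple(posts), t_max, cache=cache)
    pres = posts - delta_t
    tr = engine.calcium_transient(tuple(pres))
    c, t = tr.conc_uM, tr.t_ms
    dt_s = float(t[1] - t[0])
    # one cycle per presynaptic event: the calcium it can gate (including a
    # coincidence with the following action potential) falls in [pre_i,
    # pre_i + period), so cycle peaks vary continuously with frequency
    ratios = np.empty(n_pairings)
    for i, p in enumerate(pres):
        win = (t >= p) & (t < p + period)
        peak_i = float(np.max(c[win], initial=0.0))
        denom = float(np.sum(c[win])) * dt_s
        ratios[i] = peak_i / denom if denom > 0 else 0.0
    return tr.peak, ratios


def run_frequency_protocol(
    model: Model,
    location_um: float,
    frequencies_Hz=None,
    delta_ts=(10.0, -10.0),
    n_pairings: int = 60,
    drive_mode: str | None = None,
    normalizer: float | None = None,
    cache: KernelCache | None = None,
) -> FrequencyCurveResult:
    """Pairing-frequency curves: final weight change per repetition frequency.

    For each frequency the full n-pairing train is simulated, the calcium
    drive of the whole train extracted per the configured mode, and the
    weight ODE evolved (per-pairing accumulation by default).  Drives are
    normalized by the scan maximum unless an explicit normalizer is given.
    """
    rule = model.rule
    mode = drive_mode or rule.drive_mode
    freqs = np.asarray(
        frequencies_Hz if frequencies_Hz is not None else np.arange(2.0, 61.0, 2.0),
        dtype=float,
    )
    cache = cache if cache is not None else KernelCache(model.geometry, model.dt_ms)
    raw = {}
    for dt_pair in delta_ts:
        vals = []
        for f in freqs:
            peak, ratios = _train_drive(model, location_um, dt_pair, f, n_pairings, cache)
            vals.append(np.full(n_pairings, peak) if mode == "peak" else ratios)
        raw[dt_pair] = vals
    if normalizer is None:
        # anchor: the first causal pairing of a reference low-frequency train
        # sits just above the potentiation threshold (see PlasticityRule);
        # anchoring at a fixed reference frequency keeps the scale independent
        # of the scanned grid, and causal pairings potentiate at every
        # frequency as in the reference experiments
        causal = max(delta_ts)
        pk_ref, ref = _train_drive(
            model, location_um, causal, rule.ratio_anchor_freq_Hz, n_pairings, cache
        )
        anchor_raw = ref[0] if mode == "ratio" else pk_ref
        normalizer = float(anchor_raw / rule.ratio_anchor)
    drives = {k: np.array([np.mean(s) / normalizer for s in v]) for k, v in raw.items()}
    dw = {
        k: np.array(
            [
                weight_evolve_train(s / normalizer, rule, dt_s=rule.pairing_gain_s)
                for s in v
            ]
        )
        for k, v in raw.items()
    }
    result = FrequencyCurveResult(
        frequency_Hz=freqs,
        dw_by_delta_t=dw,
        drives_by_delta_t=drives,
        location_um=location_um,
        drive_mode=mode,
        normalizer=normalizer,
    )
    if len(delta_ts) == 2:
        pos, neg = delta_ts[0], delta_ts[1]
        cross, all_cross, degen = find_crossover(dw[pos], dw[neg], freqs, full=True)
        result.crossover_Hz = cross
        result.all_crossovers_Hz = tuple(all_cross)
        result.degenerate = degen
    return result


def find_crossover(curve_pos, curve_neg, frequency_Hz, full: bool = False):
    """Frequency where the two weight-change curves intersect.

    Locates sign changes of (curve_pos - curve_neg) on the shared grid and
    linearly interpolates each zero; returns the lowest (and, with
    ``full=True``, all crossings plus a degeneracy flag for identical
    curves).  Returns None when the curves do not cross.
    """
    curve_pos = np.asarray(curve_pos, float)
    curve_neg = np.asarray(curve_neg, float)
    f = np.asarray(frequency_Hz, float)
    if curve_pos.shape != curve_neg.shape or curve_pos.shape != f.shape:
        raise ValidationError("curves and frequency grid must share a shape")
    diff = curve_pos - curve_neg
    if np.allclose(diff, 0.0):
        return (None, [], True) if full else None
    crossings = []
    for i in range(len(f) - 1):
        a, b = diff[i], diff[i + 1]
        if a == 0.0:
            crossings.append(float(f[i]))
        elif a * b < 0:
            crossings.append(float(f[i] - a * (f[i + 1] - f[i]) / (b - a)))
    if diff[-1] == 0.0:
        crossings.append(float(f[-1]))
    lowest = crossings[0] if crossings else None
    return (lowest, crossings, False) if full else lowest


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

_SWEEP_PARAMS = ("diameter", "Na", "K_DR", "K_A", "Ca_T", "Ca_L", "nmda")


def run_sweep(
    model: Model,
    parameter: str,
    factors,
    locations_um,
    delta_ts=None,
    drive_mode: str | None = None,
    cache: KernelCache | None = None,
) -> dict:
    """Windows at every location for each scaled value of one parameter.

    ``parameter`` is "diameter" (cable diameter scaled by each factor, cable
    constants re-derived) or a channel name (hotspot density scaled).  Each
    scaled configuration is normalized to its own scan at the first
    (reference, proximal) location — the convention under which a parameter
    change shows up through the spatial profile of calcium rather than
    through a global concentration scale.
    Returns {factor: {location: STDPWindowResult}}.
    """
    from .io_fixtures import build_model

    if parameter not in _SWEEP_PARAMS:
        raise ValidationError(
            f"unknown sweep parameter {parameter!r}; valid: {_SWEEP_PARAMS}"
        )
    rule = model.rule
    mode = drive_mode or rule.drive_mode
    delta_ts = np.asarray(
        delta_ts if delta_ts is not None else np.arange(-100.0, 121.0, 5.0), dtype=float
    )
    reference = locations_um[0]

    out = {}
    for factor in factors:
        if factor <= 0:
            raise ValidationError("sweep factors must be positive")
        if parameter == "diameter":
            cfg = {"cable": {"diameter_um": model.geometry.diameter_um * factor}}
            m = build_model(model.config, overrides=cfg)
            sweep_cache = None  # geometry changed; kernels cannot be shared
        else:
            m = replace(model)
            m.channels = dict(model.channels)
            if parameter == "nmda":
                m.nmda = model.nmda.scaled(factor)
            else:
                m.channels[parameter] = model.channels[parameter].scaled(factor)
            sweep_cache = cache
        ref_peaks, ref_ratios = _window_raw(m, reference, delta_ts, cache=sweep_cache)
        normalizer = float(np.max(ref_peaks if mode == "peak" else ref_ratios))
        out[factor] = {
            loc: run_stdp_window(
                m,
                loc,
                delta_ts,
                drive_mode=mode,
                normalizer=normalizer,
                cache=sweep_cache,
            )
            for loc in locations_um
        }
    return out
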
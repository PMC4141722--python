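"""Config parsing and validation, model assembly, result writers, fixtures.

The configuration is a nested key/value mapping (YAML on disk).  Every block
has documented defaults (see :func:`default_config`); :func:`build_model`
deep-merges user values over the defaults, validates cross-field invariants
and assembles a :class:`~ioniccable.model_core.Model`.

Channel hotspots are laid out on a regular grid along the cable with cluster
counts derived from a membrane density: ``count = density * pi * d * spacing
/ gamma`` (the channels a hotspot represents from its stretch of membrane).
The synapse adds the NMDA receptor hotspot plus co-located T- and L-type
calcium clusters at a configurable position.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calcium_plasticity import CalciumSystem, CalciumTransient, PlasticityRule
from .channels import Hotspot, NMDASpec, standard_channel_set
from .model_core import BoundaryWaveform, Model, ValidationError, derive_constants

__all__ = [
    "default_config",
    "load_config",
    "build_model",
    "relocate_synapse",
    "make_fixture",
    "write_results",
    "solution_to_frame",
    "save_fields_h5",
    "validate_summary",
    "RunManifest",
]


def default_config() -> dict:
    """The shipped baseline configuration (all units in the key names)."""
    return {
        "cable": {
            "diameter_um": 1.0,
            "Cm_uF_cm2": 1.0,
            "Ri_ohm_cm": 100.0,
            "Rm_ohm_cm2": 1.0e4,
            "EL_mV": -65.0,
            "Er_mV": -65.0,
            "Vmax_mV": 100.0,
        },
        "stimulus": {
            "kind": "ap_adp",
            "amplitude_mV": 100.0,
            "width_ms": 1.2,
            "adp_amplitude_mV": 16.0,
            "adp_tau_ms": 35.0,
            "adp_rise_ms": 3.0,
            "ahp_amplitude_mV": 0.0,
            "ahp_tau_ms": 8.0,
            "ahp_rise_ms": 1.0,
        },
        "channels": {
            "Na": {"density_pS_um2": 30.0, "gamma_pS": 20.0},
            "K_DR": {"density_pS_um2": 40.0, "gamma_pS": 20.0},
            "K_A": {"density_pS_um2": 20.0, "gamma_pS": 20.0},
            "Ca_T": {"density_pS_um2": 3.0, "gamma_pS": 10.0},
            "Ca_L": {"density_pS_um2": 3.0, "gamma_pS": 10.0},
        },
        "hotspots": {"start_um": 25.0, "spacing_um": 50.0, "end_um": 480.0},
        "synapse": {
            "x_um": 50.0,
            "nmda": {
                "gamma_pS": 50.0,
                "count": 60.0,
                "E_mV": 0.0,
                "ECa_mV": 120.0,
                "tau_rise_ms": 2.0,
                "tau_decay_ms": 12.0,
                "tau_slow_ms": 110.0,
                "fraction_fast": 0.65,
                "ca_fraction": 0.1,
                "Mg_mM": 1.0,
                "pool_capacity": None,
            },
            "ca_t_count": 10.0,
            "ca_l_count": 10.0,
        },
        "calcium": {
            "DCa_um2_ms": 0.22,
            "DB_um2_ms": 0.05,
            "BT_uM": 100.0,
            "Kd_uM": 1.0,
            "Pm_um_ms": 1.0,
            "Kp_uM": 1.0,
            "rest_uM": 0.05,
            "k_on_per_uM_ms": 0.5,
        },
        "plasticity": {
            "theta_d": 0.35,
            "theta_p": 0.55,
            "beta1": 80.0,
            "beta2": 80.0,
            "baseline": 0.25,
            "eta_p1": 0.1,
            "eta_p2": 1.0e-5,
            "eta_p3": 3.0,
            "eta_p4": 1.0,
            "lambda_w": 0.0,
            "drive_mode": "peak",
            "pairing_gain_s": 1.0,
            "ratio_anchor": 0.57,
            "ratio_anchor_freq_Hz": 2.0,
        },
        "solver": {"dT": 0.01},
        "protocol": {
            "proximal_um": 50.0,
            "distal_um": 300.0,
            "delta_t_min_ms": -100.0,
            "delta_t_max_ms": 120.0,
            "delta_t_step_ms": 5.0,
            "freq_min_Hz": 2.0,
            "freq_max_Hz": 60.0,
            "freq_step_Hz": 2.0,
            "n_pairings": 60,
        },
    }


def _deep_merge(base: dict, over: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in (over or {}).items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ValidationError(f"unknown config key {where!r}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ValidationError(f"config key {where!r} must be a mapping")
            out[key] = _deep_merge(base[key], val, where)
        else:
            out[key] = val
    return out


def load_config(path) -> dict:
    """Read a YAML config, merge over defaults, and validate by building."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = _deep_merge(default_config(), user)
    build_model(cfg)  # raises ValidationError naming the offending key
    return cfg


def build_model(config: dict | None = None, overrides: dict | None = None,
                synapse_x_um: float | None = None) -> Model:
    """Assemble a validated Model from a (possibly partial) configuration."""
    cfg = _deep_merge(default_config(), config or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)

    cal_cfg = cfg["calcium"]
    calcium = CalciumSystem(
        D_Ca_um2_ms=cal_cfg["DCa_um2_ms"],
        D_B_um2_ms=cal_cfg["DB_um2_ms"],
        B_total_uM=cal_cfg["BT_uM"],
        K_d_uM=cal_cfg["Kd_uM"],
        pump_Pm_um_ms=cal_cfg["Pm_um_ms"],
        pump_Kp_uM=cal_cfg["Kp_uM"],
        rest_uM=cal_cfg["rest_uM"],
        k_on_per_uM_ms=cal_cfg["k_on_per_uM_ms"],
    )
    geometry = derive_constants(**cfg["cable"], calcium=calcium)
    waveform = BoundaryWaveform(**cfg["stimulus"])

    factories = {}
    for name, ch in cfg["channels"].items():
        factories[name] = {
            k: v for k, v in ch.items() if k not in ("density_pS_um2", "epsilon")
        }
    channels = standard_channel_set(**factories)

    hs = cfg["hotspots"]
    if hs["spacing_um"] <= 0 or hs["start_um"] < 0:
        raise ValidationError("hotspots.spacing_um must be > 0 and start_um >= 0")
    grid = np.arange(hs["start_um"], hs["end_um"] + 1e-9, hs["spacing_um"])

    syn = cfg["synapse"]
    x_syn = float(synapse_x_um if synapse_x_um is not None else syn["x_um"])
    if x_syn < 0:
        raise ValidationError("synapse.x_um must be >= 0")

    d = geometry.diameter_um
    for name, spec in channels.items():
        ch_cfg = cfg["channels"][name]
        dens = ch_cfg["density_pS_um2"]
        if dens < 0:
            raise ValidationError(f"channels.{name}.density_pS_um2 must be >= 0")
        count = dens * np.pi * d * hs["spacing_um"] / spec.gamma_pS
        spots = [Hotspot(x_um=float(x), count=float(count)) for x in grid]
        if spec.carries_calcium:
            syn_count = syn["ca_t_count"] if name == "Ca_T" else syn["ca_l_count"]
            if syn_count > 0:
                spots.append(Hotspot(x_um=x_syn, count=float(syn_count)))
        channels[name] = replace(
            spec, hotspots=tuple(spots), epsilon=float(ch_cfg.get("epsilon", 1.0))
        )

    nmda = NMDASpec(x_um=x_syn, **syn["nmda"])
    rule = PlasticityRule(**cfg["plasticity"])
    dt_ms = cfg["solver"]["dT"] * geometry.tau_ms

    return Model(
        geometry=geometry,
        waveform=waveform,
        channels=channels,
        nmda=nmda,
        calcium=calcium,
        rule=rule,
        dt_ms=dt_ms,
        config=cfg,
    )


def relocate_synapse(model: Model, x_um: float) -> Model:
    """Copy of the model with the synapse (NMDA + co-located VGCC) moved."""
    if abs(model.nmda.x_um - x_um) < 1e-12:
        return model
    old = model.nmda.x_um
    channels = {}
    for name, spec in model.channels.items():
        spots = tuple(
            replace(h, x_um=float(x_um)) if abs(h.x_um - old) < 1e-12 else h
            for h in spec.hotspots
        )
        channels[name] = replace(spec, hotspots=spots)
    m = replace(model)
    m.channels = channels
    m.nmda = replace(model.nmda, x_um=float(x_um))
    return m


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Analytically-known synthetic objects for testing fit/summary code.

    kinds: ``clamp`` (an AP+ADP waveform), ``window`` (STDP window with an
    exponential LTD lobe of known time constant), ``transient`` (rectangular
    calcium pulse), ``crossing-curves`` (two frequency curves crossing at a
    known frequency).
    """
    from .protocols import STDPWindowResult

    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "clamp":
        return BoundaryWaveform(
            amplitude_mV=p.get("amplitude_mV", 100.0),
            width_ms=p.get("width_ms", 1.2),
            adp_amplitude_mV=p.get("adp_amplitude_mV", 25.0),
            adp_tau_ms=p.get("adp_tau_ms", 35.0),
        )
    if kind == "window":
        tau = p.get("tau_ltd_ms", 25.0)
        amp = p.get("amplitude", 1.0)
        dts = np.asarray(p.get("delta_t_ms", np.arange(-100.0, 121.0, 5.0)), float)
        noise = p.get("noise", 0.0)
        dw = np.where(
            dts < 0,
            -amp * np.exp(dts / tau),
            2.0 * amp * np.exp(-dts / 15.0),
        )
        dw = dw * (1.0 + noise * rng.standard_normal(dw.shape))
        return STDPWindowResult(
            delta_t_ms=dts,
            dw=dw,
            location_um=p.get("location_um", 50.0),
            drive_mode="peak",
            drives=np.abs(dw),
            peaks_uM=np.abs(dw),
            normalizer=1.0,
        )
    if kind == "transient":
        height = p.get("height_uM", 1.0)
        duration = p.get("duration_ms", 20.0)
        dt = p.get("dt_ms", 0.1)
        t = np.arange(0.0, p.get("t_max_ms", 100.0) + dt / 2, dt)
        c = np.where(t < duration, height, 0.0)
        return CalciumTransient(t_ms=t, conc_uM=c, rest_uM=p.get("rest_uM", 0.05))
    if kind == "crossing-curves":
        f = np.asarray(p.get("frequency_Hz", np.arange(1.0, 61.0)), float)
        fc = p.get("crossover_Hz", 30.0)
        slope = p.get("slope", 0.01)
        return f, slope * (f - fc), -slope * (f - fc)
    raise ValidationError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"

# minimal structural schema for summary.json entries (checked without any
# external schema library)
SUMMARY_SCHEMA = {
    "stdp_window": {"location_um": (int, float), "drive_mode": str,
                     "normalizer": (int, float)},
    "frequency_curves": {"location_um": (int, float), "drive_mode": str,
                          "normalizer": (int, float)},
    "calcium_transient": {"peak_uM": (int, float)},
    "table": {},
}


def validate_summary(summary: dict) -> None:
    """Structural validation of a results summary; raises ValidationError."""
    for name, entry in summary.items():
        if not isinstance(entry, dict) or "kind" not in entry:
            raise ValidationError(f"summary entry {name!r} lacks a 'kind'")
        kind = entry["kind"]
        if kind not in SUMMARY_SCHEMA:
            raise ValidationError(f"summary entry {name!r}: unknown kind {kind!r}")
        for key, types in SUMMARY_SCHEMA[kind].items():
            if key not in entry or not isinstance(entry[key], types):
                raise ValidationError(
                    f"summary entry {name!r}: field {key!r} missing or mistyped"
                )


def solution_to_frame(solution) -> pd.DataFrame:
    """Tabular (X, T, u) view of a voltage solution, in dimensionless units."""
    geom = solution.geometry
    X = np.repeat(solution.x_um / geom.lambda_um, len(solution.t_ms))
    T = np.tile(solution.t_ms / geom.tau_ms, len(solution.x_um))
    return pd.DataFrame({"X": X, "T": T, "u": solution.u.ravel()})


def save_fields_h5(solution, path) -> None:
    """Full voltage fields in an HDF5 container (datasets x_um, t_ms, u0, u1)."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("x_um", data=solution.x_um)
        fh.create_dataset("t_ms", data=solution.t_ms)
        fh.create_dataset("u0", data=solution.u0)
        fh.create_dataset("u1", data=solution.u1)
        fh.attrs["order"] = solution.order


@dataclass
class RunManifest:
    """Snapshot that makes a run bit-for-bit reproducible."""

    config: dict
    grids: dict
    software_version: str
    wall_time_s: float
    input_hash: str

    @classmethod
    def create(cls, config: dict, grids: dict, wall_time_s: float = 0.0) -> "RunManifest":
        from . import __version__

        blob = json.dumps(config, sort_keys=True).encode()
        return cls(
            config=config,
            grids=grids,
            software_version=__version__,
            wall_time_s=wall_time_s,
            input_hash=hashlib.sha256(blob).hexdigest(),
        )


def _window_frame(w) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "delta_t_ms": w.delta_t_ms,
            "dw": w.dw,
            "drive": w.drives,
            "peak_ca_uM": w.peaks_uM,
        }
    )


def _frequency_frame(r) -> pd.DataFrame:
    data = {"frequency_Hz": r.frequency_Hz}
    for dt_pair, dw in r.dw_by_delta_t.items():
        tag = f"{dt_pair:+g}ms"
        data[f"dw_{tag}"] = dw
        data[f"drive_{tag}"] = r.drives_by_delta_t[dt_pair]
    return pd.DataFrame(data)


def write_results(results: dict, out_dir, config: dict | None = None) -> list:
    """Write window/frequency/transient results as CSV plus a JSON summary.

    ``results`` maps a name to a result object (STDPWindowResult,
    FrequencyCurveResult, CalciumTransient or a plain DataFrame).  Floats are
    written with 17 significant digits so a read round-trips exactly.
    """
    from .protocols import FrequencyCurveResult, STDPWindowResult

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    summary: dict = {}
    t0 = time.time()
    for name, res in results.items():
        path = out / f"{name}.csv"
        if isinstance(res, STDPWindowResult):
            frame = _window_frame(res)
            summary[name] = {
                "kind": "stdp_window",
                "location_um": res.location_um,
                "drive_mode": res.drive_mode,
                "normalizer": res.normalizer,
                "tau_ltd_ms": res.tau_ltd_ms,
            }
            from .protocols import positive_lobe_bounds

            bounds = positive_lobe_bounds(res)
            summary[name]["positive_ltd_lobe_ms"] = list(bounds) if bounds else None
        elif isinstance(res, FrequencyCurveResult):
            frame = _frequency_frame(res)
            summary[name] = {
                "kind": "frequency_curves",
                "location_um": res.location_um,
                "drive_mode": res.drive_mode,
                "normalizer": res.normalizer,
                "crossover_Hz": res.crossover_Hz,
                "all_crossovers_Hz": list(res.all_crossovers_Hz),
            }
        elif isinstance(res, CalciumTransient):
            frame = pd.DataFrame({"t_ms": res.t_ms, "ca_uM": res.conc_uM + res.rest_uM})
            summary[name] = {"kind": "calcium_transient", "peak_uM": res.peak}
        elif isinstance(res, pd.DataFrame):
            frame = res
            summary[name] = {"kind": "table"}
        else:
            raise ValidationError(f"cannot write result of type {type(res).__name__}")
        try:
            frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
        except OSError as exc:  # pragma: no cover - environment dependent
            raise ValidationError(f"failed writing {path}: {exc}") from exc
        written.append(path)

    validate_summary(summary)
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(summary_path)
    if config is not None:
        manifest = RunManifest.create(config, grids={}, wall_time_s=time.time() - t0)
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True))
        written.append(manifest_path)
    return written
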
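"""Core domain types: cable geometry, dimensionless frames, boundary waveforms.

The dendrite is a semi-infinite cylindrical cable (boundary at ``x = 0``,
domain ``x >= 0``).  Two linear cables live on it:

* the *electrical* cable (membrane potential), with space constant
  ``lambda = sqrt(d * R_m / (4 * R_i))`` and time constant ``tau = R_m * C_m``;
* the *chemical* cable (free calcium after the rapid-buffer reduction), with
  its own, much shorter, constants ``lambda_c`` and ``tau_c``.

The same physical point therefore has two different dimensionless coordinates
— electrotonic ``X = x/lambda`` and chemicotonic ``X_c = x/lambda_c`` — linked
by the identity ``X_c * lambda_c = X * lambda = x``.

Public units: position um, time ms, voltage mV, concentration uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .calcium_plasticity import CalciumSystem

__all__ = [
    "CableGeometry",
    "DimensionlessFrame",
    "BoundaryWaveform",
    "derive_constants",
    "to_electrotonic",
    "to_chemicotonic",
    "ap_clamp",
]

# Unit conversions used throughout: the public interface takes textbook CGS
# membrane constants (Ohm cm, Ohm cm^2, uF/cm^2) but all internal lengths are
# micrometres.
_OHM_CM_TO_OHM_UM = 1.0e4          # axial resistivity
_OHM_CM2_TO_OHM_UM2 = 1.0e8        # membrane resistivity


class ValidationError(ValueError):
    """A model parameter violates its physical constraint."""


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        try:
            value = float(value)
        except (TypeError, ValueError):
            raise ValidationError(f"{name} must be a number, got {value!r}") from None
        if not np.isfinite(value) or value <= 0:
            raise ValidationError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class CableGeometry:
    """Physical constants of the cable and the derived cable constants.

    ``lambda_um``/``tau_ms`` belong to the electrical cable; ``lambda_c_um``/
    ``tau_c_ms`` to the calcium (chemical) cable after the rapid-buffer
    reduction.  Build instances with :func:`derive_constants`.
    """

    diameter_um: float
    Cm_uF_cm2: float
    Ri_ohm_cm: float
    Rm_ohm_cm2: float
    EL_mV: float
    Er_mV: float
    Vmax_mV: float
    lambda_um: float
    tau_ms: float
    lambda_c_um: float
    tau_c_ms: float

    @property
    def gL_S_cm2(self) -> float:
        """Leak conductance, the reciprocal of the membrane resistivity."""
        return 1.0 / self.Rm_ohm_cm2

    @property
    def cross_section_um2(self) -> float:
        return np.pi * self.diameter_um**2 / 4.0

    @property
    def input_resistance_Mohm(self) -> float:
        """Input resistance of the semi-infinite cable at the origin."""
        rm = self.Rm_ohm_cm2 * _OHM_CM2_TO_OHM_UM2
        return rm / (np.pi * self.diameter_um * self.lambda_um) / 1e6


def derive_constants(
    diameter_um: float = 1.0,
    Cm_uF_cm2: float = 1.0,
    Ri_ohm_cm: float = 100.0,
    Rm_ohm_cm2: float = 1.0e4,
    EL_mV: float = -65.0,
    Er_mV: float = -65.0,
    Vmax_mV: float = 100.0,
    calcium: "CalciumSystem | None" = None,
) -> CableGeometry:
    """Validate physical constants and derive the cable constants.

    ``lambda = sqrt(d R_m / (4 R_i))`` and ``tau = R_m C_m``.  When a
    :class:`~ioniccable.calcium_plasticity.CalciumSystem` is supplied its
    rapid-buffer reduction provides ``lambda_c``/``tau_c``; otherwise they are
    left as placeholders (1 um, 1 ms) and should not be relied upon.
    """
    _require_positive(
        diameter_um=diameter_um,
        Cm_uF_cm2=Cm_uF_cm2,
        Ri_ohm_cm=Ri_ohm_cm,
        Rm_ohm_cm2=Rm_ohm_cm2,
        Vmax_mV=Vmax_mV,
    )
    rm_um = Rm_ohm_cm2 * _OHM_CM2_TO_OHM_UM2
    ri_um = Ri_ohm_cm * _OHM_CM_TO_OHM_UM
    lambda_um = float(np.sqrt(diameter_um * rm_um / (4.0 * ri_um)))
    tau_ms = float(Rm_ohm_cm2 * Cm_uF_cm2 * 1.0e-3)  # Ohm cm^2 * uF/cm^2 = 1e-3 ms

    lambda_c_um, tau_c_ms = 1.0, 1.0
    if calcium is not None:
        from .calcium_plasticity import rba_reduce

        rba = rba_reduce(calcium, diameter_um=diameter_um)
        lambda_c_um, tau_c_ms = rba.lambda_c_um, rba.tau_c_ms

    return CableGeometry(
        diameter_um=diameter_um,
        Cm_uF_cm2=Cm_uF_cm2,
        Ri_ohm_cm=Ri_ohm_cm,
        Rm_ohm_cm2=Rm_ohm_cm2,
        EL_mV=EL_mV,
        Er_mV=Er_mV,
        Vmax_mV=Vmax_mV,
        lambda_um=lambda_um,
        tau_ms=tau_ms,
        lambda_c_um=lambda_c_um,
        tau_c_ms=tau_c_ms,
    )


@dataclass(frozen=True)
class DimensionlessFrame:
    """Space/time scales of one subsystem ('electrical' or 'chemical')."""

    subsystem: str
    space_um: float
    time_ms: float

    def __post_init__(self) -> None:
        _require_positive(space_um=self.space_um, time_ms=self.time_ms)
        if self.subsystem not in ("electrical", "chemical"):
            raise ValidationError(
                f"subsystem must be 'electrical' or 'chemical', got {self.subsystem!r}"
            )

    @classmethod
    def electrical(cls, geometry: CableGeometry) -> "DimensionlessFrame":
        return cls("electrical", geometry.lambda_um, geometry.tau_ms)

    @classmethod
    def chemical(cls, geometry: CableGeometry) -> "DimensionlessFrame":
        return cls("chemical", geometry.lambda_c_um, geometry.tau_c_ms)

    def to_dimensionless(self, x_um, t_ms):
        x_um = np.asarray(x_um, dtype=float)
        if np.any(x_um < 0):
            raise ValidationError("position must be >= 0 on the semi-infinite cable")
        return x_um / self.space_um, np.asarray(t_ms, dtype=float) / self.time_ms

    def to_physical(self, X, T):
        return np.asarray(X, dtype=float) * self.space_um, np.asarray(T, dtype=float) * self.time_ms


def to_electrotonic(x_um, t_ms, frame: DimensionlessFrame):
    """Map physical (um, ms) to electrotonic (X, T) = (x/lambda, t/tau)."""
    if frame.subsystem != "electrical":
        raise ValidationError("to_electrotonic requires the electrical frame")
    return frame.to_dimensionless(x_um, t_ms)


def to_chemicotonic(x_um, t_ms, frame: DimensionlessFrame):
    """Map physical (um, ms) to chemicotonic (X_c, T_c) = (x/lambda_c, t/tau_c)."""
    if frame.subsystem != "chemical":
        raise ValidationError("to_chemicotonic requires the chemical frame")
    return frame.to_dimensionless(x_um, t_ms)


@dataclass(frozen=True)
class BoundaryWaveform:
    """Voltage clamp applied at the cable origin, in mV above rest.

    The default kind ``"ap_adp"`` is a back-propagating action potential
    surrogate: a narrow sech^2 spike of height ``amplitude_mV`` followed by a
    slow after-depolarizing (ADP) tail, a difference of exponentials gated
    from the spike offset.  The waveform is exactly zero before ``onset_ms``,
    continuous at onset, bounded by ``amplitude_mV + adp_amplitude_mV`` and
    decays to zero.

    ``kind="custom"`` interpolates user samples (``custom_t_ms``,
    ``custom_mV``) and is zero outside their span.
    """

    kind: str = "ap_adp"
    amplitude_mV: float = 100.0
    width_ms: float = 1.0
    adp_amplitude_mV: float = 25.0
    adp_tau_ms: float = 35.0
    adp_rise_ms: float = 3.0
    ahp_amplitude_mV: float = 0.0  # fast after-hyperpolarization depth (>= 0)
    ahp_tau_ms: float = 8.0
    ahp_rise_ms: float = 1.0
    onset_ms: float = 0.0
    custom_t_ms: tuple = field(default=())
    custom_mV: tuple = field(default=())

    def __post_init__(self) -> None:
        if self.kind not in ("ap_adp", "custom"):
            raise ValidationError(f"unknown waveform kind {self.kind!r}")
        if self.kind == "ap_adp":
            _require_positive(width_ms=self.width_ms, amplitude_mV=self.amplitude_mV)
            if self.adp_amplitude_mV < 0:
                raise ValidationError("adp_amplitude_mV must be >= 0")

    # -- shape pieces ------------------------------------------------------
    @property
    def _spike_peak_ms(self) -> float:
        # peak sits 2.5 widths after onset so the masked onset step is tiny
        return 2.5 * self.width_ms

    @property
    def _spike_offset_ms(self) -> float:
        return 2.0 * self._spike_peak_ms

    def _spike(self, s: np.ndarray) -> np.ndarray:
        z = np.clip((s - self._spike_peak_ms) / self.width_ms, -40.0, 40.0)
        raw = np.cosh(z) ** -2.0
        floor = np.cosh(self._spike_peak_ms / self.width_ms) ** -2.0
        out = self.amplitude_mV * np.clip(raw - floor, 0.0, None) / (1.0 - floor)
        return np.where(s >= 0.0, out, 0.0)

    @staticmethod
    def _gated_biexp(u: np.ndarray, amplitude: float, td: float, tr: float) -> np.ndarray:
        """Double exponential gated at u = 0, normalized to peak `amplitude`."""
        if amplitude == 0.0:
            return np.zeros_like(u)
        tpk = td * tr / (td - tr) * np.log(td / tr) if td != tr else tr
        norm = np.exp(-tpk / td) - np.exp(-tpk / tr)
        uu = np.clip(u, 0.0, None)
        shape = np.where(u >= 0.0, np.exp(-uu / td) - np.exp(-uu / tr), 0.0)
        return amplitude * shape / norm

    def _adp(self, s: np.ndarray) -> np.ndarray:
        # fast AHP gated at the spike offset, slower ADP gated after the AHP
        u = s - self._spike_offset_ms
        out = -self._gated_biexp(u, self.ahp_amplitude_mV, self.ahp_tau_ms, self.ahp_rise_ms)
        out = out + self._gated_biexp(u, self.adp_amplitude_mV, self.adp_tau_ms, self.adp_rise_ms)
        return out

    def __call__(self, t_ms) -> np.ndarray:
        """Clamp voltage (mV above rest) at time ``t_ms`` (scalar or array)."""
        t = np.asarray(t_ms, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if self.kind == "custom":
            out = np.interp(t, self.custom_t_ms, self.custom_mV, left=0.0, right=0.0)
        else:
            s = t - self.onset_ms
            out = self._spike(s) + self._adp(s)
        return float(out[0]) if scalar else out

    def shifted(self, onset_ms: float) -> "BoundaryWaveform":
        return replace(self, onset_ms=onset_ms)


@dataclass(frozen=True)
class StimulusEvents:
    """Times of boundary action potentials and presynaptic (NMDA) events."""

    post_onsets_ms: tuple = ()
    pre_times_ms: tuple = ()

    @classmethod
    def pairing(cls, t_post_ms: float, delta_t_ms: float) -> "StimulusEvents":
        """One pre/post pairing; delta_t = t_post - t_pre (>0: pre first)."""
        return cls(post_onsets_ms=(t_post_ms,), pre_times_ms=(t_post_ms - delta_t_ms,))


@dataclass
class Model:
    """Everything one simulation needs, assembled by io_fixtures.build_model.

    Fields are duck-typed to keep module dependencies one-directional:
    ``channels`` maps name -> ChannelSpec (with hotspots attached), ``nmda``
    is an NMDASpec or None, ``calcium`` a CalciumSystem, ``rule`` a
    PlasticityRule.  ``dt_ms`` is the solver grid step (default 0.01 * tau,
    i.e. dimensionless dT = 0.01).
    """

    geometry: CableGeometry
    waveform: BoundaryWaveform
    channels: dict
    nmda: object = None
    calcium: object = None
    rule: object = None
    dt_ms: float = 0.1
    config: dict = field(default_factory=dict)


def ap_clamp(waveform: BoundaryWaveform, t_ms):
    """Evaluate the boundary clamp waveform (mV above rest) at time ``t_ms``."""
    return waveform(t_ms)


def clamp_train(waveform: BoundaryWaveform, onsets_ms, t_ms) -> np.ndarray:
    """Superpose one clamp waveform per onset time (a spike train at x=0).

    On a uniform grid with grid-aligned onsets the single-onset samples are
    shifted and added, which keeps long high-frequency trains cheap; other
    inputs fall back to direct evaluation.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    n = len(t)
    if n > 1:
        dt = t[1] - t[0]
        uniform = np.allclose(np.diff(t), dt, rtol=0, atol=1e-9)
        shifts = np.asarray(onsets_ms, dtype=float) / dt if dt > 0 else None
        aligned = uniform and np.allclose(shifts, np.round(shifts), atol=1e-6)
        if aligned and len(out) and t[0] == 0.0:
            base = waveform.shifted(0.0)(t)
            for s in np.round(shifts).astype(int):
                if s >= n:
                    continue
                if s >= 0:
                    out[s:] += base[: n - s]
                else:
                    out += base[-s:][:n]
            return out
    for onset in onsets_ms:
        out += waveform.shifted(onset)(t)
    return out
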
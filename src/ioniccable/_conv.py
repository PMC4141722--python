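"""Product-trapezoidal Volterra convolution with panel-integrated kernels.

The solver repeatedly evaluates convolutions ``(K * f)(t_n) = int_0^{t_n}
K(t_n - s) f(s) ds`` whose kernels have an Abel-type ``1/sqrt(t)``
singularity at the origin (the cable Green's function evaluated at the source
point).  The product rule used here integrates the kernel *exactly* over each
panel (the square-root substitution ``t = v^2`` removes the singularity) and
interpolates the smooth density ``f`` linearly, so the endpoint panel needs no
special casing and the global error is second order in the step.

Kernels decay like ``exp(-t/t_decay)``; samples are truncated once the
remaining panel mass falls below a relative tolerance, which keeps the
kernels short and the FFT convolutions cheap.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.signal import oaconvolve

__all__ = ["panel_kernel", "volterra_convolve"]

_GAUSS_N = 10
_GN, _GW = leggauss(_GAUSS_N)


def _gauss_panels(fun, lo: np.ndarray, hi: np.ndarray, weight=None):
    """Vectorized fixed-order Gauss quadrature of ``fun`` (optionally times
    ``weight``) over many panels [lo_i, hi_i]."""
    mid = 0.5 * (hi + lo)
    half = 0.5 * (hi - lo)
    nodes = mid[:, None] + half[:, None] * _GN[None, :]
    vals = fun(nodes)
    if weight is not None:
        vals = vals * weight(nodes)
    return half * (vals @ _GW)


def panel_kernel(
    kern,
    dt: float,
    n_max: int,
    n_sqrt_panels: int = 48,
    decay_ms: float | None = None,
    tol: float = 1e-13,
):
    """Panel moments (K0, K1) of a Volterra kernel on a uniform grid.

    K0[j] = int_{j dt}^{(j+1) dt} kern(u) du
    K1[j] = int_{j dt}^{(j+1) dt} kern(u) * ((j+1) dt - u)/dt du

    The first ``n_sqrt_panels`` panels are integrated in the variable
    ``v = sqrt(u)`` so integrable ``1/sqrt(u)`` singularities at the origin
    are handled exactly.  If ``decay_ms`` is given the kernel tail is
    truncated once ``exp(-t/decay_ms) < tol``.
    """
    if decay_ms is not None:
        n_cut = int(np.ceil(-decay_ms * np.log(tol) / dt)) + 2
        n_max = min(n_max, n_cut)
    n_max = max(n_max, 1)
    edges = dt * np.arange(n_max + 1)

    ns = min(n_sqrt_panels, n_max)
    K0 = np.empty(n_max)
    K1 = np.empty(n_max)

    if ns > 0:
        lo, hi = np.sqrt(edges[:ns]), np.sqrt(edges[1 : ns + 1])
        f_v = lambda v: 2.0 * v * kern(v * v)
        K0[:ns] = _gauss_panels(f_v, lo, hi)
        upper = edges[1 : ns + 1]
        K1[:ns] = _gauss_panels(f_v, lo, hi, weight=lambda v: (upper[:, None] - v * v) / dt)
    if n_max > ns:
        lo, hi = edges[ns:-1], edges[ns + 1 :]
        K0[ns:] = _gauss_panels(kern, lo, hi)
        upper = edges[ns + 1 :]
        K1[ns:] = _gauss_panels(kern, lo, hi, weight=lambda u: (upper[:, None] - u) / dt)
    return K0, K1


def volterra_convolve(K0: np.ndarray, K1: np.ndarray, f: np.ndarray, n_out: int) -> np.ndarray:
    """Evaluate (K * f)(t_n) for n = 0..n_out-1 by the product trapezoid rule.

    Over source panel i, with kernel panel j = n-1-i, the linear interpolant
    of f contributes f[i+1]*K1[j] + f[i]*(K0[j]-K1[j]).
    """
    if n_out <= 0:
        return np.zeros(0)
    out = np.zeros(n_out)
    if len(f) < 2:
        return out
    a = K0 - K1
    # sum_i f[i] * a[n-1-i]  -> conv(f, a) at index n-1
    ca = oaconvolve(f[:-1], a)[: n_out - 1]
    cb = oaconvolve(f[1:], K1)[: n_out - 1]
    m = min(n_out - 1, len(ca))
    out[1 : 1 + m] = ca[:m] + cb[:m]
    return out
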
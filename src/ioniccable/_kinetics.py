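"""First-order gating recurrences (Rush-Larsen scan), numba-accelerated.

The exponential update x[n+1] = xinf[n] + (x[n] - xinf[n]) * exp(-dt/tau[n])
is an inherently sequential scan; numba compiles it to native speed.  A pure
python fallback keeps the package importable without numba.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _rl_scan_core(xinf: np.ndarray, efac: np.ndarray, x0: float) -> np.ndarray:
    n = xinf.shape[0]
    out = np.empty(n, dtype=np.float64)
    x = x0
    out[0] = x
    for i in range(n - 1):
        x = xinf[i] + (x - xinf[i]) * efac[i]
        out[i + 1] = x
    return out


def rush_larsen_scan(xinf: np.ndarray, efac: np.ndarray, x0: float) -> np.ndarray:
    """Run the exponential-integrator scan; returns x on the same grid.

    ``xinf[i]`` and ``efac[i] = exp(-dt/tau[i])`` are held constant on the
    step ``[t_i, t_{i+1})``.
    """
    xinf = np.ascontiguousarray(xinf, dtype=np.float64)
    efac = np.ascontiguousarray(efac, dtype=np.float64)
    return _rl_scan_core(xinf, efac, float(x0))
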
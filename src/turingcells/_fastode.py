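"""Compiled right-hand-side kernels and the segment integrator.

The model is integrated with LSODA (scipy.integrate.odeint) driving a
numba-compiled kernel; the large-amplitude glycolytic spikes force tens of
thousands of steps per 1000 s of model time, so the per-call overhead of
the callback dominates total runtime.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.integrate import odeint

from .model import ArrayTopology, KineticParams


@njit(cache=True)
def _f(z, lap, pulse, nu, si, sM, Mn, n, L, phi, ks, qk, k):
    N = z.shape[0] // 2
    out = np.empty(2 * N)
    for i in range(N):
        x = z[i]
        y = z[N + i]
        yn = y ** n
        h = yn / (Mn + yn)
        a = 1.0 + x
        b2 = (1.0 + y) ** 2
        g = x * a * b2 / (L + a * a * b2)
        cx = 0.0
        cy = 0.0
        for j in range(N):
            cx += lap[i, j] * z[j]
            cy += lap[i, j] * z[N + j]
        out[i] = nu + si * h - sM * g - qk * cx + pulse[i]
        out[N + i] = phi * sM * g - ks * y - phi * si * h - k * cy
    return out


@njit(cache=True)
def _jac(z, lap, nu, si, sM, Mn, n, L, phi, ks, qk, k):
    N = z.shape[0] // 2
    J = np.zeros((2 * N, 2 * N))
    for i in range(N):
        x = z[i]
        y = z[N + i]
        yn1 = y ** (n - 1)
        den = Mn + y * yn1
        hy = n * Mn * yn1 / (den * den)
        a = 1.0 + x
        b = 1.0 + y
        b2 = b * b
        D = L + a * a * b2
        gx = b2 * ((1.0 + 2.0 * x) * D - 2.0 * x * a * a * b2) / (D * D)
        gy = 2.0 * x * a * b * L / (D * D)
        J[i, i] = -sM * gx
        J[i, N + i] = si * hy - sM * gy
        J[N + i, i] = phi * sM * gx
        J[N + i, N + i] = phi * sM * gy - ks - phi * si * hy
        for j in range(N):
            J[i, j] -= qk * lap[i, j]
            J[N + i, N + j] -= k * lap[i, j]
    return J


def _args(params: KineticParams, topology: ArrayTopology):
    p = params
    return (np.ascontiguousarray(topology.laplacian), p.nu, p.sigma_inh, p.sigma_M,
            p.M ** p.n, p.n, p.L, p.phi, p.k_s, p.q * p.k_ADP, p.k_ADP)


def integrate_segment(z0: np.ndarray, t_grid: np.ndarray,
                      params: KineticParams, topology: ArrayTopology,
                      pulse_vec: np.ndarray, rtol: float, atol: float) -> np.ndarray:
    """LSODA integration on a fixed sample grid with constant pulse vector."""
    lap, *rest = _args(params, topology)
    pulse = np.ascontiguousarray(pulse_vec, dtype=float)

    def f(z, t):
        return _f(z, lap, pulse, *rest)

    def jac(z, t):
        return _jac(z, lap, *rest)

    out, info = odeint(f, z0, t_grid, Dfun=jac, rtol=rtol, atol=atol,
                       mxstep=200000, full_output=True)
    if info["message"] != "Integration successful.":
        tlast = info["tcur"][-1] if len(info.get("tcur", [])) else t_grid[0]
        raise RuntimeError(f"integrator failed near t = {tlast:.3f} s: {info['message']}")
    return out
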
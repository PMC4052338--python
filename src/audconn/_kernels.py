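"""Hot propagation loops for the bilinear state equation.

The inputs are piecewise constant on the micro-time grid, so the bilinear
system ``dz/dt = (A + sum_j u_j B_j) z + C u`` is linear time-invariant
within each step.  The caller precomputes, for every distinct input
combination, the exact one-step transition ``z -> E z + d`` (and, for the
sensitivity variant, its derivatives with respect to every free
parameter); these loops only chain the steps.  Compiled with numba when
available, with a plain-numpy fallback.
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(cache=True)
def propagate(E: np.ndarray, d: np.ndarray, idx: np.ndarray,
              z0: np.ndarray) -> np.ndarray:
    """Chain one-step transitions; returns states at the step *starts*.

    ``Z[t]`` is the state at time ``t*dt`` (so ``Z[0] == z0``); the input
    active over ``[t*dt, (t+1)*dt)`` selects transition ``idx[t]``.
    """
    T = idx.shape[0]
    n = z0.shape[0]
    Z = np.empty((T, n))
    z = z0.copy()
    for t in range(T):
        Z[t] = z
        k = idx[t]
        zn = np.zeros(n)
        for i in range(n):
            acc = d[k, i]
            for j in range(n):
                acc += E[k, i, j] * z[j]
            zn[i] = acc
        z = zn
    return Z


@njit(cache=True, fastmath=True)
def propagate_sens(E: np.ndarray, d: np.ndarray, dE: np.ndarray,
                   dd: np.ndarray, idx: np.ndarray,
                   z0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """As `propagate`, also chaining first-order parameter sensitivities.

    ``dE[k, p]``/``dd[k, p]`` are the derivatives of the transition for
    input-combination ``k`` with respect to parameter ``p``.  Returns one
    array ``ZS`` with ``ZS[t, :n]`` the state and ``ZS[t, n + p*n + i]``
    its sensitivity ``dz_i[t]/dtheta_p`` (zero at t=0), packed together so
    the HRF convolution can run over all columns at once.
    """
    T = idx.shape[0]
    n = z0.shape[0]
    P = dE.shape[1]
    ZS = np.empty((T, (1 + P) * n))
    z = z0.copy()
    s = np.zeros((P, n))
    for t in range(T):
        for i in range(n):
            ZS[t, i] = z[i]
        for p in range(P):
            for i in range(n):
                ZS[t, n + p * n + i] = s[p, i]
        k = idx[t]
        zn = np.zeros(n)
        for i in range(n):
            acc = d[k, i]
            for j in range(n):
                acc += E[k, i, j] * z[j]
            zn[i] = acc
        sn = np.zeros((P, n))
        for p in range(P):
            for i in range(n):
                acc = dd[k, p, i]
                for j in range(n):
                    acc += E[k, i, j] * s[p, j] + dE[k, p, i, j] * z[j]
                sn[p, i] = acc
        z = zn
        s = sn
    return ZS


@njit(cache=True, fastmath=True)
def conv_downsample(z: np.ndarray, kdt: np.ndarray, stride: int) -> np.ndarray:
    """Causal convolution with ``kdt`` sampled only at every ``stride``-th point."""
    T, C = z.shape
    kl = kdt.shape[0]
    V = T // stride
    y = np.zeros((V, C))
    for v in range(V):
        tmax = v * stride
        lim = kl if kl <= tmax + 1 else tmax + 1
        for tau in range(lim):
            w = kdt[tau]
            if w == 0.0:
                continue
            t = tmax - tau
            for c in range(C):
                y[v, c] += w * z[t, c]
    return y
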
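"""Compiled inner loops for simulation and dynamic time warping.

These kernels mirror the reference implementations in :mod:`fuzzysig.logic`
and :mod:`fuzzysig.objective` exactly (same update order, same tie-breaks);
the test suite asserts agreement.  If ``numba`` is unavailable the module
still imports and callers fall back to the reference path.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _step(x, fx, node_ptr, clause_ptr, parents, signs, clamp_mask, clamp_vals):
    m = x.shape[0]
    new = np.empty(m)
    for j in range(m):
        if clamp_mask[j]:
            new[j] = clamp_vals[j]
            continue
        c0, c1 = node_ptr[j], node_ptr[j + 1]
        if c0 == c1:
            new[j] = x[j]
            continue
        best = 0.0
        for c in range(c0, c1):
            v = 1.0
            for t in range(clause_ptr[c], clause_ptr[c + 1]):
                i = parents[t]
                e = fx[i] if signs[t] else 1.0 - fx[i]
                if e < v:
                    v = e
            if v > best:
                best = v
        new[j] = best
    return new


@njit(cache=True)
def _transfer(x, p, h, boolean):
    if boolean:
        return x.copy()
    m = x.shape[0]
    out = np.empty(m)
    hp = h ** p
    for i in range(m):
        xp = x[i] ** p
        out[i] = xp / (xp + hp)
    return out


@njit(cache=True)
def sim_steady_state(
    x0, node_ptr, clause_ptr, parents, signs, clamp_mask, clamp_vals,
    p, h, boolean, eps, max_iter,
):
    """Iterate synchronously from ``x0`` until the state settles.

    Returns ``(state, converged, iterations)``.
    """
    x = x0.copy()
    for it in range(1, max_iter + 1):
        fx = _transfer(x, p, h, boolean)
        nxt = _step(x, fx, node_ptr, clause_ptr, parents, signs, clamp_mask, clamp_vals)
        d = 0.0
        for i in range(x.shape[0]):
            a = abs(nxt[i] - x[i])
            if a > d:
                d = a
        x = nxt
        if d < eps:
            return x, True, it
    return x, False, max_iter


@njit(cache=True)
def sim_timeseries(
    x0, node_ptr, clause_ptr, parents, signs, clamp_mask, clamp_vals,
    p, h, boolean, n_points,
):
    """Synchronous trajectory of length ``n_points`` starting at ``x0``."""
    m = x0.shape[0]
    out = np.empty((n_points, m))
    x = x0.copy()
    out[0] = x
    for t in range(1, n_points):
        fx = _transfer(x, p, h, boolean)
        x = _step(x, fx, node_ptr, clause_ptr, parents, signs, clamp_mask, clamp_vals)
        out[t] = x
    return out


@njit(cache=True)
def dtw_loss(y, z):
    """Path-length-normalized DTW loss with squared local cost.

    Minimizes total cost over monotone, continuous, endpoint-pinned warping
    paths; among minimum-cost paths the shortest is used for the 1/S
    normalization (matching :func:`fuzzysig.objective.dtw_align`).
    """
    ny = y.shape[0]
    nz = z.shape[0]
    D = np.empty((ny, nz))
    L = np.empty((ny, nz), dtype=np.int64)
    D[0, 0] = (y[0] - z[0]) ** 2
    L[0, 0] = 1
    for j in range(1, nz):
        D[0, j] = D[0, j - 1] + (y[0] - z[j]) ** 2
        L[0, j] = j + 1
    for i in range(1, ny):
        D[i, 0] = D[i - 1, 0] + (y[i] - z[0]) ** 2
        L[i, 0] = i + 1
    for i in range(1, ny):
        for j in range(1, nz):
            c = (y[i] - z[j]) ** 2
            best = D[i - 1, j - 1]
            blen = L[i - 1, j - 1]
            if D[i - 1, j] < best or (D[i - 1, j] == best and L[i - 1, j] < blen):
                best = D[i - 1, j]
                blen = L[i - 1, j]
            if D[i, j - 1] < best or (D[i, j - 1] == best and L[i, j - 1] < blen):
                best = D[i, j - 1]
                blen = L[i, j - 1]
            D[i, j] = best + c
            L[i, j] = blen + 1
    return D[ny - 1, nz - 1] / L[ny - 1, nz - 1]
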
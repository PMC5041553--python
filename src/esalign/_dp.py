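"""Compiled kernels for the dynamic-programming curve matching.

The matching graph has one vertex per pair of grid indices (i, j); edges
step forward by 1..w in each index, so the graph is a DAG and a single
topological-order pass finds the global optimum.  Edge weights are the
elastic matching cost of the corresponding parameter segments, evaluated
by trapezoidal quadrature on the merged grid points inside the segment.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

INF = 1e300


@njit(cache=True)
def edge_cost(Q1, Q2, T, a, b, i, j):  # pragma: no cover - exercised via wrappers
    """∫ₐⁱ ‖q₁(t) − √γ̇ q₂(γ(t))‖² dt for the linear γ: [Tₐ,Tᵢ] → [T_b,T_j].

    Quadrature nodes are the grid points T[a..i]; q₂ is evaluated at γ(t)
    by linear interpolation between its grid columns.
    """
    d = Q1.shape[0]
    gdot = (T[j] - T[b]) / (T[i] - T[a])
    sg = math.sqrt(gdot)
    total = 0.0
    prev = 0.0
    p = b
    for m in range(a, i + 1):
        s = T[b] + gdot * (T[m] - T[a])
        # locate s within T[p] .. T[p+1], p in [b, j-1]
        while p < j - 1 and T[p + 1] < s:
            p += 1
        frac = (s - T[p]) / (T[p + 1] - T[p])
        if frac < 0.0:
            frac = 0.0
        elif frac > 1.0:
            frac = 1.0
        val = 0.0
        for r in range(d):
            q2v = Q2[r, p] + frac * (Q2[r, p + 1] - Q2[r, p])
            diff = Q1[r, m] - sg * q2v
            val += diff * diff
        if m > a:
            total += 0.5 * (val + prev) * (T[m] - T[m - 1])
        prev = val
    return total


@njit(cache=True)
def dp_match(Q1, Q2, T, w):  # pragma: no cover - exercised via wrappers
    """Minimum-cost monotone path from (0, 0) to (n−1, n−1).

    Returns (dist, pred_i, pred_j): the cost-to-reach matrix and the
    predecessor indices for path reconstruction.
    """
    n = T.shape[0]
    dist = np.full((n, n), INF)
    pred_i = np.full((n, n), -1, dtype=np.int64)
    pred_j = np.full((n, n), -1, dtype=np.int64)
    dist[0, 0] = 0.0
    for i in range(1, n):
        for j in range(1, n):
            best = INF
            bi = -1
            bj = -1
            di_max = w if w < i else i
            dj_max = w if w < j else j
            for di in range(1, di_max + 1):
                a = i - di
                for dj in range(1, dj_max + 1):
                    b = j - dj
                    if dist[a, b] >= INF:
                        continue
                    v = dist[a, b] + edge_cost(Q1, Q2, T, a, b, i, j)
                    if v < best:
                        best = v
                        bi = a
                        bj = b
            dist[i, j] = best
            pred_i[i, j] = bi
            pred_j[i, j] = bj
    return dist, pred_i, pred_j
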
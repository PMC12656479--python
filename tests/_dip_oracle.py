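"""Exact brute-force dip statistic via linear programming (tiny n only).

A unimodal CDF G is represented piecewise-linearly on nodes: a far-away left
endpoint pinned to 0, the distinct sorted data values, a far-away right
endpoint pinned to 1.  Unimodality = slopes nondecreasing left of the mode
and nonincreasing right of it.  Mode cases enumerated exhaustively: at a
node (where an atom — a jump g^- <= g^+ — is allowed, as for a distribution
with a point mass at its mode) or inside a segment (then that segment's
average slope must dominate one of its neighbours; both sub-cases tried).
sup|F_n - G| attains its value at data points, at both one-sided limits of
the empirical CDF, so minimizing it is a linear program per mode case.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _solve(pos, data_idx, n, mode_node=None, mode_seg=None, seg_side=None):
    m_nodes = len(pos)
    extra = 1 if mode_node is not None else 0
    nv = m_nodes + extra + 1
    tid = nv - 1
    gplus = m_nodes
    a_ub, b_ub = [], []

    def le(coeffs, rhs=0.0):
        row = np.zeros(nv)
        for k, v in coeffs.items():
            row[k] += v
        a_ub.append(row)
        b_ub.append(rhs)

    def node_val(i, side):
        if mode_node is not None and i == mode_node and side == "right":
            return gplus
        return i

    for r, i in enumerate(data_idx, start=1):
        vl, vr = node_val(i, "left"), node_val(i, "right")
        le({vl: 1, tid: -1}, (r - 1) / n)
        le({vl: -1, tid: -1}, -(r - 1) / n)
        le({vr: 1, tid: -1}, r / n)
        le({vr: -1, tid: -1}, -r / n)

    for i in range(m_nodes - 1):
        le({node_val(i, "right"): 1, node_val(i + 1, "left"): -1})
    if mode_node is not None:
        le({mode_node: 1, gplus: -1})

    dx = np.diff(pos)

    def slope(j):
        a, b = node_val(j, "right"), node_val(j + 1, "left")
        return {b: 1.0 / dx[j], a: -1.0 / dx[j]}

    def le_slopes(lo_seg, hi_seg):
        # slope(lo_seg) - slope(hi_seg) <= 0
        c: dict[int, float] = {}
        for k, v in slope(lo_seg).items():
            c[k] = c.get(k, 0) + v
        for k, v in slope(hi_seg).items():
            c[k] = c.get(k, 0) - v
        le(c)

    nseg = m_nodes - 1
    if mode_node is not None:
        for j in range(0, mode_node - 1):
            le_slopes(j, j + 1)          # convex left of the mode
        for j in range(mode_node, nseg - 1):
            le_slopes(j + 1, j)          # concave right of the mode
    else:
        j = mode_seg
        for k in range(0, j - 1):
            le_slopes(k, k + 1)
        for k in range(j + 1, nseg - 1):
            le_slopes(k + 1, k)
        nb = j - 1 if seg_side == "L" else j + 1
        if 0 <= nb <= nseg - 1:
            le_slopes(nb, j)             # mode segment dominates a neighbour

    a_eq = np.zeros((2, nv))
    a_eq[0, 0] = 1.0
    a_eq[1, m_nodes - 1] = 1.0
    c = np.zeros(nv)
    c[tid] = 1.0
    bounds = [(None, None)] * nv
    bounds[tid] = (0, None)
    res = linprog(c, A_ub=np.array(a_ub), b_ub=np.array(b_ub),
                  A_eq=a_eq, b_eq=np.array([0.0, 1.0]),
                  bounds=bounds, method="highs")
    return res.fun if res.success else np.inf


def dip_bruteforce(sample) -> float:
    x = np.sort(np.asarray(sample, float))
    n = len(x)
    span = x[-1] - x[0] if x[-1] > x[0] else 1.0
    big = 1e7 * span
    pos = [x[0] - big]
    data_idx = []
    for v in x:
        if pos[-1] != v:
            pos.append(v)
        data_idx.append(len(pos) - 1)
    pos.append(x[-1] + big)
    pos = np.array(pos)
    best = np.inf
    for k in range(1, len(pos) - 1):
        best = min(best, _solve(pos, data_idx, n, mode_node=k))
    for j in range(len(pos) - 1):
        for side in ("L", "R"):
            best = min(best, _solve(pos, data_idx, n, mode_seg=j, seg_side=side))
    return float(best)
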
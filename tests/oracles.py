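"""Independent brute-force re-implementations used as test oracles.

Everything here is deliberately written in the most naive correct way
(double loops, textbook formulas) and kept free of any import from the
module it checks beyond plain data containers.
"""

from __future__ import annotations

import math

import numpy as np


def gini_pairwise(values) -> float:
    """Gini coefficient by the mean-absolute-pairwise-difference formula."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    mu = v.mean()
    s = 0.0
    for i in range(n):
        for j in range(n):
            s += abs(v[i] - v[j])
    return s / (2 * n * n * mu)


def brute_variogram(points, values, direction, lag_width, n_lags, angular_tol, azimuth=0.0):
    """Double-loop Matheron estimator with explicit pair accounting."""
    pts = np.asarray(points, dtype=float)
    v = np.asarray(values, dtype=float)
    a = math.radians(azimuth)
    sums = np.zeros(n_lags)
    counts = np.zeros(n_lags, dtype=int)
    n = len(pts)
    for i in range(n):
        for j in range(i + 1, n):
            dx = pts[j, 0] - pts[i, 0]
            dy = pts[j, 1] - pts[i, 1]
            ha = dx * math.sin(a) + dy * math.cos(a)
            hx = dx * math.cos(a) - dy * math.sin(a)
            r = math.hypot(ha, hx)
            if r == 0:
                continue
            if direction == "along":
                ang = math.degrees(math.atan2(abs(hx), abs(ha)))
            else:
                ang = math.degrees(math.atan2(abs(ha), abs(hx)))
            if ang > angular_tol:
                continue
            k = int(r // lag_width)
            if k < n_lags:
                sums[k] += (v[i] - v[j]) ** 2
                counts[k] += 1
    gamma = np.full(n_lags, np.nan)
    nz = counts > 0
    gamma[nz] = 0.5 * sums[nz] / counts[nz]
    return gamma, counts


def patch_assignments(points, values, d_along, d_across, azimuth=0.0):
    """Step-by-step greedy patch recursion; returns patch index per sample
    (-1 for absences), following decreasing-biomass processing order."""
    pts = np.asarray(points, dtype=float)
    v = np.asarray(values, dtype=float)
    a = math.radians(azimuth)
    along = pts[:, 0] * math.sin(a) + pts[:, 1] * math.cos(a)
    across = pts[:, 0] * math.cos(a) - pts[:, 1] * math.sin(a)
    idx = [int(i) for i in np.argsort(-v, kind="stable") if v[i] > 0]
    patches = []  # dicts: cg_along, cg_across, weight
    assign = np.full(len(v), -1, dtype=int)
    for i in idx:
        best_k, best_d = -1, float("inf")
        for k, p in enumerate(patches):
            d = math.sqrt(
                ((along[i] - p["cg_along"]) / d_along) ** 2
                + ((across[i] - p["cg_across"]) / d_across) ** 2
            )
            if d < best_d:  # strict: ties stay with the earlier patch
                best_k, best_d = k, d
        if best_k >= 0 and best_d <= 1.0:
            p = patches[best_k]
            w = p["weight"] + v[i]
            p["cg_along"] = (p["cg_along"] * p["weight"] + along[i] * v[i]) / w
            p["cg_across"] = (p["cg_across"] * p["weight"] + across[i] * v[i]) / w
            p["weight"] = w
            assign[i] = best_k
        else:
            patches.append({"cg_along": along[i], "cg_across": across[i], "weight": v[i]})
            assign[i] = len(patches) - 1
    return assign


def ordinary_kriging_dense(points, values, gamma_fn, node):
    """Textbook global-neighbourhood ordinary kriging in variogram form.

    Solves [[Gamma, 1], [1, 0]] [lambda, mu] = [gamma0, 1] and returns
    (prediction, kriging variance).  ``gamma_fn(dx, dy)`` evaluates the
    variogram for separation vectors.
    """
    pts = np.asarray(points, dtype=float)
    v = np.asarray(values, dtype=float)
    n = len(pts)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            A[i, j] = gamma_fn(pts[j, 0] - pts[i, 0], pts[j, 1] - pts[i, 1])
        A[i, n] = 1.0
        A[n, i] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        b[i] = gamma_fn(node[0] - pts[i, 0], node[1] - pts[i, 1])
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    lam, mu = sol[:n], sol[n]
    pred = float(lam @ v)
    var = float(lam @ b[:n] + mu)
    return pred, var, lam
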
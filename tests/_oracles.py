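"""Independent brute-force oracles used by the test suite.

These are deliberately literal, slow transcriptions of the update
equations and geometric definitions, kept free of any code shared with
the implementation they check.
"""

import numpy as np


def cone_element(scatter, absorb, theta, voxel, a, sigma):
    """Literal cone system-matrix element (no truncation)."""
    scatter = np.asarray(scatter, float)
    axis = scatter - np.asarray(absorb, float)
    axis = axis / np.sqrt((axis**2).sum())
    rel = np.asarray(voxel, float) - scatter
    d = np.sqrt((rel**2).sum())
    solid = 2.0 * np.pi * (1.0 - d / np.sqrt(d * d + a * a))
    if d == 0:
        big = 0.0
    else:
        big = np.arccos(min(1.0, max(-1.0, float(rel @ axis) / d)))
    g = np.exp(-0.5 * ((abs(big) - abs(theta)) / sigma) ** 2)
    return solid * g / np.sin(theta)


def listmode_mlem_step(lam, t, inv_s, v):
    """One literal list-mode MLEM update with dense loops.

    lam: (J,), t: (K, J), inv_s: (K, J) per-event 1/s_j^l, v: (K,).
    """
    K, J = t.shape
    new = np.zeros(J)
    for j in range(J):
        acc = 0.0
        for k in range(K):
            denom = 0.0
            for jp in range(J):
                denom += t[k, jp] * lam[jp]
            if denom > 0:
                acc += inv_s[k, j] * t[k, j] * v[k] / denom
        new[j] = lam[j] * acc
    return new


def hist_mlem_step(lam, c, y):
    """One literal hist-mode MLEM update with dense loops."""
    I, J = c.shape
    new = np.zeros(J)
    for j in range(J):
        s_j = sum(c[i, j] for i in range(I))
        if s_j == 0:
            continue
        acc = 0.0
        for i in range(I):
            denom = sum(c[i, jp] * lam[jp] for jp in range(J))
            if denom > 0:
                acc += c[i, j] * y[i] / denom
        new[j] = lam[j] / s_j * acc
    return new


def segment_box_chord(p0, p1, lo, hi):
    """Chord length of segment p0-p1 inside the axis-aligned box [lo, hi)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if d[ax] == 0:
            if not (lo[ax] <= p0[ax] < hi[ax]):
                return 0.0
            continue
        ta = (lo[ax] - p0[ax]) / d[ax]
        tb = (hi[ax] - p0[ax]) / d[ax]
        ta, tb = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, ta), min(t1, tb)
    if t1 <= t0:
        return 0.0
    return float((t1 - t0) * np.sqrt((d**2).sum()))


def kn_pdf_cos(energy_kev, cos_grid):
    """Unnormalised Klein--Nishina pdf of cos(theta)."""
    k = energy_kev / 511.0
    eps = 1.0 / (1.0 + k * (1.0 - cos_grid))
    return eps**2 * (eps + 1.0 / eps - (1.0 - cos_grid**2))
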
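"""Independent reference implementations used to check the package.

Everything here is deliberately written the slow, obvious way (per-voxel
path tracing, direct quadrature, exhaustive enumeration) and shares no code
path with the implementations under test.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def greedy_ascent_labels(values: np.ndarray, spacing, background_fraction: float) -> np.ndarray:
    """Label voxels by tracing each voxel's steepest ascent path one step at
    a time until it stops at a local maximum."""
    values = np.asarray(values, dtype=np.float64)
    spacing = np.asarray(spacing, dtype=np.float64)
    shape = values.shape
    vmax = values.max()
    fg = (values >= background_fraction * vmax) & (values > 0)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    strides = (shape[1] * shape[2], shape[2], 1)
    offsets.sort(key=lambda o: o[0] * strides[0] + o[1] * strides[1] + o[2] * strides[2])

    def ascend(idx):
        while True:
            best, best_steep = None, 0.0
            for off in offsets:
                nb = tuple(idx[k] + off[k] for k in range(3))
                if any(nb[k] < 0 or nb[k] >= shape[k] for k in range(3)):
                    continue
                dist = float(np.linalg.norm(spacing * np.asarray(off)))
                steep = (values[nb] - values[idx]) / dist
                if steep > best_steep:
                    best_steep, best = steep, nb
            if best is None:
                return idx
            idx = best

    labels = np.zeros(shape, dtype=int)
    roots: dict[tuple, int] = {}
    for idx in itertools.product(*map(range, shape)):
        if not fg[idx]:
            continue
        root = ascend(idx)
        labels[idx] = roots.setdefault(root, len(roots) + 1)
    return labels


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label images define the same partition up to a label
    permutation (background label 0 must coincide exactly)."""
    m_ab: dict[int, int] = {}
    m_ba: dict[int, int] = {}
    for x, y in zip(a.ravel().tolist(), b.ravel().tolist()):
        if (x == 0) != (y == 0):
            return False
        if x == 0:
            continue
        if m_ab.setdefault(x, y) != y or m_ba.setdefault(y, x) != x:
            return False
    return True


def quadrature_tac(mbf, vt, va, vv, ca_func, cv_func, frame_start, frame_end, dt=0.05):
    """Single-tissue model TAC by direct quadrature on a dense grid.

    ``ca_func`` / ``cv_func`` are callables giving the analytic blood curves.
    The tissue response is evaluated pointwise as
    MBF/60 * integral_0^t ca(s) exp(-k2 (t - s)) ds using trapezoidal
    quadrature, then frame values are trapezoid averages over each frame.
    """
    frame_start = np.asarray(frame_start, dtype=np.float64)
    frame_end = np.asarray(frame_end, dtype=np.float64)
    t = np.arange(0.0, frame_end[-1] + dt / 2, dt)
    ca = ca_func(t)
    cv = cv_func(t)
    tissue = np.zeros_like(t)
    if mbf > 0 and (1 - va - vv) > 0:
        k2_s = (mbf / vt) / 60.0
        # integral via the exponential-weighted cumulative trapezoid:
        # I(t) = e^{-k2 t} * int_0^t ca(s) e^{k2 s} ds
        w = ca * np.exp(np.clip(k2_s * t, None, 700))
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * dt)])
        tissue = (1 - va - vv) * (mbf / 60.0) * np.exp(-k2_s * t) * cum
    c = tissue + va * ca + vv * cv
    out = np.empty(len(frame_start))
    for i, (s, e) in enumerate(zip(frame_start, frame_end)):
        sel = (t >= s - 1e-9) & (t <= e + 1e-9)
        out[i] = np.trapezoid(c[sel], t[sel]) / (e - s)
    return out


def wilcoxon_exact_enumeration(diffs: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=np.float64)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    t_plus = ranks[d > 0].sum()
    dist = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=n)
        ]
    )
    p = 2.0 * min((dist <= t_plus).mean(), (dist >= t_plus).mean())
    return min(1.0, p)
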
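"""Independent brute-force oracles used to pin the package's algorithms.

Everything here is deliberately naive pure-Python (loops, literal
definitions) and shares no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def brute_force_local_maxima(y) -> list[int]:
    """Interior strict local maxima; a flat plateau yields its floor-midpoint."""
    y = list(y)
    n = len(y)
    out = []
    i = 1
    while i < n - 1:
        if y[i - 1] < y[i]:
            j = i
            while j < n - 1 and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def brute_force_prominence(y, peak: int) -> float:
    """Height above the higher of the two lowest minima toward the nearest
    higher peaks (or the profile ends)."""
    y = list(y)
    n = len(y)
    left_min = y[peak]
    i = peak - 1
    while i >= 0 and y[i] <= y[peak]:
        left_min = min(left_min, y[i])
        i -= 1
    if i < 0:
        # ran off the end without meeting a higher value
        left_min = min(y[: peak + 1])
    right_min = y[peak]
    i = peak + 1
    while i < n and y[i] <= y[peak]:
        right_min = min(right_min, y[i])
        i += 1
    if i >= n:
        right_min = min(y[peak:])
    return y[peak] - max(left_min, right_min)


def brute_force_detect(y, background, med_ratio, min_ratio, distance, prominence):
    """Literal filter application plus greedy-by-height distance resolution.

    Returns sorted retained peak indices. The caller is responsible for any
    pre-smoothing (pass the smoothed profile).
    """
    y = list(map(float, y))
    threshold = max(background, med_ratio * float(np.median(y)), min_ratio * min(y))
    candidates = [
        i
        for i in brute_force_local_maxima(y)
        if y[i] >= threshold and brute_force_prominence(y, i) >= prominence
    ]
    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: (-y[i], i)):
        if all(abs(i - k) >= distance for k in kept):
            kept.append(i)
    return sorted(kept)


def bh_literal(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up applied literally to its definition."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        idx = order[rank_from_top]
        value = p[idx] * n / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def numeric_crossings(spec, transect, n_samples: int = 10_000) -> list[float]:
    """Crossing positions from sign changes of the implicit ellipse function
    sampled densely along the transect (µm)."""
    import math

    px = spec.pixel_size_um
    p0 = np.array([transect.x0 * px, transect.y0 * px])
    p1 = np.array([transect.x1 * px, transect.y1 * px])
    length = float(np.hypot(*(p1 - p0)))
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    positions = []
    for e in spec.compartments:
        c, s = math.cos(e.theta_rad), math.sin(e.theta_rad)
        dx = pts[:, 0] - e.cx_um
        dy = pts[:, 1] - e.cy_um
        u = c * dx + s * dy
        v = -s * dx + c * dy
        f = (u / e.a_um) ** 2 + (v / e.b_um) ** 2 - 1.0
        signs = np.sign(f)
        for i in np.nonzero(np.diff(signs) != 0)[0]:
            if signs[i] == 0:
                continue
            positions.append(0.5 * (ts[i] + ts[i + 1]) * length)
    return sorted(positions)
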
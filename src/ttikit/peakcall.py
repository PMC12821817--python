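"""Stage-2 peak calling: find genuine membrane-crossing peaks in a profile.

A tonoplast crossing appears as a local intensity maximum along the transect.
Candidates (strict interior maxima; a flat plateau contributes one candidate
at its floor-midpoint) are filtered by six adjustable parameters:

* ``background`` — absolute minimum peak height.
* ``med_ratio`` / ``min_ratio`` — peak height must also exceed
  ``med_ratio * median(profile)`` and ``min_ratio * min(profile)``; these
  compensate for intensity-range differences between profiles and are
  unaffected by source bit depth.
* ``prominence`` — minimum height above the higher of the two interleaving
  minima toward the nearest higher peaks or the profile ends.
* ``distance`` — minimum index separation between retained peaks, in samples.
* ``sigma`` — optional Gaussian pre-smoothing of the profile, in samples.

The combined height threshold is the maximum of the three height criteria;
distance conflicts are resolved by retaining peaks in decreasing height order
(ties: leftmost first) and discarding any candidate closer than ``distance``
samples to an already-retained peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .imaging import IntensityProfile

__all__ = [
    "PeakParams",
    "PeakSet",
    "gaussian_smooth",
    "height_threshold",
    "detect_crossings",
    "misdetection_rate",
]


@dataclass(frozen=True)
class PeakParams:
    """The six stage-2 filter parameters plus the stage-1 smoothing rounds.

    Defaults target 8-bit benchmark-like images and are meant to be tuned per
    dataset; ``smooth_rounds`` is carried for provenance (it acts in stage 1,
    on the image, not here).
    """

    background: float = 0.0
    med_ratio: float = 1.0
    min_ratio: float = 1.5
    distance: int = 5
    prominence: float = 10.0
    sigma: float = 1.0
    smooth_rounds: int = 2

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1 sample")
        for name in ("background", "med_ratio", "min_ratio", "prominence", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.smooth_rounds < 0:
            raise ValueError("smooth_rounds must be >= 0")


@dataclass
class PeakSet:
    """Retained crossing peaks of one transect; ``count`` is the N in TTI = N/L."""

    cell_id: str
    indices: np.ndarray
    positions_um: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.indices.shape != self.positions_um.shape:
            raise ValueError("indices and positions_um must have equal length")
        if len(self.indices) > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("indices must be strictly increasing")

    @property
    def count(self) -> int:
        return int(len(self.indices))


def gaussian_smooth(p: IntensityProfile, sigma: float) -> IntensityProfile:
    """Gaussian-smooth a profile (kernel truncated at 4 sigma, reflect boundary).

    ``sigma`` is in samples; 0 returns the profile unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return p
    smoothed = ndimage.gaussian_filter1d(p.intensity, sigma, mode="reflect", truncate=4.0)
    return replace(p, intensity=np.maximum(smoothed, 0.0))


def height_threshold(p: IntensityProfile, params: PeakParams) -> float:
    """Combined minimum peak height: max of the three height criteria."""
    intensity = p.intensity
    if len(intensity) == 0:
        raise ValueError("empty profile")
    return float(
        max(
            params.background,
            params.med_ratio * float(np.median(intensity)),
            params.min_ratio * float(np.min(intensity)),
        )
    )


def _select_by_distance(candidates: np.ndarray, heights: np.ndarray, distance: int) -> np.ndarray:
    # Decreasing height, ties broken toward the leftmost candidate.
    order = sorted(range(len(candidates)), key=lambda k: (-heights[k], candidates[k]))
    kept: list[int] = []
    for k in order:
        idx = candidates[k]
        if all(abs(idx - other) >= distance for other in kept):
            kept.append(idx)
    return np.array(sorted(kept), dtype=int)


def detect_crossings(p: IntensityProfile, params: PeakParams) -> PeakSet:
    """Detect membrane crossings in one intensity profile.

    Operates on the sigma-smoothed profile (the height threshold is also
    computed on the smoothed values). The first and last samples are never
    peaks.
    """
    if len(p) < 3:
        raise ValueError(f"profile for cell {p.cell_id!r} has fewer than 3 samples")
    sp = gaussian_smooth(p, params.sigma)
    y = sp.intensity
    candidates, _ = signal.find_peaks(y)
    if len(candidates) == 0:
        return PeakSet(p.cell_id, np.empty(0, dtype=int), np.empty(0))
    prominences = signal.peak_prominences(y, candidates)[0]
    threshold = height_threshold(sp, params)
    ok = (y[candidates] >= threshold) & (prominences >= params.prominence)
    candidates = candidates[ok]
    kept = _select_by_distance(candidates, y[candidates], params.distance)
    return PeakSet(p.cell_id, kept, sp.distance_um[kept])


def misdetection_rate(
    detected: PeakSet | Sequence[float],
    truth_positions_um: Sequence[float],
    tolerance_um: float = 0.5,
) -> tuple[int, float]:
    """Count detection errors against ground-truth crossing positions.

    Detected and true positions are matched greedily by nearest distance
    within ``tolerance_um``, each true position at most once. Errors are
    unmatched detections (false positives) plus unmatched truths (false
    negatives); the fraction is errors over the number of true positions
    (``inf`` when there is no truth but something was detected).

    Returns ``(per_transect_errors, fraction)``.
    """
    if not tolerance_um > 0:
        raise ValueError("tolerance_um must be positive")
    det = np.asarray(
        detected.positions_um if isinstance(detected, PeakSet) else detected, dtype=float
    )
    truth = np.asarray(truth_positions_um, dtype=float)
    if len(truth) == 0:
        errors = len(det)
        return errors, (0.0 if errors == 0 else math.inf)
    pairs = [
        (abs(d - t), i, j)
        for i, d in enumerate(det)
        for j, t in enumerate(truth)
        if abs(d - t) <= tolerance_um
    ]
    pairs.sort()
    used_det: set[int] = set()
    used_truth: set[int] = set()
    for _, i, j in pairs:
        if i not in used_det and j not in used_truth:
            used_det.add(i)
            used_truth.add(j)
    errors = (len(det) - len(used_det)) + (len(truth) - len(used_truth))
    return errors, errors / len(truth)
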
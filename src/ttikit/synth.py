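"""Synthetic rhizodermis-like cells with analytically known ground truth.

Each simulated cell is a rectangle (µm) containing closed tonoplast contours
modelled as ellipses: one large compartment (the nascent central vacuole) and
a configurable number of smaller ones. Rendering draws every contour as a
Gaussian-profile bright ridge over a dark baseline, adds Gaussian noise and
quantizes to the bit range — a deliberately simple stand-in for a
fluorescent-marker optical section. Because the geometry is parametric, the
crossing positions of any transect are available in closed form
(line–ellipse intersection), giving an exact oracle for the peak-calling
pipeline, and the ground-truth VMI is the bounding-box product of the
largest compartment.

Conventions: the cell rectangle spans [0, cell_w_um] x [0, cell_h_um] with
the long axis along x; pixel (j, i) has its center at (j * pixel_size_um,
i * pixel_size_um). Cell sizes are snapped to the pixel grid so that image
corners coincide exactly with cell corners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .imaging import ImageStack, Transect

__all__ = [
    "Ellipse",
    "SyntheticCellSpec",
    "PopulationSpec",
    "SimulatedCell",
    "truth_crossings",
    "render_cell",
    "diagonal_transect",
    "longitudinal_transect",
    "largest_compartment",
    "vmi_truth",
    "sample_cell_spec",
    "sample_population",
    "simulate_two_populations",
    "contrasting_population_specs",
    "benchmark_population",
    "fragmentation_gradient",
]

#: Compartments keep this clearance from the cell wall (thin cortical
#: cytoplasm layer between tonoplast and plasma membrane).
EDGE_MARGIN_UM = 0.5

#: FWHM of the rendered membrane cross-section: a diffraction-limited line
#: at high NA. The Gaussian sigma is FWHM / (2 sqrt(2 ln 2)).
MEMBRANE_FWHM_UM = 0.25
MEMBRANE_SIGMA_UM = MEMBRANE_FWHM_UM / 2.3548200450309493

#: Minimum distance between contours of distinct compartments. Tonoplast
#: contours of distinct vacuole sections do not interpenetrate, and contours
#: closer than the optical resolution would image as a single membrane.
CONTOUR_CLEARANCE_UM = 0.6

#: Clean-crossing placement rules relative to the two cell diagonals. The
#: generator emulates a hand-drawn validation set whose membranes cross the
#: transect unambiguously: a compartment either crosses a diagonal with a
#: chord of at least MIN_CHORD_UM, each crossing at least MIN_CROSSING_GAP_UM
#: from every other crossing and from any non-crossing contour stretch, or it
#: stays at least MIN_MISS_UM away from that diagonal. Both diagonal
#: orientations are constrained identically, so no direction is privileged.
MIN_CHORD_UM = 0.8
MIN_CROSSING_GAP_UM = 0.8
MIN_MISS_UM = 0.5
#: Minimum sine of the incidence angle between transect and membrane at a
#: crossing; shallower crossings smear the ridge along the transect.
MIN_INCIDENCE_SIN = 0.4


@dataclass(frozen=True)
class Ellipse:
    """A tonoplast contour: center (µm), semi-axes (µm), rotation (rad)."""

    cx_um: float
    cy_um: float
    a_um: float
    b_um: float
    theta_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.a_um <= 0 or self.b_um <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    @property
    def area_um2(self) -> float:
        return math.pi * self.a_um * self.b_um

    def bbox_half_extents_um(self) -> tuple[float, float]:
        """Half-width/half-height of the axis-aligned bounding box."""
        c, s = math.cos(self.theta_rad), math.sin(self.theta_rad)
        hx = math.sqrt((self.a_um * c) ** 2 + (self.b_um * s) ** 2)
        hy = math.sqrt((self.a_um * s) ** 2 + (self.b_um * c) ** 2)
        return hx, hy

    def bbox_sides_um(self) -> tuple[float, float]:
        hx, hy = self.bbox_half_extents_um()
        return 2 * hx, 2 * hy

    def perimeter_um(self) -> float:
        a, b = self.a_um, self.b_um
        return math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))

    def contour_points_um(self, spacing_um: float) -> np.ndarray:
        n = max(64, int(math.ceil(self.perimeter_um() / spacing_um)))
        phi = np.linspace(0, 2 * math.pi, n, endpoint=False)
        x = self.a_um * np.cos(phi)
        y = self.b_um * np.sin(phi)
        c, s = math.cos(self.theta_rad), math.sin(self.theta_rad)
        return np.column_stack(
            [self.cx_um + c * x - s * y, self.cy_um + s * x + c * y]
        )


@dataclass
class SyntheticCellSpec:
    """Full description of one simulated cell; rendering is deterministic."""

    cell_id: str
    cell_w_um: float
    cell_h_um: float
    compartments: list[Ellipse]
    membrane_intensity: float = 120.0
    membrane_sigma_um: float = MEMBRANE_SIGMA_UM
    baseline: float = 10.0
    noise_sd: float = 0.0
    pixel_size_um: float = 0.1
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_w_um <= 0 or self.cell_h_um <= 0:
            raise ValueError("cell dimensions must be positive")
        if not self.membrane_intensity >= self.baseline >= 0:
            raise ValueError("need membrane_intensity >= baseline >= 0")
        if self.noise_sd < 0 or self.membrane_sigma_um <= 0:
            raise ValueError("noise_sd must be >= 0 and membrane_sigma_um > 0")
        for e in self.compartments:
            hx, hy = e.bbox_half_extents_um()
            if not (
                0 <= e.cx_um - hx
                and e.cx_um + hx <= self.cell_w_um
                and 0 <= e.cy_um - hy
                and e.cy_um + hy <= self.cell_h_um
            ):
                raise ValueError(
                    f"cell {self.cell_id!r}: compartment exceeds the cell rectangle"
                )

    @property
    def shape_px(self) -> tuple[int, int]:
        """(ny, nx) of the rendered image (grid covering the rectangle)."""
        nx = int(round(self.cell_w_um / self.pixel_size_um)) + 1
        ny = int(round(self.cell_h_um / self.pixel_size_um)) + 1
        return ny, nx


def diagonal_transect(spec: SyntheticCellSpec, direction: str = "main") -> Transect:
    """Corner-to-corner diagonal; ``main`` runs top-left to bottom-right."""
    ny, nx = spec.shape_px
    if direction == "main":
        x0, y0, x1, y1 = 0.0, 0.0, nx - 1.0, ny - 1.0
    elif direction == "anti":
        x0, y0, x1, y1 = 0.0, ny - 1.0, nx - 1.0, 0.0
    else:
        raise ValueError("direction must be 'main' or 'anti'")
    return Transect(
        cell_id=spec.cell_id,
        kind="diagonal",
        x0=x0,
        y0=y0,
        x1=x1,
        y1=y1,
        direction_label=direction,
    )


def longitudinal_transect(spec: SyntheticCellSpec) -> Transect:
    """Full-length mid-height transect used for cell-length measurement."""
    ny, nx = spec.shape_px
    ymid = (ny - 1) / 2
    return Transect(
        cell_id=spec.cell_id, kind="longitudinal", x0=0.0, y0=ymid, x1=nx - 1.0, y1=ymid
    )


def _line_ellipse_ts(p0: np.ndarray, p1: np.ndarray, e: Ellipse) -> list[float]:
    """Parameters t in [0, 1] where segment p0 + t(p1-p0) crosses the ellipse.

    A tangency (discriminant zero within 1e-9) yields one value.
    """
    d = p1 - p0
    c, s = math.cos(e.theta_rad), math.sin(e.theta_rad)
    rot = np.array([[c, s], [-s, c]])  # world -> ellipse frame
    q0 = rot @ (p0 - np.array([e.cx_um, e.cy_um]))
    dq = rot @ d
    ax, ay = e.a_um, e.b_um
    A = (dq[0] / ax) ** 2 + (dq[1] / ay) ** 2
    B = 2 * (q0[0] * dq[0] / ax**2 + q0[1] * dq[1] / ay**2)
    C = (q0[0] / ax) ** 2 + (q0[1] / ay) ** 2 - 1
    disc = B * B - 4 * A * C
    tol = 1e-9 * max(1.0, B * B)
    if disc < -tol or A == 0:
        return []
    if disc <= tol:
        roots = [-B / (2 * A)]
    else:
        sq = math.sqrt(disc)
        roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
    return [r for r in roots if 0 <= r <= 1]


def truth_crossings(spec: SyntheticCellSpec, t: Transect) -> np.ndarray:
    """Exact crossing positions (µm along the transect), sorted.

    Solves the parametric line–ellipse intersection per compartment; a
    tangency (discriminant zero within 1e-9) contributes one crossing.
    """
    px = spec.pixel_size_um
    p0 = np.array([t.x0 * px, t.y0 * px])
    p1 = np.array([t.x1 * px, t.y1 * px])
    length_um = float(np.hypot(*(p1 - p0)))
    positions = [
        r * length_um for e in spec.compartments for r in _line_ellipse_ts(p0, p1, e)
    ]
    return np.sort(np.asarray(positions))


def render_cell(spec: SyntheticCellSpec) -> ImageStack:
    """Render the cell as an 8/16-bit grayscale plane.

    Each contour becomes a Gaussian ridge of width ``membrane_sigma_um``
    peaking at ``membrane_intensity``; overlapping ridges combine by maximum
    so membrane brightness stays constant. Additive Gaussian noise
    (``noise_sd``) is applied, then values are clipped to the bit range and
    rounded. Deterministic for a given seed.
    """
    ny, nx = spec.shape_px
    px = spec.pixel_size_um
    sigma = spec.membrane_sigma_um
    base = np.full((ny, nx), float(spec.baseline))
    if spec.compartments and spec.membrane_intensity > spec.baseline:
        pts = np.vstack(
            [e.contour_points_um(spacing_um=0.25 * px) for e in spec.compartments]
        )
        tree = cKDTree(pts)
        ys, xs = np.mgrid[0:ny, 0:nx]
        coords = np.column_stack([(xs.ravel() * px), (ys.ravel() * px)])
        cutoff = 5.0 * sigma
        dist, _ = tree.query(coords, k=1, distance_upper_bound=cutoff)
        dist = np.where(np.isfinite(dist), dist, cutoff)
        ridge = np.exp(-(dist**2) / (2 * sigma**2)).reshape(ny, nx)
        base = base + (spec.membrane_intensity - spec.baseline) * ridge
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        base = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
    hi = 2**spec.bit_depth - 1
    pixels = np.clip(np.floor(base + 0.5), 0, hi).astype(
        np.uint8 if spec.bit_depth == 8 else np.uint16
    )
    return ImageStack(
        pixels=pixels,
        pixel_size_um=px,
        bit_depth=spec.bit_depth,
        source_id=spec.cell_id,
    )


def ideal_profile(spec: SyntheticCellSpec, t: Transect) -> "IntensityProfile":
    """Analytic noiseless intensity profile along a transect.

    Computed from contour distances directly (no rasterization, no noise):
    the ideal signal the rendered pipeline approximates.
    """
    from .imaging import IntensityProfile

    px = spec.pixel_size_um
    length_px = t.length_px
    n = int(round(length_px)) + 1
    frac = np.arange(n) / (n - 1)
    xs = (t.x0 + frac * (t.x1 - t.x0)) * px
    ys = (t.y0 + frac * (t.y1 - t.y0)) * px
    intensity = np.full(n, float(spec.baseline))
    if spec.compartments and spec.membrane_intensity > spec.baseline:
        pts = np.vstack([e.contour_points_um(spacing_um=0.05) for e in spec.compartments])
        tree = cKDTree(pts)
        dist, _ = tree.query(np.column_stack([xs, ys]), k=1)
        intensity = intensity + (spec.membrane_intensity - spec.baseline) * np.exp(
            -(dist**2) / (2 * spec.membrane_sigma_um**2)
        )
    length_um = length_px * px
    return IntensityProfile(
        cell_id=spec.cell_id,
        distance_um=frac * length_um,
        intensity=intensity,
        transect_length_um=length_um,
    )


def _countable(spec: SyntheticCellSpec) -> bool:
    # The generator's contract: on the ideal noiseless profile, peak calling
    # at default parameters recovers the geometric crossing count exactly,
    # for both diagonal orientations.
    from .peakcall import PeakParams, detect_crossings

    for direction in ("main", "anti"):
        t = diagonal_transect(spec, direction)
        profile = ideal_profile(spec, t)
        n_truth = len(truth_crossings(spec, t))
        # sigma=2 adds margin for the image-space smoothing of stage 1; the
        # prominence bracket demands true peaks stay robustly above, and any
        # spurious bump robustly below, the default prominence filter.
        for sigma in (1.0, 2.0):
            for prominence in (6.0, 15.0):
                params = PeakParams(sigma=sigma, prominence=prominence)
                if detect_crossings(profile, params).count != n_truth:
                    return False
    # Definitive check: a noiseless render processed by the actual pipeline
    # (stage-1 smoothing included) must recover the count exactly too.
    from .imaging import extract_profile, smooth_image

    defaults = PeakParams()
    clean = render_cell(replace(spec, noise_sd=0.0))
    smoothed = smooth_image(clean, defaults.smooth_rounds)
    for direction in ("main", "anti"):
        t = diagonal_transect(spec, direction)
        peaks = detect_crossings(extract_profile(smoothed, t), defaults)
        if peaks.count != len(truth_crossings(spec, t)):
            return False
    return True


def largest_compartment(spec: SyntheticCellSpec) -> Ellipse:
    if not spec.compartments:
        raise ValueError(f"cell {spec.cell_id!r} has no compartments")
    return max(spec.compartments, key=lambda e: e.area_um2)


def vmi_truth(spec: SyntheticCellSpec) -> float:
    """Ground-truth VMI: bounding-box side product of the largest compartment."""
    w, h = largest_compartment(spec).bbox_sides_um()
    return w * h


# ---------------------------------------------------------------------------
# Population sampling


@dataclass
class PopulationSpec:
    """Distributional description of one simulated cell population.

    Defaults emulate transition-zone rhizodermis atrichoblasts imaged at
    high magnification: ~30 x 12 µm cells at 0.1 µm/px, one dominant vacuolar
    compartment plus a few smaller ones, diffraction-limited membrane ridges
    (sigma 0.25 µm) at 8-bit brightness 150 over baseline 10.
    """

    name: str = "pop"
    n_cells: int = 30
    cell_w_um: tuple[float, float] = (30.0, 5.0)  # mean, SD of cell length
    cell_h_um: tuple[float, float] = (12.0, 1.2)
    large_axes_um: tuple[tuple[float, float], tuple[float, float]] = ((10.0, 1.5), (4.0, 0.6))
    n_small: tuple[int, int] = (2, 6)  # inclusive discrete-uniform range
    small_axes_um: tuple[tuple[float, float], tuple[float, float]] = ((1.6, 0.35), (1.1, 0.25))
    membrane_intensity: float = 120.0
    membrane_sigma_um: float = MEMBRANE_SIGMA_UM
    baseline: float = 10.0
    noise_sd: float = 0.0
    pixel_size_um: float = 0.1
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 <= self.n_small[0] <= self.n_small[1]:
            raise ValueError("n_small range must satisfy 0 <= low <= high")


@dataclass
class SimulatedCell:
    """One simulated cell with its rendered image and analytic ground truth."""

    population: str
    spec: SyntheticCellSpec
    image: ImageStack
    diagonal: Transect
    truth_positions_um: np.ndarray
    vmi_truth_um2: float

    @property
    def cell_id(self) -> str:
        return self.spec.cell_id


def _snap(value: float, px: float) -> float:
    return round(value / px) * px


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= low:
            return v
    raise RuntimeError("truncated-normal rejection cap exceeded")


def _diagonal_endpoints_um(w: float, h: float) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return {
        "main": (np.array([0.0, 0.0]), np.array([w, h])),
        "anti": (np.array([0.0, h]), np.array([w, 0.0])),
    }


def _sample_large(
    rng: np.random.Generator,
    pop: PopulationSpec,
    w: float,
    h: float,
    crossings: dict[str, list[float]],
    shrink: float = 1.0,
) -> Ellipse:
    (am, asd), (bm, bsd) = pop.large_axes_um
    margin = EDGE_MARGIN_UM
    diags = _diagonal_endpoints_um(w, h)
    for _ in range(2000):
        a = _truncated_normal(rng, am * shrink, asd, 0.5)
        b = _truncated_normal(rng, bm * shrink, bsd, 0.5)
        cx = w / 2 + rng.normal(0, 1.0)
        cy = h / 2 + rng.normal(0, 0.4)
        theta = rng.normal(0, 0.08)
        e = Ellipse(cx, cy, a, b, theta)
        hx, hy = e.bbox_half_extents_um()
        if not (
            margin <= cx - hx
            and cx + hx <= w - margin
            and margin <= cy - hy
            and cy + hy <= h - margin
        ):
            continue
        found: dict[str, list[float]] = {}
        for name, (p0, p1) in diags.items():
            ok, pos = _clean_interaction(e, p0, p1, crossings[name])
            if not ok:
                break
            found[name] = pos
        else:
            for name, pos in found.items():
                crossings[name].extend(pos)
            return e
    raise RuntimeError("could not place the large compartment (rejection cap)")


def _point_segment_distance(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    d = p1 - p0
    t = np.clip(((pts - p0) @ d) / (d @ d), 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.hypot(*(pts - proj).T)


def _clean_interaction(
    e: Ellipse,
    p0: np.ndarray,
    p1: np.ndarray,
    existing_crossings_um: Sequence[float],
) -> tuple[bool, list[float]]:
    """Check that a compartment interacts unambiguously with one diagonal.

    Returns (ok, crossing positions in µm along the segment). A compartment
    passes if it misses the diagonal by at least MIN_MISS_UM everywhere, or
    crosses it with a chord of at least MIN_CHORD_UM, every crossing at least
    MIN_CROSSING_GAP_UM from previously placed crossings, and no contour
    stretch hugging the diagonal away from its own crossing points.
    """
    length_um = float(np.hypot(*(p1 - p0)))
    ts = _line_ellipse_ts(p0, p1, e)
    pts = e.contour_points_um(spacing_um=0.1)
    dist = _point_segment_distance(pts, p0, p1)
    if not ts:
        return bool(dist.min() >= MIN_MISS_UM), []
    if len(ts) == 1:  # tangency is maximally ambiguous
        return False, []
    positions = sorted(t * length_um for t in ts)
    if positions[1] - positions[0] < MIN_CHORD_UM:
        return False, []
    d_hat = (p1 - p0) / length_um
    c, s = math.cos(e.theta_rad), math.sin(e.theta_rad)
    rot = np.array([[c, s], [-s, c]])
    for t in ts:
        u = rot @ (p0 + t * (p1 - p0) - np.array([e.cx_um, e.cy_um]))
        grad = np.array([2 * u[0] / e.a_um**2, 2 * u[1] / e.b_um**2])
        normal = rot.T @ grad
        normal /= np.hypot(*normal)
        if abs(float(d_hat @ normal)) < MIN_INCIDENCE_SIN:
            return False, []
    for pos in positions:
        if any(abs(pos - prev) < MIN_CROSSING_GAP_UM for prev in existing_crossings_um):
            return False, []
    # contour points close to the diagonal must belong to a crossing region
    crossing_xy = [p0 + (pos / length_um) * (p1 - p0) for pos in positions]
    near = dist < MIN_MISS_UM
    if near.any():
        near_pts = pts[near]
        dist_to_cross = np.min(
            np.stack([np.hypot(*(near_pts - c).T) for c in crossing_xy]), axis=0
        )
        if dist_to_cross.max() > MIN_CROSSING_GAP_UM:
            return False, []
    return True, positions


def _contour_clearance_ok(
    e: Ellipse, existing: Sequence[Ellipse], clearance_um: float
) -> bool:
    # Contours of distinct compartments must stay clearance_um apart; nesting
    # (one fully inside another, away from its boundary) is allowed.
    pts = e.contour_points_um(spacing_um=0.15)
    for other in existing:
        opts = other.contour_points_um(spacing_um=0.15)
        d2 = (
            (pts[:, None, 0] - opts[None, :, 0]) ** 2
            + (pts[:, None, 1] - opts[None, :, 1]) ** 2
        )
        if d2.min() < clearance_um**2:
            return False
    return True


def _sample_small(
    rng: np.random.Generator,
    pop: PopulationSpec,
    w: float,
    h: float,
    existing: Sequence[Ellipse],
    crossings: dict[str, list[float]],
) -> Ellipse | None:
    (am, asd), (bm, bsd) = pop.small_axes_um
    margin = EDGE_MARGIN_UM
    diags = _diagonal_endpoints_um(w, h)
    for _ in range(300):
        a = _truncated_normal(rng, am, asd, 0.35)
        b = _truncated_normal(rng, bm, bsd, 0.25)
        if b > a:
            a, b = b, a
        theta = rng.uniform(0, math.pi)
        e = Ellipse(rng.uniform(0, w), rng.uniform(0, h), a, b, theta)
        hx, hy = e.bbox_half_extents_um()
        if not (
            margin <= e.cx_um - hx
            and e.cx_um + hx <= w - margin
            and margin <= e.cy_um - hy
            and e.cy_um + hy <= h - margin
        ):
            continue
        if not _contour_clearance_ok(e, existing, CONTOUR_CLEARANCE_UM):
            continue
        found: dict[str, list[float]] = {}
        for name, (p0, p1) in diags.items():
            ok, pos = _clean_interaction(e, p0, p1, crossings[name])
            if not ok:
                break
            found[name] = pos
        else:
            for name, pos in found.items():
                crossings[name].extend(pos)
            return e
    return None


def sample_cell_spec(
    pop: PopulationSpec,
    rng: np.random.Generator,
    cell_id: str,
    render_seed: int,
    n_small: int | None = None,
    large_shrink: float = 1.0,
) -> SyntheticCellSpec:
    """Draw one cell geometry from a population specification."""
    px = pop.pixel_size_um
    for _attempt in range(50):
        w = _snap(_truncated_normal(rng, *pop.cell_w_um, low=0.6 * pop.cell_w_um[0]), px)
        h = _snap(_truncated_normal(rng, *pop.cell_h_um, low=0.6 * pop.cell_h_um[0]), px)
        crossings: dict[str, list[float]] = {"main": [], "anti": []}
        compartments = [_sample_large(rng, pop, w, h, crossings, shrink=large_shrink)]
        n_target = n_small
        if n_target is None:
            n_target = int(rng.integers(pop.n_small[0], pop.n_small[1] + 1))
        for _ in range(n_target):
            e = _sample_small(rng, pop, w, h, compartments, crossings)
            if e is None:  # cell too crowded for another compartment
                break
            compartments.append(e)
        spec = SyntheticCellSpec(
            cell_id=cell_id,
            cell_w_um=w,
            cell_h_um=h,
            compartments=compartments,
            membrane_intensity=pop.membrane_intensity,
            membrane_sigma_um=pop.membrane_sigma_um,
            baseline=pop.baseline,
            noise_sd=pop.noise_sd,
            pixel_size_um=px,
            bit_depth=pop.bit_depth,
            seed=render_seed,
        )
        if _countable(spec):
            return spec
    raise RuntimeError(f"cell {cell_id}: could not draw countable geometry (cap)")


def sample_population(
    pop: PopulationSpec, direction: str = "main", render: bool = True
) -> list[SimulatedCell]:
    """Sample and (optionally) render every cell of one population."""
    rng = np.random.default_rng(pop.seed)
    render_seeds = rng.integers(0, 2**31 - 1, size=pop.n_cells)
    cells: list[SimulatedCell] = []
    for i in range(pop.n_cells):
        spec = sample_cell_spec(
            pop, rng, cell_id=f"{pop.name}_{i:03d}", render_seed=int(render_seeds[i])
        )
        diag = diagonal_transect(spec, direction)
        cells.append(
            SimulatedCell(
                population=pop.name,
                spec=spec,
                image=render_cell(spec) if render else None,
                diagonal=diag,
                truth_positions_um=truth_crossings(spec, diag),
                vmi_truth_um2=vmi_truth(spec),
            )
        )
    return cells


def simulate_two_populations(
    a: PopulationSpec, b: PopulationSpec, direction: str = "main"
) -> list[SimulatedCell]:
    """Simulate two populations (images + crossing truth + VMI truth per cell)."""
    if a.name == b.name:
        raise ValueError("populations must have distinct names")
    return sample_population(a, direction) + sample_population(b, direction)


def contrasting_population_specs(
    seed: int, n_cells: int = 30, noise_sd: float = 12.0
) -> tuple[PopulationSpec, PopulationSpec]:
    """Two populations sharing the large-compartment law, differing only in
    the number of small compartments (A: none, B: 4–8)."""
    ss = np.random.SeedSequence(seed)
    seed_a, seed_b = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    base = dict(n_cells=n_cells, noise_sd=noise_sd)
    a = PopulationSpec(name="A", n_small=(0, 0), seed=seed_a, **base)
    b = PopulationSpec(name="B", n_small=(4, 8), seed=seed_b, **base)
    return a, b


def benchmark_population(seed: int, n_cells: int = 200) -> PopulationSpec:
    """The detection benchmark: default geometry, noise SD = 10% of membrane
    intensity."""
    pop = PopulationSpec(name="bench", n_cells=n_cells, seed=seed)
    return replace(pop, noise_sd=0.10 * pop.membrane_intensity)


def fragmentation_gradient(
    n_cells: int, seed: int, noise_sd: float = 12.0, shrink_per_compartment: float = 0.05
) -> list[SimulatedCell]:
    """Cells where added small compartments shrink the largest compartment.

    The number of small compartments is uniform on 0..8 and the large
    compartment's axes are scaled by ``1 - shrink_per_compartment * n_small``,
    emulating vacuole fragmentation: more, smaller compartments at the
    expense of the central one. Used to probe the TTI-vs-log(VMI)
    relationship.
    """
    pop = PopulationSpec(name="frag", n_cells=n_cells, noise_sd=noise_sd, seed=seed)
    rng = np.random.default_rng(pop.seed)
    render_seeds = rng.integers(0, 2**31 - 1, size=n_cells)
    cells: list[SimulatedCell] = []
    for i in range(n_cells):
        n_small = int(rng.integers(0, 9))
        spec = sample_cell_spec(
            pop,
            rng,
            cell_id=f"frag_{i:03d}",
            render_seed=int(render_seeds[i]),
            n_small=n_small,
            large_shrink=1.0 - shrink_per_compartment * n_small,
        )
        diag = diagonal_transect(spec)
        cells.append(
            SimulatedCell(
                population="frag",
                spec=spec,
                image=render_cell(spec),
                diagonal=diag,
                truth_positions_um=truth_crossings(spec, diag),
                vmi_truth_um2=vmi_truth(spec),
            )
        )
    return cells
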
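"""Calibrated image handling and transect sampling.

This module covers the microscopy-facing stage of the TTI pipeline: reading
calibrated 8/16-bit grayscale TIFF / OME-TIFF optical sections, the stage-1
preprocessing (contrast enhancement and repeated 3x3 mean-filter smoothing),
and sampling of 1-D intensity profiles along user-defined cell transects.

Coordinates are 0-based and continuous, with pixel centers at integer
coordinates; all physical distances are micrometers.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "ImageStack",
    "Transect",
    "IntensityProfile",
    "smooth_image",
    "enhance_contrast",
    "extract_profile",
    "transect_length",
    "read_image",
    "write_image",
    "read_transects",
    "write_transects",
    "read_profile_csv",
    "write_profile_csv",
    "read_profiles_long",
    "write_profiles_long",
]

TRANSECT_COLUMNS = ["cell_id", "kind", "z_index", "x0", "y0", "x1", "y1", "direction_label"]


@dataclass
class ImageStack:
    """A calibrated 2-D or 3-D (z, y, x) grayscale intensity grid.

    Parameters
    ----------
    pixels
        Non-negative intensities, shape (y, x) or (z, y, x).
    pixel_size_um
        Isotropic x/y pixel size in micrometers; must be positive.
    bit_depth
        8 or 16; intensities must fit the corresponding range.
    source_id
        Free-text provenance (file name, simulation seed, ...).
    """

    pixels: np.ndarray
    pixel_size_um: float
    bit_depth: int = 8
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D (y, x) or 3-D (z, y, x)")
        if self.pixels.shape[-1] < 2 or self.pixels.shape[-2] < 2:
            raise ValueError("each plane must be at least 2x2 pixels")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > 2**self.bit_depth - 1
        ):
            raise ValueError(f"intensities outside [0, {2**self.bit_depth - 1}]")

    @property
    def n_planes(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[-2], self.pixels.shape[-1]

    def plane(self, z_index: int = 0) -> np.ndarray:
        """Return one optical section as a 2-D array."""
        if self.pixels.ndim == 2:
            if z_index != 0:
                raise IndexError(f"z_index {z_index} out of range for a single-plane image")
            return self.pixels
        if not 0 <= z_index < self.pixels.shape[0]:
            raise IndexError(f"z_index {z_index} out of range (0..{self.pixels.shape[0] - 1})")
        return self.pixels[z_index]


@dataclass
class Transect:
    """A straight sampling segment across one cell's optical section.

    ``kind`` is ``"diagonal"`` (TTI transect) or ``"longitudinal"`` (cell
    length). Endpoints are continuous pixel coordinates with pixel centers at
    integers. ``direction_label`` distinguishes the two uniform diagonal
    orientations (e.g. ``"main"`` / ``"anti"``).
    """

    cell_id: str
    kind: str
    x0: float
    y0: float
    x1: float
    y1: float
    z_index: int = 0
    direction_label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("diagonal", "longitudinal"):
            raise ValueError(f"transect kind must be diagonal or longitudinal, got {self.kind!r}")
        if self.length_px < 2:
            raise ValueError(
                f"transect for cell {self.cell_id!r} is shorter than 2 pixels"
            )

    @property
    def length_px(self) -> float:
        return math.hypot(self.x1 - self.x0, self.y1 - self.y0)

    def reversed(self) -> "Transect":
        return replace(self, x0=self.x1, y0=self.y1, x1=self.x0, y1=self.y0)


@dataclass
class IntensityProfile:
    """Intensities sampled at uniform spacing along one transect."""

    cell_id: str
    distance_um: np.ndarray
    intensity: np.ndarray
    transect_length_um: float

    def __post_init__(self) -> None:
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.distance_um.shape != self.intensity.shape or self.distance_um.ndim != 1:
            raise ValueError("distance_um and intensity must be equal-length 1-D arrays")
        if len(self.distance_um) < 3:
            raise ValueError(f"profile for cell {self.cell_id!r} needs >= 3 samples")
        if self.distance_um[0] != 0:
            raise ValueError("distance axis must start at 0")
        steps = np.diff(self.distance_um)
        if np.any(steps <= 0):
            raise ValueError("distance_um must be strictly increasing")
        rel = abs(self.distance_um[-1] - self.transect_length_um) / max(
            self.transect_length_um, 1e-300
        )
        if rel > 1e-9:
            raise ValueError("last sample position must equal transect_length_um")
        if steps.max() - steps.min() > 1e-9 * steps.mean():
            raise ValueError("sample spacing must be uniform")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.distance_um)

    @property
    def spacing_um(self) -> float:
        return float(self.distance_um[1] - self.distance_um[0])


def _round_half_up(values: np.ndarray) -> np.ndarray:
    return np.floor(values + 0.5)


def _cast_like(values: np.ndarray, img: ImageStack) -> np.ndarray:
    dtype = img.pixels.dtype
    if np.issubdtype(dtype, np.integer):
        hi = 2**img.bit_depth - 1
        return np.clip(_round_half_up(values), 0, hi).astype(dtype)
    return np.clip(values, 0, 2**img.bit_depth - 1).astype(dtype)


def smooth_image(img: ImageStack, rounds: int) -> ImageStack:
    """Apply ``rounds`` passes of a 3x3 mean filter per optical section.

    Edges use reflected padding. Accumulation is in float64 across rounds;
    integer inputs are rounded half-up once at the end, so total intensity of
    interior-supported features is conserved to within one count per pixel.
    ``rounds=0`` returns the input unchanged.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if rounds == 0:
        return img
    work = img.pixels.astype(np.float64)
    planes = work[None] if work.ndim == 2 else work
    out = np.empty_like(planes)
    for i, plane in enumerate(planes):
        for _ in range(rounds):
            plane = ndimage.uniform_filter(plane, size=3, mode="reflect")
        out[i] = plane
    if img.pixels.ndim == 2:
        out = out[0]
    return replace(img, pixels=_cast_like(out, img))


def enhance_contrast(img: ImageStack, saturated_fraction: float = 0.0035) -> ImageStack:
    """Linearly rescale each plane to the full bit range.

    ``saturated_fraction`` of pixels is clipped at each tail (quantiles of the
    per-plane histogram). Rank order of distinct pixel values is preserved up
    to the ties the clipping introduces. A constant plane is returned
    unchanged, as no rescale is possible.
    """
    if not 0 <= saturated_fraction < 0.5:
        raise ValueError("saturated_fraction must be in [0, 0.5)")
    hi_val = 2**img.bit_depth - 1
    work = img.pixels.astype(np.float64)
    planes = work[None] if work.ndim == 2 else work
    out = np.empty_like(planes)
    for i, plane in enumerate(planes):
        lo = np.quantile(plane, saturated_fraction)
        hi = np.quantile(plane, 1 - saturated_fraction)
        if hi <= lo:
            out[i] = plane
        else:
            out[i] = np.clip((plane - lo) / (hi - lo), 0, 1) * hi_val
    if img.pixels.ndim == 2:
        out = out[0]
    return replace(img, pixels=_cast_like(out, img))


def _sample_coordinates(t: Transect, n: int) -> tuple[np.ndarray, np.ndarray]:
    # Integer-weight convex combination: exactly symmetric under transect
    # reversal, so reversed transects yield bit-identical reversed profiles.
    i = np.arange(n, dtype=np.float64)
    j = np.arange(n - 1, -1, -1, dtype=np.float64)
    denom = float(n - 1)
    xs = (t.x0 * j + t.x1 * i) / denom
    ys = (t.y0 * j + t.y1 * i) / denom
    return xs, ys


def extract_profile(img: ImageStack, t: Transect) -> IntensityProfile:
    """Sample an intensity profile along a transect at ~1-pixel spacing.

    The number of samples is ``round(length_px) + 1``, evenly spaced from one
    endpoint to the other; intensities are bilinearly interpolated. The
    distance axis is in micrometers.
    """
    plane = img.plane(t.z_index).astype(np.float64)
    ny, nx = plane.shape
    for x, y in ((t.x0, t.y0), (t.x1, t.y1)):
        if not (0 <= x <= nx - 1 and 0 <= y <= ny - 1):
            raise ValueError(
                f"transect for cell {t.cell_id!r} exits image bounds "
                f"({x:.2f}, {y:.2f}) outside [0, {nx - 1}] x [0, {ny - 1}]"
            )
    length_px = t.length_px
    n = int(round(length_px)) + 1
    xs, ys = _sample_coordinates(t, n)
    intensity = ndimage.map_coordinates(plane, [ys, xs], order=1, mode="nearest")
    length_um = length_px * img.pixel_size_um
    distance = (np.arange(n) / (n - 1)) * length_um
    return IntensityProfile(
        cell_id=t.cell_id,
        distance_um=distance,
        intensity=np.maximum(intensity, 0.0),
        transect_length_um=length_um,
    )


def transect_length(t: Transect, pixel_size_um: float) -> float:
    """Physical transect length: Euclidean pixel length times pixel size."""
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    return t.length_px * pixel_size_um


# ---------------------------------------------------------------------------
# File I/O


def _ome_pixel_size(tf: tifffile.TiffFile) -> float | None:
    if not tf.ome_metadata:
        return None
    try:
        root = ET.fromstring(tf.ome_metadata)
    except ET.ParseError:
        return None
    for elem in root.iter():
        if elem.tag.endswith("Pixels"):
            size = elem.attrib.get("PhysicalSizeX")
            if size is not None:
                return float(size)
    return None


def read_image(path: str | Path, pixel_size_um: float | None = None) -> ImageStack:
    """Read a grayscale 8/16-bit TIFF or OME-TIFF.

    Pixel size is taken from OME metadata when present; otherwise
    ``pixel_size_um`` is required.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pixels = tf.asarray()
        meta_size = _ome_pixel_size(tf)
    size = pixel_size_um if pixel_size_um is not None else meta_size
    if size is None:
        raise ValueError(
            f"{path.name}: no pixel calibration in metadata; supply --pixel-size-um"
        )
    if pixels.dtype == np.uint8:
        bit_depth = 8
    elif pixels.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"{path.name}: unsupported dtype {pixels.dtype}; need uint8/uint16")
    return ImageStack(pixels=pixels, pixel_size_um=size, bit_depth=bit_depth, source_id=path.name)


def write_image(img: ImageStack, path: str | Path) -> None:
    """Write a plain grayscale TIFF with resolution tags in µm."""
    tifffile.imwrite(
        Path(path),
        img.pixels,
        resolution=(1.0 / img.pixel_size_um, 1.0 / img.pixel_size_um),
        metadata={"unit": "um", "pixel_size_um": img.pixel_size_um},
    )


def read_transects(path: str | Path) -> list[Transect]:
    """Read the transect CSV (``cell_id,kind,z_index,x0,y0,x1,y1,direction_label``)."""
    df = pd.read_csv(path, dtype={"cell_id": str, "direction_label": str})
    missing = set(TRANSECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transect CSV {path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        label = "" if pd.isna(row.direction_label) else str(row.direction_label)
        out.append(
            Transect(
                cell_id=str(row.cell_id),
                kind=str(row.kind),
                z_index=int(row.z_index),
                x0=float(row.x0),
                y0=float(row.y0),
                x1=float(row.x1),
                y1=float(row.y1),
                direction_label=label,
            )
        )
    return out


def write_transects(transects: Iterable[Transect], path: str | Path) -> None:
    rows = [
        {
            "cell_id": t.cell_id,
            "kind": t.kind,
            "z_index": t.z_index,
            "x0": t.x0,
            "y0": t.y0,
            "x1": t.x1,
            "y1": t.y1,
            "direction_label": t.direction_label,
        }
        for t in transects
    ]
    pd.DataFrame(rows, columns=TRANSECT_COLUMNS).to_csv(path, index=False)


def write_profile_csv(profile: IntensityProfile, path: str | Path) -> None:
    """Write one profile in the two-column ImageJ Plot-Profile dialect (X,Y)."""
    pd.DataFrame({"X": profile.distance_um, "Y": profile.intensity}).to_csv(
        path, index=False, float_format="%.6f"
    )


def _profile_from_xy(x: np.ndarray, y: np.ndarray, cell_id: str) -> IntensityProfile:
    # The Plot-Profile dialect guarantees uniform sampling; reconstruct the
    # exact axis so that file rounding cannot violate the uniformity invariant.
    if len(x) < 3:
        raise ValueError(f"profile for cell {cell_id!r} needs >= 3 samples")
    steps = np.diff(x)
    # tolerate 6-decimal file rounding (up to 2e-6 jitter between steps)
    if np.any(steps <= 0) or steps.max() - steps.min() > 2.5e-6 + 1e-6 * steps.mean():
        raise ValueError(f"profile for cell {cell_id!r}: X axis not uniformly spaced")
    length = float(x[-1] - x[0])
    distance = (np.arange(len(x)) / (len(x) - 1)) * length
    return IntensityProfile(
        cell_id=cell_id, distance_um=distance, intensity=y, transect_length_um=length
    )


def read_profile_csv(path: str | Path, cell_id: str | None = None) -> IntensityProfile:
    """Read a two-column ``X,Y`` profile CSV; cell_id defaults to the file stem."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"X", "Y"}.issubset(df.columns):
        raise ValueError(f"profile CSV {path.name}: expected columns X,Y")
    return _profile_from_xy(
        df["X"].to_numpy(dtype=float),
        df["Y"].to_numpy(dtype=float),
        cell_id if cell_id is not None else path.stem,
    )


def write_profiles_long(profiles: Iterable[IntensityProfile], path: str | Path) -> None:
    """Write many profiles in the long dialect (``cell_id,X,Y``)."""
    frames = [
        pd.DataFrame({"cell_id": p.cell_id, "X": p.distance_um, "Y": p.intensity})
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_profiles_long(path: str | Path) -> list[IntensityProfile]:
    """Read the long-format variant (``cell_id,X,Y``), one profile per cell_id."""
    df = pd.read_csv(path, dtype={"cell_id": str})
    if not {"cell_id", "X", "Y"}.issubset(df.columns):
        raise ValueError(f"profile CSV {path}: expected columns cell_id,X,Y")
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        out.append(
            _profile_from_xy(
                grp["X"].to_numpy(dtype=float),
                grp["Y"].to_numpy(dtype=float),
                str(cell_id),
            )
        )
    return out
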
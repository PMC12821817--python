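"""Per-cell vacuole-morphology metrics and the matched results table.

Two metrics are computed per cell:

* TTI (Tonoplast Topology Index) — the number of tonoplast–transect crossings
  along the cell's diagonal transect divided by the transect length, in
  crossings per micrometer. Higher TTI means a more complex vacuome.
* VMI (Vacuolar Morphology Index) — length times width of the largest
  vacuolar compartment section, in µm²; supplied from manual measurements and
  usually log-transformed before statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import IntensityProfile, Transect, transect_length
from .peakcall import PeakSet

__all__ = [
    "CellMeasurement",
    "compute_tti",
    "compute_vmi",
    "log_transform_vmi",
    "assemble_table",
    "measurements_to_frame",
    "write_results_csv",
    "read_results_csv",
    "read_vmi_csv",
]

RESULTS_COLUMNS = [
    "cell_id",
    "root_id",
    "group",
    "direction_label",
    "cell_length_um",
    "transect_length_um",
    "n_crossings",
    "tti_per_um",
    "vmi_um2",
    "log_vmi",
]


@dataclass
class CellMeasurement:
    """One cell's matched morphometric record."""

    cell_id: str
    transect_length_um: float
    crossing_count: int
    tti_per_um: float
    root_id: str = ""
    group: str = ""
    direction_label: str = ""
    cell_length_um: float | None = None
    vmi_um2: float | None = None
    log_vmi: float | None = None

    def __post_init__(self) -> None:
        if not self.transect_length_um > 0:
            raise ValueError(f"cell {self.cell_id!r}: transect length must be positive")
        if self.crossing_count < 0:
            raise ValueError(f"cell {self.cell_id!r}: crossing count must be >= 0")
        expected = self.crossing_count / self.transect_length_um
        if abs(self.tti_per_um - expected) > 1e-12 * max(expected, 1e-300):
            raise ValueError(f"cell {self.cell_id!r}: tti_per_um inconsistent with count/length")
        if self.cell_length_um is not None and not self.cell_length_um > 0:
            raise ValueError(f"cell {self.cell_id!r}: cell length must be positive")
        if self.vmi_um2 is not None and self.vmi_um2 < 0:
            raise ValueError(f"cell {self.cell_id!r}: VMI must be >= 0")


def compute_tti(crossing_count: int, transect_length_um: float, cell_id: str = "?") -> float:
    """TTI = crossings / diagonal transect length (per µm)."""
    if not transect_length_um > 0:
        raise ValueError(f"cell {cell_id!r}: transect length must be positive")
    if crossing_count < 0 or int(crossing_count) != crossing_count:
        raise ValueError(f"cell {cell_id!r}: crossing count must be a non-negative integer")
    return crossing_count / transect_length_um


def compute_vmi(length_um: float, width_um: float) -> float:
    """VMI = length x width of the largest compartment section (µm²)."""
    if length_um < 0 or width_um < 0:
        raise ValueError("VMI length and width must be >= 0")
    return length_um * width_um


def log_transform_vmi(vmi_um2: float) -> float:
    """Natural logarithm of a positive VMI value."""
    if not vmi_um2 > 0:
        raise ValueError("VMI must be positive for log transform")
    return math.log(vmi_um2)


def _by_cell(transects: Iterable[Transect], kind: str) -> dict[str, Transect]:
    out: dict[str, Transect] = {}
    for t in transects:
        if t.kind != kind:
            continue
        if t.cell_id in out:
            raise ValueError(f"duplicate {kind} transect for cell {t.cell_id!r}")
        out[t.cell_id] = t
    return out


def assemble_table(
    profiles: Sequence[IntensityProfile],
    peaksets: Sequence[PeakSet],
    transects: Sequence[Transect],
    pixel_size_um: float,
    vmi_records: Mapping[str, tuple[float, float]] | None = None,
    labels: Mapping[str, Mapping[str, str]] | None = None,
) -> list[CellMeasurement]:
    """Assemble one matched row per cell.

    TTI comes from the diagonal transect (via its profile and peak set); cell
    length from the longitudinal transect with the same cell_id. Cells without
    a longitudinal transect keep an absent ``cell_length_um`` rather than
    being dropped. ``vmi_records`` maps cell_id to manually measured
    (length_um, width_um) of the largest compartment; ``labels`` may supply
    ``root_id`` / ``group`` per cell. Duplicate transects for one cell within
    one role are an error (cell sets must be non-redundant).
    """
    diagonals = _by_cell(transects, "diagonal")
    longitudinals = _by_cell(transects, "longitudinal")
    profile_by_cell: dict[str, IntensityProfile] = {}
    for p in profiles:
        if p.cell_id in profile_by_cell:
            raise ValueError(f"duplicate profile for cell {p.cell_id!r}")
        profile_by_cell[p.cell_id] = p
    rows: list[CellMeasurement] = []
    for ps in peaksets:
        cid = ps.cell_id
        if cid not in diagonals:
            raise ValueError(f"no diagonal transect for cell {cid!r}")
        profile = profile_by_cell.get(cid)
        if profile is None:
            raise ValueError(f"no profile for cell {cid!r}")
        length = profile.transect_length_um
        lon = longitudinals.get(cid)
        cell_length = transect_length(lon, pixel_size_um) if lon is not None else None
        vmi = log_vmi = None
        if vmi_records is not None and cid in vmi_records:
            l, w = vmi_records[cid]
            vmi = compute_vmi(l, w)
            log_vmi = log_transform_vmi(vmi) if vmi > 0 else None
        meta = dict(labels.get(cid, {})) if labels is not None else {}
        rows.append(
            CellMeasurement(
                cell_id=cid,
                root_id=str(meta.get("root_id", "")),
                group=str(meta.get("group", "")),
                direction_label=diagonals[cid].direction_label,
                cell_length_um=cell_length,
                transect_length_um=length,
                crossing_count=ps.count,
                tti_per_um=compute_tti(ps.count, length, cid),
                vmi_um2=vmi,
                log_vmi=log_vmi,
            )
        )
    return rows


def measurements_to_frame(rows: Sequence[CellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "root_id": r.root_id,
                "group": r.group,
                "direction_label": r.direction_label,
                "cell_length_um": r.cell_length_um,
                "transect_length_um": r.transect_length_um,
                "n_crossings": r.crossing_count,
                "tti_per_um": r.tti_per_um,
                "vmi_um2": r.vmi_um2,
                "log_vmi": r.log_vmi,
            }
            for r in rows
        ],
        columns=RESULTS_COLUMNS,
    )


def write_results_csv(rows: Sequence[CellMeasurement], path: str | Path) -> None:
    """Write the per-cell results table; missing optionals become empty fields."""
    measurements_to_frame(rows).to_csv(path, index=False, float_format="%.6g")


def read_results_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "root_id": str, "group": str})
    missing = set(RESULTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"results CSV {path}: missing columns {sorted(missing)}")
    return df


def read_vmi_csv(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read manual VMI measurements (``cell_id,largest_length_um,largest_width_um``)."""
    df = pd.read_csv(path, dtype={"cell_id": str})
    need = {"cell_id", "largest_length_um", "largest_width_um"}
    if not need.issubset(df.columns):
        raise ValueError(f"VMI CSV {path}: expected columns {sorted(need)}")
    out: dict[str, tuple[float, float]] = {}
    for row in df.itertuples(index=False):
        cid = str(row.cell_id)
        if cid in out:
            raise ValueError(f"duplicate VMI record for cell {cid!r}")
        out[cid] = (float(row.largest_length_um), float(row.largest_width_um))
    return out
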
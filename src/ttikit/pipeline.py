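"""Glue between stages: image -> profile -> peaks -> per-cell table.

Thin convenience layer used by the CLI, the test suite and the acceptance
script; the science lives in :mod:`imaging`, :mod:`peakcall`, :mod:`metrics`
and :mod:`synth`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .imaging import ImageStack, IntensityProfile, Transect, extract_profile, smooth_image
from .metrics import compute_tti, log_transform_vmi
from .peakcall import PeakParams, PeakSet, detect_crossings, misdetection_rate
from .synth import SimulatedCell

__all__ = ["analyze_transect", "misdetection_summary", "measure_simulated_cells"]


def analyze_transect(
    img: ImageStack, transect: Transect, params: PeakParams
) -> tuple[IntensityProfile, PeakSet]:
    """Stage 1 + 2 for one transect: smooth the image, sample, call peaks."""
    smoothed = smooth_image(img, params.smooth_rounds)
    profile = extract_profile(smoothed, transect)
    return profile, detect_crossings(profile, params)


def misdetection_summary(
    cells: Sequence[SimulatedCell],
    params: PeakParams,
    tolerance_um: float = 0.5,
) -> dict:
    """Detection-quality summary against analytic truth.

    Returns mean per-transect errors, the overall misdetected fraction
    (total errors over total true crossings) and the per-cell breakdown.
    """
    records = []
    total_errors = 0
    total_truth = 0
    for cell in cells:
        _, peaks = analyze_transect(cell.image, cell.diagonal, params)
        errors, fraction = misdetection_rate(peaks, cell.truth_positions_um, tolerance_um)
        total_errors += errors
        total_truth += len(cell.truth_positions_um)
        records.append(
            {
                "cell_id": cell.cell_id,
                "n_truth": len(cell.truth_positions_um),
                "n_detected": peaks.count,
                "errors": errors,
                "fraction": fraction,
            }
        )
    per_cell = pd.DataFrame.from_records(records)
    return {
        "mean_errors_per_transect": float(per_cell["errors"].mean()),
        "overall_fraction": total_errors / total_truth if total_truth else 0.0,
        "n_cells": len(records),
        "n_truth": total_truth,
        "n_errors": total_errors,
        "per_cell": per_cell,
    }


def measure_simulated_cells(
    cells: Sequence[SimulatedCell], params: PeakParams
) -> pd.DataFrame:
    """Run the full pipeline on simulated cells and tabulate per-cell metrics.

    TTI comes from detection on the rendered image; VMI is the analytic
    ground truth of the generating geometry (the simulated counterpart of a
    manual measurement).
    """
    rows = []
    for cell in cells:
        profile, peaks = analyze_transect(cell.image, cell.diagonal, params)
        vmi = cell.vmi_truth_um2
        rows.append(
            {
                "cell_id": cell.cell_id,
                "group": cell.population,
                "direction_label": cell.diagonal.direction_label,
                "cell_length_um": cell.spec.cell_w_um,
                "transect_length_um": profile.transect_length_um,
                "n_crossings": peaks.count,
                "n_truth": len(cell.truth_positions_um),
                "tti_per_um": compute_tti(peaks.count, profile.transect_length_um),
                "tti_truth_per_um": compute_tti(
                    len(cell.truth_positions_um), profile.transect_length_um
                ),
                "vmi_um2": vmi,
                "log_vmi": log_transform_vmi(vmi) if vmi > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
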
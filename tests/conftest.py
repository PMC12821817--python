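from __future__ import annotations

import numpy as np
import pytest

from ttikit.imaging import ImageStack, IntensityProfile, Transect
from ttikit.peakcall import PeakParams
from ttikit.synth import Ellipse, SyntheticCellSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def default_params():
    return PeakParams()


@pytest.fixture
def flat_image():
    return ImageStack(pixels=np.full((20, 30), 7, dtype=np.uint8), pixel_size_um=0.1)


@pytest.fixture
def one_circle_spec():
    """A 12x8 µm cell with one centered circular compartment of radius 2.5 µm."""
    return SyntheticCellSpec(
        cell_id="circle",
        cell_w_um=12.0,
        cell_h_um=8.0,
        compartments=[Ellipse(6.0, 4.0, 2.5, 2.5)],
    )


def make_profile(intensity, spacing_um=0.1, cell_id="p"):
    intensity = np.asarray(intensity, dtype=float)
    n = len(intensity)
    distance = np.arange(n) / (n - 1) * ((n - 1) * spacing_um)
    return IntensityProfile(
        cell_id=cell_id,
        distance_um=distance,
        intensity=intensity,
        transect_length_um=(n - 1) * spacing_um,
    )


@pytest.fixture
def profile_factory():
    return make_profile
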
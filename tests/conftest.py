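"""Shared fixtures: phantoms and solved deformation fields at a few sizes.

Solves are session-scoped because the 32-voxel-cube systems take a few
seconds each; tests treat the returned objects as read-only.
"""

import numpy as np
import pytest
from scipy import ndimage

from atrophysim import (
    AtrophyMap,
    DisplacementField,
    ModelParams,
    PhantomSpec,
    RoiAtrophyTable,
    atrophy_from_table,
    make_phantom,
    solve_deformation,
)


@pytest.fixture(scope="session")
def phantom16():
    spec = PhantomSpec.for_shape((16, 16, 16), seed=7)
    baseline, labels, rois = make_phantom(spec)
    return spec, baseline, labels, rois


@pytest.fixture(scope="session")
def atrophy16(phantom16):
    _, _, labels, rois = phantom16
    return atrophy_from_table(rois, RoiAtrophyTable({1: 0.05, 17: 0.05}), labels)


@pytest.fixture(scope="session")
def sol16(phantom16, atrophy16):
    _, _, labels, _ = phantom16
    return solve_deformation(labels, atrophy16, ModelParams(scheme="twelve_point"))


@pytest.fixture(scope="session")
def phantom8():
    spec = PhantomSpec.for_shape((8, 8, 8), seed=3)
    baseline, labels, rois = make_phantom(spec)
    return spec, baseline, labels, rois


@pytest.fixture(scope="session")
def atrophy8(phantom8):
    _, _, labels, rois = phantom8
    return atrophy_from_table(rois, RoiAtrophyTable({1: 0.04}), labels)


@pytest.fixture(scope="session")
def phantom32():
    spec = PhantomSpec.for_shape((32, 32, 32), seed=1)
    baseline, labels, rois = make_phantom(spec)
    return spec, baseline, labels, rois


@pytest.fixture(scope="session")
def atrophy32(phantom32):
    _, _, labels, rois = phantom32
    return atrophy_from_table(rois, RoiAtrophyTable({1: 0.05, 17: 0.05}), labels)


@pytest.fixture(scope="session")
def sol32_twelve(phantom32, atrophy32):
    _, _, labels, _ = phantom32
    return solve_deformation(labels, atrophy32, ModelParams(scheme="twelve_point"))


@pytest.fixture(scope="session")
def sol32_six(phantom32, atrophy32):
    _, _, labels, _ = phantom32
    return solve_deformation(labels, atrophy32, ModelParams(scheme="six_point"))


def smooth_tapered_field(shape, seed, max_mm=0.8, sigma=2.0):
    """Smooth random displacement field vanishing at the domain boundary."""
    rng = np.random.default_rng(seed)
    values = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, (*shape, 3)), (sigma, sigma, sigma, 0)
    )
    window = np.ones(shape)
    for ax in range(3):
        ramp = np.minimum(np.arange(shape[ax]), np.arange(shape[ax])[::-1])
        ramp = np.clip(ramp, 0, 3) / 3.0
        sl = [None, None, None]
        sl[ax] = slice(None)
        window = window * ramp[tuple(sl)]
    values *= window[..., None]
    values *= max_mm / max(np.abs(values).max(), 1e-12)
    return values


@pytest.fixture()
def smooth_field16():
    from atrophysim import ImageGrid

    grid = ImageGrid(shape=(16, 16, 16))
    return DisplacementField(grid, smooth_tapered_field((16, 16, 16), seed=42))
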
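"""Image warping by the pull-back action Φ⋆I = I ∘ Φ⁻¹.

Intensities are pulled through the *inverse* field: the output value at voxel
``y`` is interpolated from the source image at ``y + u_inv(y)``.  Pulling
avoids the scattered-data interpolation a forward push would need.  Callers
holding the forward field pass ``field_is_inverse=False`` and the field is
inverted by fixed-point iteration first.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .fields import _identity_coords, invert_field, mm_to_voxel_offsets
from .images import (
    DisplacementField,
    LabelImage,
    RoiSegmentation,
    ScalarImage,
    assert_same_space,
)

__all__ = ["warp_image", "warp_labels"]

logger = logging.getLogger(__name__)


def _pull_coords(field: DisplacementField) -> np.ndarray:
    return _identity_coords(field.grid.shape) + np.moveaxis(
        mm_to_voxel_offsets(field.grid, field.values), -1, 0
    )


def _count_outside(coords: np.ndarray, shape) -> int:
    outside = np.zeros(coords.shape[1:], dtype=bool)
    for ax in range(3):
        outside |= (coords[ax] < 0) | (coords[ax] > shape[ax] - 1)
    return int(outside.sum())


def _nearest_pull(values: np.ndarray, coords: np.ndarray, fill) -> np.ndarray:
    # round-half-toward-lower-index for platform-independent tie-breaking
    idx = np.ceil(coords - 0.5).astype(np.int64)
    inb = np.ones(idx.shape[1:], dtype=bool)
    for ax in range(3):
        inb &= (idx[ax] >= 0) & (idx[ax] < values.shape[ax])
    out = np.full(idx.shape[1:], fill, dtype=values.dtype)
    out[inb] = values[idx[0][inb], idx[1][inb], idx[2][inb]]
    return out


def warp_image(
    img: ScalarImage,
    field: DisplacementField,
    field_is_inverse: bool = False,
    interpolation_order: int = 3,
) -> ScalarImage:
    """Warp a scalar image by a deformation field (B-spline interpolation).

    With ``field_is_inverse=False`` (the default) ``field`` is the forward
    displacement ``u`` of ``Φ(x) = x + u(x)`` and is inverted internally;
    pass ``True`` when supplying a pre-inverted field.  Out-of-domain pulls
    return 0 and are counted in the log.  ``interpolation_order`` 0–5,
    default cubic B-spline.
    """
    assert_same_space(img, field)
    if not 0 <= interpolation_order <= 5:
        raise ValueError("interpolation_order must be in 0..5")
    inv = field if field_is_inverse else invert_field(field)
    coords = _pull_coords(inv)
    n_out = _count_outside(coords, img.grid.shape)
    if n_out:
        logger.info("warp_image: %d out-of-domain pulls set to 0", n_out)
    if interpolation_order == 0:
        values = _nearest_pull(img.values, coords, 0.0)
    else:
        values = ndimage.map_coordinates(
            img.values,
            coords,
            order=interpolation_order,
            mode="constant",
            cval=0.0,
            prefilter=interpolation_order > 1,
        )
    return type(img)(img.grid, values) if not img._integer_valued else ScalarImage(
        img.grid, values
    )


def warp_labels(
    labels: LabelImage | RoiSegmentation,
    field: DisplacementField,
    field_is_inverse: bool = False,
):
    """Warp an integer segmentation with nearest-neighbor pulls.

    No new label values can appear; out-of-domain pulls become background (0).
    Returns the same segmentation type as the input.
    """
    assert_same_space(labels, field)
    inv = field if field_is_inverse else invert_field(field)
    coords = _pull_coords(inv)
    values = _nearest_pull(labels.values, coords, 0)
    return type(labels)(labels.grid, values)
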
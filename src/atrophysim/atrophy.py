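"""Construction of prescribed atrophy maps.

An atrophy map holds the fractional volume loss per time step,
``a = (V0 - V1)/V0``, at every voxel of the prescribed (Label 2) region and
zero elsewhere.  Maps can be built from an ROI table (uniform value per
anatomical region), from the negative divergence of a stationary velocity
field (smoothly varying, registration-derived patterns), or smoothed into
region-wise averages.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import divergence_centered
from .images import (
    AtrophyMap,
    DisplacementField,
    LabelImage,
    RoiSegmentation,
    assert_same_space,
)

__all__ = [
    "RoiAtrophyTable",
    "atrophy_from_table",
    "atrophy_from_velocity",
    "regionwise_average",
]


@dataclass
class RoiAtrophyTable:
    """Mapping from ROI label to per-step atrophy value."""

    entries: dict[int, float]

    def __post_init__(self) -> None:
        entries = {int(k): float(v) for k, v in self.entries.items()}
        if not all(np.isfinite(list(entries.values()) or [0.0])):
            raise ValueError("atrophy table values must be finite")
        self.entries = entries

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "RoiAtrophyTable":
        """Read a two-column CSV (label,value); a header row is optional."""
        df = pd.read_csv(path, header=None, comment="#")
        try:
            int(df.iloc[0, 0])
        except (TypeError, ValueError):
            df = df.iloc[1:]
        labels = df.iloc[:, 0].astype(int)
        if labels.duplicated().any():
            raise ValueError("duplicate ROI labels in atrophy table")
        return cls(dict(zip(labels, df.iloc[:, 1].astype(float))))


def atrophy_from_table(
    rois: RoiSegmentation, table: RoiAtrophyTable, model_labels: LabelImage
) -> AtrophyMap:
    """Uniform per-ROI atrophy, restricted to the prescribed (Label 2) region.

    ROIs listed in the table but absent from the segmentation produce a
    warning, not an error.
    """
    assert_same_space(rois, model_labels)
    present = set(np.unique(rois.values).tolist())
    missing = sorted(set(table.entries) - present)
    if missing:
        warnings.warn(f"atrophy table references absent ROI labels: {missing}")
    values = np.zeros(rois.grid.shape)
    prescribed = model_labels.values == 2
    for label, atrophy in table.entries.items():
        values[(rois.values == label) & prescribed] = atrophy
    return AtrophyMap(rois.grid, values)


def atrophy_from_velocity(
    svf: DisplacementField, model_labels: LabelImage, negate: bool = False
) -> AtrophyMap:
    """Smooth atrophy as the negative divergence of a stationary velocity field.

    Registration-derived velocity fields encode local expansion as positive
    divergence, so ``a = -div(v)`` marks shrinking regions with positive
    atrophy.  ``negate=True`` flips the sign to turn an atrophy pattern into
    the corresponding growth pattern.
    """
    assert_same_space(svf, model_labels)
    values = -divergence_centered(svf).values
    if negate:
        values = -values
    values[model_labels.values != 2] = 0.0
    return AtrophyMap(svf.grid, values)


def regionwise_average(
    amap: AtrophyMap,
    rois: RoiSegmentation,
    model_labels: LabelImage | None = None,
) -> AtrophyMap:
    """Replace the map by its mean over each ROI (piecewise-constant output).

    Means are taken over ROI ∩ prescribed region with voxel-count weights
    (uniform spacing within one image), so the total prescribed volume change
    per ROI is preserved exactly and piecewise-constant maps are fixed
    points.  ROI label 0 is background and left untouched.  An ROI with no
    prescribed voxel gets value 0 with a warning.
    """
    assert_same_space(amap, rois)
    if model_labels is not None:
        assert_same_space(amap, model_labels)
        prescribed = model_labels.values == 2
    else:
        prescribed = np.ones(amap.grid.shape, dtype=bool)
    out = np.zeros(amap.grid.shape)
    for label in np.unique(rois.values):
        if label == 0:
            continue
        mask = (rois.values == label) & prescribed
        if not mask.any():
            warnings.warn(f"ROI {label} has no prescribed voxel; average set to 0")
            continue
        out[mask] = amap.values[mask].mean()
    return AtrophyMap(amap.grid, out)
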
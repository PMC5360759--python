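"""Image and field containers with spatial metadata, plus NIfTI/MetaImage I/O.

Every object in the pipeline lives on a regular 3D grid described by an
:class:`ImageGrid` (shape, spacing in mm, origin in mm, direction cosines).
Arrays are indexed ``(i, j, k)`` along the grid axes (x, y, z); voxel
``(i, j, k)`` has its center at ``origin + direction @ (i*hx, j*hy, k*hz)``.

Displacement fields are stored in physical units (mm), in world coordinates,
matching the vector-NIfTI convention of external registration tools.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageGrid",
    "ScalarImage",
    "LabelImage",
    "AtrophyMap",
    "RoiSegmentation",
    "DisplacementField",
    "read_image",
    "read_label_image",
    "read_roi_segmentation",
    "read_displacement_field",
    "write_image",
    "assert_same_space",
    "GridMismatchError",
]

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


class GridMismatchError(ValueError):
    """Two images that must share a grid do not."""


@dataclass(frozen=True)
class ImageGrid:
    """Regular 3D sampling grid: shape, spacing (mm), origin (mm), direction."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        direction = tuple(float(d) for d in self.direction)
        D = np.asarray(direction).reshape(3, 3)
        if not np.allclose(D @ D.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal within 1e-6")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``(*shape, 3)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        ).astype(float)
        local = idx * np.asarray(self.spacing)
        return np.asarray(self.origin) + local @ self.direction_matrix.T


def _check_values(grid: ImageGrid, values: np.ndarray, ncomp: int | None) -> np.ndarray:
    values = np.asarray(values)
    expected = grid.shape if ncomp is None else (*grid.shape, ncomp)
    if values.shape != expected:
        raise ValueError(f"values shape {values.shape} != grid shape {expected}")
    return values


@dataclass
class ScalarImage:
    """A real scalar per voxel (intensity, atrophy, pressure, Jacobian ...)."""

    grid: ImageGrid
    values: np.ndarray

    _integer_valued = False

    def __post_init__(self) -> None:
        self.values = _check_values(self.grid, self.values, None).astype(
            np.float64, copy=False
        )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar image contains non-finite values")

    def copy(self) -> "ScalarImage":
        return dataclasses.replace(self, values=self.values.copy())


@dataclass
class AtrophyMap(ScalarImage):
    """Per-voxel fractional volume loss per time step, a = (V0 - V1)/V0.

    Positive values prescribe shrinkage, negative values growth; the map is
    zero wherever no volume change is prescribed.  Values must stay below 1
    (a voxel cannot lose more than its whole volume in one step).
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values >= 1.0):
            raise ValueError("atrophy values must be < 1 (full voxel loss)")


class _IntegerImage(ScalarImage):
    _integer_valued = True

    def __post_init__(self) -> None:
        values = _check_values(self.grid, np.asarray(self.values), None)
        if not np.issubdtype(values.dtype, np.integer):
            rounded = np.rint(values)
            if not np.array_equal(rounded, values):
                raise ValueError("label image values must be integers")
            values = rounded.astype(np.int32)
        self.values = values.astype(np.int32, copy=False)


@dataclass
class LabelImage(_IntegerImage):
    """Three-regime model segmentation.

    Label 0: rigid region (skull and background) — zero displacement enforced.
    Label 1: freely compressible region (CSF) — compensates prescribed change.
    Label 2: prescribed-divergence region (brain parenchyma).
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        bad = np.setdiff1d(np.unique(self.values), [0, 1, 2])
        if bad.size:
            raise ValueError(
                f"label image must only contain values {{0,1,2}}; found {bad.tolist()}"
            )


@dataclass
class RoiSegmentation(_IntegerImage):
    """Integer ROI parcellation (arbitrary non-negative label set)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise ValueError("ROI labels must be non-negative")


@dataclass
class DisplacementField:
    """One 3-vector (mm, world coordinates) per voxel center."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_values(self.grid, self.values, 3).astype(
            np.float64, copy=False
        )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("displacement field contains non-finite values")

    @classmethod
    def zeros(cls, grid: ImageGrid) -> "DisplacementField":
        return cls(grid, np.zeros((*grid.shape, 3)))

    def copy(self) -> "DisplacementField":
        return dataclasses.replace(self, values=self.values.copy())

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.values**2).sum(axis=-1)).max())


# ---------------------------------------------------------------------------
# I/O (SimpleITK handles NIfTI-1 and MetaImage)
# ---------------------------------------------------------------------------


def _check_ext(path: str) -> None:
    low = str(path).lower()
    if not low.endswith(_SUPPORTED_EXT):
        raise ValueError(
            f"unsupported image format for {path!r}; expected one of {_SUPPORTED_EXT}"
        )


def _grid_from_sitk(img: sitk.Image) -> ImageGrid:
    return ImageGrid(
        shape=tuple(img.GetSize()),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        direction=tuple(img.GetDirection()),
    )


def _sitk_from_grid(grid: ImageGrid, img: sitk.Image) -> sitk.Image:
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    img.SetDirection(grid.direction)
    return img


def read_image(path: str | os.PathLike) -> ScalarImage:
    """Read a scalar NIfTI/MetaImage file."""
    _check_ext(str(path))
    img = sitk.ReadImage(str(path))
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(f"{path!r} is a vector image; use read_displacement_field")
    values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return ScalarImage(_grid_from_sitk(img), values.astype(np.float64))


def read_label_image(path: str | os.PathLike) -> LabelImage:
    """Read a 3-regime segmentation; validates the {0,1,2} value range."""
    scalar = read_image(path)
    return LabelImage(scalar.grid, scalar.values)


def read_roi_segmentation(path: str | os.PathLike) -> RoiSegmentation:
    scalar = read_image(path)
    return RoiSegmentation(scalar.grid, scalar.values)


def read_displacement_field(path: str | os.PathLike) -> DisplacementField:
    """Read a 3-component vector image (component order x, y, z)."""
    _check_ext(str(path))
    img = sitk.ReadImage(str(path))
    if img.GetNumberOfComponentsPerPixel() != 3:
        raise ValueError(
            f"{path!r} has {img.GetNumberOfComponentsPerPixel()} components; expected 3"
        )
    values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0, 3))
    return DisplacementField(_grid_from_sitk(img), values.astype(np.float64))


def write_image(image: ScalarImage | DisplacementField, path: str | os.PathLike) -> None:
    """Write to NIfTI/MetaImage; the extension selects the format.

    Labels are stored as 32-bit integers, scalars and vectors as 64-bit
    floats so round trips are bit exact.
    """
    _check_ext(str(path))
    if isinstance(image, DisplacementField):
        arr = np.ascontiguousarray(np.transpose(image.values, (2, 1, 0, 3)))
        img = sitk.GetImageFromArray(arr, isVector=True)
    elif image._integer_valued:
        arr = np.ascontiguousarray(np.transpose(image.values.astype(np.int32), (2, 1, 0)))
        img = sitk.GetImageFromArray(arr)
    else:
        arr = np.ascontiguousarray(np.transpose(image.values, (2, 1, 0)))
        img = sitk.GetImageFromArray(arr)
    sitk.WriteImage(_sitk_from_grid(image.grid, img), str(path))


def assert_same_space(a, b, tol: float = 1e-4) -> None:
    """Raise :class:`GridMismatchError` unless two objects share a grid.

    Shapes must match exactly; spacing, origin and direction must agree within
    ``tol`` (mm for lengths).  The error names the first differing field.
    """
    ga, gb = a.grid, b.grid
    if ga.shape != gb.shape:
        raise GridMismatchError(f"shape mismatch: {ga.shape} vs {gb.shape}")
    for name in ("spacing", "origin", "direction"):
        va = np.asarray(getattr(ga, name))
        vb = np.asarray(getattr(gb, name))
        if np.max(np.abs(va - vb)) > tol:
            raise GridMismatchError(
                f"{name} mismatch beyond tol={tol}: {va.tolist()} vs {vb.tolist()}"
            )
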
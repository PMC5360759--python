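"""Deformation-field calculus: divergence stencils, Jacobians, composition,
fixed-point inversion, and the staggered (MAC) face layout.

Two divergence discretisations coexist deliberately:

* **6-point** (face-based): per cell, the difference of the two bounding face
  values per axis divided by the spacing — the natural stencil on a staggered
  grid.
* **centered / 12-point**: the centered difference of center-sampled values,
  the default stencil of common morphometry toolchains.  Applied to the
  face-averaged center field it expands into a 12-face stencil per cell.

The two disagree at discontinuities of the solved field's divergence, which is
exactly why the solver lets callers pick which one its constraint rows use.
Jacobian determinants here use the same centered stencil as
:func:`divergence_centered`, so ``J - 1`` and ``div u`` agree to first order —
ground truth must be computed with the same scheme as the measurement that
consumes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import (
    DisplacementField,
    ImageGrid,
    ScalarImage,
    assert_same_space,
)

__all__ = [
    "StaggeredField",
    "face_to_center",
    "center_to_face",
    "divergence_staggered",
    "divergence_centered",
    "jacobian_determinant",
    "compose_fields",
    "invert_field",
    "FieldInversionError",
]

logger = logging.getLogger(__name__)


class FieldInversionError(RuntimeError):
    """Fixed-point inversion failed to converge."""


@dataclass
class StaggeredField:
    """Face-centered velocity components (MAC layout), units mm.

    ``u`` lives on x-faces (shape ``(nx+1, ny, nz)``), ``v`` on y-faces,
    ``w`` on z-faces.  Cell ``(i,j,k)`` is bounded by x-faces ``i`` and
    ``i+1`` of ``u``, etc.
    """

    grid: ImageGrid
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        nx, ny, nz = self.grid.shape
        for arr, shape, name in (
            (self.u, (nx + 1, ny, nz), "u"),
            (self.v, (nx, ny + 1, nz), "v"),
            (self.w, (nx, ny, nz + 1), "w"),
        ):
            if arr.shape != shape:
                raise ValueError(f"{name} component has shape {arr.shape}, expected {shape}")
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)

    @classmethod
    def zeros(cls, grid: ImageGrid) -> "StaggeredField":
        nx, ny, nz = grid.shape
        return cls(
            grid,
            np.zeros((nx + 1, ny, nz)),
            np.zeros((nx, ny + 1, nz)),
            np.zeros((nx, ny, nz + 1)),
        )


def face_to_center(sf: StaggeredField) -> DisplacementField:
    """Average each pair of bounding faces onto the cell center.

    ``u_{i,j,k} = (u_{i+1/2,j,k} + u_{i-1/2,j,k}) / 2`` per component; exact
    for fields linear along the face axis.
    """
    values = np.stack(
        [
            0.5 * (sf.u[1:, :, :] + sf.u[:-1, :, :]),
            0.5 * (sf.v[:, 1:, :] + sf.v[:, :-1, :]),
            0.5 * (sf.w[:, :, 1:] + sf.w[:, :, :-1]),
        ],
        axis=-1,
    )
    return DisplacementField(sf.grid, values)


def center_to_face(f: DisplacementField) -> StaggeredField:
    """Interpolate center values onto faces (inverse-direction helper).

    Interior faces average the two adjacent centers; boundary faces copy the
    single adjacent center.  Used only for constructing staggered test fields.
    """
    nx, ny, nz = f.grid.shape
    sf = StaggeredField.zeros(f.grid)
    u, v, w = f.values[..., 0], f.values[..., 1], f.values[..., 2]
    sf.u[1:-1, :, :] = 0.5 * (u[1:, :, :] + u[:-1, :, :])
    sf.u[0, :, :] = u[0, :, :]
    sf.u[-1, :, :] = u[-1, :, :]
    sf.v[:, 1:-1, :] = 0.5 * (v[:, 1:, :] + v[:, :-1, :])
    sf.v[:, 0, :] = v[:, 0, :]
    sf.v[:, -1, :] = v[:, -1, :]
    sf.w[:, :, 1:-1] = 0.5 * (w[:, :, 1:] + w[:, :, :-1])
    sf.w[:, :, 0] = w[:, :, 0]
    sf.w[:, :, -1] = w[:, :, -1]
    return sf


def divergence_staggered(sf: StaggeredField) -> ScalarImage:
    """6-point face-based divergence, one value per cell."""
    hx, hy, hz = sf.grid.spacing
    div = (
        (sf.u[1:, :, :] - sf.u[:-1, :, :]) / hx
        + (sf.v[:, 1:, :] - sf.v[:, :-1, :]) / hy
        + (sf.w[:, :, 1:] - sf.w[:, :, :-1]) / hz
    )
    return ScalarImage(sf.grid, div)


def divergence_centered(f: DisplacementField) -> ScalarImage:
    """Centered-difference divergence of a center-sampled field.

    Interior voxels use ``(u_{i+1} - u_{i-1}) / (2 h_x) + ...``; boundary
    voxels fall back to one-sided first-order differences.
    """
    div = np.zeros(f.grid.shape)
    for axis in range(3):
        div += np.gradient(f.values[..., axis], f.grid.spacing[axis], axis=axis)
    return ScalarImage(f.grid, div)


def _displacement_gradient(f: DisplacementField) -> np.ndarray:
    """∇u with the same centered stencil as divergence_centered; shape (*s,3,3)."""
    G = np.empty((*f.grid.shape, 3, 3))
    for comp in range(3):
        for axis in range(3):
            G[..., comp, axis] = np.gradient(
                f.values[..., comp], f.grid.spacing[axis], axis=axis
            )
    return G


def jacobian_determinant(f: DisplacementField) -> ScalarImage:
    """det(I + ∇u): local ratio of warped to original voxel volume (V1/V0)."""
    G = _displacement_gradient(f)
    F = G + np.eye(3)
    det = (
        F[..., 0, 0] * (F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1])
        - F[..., 0, 1] * (F[..., 1, 0] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 0])
        + F[..., 0, 2] * (F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0])
    )
    return ScalarImage(f.grid, det)


# ---------------------------------------------------------------------------
# sampling helpers: mm displacements <-> voxel offsets
# ---------------------------------------------------------------------------


def mm_to_voxel_offsets(grid: ImageGrid, disp_mm: np.ndarray) -> np.ndarray:
    """Convert world-mm displacement vectors into index-space offsets."""
    local = disp_mm @ grid.direction_matrix  # D^T u, as (u @ D)
    return local / np.asarray(grid.spacing)


def _identity_coords(shape: tuple[int, int, int]) -> np.ndarray:
    return np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"), axis=0
    )


def _sample_field(
    f: DisplacementField, coords: np.ndarray
) -> tuple[np.ndarray, int]:
    """Trilinear sample of a displacement field at fractional voxel coords.

    ``coords`` has shape ``(3, *out_shape)``.  Samples falling outside the
    domain use zero-displacement extension (consistent with the Dirichlet
    boundary); the count of such samples is returned.
    """
    sampled = np.stack(
        [
            ndimage.map_coordinates(
                f.values[..., c], coords, order=1, mode="constant", cval=0.0
            )
            for c in range(3)
        ],
        axis=-1,
    )
    upper = np.asarray(f.grid.shape, dtype=float) - 1.0
    outside = np.zeros(coords.shape[1:], dtype=bool)
    for ax in range(3):
        outside |= (coords[ax] < 0) | (coords[ax] > upper[ax])
    return sampled, int(outside.sum())


def compose_fields(
    outer: DisplacementField, inner: DisplacementField
) -> DisplacementField:
    """Displacement of Φ_outer ∘ Φ_inner: ``u(x) = u_out(x + u_in(x)) + u_in(x)``.

    The outer field is sampled trilinearly at the inner-displaced positions;
    out-of-domain samples extend by zero (fields vanish at the boundary by
    construction) with a logged count.
    """
    assert_same_space(outer, inner)
    coords = _identity_coords(inner.grid.shape) + np.moveaxis(
        mm_to_voxel_offsets(inner.grid, inner.values), -1, 0
    )
    sampled, n_outside = _sample_field(outer, coords)
    if n_outside:
        logger.info("compose_fields: %d samples outside domain (zero-extended)", n_outside)
    return DisplacementField(inner.grid, sampled + inner.values)


def invert_field(
    f: DisplacementField,
    tol: float | None = None,
    max_iter: int = 100,
) -> DisplacementField:
    """Invert a displacement field by fixed-point iteration.

    Iterates ``v_{n+1}(y) = -u(y + v_n(y))`` from ``v_0 = 0`` until the
    largest update falls below ``tol`` (default ``1e-3 * min(spacing)`` mm).
    The result ``v`` satisfies ``Φ^{-1}(y) = y + v(y)`` for the forward map
    ``Φ(x) = x + u(x)``; convergence requires the field to be small enough to
    be invertible (contraction, roughly ``‖∇u‖ < 1``).
    """
    if tol is None:
        tol = 1e-3 * min(f.grid.spacing)
    ident = _identity_coords(f.grid.shape)
    v = np.zeros_like(f.values)
    update = np.inf
    for _ in range(max_iter):
        coords = ident + np.moveaxis(mm_to_voxel_offsets(f.grid, v), -1, 0)
        sampled, _ = _sample_field(f, coords)
        v_new = -sampled
        update = float(np.abs(v_new - v).max())
        v = v_new
        if update < tol:
            return DisplacementField(f.grid, v)
    raise FieldInversionError(
        f"fixed-point inversion did not converge in {max_iter} iterations "
        f"(last update {update:.3e} mm, tol {tol:.3e} mm)"
    )
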
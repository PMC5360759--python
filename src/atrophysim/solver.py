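"""Three-regime brain-deformation solver on a staggered (MAC) grid.

The model treats the tissue as a quasi-static creep flow driven by prescribed
volume change.  With displacement ``u`` (mm) and a pressure-like Lagrange
multiplier ``p`` (kPa), the discretised system solved per time step is::

    Label 0 (skull / background):  u = 0            (Dirichlet, eliminated)
    Label 1 (CSF):                 mu Δu − ∇p = 0
                                   ∇·u + k p = 0     (relaxed incompressibility)
    Label 2 (parenchyma):          mu Δu − ∇p = (mu + lambda) ∇a
                                   ∇·u = −a          (prescribed divergence)

``a`` is the atrophy map (fractional volume loss per step, positive =
shrinkage).  The relaxed mass equation in Label 1 lets the CSF compartment
absorb exactly the volume prescribed to disappear from the parenchyma, since
zero boundary displacement forces the global divergence integral to vanish.

Discretisation: velocity components live on cell faces, pressure and atrophy
at cell centers.  Momentum rows use the canonical 7-point vector Laplacian
per face with face-centered pressure/atrophy gradients; mass rows use either
the 6-point face stencil or the 12-point stencil (centered difference of
face-averaged values) selected by ``ModelParams.scheme``.  The 12-point
choice makes the solved constraint consistent with centered-difference
divergence and Jacobian measurements taken on the center-sampled output
field.

A face is a zero (Dirichlet) face when it lies on the domain boundary or
either adjacent cell is Label 0; such faces are eliminated from the system,
so ``u`` is exactly zero there, not just small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import sparse
from scipy.sparse import linalg as spla

from .fields import (
    StaggeredField,
    divergence_centered,
    divergence_staggered,
    face_to_center,
)
from .images import (
    AtrophyMap,
    DisplacementField,
    ImageGrid,
    LabelImage,
    ScalarImage,
    assert_same_space,
)

__all__ = [
    "ModelParams",
    "PressureField",
    "AssembledSystem",
    "SolverDiagnostics",
    "SolverError",
    "assemble_system",
    "solve_deformation",
    "face_to_center",
    "StaggeredField",
]

logger = logging.getLogger(__name__)

SCHEMES = ("six_point", "twelve_point")


class SolverError(RuntimeError):
    pass


@dataclass
class ModelParams:
    """Tunable model parameters.

    mu, lam : shear-like and dilatational coefficients (kPa); only their sum
        enters the atrophy forcing term, mu alone the viscous smoothing.
    k : compressibility coefficient of the Label-1 regime (kPa^-1); larger k
        lets CSF absorb volume at lower pressure.
    scheme : divergence stencil used by the constraint rows.
    method : "direct" (sparse LU of the full saddle-point matrix), "schur"
        (factor the velocity Laplacian once, GMRES on the pressure Schur
        complement), or "auto" (direct below ``direct_size_limit`` unknowns,
        Schur above — direct solves keep small test systems bit-deterministic,
        the Schur route scales to production grids).
    """

    mu: float = 1.0
    lam: float = 0.0
    k: float = 1.0
    scheme: str = "twelve_point"
    solver_tol: float = 1e-8
    max_iter: int = 2000
    method: str = "auto"
    direct_size_limit: int = 25000
    pressure_epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.k <= 0 or self.lam < 0:
            raise ValueError("require mu > 0, k > 0, lam >= 0")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.method not in ("auto", "direct", "schur"):
            raise ValueError("method must be 'auto', 'direct' or 'schur'")


@dataclass
class PressureField(ScalarImage):
    """Pressure (kPa) at voxel centers; zero in eliminated Label-0 cells."""


@dataclass
class AssembledSystem:
    """Sparse saddle-point system plus the unknown ordering that built it.

    Unknown ordering: x-face velocities, then y, then z (each in lexicographic
    (i,j,k) order over the unknown faces), then cell pressures in
    lexicographic order over Label-1/2 cells.
    """

    matrix: sparse.csr_matrix
    rhs: np.ndarray
    face_ids: tuple[np.ndarray, np.ndarray, np.ndarray]
    pressure_ids: np.ndarray
    n_faces: int
    n_pressures: int
    regularized_cells: int

    @property
    def n_unknowns(self) -> int:
        return self.n_faces + self.n_pressures


@dataclass
class SolverDiagnostics:
    residual: float
    iterations: int
    max_constraint_violation: float
    mean_constraint_violation: float
    conservation_residual: float
    n_unknowns: int
    regularized_cells: int
    staggered: StaggeredField | None = None

    def as_dict(self) -> dict:
        return {
            "residual": self.residual,
            "iterations": self.iterations,
            "max_constraint_violation": self.max_constraint_violation,
            "mean_constraint_violation": self.mean_constraint_violation,
            "conservation_residual": self.conservation_residual,
            "n_unknowns": self.n_unknowns,
            "regularized_cells": self.regularized_cells,
        }


def _validate_inputs(labels: LabelImage, a: AtrophyMap) -> None:
    assert_same_space(labels, a)
    L = labels.values
    bad = (a.values != 0) & (L != 2)
    if np.any(bad):
        n = int(bad.sum())
        raise SolverError(
            f"atrophy is nonzero on {n} voxel(s) outside Label 2; the prescribed-"
            "divergence constraint can only be honored in Label 2 regions"
        )
    if np.any((a.values != 0) & (L == 2)) and not np.any(L == 1):
        raise SolverError(
            "nonzero atrophy prescribed but the segmentation has no Label 1 "
            "voxel to compensate the volume change (singular system)"
        )


def _face_numbering(L: np.ndarray):
    """Assign unknown ids to non-Dirichlet faces, component by component."""
    shape = L.shape
    fids = []
    offset = 0
    for d in range(3):
        fshape = tuple(n + 1 if ax == d else n for ax, n in enumerate(shape))
        fid = np.full(fshape, -1, dtype=np.int64)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[d] = slice(0, -1)
        hi[d] = slice(1, None)
        both_active = (L[tuple(lo)] > 0) & (L[tuple(hi)] > 0)  # (n_d - 1) interior faces
        interior = [slice(None)] * 3
        interior[d] = slice(1, -1)
        count = int(both_active.sum())
        ids = np.full(both_active.shape, -1, dtype=np.int64)
        ids[both_active] = offset + np.arange(count)
        fid[tuple(interior)] = ids
        offset += count
        fids.append(fid)
    return fids, offset


def _shifted_ids(arr: np.ndarray, axis: int, step: int) -> np.ndarray:
    """Neighbor-id lookup with -1 (absent) beyond the array bounds."""
    out = np.full_like(arr, -1)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if step > 0:
        src[axis] = slice(step, None)
        dst[axis] = slice(0, -step)
    else:
        src[axis] = slice(0, step)
        dst[axis] = slice(-step, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def assemble_system(
    labels: LabelImage, a: AtrophyMap, params: ModelParams
) -> AssembledSystem:
    """Build the sparse saddle-point system for the three-regime model."""
    _validate_inputs(labels, a)
    L = labels.values
    av = a.values
    h = np.asarray(labels.grid.spacing)
    mu, lam, k = params.mu, params.lam, params.k

    fids, n_faces = _face_numbering(L)
    pid = np.full(L.shape, -1, dtype=np.int64)
    active = L > 0
    n_p = int(active.sum())
    pid[active] = np.arange(n_p)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    rhs = np.zeros(n_faces + n_p)

    def add(r, c, v):
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        vals.append(np.broadcast_to(np.asarray(v, dtype=float), np.shape(r)).ravel())

    inv_h2 = 1.0 / h**2
    diag_lap = -2.0 * mu * inv_h2.sum()

    # --- momentum rows, one per unknown face --------------------------------
    for d in range(3):
        fid = fids[d]
        mask = fid >= 0
        if not mask.any():
            continue
        r = fid[mask]
        # 7-point Laplacian: absent / Dirichlet neighbors contribute zero.
        add(r, r, diag_lap)
        for ax in range(3):
            for step in (-1, 1):
                nb = _shifted_ids(fid, ax, step)[mask]
                ok = nb >= 0
                add(r[ok], nb[ok], mu * inv_h2[ax])
        # face-centered −∂p/∂x_d and atrophy forcing (mu+lam) ∂a/∂x_d:
        # face (…, i, …) of component d sits between cells i-1 (low) and i (high).
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[d] = slice(0, -1)
        hi[d] = slice(1, None)
        interior = [slice(None)] * 3
        interior[d] = slice(1, -1)
        m_in = mask[tuple(interior)]
        r_in = fid[tuple(interior)][m_in]
        p_lo = pid[tuple(lo)][m_in]
        p_hi = pid[tuple(hi)][m_in]
        add(r_in, p_hi + n_faces, -1.0 / h[d])
        add(r_in, p_lo + n_faces, +1.0 / h[d])
        a_lo = av[tuple(lo)][m_in]
        a_hi = av[tuple(hi)][m_in]
        rhs[r_in] = (mu + lam) * (a_hi - a_lo) / h[d]

    # --- mass rows, one per active cell -------------------------------------
    ci, cj, ck = np.nonzero(active)
    cell_rows = n_faces + pid[ci, cj, ck]
    cell_idx = (ci, cj, ck)

    def face_coef(d, offset, coef):
        """Couple each mass row to face `cell_index_along_d + offset` of comp d."""
        idx = [ci.copy(), cj.copy(), ck.copy()]
        idx[d] = idx[d] + offset
        fshape = fids[d].shape
        inb = (idx[d] >= 0) & (idx[d] < fshape[d])
        f = np.full(ci.shape, -1, dtype=np.int64)
        f[inb] = fids[d][idx[0][inb], idx[1][inb], idx[2][inb]]
        ok = f >= 0
        add(cell_rows[ok], f[ok], coef)

    for d in range(3):
        if params.scheme == "six_point":
            # (u_{i+1/2} - u_{i-1/2}) / h
            face_coef(d, 1, +1.0 / h[d])
            face_coef(d, 0, -1.0 / h[d])
        else:
            # (u_{i+3/2} + u_{i+1/2} - u_{i-1/2} - u_{i-3/2}) / (4 h)
            face_coef(d, 2, +0.25 / h[d])
            face_coef(d, 1, +0.25 / h[d])
            face_coef(d, 0, -0.25 / h[d])
            face_coef(d, -1, -0.25 / h[d])

    lab_cells = L[cell_idx]
    is_l1 = lab_cells == 1
    add(cell_rows[is_l1], cell_rows[is_l1], k)
    rhs[cell_rows[~is_l1]] = -av[cell_idx][~is_l1]

    # Label-2-only connected components have a constant-pressure nullspace
    # (all their boundary faces are Dirichlet); pin it with a tiny diagonal.
    n_reg = 0
    if n_p:
        struct = ndimage.generate_binary_structure(3, 1)
        comp, n_comp = ndimage.label(active, structure=struct)
        has_l1 = np.zeros(n_comp + 1, dtype=bool)
        np.logical_or.at(has_l1, comp[L == 1], True)
        orphan = active & ~has_l1[comp]
        n_reg = int(orphan.sum())
        if n_reg:
            logger.warning(
                "%d Label-2 cell(s) have no pressure path to Label 1; adding "
                "epsilon=%.1e regularization to their mass rows",
                n_reg,
                params.pressure_epsilon,
            )
            r_orph = n_faces + pid[orphan]
            add(r_orph, r_orph, params.pressure_epsilon)

    n = n_faces + n_p
    if n == 0:
        matrix = sparse.csr_matrix((0, 0))
    else:
        matrix = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
    return AssembledSystem(
        matrix=matrix,
        rhs=rhs,
        face_ids=tuple(fids),
        pressure_ids=pid,
        n_faces=n_faces,
        n_pressures=n_p,
        regularized_cells=n_reg,
    )


def _solve_schur(system: AssembledSystem, params: ModelParams):
    """Factor the (component-decoupled, definite) velocity Laplacian once and
    run GMRES on the pressure Schur complement ``K - D A^-1 G``.

    The MAC Stokes Schur complement is spectrally close to a scaled mass
    matrix, so unpreconditioned GMRES converges in a few dozen iterations.
    """
    M, b = system.matrix.tocsr(), system.rhs
    nF = system.n_faces
    A = M[:nF, :nF].tocsc()
    G = M[:nF, nF:].tocsr()
    D = M[nF:, :nF].tocsr()
    K = M[nF:, nF:].tocsr()
    f, g = b[:nF], b[nF:]
    lu = spla.splu(A)

    def schur_matvec(p):
        return K @ p - D @ lu.solve(G @ p)

    S = spla.LinearOperator((system.n_pressures,) * 2, schur_matvec)
    rhs_s = g - D @ lu.solve(f)
    iters = {"n": 0}

    def cb(_):
        iters["n"] += 1

    p, info = spla.gmres(
        S,
        rhs_s,
        rtol=params.solver_tol * 1e-2,
        atol=0.0,
        restart=200,
        maxiter=params.max_iter,
        callback=cb,
        callback_type="pr_norm",
    )
    if info != 0:
        raise SolverError(f"Schur-complement GMRES did not converge (info={info})")
    u = lu.solve(f - G @ p)
    return np.concatenate([u, p]), iters["n"]


def _solve_linear(system: AssembledSystem, params: ModelParams):
    method = params.method
    if method == "auto":
        method = "direct" if system.n_unknowns <= params.direct_size_limit else "schur"
    if method == "direct":
        return spla.spsolve(system.matrix.tocsc(), system.rhs), 1
    return _solve_schur(system, params)


def _scatter_solution(
    grid: ImageGrid, system: AssembledSystem, x: np.ndarray
) -> tuple[StaggeredField, np.ndarray]:
    sf = StaggeredField.zeros(grid)
    for d, comp in enumerate((sf.u, sf.v, sf.w)):
        fid = system.face_ids[d]
        m = fid >= 0
        comp[m] = x[fid[m]]
    p = np.zeros(grid.shape)
    m = system.pressure_ids >= 0
    p[m] = x[system.n_faces + system.pressure_ids[m]]
    return sf, p


def solve_deformation(
    labels: LabelImage,
    a: AtrophyMap,
    params: ModelParams | None = None,
) -> tuple[DisplacementField, PressureField, SolverDiagnostics]:
    """Solve the three-regime system and return center-sampled results.

    Returns the displacement field (faces averaged to centers), the pressure
    field, and diagnostics including the achieved relative residual and the
    worst violation of the divergence constraint over Label-2 cells, measured
    with the same stencil the solve used.
    """
    params = params or ModelParams()
    system = assemble_system(labels, a, params)
    grid = labels.grid

    if system.n_unknowns == 0:
        sf = StaggeredField.zeros(grid)
        diag = SolverDiagnostics(0.0, 0, 0.0, 0.0, 0.0, 0, 0, sf)
        return (
            DisplacementField.zeros(grid),
            PressureField(grid, np.zeros(grid.shape)),
            diag,
        )

    x, iters = _solve_linear(system, params)
    A, b = system.matrix, system.rhs
    bnorm = float(np.linalg.norm(b))
    residual = float(np.linalg.norm(A @ x - b)) / (bnorm if bnorm > 0 else 1.0)
    if residual > max(params.solver_tol, 1e-30) * 10 and bnorm > 0:
        raise SolverError(f"solver residual {residual:.3e} exceeds tolerance")

    sf, p = _scatter_solution(grid, system, x)
    if params.scheme == "six_point":
        div = divergence_staggered(sf).values
    else:
        div = divergence_centered(face_to_center(sf)).values
    l2 = labels.values == 2
    viol = np.abs(div + a.values)[l2]
    # conservation in flux form: the face-based divergence telescopes to the
    # boundary flux, which is zero by the Dirichlet condition
    conservation = float(divergence_staggered(sf).values.sum() * grid.voxel_volume)
    diag = SolverDiagnostics(
        residual=residual,
        iterations=iters,
        max_constraint_violation=float(viol.max()) if viol.size else 0.0,
        mean_constraint_violation=float(viol.mean()) if viol.size else 0.0,
        conservation_residual=conservation,
        n_unknowns=system.n_unknowns,
        regularized_cells=system.regularized_cells,
        staggered=sf,
    )
    logger.info(
        "solved %d unknowns: residual %.2e, max |div u + a| over Label2 %.2e",
        system.n_unknowns,
        residual,
        diag.max_constraint_violation,
    )
    return face_to_center(sf), PressureField(grid, p), diag
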
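"""Field calculus: divergence stencils, Jacobians, composition, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atrophysim import (
    DisplacementField,
    ImageGrid,
    StaggeredField,
    compose_fields,
    divergence_centered,
    divergence_staggered,
    face_to_center,
    invert_field,
    jacobian_determinant,
)
from atrophysim.fields import FieldInversionError

from conftest import smooth_tapered_field


def random_staggered(grid, seed):
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid.shape
    return StaggeredField(
        grid,
        rng.normal(size=(nx + 1, ny, nz)),
        rng.normal(size=(nx, ny + 1, nz)),
        rng.normal(size=(nx, ny, nz + 1)),
    )


class TestStaggeredDivergence:
    def test_zero_field(self):
        grid = ImageGrid(shape=(4, 5, 6))
        assert not divergence_staggered(StaggeredField.zeros(grid)).values.any()

    def test_linear_faces_give_constant_divergence(self):
        grid = ImageGrid(shape=(6, 6, 6), spacing=(0.5, 1.0, 2.0))
        sf = StaggeredField.zeros(grid)
        c = 0.7
        i = np.arange(7, dtype=float)[:, None, None]
        sf.u[:] = c * (i + 0.5) * grid.spacing[0]
        np.testing.assert_allclose(divergence_staggered(sf).values, c, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_triple_loop_oracle(self, seed):
        grid = ImageGrid(shape=(4, 3, 5), spacing=(1.0, 0.8, 1.3))
        sf = random_staggered(grid, seed)
        hx, hy, hz = grid.spacing
        oracle = np.zeros(grid.shape)
        for i in range(4):
            for j in range(3):
                for k in range(5):
                    oracle[i, j, k] = (
                        (sf.u[i + 1, j, k] - sf.u[i, j, k]) / hx
                        + (sf.v[i, j + 1, k] - sf.v[i, j, k]) / hy
                        + (sf.w[i, j, k + 1] - sf.w[i, j, k]) / hz
                    )
        assert np.array_equal(divergence_staggered(sf).values, oracle)


class TestCenteredDivergence:
    def test_linear_center_field_constant_interior(self):
        grid = ImageGrid(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.5))
        x = np.arange(8, dtype=float)[:, None, None] * np.ones((8, 8, 8))
        values = np.zeros((8, 8, 8, 3))
        values[..., 0] = 0.4 * x * grid.spacing[0]
        div = divergence_centered(DisplacementField(grid, values))
        np.testing.assert_allclose(div.values, 0.4, atol=1e-12)

    def test_twelve_point_identity_on_faces(self):
        """Centered divergence of the face-averaged field == 12-point stencil.

        Algebraic identity, checked bit-level against a brute-force loop that
        mirrors the centered-difference arithmetic on interior cells.
        """
        grid = ImageGrid(shape=(6, 6, 6), spacing=(1.0, 1.25, 0.75))
        sf = random_staggered(grid, seed=11)
        via_centers = divergence_centered(face_to_center(sf)).values
        h = grid.spacing
        faces = (sf.u, sf.v, sf.w)
        oracle = np.zeros(grid.shape)
        for i in range(1, 5):
            for j in range(1, 5):
                for k in range(1, 5):
                    total = 0.0
                    for d, f in enumerate(faces):
                        idx_hi = [i, j, k]
                        idx_lo = [i, j, k]
                        idx_hi[d] += 1
                        idx_lo[d] -= 1
                        c_hi = 0.5 * (
                            f[tuple(np.add(idx_hi, np.eye(3, dtype=int)[d]))]
                            + f[tuple(idx_hi)]
                        )
                        c_lo = 0.5 * (
                            f[tuple(np.add(idx_lo, np.eye(3, dtype=int)[d]))]
                            + f[tuple(idx_lo)]
                        )
                        total += (c_hi - c_lo) / (2.0 * h[d])
                    oracle[i, j, k] = total
        interior = (slice(1, 5),) * 3
        assert np.array_equal(via_centers[interior], oracle[interior])

    def test_schemes_agree_at_second_order_on_smooth_field(self):
        """Staggered and centered divergence converge to the analytic value
        with observed order >= 1.9 under grid refinement."""
        errors = {}
        for n in (16, 32):
            grid = ImageGrid(shape=(n, n, n), spacing=(8.0 / n,) * 3)
            coords = [np.arange(n) * 8.0 / n for _ in range(3)]
            X, Y, Z = np.meshgrid(*coords, indexing="ij")
            values = np.zeros((n, n, n, 3))
            values[..., 0] = np.sin(X) * np.cos(Y)
            values[..., 1] = np.sin(Y) * np.cos(Z)
            values[..., 2] = np.sin(Z) * np.cos(X)
            analytic = (
                np.cos(X) * np.cos(Y) + np.cos(Y) * np.cos(Z) + np.cos(Z) * np.cos(X)
            )
            div = divergence_centered(DisplacementField(grid, values)).values
            interior = (slice(2, -2),) * 3
            errors[n] = np.abs(div - analytic)[interior].max()
        order = np.log2(errors[16] / errors[32])
        assert order >= 1.9


class TestJacobian:
    def test_identity_map(self):
        grid = ImageGrid(shape=(5, 5, 5))
        J = jacobian_determinant(DisplacementField.zeros(grid))
        np.testing.assert_allclose(J.values, 1.0)

    def test_uniform_scaling_closed_form(self):
        grid = ImageGrid(shape=(8, 8, 8))
        s = -0.05
        centers = grid.voxel_centers()
        values = s * (centers - 3.5)
        J = jacobian_determinant(DisplacementField(grid, values))
        interior = (slice(1, -1),) * 3
        np.testing.assert_allclose(J.values[interior], (1 + s) ** 3, atol=1e-12)


class TestCompose:
    def test_identity_inner(self, smooth_field16):
        grid = smooth_field16.grid
        out = compose_fields(smooth_field16, DisplacementField.zeros(grid))
        assert np.array_equal(out.values, smooth_field16.values)

    def test_translations_add_interior(self):
        grid = ImageGrid(shape=(10, 10, 10))
        t1, t2 = np.array([1.0, 0.0, 0.0]), np.array([0.0, -1.0, 0.5])
        f1 = DisplacementField(grid, np.broadcast_to(t1, (10, 10, 10, 3)).copy())
        f2 = DisplacementField(grid, np.broadcast_to(t2, (10, 10, 10, 3)).copy())
        out = compose_fields(f1, f2)
        interior = (slice(2, -2),) * 3
        np.testing.assert_allclose(
            out.values[interior], np.broadcast_to(t1 + t2, (6, 6, 6, 3)), atol=1e-12
        )

    def test_associative_on_translations(self):
        grid = ImageGrid(shape=(8, 8, 8))
        ts = [np.array([0.4, 0, 0]), np.array([0, 0.3, 0]), np.array([0, 0, -0.2])]
        fs = [
            DisplacementField(grid, np.broadcast_to(t, (8, 8, 8, 3)).copy())
            for t in ts
        ]
        left = compose_fields(compose_fields(fs[0], fs[1]), fs[2])
        right = compose_fields(fs[0], compose_fields(fs[1], fs[2]))
        interior = (slice(2, -2),) * 3
        np.testing.assert_allclose(
            left.values[interior], right.values[interior], atol=1e-12
        )


class TestInvert:
    def test_zero_field(self):
        grid = ImageGrid(shape=(6, 6, 6))
        inv = invert_field(DisplacementField.zeros(grid))
        assert not inv.values.any()

    @staticmethod
    def plateau_translation(grid, t, ramp=3):
        """Constant translation in the interior, tapered to zero at the
        boundary (the inverter's zero-extension requires vanishing fields)."""
        window = np.ones(grid.shape)
        for ax in range(3):
            r = np.clip(
                np.minimum(np.arange(grid.shape[ax]), np.arange(grid.shape[ax])[::-1]),
                0,
                ramp,
            ) / ramp
            sl = [None, None, None]
            sl[ax] = slice(None)
            window = window * r[tuple(sl)]
        values = window[..., None] * np.asarray(t, dtype=float)
        return DisplacementField(grid, values)

    def test_constant_translation_interior(self):
        grid = ImageGrid(shape=(16, 16, 16))
        t = np.array([0.8, -0.5, 0.0])
        inv = invert_field(self.plateau_translation(grid, t))
        interior = (slice(5, -5),) * 3
        np.testing.assert_allclose(
            inv.values[interior], np.broadcast_to(-t, (6, 6, 6, 3)), atol=2e-3
        )

    def test_roundtrip_bound_smooth_field(self, smooth_field16):
        tol = 1e-3  # min spacing 1 mm
        inv = invert_field(smooth_field16, tol=tol)
        rt = compose_fields(smooth_field16, inv)
        assert rt.max_magnitude() <= 10 * tol

    def test_involution_on_plateau_translation(self):
        """Double inversion reproduces the field where it is locally constant
        (no interpolation error there), to a couple of tolerances."""
        grid = ImageGrid(shape=(16, 16, 16))
        t = np.array([0.6, -0.4, 0.3])
        f = self.plateau_translation(grid, t)
        tol = 1e-4
        back = invert_field(invert_field(f, tol=tol), tol=tol)
        interior = (slice(5, -5),) * 3
        err = np.abs(back.values - f.values)[interior].max()
        assert err <= 2 * tol + 1e-6

    def test_nonconvergence_raises(self):
        grid = ImageGrid(shape=(8, 8, 8))
        values = smooth_tapered_field((8, 8, 8), seed=1, max_mm=6.0, sigma=1.0)
        with pytest.raises(FieldInversionError, match="did not converge"):
            invert_field(DisplacementField(grid, values), max_iter=5)


def test_face_to_center_constant_and_linear():
    grid = ImageGrid(shape=(5, 4, 3))
    sf = StaggeredField.zeros(grid)
    sf.u[:], sf.v[:], sf.w[:] = 2.5, 2.5, 2.5
    out = face_to_center(sf)
    np.testing.assert_allclose(out.values, 2.5)
    # faces linear in i: u_{i+1/2} = i + 1/2  ->  centers exactly i
    sf = StaggeredField.zeros(grid)
    sf.u[:] = (np.arange(6, dtype=float) - 0.5)[:, None, None]
    centers = face_to_center(sf).values[..., 0]
    np.testing.assert_allclose(centers, np.arange(5.0)[:, None, None] * np.ones((5, 4, 3)))
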
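import math

import numpy as np
import pytest

from microvns.coil_geometry import MU0, CurrentPath
from microvns.em_fields import (
    FieldMap,
    VoxelGrid,
    b_field,
    conduction_correction,
    cut_plane_current,
    masked_gradient,
    nerve_block,
    nerve_cylinder,
    nerve_ellipse_cylinder,
    primary_e_field,
    vector_potential,
)


class TestBiotSavart:
    def test_on_axis_b_matches_loop_closed_form(self, circular_loop):
        R, loop = circular_loop
        grid = VoxelGrid((-5e-6, -5e-6, 0.0), (5e-6, 5e-6, 2e-5), (2, 2, 10))
        B = b_field(loop, grid)
        z = grid.axes()[2]
        ref = MU0 * R**2 / (2 * (R**2 + z**2) ** 1.5)
        assert np.allclose(B.values[0, 0, :, 2], ref, rtol=0.01)

    def test_vector_potential_vanishes_on_loop_axis(self, circular_loop):
        R, loop = circular_loop
        # cell centers exactly on the z axis
        grid = VoxelGrid((-0.5e-6, -0.5e-6, 0.0), (1e-6, 1e-6, 3e-5), (2, 2, 8))
        A = vector_potential(loop, grid)
        off_axis_scale = MU0 / (4 * math.pi) * 2 * math.pi  # O(mu0)
        assert np.abs(A.values[0, 0]).max() < 1e-4 * off_axis_scale

    def test_far_field_decays_as_inverse_square(self, circular_loop):
        R, loop = circular_loop
        # radial line in the equatorial plane, 10R..100R
        rr = np.geomspace(10 * R, 100 * R, 8)
        grid = VoxelGrid((rr[0], 0, 0), (1, 1, 1), (2, 2, 2))  # placeholder
        mags = []
        for r in rr:
            g = VoxelGrid((r, -1e-6, -1e-6), (1e-6, 1e-6, 1e-6), (2, 2, 2))
            A = vector_potential(loop, g)
            mags.append(np.linalg.norm(A.values[0, 0, 0]))
        slope = np.polyfit(np.log(rr), np.log(mags), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.05)

    def test_divergence_of_b_is_numerically_zero(self, circular_loop):
        R, loop = circular_loop
        h = 2e-6
        grid = VoxelGrid((2e-5, 2e-5, 1e-5), (h, h, h), (10, 10, 10))
        B = b_field(loop, grid)
        div = sum(
            np.gradient(B.values[..., i], h, axis=i)[2:-2, 2:-2, 2:-2]
            for i in range(3)
        )
        assert np.abs(div).max() < 1e-3 * np.abs(B.values).max() / h

    def test_reversing_current_negates_b(self, circular_loop):
        _, loop = circular_loop
        grid = VoxelGrid((1e-5, 1e-5, 1e-5), (1e-5, 1e-5, 1e-5), (3, 3, 3))
        B = b_field(loop, grid)
        rev = CurrentPath(loop.points[::-1].copy(), closed=True)
        B2 = b_field(rev, grid)
        assert np.allclose(B.values, -B2.values, atol=1e-18)

    def test_helmholtz_pair_uniform_at_midpoint(self):
        R = 1e-3
        th = np.linspace(0, 2 * np.pi, 721)
        circ = np.c_[R * np.cos(th), R * np.sin(th), np.zeros_like(th)]
        up = CurrentPath(circ + [0, 0, R / 2], closed=True)
        dn = CurrentPath(circ - [0, 0, R / 2], closed=True)
        zs = np.linspace(-R / 10, R / 10, 9)
        g = VoxelGrid((-0.5e-6, -0.5e-6, zs[0]), (1e-6, 1e-6, zs[1] - zs[0]),
                      (2, 2, len(zs)))
        Bz = b_field(up, g).values[0, 0, :, 2] + b_field(dn, g).values[0, 0, :, 2]
        assert np.ptp(Bz) / Bz.mean() < 0.01


class TestPrimaryField:
    def test_zero_didt_zero_field(self, circular_loop):
        _, loop = circular_loop
        g = VoxelGrid((0, 0, 1e-5), (1e-5, 1e-5, 1e-5), (3, 3, 3))
        A = vector_potential(loop, g)
        assert np.all(primary_e_field(A, 0.0).values == 0.0)

    def test_linearity_in_didt(self, circular_loop):
        _, loop = circular_loop
        g = VoxelGrid((0, 0, 1e-5), (1e-5, 1e-5, 1e-5), (3, 3, 3))
        A = vector_potential(loop, g)
        E1 = primary_e_field(A, 1e6).values
        E2 = primary_e_field(A, 2e6).values
        assert np.allclose(E2, 2 * E1)


class TestConductionCorrection:
    def test_uniform_axial_field_in_closed_column_cancels(self):
        t = nerve_block(lx=2e-4, ly=5e-5, lz=5e-5, spacing=5e-6)
        Ep = FieldMap(
            t.grid, "E_primary",
            np.tile(np.array([1.0, 0.0, 0.0]), t.grid.shape + (1,)),
        )
        Et = conduction_correction(t, Ep)
        assert np.abs(Et.values).max() < 1e-6

    def test_tangential_field_slab_passes_through(self):
        # E along x on a slab spanning the grid in x: tangential to the
        # large faces, no normal current to cancel at the short ends is
        # violated, so restrict the check to the slab interior
        t = nerve_block(lx=1e-3, ly=2e-4, lz=5e-5, spacing=1e-5)
        vals = np.zeros(t.grid.shape + (3,))
        vals[..., 1] = 1.0  # along y? no: tangential to top/bottom, ends at y-faces
        # use a solenoidal-like tangential pattern: E = (1, 0, 0) but
        # examine mid-slab where end effects are gone
        vals[..., 1] = 0.0
        vals[..., 0] = 1.0
        Et = conduction_correction(t, FieldMap(t.grid, "E_primary", vals))
        mid = Et.values[t.grid.shape[0] // 2]
        # interior of a long slab: uniform axial E is cancelled (closed
        # conductor cannot carry net current)
        assert np.abs(mid).max() < 0.05

    def test_no_net_current_through_any_cut_plane(self):
        t = nerve_block(lx=2e-4, ly=1e-4, lz=1e-4, spacing=1e-5)
        x, y, z = t.grid.axes()
        X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
        Ep = np.stack(
            [np.sin(Y / 5e-5), np.cos(X / 1e-4), 0.5 * np.sin(Z / 5e-5 + 1)], -1
        )
        Et = conduction_correction(t, FieldMap(t.grid, "E_primary", Ep))
        currents = [
            cut_plane_current(t, Et, 0, i) for i in (3, 10, 16)
        ]
        scale = 0.27 * np.abs(Et.values).max() * (1e-4) ** 2
        assert all(abs(c) < 1e-8 * scale for c in currents)

    def test_superposition_of_two_sources(self, circular_loop):
        _, loop = circular_loop
        t = nerve_block(lx=2e-4, ly=1e-4, lz=1e-4, spacing=1e-5)
        A1 = vector_potential(loop, t.grid)
        loop2 = CurrentPath(loop.points + [0, 5e-5, 2e-4], closed=True)
        A2 = vector_potential(loop2, t.grid)
        E1 = conduction_correction(t, primary_e_field(A1, 1e6))
        E2 = conduction_correction(t, primary_e_field(A2, 1e6))
        Esum = FieldMap(
            t.grid, "E_primary", primary_e_field(A1, 1e6).values
            + primary_e_field(A2, 1e6).values,
        )
        E12 = conduction_correction(t, Esum)
        assert np.allclose(E12.values, E1.values + E2.values, atol=1e-6)

    def test_field_zero_outside_conductor(self, circular_loop):
        _, loop = circular_loop
        t = nerve_cylinder(radius=5e-5, length=2e-4, spacing=1e-5)
        A = vector_potential(loop, t.grid)
        Et = conduction_correction(t, primary_e_field(A, 1e6))
        assert np.all(Et.values[~t.mask] == 0.0)


class TestTissueModels:
    def test_block_dimensions_and_conductivity(self):
        t = nerve_block(spacing=1e-5)
        assert t.grid.shape == (150, 30, 30)
        assert np.all(t.sigma == 0.27)
        assert t.nerve_volume == pytest.approx(1.5e-3 * 0.3e-3 * 0.3e-3)

    def test_cylinder_mask_matches_analytic_area(self):
        t = nerve_cylinder(spacing=2.5e-6)
        frac = t.mask[0].mean() * (2 * 150e-6) ** 2 / (math.pi * (150e-6) ** 2)
        assert frac == pytest.approx(1.0, rel=0.01)

    def test_flattened_model_preserves_cross_section_area(self):
        c = nerve_cylinder()
        e = nerve_ellipse_cylinder()
        a_c = math.pi * c.dimensions["radius"] ** 2
        a_e = (
            math.pi * e.dimensions["semi_axis_y"] * e.dimensions["semi_axis_z"]
        )
        assert a_e == pytest.approx(a_c, rel=0.01)
        assert e.dimensions["semi_axis_y"] / e.dimensions["semi_axis_z"] == (
            pytest.approx(2.0, rel=0.01)
        )

    def test_contains_agrees_with_mask(self):
        t = nerve_cylinder(spacing=1e-5)
        pts = t.grid.centers().reshape(-1, 3)
        assert np.array_equal(t.contains(pts).reshape(t.grid.shape), t.mask)


def test_masked_gradient_linear_field_exact_interior():
    mask = np.ones((6, 6, 6), bool)
    x = np.arange(6) * 2.0
    f = x[:, None, None] * np.ones((6, 6, 6))
    g = masked_gradient(f, mask, (2.0, 2.0, 2.0))
    assert np.allclose(g[..., 0], 1.0)
    assert np.allclose(g[..., 1:], 0.0)
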
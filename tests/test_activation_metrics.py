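import numpy as np
import pandas as pd
import pytest

from microvns.em_fields import FieldMap, VoxelGrid, nerve_block, nerve_cylinder
from microvns.activation_metrics import (
    AFMap,
    activating_function,
    compare_coils,
    depth_profile,
    first_crossing,
    gradient_tensor,
    orientation_scan,
    selectivity,
    volume_of_activation,
)


def _uniform_grid(shape=(8, 8, 8), h=1e-5):
    return VoxelGrid((0.0, 0.0, 0.0), (h, h, h), shape)


def _linear_ex_field(grid, alpha):
    """E = (alpha * x, 0, 0)."""
    x = grid.axes()[0]
    vals = np.zeros(grid.shape + (3,))
    vals[..., 0] = alpha * x[:, None, None]
    return FieldMap(grid, "E_total", vals)


class TestGradientTensor:
    def test_uniform_field_zero_tensor(self):
        g = _uniform_grid()
        E = FieldMap(g, "E_total", np.ones(g.shape + (3,)))
        T = gradient_tensor(E, np.ones(g.shape, bool))
        assert np.allclose(T, 0.0)

    def test_linear_field_recovers_alpha_exactly(self):
        g = _uniform_grid()
        T = gradient_tensor(_linear_ex_field(g, 7.5), np.ones(g.shape, bool))
        assert np.allclose(T[..., 0, 0], 7.5)
        assert np.allclose(T[..., 1:, :], 0.0)

    def test_small_grid_rejected(self):
        g = VoxelGrid((0, 0, 0), (1e-5,) * 3, (2, 2, 2))
        E = FieldMap(g, "E_total", np.zeros(g.shape + (3,)))
        with pytest.raises(ValueError, match="grid too small"):
            gradient_tensor(E, np.ones(g.shape, bool))


class TestActivatingFunction:
    def test_axis_aligned_linear_field(self):
        g = _uniform_grid()
        af = activating_function(_linear_ex_field(g, 3.0), (1, 0, 0))
        assert np.allclose(af.af_values, 3.0)

    def test_zero_axis_rejected(self):
        g = _uniform_grid()
        E = FieldMap(g, "E_total", np.zeros(g.shape + (3,)))
        with pytest.raises(ValueError, match="non-zero"):
            activating_function(E, (0, 0, 0))

    def test_oblique_axis_projects_gradient(self):
        # E = (a*x, a*y, 0); along n=(1,1,0)/sqrt2 the AF is a
        g = _uniform_grid()
        x, y, _ = g.axes()
        vals = np.zeros(g.shape + (3,))
        vals[..., 0] = 2.0 * x[:, None, None]
        vals[..., 1] = 2.0 * y[None, :, None]
        af = activating_function(
            FieldMap(g, "E_total", vals), (1 / np.sqrt(2), 1 / np.sqrt(2), 0)
        )
        interior = af.af_values[1:-1, 1:-1, :]
        assert np.allclose(interior, 2.0)


class TestVolumeOfActivation:
    def test_threshold_above_max_gives_zero(self):
        g = _uniform_grid()
        af = AFMap(g, np.full(g.shape, 10.0), np.ones(g.shape, bool))
        assert volume_of_activation(af, threshold=11.0) == 0.0

    def test_vanishing_threshold_recovers_whole_mask(self):
        g = _uniform_grid()
        mask = np.zeros(g.shape, bool)
        mask[:4] = True
        af = AFMap(g, np.random.default_rng(0).normal(size=g.shape), mask)
        voa = volume_of_activation(af, threshold=1e-300)
        assert voa == pytest.approx(mask.sum() * g.voxel_volume)

    def test_matches_brute_force_voxel_count(self):
        g = _uniform_grid()
        rng = np.random.default_rng(42)
        vals = rng.normal(scale=2e5, size=g.shape)
        mask = rng.uniform(size=g.shape) > 0.3
        af = AFMap(g, vals, mask)
        thr = 1e5
        # independent counting oracle
        count = 0
        for i in range(g.shape[0]):
            for j in range(g.shape[1]):
                for k in range(g.shape[2]):
                    if mask[i, j, k] and abs(vals[i, j, k]) >= thr:
                        count += 1
        assert volume_of_activation(af, thr) == count * g.voxel_volume

    def test_monotone_nonincreasing_in_threshold(self):
        g = _uniform_grid()
        af = AFMap(g, np.random.default_rng(1).normal(size=g.shape),
                   np.ones(g.shape, bool))
        voas = [volume_of_activation(af, t) for t in (0.1, 0.5, 1.0, 2.0)]
        assert all(a >= b for a, b in zip(voas, voas[1:]))


class TestSelectivity:
    def test_zero_voa(self):
        assert selectivity(0.0, nerve_cylinder(spacing=2e-5)) == 0.0

    def test_voa_equal_voc_gives_one(self):
        t = nerve_cylinder(spacing=2e-5)
        assert selectivity(t.nerve_volume, t) == pytest.approx(1.0)

    def test_cylinder_volume_formula(self):
        t = nerve_cylinder(radius=150e-6, length=1.5e-3, spacing=2e-5)
        assert t.nerve_volume == pytest.approx(np.pi * 150e-6**2 * 1.5e-3)


class TestProfiles:
    def test_constant_field_has_zero_gradient_and_no_crossing(self):
        t = nerve_block(lx=3e-4, ly=1e-4, lz=1e-4, spacing=1e-5)
        E = FieldMap(t.grid, "E_total", np.ones(t.grid.shape + (3,)))
        prof = depth_profile(E, (0, 0, -5e-6), (0, 0, -1), t.mask)
        assert np.allclose(prof["grad_e"], 0.0, atol=1e-9)
        assert first_crossing(prof["offset_m"], prof["e_rms"], 0.5) is None

    def test_line_missing_conductor_rejected(self):
        t = nerve_cylinder(radius=5e-5, length=2e-4, spacing=1e-5)
        E = FieldMap(t.grid, "E_total", np.ones(t.grid.shape + (3,)))
        with pytest.raises(ValueError, match="intersect"):
            depth_profile(E, (0, 2e-4, 2e-4), (0, 0, 1), t.mask)

    def test_first_crossing_interpolates_linearly(self):
        off = np.array([0.0, 1.0, 2.0, 3.0])
        vals = np.array([10.0, 8.0, 4.0, 2.0])
        # crosses 6.0 between offsets 1 and 2 at 1.5
        assert first_crossing(off, vals, 6.0) == pytest.approx(1.5)


class TestCompareCoils:
    def _profile(self, f):
        z = np.linspace(0, 5, 201)
        return pd.DataFrame(
            {"offset_m": z, "e_rms": f(z), "grad_e": np.zeros_like(z)}
        )

    def test_identical_profiles_ratio_one_no_crossover(self):
        p = self._profile(lambda z: np.exp(-z))
        out = compare_coils(p, p.copy())
        assert out["surface_ratio"] == 1.0
        assert out["crossover_depth_m"] is None

    def test_synthetic_exponentials_cross_at_2ln2(self):
        pa = self._profile(lambda z: 2 * np.exp(-z))
        pb = self._profile(lambda z: np.exp(-z / 2))
        out = compare_coils(pa, pb)
        assert out["surface_ratio"] == pytest.approx(2.0)
        assert out["crossover_depth_m"] == pytest.approx(2 * np.log(2), abs=0.025)

    def test_mismatched_grids_rejected(self):
        pa = self._profile(lambda z: np.exp(-z))
        pb = pa.iloc[:-5].copy()
        with pytest.raises(ValueError, match="same offsets"):
            compare_coils(pa, pb)


@pytest.fixture(scope="module")
def scan_setup():
    from dataclasses import replace

    from microvns.coil_geometry import build_planar_spiral, default_spiral_spec

    spec = replace(default_spiral_spec(pitch=20e-6), center=(0, 0, 5e-6))
    tissue = nerve_block(lx=1.2e-3, ly=3e-4, lz=2e-4, spacing=2e-5)
    return (lambda: build_planar_spiral(spec, 30e-6)), tissue


class TestOrientationScan:

    def test_centered_x_aligned_placement_ranks_first(self, scan_setup):
        builder, tissue = scan_setup
        rot90 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        placements = [
            {"name": "centered_x"},
            {"name": "rot90", "rotation": rot90},
            {"name": "offset", "translation": (4e-4, 0, 0)},
        ]
        df = orientation_scan(builder, placements, tissue, 1e6, solve=False)
        assert df.iloc[0]["name"] == "centered_x"

    def test_rot90_strictly_decreases_max_af(self, scan_setup):
        builder, tissue = scan_setup
        rot90 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        df = orientation_scan(
            builder,
            [{"name": "aligned"}, {"name": "rot90", "rotation": rot90}],
            tissue, 1e6, solve=False,
        ).set_index("name")
        assert df.loc["rot90", "max_af"] < df.loc["aligned", "max_af"]

    def test_duplicate_placements_identical_scores(self, scan_setup):
        builder, tissue = scan_setup
        df = orientation_scan(
            builder, [{"name": "a"}, {"name": "b"}], tissue, 1e6, solve=False
        )
        assert df["max_af"].iloc[0] == pytest.approx(df["max_af"].iloc[1])

    def test_colliding_placement_skipped_with_warning(self, scan_setup):
        builder, tissue = scan_setup
        with pytest.warns(UserWarning, match="collides"):
            df = orientation_scan(
                builder,
                [{"name": "ok"}, {"name": "sunk", "translation": (0, 0, -1.2e-5)}],
                tissue, 1e6, solve=False,
            )
        assert df.set_index("name").loc["sunk", "skipped"].item() is True
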
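"""Reslicing geometry: index/world mapping, slab offsets, plane sampling."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from lgequant.errors import GeometryError, InvalidParameterError
from lgequant.geometry import (
    index_to_world,
    reslice,
    sample_plane,
    shifted_plane_offsets,
    world_to_index,
)

from conftest import make_slice, make_volume, random_orthonormal_axes


class TestWorldIndexMapping:
    def test_origin_maps_to_zero_index(self):
        vol = make_volume(np.zeros((4, 4, 4)), origin=(10.0, -5.0, 3.0))
        assert np.allclose(world_to_index(vol, np.array([10.0, -5.0, 3.0])), 0.0)

    def test_one_step_along_first_axis(self):
        rng = np.random.default_rng(0)
        axes = random_orthonormal_axes(rng)
        vol = make_volume(np.zeros((4, 4, 4)), origin=(1.0, 2.0, 3.0), axes=axes, spacing=(1.25, 1.25, 1.25))
        p = vol.origin + vol.spacing[0] * axes[0]
        assert np.allclose(world_to_index(vol, p), [1.0, 0.0, 0.0], atol=1e-12)

    def test_round_trip_on_random_voxel_centers(self):
        rng = np.random.default_rng(7)
        axes = random_orthonormal_axes(rng)
        vol = make_volume(
            np.zeros((30, 40, 50)), origin=(-20.0, 13.0, 5.0), axes=axes, spacing=(1.25, 0.7, 2.0)
        )
        idx = rng.integers(0, [30, 40, 50], size=(1000, 3)).astype(float)
        back = world_to_index(vol, index_to_world(vol, idx))
        assert np.abs(back - idx).max() < 1e-9

    def test_non_orthonormal_axes_rejected(self):
        axes = np.eye(3)
        axes[0, 1] = 0.1  # shear
        with pytest.raises(GeometryError):
            make_volume(np.zeros((2, 2, 2)), axes=axes)


class TestShiftedPlaneOffsets:
    def test_paper_geometry_seven_planes(self):
        # 7 mm slab at 1.25 mm isotropic steps: k = 3, span 7.5 mm
        off = shifted_plane_offsets(7.0, 1.25)
        assert np.allclose(off, np.arange(-3, 4) * 1.25)
        assert len(off) == 7

    @pytest.mark.parametrize("slab,step,expected_k", [(1.0, 1.0, 1), (2.0, 1.0, 1), (2.1, 1.0, 2)])
    def test_small_slabs(self, slab, step, expected_k):
        off = shifted_plane_offsets(slab, step)
        assert len(off) == 2 * expected_k + 1
        assert off[0] == -expected_k * step and off[-1] == expected_k * step

    def test_floor_rule(self):
        assert len(shifted_plane_offsets(7.0, 1.25, rule="floor")) == 5  # k = floor(2.8) = 2

    def test_zero_offset_always_present_and_sorted(self):
        off = shifted_plane_offsets(5.3, 0.8)
        assert 0.0 in off
        assert np.all(np.diff(off) > 0)

    @pytest.mark.parametrize("slab,step", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_invalid_parameters(self, slab, step):
        with pytest.raises(InvalidParameterError):
            shifted_plane_offsets(slab, step)


class TestSamplePlane:
    def test_constant_volume_samples_constant(self):
        vol = make_volume(np.full((10, 10, 10), 3.5))
        geom = make_slice(origin=(2.0, 3.0, 4.0), n_rows=5, n_cols=5)
        img = sample_plane(vol, geom)
        assert np.all(img.valid_mask)
        assert np.allclose(img.pixels, 3.5)

    def test_lattice_coincident_plane_reproduces_voxels(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(6, 7, 8))
        vol = make_volume(data)
        # plane z = index 3, pixel grid matching the voxel grid
        geom = make_slice(origin=(0.0, 0.0, 3.0), n_rows=7, n_cols=6)
        img = sample_plane(vol, geom)
        # pixel (r, c) sits at world (c, r, 3) -> voxel (c, r, 3)
        assert np.allclose(img.pixels, data[:, :, 3].T)

    def test_affine_field_sampled_exactly_on_oblique_plane(self):
        # trilinear interpolation is exact for f(x, y, z) = x
        n = 24
        idx = np.arange(n, dtype=float)
        vol = make_volume(np.broadcast_to(idx[:, None, None], (n, n, n)).copy(), spacing=(1.0, 1.0, 1.0))
        rng = np.random.default_rng(3)
        axes = random_orthonormal_axes(rng)
        geom = make_slice(
            origin=(12.0, 12.0, 12.0), row_dir=axes[0], col_dir=axes[1], pixel_spacing=(0.7, 0.7), n_rows=9, n_cols=9
        )
        img = sample_plane(vol, geom)
        expected = geom.pixel_centers_world()[..., 0]
        assert np.abs(img.pixels[img.valid_mask] - expected[img.valid_mask]).max() < 1e-9

    def test_fully_outside_plane_all_invalid(self):
        vol = make_volume(np.zeros((4, 4, 4)))
        geom = make_slice(origin=(100.0, 100.0, 100.0))
        img = sample_plane(vol, geom)
        assert not img.valid_mask.any()


def _smooth_volume(n=48, spacing=1.25, seed=0):
    rng = np.random.default_rng(seed)
    coord = np.arange(n) * spacing
    x, y, z = np.meshgrid(coord, coord, coord, indexing="ij")
    data = np.zeros_like(x)
    for _ in range(4):
        cx, cy, cz = rng.uniform(0.2 * n, 0.8 * n, 3) * spacing
        w = rng.uniform(8, 18)
        data += rng.uniform(50, 150) * np.exp(-((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) / w**2)
    return make_volume(data, spacing=(spacing,) * 3)


def _dense_slab_oracle(vol, geom, step=0.1):
    """Independent slab average: dense normal sampling of the trilinear
    interpolant via scipy.ndimage.map_coordinates (order=1)."""
    offsets = shifted_plane_offsets(geom.thickness, float(vol.spacing.min()))
    span = (offsets[0], offsets[-1])
    dense = np.arange(span[0], span[1] + step / 2, step)
    acc = np.zeros((geom.n_rows, geom.n_cols))
    cnt = np.zeros((geom.n_rows, geom.n_cols))
    for off in dense:
        pts = geom.pixel_centers_world(float(off))
        idx = world_to_index(vol, pts).reshape(-1, 3).T
        vals = map_coordinates(vol.voxels, idx, order=1, cval=np.nan).reshape(geom.n_rows, geom.n_cols)
        ok = np.isfinite(vals)
        acc[ok] += vals[ok]
        cnt += ok
    out = np.full_like(acc, np.nan)
    out[cnt > 0] = acc[cnt > 0] / cnt[cnt > 0]
    return out


class TestReslice:
    def test_constant_volume_reslices_to_constant(self):
        vol = make_volume(np.full((20, 20, 20), 7.0), spacing=(1.25, 1.25, 1.25))
        geom = make_slice(origin=(10.0, 10.0, 10.0), thickness=7.0, n_rows=4, n_cols=4)
        img = reslice(vol, geom)
        assert np.allclose(img.pixels, 7.0)
        assert img.meta["n_planes"] == 7

    def test_normal_ramp_cancels_by_symmetry(self):
        n = 20
        idx = np.arange(n, dtype=float)
        vol = make_volume(np.broadcast_to(idx[None, None, :], (n, n, n)).copy())
        geom = make_slice(origin=(8.0, 8.0, 9.0), thickness=4.0, n_rows=4, n_cols=4)
        img = reslice(vol, geom)  # normal = +z, field = z
        assert np.allclose(img.pixels, 9.0, atol=1e-12)

    def test_volume_constant_along_normal_equals_single_plane(self):
        rng = np.random.default_rng(5)
        slab = rng.normal(size=(16, 16))
        vol = make_volume(np.broadcast_to(slab[:, :, None], (16, 16, 16)).copy())
        geom = make_slice(origin=(4.0, 4.0, 8.0), thickness=6.0, n_rows=6, n_cols=6)
        assert np.allclose(reslice(vol, geom).pixels, sample_plane(vol, geom, 0.0).pixels)

    def test_pixel_bounded_by_plane_extremes(self):
        vol = _smooth_volume(seed=2)
        geom = make_slice(origin=(20.0, 25.0, 30.0), pixel_spacing=(1.4, 1.4), n_rows=10, n_cols=10, thickness=7.0)
        offsets = shifted_plane_offsets(7.0, 1.25)
        planes = np.stack([sample_plane(vol, geom, float(o)).pixels for o in offsets])
        img = reslice(vol, geom)
        ok = img.valid_mask & np.all(np.isfinite(planes), axis=0)
        assert np.all(img.pixels[ok] <= np.max(planes, axis=0)[ok] + 1e-12)
        assert np.all(img.pixels[ok] >= np.min(planes, axis=0)[ok] - 1e-12)

    def test_row_col_relabel_invariance(self):
        vol = _smooth_volume(seed=4)
        o = np.array([25.0, 25.0, 25.0])
        rng = np.random.default_rng(11)
        axes = random_orthonormal_axes(rng)
        n = 8
        ps = 1.4
        a = make_slice(origin=o, row_dir=axes[0], col_dir=axes[1], pixel_spacing=(ps, ps), n_rows=n, n_cols=n, thickness=7.0)
        # swap roles of rows and columns: same pixel-center set, flipped normal
        b = make_slice(origin=o, row_dir=axes[1], col_dir=axes[0], pixel_spacing=(ps, ps), n_rows=n, n_cols=n, thickness=7.0)
        ia, ib = reslice(vol, a), reslice(vol, b)
        assert np.allclose(ia.pixels, ib.pixels.T, equal_nan=True)

    def test_anisotropic_volume_warns_and_uses_min_spacing(self):
        vol = make_volume(np.zeros((20, 20, 8)), spacing=(1.0, 1.0, 3.0))
        geom = make_slice(origin=(8.0, 8.0, 8.0), thickness=4.0, n_rows=3, n_cols=3)
        with pytest.warns(UserWarning, match="anisotropic"):
            img = reslice(vol, geom)
        assert img.meta["step_mm"] == 1.0

    def test_agrees_with_dense_slab_average_oracle(self):
        """Plane-mean reslice vs dense 0.1 mm normal-sampling slab average."""
        vol = _smooth_volume(seed=0)
        vrange = np.ptp(vol.voxels)
        rng = np.random.default_rng(42)
        for _ in range(5):
            axes = random_orthonormal_axes(rng)
            origin = rng.uniform(18, 42, 3)
            geom = make_slice(
                origin=origin, row_dir=axes[0], col_dir=axes[1],
                pixel_spacing=(1.4, 1.4), n_rows=12, n_cols=12, thickness=7.0,
            )
            img = reslice(vol, geom)
            oracle = _dense_slab_oracle(vol, geom)
            both = img.valid_mask & np.isfinite(oracle)
            assert both.any()
            err = np.abs(img.pixels[both] - oracle[both]).max()
            assert err <= 0.02 * vrange
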
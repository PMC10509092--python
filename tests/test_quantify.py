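"""Thresholding, fallback routing, masses and contrast ratio."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

from lgequant.errors import (
    ContourError,
    EmptyRoiError,
    InvalidParameterError,
    NoReferenceError,
)
from lgequant.geometry import PlanarImage
from lgequant.quantify import (
    ContourSet,
    SliceContours,
    blood_pool_rim_mask,
    compute_masses,
    contrast_ratio,
    fwhm_threshold,
    nsd_threshold,
    quantify_slice,
    rasterize_polygon,
    resolve_reference,
    rim_artifact_removal,
)

from conftest import make_slice


def _image(values: np.ndarray, pixel_spacing=(1.0, 1.0)) -> PlanarImage:
    values = np.asarray(values, dtype=float)
    geom = make_slice(
        pixel_spacing=pixel_spacing, n_rows=values.shape[0], n_cols=values.shape[1]
    )
    return PlanarImage(values, geom, np.ones(values.shape, bool))


def _disk(x, y, r=0.3) -> Polygon:
    return Point(x, y).buffer(r, quad_segs=8)


class TestThresholds:
    def test_fwhm_is_half_the_roi_maximum(self):
        img = _image([[180.0, 200.0, 150.0], [0.0, 0.0, 0.0]])
        roi = box(-0.4, -0.4, 2.4, 0.4)  # covers the three top-row centers
        assert fwhm_threshold(img.pixels, roi, img.geometry) == 100.0

    def test_fwhm_uniform_roi(self):
        img = _image(np.full((4, 4), 37.0))
        assert fwhm_threshold(img.pixels, box(0, 0, 3, 3), img.geometry) == 18.5

    def test_fwhm_empty_roi_raises(self):
        img = _image(np.zeros((4, 4)))
        with pytest.raises(EmptyRoiError):
            fwhm_threshold(img.pixels, _disk(0.5, 0.5, 0.1), img.geometry)

    def test_fwhm_scaling_covariance(self):
        """Scaling the image by c scales the threshold by c; the mask is unchanged."""
        rng = np.random.default_rng(0)
        img = _image(rng.uniform(50, 300, (8, 8)))
        roi = box(1, 1, 6, 6)
        thr = fwhm_threshold(img.pixels, roi, img.geometry)
        for c in (0.25, 3.0, 17.5):
            thr_c = fwhm_threshold(c * img.pixels, roi, img.geometry)
            assert thr_c == pytest.approx(c * thr, rel=1e-12)
            assert np.array_equal(img.pixels >= thr, c * img.pixels >= thr_c)

    def test_nsd_mean_plus_three_sd(self):
        # values {40, 50, 60}: mean 50, sample SD exactly 10
        img = _image([[40.0, 50.0, 60.0]])
        roi = box(-0.4, -0.4, 2.4, 0.4)
        assert nsd_threshold(img.pixels, roi, img.geometry, n=3) == pytest.approx(80.0)
        assert nsd_threshold(img.pixels, roi, img.geometry, n=0) == pytest.approx(50.0)

    def test_nsd_constant_roi_threshold_is_the_constant(self):
        img = _image(np.full((3, 3), 42.0))
        assert nsd_threshold(img.pixels, box(0, 0, 2, 2), img.geometry) == 42.0

    def test_nsd_single_pixel_raises(self):
        img = _image(np.zeros((4, 4)))
        with pytest.raises(EmptyRoiError):
            nsd_threshold(img.pixels, _disk(1.0, 1.0), img.geometry)


def _ring_contours(slice_index, r_endo=20.0, r_epi=30.0, center=(31.5, 31.5), rois=None):
    cx, cy = center
    return SliceContours(
        slice_index=slice_index,
        endo=Point(cx, cy).buffer(r_endo, quad_segs=90),
        epi=Point(cx, cy).buffer(r_epi, quad_segs=90),
        rois=rois or {},
    )


def _stack(values_per_slice, rois_per_slice):
    images, entries = [], []
    for k, (vals, rois) in enumerate(zip(values_per_slice, rois_per_slice)):
        images.append(_image(vals))
        entries.append(_ring_contours(k, rois=rois))
    return images, ContourSet(entries)


class TestResolveReference:
    def _roi_at_center(self):
        return {"scar_roi": _disk(31.5, 31.5 - 25.0, 1.2)}  # inside the ring

    def test_single_donor_propagates_to_all(self):
        vals = np.full((64, 64), 10.0)
        roi = self._roi_at_center()
        donor = vals.copy()
        donor[6, 31] = 200.0  # inside scar roi (y=6.5 -> ~r 25 from center)
        donor[6, 32] = 200.0
        values = [vals, vals, donor, vals, vals]
        rois = [{}, {}, roi, {}, {}]
        images, contours = _stack(values, rois)
        out = resolve_reference(images, contours, "fwhm")
        assert [t for t, _ in out] == [100.0] * 5
        assert [s for _, s in out] == [
            "nearest_slice:2", "nearest_slice:2", "self", "nearest_slice:2", "nearest_slice:2",
        ]

    def test_equidistant_tie_breaks_toward_base(self):
        vals = np.full((64, 64), 10.0)
        roi = {"remote_roi": box(28, 4, 35, 9)}
        basal = vals.copy()
        basal[5:9, 28:36] = 50.0
        apical = vals.copy()
        apical[5:9, 28:36] = 70.0
        values = [basal, vals, vals, vals, apical]
        rois = [roi, {}, {}, {}, roi]
        images, contours = _stack(values, rois)
        out = resolve_reference(images, contours, "nsd")
        # slice 2 is equidistant from donors 0 and 4 -> inherits the basal one
        assert out[2][1] == "nearest_slice:0"
        assert out[2][0] == pytest.approx(out[0][0])
        assert out[3][1] == "nearest_slice:4"

    def test_all_self_when_every_slice_has_roi(self):
        vals = np.full((64, 64), 10.0)
        vals[5:9, 28:36] = 60.0
        roi = {"remote_roi": box(28, 4, 35, 9)}
        images, contours = _stack([vals] * 3, [roi] * 3)
        out = resolve_reference(images, contours, "nsd")
        assert all(s == "self" for _, s in out)

    def test_no_reference_anywhere_raises(self):
        vals = np.full((64, 64), 10.0)
        images, contours = _stack([vals] * 3, [{}] * 3)
        with pytest.raises(NoReferenceError):
            resolve_reference(images, contours, "fwhm")


class TestQuantifySlice:
    def test_threshold_above_everything_gives_zero_scar(self):
        img = _image(np.full((64, 64), 50.0))
        q = quantify_slice(img, _ring_contours(0), threshold=1e9)
        assert q.scar_area == 0.0 and q.myo_area > 0

    def test_threshold_below_everything_gives_full_scar(self):
        img = _image(np.full((64, 64), 50.0))
        q = quantify_slice(img, _ring_contours(0), threshold=-1e9)
        assert q.scar_area == q.myo_area

    def test_annulus_area_close_to_analytic(self):
        """Pixel-center counting vs the exact annulus area pi (30^2 - 20^2)."""
        img = _image(np.zeros((64, 64)))
        q = quantify_slice(img, _ring_contours(0), threshold=1.0)
        assert q.myo_area == pytest.approx(np.pi * (30.0**2 - 20.0**2), rel=0.01)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        img = _image(rng.uniform(0, 100, (64, 64)))
        ctr = _ring_contours(0)
        areas = [quantify_slice(img, ctr, thr).scar_area for thr in np.linspace(0, 110, 23)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_manual_correction_masks(self):
        img = _image(np.full((64, 64), 50.0))
        ctr = _ring_contours(0)
        base = quantify_slice(img, ctr, threshold=60.0)
        add = np.zeros((64, 64), bool)
        add[31, 2:8] = True  # inside the ring on the left
        q_add = quantify_slice(img, ctr, 60.0, add_mask=add)
        assert q_add.scar_area > base.scar_area
        q_rem = quantify_slice(img, ctr, -1e9, remove_mask=np.ones((64, 64), bool))
        assert q_rem.scar_area == 0.0

    def test_degenerate_contour_rejected(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        with pytest.raises(ContourError):
            SliceContours(0, endo=bowtie, epi=Point(1, 1).buffer(5))

    def test_endo_must_be_inside_epi(self):
        with pytest.raises(ContourError):
            SliceContours(0, endo=Point(10, 0).buffer(3), epi=Point(0, 0).buffer(5))

    def test_nonfinite_threshold_rejected(self):
        img = _image(np.zeros((8, 8)))
        with pytest.raises(InvalidParameterError):
            quantify_slice(img, _ring_contours(0, 1.0, 2.0, center=(3.5, 3.5)), np.nan)


class TestMasses:
    def _quant(self, myo, scar, idx=0):
        q = quantify_slice(_image(np.full((64, 64), 50.0)), _ring_contours(idx), -1e9)
        q.myo_area, q.scar_area = myo, scar
        return q

    def test_single_slice_mass_arithmetic(self):
        res = compute_masses([self._quant(1000.0, 0.0)], slice_thickness=7.0, density=1.05)
        assert res.myocardial_mass == pytest.approx(7.35)

    def test_full_scar_means_extent_100(self):
        res = compute_masses([self._quant(800.0, 800.0, k) for k in range(4)], 7.0)
        assert res.lge_extent == pytest.approx(100.0)

    def test_mass_additivity_over_substacks(self):
        slices = [self._quant(1000.0 + 10 * k, 100.0 * k, k) for k in range(6)]
        full = compute_masses(slices, 7.0)
        a = compute_masses(slices[:3], 7.0)
        b = compute_masses(slices[3:], 7.0)
        assert a.myocardial_mass + b.myocardial_mass == pytest.approx(full.myocardial_mass)
        assert a.scar_mass + b.scar_mass == pytest.approx(full.scar_mass)

    def test_zero_myocardium_flags_extent_undefined(self):
        res = compute_masses([self._quant(0.0, 0.0)], 7.0)
        assert not res.extent_defined and np.isnan(res.lge_extent)


class TestContrastRatio:
    def test_paper_style_values(self):
        assert contrast_ratio(np.full(10, 100.0), np.full(10, 23.0)) == pytest.approx(0.77)

    def test_identical_rois_give_zero(self):
        assert contrast_ratio(np.full(5, 80.0), np.full(7, 80.0)) == 0.0

    def test_perfect_nulling_gives_one(self):
        assert contrast_ratio(np.full(5, 80.0), np.zeros(4)) == 1.0

    def test_empty_roi_rejected(self):
        with pytest.raises(EmptyRoiError):
            contrast_ratio(np.array([]), np.array([1.0]))

    def test_nonpositive_blood_rejected(self):
        with pytest.raises(InvalidParameterError):
            contrast_ratio(np.zeros(4), np.ones(4))


class TestRimCorrection:
    def _setup(self):
        ctr = _ring_contours(0)
        geom = make_slice(n_rows=64, n_cols=64)
        rim = blood_pool_rim_mask(ctr, geom, rim_mm=2.0)
        myo = rasterize_polygon(ctr.epi, geom) & ~rasterize_polygon(ctr.endo, geom)
        return ctr, geom, rim, myo

    def test_rim_band_is_thin_and_inside_myocardium(self):
        _, _, rim, myo = self._setup()
        assert rim.any()
        assert not (rim & ~myo).any()

    def test_isolated_rim_ring_removed(self):
        _, _, rim, _ = self._setup()
        removed = rim_artifact_removal(rim.copy(), rim)
        assert np.array_equal(removed, rim)  # nothing rescued: all removed

    def test_transmural_scar_touching_rim_is_kept(self):
        _, _, rim, myo = self._setup()
        # scar = rim ring plus a transmural wedge on the right side
        wedge = myo & (np.arange(64)[None, :] > 51.5)
        scar = rim | wedge
        removed = rim_artifact_removal(scar, rim)
        kept = scar & ~removed
        assert (kept & rim & wedge.any(axis=1)[:, None]).any()  # wedge rim survives
        assert not removed[wedge & ~rim].any()  # interior never removed
        # far side of the ring (pure rim, no adjacent wedge) is cleared
        assert removed[:, :10].sum() == rim[:, :10].sum()
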
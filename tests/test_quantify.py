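"""Planar template and 3D lobar quantification."""

import numpy as np
import pytest

import vqlobes as vq
from vqlobes.quantify import (BAND_ORDER, build_third_rois, combine_views,
                              place_background_roi, redistribute_left_middle)


def box_mask(shape, x0, x1, z0, z1):
    m = np.zeros(shape, dtype=bool)
    m[x0:x1 + 1, z0:z1 + 1] = True
    return m


def planar_from(pixels, view="anterior"):
    return vq.PlanarImage(view=view, pixels=np.asarray(pixels, float),
                          pixel_spacing_mm=(3.3, 3.3), attenuated=False)


class TestThirdROIs:
    @pytest.mark.parametrize("H, heights", [
        (30, (10, 10, 10)),
        (31, (10, 11, 10)),   # boundaries round(31/3)=10, round(62/3)=21
        (32, (11, 10, 11)),
    ])
    def test_band_heights_rounding(self, H, heights):
        mask = box_mask((20, H + 10), 3, 15, 4, 4 + H - 1)
        rois = build_third_rois(mask)
        got = {b: r[3] - r[2] + 1 for b, r in rois.rects.items()}
        assert (got["inferior"], got["middle"], got["superior"]) == heights

    def test_bands_partition_bbox(self):
        mask = box_mask((20, 50), 2, 17, 5, 41)
        rois = build_third_rois(mask)
        union = np.zeros_like(mask)
        for b in BAND_ORDER:
            band = rois.bands[b]
            assert not (union & band).any()  # no overlap
            union |= band
        assert np.array_equal(union, mask)   # box mask: bands tile it

    def test_rect_mask_thirds_within_one_row(self):
        mask = box_mask((20, 50), 2, 17, 5, 41)  # H=37, 16 px wide
        rois = build_third_rois(mask)
        counts = {b: int(rois.bands[b].sum()) for b in BAND_ORDER}
        third = mask.sum() / 3
        for b in BAND_ORDER:
            assert abs(counts[b] - third) <= 16  # ±1 row of 16 px

    def test_superior_band_is_highest_z(self):
        mask = box_mask((10, 30), 0, 9, 0, 29)
        rois = build_third_rois(mask)
        assert rois.rects["superior"][3] == 29
        assert rois.rects["inferior"][2] == 0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            build_third_rois(np.zeros((5, 5), dtype=bool))


class TestBackgroundROI:
    def test_disjoint_from_body(self, coarse_phantom):
        from vqlobes.projection import project_body_mask, project_mask
        body = project_body_mask(coarse_phantom.body_mask())
        for lung in ("right", "left"):
            mask = project_mask(coarse_phantom.labels, lung=lung)
            x0, x1, z0, z1 = place_background_roi(mask, body)
            assert not body[x0:x1 + 1, z0:z1 + 1].any()
            assert not mask[x0:x1 + 1, z0:z1 + 1].any()

    def test_symmetric_phantom_mirror_placement(self, coarse_phantom):
        """On the x-symmetric silhouettes the two background ROIs mirror
        each other (64-wide image: x ↦ 63−x)."""
        from vqlobes.projection import project_body_mask, project_mask
        body = project_body_mask(coarse_phantom.body_mask())
        right = project_mask(coarse_phantom.labels, lung="right")
        # mirror the right silhouette to stand in for a perfectly symmetric left
        left = right[::-1, :].copy()
        body_sym = body | body[::-1, :]
        r = place_background_roi(right, body_sym)
        l = place_background_roi(left, body_sym)
        nx = right.shape[0]
        assert (l[0], l[1]) == (nx - 1 - r[1], nx - 1 - r[0])
        assert (l[2], l[3]) == (r[2], r[3])

    def test_no_room_raises(self):
        mask = box_mask((10, 30), 1, 8, 5, 25)
        body = np.ones((10, 30), dtype=bool)
        with pytest.raises(ValueError, match="field of view"):
            place_background_roi(mask, body)


class TestBackgroundSubtract:
    def test_closed_form(self):
        pixels = np.zeros((30, 30))
        pixels[5:15, 5:15] = 5.0      # ROI raw sum = 500 over 100 px
        pixels[20:25, 20:25] = 2.0    # background mean 2/px
        img = planar_from(pixels)
        roi = box_mask((30, 30), 5, 14, 5, 14)
        got = vq.background_subtract(img, roi, (20, 24, 20, 24))
        assert got == pytest.approx(500 - 2 * 100)

    def test_zero_background_is_noop(self):
        pixels = np.zeros((20, 20))
        pixels[2:6, 2:6] = 3.0
        img = planar_from(pixels)
        roi = box_mask((20, 20), 2, 5, 2, 5)
        assert vq.background_subtract(img, roi, (10, 14, 10, 14)) == \
            pytest.approx(pixels.sum())

    def test_clipping_at_zero(self, caplog):
        pixels = np.zeros((30, 30))
        pixels[5:15, 5:15] = 5.0      # raw 500
        pixels[20:25, 20:25] = 10.0   # bg mean 10 → correction 1000 > raw
        img = planar_from(pixels)
        roi = box_mask((30, 30), 5, 14, 5, 14)
        with caplog.at_level("WARNING"):
            got = vq.background_subtract(img, roi, (20, 24, 20, 24))
        assert got == 0.0
        assert "clipped" in caplog.text


class TestCombineAndRedistribute:
    @pytest.mark.parametrize("mode", ["geometric_mean", "arithmetic_mean",
                                      "anterior_only", "posterior_only"])
    def test_equal_views_any_mode(self, mode):
        assert combine_views(100, 100, mode) == pytest.approx(100)

    def test_geometric_mean(self):
        assert combine_views(400, 100, "geometric_mean") == pytest.approx(200)
        assert combine_views(0, 100, "geometric_mean") == 0.0

    @pytest.mark.parametrize("smi, expected", [
        ((30, 20, 50), (40, 60)),
        ((0, 0, 0), (0, 0)),
        ((0, 100, 0), (50, 50)),
    ])
    def test_left_middle_redistribution(self, smi, expected):
        assert redistribute_left_middle(*smi) == pytest.approx(expected)

    def test_redistribution_conserves_total(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s, m, i = rng.random(3) * 100
            s2, i2 = redistribute_left_middle(s, m, i)
            assert s2 + i2 == pytest.approx(s + m + i, rel=1e-15)


def _box_lung_images(nx=64, nz=64, value=4.0):
    """Uniform rectangular 'lungs' with no attenuation and zero background."""
    pixels = np.zeros((nx, nz))
    right = box_mask((nx, nz), 14, 30, 10, 51)   # H = 42 → thirds of 14
    left = box_mask((nx, nz), 33, 49, 10, 51)
    pixels[right] = value
    pixels[left] = value
    body = np.zeros((nx, nz), dtype=bool)
    body[12:52, 6:58] = True
    ant = planar_from(pixels, "anterior")
    post = planar_from(pixels, "posterior")
    roiset = vq.ROISet(
        right=build_third_rois(right),
        left=build_third_rois(left),
        right_background=place_background_roi(right, body),
        left_background=place_background_roi(left, body),
    )
    return ant, post, roiset


class TestQuantifyPlanar:
    def test_uniform_box_lungs_give_equal_thirds(self):
        """Box-shaped lungs, flat counts, no attenuation: each right third
        holds one third of the right-lung counts, so RUL=RML=RLL."""
        ant, post, roiset = _box_lung_images()
        dist = vq.quantify_planar(ant, post, roiset)
        assert dist.rul == pytest.approx(dist.rml, rel=1e-12)
        assert dist.rml == pytest.approx(dist.rll, rel=1e-12)
        assert dist.right_lung == pytest.approx(50.0, rel=1e-12)
        # left middle redistributed: LUL = LLL = 25 each
        assert dist.lul == pytest.approx(25.0, rel=1e-12)

    def test_output_sums_to_100(self, default_phantom, noiseless_spect):
        mu = vq.hu_to_mu(default_phantom.hu, default_phantom.grid)
        ant = vq.project_planar(noiseless_spect, mu, "anterior")
        post = vq.project_planar(noiseless_spect, mu, "posterior")
        roiset = vq.default_roiset(default_phantom.labels,
                                   default_phantom.body_mask())
        dist = vq.quantify_planar(ant, post, roiset)
        assert dist.values().sum() == pytest.approx(100, abs=1e-9)

    def test_template_inflates_small_middle_lobe(self, default_phantom,
                                                 noiseless_spect):
        """The anterior-wedge RML is far smaller than one axial third, so the
        equal-thirds template overestimates it."""
        mu = vq.hu_to_mu(default_phantom.hu, default_phantom.grid)
        ant = vq.project_planar(noiseless_spect, mu, "anterior")
        post = vq.project_planar(noiseless_spect, mu, "posterior")
        roiset = vq.default_roiset(default_phantom.labels,
                                   default_phantom.body_mask())
        planar = vq.quantify_planar(ant, post, roiset)
        truth = default_phantom.truth_v
        assert planar.rml > truth.rml
        assert planar.rul < truth.rul
        assert planar.rll < truth.rll


class TestQuantifyLobar:
    def test_exact_on_unblurred_noiseless(self, default_phantom):
        """Truth labels + raw activity scaled to counts: identical sums."""
        sv = vq.simulate_spect(default_phantom.activity_v,
                               default_phantom.grid, psf_fwhm_mm=0.0,
                               total_counts=5e6, noise=False)
        dist = vq.quantify_lobar(sv, default_phantom.labels)
        assert np.allclose(dist.values(), default_phantom.truth_v.values(),
                           atol=1e-9)

    def test_all_counts_in_one_lobe(self, coarse_phantom):
        counts = np.zeros(coarse_phantom.grid.shape)
        counts[coarse_phantom.labels.lobe_mask("RUL")] = 2.0
        sv = vq.SpectVolume(grid=coarse_phantom.grid, counts=counts,
                            noise=False)
        dist = vq.quantify_lobar(sv, coarse_phantom.labels)
        assert dist.values() == pytest.approx([100, 0, 0, 0, 0])

    def test_blurred_within_1p5_points(self, default_phantom, noiseless_spect):
        dist = vq.quantify_lobar(noiseless_spect, default_phantom.labels)
        err = np.abs(dist.values() - default_phantom.truth_v.values())
        assert np.all(err < 1.5)

    def test_absent_lobe_flagged(self, coarse_phantom):
        removed = vq.apply_lobectomy(coarse_phantom, "RML")
        sv = vq.simulate_spect(removed.activity_v, removed.grid,
                               psf_fwhm_mm=0.0, noise=False)
        dist = vq.quantify_lobar(sv, removed.labels)
        assert dist.rml == 0.0
        assert "RML" in dist.absent

    def test_grid_mismatch_raises(self, coarse_phantom):
        sv = vq.SpectVolume(grid=vq.DEFAULT_SPECT_GRID,
                            counts=np.ones(vq.DEFAULT_SPECT_GRID.shape),
                            noise=False)
        with pytest.raises(ValueError, match="grid"):
            vq.quantify_lobar(sv, coarse_phantom.labels)
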
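"""Phantom geometry, ground-truth fractions, and structural modifications."""

import numpy as np
import pytest
from dataclasses import replace

import vqlobes as vq
from vqlobes.distribution import LOBE_CODES, LOBE_NAMES

from conftest import COARSE_GRID


class TestTruthFractions:
    def test_uniform_activity_matches_volume_shares(self, default_phantom):
        """With specific activity 1 everywhere, truth fractions equal each
        lobe's voxel-volume share of the total lung volume."""
        vc = default_phantom.labels.voxel_counts()
        total = sum(vc.values())
        truth = default_phantom.truth_v
        for name in LOBE_NAMES:
            assert truth.region(name) == pytest.approx(100 * vc[name] / total,
                                                       abs=1e-9)

    def test_activity_only_in_rml(self):
        spec = replace(vq.PhantomSpec(),
                       activity_v={n: (1.0 if n == "RML" else 0.0)
                                   for n in LOBE_NAMES})
        ph = vq.build_phantom(spec, COARSE_GRID)
        assert ph.truth_v.values() == pytest.approx([0, 100, 0, 0, 0])

    def test_prescribed_lobe_sums(self, coarse_phantom):
        """Per-lobe activity sums (2000, 1000, 2500, 2500, 2000) must yield
        (20, 10, 25, 25, 20)% regardless of lobe volumes."""
        targets = dict(zip(LOBE_NAMES, (2000.0, 1000.0, 2500.0, 2500.0, 2000.0)))
        vc = coarse_phantom.labels.voxel_counts()
        spec = replace(coarse_phantom.spec,
                       activity_v={n: targets[n] / vc[n] for n in LOBE_NAMES})
        ph = vq.build_phantom(spec, COARSE_GRID)
        assert ph.truth_v.values() == pytest.approx([20, 10, 25, 25, 20],
                                                    abs=1e-6)

    def test_fractions_sum_to_100(self, default_phantom):
        assert default_phantom.truth_v.values().sum() == pytest.approx(
            100, abs=1e-9)
        assert default_phantom.truth_q.values().sum() == pytest.approx(
            100, abs=1e-9)

    def test_zero_total_activity_is_error(self):
        spec = replace(vq.PhantomSpec(),
                       activity_v={n: 0.0 for n in LOBE_NAMES})
        ph = vq.build_phantom(spec, COARSE_GRID)
        with pytest.raises(ValueError, match="zero"):
            vq.true_lobar_fractions(ph, "V")


class TestRasterization:
    def test_label_conservation(self, default_phantom):
        """Per-lobe voxel counts sum to the total lung voxel count."""
        labels = default_phantom.labels.labels
        lung_total = int((labels > 0).sum())
        assert sum(default_phantom.labels.voxel_counts().values()) == lung_total

    def test_hu_values(self, default_phantom):
        ph = default_phantom
        labels = ph.labels.labels
        thorax = ph.body_mask()
        assert np.all(ph.hu[~thorax] == ph.spec.hu_air)
        assert np.all(ph.hu[labels > 0] == ph.spec.hu_parenchyma)
        soft = thorax & (labels == 0)
        assert np.all(ph.hu[soft] == ph.spec.hu_soft_tissue)

    def test_activity_zero_outside_lungs(self, default_phantom):
        outside = default_phantom.labels.labels == 0
        assert np.all(default_phantom.activity_v[outside] == 0)
        assert np.all(default_phantom.activity_q[outside] == 0)

    def test_determinism(self):
        spec = vq.sample_spec(123)
        a = vq.build_phantom(spec, COARSE_GRID)
        b = vq.build_phantom(spec, COARSE_GRID)
        assert np.array_equal(a.labels.labels, b.labels.labels)
        assert np.array_equal(a.hu, b.hu)
        assert np.array_equal(a.activity_v, b.activity_v)

    def test_resolution_stability(self):
        """Truth fractions at 1.1 mm vs 3.3 mm agree within 1.5 points/lobe
        (pure discretisation error of the analytic rasterisation)."""
        spec = vq.PhantomSpec()
        fine = vq.VoxelGrid(shape=(320, 224, 352), spacing_mm=(1.1, 1.1, 1.1))
        t_fine = vq.build_phantom(spec, fine).truth_v.values()
        t_coarse = vq.build_phantom(spec, vq.DEFAULT_SPECT_GRID).truth_v.values()
        assert np.all(np.abs(t_fine - t_coarse) < 1.5)

    def test_empty_lobe_raises_named_error(self):
        """A horizontal fissure below the oblique one leaves no middle lobe."""
        fiss = replace(vq.FissureSet(), right_horizontal_height=0.2,
                       right_oblique_tilt_deg=0.0)
        spec = replace(vq.PhantomSpec(), fissures=fiss)
        with pytest.raises(ValueError, match="RML"):
            vq.build_phantom(spec, COARSE_GRID)

    def test_lung_outside_thorax_raises(self):
        spec = replace(vq.PhantomSpec(),
                       right_lung_center_mm=(-140.0, -4.0, 5.0))
        with pytest.raises(ValueError, match="thorax"):
            vq.build_phantom(spec, COARSE_GRID)


class TestAnatomicalOrdering:
    def test_ordering_invariants_over_random_specs(self):
        """Laterality and centroid ordering of the lobes hold for every draw
        from the default population ranges."""
        rng = np.random.default_rng(2024)
        x, y, z = COARSE_GRID.coordinate_mesh()
        for _ in range(100):
            ph = vq.build_phantom(vq.sample_spec(rng), COARSE_GRID)
            labels = ph.labels.labels
            assert set(np.unique(labels)) == {0, 1, 2, 3, 4, 5}
            # laterality: right lobes at x < 0, left lobes at x > 0
            assert np.all(np.broadcast_to(x, labels.shape)[
                np.isin(labels, [1, 2, 3])] < 0)
            assert np.all(np.broadcast_to(x, labels.shape)[
                np.isin(labels, [4, 5])] > 0)

            def centroid(code, coord):
                m = labels == code
                return float(np.broadcast_to(coord, labels.shape)[m].mean())

            # RML anterior to RLL; RUL superior to both
            assert centroid(2, y) > centroid(3, y)
            assert centroid(1, z) > centroid(2, z)
            assert centroid(1, z) > centroid(3, z)


class TestLobectomy:
    def test_remove_rml_renormalises(self, coarse_phantom):
        before = coarse_phantom.truth_v
        after = vq.apply_lobectomy(coarse_phantom, "RML")
        dist = after.truth_v
        assert dist.rml == 0
        assert "RML" in dist.absent
        assert dist.values().sum() == pytest.approx(100, abs=1e-9)
        # remaining lobes keep their relative proportions
        keep = [n for n in LOBE_NAMES if n != "RML"]
        ratios = [dist.region(n) / before.region(n) for n in keep]
        assert np.ptp(ratios) < 1e-9

    def test_remove_lul_leaves_lll_only(self, coarse_phantom):
        dist = vq.apply_lobectomy(coarse_phantom, "LUL").truth_v
        assert dist.left_lung == pytest.approx(dist.lll)

    def test_activity_conservation(self, coarse_phantom):
        lobe_sum = float(coarse_phantom.activity_v[
            coarse_phantom.labels.lobe_mask("RLL")].sum())
        after = vq.apply_lobectomy(coarse_phantom, "RLL")
        assert after.activity_v.sum() == pytest.approx(
            coarse_phantom.activity_v.sum() - lobe_sum, rel=1e-12)

    def test_labels_and_hu_updated(self, coarse_phantom):
        after = vq.apply_lobectomy(coarse_phantom, "RUL")
        removed = coarse_phantom.labels.lobe_mask("RUL")
        assert np.all(after.labels.labels[removed] == 0)
        assert np.all(after.hu[removed] == coarse_phantom.spec.hu_soft_tissue)

    def test_removing_absent_lobe_raises(self, coarse_phantom):
        once = vq.apply_lobectomy(coarse_phantom, "RML")
        with pytest.raises(ValueError, match="absent"):
            vq.apply_lobectomy(once, "RML")


class TestEmphysema:
    def test_factor_one_is_identity(self, coarse_phantom):
        after = vq.apply_emphysema(coarse_phantom, ("RUL",), 1.0,
                                   hu_value=-950.0)
        assert np.allclose(after.truth_v.values(),
                           coarse_phantom.truth_v.values())

    def test_closed_form_fraction(self, coarse_phantom):
        """factor f on one lobe: new fraction = 100·f·a/(T − (1−f)·a)."""
        f = 0.5
        a = float(coarse_phantom.activity_v[
            coarse_phantom.labels.lobe_mask("RUL")].sum())
        T = float(coarse_phantom.activity_v.sum())
        expected = 100 * f * a / (T - (1 - f) * a)
        after = vq.apply_emphysema(coarse_phantom, ("RUL",), f)
        assert after.truth_v.rul == pytest.approx(expected, rel=1e-9)
        # the stated arithmetic instance: equal-volume lobes of 20% each
        assert 100 * 0.5 * 20 / (0.5 * 20 + 80) == pytest.approx(100 / 9)

    def test_factor_zero_empties_lobe(self, coarse_phantom):
        after = vq.apply_emphysema(coarse_phantom, ("LLL",), 0.0)
        assert after.truth_v.lll == 0
        assert np.all(after.hu[coarse_phantom.labels.lobe_mask("LLL")]
                      == coarse_phantom.spec.hu_emphysema)

    def test_empty_lobe_set_warns_noop(self, coarse_phantom):
        with pytest.warns(UserWarning, match="empty lobe set"):
            after = vq.apply_emphysema(coarse_phantom, (), 0.5)
        assert after is coarse_phantom


class TestHotspot:
    CENTER = (-60.0, -4.0, 60.0)  # inside RUL

    def test_multiplier_one_is_identity(self, coarse_phantom):
        after = vq.insert_hotspot(coarse_phantom, self.CENTER, 20.0, 1.0)
        assert np.array_equal(after.activity_v, coarse_phantom.activity_v)

    def test_hotspot_increases_lobe_fraction(self, coarse_phantom):
        after = vq.insert_hotspot(coarse_phantom, self.CENTER, 20.0, 10.0)
        assert after.truth_v.rul > coarse_phantom.truth_v.rul

    def test_activity_conservation(self, coarse_phantom):
        x, y, z = coarse_phantom.grid.coordinate_mesh()
        cx, cy, cz = self.CENTER
        sphere = ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) <= 20.0 ** 2
        inside = float(coarse_phantom.activity_v[sphere].sum())
        after = vq.insert_hotspot(coarse_phantom, self.CENTER, 20.0, 10.0)
        assert after.activity_v.sum() == pytest.approx(
            coarse_phantom.activity_v.sum() + 9.0 * inside, rel=1e-9)

    def test_sphere_outside_lungs_warns_noop(self, coarse_phantom):
        with pytest.warns(UserWarning, match="does not intersect"):
            after = vq.insert_hotspot(coarse_phantom, (0.0, 0.0, 300.0),
                                      10.0, 5.0)
        assert after is coarse_phantom
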
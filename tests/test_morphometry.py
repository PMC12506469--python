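import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

from epsquant import (
    Micrograph,
    ObjectMeasure,
    area_report,
    exclusion_filter,
    measure_attachments,
    measure_rod,
    measure_tube_width,
    summarize,
)
from epsquant.io import CalibrationError

from _oracles import loop_mean_sd


def _img(shape, scale):
    return Micrograph(np.zeros(shape), scale=scale)


class TestAreaReport:
    def test_worked_example(self):
        """10x10 field, 25 vessel pixels, 0.5 um/px."""
        mask = np.zeros((10, 10), bool)
        mask.flat[:25] = True
        rep = area_report(mask, _img((10, 10), 0.5))
        assert rep.A_v == pytest.approx(6.25)
        assert rep.A_t == pytest.approx(25.0)
        assert rep.P_v == pytest.approx(25.0)

    def test_empty_and_full_masks(self):
        img = _img((8, 8), 0.1)
        empty = area_report(np.zeros((8, 8), bool), img)
        assert empty.A_v == 0.0 and empty.P_v == 0.0
        full = area_report(np.ones((8, 8), bool), img)
        assert full.A_v == pytest.approx(full.A_t)
        assert full.P_v == pytest.approx(100.0)

    def test_identities_on_random_masks(self, rng):
        """A_v = vessels * scale^2, P_v = 100 * A_v / A_t, 0 <= P_v <= 100."""
        for _ in range(100):
            m = int(rng.integers(2, 40))
            n = int(rng.integers(2, 40))
            scale = float(rng.uniform(0.01, 2.0))
            mask = rng.random((m, n)) < rng.uniform(0, 1)
            rep = area_report(mask, _img((m, n), scale))
            assert rep.A_v == pytest.approx(mask.sum() * scale**2, rel=1e-9)
            assert rep.A_t == pytest.approx(m * n * scale**2, rel=1e-9)
            assert rep.P_v == pytest.approx(100.0 * rep.A_v / rep.A_t, rel=1e-9)
            assert 0.0 <= rep.P_v <= 100.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        m=st.integers(2, 30), n=st.integers(2, 30),
        scale=st.floats(0.01, 2.0, allow_nan=False),
        density=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**16),
    )
    def test_identities_property(self, m, n, scale, density, seed):
        mask = np.random.default_rng(seed).random((m, n)) < density
        rep = area_report(mask, _img((m, n), scale))
        assert rep.A_v == pytest.approx(int(mask.sum()) * scale**2, rel=1e-9, abs=1e-15)
        assert rep.P_v == pytest.approx(100.0 * rep.A_v / rep.A_t, rel=1e-9)
        assert 0.0 <= rep.P_v <= 100.0

    def test_coverage_invariant_to_calibration(self, rng):
        mask = rng.random((20, 20)) < 0.3
        a = area_report(mask, _img((20, 20), 0.05))
        b = area_report(mask, _img((20, 20), 0.15))
        assert a.P_v == pytest.approx(b.P_v, rel=1e-12)
        assert b.A_v == pytest.approx(a.A_v * 9.0, rel=1e-9)

    def test_uncalibrated_raises(self):
        with pytest.raises(CalibrationError):
            area_report(np.zeros((4, 4), bool), Micrograph(np.zeros((4, 4))))


def _rod_mask(length_um, width_um, angle_deg, ppm=20.0, shape=(128, 128)):
    mask = np.zeros(shape, bool)
    rot = float(-np.radians(angle_deg))
    rr, cc = draw_ellipse(shape[0] / 2, shape[1] / 2,
                          0.5 * width_um * ppm, 0.5 * length_um * ppm,
                          shape=shape, rotation=rot)
    mask[rr, cc] = True
    return mask


class TestMeasureRod:
    @pytest.mark.parametrize("angle", [0.0, 37.0, 90.0])
    def test_recovers_truth_within_a_pixel(self, angle):
        mask = _rod_mask(1.4, 0.5, angle)
        length, width = measure_rod(mask, scale=0.05)
        assert length == pytest.approx(1.4, abs=0.05)
        assert width == pytest.approx(0.5, abs=0.05)

    def test_disc_has_equal_axes(self):
        mask = _rod_mask(1.0, 1.0, 0.0)
        length, width = measure_rod(mask, scale=0.05)
        assert length == pytest.approx(width, rel=0.02)

    def test_resolution_doubling_stability(self):
        """Doubling pixels/um changes recovered lengths by less than one
        coarse-resolution pixel."""
        lo = measure_rod(_rod_mask(1.4, 0.5, 25.0, ppm=20.0), scale=1 / 20.0)
        hi = measure_rod(_rod_mask(1.4, 0.5, 25.0, ppm=40.0, shape=(256, 256)), scale=1 / 40.0)
        assert abs(lo[0] - hi[0]) < 1 / 20.0
        assert abs(lo[1] - hi[1]) < 1 / 20.0

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            measure_rod(np.zeros((8, 8), bool), 0.05)


class TestMeasureTubeWidth:
    def test_straight_tube(self):
        mask = np.zeros((200, 120), bool)
        mask[:, 30:90] = True  # 60 px = 3 um at 20 px/um
        assert measure_tube_width(mask, 0.05) == pytest.approx(3.0, abs=0.05)

    def test_curved_tube_constant_width(self):
        yy = np.arange(300)
        center = 100 + 40 * np.sin(2 * np.pi * yy / 300)
        line = np.zeros((300, 200), bool)
        line[yy, np.round(center).astype(int)] = True
        mask = ndimage.distance_transform_edt(~line) <= 30.0
        assert measure_tube_width(mask, 0.05) == pytest.approx(3.0, abs=0.1)

    def test_one_pixel_line_is_pixel_limited(self):
        mask = np.zeros((50, 50), bool)
        mask[:, 25] = True
        with pytest.warns(UserWarning, match="pixel-limited"):
            width = measure_tube_width(mask, 0.05)
        assert width == pytest.approx(0.05)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            measure_tube_width(np.zeros((8, 8), bool), 0.05)


class TestMeasureAttachments:
    def _scene_masks(self, gap_px=6, shape=(64, 64)):
        """Crisp rod/tube/filament masks with a known boundary gap."""
        tube = np.zeros(shape, bool)
        tube[:, :20] = True
        rod = np.zeros(shape, bool)
        rod[26:38, 20 + gap_px: 20 + gap_px + 10] = True
        eps = np.zeros(shape, bool)
        eps[31, 20: 20 + gap_px] = True
        return eps, rod, tube

    def test_straight_filament_recovered_within_15_percent(self):
        gap_px = 6  # 0.3 um at 20 px/um
        eps, rod, tube = self._scene_masks(gap_px)
        out = measure_attachments(eps, rod, tube, scale=0.05)
        assert len(out) == 1
        assert out[0].length_um == pytest.approx(0.3, rel=0.15)

    def test_no_eps_components_is_empty(self):
        _, rod, tube = self._scene_masks()
        assert measure_attachments(np.zeros((64, 64), bool), rod, tube, 0.05) == []

    def test_filament_between_two_bacteria_contributes_nothing(self):
        shape = (64, 64)
        rods = np.zeros(shape, bool)
        rods[10:20, 10:20] = True
        rods[10:20, 30:40] = True
        eps = np.zeros(shape, bool)
        eps[15, 20:30] = True
        hyph = np.zeros(shape, bool)
        hyph[50:60, :] = True
        assert measure_attachments(eps, rods, hyph, 0.05) == []

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            measure_attachments(np.zeros((4, 4), bool), np.zeros((5, 5), bool),
                                np.zeros((4, 4), bool), 0.05)

    def test_overlapping_masks_raise(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            measure_attachments(m, m, np.zeros((4, 4), bool), 0.05)


class TestExclusionFilter:
    def _measure(self, **kw):
        base = dict(label=1, cls="bacterium", length_um=1.4, width_um=0.5,
                    touches_border=False, solidity=0.95)
        base.update(kw)
        return ObjectMeasure(**base)

    def test_border_touching_rod_partial(self):
        out = exclusion_filter([self._measure(touches_border=True)], (64, 64))
        assert out[0].excluded and out[0].reason == "partial"

    def test_interior_solid_rod_retained(self):
        out = exclusion_filter([self._measure()], (64, 64))
        assert not out[0].excluded

    def test_bent_object_deformed(self):
        """A C-shaped region has solidity well below 0.8 (convex hull)."""
        mask = np.zeros((40, 40), bool)
        yy, xx = np.mgrid[:40, :40]
        r = np.hypot(yy - 20, xx - 20)
        mask[(r > 10) & (r < 15) & (xx < 22)] = True
        from skimage.measure import regionprops

        solidity = regionprops(mask.astype(np.uint8))[0].solidity
        assert solidity < 0.8  # convex-hull oracle on the generated shape
        out = exclusion_filter([self._measure(solidity=solidity)], (40, 40))
        assert out[0].excluded and out[0].reason == "deformed"

    def test_field_spanning_hypha_not_partial(self):
        m = self._measure(cls="hypha", length_um=50.0, width_um=3.0,
                          touches_border=True, solidity=1.0)
        out = exclusion_filter([m], (1024, 1024))
        assert not out[0].excluded


class TestSummarize:
    def test_hand_computable_example(self):
        records = [("s1", "x", 1.0), ("s1", "x", 2.0), ("s1", "x", 3.0)]
        per_sample, pooled = summarize(records)
        assert pooled.metrics["x"].mean == pytest.approx(2.0)
        assert pooled.metrics["x"].sd == pytest.approx(0.8165, abs=1e-4)
        assert pooled.metrics["x"].n == 3

    def test_single_value(self):
        _, pooled = summarize([("s", "x", 5.0)])
        st = pooled.metrics["x"]
        assert (st.mean, st.sd, st.n) == (5.0, 0.0, 1)

    def test_excluded_objects_ignored_and_empty_flagged(self):
        measures = [
            ObjectMeasure(label=1, cls="bacterium", length_um=1.0, width_um=0.5,
                          excluded=True, reason="partial", sample_id="a"),
        ]
        _, pooled = summarize(measures)
        assert pooled.metrics == {}

    def test_matches_loop_oracle(self, rng):
        values = rng.random(37) * 5
        _, pooled = summarize([("s", "v", float(v)) for v in values])
        mean, sd = loop_mean_sd(values, ddof=0)
        assert pooled.metrics["v"].mean == pytest.approx(mean, rel=1e-12)
        assert pooled.metrics["v"].sd == pytest.approx(sd, rel=1e-12)

    def test_groups_by_sample(self):
        records = [("a", "x", 1.0), ("a", "x", 3.0), ("b", "x", 10.0)]
        per_sample, pooled = summarize(records)
        by_id = {s.sample_id: s for s in per_sample}
        assert by_id["a"].metrics["x"].mean == pytest.approx(2.0)
        assert by_id["b"].metrics["x"].n == 1
        assert pooled.metrics["x"].n == 3
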
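"""Reference Logan DVR, frame averaging, SUV/SUVR."""

import numpy as np
import pytest

from tauquant.containers import TAC, DynamicImage, FrameSchedule
from tauquant.kinetics import (
    SuvInputs,
    classify_amyloid,
    frame_average,
    logan_dvr,
    logan_dvr_image,
    suv_image,
    suvr_image,
)
from tauquant.phantom import (
    KineticParams,
    render_dynamic_image,
    simulate_reference_tac,
    simulate_target_tac,
)


class TestFrameAverage:
    def _dyn(self, schedule, values):
        data = np.broadcast_to(values, (2, 2, 2, len(values))).copy()
        return DynamicImage(data, schedule)

    def test_constant_image_any_window(self, schedule):
        dyn = self._dyn(schedule, np.full(22, 3.5))
        assert np.allclose(frame_average(dyn, (5, 47)), 3.5)

    def test_window_covering_last_three_600s_frames(self, schedule):
        values = np.arange(22, dtype=float)
        dyn = self._dyn(schedule, values)
        out = frame_average(dyn, (30.0, 60.0))
        assert np.allclose(out, values[-3:].mean())

    def test_partial_overlap_matches_fine_resampling_oracle(self, schedule):
        tac = simulate_reference_tac(5.0, 10.0, schedule)
        dyn = self._dyn(schedule, tac.values)
        out = frame_average(dyn, (40.0, 60.0))
        # resample the frame-wise step function at 0.1 s
        t = np.arange(40.0 * 60, 60.0 * 60, 0.1)
        idx = np.searchsorted(schedule.end_s, t, side="right")
        oracle = tac.values[np.minimum(idx, 21)].mean()
        assert out[0, 0, 0] == pytest.approx(oracle, rel=1e-3)

    def test_empty_overlap_rejected(self, schedule):
        dyn = self._dyn(schedule, np.ones(22))
        with pytest.raises(ValueError):
            frame_average(dyn, (61.0, 70.0))


class TestLoganDvr:
    def test_identity_tac_gives_unit_slope_zero_intercept(self, schedule):
        tac = simulate_reference_tac(50.0, 10.0, schedule)
        fit = logan_dvr(tac, tac, (30, 60))
        assert fit.dvr == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)
        assert fit.n_points_used >= 2

    def test_published_example_dvr_1p5_recovered_within_2pct(self, schedule):
        ref = simulate_reference_tac(50.0, 10.0, schedule)
        p = KineticParams(r1=1.0, k2=0.1, bp_nd=0.5)
        tgt = simulate_target_tac(50.0, 10.0, p, schedule)
        fit = logan_dvr(tgt, ref, (30, 60))
        assert fit.dvr == pytest.approx(1.5, rel=0.02)

    @pytest.mark.parametrize("dvr", [1.0, 1.25, 1.5, 2.0])
    def test_recovery_across_dvr_range_with_default_kinetics(self, schedule, dvr):
        ref = simulate_reference_tac(50.0, 10.0, schedule)
        p = KineticParams(r1=0.9, k2=0.15, bp_nd=dvr - 1.0)
        tgt = simulate_target_tac(50.0, 10.0, p, schedule)
        fit = logan_dvr(tgt, ref, (30, 60))
        assert fit.dvr == pytest.approx(dvr, rel=0.02)

    def test_scaling_target_scales_dvr(self, schedule):
        ref = simulate_reference_tac(50.0, 10.0, schedule)
        p = KineticParams(r1=0.9, k2=0.15, bp_nd=0.3)
        tgt = simulate_target_tac(50.0, 10.0, p, schedule)
        base = logan_dvr(tgt, ref, (30, 60)).dvr
        scaled_tac = TAC(tgt.mid_min, tgt.duration_min, 2.5 * tgt.values)
        assert logan_dvr(scaled_tac, ref, (30, 60)).dvr == pytest.approx(
            2.5 * base, rel=1e-9
        )

    @pytest.mark.parametrize("c", [0.1, 0.7, 3.0, 40.0])
    def test_invariant_under_common_rescaling(self, schedule, c):
        ref = simulate_reference_tac(50.0, 10.0, schedule)
        p = KineticParams(r1=0.9, k2=0.15, bp_nd=0.4)
        tgt = simulate_target_tac(50.0, 10.0, p, schedule)
        base = logan_dvr(tgt, ref, (30, 60)).dvr
        fit = logan_dvr(
            TAC(tgt.mid_min, tgt.duration_min, c * tgt.values),
            TAC(ref.mid_min, ref.duration_min, c * ref.values),
            (30, 60),
        )
        assert fit.dvr == pytest.approx(base, rel=1e-9)

    def test_mismatched_schedules_and_short_windows_rejected(self, schedule):
        tac = simulate_reference_tac(1.0, 10.0, schedule)
        other = FrameSchedule.from_blocks([(10, 360.0)])
        with pytest.raises(ValueError):
            logan_dvr(tac, simulate_reference_tac(1.0, 10.0, other), (30, 60))
        with pytest.raises(ValueError):
            logan_dvr(tac, tac, (60, 30))

    def test_nonpositive_frames_dropped_and_counted(self, schedule):
        ref = simulate_reference_tac(50.0, 10.0, schedule)
        vals = ref.values.copy()
        vals[-1] = 0.0  # kill one late frame
        broken = TAC(ref.mid_min, ref.duration_min, vals)
        fit = logan_dvr(broken, ref, (30, 60))
        # the 30-60 min window holds the three 600-s frames; one was killed
        assert fit.n_points_dropped == 1
        assert fit.n_points_used == 2


class TestLoganImage:
    def test_uniform_image_equal_to_reference_gives_unit_map(self, schedule):
        tac = simulate_reference_tac(50.0, 10.0, schedule)
        data = np.broadcast_to(tac.values, (4, 4, 4, 22)).copy()
        dyn = DynamicImage(data, schedule)
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True
        dvr_map = logan_dvr_image(dyn, mask, (30, 60))
        assert np.allclose(dvr_map, 1.0, atol=1e-9)

    def test_noiseless_phantom_roi_means_within_2pct(self, schedule, scene):
        hot = {
            lab: 1.4
            for lab, n in scene.region_names.items()
            if n != "cerebellum_gm"
        }
        hot_scene = scene.with_dvrs(hot)
        img = render_dynamic_image(hot_scene, schedule, psf_fwhm_mm=0, noise_scale=0)
        dvr_map = logan_dvr_image(img, scene.atlas == scene.reference_label, (30, 60))
        for lab, name in scene.region_names.items():
            true = hot_scene.region_params[lab].dvr
            est = float(np.nanmean(dvr_map[scene.atlas == lab]))
            assert est == pytest.approx(true, rel=0.02), name

    def test_voxelwise_agrees_with_roi_tac_first(self, schedule, scene):
        hot_scene = scene.with_dvrs(
            {lab: 1.3 for lab, n in scene.region_names.items() if n != "cerebellum_gm"}
        )
        img = render_dynamic_image(hot_scene, schedule, psf_fwhm_mm=0, noise_scale=0)
        ref_mask = scene.atlas == scene.reference_label
        dvr_map = logan_dvr_image(img, ref_mask, (30, 60))
        roi_mask = scene.atlas == 1
        roi_first = logan_dvr(img.mask_tac(roi_mask), img.mask_tac(ref_mask), (30, 60))
        assert float(np.nanmean(dvr_map[roi_mask])) == pytest.approx(
            roi_first.dvr, rel=0.01
        )

    def test_empty_reference_mask_rejected(self, schedule):
        dyn = DynamicImage(np.ones((3, 3, 3, 22)), schedule)
        with pytest.raises(ValueError):
            logan_dvr_image(dyn, np.zeros((3, 3, 3), bool), (30, 60))


class TestSuvSuvr:
    def test_suv_printed_definition(self):
        out = suv_image(np.full((2, 2, 2), 2.0), SuvInputs(dose_mbq=100, weight_kg=50))
        assert np.allclose(out, 1.0)

    def test_suv_equals_one_when_volume_is_dose_per_weight(self):
        out = suv_image(np.full((2, 2), 4.0), SuvInputs(dose_mbq=200, weight_kg=50))
        assert np.allclose(out, 1.0)

    def test_suv_linear_in_weight(self):
        vol = np.random.default_rng(0).uniform(1, 3, (3, 3))
        a = suv_image(vol, SuvInputs(100, 40))
        b = suv_image(vol, SuvInputs(100, 80))
        assert np.allclose(b, 2 * a)

    def test_suv_requires_positive_dose_and_weight(self):
        with pytest.raises(ValueError):
            SuvInputs(dose_mbq=0, weight_kg=70)
        with pytest.raises(ValueError):
            SuvInputs(dose_mbq=200, weight_kg=-1)

    def test_suvr_uniform_image_is_one_and_reference_is_one(self):
        vol = np.full((4, 4, 4), 2.7)
        mask = np.zeros((4, 4, 4), bool)
        mask[0] = True
        assert np.allclose(suvr_image(vol, mask), 1.0)
        vol2 = np.random.default_rng(1).uniform(1, 4, (4, 4, 4))
        out = suvr_image(vol2, mask)
        assert out[mask].mean() == pytest.approx(1.0)

    def test_suvr_simple_ratio(self):
        vol = np.full((2, 2, 2), 3.0)
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        vol[0, 0, 0] = 2.0
        assert suvr_image(vol, mask)[1, 1, 1] == pytest.approx(1.5)

    def test_suvr_rejects_nonpositive_reference(self):
        vol = np.zeros((2, 2, 2))
        mask = np.ones((2, 2, 2), bool)
        with pytest.raises(ValueError):
            suvr_image(vol, mask)

    def test_amyloid_positivity_threshold(self):
        assert classify_amyloid(1.42)
        assert not classify_amyloid(1.41)
        assert not classify_amyloid(1.10)
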
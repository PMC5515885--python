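"""Anaphase onset, chromosome-rim signals, and half-time extraction."""

import numpy as np
import pytest

from npcrowd.config import load_preset
from npcrowd.mitotic import (
    OnsetNotFoundError,
    analyze_timelapse,
    chromosome_area_timecourse,
    chromosome_mask,
    chromosome_rim_mask,
    detect_anaphase_onset,
    extract_half_time,
    localization_signal,
)
from npcrowd.phantoms import localization_kinetics, make_timelapse


class TestOnsetDetection:
    def test_frame_accurate_on_phantoms(self):
        for seed in (1, 2, 3):
            cfg = load_preset("early_assembler", seed=seed, anaphase_onset_frame=5)
            stack, manifest = make_timelapse(cfg)
            assert detect_anaphase_onset(stack[:, 2]) == manifest.anaphase_onset_frame

    def test_static_mass_raises(self):
        cfg = load_preset("early_assembler", noise="none")
        stack, _ = make_timelapse(cfg)
        static = np.repeat(stack[:1, 2], 8, axis=0)
        with pytest.raises(OnsetNotFoundError):
            detect_anaphase_onset(static)

    def test_spurious_single_frame_split_ignored(self):
        cfg = load_preset("early_assembler", noise="none", anaphase_onset_frame=5)
        stack, manifest = make_timelapse(cfg)
        chrom = stack[:, 2].copy()
        chrom[1] = chrom[manifest.anaphase_onset_frame + 2]  # 1-frame fake split
        assert detect_anaphase_onset(chrom) == manifest.anaphase_onset_frame


class TestChromosomeRim:
    def test_circular_mass_area_matches_geometry(self):
        rr, cc = np.mgrid[0:128, 0:128]
        mask = np.hypot(rr - 64, cc - 64) <= 30
        rim = chromosome_rim_mask(mask, 3.0)
        assert rim.sum() == pytest.approx(2 * np.pi * 30 * 3, rel=0.15)

    def test_two_masses_get_two_bands(self):
        from skimage.measure import label as cc_label

        rr, cc = np.mgrid[0:128, 0:128]
        mask = (np.hypot(rr - 64, cc - 30) <= 15) | (np.hypot(rr - 64, cc - 98) <= 15)
        rim = chromosome_rim_mask(mask, 3.0)
        assert cc_label(rim).max() == 2

    def test_phantom_frame_iou_vs_manifest(self, early_assembler_stack):
        stack, manifest, _ = early_assembler_stack
        f = manifest.anaphase_onset_frame + 3
        rim = chromosome_rim_mask(stack[f, 2], 3.0)
        gt = manifest.rim_masks[f]
        assert (rim & gt).sum() / (rim | gt).sum() >= 0.7

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            chromosome_rim_mask(np.zeros((32, 32), bool), 3.0)


class TestLocalizationSignal:
    def _masks(self):
        rim = np.zeros((20, 20), bool)
        cyto = np.zeros((20, 20), bool)
        rim[5:8, 5:15] = True
        cyto[12:18, 2:18] = True
        return rim, cyto

    def test_rim_equal_cytoplasm_is_zero(self):
        rim, cyto = self._masks()
        img = np.full((20, 20), 50.0)
        assert localization_signal(img, rim, cyto, background=10.0) == 0.0

    def test_double_cytoplasm_is_one(self):
        rim, cyto = self._masks()
        img = np.where(rim, 210.0, 110.0)
        assert localization_signal(img, rim, cyto, background=10.0) == pytest.approx(1.0)

    def test_crisp_phantom_matches_kinetic_truth(self):
        # no PSF and no noise: the rim band is crisp, so the measured
        # rim/cyto excess equals L(t)/density_cyto exactly
        cfg = load_preset("early_assembler", noise="none", psf_sigma=0.0)
        stack, manifest = make_timelapse(cfg)
        trace = analyze_timelapse(stack, frame_interval=cfg.frame_interval)
        mid = manifest.anaphase_onset_frame + 3
        assert trace.localization[mid] == pytest.approx(
            manifest.localization_truth[mid] / cfg.probe_density_cyto, rel=0.10
        )


class TestProbeTimecourse:
    def test_unity_at_onset_and_flat_without_ramp(self):
        cfg = load_preset("early_assembler", noise="none", c_plateau=100.0)
        stack, manifest = make_timelapse(cfg)
        trace = analyze_timelapse(stack, frame_interval=cfg.frame_interval)
        onset = manifest.anaphase_onset_frame
        assert trace.probe[onset] == 1.0
        assert np.abs(trace.probe - 1.0).max() < 0.02

    def test_early_assembler_plateau_drop(self, early_assembler_stack):
        stack, manifest, cfg = early_assembler_stack
        trace = analyze_timelapse(stack, frame_interval=cfg.frame_interval)
        plateau = np.mean(trace.probe[-3:])
        assert plateau == pytest.approx(
            1.0 - manifest.expected_plateau_probe_drop, abs=0.02
        )

    def test_localization_shape_invariant_to_plateau_density(self):
        # expression independence carried into mitosis: max-normalized
        # localization traces agree when the plateau density doubles
        base = load_preset("early_assembler", noise="none")
        t1 = analyze_timelapse(make_timelapse(base)[0], frame_interval=2.0)
        doubled = base.model_copy(update={"plateau_density": 4.0})
        t2 = analyze_timelapse(make_timelapse(doubled)[0], frame_interval=2.0)
        n1 = t1.localization / t1.localization.max()
        n2 = t2.localization / t2.localization.max()
        assert np.abs(n1 - n2).max() < 0.10

    def test_dissociation_signature_of_early_class(self):
        # after telophase the localization falls from its peak while the
        # probe signal stays on its plateau (crowding does not reverse)
        cfg = load_preset("early_assembler_decay", noise="none")
        stack, _ = make_timelapse(cfg)
        trace = analyze_timelapse(stack, frame_interval=cfg.frame_interval)
        loc = trace.localization
        assert loc[-1] < 0.7 * loc.max()
        plateau = np.mean(trace.probe[-3:])
        post_peak = trace.probe[np.argmax(loc):]
        assert np.abs(post_peak / plateau - 1.0).max() < 0.05


class TestExtractHalfTime:
    def test_step_series_midpoint_convention(self):
        times = np.arange(0.0, 21.0, 2.0)
        series = np.where(times >= 6.0, 1.0, 0.0)
        res = extract_half_time(series, times, "rise-to-max")
        assert res.recovered
        assert res.time == pytest.approx(5.0)

    @pytest.mark.parametrize("t0,expected", [(1.0, 4.0), (3.0, 6.0), (10.0, 13.0)])
    def test_exponential_rise_closed_form(self, t0, expected):
        cfg = load_preset("early_assembler", t0=t0, plateau_density=1.0)
        times = np.arange(0.0, 31.0, 2.0)
        series = localization_kinetics(times, cfg)
        res = extract_half_time(series, times, "rise-to-max")
        assert res.time == pytest.approx(expected, abs=0.2)

    def test_flat_series_unrecoverable(self):
        times = np.arange(0.0, 21.0, 2.0)
        res = extract_half_time(np.ones_like(times), times, "fall-to-min")
        assert not res.recovered
        assert res.time is None

    def test_falling_series(self):
        times = np.arange(0.0, 31.0, 2.0)
        series = 0.8 + 0.2 * np.exp(-times / 5.0)
        res = extract_half_time(series, times, "fall-to-min")
        # midpoint of [~0.8, 1.0] crossed at t = 5*ln(2) ~ 3.47
        assert res.recovered
        assert res.time == pytest.approx(5 * np.log(2), abs=0.3)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="3 frames"):
            extract_half_time(np.array([0.0, 1.0]), np.array([0.0, 2.0]), "rise-to-max")


class TestChromosomeArea:
    def test_static_phantom_constant_area(self):
        cfg = load_preset("late_assembler", noise="none")
        stack, manifest = make_timelapse(cfg)
        area, flags = chromosome_area_timecourse(
            stack[:, 2], manifest.anaphase_onset_frame
        )
        post = area[manifest.anaphase_onset_frame :]
        assert np.abs(post - 1.0).max() < 0.10
        assert flags == []

    def test_decondensation_ramp_recovered(self):
        cfg = load_preset("late_assembler", noise="none", area_growth=1.5)
        stack, manifest = make_timelapse(cfg)
        onset = manifest.anaphase_onset_frame
        area, _ = chromosome_area_timecourse(stack[:, 2], onset)
        truth = manifest.chromosome_area_px / manifest.chromosome_area_px[onset]
        assert np.abs(area[onset:] / truth[onset:] - 1.0).max() < 0.10
        assert area[-1] == pytest.approx(1.5, rel=0.10)

    def test_empty_frame_gap_flagged(self):
        cfg = load_preset("late_assembler", noise="none")
        stack, manifest = make_timelapse(cfg)
        chrom = stack[:, 2].copy()
        chrom[-1] = cfg.background  # signal lost in the last frame
        area, flags = chromosome_area_timecourse(chrom, manifest.anaphase_onset_frame)
        assert np.isnan(area[-1])
        assert any("empty_chromosome_mask" in f for f in flags)


class TestAnalyzeTimelapse:
    def test_half_times_within_half_frame_of_truth(self):
        for preset in ("early_assembler", "pom121_like", "late_assembler"):
            cfg = load_preset(preset, noise="none")
            stack, manifest = make_timelapse(cfg)
            trace = analyze_timelapse(stack, frame_interval=cfg.frame_interval)
            assert trace.half_max_localization.recovered
            assert trace.half_max_localization.time == pytest.approx(
                manifest.half_max_time, abs=1.0
            )

    def test_manual_onset_override(self, early_assembler_stack):
        stack, manifest, cfg = early_assembler_stack
        trace = analyze_timelapse(
            stack, frame_interval=cfg.frame_interval,
            onset_frame=manifest.anaphase_onset_frame,
        )
        assert trace.anaphase_onset_frame == manifest.anaphase_onset_frame

    def test_times_metadata_respected(self, early_assembler_stack):
        stack, manifest, cfg = early_assembler_stack
        times = np.asarray(manifest.times_min) + 0.5
        trace = analyze_timelapse(stack, config=None, times=times)
        np.testing.assert_array_equal(trace.times, times)
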
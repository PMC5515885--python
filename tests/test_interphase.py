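"""Segmentation, per-cell probe statistics, group summaries, Welch test."""

import numpy as np
import pytest
from scipy import stats

from npcrowd.config import SegmentationParams, load_preset
from npcrowd.interphase import (
    SegmentationError,
    UndefinedRatioError,
    compare_treatments,
    expression_independence_check,
    measure_cell,
    probe_signal,
    quantify_image,
    segment_cell,
    summarize_group,
    welch_t_test,
)
from npcrowd.phantoms import make_interphase_image


def iou(a, b):
    return (a & b).sum() / (a | b).sum()


class TestSegmentCell:
    def test_rim_iou_noise_free(self, peripheral_noise_free):
        donor, _, manifest = peripheral_noise_free
        masks = segment_cell(donor)
        assert iou(masks.rim, manifest.labels == 3) >= 0.8

    def test_blank_image_raises(self):
        with pytest.raises(SegmentationError):
            segment_cell(np.full((128, 128), 100.0))

    def test_rim_iou_under_poisson_noise(self):
        ok = 0
        for seed in range(1, 21):
            donor, _, manifest = make_interphase_image(
                load_preset("peripheral", seed=seed)
            )
            masks = segment_cell(donor)
            ok += iou(masks.rim, manifest.labels == 3) >= 0.7
        assert ok >= 19

    def test_labels_mutually_exclusive_and_nonempty(self, peripheral_noise_free):
        donor, _, _ = peripheral_noise_free
        masks = segment_cell(donor)
        for region in (masks.rim, masks.nucleus, masks.cytoplasm, masks.background):
            assert region.any()
        total = (
            masks.rim.astype(int)
            + masks.nucleus.astype(int)
            + masks.cytoplasm.astype(int)
            + masks.background.astype(int)
        )
        assert (total == 1).all()


class TestProbeSignal:
    def test_proportional_channels(self):
        donor = np.full((20, 20), 5.0)
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        assert probe_signal(2 * donor, donor, mask) == pytest.approx(2.0)

    def test_background_offset_invariance(self, rng):
        donor = rng.uniform(10, 20, (30, 30))
        acceptor = rng.uniform(10, 20, (30, 30))
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True
        base = probe_signal(acceptor, donor, mask)
        shifted = probe_signal(acceptor + 37.0, donor + 11.0, mask, (11.0, 37.0))
        assert shifted == pytest.approx(base, rel=1e-12)

    def test_low_donor_raises(self):
        donor = np.full((10, 10), 1.0)
        mask = np.ones((10, 10), bool)
        with pytest.raises(UndefinedRatioError):
            probe_signal(donor, donor, mask, background=(1.0, 0.0))

    def test_noise_free_peripheral_recovers_quench_ratio(self, peripheral_noise_free):
        donor, acceptor, manifest = peripheral_noise_free
        m = quantify_image(donor, acceptor)
        assert m.relative_probe == pytest.approx(
            manifest.expected_relative_probe, abs=0.01
        )

    def test_expression_independence_noise_free(self):
        cfg = load_preset("peripheral", noise="none", seed=5)
        m1 = quantify_image(*make_interphase_image(cfg)[:2])
        cfg2 = cfg.model_copy(update={"probe_density_rim": 6.0})
        m2 = quantify_image(*make_interphase_image(cfg2)[:2])
        assert abs(m2.relative_probe - m1.relative_probe) < 0.01
        assert m2.localization_ne > 1.5 * m1.localization_ne  # expression did change


class TestMeasureCell:
    @pytest.mark.parametrize(
        "preset,expected", [("central_cavity", 0.90), ("peripheral", 0.75)]
    )
    def test_noise_free_presets(self, preset, expected):
        cfg = load_preset(preset, noise="none", seed=7)
        donor, acceptor, _ = make_interphase_image(cfg)
        m = quantify_image(donor, acceptor)
        assert m.relative_probe == pytest.approx(expected, abs=0.01)

    def test_equal_concentrations_give_unity(self):
        cfg = load_preset("peripheral", noise="none", concentration_rim=100.0)
        donor, acceptor, _ = make_interphase_image(cfg)
        m = quantify_image(donor, acceptor)
        assert m.relative_probe == pytest.approx(1.0, abs=0.01)

    def test_noisy_batch_mean_near_expectation(self):
        vals = [
            quantify_image(
                *make_interphase_image(load_preset("peripheral", seed=s))[:2]
            ).relative_probe
            for s in range(1, 21)
        ]
        assert 0.73 <= np.mean(vals) <= 0.77

    def test_small_region_flagged(self, peripheral_noise_free):
        donor, acceptor, _ = peripheral_noise_free
        masks = segment_cell(donor)
        m = measure_cell(donor, acceptor, masks, min_region_px=10**6)
        assert any(f.startswith("small_region") for f in m.qc_flags)


class TestSummarizeGroup:
    def test_hand_computed_oracle(self):
        s = summarize_group([1, 2, 3, 4, 5])
        assert s.mean == 3
        assert s.sd == pytest.approx(np.sqrt(2.5))
        assert (s.median, s.q1, s.q3) == (3, 2, 4)
        assert s.outliers == []

    def test_single_value(self):
        s = summarize_group([4.2])
        assert s.sd is None
        assert s.median == s.q1 == s.q3 == 4.2

    def test_outlier_flagged(self):
        s = summarize_group([1, 2, 3, 4, 5, 100])
        assert s.outliers == [100.0]

    def test_quartile_ordering_invariant(self, rng):
        vals = rng.normal(size=137)
        s = summarize_group(vals)
        assert s.q1 <= s.median <= s.q3


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_direct_formula_example(self):
        res = welch_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.t == pytest.approx(-1.0, abs=1e-12)
        assert res.df == pytest.approx(8.0, abs=1e-12)

    def test_matches_independent_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(5, 40))
            b = rng.normal(0.3, 2, rng.integers(5, 40))
            res = welch_t_test(a, b)
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
            assert res.t == pytest.approx(t_ref, abs=1e-10)
            assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(42)
        rejections = sum(
            welch_t_test(rng.normal(0, 1, 30), rng.normal(0, 1, 30)).p < 0.05
            for _ in range(2000)
        )
        assert 0.035 <= rejections / 2000 <= 0.065

    def test_insufficient_sample_raises(self):
        with pytest.raises(ValueError, match="n >= 2"):
            welch_t_test([1.0], [1.0, 2.0])


class TestExpressionIndependence:
    def test_varied_density_uncorrelated(self):
        ms = []
        for i, seed in enumerate(range(1, 21)):
            scale = 1.0 + 3.0 * i / 19
            cfg = load_preset("peripheral", seed=seed).model_copy(
                update={
                    "probe_density_rim": 3.0 * scale,
                    "probe_density_cyto": scale,
                    "probe_density_nucleus": scale,
                }
            )
            ms.append(quantify_image(*make_interphase_image(cfg)[:2]))
        _, r = expression_independence_check(ms)
        assert abs(r) < 0.3

    def test_adversarial_proportional_fixture(self):
        from npcrowd.interphase import CellMeasurement

        ms = [
            CellMeasurement(
                probe_ne=0.1 * x, probe_cyto=1.0, relative_probe=0.1 * x,
                localization_ne=float(x), localization_cyto=1.0,
            )
            for x in range(1, 11)
        ]
        _, r = expression_independence_check(ms)
        assert r == pytest.approx(1.0)

    def test_constant_localization_undefined(self):
        from npcrowd.interphase import CellMeasurement

        ms = [
            CellMeasurement(1.0, 1.0, 1.0, localization_ne=5.0, localization_cyto=1.0)
            for _ in range(6)
        ]
        with pytest.raises(ValueError, match="zero variance"):
            expression_independence_check(ms)


class TestCompareTreatments:
    def test_self_comparison_is_null(self):
        ms = [
            quantify_image(*make_interphase_image(load_preset("peripheral", seed=s))[:2])
            for s in range(1, 7)
        ]
        comp = compare_treatments(ms, ms)
        assert comp.relative_mean == pytest.approx(1.0)
        assert comp.welch.p == pytest.approx(1.0)

    def test_raised_rim_crowding_detected(self):
        ref, treated = [], []
        for s in range(1, 21):
            ref.append(
                quantify_image(*make_interphase_image(load_preset("peripheral", seed=s))[:2])
            )
            cfg = load_preset("peripheral", seed=100 + s, concentration_rim=280.0)
            treated.append(quantify_image(*make_interphase_image(cfg)[:2]))
        comp = compare_treatments(ref, treated)
        assert comp.relative_mean < 1.0
        assert comp.welch.p < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_treatments([], [])
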
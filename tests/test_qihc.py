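"""qIHC: morphometry, positive fractions, size tests, alignment, colocalization."""

import numpy as np
import pytest
from skimage.transform import rotate

from hifsig import SynthImageConfig, gen_histology
from hifsig.exceptions import AlignmentError, InputError, ZeroAreaError
from hifsig.qihc import (
    NoduleRecord,
    StainImage,
    ThresholdSpec,
    align_sections,
    coloc_correlation,
    group_stats,
    isolate_nodules,
    lognormal_check,
    perfusion_fraction,
    positive_fraction,
    size_dichotomize,
)


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestMorphometry:
    def test_disk_diameter_within_rasterization_bound(self):
        mask = _disk_mask((200, 200), (100, 100), 50)
        recs = isolate_nodules(mask, um_per_px=1.0)
        assert len(recs) == 1
        assert recs[0].equivalent_diameter_um == pytest.approx(100.0, abs=1.0)

    def test_square_equivalent_diameter_formula(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[50:150, 50:150] = True  # 100x100 square
        recs = isolate_nodules(mask, um_per_px=1.0)
        assert recs[0].area_um2 == pytest.approx(10000.0)
        assert recs[0].equivalent_diameter_um == pytest.approx(
            2 * np.sqrt(10000 / np.pi), rel=1e-6
        )

    def test_two_disjoint_disks_ordered_by_label(self):
        mask = _disk_mask((200, 200), (50, 50), 20) | _disk_mask(
            (200, 200), (150, 150), 30
        )
        recs = isolate_nodules(mask, um_per_px=2.0)
        assert [r.nodule_id for r in recs] == [1, 2]
        assert recs[1].area_um2 > recs[0].area_um2

    def test_rotation_leaves_area_within_one_percent(self):
        mask = np.zeros((300, 300))
        mask[100:180, 120:200] = 1.0
        rot = rotate(mask, 37.0, order=0, preserve_range=True) > 0.5
        a0 = isolate_nodules(mask.astype(bool), 1.0)[0].area_um2
        a1 = isolate_nodules(rot, 1.0)[0].area_um2
        assert abs(a1 - a0) / a0 < 0.01

    def test_border_touching_flagged(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[0:30, 40:60] = True
        assert isolate_nodules(mask, 1.0)[0].touches_border

    def test_empty_mask_and_bad_scale(self):
        assert isolate_nodules(np.zeros((50, 50), dtype=bool), 1.0) == []
        with pytest.raises(InputError):
            isolate_nodules(np.ones((5, 5), dtype=bool), 0.0)


@pytest.fixture(scope="module")
def slide():
    cfg = SynthImageConfig(
        canvas_px=(400, 400),
        nodules=[
            ((100, 100), 50, 0.30),
            ((280, 280), 60, 1.0),
            ((100, 300), 40, 0.0),
        ],
        rng_seed=3,
    )
    img, labels, recs = gen_histology(cfg)
    return StainImage(img, 1.0), labels, recs


class TestPositiveFraction:
    def test_fully_positive_nodule(self, slide):
        img, labels, recs = slide
        assert positive_fraction(img, labels == 2, ThresholdSpec()) == 1.0

    def test_recovers_planted_fraction(self, slide):
        img, labels, recs = slide
        f = positive_fraction(img, labels == 1, ThresholdSpec())
        assert f == pytest.approx(recs[0]["positive_fraction"], abs=0.02)

    def test_threshold_beyond_channel_range_gives_zero(self, slide):
        img, labels, _ = slide
        spec = ThresholdSpec(channel="raw_channel", cutoff=300.0, polarity="above")
        assert positive_fraction(img, labels == 1, spec) == 0.0

    def test_monotone_nonincreasing_in_cutoff(self, slide):
        img, labels, _ = slide
        fractions = [
            positive_fraction(img, labels == 1, ThresholdSpec(cutoff=c))
            for c in [0.0, 0.02, 0.05, 0.1, 0.2]
        ]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_empty_mask_rejected(self, slide):
        img, labels, _ = slide
        with pytest.raises(ZeroAreaError):
            positive_fraction(img, labels == 99, ThresholdSpec())

    def test_shape_mismatch_rejected(self, slide):
        img, _, _ = slide
        with pytest.raises(InputError):
            positive_fraction(img, np.ones((10, 10), bool), ThresholdSpec())


class TestSizeDichotomize:
    def _records(self, group, n_small, n_large):
        out = []
        for i in range(n_small):
            out.append(NoduleRecord(i, group=group, equivalent_diameter_um=500.0))
        for i in range(n_large):
            out.append(NoduleRecord(100 + i, group=group, equivalent_diameter_um=1500.0))
        return out

    def test_chi_square_fixture_matches_hand_computation(self):
        # [[30 large, 10 small], [20 large, 20 small]] -> chi2 = 5.333, df 1
        recs = self._records("vehicle", 10, 30) + self._records("treated", 20, 20)
        res = size_dichotomize(recs, reference_median_um=970.0)
        assert res.chi2 == pytest.approx(5.333, abs=1e-3)
        assert res.df == 1
        assert res.p < 0.05
        assert res.warning is None

    def test_boundary_closed_on_large_side(self):
        recs = [
            NoduleRecord(1, group="a", equivalent_diameter_um=970.0),
            NoduleRecord(2, group="a", equivalent_diameter_um=969.9),
            NoduleRecord(3, group="b", equivalent_diameter_um=971.0),
            NoduleRecord(4, group="b", equivalent_diameter_um=100.0),
        ]
        size_dichotomize(recs, 970.0)
        assert [r.size_class for r in recs] == ["large", "small", "large", "small"]

    def test_symmetric_swap_gives_identical_statistic(self):
        a = self._records("g1", 12, 4) + self._records("g2", 4, 12)
        b = self._records("g1", 4, 12) + self._records("g2", 12, 4)
        assert size_dichotomize(a, 970.0).chi2 == pytest.approx(
            size_dichotomize(b, 970.0).chi2
        )

    def test_degenerate_single_class_flagged(self):
        recs = self._records("g1", 0, 10) + self._records("g2", 0, 10)
        res = size_dichotomize(recs, 970.0)
        assert res.warning is not None

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            size_dichotomize(self._records("only", 5, 5), 970.0)


class TestLognormalCheck:
    def test_lognormal_samples_pass_in_most_seeds(self):
        passed = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d = rng.lognormal(mean=6.9, sigma=0.5, size=100)
            if lognormal_check(d)["shapiro_p"] > 0.05:
                passed += 1
        assert passed >= 90

    def test_exponential_samples_usually_rejected(self):
        rejected = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            d = rng.exponential(1000.0, size=200)
            if lognormal_check(d)["shapiro_p"] <= 0.05:
                rejected += 1
        assert rejected / n_seeds >= 0.5

    def test_mle_parameters_returned(self):
        rng = np.random.default_rng(0)
        d = rng.lognormal(mean=6.88, sigma=0.4, size=4000)
        res = lognormal_check(d)
        assert res["mu_hat"] == pytest.approx(6.88, abs=0.05)
        assert res["sigma_hat"] == pytest.approx(0.4, abs=0.05)

    def test_too_few_or_nonpositive_rejected(self):
        with pytest.raises(InputError):
            lognormal_check([1, 2, 3])
        with pytest.raises(InputError):
            lognormal_check([1.0] * 7 + [-2.0])


class TestAlignment:
    def test_self_alignment_is_identity_with_full_score(self, slide):
        img, _, _ = slide
        offset, score = align_sections(img, img)
        assert offset == (0, 0)
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_recovers_known_translation(self, slide):
        img, _, _ = slide
        shifted = np.zeros_like(img.pixels)
        shifted[5:, 8:] = img.pixels[:-5, :-8]
        offset, _ = align_sections(img, StainImage(shifted, 1.0))
        assert offset == (5, 8)

    def test_uncorrelated_noise_fails(self):
        a = np.random.default_rng(1).uniform(size=(80, 90))
        b = np.random.default_rng(2).uniform(size=(80, 90))
        with pytest.raises(AlignmentError):
            align_sections(StainImage(a, 1.0), StainImage(b, 1.0))

    def test_scale_mismatch_rejected(self, slide):
        img, _, _ = slide
        with pytest.raises(InputError):
            align_sections(img, StainImage(img.pixels, 2.0))


class TestColocalization:
    def test_identity_gives_unit_slope_and_correlation(self):
        a = {i: f for i, f in enumerate([0.1, 0.2, 0.3, 0.4, 0.5])}
        res = coloc_correlation(a, dict(a))
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(1.0)

    def test_power_law_gives_slope_two(self):
        a = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        res = coloc_correlation(a, a**2)
        assert res["slope"] == pytest.approx(2.0, abs=1e-9)
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InputError):
            coloc_correlation([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])

    def test_recovers_analytic_log_scale_correlation(self):
        # log B = log A + noise(sd=0.3); log A has sd sigma_a:
        # true r = sigma_a / sqrt(sigma_a^2 + 0.09)
        sigma_a = 0.5
        target = sigma_a / np.sqrt(sigma_a**2 + 0.09)
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            la = rng.normal(np.log(0.2), sigma_a, 60)
            lb = la + rng.normal(0, 0.3, 60)
            rs.append(
                coloc_correlation(np.exp(la), np.exp(lb))["pearson_r"]
            )
        assert np.mean(rs) == pytest.approx(target, abs=0.1)

    def test_zero_fractions_floored_and_reported(self):
        res = coloc_correlation([0.0, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        assert res["zero_floor"] == pytest.approx(0.05)


class TestPerfusion:
    def test_fully_perfused_field(self):
        img = StainImage(np.full((50, 50), 200.0), 1.0, kind="fluorescence")
        spec = ThresholdSpec(channel="raw_channel", cutoff=100.0)
        assert perfusion_fraction(img, np.ones((50, 50), bool), spec) == 1.0

    def test_half_field(self):
        px = np.zeros((50, 50))
        px[:25] = 200.0
        img = StainImage(px, 1.0, kind="fluorescence")
        spec = ThresholdSpec(channel="raw_channel", cutoff=100.0)
        f = perfusion_fraction(img, np.ones((50, 50), bool), spec)
        assert f == pytest.approx(0.5, abs=0.01)

    def test_empty_tissue_mask_rejected(self):
        img = StainImage(np.zeros((20, 20)), 1.0, kind="fluorescence")
        with pytest.raises(ZeroAreaError):
            perfusion_fraction(
                img, np.zeros((20, 20), bool), ThresholdSpec(channel="raw_channel")
            )

    def test_brightfield_image_rejected(self):
        img = StainImage(np.zeros((20, 20, 3), dtype=np.uint8), 1.0)
        with pytest.raises(InputError):
            perfusion_fraction(
                img, np.ones((20, 20), bool), ThresholdSpec(channel="raw_channel")
            )


class TestGroupStats:
    def test_identical_groups_not_significant(self):
        v = np.linspace(1, 2, 30)
        res = group_stats({"a": v, "b": v.copy(), "c": v.copy()})
        assert res["test"] == "welch_anova"
        assert res["p"] > 0.99

    def test_shifted_mean_detected(self):
        rng = np.random.default_rng(0)
        base = np.exp(rng.normal(0, 1, 30))
        shifted = np.exp(rng.normal(2, 1, 30))
        res = group_stats({"a": base, "b": np.exp(rng.normal(0, 1, 30)), "c": shifted})
        assert res["p"] < 0.01
        assert res["posthoc"]["significant"].any()

    def test_two_groups_routed_to_welch_with_notice(self):
        rng = np.random.default_rng(1)
        res = group_stats(
            {"a": np.exp(rng.normal(0, 1, 20)), "b": np.exp(rng.normal(1, 1, 20))}
        )
        assert res["test"] == "welch_t"
        assert res["notice"] is not None

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            group_stats({"a": [1.0], "b": [1.0, 2.0]})


class TestEndToEndSlide:
    def test_twenty_nodules_match_ground_truth(self):
        rng = np.random.default_rng(17)
        nodules = []
        for i in range(4):
            for j in range(5):
                r = int(rng.integers(18, 34))
                f = float(rng.uniform(0.05, 0.95))
                nodules.append(((90 + 160 * i, 90 + 150 * j), r, f))
        cfg = SynthImageConfig(canvas_px=(720, 860), nodules=nodules, rng_seed=21)
        img, labels, truth = gen_histology(cfg)
        si = StainImage(img, 1.0)
        recs = isolate_nodules(labels, 1.0)
        assert len(recs) == 20
        for rec, tr in zip(recs, truth):
            assert rec.equivalent_diameter_um == pytest.approx(
                tr["equivalent_diameter_um"], abs=1.0
            )
            f = positive_fraction(si, labels == rec.nodule_id, ThresholdSpec())
            assert f == pytest.approx(tr["positive_fraction"], abs=0.02)
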
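"""Power spectrum, mask geometry, fftscore and threshold calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyrocascade.dataio import GrayImage
from thyrocascade.freqdomain import (DegenerateSpectrumError, ThresholdModel,
                                     calibrate_thresholds, classify_frequency,
                                     fftscore, make_mask, power_spectrum,
                                     tune_mask)


def naive_power_spectrum(pixels: np.ndarray) -> np.ndarray:
    """Direct O(N^4) double-sum DFT (orthonormal), shifted and squared."""
    n = pixels.shape[0]
    f = pixels - pixels.mean()
    out = np.zeros((n, n), dtype=complex)
    for u in range(n):
        for v in range(n):
            acc = 0.0 + 0.0j
            for x in range(n):
                for y in range(n):
                    acc += f[x, y] * np.exp(-2j * np.pi * (u * x + v * y) / n)
            out[u, v] = acc / n  # 1/sqrt(n*n), orthonormal convention
    return np.abs(np.fft.fftshift(out)) ** 2


class TestPowerSpectrum:
    def test_matches_naive_dft_oracle_on_random_8x8(self):
        rng = np.random.default_rng(5)
        px = rng.integers(0, 256, size=(8, 8)).astype(float)
        spec = power_spectrum(GrayImage(px), side=8)
        expected = naive_power_spectrum(px)
        np.testing.assert_allclose(spec.power, expected, rtol=1e-8,
                                   atol=1e-10)

    def test_single_tone_concentrates_in_two_bins(self):
        side = 32
        x = np.arange(side)
        px = 100.0 + 50.0 * np.cos(2 * np.pi * 4 * x / side)
        px = np.tile(px, (side, 1))  # variation along columns
        spec = power_spectrum(GrayImage(px), side=side)
        c = side // 2
        hot = spec.power > 1e-6 * spec.power.max()
        assert set(zip(*np.nonzero(hot))) == {(c, c - 4), (c, c + 4)}
        assert spec.power[c, c - 4] == pytest.approx(spec.power[c, c + 4])

    def test_constant_image_flagged_degenerate(self):
        spec = power_spectrum(GrayImage(np.full((16, 16), 77.0)), side=16)
        assert spec.degenerate
        assert spec.total_power == pytest.approx(0.0, abs=1e-9)

    def test_parseval_total_power_is_side2_times_variance(self, random_image):
        side = 64
        spec = power_spectrum(random_image, side=side)
        from skimage.transform import resize
        resampled = resize(random_image.pixels, (side, side), order=1,
                           mode="edge", anti_aliasing=False,
                           preserve_range=True)
        assert spec.total_power == pytest.approx(
            side ** 2 * resampled.var(), rel=1e-6)

    @pytest.mark.parametrize("side", [7, 6, 9])
    def test_bad_side_rejected(self, side, random_image):
        with pytest.raises(ValueError):
            power_spectrum(random_image, side=side)


class TestMakeMask:
    def test_radius_zero_circle_selects_only_center(self):
        m = make_mask("circle", 16, radius=0)
        assert m.n_selected == 1
        assert m.select[8, 8]

    def test_plus_is_union_of_bars(self):
        h = make_mask("horizontal", 16, bar_half_width=2)
        v = make_mask("vertical", 16, bar_half_width=2)
        p = make_mask("plus", 16, bar_half_width=2)
        assert np.array_equal(p.select, h.select | v.select)
        inter = (h.select & v.select).sum()
        assert p.n_selected == h.n_selected + v.n_selected - inter

    def test_circle_plus_matches_per_bin_predicate(self):
        side, radius, bar = 16, 3, 1
        m = make_mask("circle_plus", side, radius=radius, bar_half_width=bar)
        c = side // 2
        expected = np.zeros((side, side), dtype=bool)
        for i in range(side):
            for j in range(side):
                in_circle = (i - c) ** 2 + (j - c) ** 2 <= radius ** 2
                in_h = abs(i - c) <= bar
                in_v = abs(j - c) <= bar
                expected[i, j] = in_circle or in_h or in_v
        assert np.array_equal(m.select, expected)

    def test_oversized_geometry_clipped_not_error(self):
        m = make_mask("circle", 16, radius=1000)
        assert m.n_selected == 16 * 16

    @given(st.sampled_from(["circle", "horizontal", "vertical", "plus",
                            "circle_plus"]),
           st.integers(0, 6), st.integers(0, 3))
    @settings(deadline=None, max_examples=30)
    def test_masks_symmetric_under_180_rotation(self, kind, radius, bar):
        side = 16
        m = make_mask(kind, side, radius=radius, bar_half_width=bar)
        c = side // 2
        sel = m.select
        for i in range(1, side):
            for j in range(1, side):
                ri, rj = 2 * c - i, 2 * c - j
                if 0 < ri < side and 0 < rj < side:
                    assert sel[i, j] == sel[ri, rj]


class TestFftscore:
    def test_full_mask_scores_one_empty_mask_zero(self, random_image):
        spec = power_spectrum(random_image, side=16)
        full = make_mask("circle", 16, radius=1000)
        assert fftscore(spec, full) == pytest.approx(1.0)
        empty = make_mask("circle", 16, radius=0)
        # radius-0 circle holds only the DC bin, which is excluded
        assert fftscore(spec, empty) == pytest.approx(0.0)

    def test_matches_naive_oracle_ratio(self):
        rng = np.random.default_rng(8)
        px = rng.integers(0, 256, size=(8, 8)).astype(float)
        spec = power_spectrum(GrayImage(px), side=8)
        mask = make_mask("circle", 8, radius=2)
        power = naive_power_spectrum(px)
        power[4, 4] = 0.0
        expected = power[mask.select].sum() / power.sum()
        assert fftscore(spec, mask) == pytest.approx(expected, rel=1e-8)

    def test_degenerate_spectrum_raises(self):
        spec = power_spectrum(GrayImage(np.full((16, 16), 5.0)), side=16)
        with pytest.raises(DegenerateSpectrumError):
            fftscore(spec, make_mask("circle", 16, radius=3))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=15)
    def test_scale_and_brightness_invariance(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.uniform(20, 120, size=(20, 20))
        mask = make_mask("plus", 16, bar_half_width=2)
        base = fftscore(power_spectrum(GrayImage(px), 16), mask)
        scaled = fftscore(power_spectrum(GrayImage(0.5 * px), 16), mask)
        shifted = fftscore(power_spectrum(GrayImage(px + 30.0), 16), mask)
        assert scaled == pytest.approx(base, rel=1e-9)
        assert shifted == pytest.approx(base, rel=1e-9)

    def test_nested_masks_monotone(self, random_image):
        spec = power_spectrum(random_image, side=16)
        small = make_mask("circle", 16, radius=3)
        big = make_mask("circle", 16, radius=6)
        bigger = make_mask("circle_plus", 16, radius=6, bar_half_width=2)
        s1, s2, s3 = (fftscore(spec, m) for m in (small, big, bigger))
        assert s1 <= s2 <= s3


def quantile_oracle(sorted_vals, q):
    """Linear interpolation between order statistics."""
    a = np.sort(np.asarray(sorted_vals, dtype=float))
    pos = (len(a) - 1) * q
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    return a[lo] + (pos - lo) * (a[hi] - a[lo])


class TestCalibration:
    def test_alpha_zero_overlapping_classes(self):
        model = calibrate_thresholds([0.10, 0.20, 0.30], [0.25, 0.40, 0.50],
                                     alpha=0.0)
        assert model.direction == 1
        assert model.th_low == pytest.approx(0.25)
        assert model.th_high == pytest.approx(0.30)

    def test_separable_classes_collapse_to_midpoint(self):
        model = calibrate_thresholds([0.1, 0.2], [0.6, 0.7], alpha=0.0)
        assert model.th_low == model.th_high == pytest.approx(0.4)

    def test_direction_flips_when_malign_scores_low(self):
        model = calibrate_thresholds([0.6, 0.7, 0.8], [0.1, 0.2, 0.3],
                                     alpha=0.0)
        assert model.direction == -1
        assert classify_frequency(0.05, model).value == "malign"
        assert classify_frequency(0.9, model).value == "benign"

    def test_quantiles_match_sort_based_oracle(self):
        rng = np.random.default_rng(17)
        benign = rng.normal(0.3, 0.1, 200)
        malign = rng.normal(0.5, 0.1, 200)   # overlapping: band stays open
        model = calibrate_thresholds(benign, malign, alpha=0.05)
        assert model.th_low == pytest.approx(quantile_oracle(malign, 0.05))
        assert model.th_high == pytest.approx(quantile_oracle(benign, 0.95))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds([0.1], [0.4, 0.5])

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds([0.1, 0.2], [0.4, 0.5], alpha=0.5)

    @given(st.lists(st.floats(0, 1, width=32), min_size=2, max_size=20),
           st.lists(st.floats(0, 1, width=32), min_size=2, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_alpha_zero_gives_zero_training_error(self, benign, malign):
        """With alpha=0, no training benign is called malign and no
        training malign is called benign."""
        model = calibrate_thresholds(benign, malign, alpha=0.0)
        for s in benign:
            assert classify_frequency(s, model).value != "malign"
        for s in malign:
            assert classify_frequency(s, model).value != "benign"


class TestClassifyFrequency:
    @pytest.fixture()
    def model(self):
        return ThresholdModel(th_low=0.25, th_high=0.30, direction=1)

    @pytest.mark.parametrize("score,expected", [
        (0.1, "benign"),
        (0.25, "benign_malign"),   # boundary falls into the band
        (0.28, "benign_malign"),
        (0.30, "benign_malign"),   # boundary falls into the band
        (0.31, "malign"),
    ])
    def test_tri_state_rule(self, model, score, expected):
        assert classify_frequency(score, model).value == expected

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            ThresholdModel(th_low=0.5, th_high=0.4, direction=1)


def auc_concordance_oracle(benign_scores, malign_scores):
    """All-pairs concordance count; oriented (>= 0.5)."""
    wins = ties = 0
    for b in benign_scores:
        for m in malign_scores:
            if m > b:
                wins += 1
            elif m == b:
                ties += 1
    auc = (wins + 0.5 * ties) / (len(benign_scores) * len(malign_scores))
    return max(auc, 1.0 - auc)


class TestTuneMask:
    def test_singleton_grid_returned(self, rng):
        imgs = [GrayImage(rng.uniform(10, 200, size=(20, 20)))
                for _ in range(8)]
        labels = ["benign"] * 4 + ["malign"] * 4
        best, _ = tune_mask(imgs, labels, side=16, radii=[5],
                            bar_half_widths=[])
        assert best.shape_kind == "circle" and best.radius == 5

    def test_empty_grid_rejected(self, rng):
        imgs = [GrayImage(rng.uniform(10, 200, size=(8, 8)))
                for _ in range(4)]
        with pytest.raises(ValueError):
            tune_mask(imgs, ["benign", "benign", "malign", "malign"],
                      side=16, radii=[], bar_half_widths=[])

    def test_winning_auc_matches_concordance_oracle(self, rng):
        imgs = [GrayImage(rng.uniform(10, 200, size=(24, 24)))
                for _ in range(10)]
        labels = ["benign"] * 5 + ["malign"] * 5
        best, auc = tune_mask(imgs, labels, side=16, radii=[3, 5],
                              bar_half_widths=[1])
        from thyrocascade.freqdomain import power_spectrum as ps
        scores = [fftscore(ps(img, 16), best) for img in imgs]
        assert auc == pytest.approx(
            auc_concordance_oracle(scores[:5], scores[5:]))

    def test_plus_family_ranks_at_least_circle_on_phantoms(
            self, phantom_cohort_dir):
        from thyrocascade.dataio import load_image, read_manifest
        from thyrocascade.roi import extract_roi
        cohort = read_manifest(phantom_cohort_dir / "manifest.csv")
        crops, labels = [], []
        for rec in cohort.records:
            crops.append(extract_roi(load_image(rec.image_paths[0])).cropped)
            labels.append(rec.label)
        plus = make_mask("plus", 256, bar_half_width=2)
        circle = make_mask("circle", 256, radius=16)
        from thyrocascade.freqdomain import power_spectrum as ps
        specs = [ps(c, 256) for c in crops]
        b_idx = [i for i, l in enumerate(labels) if l == "benign"]
        m_idx = [i for i, l in enumerate(labels) if l == "malign"]

        def oriented_auc(mask):
            scores = [fftscore(s, mask) for s in specs]
            return auc_concordance_oracle([scores[i] for i in b_idx],
                                          [scores[i] for i in m_idx])

        assert oriented_auc(plus) >= oriented_auc(circle) - 1e-12
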
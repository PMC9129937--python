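"""Descriptor correctness: oracles, analytic limits, orderings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mseeg.features import (
    FeatureConfig,
    FeatureError,
    build_feature_matrix,
    compute_segment_features,
    correlation_dimension,
    higuchi_fd,
    katz_fd,
    petrosian_fd,
    sample_entropy,
    spectral_entropy,
    statistical_features,
    welch_psd,
)
from mseeg.preprocess import Segment


def sampen_oracle(x, m, r):
    """O(N^2) direct template counting, pure Python."""
    n = len(x)
    def count(length):
        templates = [x[i : i + length] for i in range(n - m)]
        c = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                if max(abs(a - b) for a, b in zip(templates[i], templates[j])) <= r:
                    c += 1
        return c
    b = count(m)
    a = count(m + 1)
    if b == 0:
        return 0.0
    if a == 0:
        return float("inf")
    return -math.log(a / b)


class TestWelchPsd:
    def test_white_noise_spectrum_flat(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(256 * 11)  # ~20 averaged 50%-overlap segments
        psd = welch_psd(x, fs=250.0, seg_len=256)
        interior = psd.power[1:-1]  # edge bins carry half-width densities
        assert interior.max() / interior.min() < 3.0

    def test_tone_localized_to_its_bin(self):
        fs = 250.0
        t = np.arange(2048) / fs
        psd = welch_psd(np.sin(2 * np.pi * 10.0 * t), fs, seg_len=256)
        peak = psd.frequencies[np.argmax(psd.power)]
        df = psd.frequencies[1] - psd.frequencies[0]
        assert abs(peak - 10.0) <= df / 2

    def test_integrated_psd_matches_variance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(4096)
        psd = welch_psd(x, fs=250.0, seg_len=256)
        assert abs(psd.total_power - x.var()) / x.var() < 0.10

    def test_segment_longer_than_signal_rejected(self):
        with pytest.raises(FeatureError):
            welch_psd(np.zeros(64), 250.0, seg_len=128)


class TestSampleEntropy:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        r = 0.2 * x.std()
        ours = sample_entropy(x, m=2, r=r)
        assert abs(ours - sampen_oracle(list(x), 2, r)) < 1e-12

    def test_constant_series_has_zero_entropy(self):
        assert sample_entropy(np.full(60, 3.0), m=2, r=0.1) == 0.0

    def test_noise_more_irregular_than_sine(self):
        fs = 250.0
        t = np.arange(1000) / fs
        sine = np.sin(2 * np.pi * 10.0 * t)
        se_sine = sample_entropy(sine, m=2, r=0.2 * sine.std())
        wins = 0
        for s in range(20):
            x = np.random.default_rng(s).standard_normal(1000)
            wins += sample_entropy(x, m=2, r=0.2 * x.std()) > se_sine
        assert wins >= 19

    def test_zero_tolerance_rejected(self):
        with pytest.raises(FeatureError):
            sample_entropy(np.zeros(50), m=2, r=0.0)


class TestSpectralEntropy:
    def test_uniform_spectrum_maximal(self):
        assert abs(spectral_entropy(np.ones(8)) - np.log(8)) < 1e-12
        assert abs(spectral_entropy(np.ones(8), normalize=True) - 1.0) < 1e-12

    def test_single_bin_zero(self):
        p = np.zeros(16)
        p[3] = 2.5
        assert spectral_entropy(p) == 0.0

    def test_two_point_distribution(self):
        p = np.array([0.5, 0.5, 0.0, 0.0])
        assert abs(spectral_entropy(p) - np.log(2)) < 1e-12

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(FeatureError):
            spectral_entropy(np.zeros(8))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 1e6), min_size=2, max_size=64).filter(lambda p: sum(p) > 0))
    def test_entropy_bounds(self, p):
        h = spectral_entropy(np.array(p))
        assert -1e-9 <= h <= np.log(len(p)) + 1e-9


class TestKatz:
    def test_linear_ramp_dimension_one(self):
        assert abs(katz_fd(np.arange(1000.0)) - 1.0) < 1e-9

    def test_similarity_invariance(self):
        x = np.random.default_rng(4).standard_normal(500)
        assert abs(katz_fd(x) - katz_fd(5.0 * x)) < 1e-9

    def test_white_noise_clearly_above_one(self):
        wins = 0
        for s in range(20):
            wins += katz_fd(np.random.default_rng(s).standard_normal(1000)) > 1.2
        assert wins >= 19

    def test_constant_series_rejected(self):
        with pytest.raises(FeatureError):
            katz_fd(np.ones(100))


class TestHiguchi:
    def test_linear_ramp_near_one(self):
        assert 0.95 <= higuchi_fd(np.arange(1000.0)) <= 1.05

    def test_white_noise_near_two(self):
        vals = [higuchi_fd(np.random.default_rng(s).standard_normal(2000), 8) for s in range(20)]
        assert 1.85 <= np.mean(vals) <= 2.05

    def test_smooth_sine_stays_low(self):
        t = np.arange(2000) / 250.0
        assert higuchi_fd(np.sin(2 * np.pi * 10.0 * t), 8) <= 1.1

    def test_small_kmax_rejected(self):
        with pytest.raises(FeatureError):
            higuchi_fd(np.arange(100.0), k_max=1)


class TestPetrosian:
    def test_monotone_ramp_is_one(self):
        assert petrosian_fd(np.arange(100.0)) == 1.0

    def test_alternating_series_sign_changes(self):
        n = 100
        x = np.tile([1.0, -1.0], n // 2)
        d = np.diff(x)
        assert int(np.sum(d[:-1] * d[1:] < 0)) == n - 2
        assert petrosian_fd(x) > 1.0

    def test_noise_above_sine(self):
        t = np.arange(1000) / 250.0
        pd_sine = petrosian_fd(np.sin(2 * np.pi * 10.0 * t))
        wins = 0
        for s in range(20):
            wins += petrosian_fd(np.random.default_rng(s).standard_normal(1000)) > pd_sine
        assert wins >= 19


class TestCorrelationDimension:
    def test_line_has_dimension_one(self):
        assert abs(correlation_dimension(np.arange(500.0), 2, 1) - 1.0) <= 0.15

    def test_iid_noise_fills_the_plane(self):
        x = np.random.default_rng(3).uniform(size=2000)
        assert abs(correlation_dimension(x, 2, 1) - 2.0) <= 0.3

    def test_correlation_sum_is_cdf(self):
        x = np.random.default_rng(5).standard_normal(300)
        from scipy.spatial.distance import pdist

        emb = np.stack([x[:-1], x[1:]], axis=1)
        d = np.sort(pdist(emb))
        radii = np.logspace(np.log10(d[d > 0].min()), np.log10(d[-1]), 25)
        c = np.searchsorted(d, radii, side="right") / d.size
        assert np.all(np.diff(c) >= 0)
        assert c[-1] == 1.0

    def test_too_short_series_rejected(self):
        with pytest.raises(FeatureError):
            correlation_dimension(np.arange(5.0), 2, 1)


class TestStatisticalFeatures:
    def test_hand_computed_pair(self):
        f = statistical_features(np.array([3.0, -4.0]))
        assert f["rms"] == pytest.approx(np.sqrt(12.5))
        assert f["mav"] == 3.5
        assert f["waveform_length"] == 7.0
        assert f["zero_crossings"] == 1.0

    def test_alternating_crossings(self):
        f = statistical_features(np.array([1.0, -1.0, 1.0, -1.0]))
        assert f["zero_crossings"] == 3.0

    def test_constant_degeneracies(self):
        f = statistical_features(np.full(10, -2.0))
        assert f["waveform_length"] == 0.0
        assert f["rms"] == 2.0
        assert f["zero_crossings"] == 0.0


class TestFeatureMatrix:
    @staticmethod
    def _segments(n_frames=10, bands=("alpha",), channels=(0,), fs=250.0, seed=0):
        rng = np.random.default_rng(seed)
        segs = []
        for b in bands:
            for c in channels:
                for i in range(n_frames):
                    segs.append(
                        Segment(
                            samples=rng.standard_normal(100),
                            band=b,
                            channel=c,
                            frame_index=i,
                            fs=fs,
                            recording_id="rec0",
                            label="healthy",
                        )
                    )
        return segs

    def test_shape_and_no_missing(self):
        cfg = FeatureConfig(aggregate="none", channel_average=False)
        fm = build_feature_matrix(self._segments(), cfg)
        assert fm.values.shape == (10, 17)
        assert not fm.values.isna().any().any()

    def test_standardized_training_columns(self):
        cfg = FeatureConfig(aggregate="none", channel_average=False)
        fm = build_feature_matrix(self._segments(n_frames=20), cfg)
        train = list(range(12))
        fm.fit_standardize(train)
        z = fm.transform(train)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_disabling_fractal_group_removes_exactly_those_columns(self):
        full = build_feature_matrix(self._segments(), FeatureConfig(aggregate="none", channel_average=False))
        trimmed = build_feature_matrix(
            self._segments(),
            FeatureConfig(groups=("statistical", "entropy", "spectral"), aggregate="none", channel_average=False),
        )
        dropped = set(full.columns) - set(trimmed.columns)
        assert dropped == {c for c in full.columns if full.groups[c] == "fractal"}

    def test_recording_aggregation_single_row(self):
        cfg = FeatureConfig(aggregate="recording", channel_average=True)
        fm = build_feature_matrix(self._segments(bands=("alpha", "beta"), channels=(0, 1)), cfg)
        assert fm.values.shape == (1, 2 * 17)
        assert fm.labels.iloc[0] == "healthy"

    def test_pipeline_features_all_finite(self, small_features):
        assert np.all(np.isfinite(small_features.values.to_numpy()))
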
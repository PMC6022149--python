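import numpy as np
import pytest
from _oracles import feature_oracle
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from uahar.features import (
    FEATURE_NAMES,
    TA_INDEX,
    _track_stats,
    apply_normalizer,
    extract_features,
    fit_normalizer,
    magnitude,
    mean_crossing_rate,
    tilt_angle,
)
from uahar.preprocessing import Window


class TestMagnitude:
    @pytest.mark.parametrize(
        "xyz,expected",
        [((0, 0, 0), 0.0), ((3, 4, 0), 5.0), ((1, 1, 1), np.sqrt(3))],
    )
    def test_euclidean_norm(self, xyz, expected):
        assert magnitude(np.array(xyz)) == pytest.approx(expected, abs=1e-12)

    def test_vectorized_over_rows(self, rng):
        block = rng.normal(size=(20, 3))
        np.testing.assert_allclose(
            magnitude(block), np.linalg.norm(block, axis=1), rtol=1e-12
        )


class TestTiltAngle:
    def test_silent_gyro_gives_zero(self):
        assert tilt_angle(np.zeros((50, 3)), 50.0) == 0.0

    def test_constant_rotation_integrates_to_angle(self):
        # 90 deg/s about x over a 1-s window at 50 Hz: 50 * 90 * 0.02 = 90
        gyro = np.zeros((50, 3))
        gyro[:, 0] = 90.0
        assert tilt_angle(gyro, 50.0) == pytest.approx(90.0, abs=1e-9)

    def test_symmetric_in_x_and_z(self, rng):
        gyro = rng.normal(0, 50, size=(50, 3))
        swapped = gyro[:, [2, 1, 0]]
        assert tilt_angle(gyro, 50.0) == pytest.approx(tilt_angle(swapped, 50.0), rel=1e-12)

    def test_y_axis_rotation_ignored(self, rng):
        gyro = np.zeros((50, 3))
        gyro[:, 1] = rng.normal(0, 100, 50)
        assert tilt_angle(gyro, 50.0) == 0.0


class TestExtractFeatures:
    def test_thirteen_features_in_declared_order(self, random_window):
        fv = extract_features(random_window)
        assert fv.shape == (13,)
        assert len(FEATURE_NAMES) == 13
        assert FEATURE_NAMES[TA_INDEX] == "tilt_angle"

    def test_constant_magnitude_window(self):
        # body magnitude constant c: mean=max=min=c, std=mcr=0, energy=c^2
        samples = np.zeros((50, 6))
        body = np.zeros((50, 3))
        body[:, 0] = 2.0
        fv = extract_features(Window(1, 0, samples, body, 50.0))
        a_mean, a_std, a_energy, a_mcr, a_max, a_min = fv[:6]
        assert (a_mean, a_max, a_min) == (2.0, 2.0, 2.0)
        assert (a_std, a_mcr) == (0.0, 0.0)
        assert a_energy == 4.0

    def test_alternating_track_statistics(self):
        # synthetic +-1 track: mean 0, std 1, energy 1, mcr 1, max 1, min -1
        stats = _track_stats(np.array([1.0, -1.0, 1.0, -1.0]))
        assert stats == [0.0, 1.0, 1.0, 1.0, 1.0, -1.0]

    def test_mean_crossing_rate_bounds(self, rng):
        track = rng.normal(size=200)
        assert 0.0 <= mean_crossing_rate(track) <= 1.0

    def test_agrees_with_straight_loop_oracle(self, rng):
        for _ in range(10):
            samples = rng.normal(size=(50, 6)) * [0.3, 0.3, 0.3, 40, 40, 40]
            body = samples[:, :3] - rng.normal(size=3) * 0.1
            w = Window(1, 0, samples, body, 50.0)
            expected = feature_oracle(
                np.linalg.norm(body, axis=1),
                np.linalg.norm(samples[:, 3:], axis=1),
                samples[:, 3:],
                50.0,
            )
            np.testing.assert_allclose(extract_features(w), expected, atol=1e-12)

    def test_translation_covariance_of_magnitude_statistics(self, rng):
        # shifting the magnitude track shifts mean/max/min, fixes std and mcr
        track = rng.normal(5, 1, size=50)
        base = _track_stats(track)
        shifted = _track_stats(track + 3.0)
        assert shifted[0] == pytest.approx(base[0] + 3.0, rel=1e-12)
        assert shifted[4] == pytest.approx(base[4] + 3.0, rel=1e-12)
        assert shifted[5] == pytest.approx(base[5] + 3.0, rel=1e-12)
        assert shifted[1] == pytest.approx(base[1], rel=1e-9)
        assert shifted[3] == pytest.approx(base[3], abs=1e-12)


class TestFeatureInvariants:
    """Structural invariants that hold for arbitrary finite tracks."""

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(np.float64, (20, 3), elements=st.floats(-100, 100)))
    def test_magnitude_nonnegative_and_homogeneous(self, block):
        mags = magnitude(block)
        assert np.all(mags >= 0)
        np.testing.assert_allclose(magnitude(2.0 * block), 2.0 * mags, rtol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(np.float64, 30, elements=st.floats(-50, 50)))
    def test_track_statistics_ordering(self, track):
        mean, std, energy, mcr, mx, mn = _track_stats(track)
        # min <= mean <= max up to summation rounding (1 ulp on ties)
        slack = 4 * np.spacing(max(abs(mn), abs(mx), 1e-300))
        assert mn - slack <= mean <= mx + slack
        assert std >= 0 and energy >= 0
        assert 0.0 <= mcr <= 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(np.float64, (25, 3), elements=st.floats(-200, 200)))
    def test_tilt_angle_nonnegative_and_sign_symmetric(self, gyro):
        ta = tilt_angle(gyro, 50.0)
        assert ta >= 0.0
        assert tilt_angle(-gyro, 50.0) == pytest.approx(ta, rel=1e-12, abs=1e-12)


class TestNormalizer:
    def test_unit_box_training_set_gives_identity(self):
        X = np.vstack([np.zeros(13), np.ones(13)])
        norm = fit_normalizer(X)
        probe = np.full(13, 0.25)
        np.testing.assert_allclose(apply_normalizer(norm, probe), probe)

    def test_training_minimum_maps_to_zero(self, rng):
        X = rng.normal(size=(30, 13))
        norm = fit_normalizer(X)
        np.testing.assert_allclose(norm.transform(X.min(axis=0)), 0.0, atol=1e-12)
        assert norm.transform(X).min() >= 0.0 and norm.transform(X).max() <= 1.0 + 1e-12

    def test_constant_feature_maps_to_zero(self):
        X = np.ones((5, 13))
        X[:, 0] = [0, 1, 2, 3, 4]
        norm = fit_normalizer(X)
        assert np.all(norm.transform(X)[:, 1:] == 0.0)

    def test_values_outside_training_range_not_clamped(self, rng):
        X = rng.uniform(size=(10, 13))
        norm = fit_normalizer(X)
        big = norm.transform(X.max(axis=0) + 1.0)
        assert np.all(big > 1.0)

    def test_fit_requires_two_vectors(self):
        with pytest.raises(ValueError):
            fit_normalizer(np.empty((0, 13)))
        with pytest.raises(ValueError):
            fit_normalizer(np.ones((1, 13)))
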
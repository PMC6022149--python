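import numpy as np
import pytest
from scipy.stats import multivariate_normal

from uahar.features import Normalizer, extract_features
from uahar.mgd_classifier import (
    MGDModel,
    PersonalizedClassifier,
    calibrate_thresholds,
    classifier_from_json,
    classifier_to_json,
    classify_window,
    fit_mgd,
    mgd_density,
    train_personalized,
)
from uahar.preprocessing import preprocess_stream
from uahar.synthetic_data import SubjectProfile, default_train_script, simulate_subject


def _random_spd(rng, d):
    A = rng.normal(size=(d, d))
    return A @ A.T + d * np.eye(d)


class TestFitMGD:
    def test_mean_of_two_samples(self):
        model = fit_mgd(np.array([[0.0] * 13, [2.0] * 13]), label="LIA")
        np.testing.assert_allclose(model.mu, np.ones(13))

    def test_identical_samples_regularized_to_positive_definite(self):
        model = fit_mgd(np.ones((10, 13)), label="LIA")
        assert np.all(np.linalg.eigvalsh(model.sigma) > 0)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            fit_mgd(np.ones((1, 13)))

    def test_covariance_uses_divisor_m(self, rng):
        X = rng.normal(size=(40, 3))
        model = fit_mgd(X)
        expected = np.cov(X, rowvar=False, bias=True)  # MLE (1/m)
        np.testing.assert_allclose(model.sigma, expected, atol=1e-10)

    def test_parameter_recovery_from_large_sample(self):
        rng = np.random.default_rng(7)
        d = 13
        mu_true = rng.uniform(-1, 1, d)
        A = rng.normal(size=(d, d)) / np.sqrt(d)
        sigma_true = A @ A.T
        scale = np.sqrt(np.diag(sigma_true))
        sigma_true = sigma_true / np.outer(scale, scale)  # unit variances
        X = rng.multivariate_normal(mu_true, sigma_true, size=5000)
        model = fit_mgd(X)
        assert np.max(np.abs(model.mu - mu_true)) < 0.05
        assert np.max(np.abs(model.sigma - sigma_true)) < 0.1


class TestMGDDensity:
    def test_standard_normal_peak_in_one_dimension(self):
        model = MGDModel(mu=np.zeros(1), sigma=np.eye(1))
        assert mgd_density(model, np.zeros(1)) == pytest.approx(1 / np.sqrt(2 * np.pi), rel=1e-12)

    def test_density_at_mean_is_normalization_constant(self, rng):
        d = 5
        sigma = _random_spd(rng, d)
        mu = rng.normal(size=d)
        model = MGDModel(mu=mu, sigma=sigma)
        expected = (2 * np.pi) ** (-d / 2) * np.linalg.det(sigma) ** -0.5
        assert mgd_density(model, mu) == pytest.approx(expected, rel=1e-10)

    def test_agrees_with_reference_implementation(self, rng):
        d = 13
        sigma = _random_spd(rng, d)
        mu = rng.normal(size=d)
        model = MGDModel(mu=mu, sigma=sigma)
        ref = multivariate_normal(mean=mu, cov=sigma)
        for _ in range(20):
            x = rng.normal(size=d) * 3
            assert mgd_density(model, x) == pytest.approx(ref.pdf(x), rel=1e-10)
            assert model.logpdf(x) == pytest.approx(ref.logpdf(x), rel=1e-10)

    def test_non_finite_input_rejected(self):
        model = MGDModel(mu=np.zeros(2), sigma=np.eye(2))
        with pytest.raises(ValueError, match="finite"):
            model.logpdf(np.array([np.nan, 0.0]))


def _toy_classifier(eps3=60.0, log_eps2=-50.0):
    """Three tight Gaussians centered so the argmax is easy to steer.

    In normalized feature space the LIA/MIA/VIA means sit at 0.1/0.5/0.9
    on every coordinate; the tilt-angle feature is scaled like real
    training data (tens of degrees map into [0, 1]), so a raw tilt of
    80 degrees lands at 0.9 normalized.
    """
    d = 13
    models = tuple(
        MGDModel(mu=np.full(d, c), sigma=0.01 * np.eye(d), label=lab)
        for c, lab in zip((0.1, 0.5, 0.9), ("LIA", "MIA", "VIA"))
    )
    scale = np.ones(d)
    scale[12] = 80.0 / 0.9
    norm = Normalizer(min_=np.zeros(d), scale_=scale)
    return PersonalizedClassifier(models=models, log_eps2=log_eps2, eps3_deg=eps3, normalizer=norm)


class TestClassifyWindow:
    def test_largest_density_wins_for_lia_and_mia(self):
        clf = _toy_classifier()
        assert classify_window(clf, np.full(13, 0.1)) == "LIA"
        assert classify_window(clf, np.full(13, 0.5)) == "MIA"

    def test_via_when_density_above_threshold_and_small_tilt(self):
        clf = _toy_classifier(log_eps2=-50.0)
        fv = np.full(13, 0.9)
        fv[12] = 10.0  # small tilt angle (degrees, raw)
        assert classify_window(clf, fv) == "VIA"

    def test_fall_requires_low_density_and_large_tilt(self):
        clf = _toy_classifier(log_eps2=-50.0)
        fv = np.full(13, 1.6)  # far from VIA: log density below threshold
        fv[12] = 80.0
        assert classify_window(clf, fv) == "Fall"

    def test_incoherent_combinations_resolve_to_via(self):
        clf = _toy_classifier(log_eps2=-50.0)
        low_density_small_tilt = np.full(13, 1.6)
        low_density_small_tilt[12] = 10.0
        assert classify_window(clf, low_density_small_tilt) == "VIA"
        high_density_large_tilt = np.full(13, 0.9)
        high_density_large_tilt[12] = 80.0  # at the VIA center, huge raw tilt
        assert classify_window(clf, high_density_large_tilt) == "VIA"

    def test_argmax_tie_prefers_lower_intensity(self):
        d = 13
        models = tuple(
            MGDModel(mu=np.full(d, 0.5), sigma=np.eye(d), label=lab)
            for lab in ("LIA", "MIA", "VIA")
        )
        clf = PersonalizedClassifier(
            models=models, log_eps2=-50.0, eps3_deg=60.0,
            normalizer=Normalizer(min_=np.zeros(d), scale_=np.ones(d)),
        )
        assert classify_window(clf, np.full(d, 0.5)) == "LIA"

    def test_uniform_density_rescaling_preserves_argmax(self, rng):
        # adding a constant to every log density (scaling all densities by
        # the same factor) must not change the LIA/MIA decision
        clf = _toy_classifier()
        fv = np.full(13, 0.3)
        logp = clf.log_densities(fv[None])[0]
        assert np.argmax(logp) == np.argmax(logp + 123.4)


class TestCalibrateThresholds:
    def test_percentile_bounded_by_training_densities(self, rng):
        d = 4
        model = MGDModel(mu=np.zeros(d), sigma=np.eye(d))
        X = rng.normal(size=(200, d))
        log_eps2, _ = calibrate_thresholds(model, X, eps2_percentile=1.0)
        logp = model.logpdf(X)
        assert log_eps2 <= np.partition(logp, 3)[3]  # below ~2nd percentile point
        assert log_eps2 >= logp.min()

    def test_zeroth_percentile_is_training_minimum(self, rng):
        d = 4
        model = MGDModel(mu=np.zeros(d), sigma=np.eye(d))
        X = rng.normal(size=(50, d))
        log_eps2, _ = calibrate_thresholds(model, X, eps2_percentile=0.0)
        assert log_eps2 == pytest.approx(float(np.min(model.logpdf(X))))

    def test_too_few_windows_falls_back_with_warning(self):
        model = MGDModel(mu=np.zeros(3), sigma=np.eye(3))
        with pytest.warns(UserWarning, match="fallback"):
            log_eps2, eps3 = calibrate_thresholds(model, np.zeros((5, 3)), eps2_override=1e-4)
        assert log_eps2 == pytest.approx(np.log(1e-4))
        assert eps3 == 60.0


@pytest.fixture(scope="module")
def training_setup():
    profile = SubjectProfile(subject_id=0, seed=42)
    stream = simulate_subject(profile, default_train_script())
    seed_profile = SubjectProfile(subject_id=1, seed=43)
    seed_stream = simulate_subject(seed_profile, default_train_script())
    windows = preprocess_stream(seed_stream)
    seed_X = np.array([extract_features(w) for w in windows])
    seed_y = np.array([w.label for w in windows], dtype=object)
    return stream, seed_X, seed_y


class TestTrainPersonalized:
    def test_class_means_ordered_by_intensity(self, training_setup):
        stream, seed_X, seed_y = training_setup
        clf, report = train_personalized(stream, seed_X, seed_y)
        # a_std (feature 1) in the shared normalized space: LIA < MIA < VIA
        a_std = [m.mu[1] for m in clf.models]
        assert a_std[0] < a_std[1] < a_std[2]
        assert report["kmeans_converged"]

    def test_infinite_eps1_equals_unfiltered_pipeline(self, training_setup):
        stream, seed_X, seed_y = training_setup
        clf_inf, rep_inf = train_personalized(stream, seed_X, seed_y, llof_eps1=np.inf)
        assert rep_inf["n_removed"] == 0
        clf_def, rep_def = train_personalized(stream, seed_X, seed_y)
        assert rep_def["n_removed"] >= 0
        assert sum(rep_inf["class_sizes"].values()) == rep_inf["n_windows"]

    def test_report_counts_are_conserved(self, training_setup):
        stream, seed_X, seed_y = training_setup
        _, report = train_personalized(stream, seed_X, seed_y)
        assert sum(report["class_sizes"].values()) == report["n_windows"] - report["n_removed"]

    def test_training_is_deterministic(self, training_setup):
        stream, seed_X, seed_y = training_setup
        clf1, _ = train_personalized(stream, seed_X, seed_y)
        clf2, _ = train_personalized(stream, seed_X, seed_y)
        for m1, m2 in zip(clf1.models, clf2.models):
            np.testing.assert_array_equal(m1.mu, m2.mu)
            np.testing.assert_array_equal(m1.sigma, m2.sigma)
        assert clf1.log_eps2 == clf2.log_eps2

    def test_json_roundtrip_preserves_predictions(self, training_setup, rng):
        stream, seed_X, seed_y = training_setup
        clf, _ = train_personalized(stream, seed_X, seed_y)
        back = classifier_from_json(classifier_to_json(clf))
        probes = rng.uniform(0, 1, size=(20, 13)) * seed_X.max(axis=0)
        assert list(back.classify(probes)) == list(clf.classify(probes))
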
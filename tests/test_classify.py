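"""Preprocessing, CSP, cross-validated classification and confusion metrics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esiopt.classify import (
    FeatureSpec,
    PreprocConfig,
    cross_validate,
    csp_fit,
    metrics_from_confusion,
    preprocess,
    source_features,
)
from esiopt.inverse import lambda2_for_snr
from esiopt.simulate import EpochSet


class TestPreprocess:
    def test_car_removes_per_sample_channel_mean(self, mi_epochs):
        out = preprocess(mi_epochs, PreprocConfig())
        assert np.max(np.abs(out.data.mean(axis=1))) < 1e-12

    def test_mains_tone_strongly_attenuated(self):
        """A pure 50 Hz sinusoid must lose >= 40 dB through notch + mu band-pass."""
        sfreq, n = 250.0, 1000
        t = np.arange(n) / sfreq
        tone = np.sin(2 * np.pi * 50.0 * t)
        data = np.tile(tone, (1, 3, 1)) * np.array([1.0, 2.0, -1.0])[None, :, None]
        epochs = EpochSet(data, sfreq, np.zeros(1))
        out = preprocess(epochs, PreprocConfig(reference="none"))
        core = slice(n // 4, 3 * n // 4)  # avoid filter edges
        attenuation_db = 20 * np.log10(
            np.sqrt(np.mean(data[0, 1, core] ** 2))
            / max(np.sqrt(np.mean(out.data[0, 1, core] ** 2)), 1e-30)
        )
        assert attenuation_db >= 40.0

    def test_subset_car_differs_from_full_car(self):
        """Referencing within the subset is not the full-set reference restricted."""
        rng = np.random.default_rng(0)
        data = rng.standard_normal((2, 32, 200))
        epochs = EpochSet(data, 250.0, np.zeros(2))
        sub = np.arange(16)
        cfg = PreprocConfig(notch_freqs=(), highpass=None)
        car_sub = preprocess(epochs, cfg, sub)
        car_full = preprocess(epochs, cfg)
        assert not np.allclose(car_sub.data, car_full.data[:, sub, :], atol=1e-6)

    def test_bandpass_above_nyquist_rejected(self, mi_epochs):
        with pytest.raises(ValueError):
            preprocess(mi_epochs, PreprocConfig(bandpass=(8.0, 200.0)))

    def test_car_needs_two_channels(self, mi_epochs):
        with pytest.raises(ValueError):
            preprocess(mi_epochs, PreprocConfig(), np.array([3]))


class TestSourceFeatures:
    def test_shape_and_trial_preservation(self, mi_epochs, lf600, mi_roi):
        out = source_features(mi_epochs, lf600, mi_roi, lambda2=0.1)
        assert out.data.shape == (mi_epochs.n_trials, 40, mi_epochs.n_samples)
        np.testing.assert_array_equal(out.truth, mi_epochs.truth)

    def test_linear_in_the_input(self, lf72, roi40):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((1, lf72.n_channels, 100))
        b = rng.standard_normal((1, lf72.n_channels, 100))
        f = lambda d: source_features(
            EpochSet(d, 250.0, np.zeros(1)), lf72, roi40, 0.1
        ).data
        np.testing.assert_allclose(f(a) + f(b), f(a + b), atol=1e-10)

    def test_roi_out_of_range_rejected(self, mi_epochs, lf72):
        with pytest.raises(IndexError):
            source_features(mi_epochs, lf72, [10_000], 0.1)


class TestCsp:
    def test_identical_classes_cluster_at_half(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((200, 4, 100))
        labels = np.repeat([0, 1], 100)
        filters = csp_fit(data, labels, 4)
        assert np.all(np.abs(filters.eigenvalues - 0.5) < 0.1)

    def test_axis_aligned_construction_recovered(self):
        """Class A strong on channel 1, class B on channel 2: the extreme
        filters must align with the coordinate axes."""
        rng = np.random.default_rng(3)
        n, s = 60, 200
        a = np.stack([np.vstack([3.0 * rng.standard_normal(s), 0.3 * rng.standard_normal(s)]) for _ in range(n)])
        b = np.stack([np.vstack([0.3 * rng.standard_normal(s), 3.0 * rng.standard_normal(s)]) for _ in range(n)])
        data = np.concatenate([a, b])
        labels = np.repeat([0, 1], n)
        filters = csp_fit(data, labels, 2).filters
        for row in filters:
            direction = np.abs(row) / np.linalg.norm(row)
            assert max(direction) >= 0.99

    def test_filters_whiten_composite_covariance(self):
        rng = np.random.default_rng(14)
        data = rng.standard_normal((80, 8, 150))
        data[:40, :4] *= 2.5  # class asymmetry
        labels = np.repeat([0, 1], 40)
        filters = csp_fit(data, labels, 6).filters
        covs = []
        for c in (0, 1):
            trials = data[labels == c]
            per = np.matmul(trials, trials.transpose(0, 2, 1))
            per /= np.trace(per, axis1=1, axis2=2)[:, None, None]
            covs.append(per.mean(axis=0))
        composite = covs[0] + covs[1]
        np.testing.assert_allclose(
            filters @ composite @ filters.T, np.eye(6), atol=1e-8
        )

    def test_requires_two_classes_and_enough_trials(self):
        data = np.zeros((4, 3, 10))
        with pytest.raises(ValueError):
            csp_fit(data, np.zeros(4), 2)
        with pytest.raises(ValueError):
            csp_fit(data, np.array([0, 0, 0, 1]), 2)


class TestMetrics:
    @pytest.mark.parametrize(
        "confusion,expected",
        [
            ((5, 0, 0, 5), (1.0, 1.0, 1.0, 1.0)),
            ((0, 5, 5, 0), (0.0, 0.0, 0.0, 0.0)),
            ((40, 10, 5, 45), (0.85, 45 / 55, 0.9, 90 / 105)),
        ],
    )
    def test_hand_computed_examples(self, confusion, expected):
        assert metrics_from_confusion(*confusion).as_tuple() == pytest.approx(expected)

    def test_undefined_quotients_flagged(self):
        m = metrics_from_confusion(10, 0, 0, 0)
        assert m.precision == 0.0 and m.recall == 0.0
        assert set(m.undefined) == {"precision", "recall", "f1"}

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(0, 0, 0, 0)
        with pytest.raises(ValueError):
            metrics_from_confusion(-1, 0, 0, 2)

    @given(
        tn=st.integers(0, 500),
        fp=st.integers(0, 500),
        fn=st.integers(0, 500),
        tp=st.integers(1, 500),
    )
    @settings(max_examples=200, derandomize=True)
    def test_f1_harmonic_mean_identity(self, tn, fp, fn, tp):
        """F1 = 2PR/(P+R) and F1 = 2TP/(2TP+FP+FN) agree whenever TP > 0."""
        m = metrics_from_confusion(tn, fp, fn, tp)
        harmonic = 2 * m.precision * m.recall / (m.precision + m.recall)
        assert m.f1 == pytest.approx(harmonic)
        assert all(0.0 <= v <= 1.0 for v in m.as_tuple())


class TestCrossValidate:
    def test_perfect_separation_scores_unity(self):
        rng = np.random.default_rng(4)
        n = 40
        a = np.stack([np.vstack([2.0 * rng.standard_normal(100), 0.1 * rng.standard_normal(100)]) for _ in range(n)])
        b = np.stack([np.vstack([0.1 * rng.standard_normal(100), 2.0 * rng.standard_normal(100)]) for _ in range(n)])
        epochs = EpochSet(np.concatenate([a, b]), 250.0, np.repeat([0, 1], n))
        report = cross_validate(
            epochs, feature_spec=FeatureSpec(n_csp_components=2), classifier="lda", seed=0
        )
        for fold in report.folds:
            assert fold.metrics.as_tuple() == (1.0, 1.0, 1.0, 1.0)

    def test_shuffled_labels_score_at_chance(self, mi_prepared):
        rng = np.random.default_rng(5)
        shuffled = rng.permutation(mi_prepared.truth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = cross_validate(
                mi_prepared, labels=shuffled, classifier="lda", seed=1
            )
        assert abs(report.mean.accuracy - 0.5) <= 0.1

    def test_metrics_consistent_with_confusions(self, mi_prepared):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = cross_validate(mi_prepared, classifier="lda", seed=2, n_repeats=3)
        for fold in report.folds:
            tn, fp, fn, tp = fold.confusion
            assert tn + fp + fn + tp == 36  # 30% of 120 trials
            assert fold.metrics == metrics_from_confusion(tn, fp, fn, tp)

    def test_deterministic_for_fixed_seed(self, mi_prepared):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = cross_validate(mi_prepared, classifier="rf", seed=3, n_repeats=2)
            b = cross_validate(mi_prepared, classifier="rf", seed=3, n_repeats=2)
        assert a == b

    def test_source_space_not_worse_than_electrode_space(self, mi_prepared, lf600, mi_roi):
        """Hand-knob source features should match or beat raw electrodes
        (direction of the paper-style comparison; 0.05 simulation tolerance)."""
        lam = lambda2_for_snr(lf600, 10.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            electrode = cross_validate(mi_prepared, classifier="lda", seed=4)
            source = cross_validate(
                mi_prepared,
                feature_spec=FeatureSpec("source", roi_indices=mi_roi, lambda2=lam),
                classifier="lda",
                seed=4,
                lf=lf600,
            )
        assert source.mean.accuracy >= electrode.mean.accuracy - 0.05

    @pytest.mark.parametrize("clf", ["rf", "svm", "lda"])
    def test_all_classifier_tags_run(self, mi_prepared, clf):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = cross_validate(mi_prepared, classifier=clf, seed=6, n_repeats=2)
        assert len(report.folds) == 2
        assert report.classifier == clf

    def test_unknown_classifier_rejected(self, mi_prepared):
        with pytest.raises(ValueError):
            cross_validate(mi_prepared, classifier="mlp", seed=0, n_repeats=1)
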
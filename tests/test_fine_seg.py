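"""Voxel classification stage: PCA, balancing, classifiers, baselines, provenance."""

import numpy as np
import pytest

from renodce import fine_seg, metrics, pk
from renodce.dataio import CompartmentLabelMap
from renodce.errors import (
    EmptyRegionError,
    MissingClassError,
    ParameterError,
    ProvenanceError,
    ShapeError,
)
from renodce.fine_seg import (
    ClassifierConfig,
    TimeCourseSet,
    balance_classes,
    baseline_normalize,
    classify_voxels,
    dwt_features,
    extract_time_courses,
    fit_pca,
    grid_search_svm,
    kmeans_partition,
    train_classifier,
    transform_pca,
)


def _blobs(n_per_class=60, seed=0, spread=0.1):
    """Three well-separated Gaussian blobs labelled 1/2/3."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [5, 0], [0, 5]], dtype=float)
    x = np.vstack([c + spread * rng.standard_normal((n_per_class, 2)) for c in centers])
    y = np.repeat([1, 2, 3], n_per_class)
    return x, y


class TestExtractTimeCourses:
    def test_row_count_equals_mask_voxels(self, small_phantom):
        ph = small_phantom
        tcs = extract_time_courses(ph.series, ph.labels.data > 0, ph.labels)
        assert len(tcs) == int((ph.labels.data > 0).sum())
        assert tcs.values.shape[1] == ph.series.n_frames

    def test_cortex_rows_equal_forward_model(self, small_phantom):
        ph = small_phantom
        tcs = extract_time_courses(ph.series, ph.labels.data > 0, ph.labels)
        conc = pk.forward_2cfm(ph.true_params["cortex"], ph.aif).concentration
        expected = pk.concentration_to_signal(
            conc, ph.config.s0_kidney, ph.config.t10_s["cortex"], ph.config.r1,
            ph.config.tr_ms, ph.config.flip_angle_deg,
        )
        rows = tcs.values[tcs.labels == 1]
        assert np.max(np.abs(rows - expected)) == 0.0

    def test_empty_mask_rejected(self, small_phantom):
        with pytest.raises(EmptyRegionError):
            extract_time_courses(small_phantom.series, np.zeros(small_phantom.series.shape[:3], bool))


class TestPCA:
    def _tcs(self, values, n_baseline=2):
        n = len(values)
        return TimeCourseSet(values, np.zeros((n, 3), int), subjects=np.full(n, "a"),
                             n_baseline=n_baseline)

    def test_rank2_data_explained_by_two_components(self):
        rng = np.random.default_rng(0)
        basis = rng.random((2, 30))
        coefs = rng.random((100, 2))
        tcs = self._tcs(1.0 + coefs @ basis)
        model = fit_pca(tcs, k=2, min_variance=0.0, normalize=False)
        assert model.explained_variance_ratio[:2].sum() == pytest.approx(1.0, abs=1e-9)

    def test_min_variance_requirement_met(self, classification_artifacts):
        pca = classification_artifacts["pca"]
        assert pca.explained_variance_ratio.sum() >= 0.90
        assert pca.k >= 20

    def test_transform_matches_direct_projection(self):
        rng = np.random.default_rng(1)
        tcs = self._tcs(rng.random((50, 20)))
        model = fit_pca(tcs, k=5, normalize=False)
        feats = transform_pca(model, tcs)
        direct = (tcs.values - model.mean) @ model.components.T
        assert np.allclose(feats, direct)

    def test_mean_vector_maps_to_zero(self):
        rng = np.random.default_rng(2)
        tcs = self._tcs(rng.random((50, 20)))
        model = fit_pca(tcs, k=4, normalize=False)
        mean_tcs = self._tcs(model.mean[None, :])
        assert np.allclose(transform_pca(model, mean_tcs), 0.0, atol=1e-10)

    def test_reconstruction_error_monotone_in_k(self):
        rng = np.random.default_rng(3)
        x = rng.random((80, 25))
        tcs = self._tcs(x)
        errs = []
        for k in (3, 5, 10):
            m = fit_pca(tcs, k=k, min_variance=0.0, normalize=False)
            f = transform_pca(m, tcs)
            recon = f @ m.components + m.mean
            errs.append(np.linalg.norm(x - recon))
        assert errs[0] >= errs[1] >= errs[2]

    def test_k_larger_than_frames_rejected(self):
        tcs = self._tcs(np.random.default_rng(0).random((30, 10)))
        with pytest.raises(ParameterError):
            fit_pca(tcs, k=11)

    def test_resampling_bridges_different_time_grids(self):
        rng = np.random.default_rng(4)
        t_train = np.arange(0, 60, 2.0)
        curves = np.sin(np.outer(rng.random(40) + 0.5, t_train / 10.0)) + 2.0
        tcs = TimeCourseSet(curves, np.zeros((40, 3), int), subjects=np.full(40, "a"),
                            frame_times=t_train, n_baseline=3)
        model = fit_pca(tcs, k=5, normalize=False)
        t_new = np.arange(0, 60, 3.0)
        resampled = np.stack([np.interp(t_new, t_train, row) for row in curves[:5]])
        other = TimeCourseSet(resampled, np.zeros((5, 3), int), subjects=np.full(5, "b"),
                              frame_times=t_new, n_baseline=2)
        feats = transform_pca(model, other)
        assert feats.shape == (5, model.k)

    def test_frame_mismatch_without_grids_rejected(self):
        tcs = self._tcs(np.random.default_rng(0).random((30, 20)))
        model = fit_pca(tcs, k=3, normalize=False)
        short = self._tcs(np.random.default_rng(1).random((4, 15)))
        with pytest.raises(ShapeError):
            transform_pca(model, short)


class TestBalanceClasses:
    def test_published_class_mix_counts(self):
        """Counts (580, 310, 110) resample to (110, 110, 110)."""
        rng = np.random.default_rng(0)
        labels = np.repeat([1, 2, 3], [580, 310, 110])
        feats = rng.random((1000, 4))
        bx, by = balance_classes(feats, labels, seed=1)
        assert [int((by == c).sum()) for c in (1, 2, 3)] == [110, 110, 110]

    def test_balanced_input_is_permutation(self):
        feats = np.arange(30).reshape(15, 2)
        labels = np.repeat([1, 2, 3], 5)
        bx, by = balance_classes(feats, labels, seed=0)
        assert sorted(map(tuple, bx)) == sorted(map(tuple, feats))

    def test_seeded_determinism(self):
        feats, labels = _blobs(40)
        a = balance_classes(feats, labels, seed=9)
        b = balance_classes(feats, labels, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_smaller_class_oversampled(self):
        labels = np.repeat([1, 2, 3], [4, 100, 50])
        feats = np.random.default_rng(0).random((154, 2))
        _, by = balance_classes(feats, labels, seed=0)
        assert [int((by == c).sum()) for c in (1, 2, 3)] == [50, 50, 50]

    def test_absent_class_rejected(self):
        with pytest.raises(MissingClassError):
            balance_classes(np.zeros((4, 2)), np.array([1, 1, 2, 2]))


class TestClassifiers:
    @pytest.mark.parametrize("algorithm", ["svm_rbf", "logistic", "xgboost"])
    def test_separable_blobs_learned_perfectly(self, algorithm):
        x, y = _blobs()
        clf = train_classifier(x, y, ClassifierConfig(algorithm=algorithm))
        rep = metrics.classification_report(y, clf.predict(x))
        assert rep.balanced_accuracy == 1.0

    def test_logistic_probabilities_sum_to_one(self):
        x, y = _blobs()
        clf = train_classifier(x, y, ClassifierConfig(algorithm="logistic"))
        probs = clf.scores(x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            train_classifier(np.zeros((10, 2)), np.ones(10))

    def test_pca_features_competitive_with_raw_curves(self, classification_phantoms,
                                                      classification_artifacts):
        """k=20 PCA features lose at most 1 point of balanced accuracy vs raw 74-dim."""
        _, test_ph = classification_phantoms
        art = classification_artifacts
        test_tcs = extract_time_courses(test_ph.series, test_ph.labels.data > 0,
                                        test_ph.labels, subject="held_out")
        # PCA route
        clf = train_classifier(art["features"], art["labels"], training_subjects=art["subjects"])
        pred = clf.predict(transform_pca(art["pca"], test_tcs))
        acc_pca = metrics.classification_report(test_tcs.labels, pred).balanced_accuracy
        # raw route (baseline-normalized full curves)
        raw_train = baseline_normalize(art["tcs"].values, art["tcs"].n_baseline)
        bx, by = balance_classes(raw_train, art["tcs"].labels, seed=0)
        clf_raw = train_classifier(bx, by)
        raw_test = baseline_normalize(test_tcs.values, test_tcs.n_baseline)
        acc_raw = metrics.classification_report(
            test_tcs.labels, clf_raw.predict(raw_test)
        ).balanced_accuracy
        assert acc_pca >= acc_raw - 0.01


class TestGridSearch:
    def test_single_point_grid(self):
        x, y = _blobs(30)
        gamma, c, _ = grid_search_svm(x, y, gammas=[0.05], cs=[1.0], folds=3)
        assert (gamma, c) == (0.05, 1.0)

    def test_overfitting_gamma_rejected_by_cv(self):
        """Noisy overlapping classes: gamma=50 memorises folds, gamma=0.05 generalises."""
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 1.2, (80, 2)), rng.normal(2.0, 1.2, (80, 2))])
        y = np.repeat([1, 2], 80)
        gamma, c, results = grid_search_svm(x, y, gammas=[0.05, 50.0], cs=[1.0], folds=5, seed=0)
        assert gamma == 0.05
        assert results[(0.05, 1.0)] > results[(50.0, 1.0)]

    def test_tie_broken_toward_simpler_model(self):
        x, y = _blobs(30)  # trivially separable: all grid points score 1.0
        gamma, c, _ = grid_search_svm(x, y, gammas=[0.5, 0.05], cs=[10.0, 1.0], folds=3)
        assert (gamma, c) == (0.05, 1.0)

    def test_fold_assignment_seeded(self):
        x, y = _blobs(20, spread=1.0)
        a = grid_search_svm(x, y, [0.1], [1.0], folds=4, seed=3)[2]
        b = grid_search_svm(x, y, [0.1], [1.0], folds=4, seed=3)[2]
        assert a == b

    def test_fewer_samples_than_folds_rejected(self):
        with pytest.raises(ParameterError):
            grid_search_svm(np.zeros((3, 2)), np.array([1, 2, 3]), [0.1], [1.0], folds=5)


class TestClassifyVoxels:
    def test_noiseless_phantom_recall_perfect(self, small_phantom):
        ph = small_phantom
        tcs = extract_time_courses(ph.series, ph.labels.data > 0, ph.labels, subject="s")
        pca = fit_pca(tcs, k=10)
        feats = transform_pca(pca, tcs)
        bx, by = balance_classes(feats, tcs.labels, seed=0)
        clf = train_classifier(bx, by, training_subjects=["s"])
        pred = classify_voxels(clf, pca, ph.series, ph.labels.data > 0)
        rep = metrics.classification_report(
            ph.labels.data[ph.labels.data > 0], pred.data[ph.labels.data > 0]
        )
        assert rep.balanced_accuracy == 1.0

    def test_output_support_equals_mask(self, small_phantom):
        ph = small_phantom
        tcs = extract_time_courses(ph.series, ph.labels.data > 0, ph.labels, subject="s")
        pca = fit_pca(tcs, k=5)
        feats = transform_pca(pca, tcs)
        clf = train_classifier(feats, tcs.labels, training_subjects=["s"])
        pred = classify_voxels(clf, pca, ph.series, ph.left_mask)
        assert np.array_equal(pred.data > 0, ph.left_mask.data)

    def test_empty_mask_gives_all_zero_map(self, small_phantom):
        ph = small_phantom
        tcs = extract_time_courses(ph.series, ph.labels.data > 0, ph.labels, subject="s")
        pca = fit_pca(tcs, k=5)
        clf = train_classifier(transform_pca(pca, tcs), tcs.labels, training_subjects=["s"])
        pred = classify_voxels(clf, pca, ph.series, np.zeros(ph.series.shape[:3], bool))
        assert not pred.data.any()

    def test_provenance_mismatch_rejected(self, small_phantom):
        ph = small_phantom
        tcs = extract_time_courses(ph.series, ph.labels.data > 0, ph.labels, subject="s")
        pca = fit_pca(tcs, k=5)
        clf = train_classifier(transform_pca(pca, tcs), tcs.labels,
                               training_subjects=["another_cohort"])
        with pytest.raises(ProvenanceError):
            classify_voxels(clf, pca, ph.series, ph.left_mask)


class TestDWT:
    def _tcs(self, values):
        n = len(values)
        return TimeCourseSet(values, np.zeros((n, 3), int), n_baseline=2)

    def test_zero_signal_zero_coefficients(self):
        feats = dwt_features(self._tcs(np.zeros((5, 74))))
        assert np.allclose(feats, 0.0)

    def test_parseval_energy_preservation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 74))
        feats = dwt_features(self._tcs(x))
        assert np.allclose((feats**2).sum(axis=1), (x**2).sum(axis=1), rtol=1e-6)

    def test_matches_circular_filter_bank_oracle(self):
        """Single-level decomposition vs a direct periodized filter bank
        (y[k] = sum_m f[m] x[(2k+1-m+3) mod n] for the db4 filters)."""
        import pywt

        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 16))
        feats = dwt_features(self._tcs(x), level=1)
        w = pywt.Wavelet("db4")
        lo, hi = np.array(w.dec_lo), np.array(w.dec_hi)
        n = x.shape[1]
        for row, frow in zip(x, feats):
            a = [sum(lo[m] * row[(2 * k + 4 - m) % n] for m in range(8)) for k in range(n // 2)]
            d = [sum(hi[m] * row[(2 * k + 4 - m) % n] for m in range(8)) for k in range(n // 2)]
            assert np.allclose(frow, np.concatenate([a, d]), atol=1e-10)

    def test_unknown_wavelet_rejected(self):
        from renodce.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            dwt_features(self._tcs(np.zeros((2, 74))), wavelet="nosuchwavelet")

    def test_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            dwt_features(self._tcs(np.zeros((2, 4))))


class TestKMeans:
    def test_perfect_partition_of_separated_blobs(self):
        x, y = _blobs(50)
        res = kmeans_partition(x, k=3, seed=0, true_labels=y)
        assert metrics.classification_report(y, res.mapped_labels).balanced_accuracy == 1.0

    def test_seeded_determinism(self):
        x, _ = _blobs(40, spread=1.5)
        a = kmeans_partition(x, seed=5)
        b = kmeans_partition(x, seed=5)
        assert np.array_equal(a.cluster_labels, b.cluster_labels)

    def test_sse_beats_random_assignment(self):
        rng = np.random.default_rng(0)
        x, _ = _blobs(40, spread=1.0)
        res = kmeans_partition(x, k=3, seed=0)
        rand = rng.integers(0, 3, len(x))
        sse_rand = sum(
            ((x[rand == c] - x[rand == c].mean(axis=0)) ** 2).sum() for c in range(3)
        )
        assert res.inertia <= sse_rand

    def test_more_clusters_than_samples_rejected(self):
        with pytest.raises(ParameterError):
            kmeans_partition(np.zeros((2, 2)), k=3)


class TestLeaveOneSubjectOutDiscipline:
    def test_pca_records_training_subjects_only(self, classification_artifacts):
        assert "held_out" not in classification_artifacts["pca"].training_subjects

    def test_baseline_normalize_removes_gain(self):
        rng = np.random.default_rng(0)
        curve = rng.random((1, 30)) + 1.0
        scaled = 3.7 * curve
        a = baseline_normalize(curve, 8)
        b = baseline_normalize(scaled, 8)
        assert np.allclose(a, b)
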
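"""DTW, TSF, splitting and the benchmark harness."""

import itertools
from functools import lru_cache

import numpy as np
import pytest

from phnrlab.tsc import (CLASSIFIER_KINDS, ClassifierConfig, LSTMClassifier,
                         dtw_distance, fit_standard_classifier,
                         grouped_stratified_split, interval_features,
                         knn_dtw_predict, run_benchmark, tsf_fit, tsf_predict)
from phnrlab.tsc.forest import tsf_predict_batch
import phnrlab.tsc.bench as bench_mod


@lru_cache(maxsize=None)
def all_paths(n, m):
    """Every monotone warping path from (0,0) to (n-1,m-1)."""
    if n == 1 and m == 1:
        return (((0, 0),),)
    out = []
    for pn, pm in ((n - 1, m), (n, m - 1), (n - 1, m - 1)):
        if pn >= 1 and pm >= 1:
            out.extend(p + ((n - 1, m - 1),) for p in all_paths(pn, pm))
    return tuple(out)


def brute_force_dtw(x, y):
    return min(sum(abs(x[i] - y[j]) for i, j in path)
               for path in all_paths(len(x), len(y)))


class TestDtw:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=25)
        assert dtw_distance(x, x) == 0.0
        assert dtw_distance(x, y) == pytest.approx(dtw_distance(y, x))
        assert dtw_distance(x, y) >= 0

    def test_diagonal_example(self):
        # all monotone paths for [0,0] vs [1,1] other than the diagonal cost >= 3
        assert dtw_distance([0, 0], [1, 1]) == pytest.approx(2.0)

    def test_band_zero_forces_diagonal(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert dtw_distance(x, y, band=0) == pytest.approx(np.abs(x - y).sum())

    def test_band_smaller_than_length_difference_errors(self):
        with pytest.raises(ValueError):
            dtw_distance([1, 2, 3, 4, 5], [1, 2], band=1)

    def test_matches_exhaustive_enumeration_short_series(self):
        symbols = (0.0, 1.0, 2.0)
        series = [s for L in (1, 2, 3) for s in itertools.product(symbols, repeat=L)]
        for x in series:
            for y in series:
                assert dtw_distance(x, y) == pytest.approx(brute_force_dtw(x, y))


class TestKnnDtw:
    TRAIN = [np.array([0.0, 0, 0]), np.array([5.0, 5, 5]), np.array([9.0, 9, 9])]
    LABELS = ["lo", "hi", "hi"]

    def test_exact_match_returns_its_label(self):
        assert knn_dtw_predict(self.TRAIN, self.LABELS, self.TRAIN[1]) == "hi"

    def test_equidistant_tie_prefers_earlier_index(self):
        train = [np.zeros(3), np.full(3, 4.0)]
        query = np.full(3, 2.0)
        assert knn_dtw_predict(train, ["a", "b"], query) == "a"

    def test_k_exceeding_training_size_errors(self):
        with pytest.raises(ValueError):
            knn_dtw_predict(self.TRAIN, self.LABELS, self.TRAIN[0], k=4)


class TestTsf:
    @staticmethod
    def _blobs(n=30, T=60, gap=4.0, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat([-1, 1], n // 2)
        X = rng.normal(size=(n, T)) + np.where(y > 0, gap, 0.0)[:, None]
        return X, y

    def test_interval_features_match_direct_recomputation(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 40))
        intervals = [(0, 5), (10, 25), (37, 40)]
        feats = interval_features(X, intervals)
        for k, (a, b) in enumerate(intervals):
            seg = X[:, a:b]
            t = np.arange(b - a)
            slopes = [np.polyfit(t, row, 1)[0] if b - a > 1 else 0.0 for row in seg]
            assert np.allclose(feats[:, 3 * k], seg.mean(axis=1))
            assert np.allclose(feats[:, 3 * k + 1], seg.std(axis=1))
            assert np.allclose(feats[:, 3 * k + 2], slopes, atol=1e-10)

    def test_exact_ramp_slope(self):
        ramp = 0.7 * np.arange(30.0) + 2.0
        feats = interval_features(ramp[None, :], [(0, 30)])
        assert feats[0, 2] == pytest.approx(0.7)

    def test_separable_means_fit_perfectly_with_one_interval(self):
        X, y = self._blobs()
        model = tsf_fit(X, y, n_estimators=5, seed=0, n_intervals=1)
        assert [tsf_predict(model, x)[0] for x in X] == list(y)

    def test_same_seed_identical_predictions_any_row_order(self):
        X, y = self._blobs(seed=3)
        m1 = tsf_fit(X, y, n_estimators=10, seed=5)
        perm = np.random.default_rng(0).permutation(len(y))
        m2 = tsf_fit(X[perm], y[perm], n_estimators=10, seed=5)
        assert m1.intervals == m2.intervals
        q = np.random.default_rng(1).normal(size=X.shape[1])
        assert tsf_predict(m1, q)[0] == tsf_predict(m2, q)[0]

    def test_unanimous_vote_probability_one(self):
        X, y = self._blobs(gap=10.0)
        model = tsf_fit(X, y, n_estimators=8, seed=1)
        label, prob = tsf_predict(model, X[-1])
        assert label == 1 and prob == 1.0

    def test_tie_goes_to_negative_class(self):
        # two trees trained on opposite labelings always split the vote
        from phnrlab.tsc.forest import TSFModel
        X, y = self._blobs()
        m_pos = tsf_fit(X, y, n_estimators=1, seed=2)
        m_neg = tsf_fit(X, -y, n_estimators=1, seed=2)
        tied = TSFModel(trees=m_pos.trees + m_neg.trees,
                        intervals=m_pos.intervals + m_neg.intervals,
                        classes=m_pos.classes, series_length=m_pos.series_length,
                        n_estimators=2, seed=2)
        label, prob = tsf_predict(tied, X[0])
        assert prob == 0.5 and label == -1

    def test_length_mismatch_errors(self):
        X, y = self._blobs()
        model = tsf_fit(X, y, n_estimators=2, seed=0)
        with pytest.raises(ValueError):
            tsf_predict(model, np.zeros(10))

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError):
            tsf_fit(np.zeros((4, 2)), [-1, -1, 1, 1])


class TestSplit:
    def test_whole_subject_grouping(self, small_cohort):
        records, _ = small_cohort
        # small cohort: per-set label granularity is coarse, so a loose tolerance
        split = grouped_stratified_split(records, seed=0, tolerance=0.15)
        for rec in records:
            assert rec.subject_id in split.subject_to_set
        # every waveform of a subject shares the subject's set by construction
        assert set(split.subject_to_set.values()) <= {"train", "validation", "test"}

    def test_label_proportions_within_tolerance(self):
        from phnrlab.simulate import CohortSpec, simulate_cohort
        records, _ = simulate_cohort(CohortSpec(n_subjects=115, seed=6,
                                                recordings_per_eye=1))
        split = grouped_stratified_split(records, fractions=(0.44, 0.27, 0.29),
                                         seed=1, tolerance=0.05)
        overall = np.mean([r.label == "ON_POS" for r in records])
        for which in ("train", "validation", "test"):
            recs = [r for r in records if split.subject_to_set[r.subject_id] == which]
            prop = np.mean([r.label == "ON_POS" for r in recs])
            assert abs(prop - overall) <= 0.05

    def test_determinism_and_seed_sensitivity(self, small_cohort):
        records, _ = small_cohort
        s1 = grouped_stratified_split(records, seed=3, tolerance=0.15)
        s2 = grouped_stratified_split(records, seed=3, tolerance=0.15)
        s3 = grouped_stratified_split(records, seed=4, tolerance=0.15)
        assert s1.subject_to_set == s2.subject_to_set
        assert s1.subject_to_set != s3.subject_to_set

    def test_infeasible_tolerance_errors(self, small_cohort):
        records, _ = small_cohort
        with pytest.raises(ValueError, match="tolerance"):
            grouped_stratified_split(records, seed=0, tolerance=1e-6, max_tries=5)


class TestConfigsAndClassifiers:
    def test_reported_hyperparameter_defaults(self):
        assert ClassifierConfig(kind="svm_rbf").resolved().C == 1.5
        assert ClassifierConfig(kind="rf").resolved().n_estimators == 200
        assert ClassifierConfig(kind="gb").resolved().n_estimators == 100
        assert ClassifierConfig(kind="tsf").resolved().n_estimators == 100
        lstm = ClassifierConfig(kind="lstm").lstm
        assert (lstm["n_layers"], lstm["batch_size"], lstm["dropout"],
                lstm["hidden_dims"], lstm["learning_rate"],
                lstm["n_epochs"]) == (3, 6, 0.6, 16, 1e-3, 100)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ClassifierConfig(kind="mlp")
        with pytest.raises(ValueError):
            fit_standard_classifier("mlp", np.zeros((4, 5)),
                                    [-1, -1, 1, 1], ClassifierConfig(kind="rf"))

    def test_all_kinds_train_on_small_cohort(self, small_cohort):
        records, _ = small_cohort
        X = np.array([r.samples for r in records[:40]])
        y = np.array([1 if r.label == "ON_POS" else -1 for r in records[:40]])
        if len(set(y)) < 2:
            y[: len(y) // 2] = -y[: len(y) // 2]
        for kind in ("svm_linear", "svm_rbf", "rf", "gb"):
            cfg = ClassifierConfig(kind=kind, n_estimators=10, seed=0)
            model = fit_standard_classifier(kind, X, y, cfg)
            assert set(np.unique(model.predict(X))) <= {-1, 1}
        lstm_cfg = ClassifierConfig(kind="lstm", lstm={
            "n_layers": 2, "batch_size": 6, "dropout": 0.5, "hidden_dims": 8,
            "learning_rate": 1e-3, "n_epochs": 2})
        model = fit_standard_classifier("lstm", X, y, lstm_cfg)
        assert set(np.unique(model.predict(X))) <= {-1, 1}

    def test_lstm_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 30))
        y = np.repeat([-1, 1], 6)
        p1 = LSTMClassifier(n_layers=2, hidden_dims=4, n_epochs=3,
                            seed=7).fit(X, y).predict_proba(X)
        p2 = LSTMClassifier(n_layers=2, hidden_dims=4, n_epochs=3,
                            seed=7).fit(X, y).predict_proba(X)
        assert np.array_equal(p1, p2)


FAST_LSTM = {"n_layers": 2, "batch_size": 6, "dropout": 0.5, "hidden_dims": 8,
             "learning_rate": 1e-3, "n_epochs": 3}


class TestBenchmark:
    def test_ensembles_beat_chance_on_planted_effect(self, separated_cohort):
        records, _ = separated_cohort
        configs = [ClassifierConfig(kind=k, n_estimators=30, seed=0)
                   for k in ("rf", "gb", "tsf")]
        report = run_benchmark(records, configs, split_seed=2)
        for kind, cm in report.metrics.items():
            assert cm.accuracy > 0.5, kind

    def test_test_subjects_disjoint_from_tuning(self, separated_cohort):
        records, _ = separated_cohort
        report = run_benchmark(records,
                               [ClassifierConfig(kind="rf", n_estimators=10)],
                               split_seed=0)
        test_subj = set(report.split.subjects("test"))
        assert test_subj.isdisjoint(report.split.subjects("train"))
        assert test_subj.isdisjoint(report.split.subjects("validation"))

    def test_validation_selects_better_config(self, separated_cohort):
        records, _ = separated_cohort
        configs = [ClassifierConfig(kind="rf", n_estimators=1, seed=0),
                   ClassifierConfig(kind="rf", n_estimators=40, seed=0)]
        report = run_benchmark(records, configs, split_seed=1)
        assert report.best_configs["rf"].n_estimators in (1, 40)
        assert report.metrics["rf"].accuracy > 0.8

    def test_test_labels_read_only_after_training(self, separated_cohort, monkeypatch):
        """Access audit: no test-subject label is read between the split and
        the end of the last training/tuning step."""
        records, _ = separated_cohort
        events = []
        real_label_of = bench_mod._label_of
        real_init = bench_mod._Predictor.__init__

        def spy_label(rec):
            events.append(("label", rec.subject_id))
            return real_label_of(rec)

        def spy_init(self, kind, cfg, X_train, y_train):
            events.append(("fit", kind))
            real_init(self, kind, cfg, X_train, y_train)

        monkeypatch.setattr(bench_mod, "_label_of", spy_label)
        monkeypatch.setattr(bench_mod._Predictor, "__init__", spy_init)
        report = run_benchmark(records,
                               [ClassifierConfig(kind="rf", n_estimators=5)],
                               split_seed=3)
        test_subjects = set(report.split.subjects("test"))
        last_fit = max(i for i, e in enumerate(events) if e[0] == "fit")
        split_phase_end = min(i for i, e in enumerate(events) if e[0] == "fit")
        for i, (kind, sid) in enumerate(events):
            if kind == "label" and sid in test_subjects:
                # allowed: during the split (before any fit) or after tuning
                assert i < split_phase_end or i > last_fit

    def test_empty_test_set_errors(self, separated_cohort):
        records, _ = separated_cohort
        with pytest.raises(ValueError):
            run_benchmark(records, [ClassifierConfig(kind="rf")],
                          split_seed=0, fractions=(0.9, 0.1, 0.0))
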
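import numpy as np
import pytest

from circlink.errors import ConfigurationError, SamplingError
from circlink.evaluation import (
    ConfusionCounts,
    _fold_slices,
    auc_score,
    compute_metrics,
    confusion_from_scores,
    rank_candidates,
    sample_negatives,
)
from circlink.features import PairFeature
from circlink.model import CnnConfig, build_cnn
from oracles import brute_force_metrics, pair_counting_auc


class TestSampleNegatives:
    def test_requested_count_disjoint_from_positives(self, study):
        A = study.network.A
        n_pos = int(A.sum())
        neg = sample_negatives(A, n_pos, seed=0)
        assert len(neg) == len(set(neg)) == n_pos
        assert all(A[i, j] == 0 for i, j in neg)

    def test_reproducible_given_seed(self, study):
        A = study.network.A
        assert sample_negatives(A, 50, seed=3) == sample_negatives(A, 50, seed=3)
        assert sample_negatives(A, 50, seed=3) != sample_negatives(A, 50, seed=4)

    def test_exhaustive_sample_is_all_zero_cells(self):
        A = np.array([[1, 0], [0, 0]])
        neg = sample_negatives(A, 3, seed=1)
        assert sorted(neg) == [(0, 1), (1, 0), (1, 1)]

    def test_oversampling_is_an_error(self):
        with pytest.raises(SamplingError):
            sample_negatives(np.array([[1, 0]]), 2, seed=0)


class TestMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(TP=5, TN=7, FP=0, FN=0))
        assert (m.Pre, m.Sen, m.Acc, m.F1, m.MCC) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_confusion_table(self):
        m = compute_metrics(ConfusionCounts(TP=3, FP=1, TN=4, FN=2))
        assert m.Pre == pytest.approx(0.75)
        assert m.Sen == pytest.approx(0.6)
        assert m.Acc == pytest.approx(0.7)
        assert m.F1 == pytest.approx(2 * 0.6 * 0.75 / 1.35)
        assert m.MCC == pytest.approx(10.0 / np.sqrt(600.0), abs=1e-12)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 40, size=4)
            if tp + tn + fp + fn == 0:
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            expected = brute_force_metrics(int(tp), int(tn), int(fp), int(fn))
            for name, want in expected.items():
                got = getattr(m, name)
                if np.isnan(want):
                    assert np.isnan(got), name
                else:
                    assert got == pytest.approx(want, abs=1e-12), name

    def test_random_scores_give_half_auc(self, rng):
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        assert auc_score(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_auc_matches_pair_counting_with_ties(self, rng):
        scores = rng.integers(0, 5, 60).astype(float)  # many ties
        labels = rng.integers(0, 2, 60)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        assert auc_score(scores, labels) == pytest.approx(
            pair_counting_auc(scores, labels), abs=1e-12
        )

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        a = auc_score(scores, labels)
        b = auc_score(np.exp(5 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_undefined_metric_reported_as_nan_with_warning(self):
        with pytest.warns(UserWarning, match="precision"):
            m = compute_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=2))
        assert np.isnan(m.Pre)

    def test_threshold_confusion(self):
        counts = confusion_from_scores(
            np.array([0.9, 0.4, 0.6, 0.1]), np.array([1, 1, 0, 0])
        )
        assert (counts.TP, counts.FN, counts.FP, counts.TN) == (1, 1, 1, 1)


class TestCrossValidation:
    def test_report_has_folds_times_repetitions_rows(self, cv_report):
        from conftest import CV_FOLDS, CV_REPS

        assert len(cv_report.rows) == CV_FOLDS * CV_REPS

    def test_planted_structure_is_recovered(self, cv_report):
        assert cv_report.mean_auc() >= 0.8

    def test_shuffled_labels_are_null(self, shuffled_report):
        assert 0.4 <= shuffled_report.mean_auc() <= 0.6

    def test_negative_manifests_are_fresh_per_repetition(self, cv_report):
        manifests = cv_report.negative_manifests
        assert len(manifests) == cv_report.repetitions
        assert manifests[0] != manifests[1]

    def test_summary_recomputable_from_rows(self, cv_report):
        s = cv_report.summary()
        assert s.loc["mean", "AUC"] == pytest.approx(cv_report.rows["AUC"].mean())
        assert s.loc["std", "MCC"] == pytest.approx(cv_report.rows["MCC"].std())

    def test_fold_slices_partition(self, rng):
        for n, folds in ((103, 5), (10, 5), (7, 3)):
            parts = _fold_slices(n, folds, rng)
            assert len(parts) == folds
            allidx = np.concatenate(parts)
            assert sorted(allidx) == list(range(n))

    def test_too_few_positives_rejected(self, toy_network, rng):
        from circlink.evaluation import cross_validate

        Sc = np.eye(5)
        Sd = np.eye(3)
        with pytest.raises(ConfigurationError):
            cross_validate(toy_network, Sc, Sd, folds=10, repetitions=1)


class TestRankCandidates:
    @pytest.fixture()
    def model_and_candidates(self, rng):
        cfg = CnnConfig(n_filters=3, kernel1=(2, 5), kernel2=(1, 3))
        model = build_cnn(cfg, 20)
        candidates = [
            PairFeature(X=rng.random((2, 20)), circ_id=f"c{k}", disease_id="d1",
                        label="unknown")
            for k in range(6)
        ]
        return model, candidates

    def test_single_model_ranking_follows_scores(self, model_and_candidates):
        from circlink.features import stack_features
        from circlink.model import score

        model, candidates = model_and_candidates
        table = rank_candidates([model], candidates)
        X, _ = stack_features(candidates)
        direct = score(model, X)
        assert table.iloc[0]["score"] == pytest.approx(direct.max())
        assert (table["score"].diff().dropna() <= 1e-15).all()

    def test_identical_models_mean_equals_single(self, model_and_candidates):
        model, candidates = model_and_candidates
        one = rank_candidates([model], candidates)
        ten = rank_candidates([model] * 10, candidates)
        np.testing.assert_allclose(one["score"], ten["score"])

    def test_dominant_pair_ranks_first(self, model_and_candidates, rng):
        model, candidates = model_and_candidates
        boosted = [
            PairFeature(X=pf.X.copy(), circ_id=pf.circ_id, disease_id=pf.disease_id,
                        label="unknown")
            for pf in candidates
        ]
        # brute-force oracle: the pair with the highest score in every model wins
        from circlink.features import stack_features
        from circlink.model import score as score_fn

        X, _ = stack_features(boosted)
        scores = score_fn(model, X)
        best = int(np.argmax(scores))
        table = rank_candidates([model], boosted)
        assert table.iloc[0]["circRNA"] == boosted[best].circ_id

    def test_labeled_candidate_is_rejected(self, model_and_candidates, rng):
        model, candidates = model_and_candidates
        candidates[0] = PairFeature(
            X=rng.random((2, 20)), circ_id="c0", disease_id="d1", label=1
        )
        with pytest.raises(ConfigurationError, match="labeled"):
            rank_candidates([model], candidates)

    def test_needs_at_least_one_model(self, model_and_candidates):
        _, candidates = model_and_candidates
        with pytest.raises(ConfigurationError):
            rank_candidates([], candidates)
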
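"""Training protocol: splits, best-of-n selection, metrics, qualification."""

import numpy as np
import pytest

from m6aforest.features import NEGATIVE, POSITIVE
from m6aforest.model import (
    ConfigurationError,
    ModelMetrics,
    evaluate,
    load_model,
    make_split,
    save_model,
    select_qualifying_motifs,
    train_best_of_n,
)

from conftest import make_window


def labeled_windows(n_pos, n_neg, flank=10, pos_level=0.8, neg_level=0.5, sd=0.0, seed=0):
    """Windows whose value level separates the classes by construction."""
    rng = np.random.default_rng(seed)
    windows = []
    for i in range(n_pos):
        vals = np.clip(pos_level + rng.normal(0, sd, 2 * flank + 1), 0, 1)
        windows.append(
            make_window(a_pos=20 + 30 * i, values=tuple(vals), label=POSITIVE)
        )
    for i in range(n_neg):
        vals = np.clip(neg_level + rng.normal(0, sd, 2 * flank + 1), 0, 1)
        windows.append(
            make_window(ref="tx2", a_pos=20 + 30 * i, values=tuple(vals), label=NEGATIVE)
        )
    return windows


class TestMakeSplit:
    def test_canonical_counts_10_pos_100_neg(self):
        split = make_split(labeled_windows(10, 100), train_frac=0.7, seed=1)
        assert len(split.train_pos) == 7
        assert len(split.train_neg) == 7
        assert len(split.test_pos) == 3
        assert len(split.test_neg) == 93

    def test_partition_properties(self):
        windows = labeled_windows(10, 100)
        split = make_split(windows, seed=2)
        pos = {w.site.key for w in windows if w.label == POSITIVE}
        assert {w.site.key for w in split.train_pos} | {
            w.site.key for w in split.test_pos
        } == pos
        assert not {w.site.key for w in split.train_pos} & {
            w.site.key for w in split.test_pos
        }
        assert not {w.site.key for w in split.train_neg} & {
            w.site.key for w in split.test_neg
        }

    def test_same_seed_identical_membership(self):
        windows = labeled_windows(10, 100)
        a, b = make_split(windows, seed=5), make_split(windows, seed=5)
        assert a.train_pos == b.train_pos and a.train_neg == b.train_neg

    def test_degenerate_train_frac_rejected(self):
        with pytest.raises(ConfigurationError):
            make_split(labeled_windows(10, 100), train_frac=1.0)

    def test_too_few_negatives_rejected(self):
        with pytest.raises(ConfigurationError, match="negatives"):
            make_split(labeled_windows(10, 3))


class TestTrainBestOfN:
    def test_single_run_is_identity(self):
        windows = labeled_windows(10, 100, sd=0.05)
        model, _ = train_best_of_n(windows, "GGACT", n_runs=1, seed=3)
        assert model.run_accuracies == (model.training_accuracy,)

    def test_best_run_has_max_training_accuracy(self):
        windows = labeled_windows(12, 120, pos_level=0.6, neg_level=0.5, sd=0.15, seed=8)
        model, _ = train_best_of_n(windows, "GGACT", n_runs=10, seed=3)
        assert len(model.run_accuracies) == 10
        assert model.training_accuracy == max(model.run_accuracies)

    def test_linearly_separable_reaches_perfect_training_accuracy(self):
        windows = labeled_windows(10, 100, pos_level=0.9, neg_level=0.2)
        model, _ = train_best_of_n(windows, "GGACT", n_runs=2, seed=0)
        assert model.training_accuracy == 1.0

    def test_seed_reproducible_end_to_end(self):
        windows = labeled_windows(10, 100, sd=0.1, seed=1)
        m1, s1 = train_best_of_n(windows, "GGACT", n_runs=3, seed=9)
        m2, s2 = train_best_of_n(windows, "GGACT", n_runs=3, seed=9)
        assert m1.run_accuracies == m2.run_accuracies
        assert s1.train_neg == s2.train_neg
        x, _ = s1.test_set()
        assert np.array_equal(m1.predict_proba(x), m2.predict_proba(x))

    def test_too_few_positives_rejected(self):
        with pytest.raises(ConfigurationError):
            train_best_of_n(labeled_windows(1, 50), "GGACT")


class TestEvaluate:
    def test_clip_detection_rate_counts_called_positives(self):
        windows = labeled_windows(20, 60, pos_level=0.9, neg_level=0.2)
        model, split = train_best_of_n(windows, "GGACT", n_runs=1, seed=0)
        metrics = evaluate(model, split)
        assert metrics.clip_detection_rate == 1.0
        assert metrics.n_test_pos == 6
        assert metrics.n_train_pos == 14

    def test_separable_data_gives_auc_one(self):
        windows = labeled_windows(20, 80, pos_level=0.9, neg_level=0.2, sd=0.02)
        model, split = train_best_of_n(windows, "GGACT", n_runs=1, seed=0)
        assert evaluate(model, split).roc_auc == 1.0

    def test_constant_scores_give_auc_half(self):
        # identical feature vectors in both classes: the forest outputs one score
        windows = labeled_windows(20, 80, pos_level=0.5, neg_level=0.5)
        model, split = train_best_of_n(windows, "GGACT", n_runs=1, seed=0)
        assert evaluate(model, split).roc_auc == pytest.approx(0.5)

    def test_detection_rate_monotone_nonincreasing_in_threshold(self):
        windows = labeled_windows(20, 80, pos_level=0.6, neg_level=0.5, sd=0.15)
        model, split = train_best_of_n(windows, "GGACT", n_runs=2, seed=1)
        rates = [
            evaluate(model, split, threshold=t).clip_detection_rate
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_empty_test_positives_rejected(self):
        windows = labeled_windows(10, 100)
        model, split = train_best_of_n(windows, "GGACT", n_runs=1, seed=0)
        split.test_pos = []
        with pytest.raises(ConfigurationError, match="test positive"):
            evaluate(model, split)


class TestQualification:
    @pytest.mark.parametrize(
        "cdr,prec,auc,kept",
        [
            (0.79, 0.90, 0.70, True),   # all thresholds exceeded
            (0.65, 0.95, 0.80, False),  # detection rate fails
            (0.70, 0.90, 0.70, False),  # boundary: thresholds are strict
            (0.80, 0.85, 0.70, False),  # precision exactly at threshold
            (0.80, 0.90, 0.67, False),  # auc exactly at threshold
            (0.71, 0.86, 0.68, True),
            (float("nan"), 0.9, 0.9, False),
        ],
    )
    def test_strict_threshold_contract(self, cdr, prec, auc, kept):
        metrics = {"GGACT": ModelMetrics(cdr, prec, auc, 10, 5, 50)}
        assert (select_qualifying_motifs(metrics) == {"GGACT"}) is kept


class TestPersistence:
    def test_save_load_identical_predictions(self, tmp_path):
        windows = labeled_windows(10, 60, sd=0.1, seed=2)
        model, split = train_best_of_n(windows, "GGACT", n_runs=2, seed=4)
        model.metrics = evaluate(model, split)
        path = tmp_path / "GGACT.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.motif == "GGACT" and loaded.flank == model.flank
        assert loaded.hyperparameters == model.hyperparameters
        assert loaded.metrics == model.metrics
        x, _ = split.test_set()
        assert np.array_equal(loaded.predict_proba(x), model.predict_proba(x))

    def test_persisted_models_byte_identical_across_saves(self, tmp_path):
        windows = labeled_windows(10, 60, sd=0.1, seed=2)
        model, _ = train_best_of_n(windows, "GGACT", n_runs=2, seed=4)
        p1, p2 = tmp_path / "a.joblib", tmp_path / "b.joblib"
        save_model(model, p1)
        save_model(model, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_flank_mismatch_detected_at_prediction(self, tmp_path):
        windows = labeled_windows(10, 60, flank=5)
        model, _ = train_best_of_n(windows, "GGACT", n_runs=1, seed=0)
        with pytest.raises(ValueError, match="flank"):
            model.predict_proba(np.zeros((1, 21)))

    def test_unsupported_format_version_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "bad.joblib"
        joblib.dump({"format_version": 999}, path)
        with pytest.raises(ValueError, match="format version"):
            load_model(path)
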
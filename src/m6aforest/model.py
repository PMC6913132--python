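"""Per-motif random-forest training, evaluation, selection and persistence.

One classifier is trained per resolved DRACH 5-mer, because the nanopore
pore responds differently to each sequence context.  The protocol:

* 70% of the truth-labeled (known) sites form the training positives; an
  equal number of unlabeled sites is sampled as training negatives so the
  training set is balanced.
* The remaining known sites plus all remaining unlabeled sites form the
  test set.
* Ten forests are fit, each on a fresh resample of the balanced negatives
  (the positive split is fixed so run accuracies are comparable), and the
  forest with the highest training accuracy is kept.

Because unlabeled sites include genuinely methylated but unannotated
positions, test metrics understate real performance; the headline metric is
the *CLIP detection rate*: the fraction of held-out known sites the model
calls methylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from m6aforest.features import NEGATIVE, POSITIVE, FeatureWindow, windows_to_matrix

FORMAT_VERSION = 1

#: Motif-qualification thresholds (all strict inequalities).
DEFAULT_ACC_MIN = 0.7
DEFAULT_PREC_MIN = 0.85
DEFAULT_AUC_MIN = 0.67


class ConfigurationError(ValueError):
    """A split or training request that cannot be satisfied."""


@dataclass
class TrainTestSplit:
    train_pos: list[FeatureWindow]
    train_neg: list[FeatureWindow]
    test_pos: list[FeatureWindow]
    test_neg: list[FeatureWindow]
    seed: int

    def training_set(self) -> tuple[np.ndarray, np.ndarray]:
        x = windows_to_matrix(self.train_pos + self.train_neg)
        y = np.r_[np.ones(len(self.train_pos)), np.zeros(len(self.train_neg))]
        return x, y

    def test_set(self) -> tuple[np.ndarray, np.ndarray]:
        x = windows_to_matrix(self.test_pos + self.test_neg)
        y = np.r_[np.ones(len(self.test_pos)), np.zeros(len(self.test_neg))]
        return x, y


@dataclass
class ModelMetrics:
    """Test-set metrics for one per-motif model.

    ``clip_detection_rate`` is the fraction of held-out known-methylated
    sites called positive; ``precision`` and ``roc_auc`` are computed over
    the pooled test positives and negatives.
    """

    clip_detection_rate: float
    precision: float
    roc_auc: float
    n_train_pos: int
    n_test_pos: int
    n_test_neg: int


@dataclass
class MotifModel:
    motif: str
    classifier: RandomForestClassifier
    hyperparameters: dict
    training_accuracy: float
    flank: int
    run_accuracies: tuple[float, ...] = ()
    metrics: ModelMetrics | None = None

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probability of the methylated class for each window row."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != 2 * self.flank + 1:
            raise ValueError(
                f"model for {self.motif} was trained with flank={self.flank} "
                f"({2 * self.flank + 1} values); got {x.shape[1]} values"
            )
        classes = list(self.classifier.classes_)
        return self.classifier.predict_proba(x)[:, classes.index(1.0)]


def _partition_positives(
    positives: Sequence[FeatureWindow], train_frac: float, rng: np.random.Generator
) -> tuple[list[FeatureWindow], list[FeatureWindow]]:
    n_train = int(round(train_frac * len(positives)))
    if n_train < 1 or n_train >= len(positives):
        raise ConfigurationError(
            f"train_frac={train_frac} with {len(positives)} positives leaves an "
            "empty training or test positive set"
        )
    order = rng.permutation(len(positives))
    train_idx = set(order[:n_train].tolist())
    train = [positives[i] for i in sorted(train_idx)]
    test = [positives[i] for i in range(len(positives)) if i not in train_idx]
    return train, test


def _sample_negatives(
    negatives: Sequence[FeatureWindow], n: int, rng: np.random.Generator
) -> tuple[list[FeatureWindow], list[FeatureWindow]]:
    if n > len(negatives):
        raise ConfigurationError(
            f"cannot balance training set: need {n} negatives, have {len(negatives)}"
        )
    chosen = set(rng.choice(len(negatives), size=n, replace=False).tolist())
    train = [negatives[i] for i in sorted(chosen)]
    rest = [negatives[i] for i in range(len(negatives)) if i not in chosen]
    return train, rest


def _split_by_label(
    windows: Sequence[FeatureWindow],
) -> tuple[list[FeatureWindow], list[FeatureWindow]]:
    positives = [w for w in windows if w.label == POSITIVE]
    negatives = [w for w in windows if w.label in (NEGATIVE, "unknown")]
    return positives, negatives


def make_split(
    windows: Sequence[FeatureWindow],
    train_frac: float = 0.7,
    seed: int = 0,
) -> TrainTestSplit:
    """Partition labeled windows into a balanced train / full test split.

    Positives are split round(train_frac * n) / rest; training negatives are
    sampled without replacement to match the training positives; every
    remaining negative goes to the test set.  Fully reproducible from seed.
    """
    positives, negatives = _split_by_label(windows)
    if len(positives) < 2:
        raise ConfigurationError(
            f"need >= 2 positive windows to split, have {len(positives)}"
        )
    rng = np.random.default_rng(seed)
    train_pos, test_pos = _partition_positives(positives, train_frac, rng)
    train_neg, test_neg = _sample_negatives(negatives, len(train_pos), rng)
    return TrainTestSplit(train_pos, train_neg, test_pos, test_neg, seed)


def _fit_forest(
    split: TrainTestSplit, n_trees: int, max_depth: int | None, seed: int
) -> tuple[RandomForestClassifier, float]:
    x, y = split.training_set()
    if len(np.unique(y)) < 2:
        raise ConfigurationError("training set contains a single class")
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    clf.fit(x, y)
    return clf, float(clf.score(x, y))


def train_best_of_n(
    windows: Sequence[FeatureWindow],
    motif: str,
    n_runs: int = 10,
    seed: int = 0,
    n_trees: int = 100,
    max_depth: int | None = None,
    train_frac: float = 0.7,
) -> tuple[MotifModel, TrainTestSplit]:
    """Fit ``n_runs`` forests on resampled training sets; keep the best.

    The positive 70/30 partition is fixed once (seeded by ``seed``) so the
    held-out positives are identical across runs; run *i* resamples the
    balanced negative training subset and seeds its forest with ``seed + i``.
    The run with the highest training accuracy wins; ties go to the lowest
    run index.  Returns the winning model together with its split (test
    negatives are the negatives that run did not train on).
    """
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    positives, negatives = _split_by_label(windows)
    if len(positives) < 2:
        raise ConfigurationError(
            f"motif {motif}: need >= 2 positive windows, have {len(positives)}"
        )
    flank = positives[0].flank
    rng = np.random.default_rng(seed)
    train_pos, test_pos = _partition_positives(positives, train_frac, rng)

    best: tuple[float, int, RandomForestClassifier, TrainTestSplit] | None = None
    accuracies = []
    for run in range(n_runs):
        run_seed = seed + run
        run_rng = np.random.default_rng(run_seed)
        train_neg, test_neg = _sample_negatives(negatives, len(train_pos), run_rng)
        split = TrainTestSplit(train_pos, train_neg, test_pos, test_neg, run_seed)
        clf, acc = _fit_forest(split, n_trees, max_depth, run_seed)
        accuracies.append(acc)
        if best is None or acc > best[0]:
            best = (acc, run, clf, split)

    acc, run, clf, split = best
    model = MotifModel(
        motif=motif,
        classifier=clf,
        hyperparameters={
            "n_trees": n_trees,
            "max_depth": max_depth,
            "seed": seed,
            "n_runs": n_runs,
            "train_frac": train_frac,
            "best_run": run,
        },
        training_accuracy=acc,
        flank=flank,
        run_accuracies=tuple(accuracies),
    )
    return model, split


def evaluate(
    model: MotifModel, split: TrainTestSplit, threshold: float = 0.5
) -> ModelMetrics:
    """Score a model on the held-out test set.

    clip_detection_rate = called positives among test positives; precision
    and ROC AUC are computed over the pooled test positives + negatives.
    Precision is NaN when the model calls nothing positive.
    """
    if not split.test_pos:
        raise ConfigurationError("empty test positive set: metrics undefined")
    x, y = split.test_set()
    proba = model.predict_proba(x)
    calls = proba >= threshold
    n_pos = len(split.test_pos)
    cdr = float(calls[:n_pos].sum() / n_pos)
    tp = int(calls[y == 1].sum())
    fp = int(calls[y == 0].sum())
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    auc = float(roc_auc_score(y, proba)) if split.test_neg else float("nan")
    return ModelMetrics(
        clip_detection_rate=cdr,
        precision=float(precision),
        roc_auc=auc,
        n_train_pos=len(split.train_pos),
        n_test_pos=n_pos,
        n_test_neg=len(split.test_neg),
    )


def select_qualifying_motifs(
    metrics_by_motif: dict[str, ModelMetrics],
    acc_min: float = DEFAULT_ACC_MIN,
    prec_min: float = DEFAULT_PREC_MIN,
    auc_min: float = DEFAULT_AUC_MIN,
) -> set[str]:
    """Keep motifs whose models pass all three thresholds strictly.

    A motif qualifies iff clip_detection_rate > acc_min AND precision >
    prec_min AND roc_auc > auc_min; NaN metrics never qualify.
    """
    return {
        motif
        for motif, m in metrics_by_motif.items()
        if m.clip_detection_rate > acc_min
        and m.precision > prec_min
        and m.roc_auc > auc_min
    }


def save_model(model: MotifModel, path: str | Path) -> None:
    """Persist a MotifModel (classifier + full provenance) with joblib."""
    payload = {
        "format_version": FORMAT_VERSION,
        "motif": model.motif,
        "flank": model.flank,
        "hyperparameters": model.hyperparameters,
        "training_accuracy": model.training_accuracy,
        "run_accuracies": model.run_accuracies,
        "metrics": model.metrics,
        "classifier": model.classifier,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> MotifModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    return MotifModel(
        motif=payload["motif"],
        classifier=payload["classifier"],
        hyperparameters=payload["hyperparameters"],
        training_accuracy=payload["training_accuracy"],
        flank=payload["flank"],
        run_accuracies=tuple(payload.get("run_accuracies", ())),
        metrics=payload.get("metrics"),
    )
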
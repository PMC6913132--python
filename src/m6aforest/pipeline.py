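"""End-to-end orchestration: files in, trained models / calls out.

Thin glue over the library modules, shared by the command-line interface,
the test suite and the reproduction script.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from m6aforest.features import FeatureWindow, extract_windows, label_windows
from m6aforest.model import (
    ModelMetrics,
    MotifModel,
    TrainTestSplit,
    evaluate,
    train_best_of_n,
)
from m6aforest.motifs import scan_fasta
from m6aforest.signal_io import read_bed_intervals, read_bedgraph, read_wiggle


def build_windows(
    reference_fasta: str | Path,
    signal_wig: str | Path,
    coverage_bedgraph: str | Path,
    truth_bed: str | Path | None = None,
    flank: int = 10,
    min_coverage: int = 5,
    motif_subset: Iterable[str] | None = None,
    strands: Sequence[str] = ("+",),
    signal_wig_minus: str | Path | None = None,
    coverage_bedgraph_minus: str | Path | None = None,
) -> tuple[list[FeatureWindow], Counter]:
    """Scan a reference, extract filtered windows, optionally label them."""
    sites = scan_fasta(reference_fasta, strands=strands, motif_subset=motif_subset)
    signal = read_wiggle(signal_wig)
    coverage = read_bedgraph(coverage_bedgraph)
    signal_minus = read_wiggle(signal_wig_minus, "-") if signal_wig_minus else None
    coverage_minus = (
        read_bedgraph(coverage_bedgraph_minus, "-") if coverage_bedgraph_minus else None
    )
    windows, drops = extract_windows(
        sites,
        signal,
        coverage,
        flank=flank,
        min_coverage=min_coverage,
        signal_minus=signal_minus,
        coverage_minus=coverage_minus,
    )
    if truth_bed is not None:
        windows = label_windows(windows, read_bed_intervals(truth_bed))
    return windows, drops


def train_models(
    windows: Sequence[FeatureWindow],
    motifs: Iterable[str] | None = None,
    n_runs: int = 10,
    seed: int = 0,
    n_trees: int = 100,
    max_depth: int | None = None,
    train_frac: float = 0.7,
    threshold: float = 0.5,
) -> tuple[dict[str, MotifModel], dict[str, TrainTestSplit]]:
    """Train one best-of-n model per motif and attach its test metrics.

    ``motifs`` defaults to every motif present among the windows.  Each
    motif trains on its own windows with the same base seed, so the result
    does not depend on which other motifs were requested.
    """
    by_motif: dict[str, list[FeatureWindow]] = {}
    for w in windows:
        by_motif.setdefault(w.site.motif, []).append(w)
    wanted = sorted(motifs) if motifs is not None else sorted(by_motif)
    models: dict[str, MotifModel] = {}
    splits: dict[str, TrainTestSplit] = {}
    for motif in wanted:
        model, split = train_best_of_n(
            by_motif.get(motif, []),
            motif,
            n_runs=n_runs,
            seed=seed,
            n_trees=n_trees,
            max_depth=max_depth,
            train_frac=train_frac,
        )
        model.metrics = evaluate(model, split, threshold=threshold)
        models[motif] = model
        splits[motif] = split
    return models, splits


def held_out_predictions(
    models: Mapping[str, MotifModel],
    splits: Mapping[str, TrainTestSplit],
) -> tuple[list[FeatureWindow], list[float]]:
    """Pool per-motif test-set windows with their predicted probabilities.

    Random forests interpolate their training windows almost perfectly, so
    any evaluation against an external truth source must be restricted to
    windows the winning run never trained on; this pools those across
    motifs.
    """
    from m6aforest.features import windows_to_matrix

    windows: list[FeatureWindow] = []
    proba: list[float] = []
    for motif in sorted(splits):
        test = splits[motif].test_pos + splits[motif].test_neg
        if not test:
            continue
        windows.extend(test)
        proba.extend(models[motif].predict_proba(windows_to_matrix(test)))
    return windows, proba


def metrics_table(models: Mapping[str, MotifModel]) -> pd.DataFrame:
    """Per-motif metrics report (one row per trained model)."""
    rows = []
    for motif in sorted(models):
        m: ModelMetrics | None = models[motif].metrics
        rows.append(
            {
                "motif": motif,
                "training_accuracy": models[motif].training_accuracy,
                "clip_detection_rate": m.clip_detection_rate if m else float("nan"),
                "precision": m.precision if m else float("nan"),
                "roc_auc": m.roc_auc if m else float("nan"),
                "n_train_pos": m.n_train_pos if m else 0,
                "n_test_pos": m.n_test_pos if m else 0,
                "n_test_neg": m.n_test_neg if m else 0,
            }
        )
    return pd.DataFrame(rows)
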
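"""Apply qualifying per-motif models to candidate windows and emit calls.

The production tool ships models only for the four motifs whose classifiers
cleared the qualification thresholds on real training data (AGACT, GGACA,
GGACC, GGACT); windows in other motif contexts are skipped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from m6aforest.features import FeatureWindow, windows_to_matrix
from m6aforest.model import ConfigurationError, MotifModel
from m6aforest.motifs import MotifSite

#: Motifs whose models qualified on real data; the shipped default.
DEFAULT_MOTIF_WHITELIST = frozenset({"AGACT", "GGACA", "GGACC", "GGACT"})

CALL_M6A = "m6A"
CALL_NOT = "not_m6A"


@dataclass(frozen=True)
class PredictionRecord:
    site: MotifSite
    probability: float
    call: str
    model_motif: str


def predict_sites(
    windows: Sequence[FeatureWindow],
    models: Mapping[str, MotifModel],
    threshold: float = 0.5,
    motif_whitelist: Iterable[str] | None = None,
) -> tuple[list[PredictionRecord], int]:
    """Classify every whitelisted-motif window; returns (records, n_skipped).

    Each window is scored by the model for its own 5-mer; probability >=
    ``threshold`` is called m6A, below is not_m6A (both are reported so
    downstream perturbation analyses can compare the classes).  Windows with
    non-whitelisted motifs are skipped and counted.  Output is sorted by
    (ref, position, strand).
    """
    whitelist = (
        frozenset(motif_whitelist)
        if motif_whitelist is not None
        else DEFAULT_MOTIF_WHITELIST
    )
    missing = {m for m in whitelist if m not in models}
    if missing:
        raise ConfigurationError(
            f"whitelisted motifs with no loaded model: {sorted(missing)}"
        )
    kept = [w for w in windows if w.site.motif in whitelist]
    skipped = len(windows) - len(kept)
    if kept:
        expected = kept[0].flank
        for motif in {w.site.motif for w in kept}:
            if models[motif].flank != expected:
                raise ConfigurationError(
                    f"model for {motif} has flank {models[motif].flank}, "
                    f"windows have flank {expected}"
                )

    records: list[PredictionRecord] = []
    by_motif: dict[str, list[FeatureWindow]] = {}
    for w in kept:
        by_motif.setdefault(w.site.motif, []).append(w)
    for motif, group in by_motif.items():
        proba = models[motif].predict_proba(windows_to_matrix(group))
        for w, p in zip(group, proba):
            call = CALL_M6A if p >= threshold else CALL_NOT
            records.append(PredictionRecord(w.site, float(p), call, motif))
    records.sort(key=lambda r: (r.site.ref_name, r.site.a_pos, r.site.strand))
    return records, skipped
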
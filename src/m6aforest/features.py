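"""Feature-window extraction and truth labeling.

Each candidate adenosine is represented by the fraction-modified values at
the 10 bases upstream and downstream of the A (21 values, 5'->3' in
transcript sense).  Windows are kept only when the central A has at least
``min_coverage`` reads and a fraction value exists at every offset; nanopore
pores read a ~5-base context, so the methylation signature spreads over
neighbouring positions and an incomplete window cannot be classified.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from m6aforest.motifs import MotifSite
from m6aforest.signal_io import CoverageTrack, SignalTrack

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class FeatureWindow:
    """Fixed-length vector of fraction-modified values around one site.

    ``values[i]`` is the fraction at transcript-sense offset ``i - flank``
    from the central A (so index 0 is the most 5' position).  For
    minus-strand genomic sites the genomic order is reversed to restore
    transcript sense.
    """

    site: MotifSite
    values: tuple[float, ...]
    center_coverage: int
    label: str = UNKNOWN

    @property
    def flank(self) -> int:
        return (len(self.values) - 1) // 2

    def value_at_offset(self, offset: int) -> float:
        """Fraction-modified value at a transcript-sense offset from the A."""
        idx = offset + self.flank
        if not 0 <= idx < len(self.values):
            raise IndexError(f"offset {offset} outside +/-{self.flank} window")
        return self.values[idx]


def extract_windows(
    sites: Iterable[MotifSite],
    signal: SignalTrack,
    coverage: CoverageTrack,
    flank: int = 10,
    min_coverage: int = 5,
    signal_minus: SignalTrack | None = None,
    coverage_minus: CoverageTrack | None = None,
) -> tuple[list[FeatureWindow], Counter]:
    """Build feature windows for candidate sites, applying the run filters.

    A window is emitted iff coverage at the central A is >= ``min_coverage``
    and a fraction value exists at every one of the 2*flank+1 offsets
    (windows running past the reference end therefore drop as incomplete).
    Returns the retained windows and a drop report (reason -> count):
    ``no_coverage`` (central A absent from the coverage track),
    ``low_coverage`` and ``incomplete_signal``.

    Genomic mode passes strand-split minus tracks; minus-strand sites then
    read from those and reverse the genomic order so index 0 is 5' in
    transcript sense.  Without minus tracks all sites use the given pair
    (cDNA mode).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    windows: list[FeatureWindow] = []
    drops: Counter = Counter()
    for site in sites:
        if site.strand == "-" and signal_minus is not None:
            sig, cov = signal_minus, coverage_minus if coverage_minus else coverage
        else:
            sig, cov = signal, coverage
        center_cov = cov.get(site.ref_name, site.a_pos)
        if center_cov is None:
            drops["no_coverage"] += 1
            continue
        if center_cov < min_coverage:
            drops["low_coverage"] += 1
            continue
        vals = [
            sig.get(site.ref_name, site.a_pos + off)
            for off in range(-flank, flank + 1)
        ]
        if any(v is None for v in vals):
            drops["incomplete_signal"] += 1
            continue
        if site.strand == "-":
            vals = vals[::-1]
        windows.append(FeatureWindow(site, tuple(vals), int(center_cov)))
    return windows, drops


def label_windows(
    windows: Sequence[FeatureWindow],
    truth_intervals: Iterable[tuple],
) -> list[FeatureWindow]:
    """Assign positive/negative labels by truth-interval containment.

    A window is positive iff its central A lies inside any truth interval
    on the same reference (0-based half-open), strand-aware when the
    interval carries a strand.  All other windows are negative: candidate
    sites absent from the truth set are treated as presumed-unmethylated
    training negatives even though some may be genuinely methylated but
    unannotated.
    """
    trees: dict[tuple[str, str | None], IntervalTree] = {}
    for interval in truth_intervals:
        ref, start, end = interval[0], int(interval[1]), int(interval[2])
        strand = interval[3] if len(interval) > 3 else None
        if end <= start:
            raise ValueError(f"truth interval with end <= start: {interval}")
        trees.setdefault((ref, strand), IntervalTree()).addi(start, end)

    labeled = []
    for w in windows:
        ref, pos = w.site.ref_name, w.site.a_pos
        hit = bool(trees.get((ref, None), IntervalTree())[pos]) or bool(
            trees.get((ref, w.site.strand), IntervalTree())[pos]
        )
        labeled.append(replace(w, label=POSITIVE if hit else NEGATIVE))
    return labeled


def windows_to_matrix(windows: Sequence[FeatureWindow]) -> np.ndarray:
    """Stack window values into an (n_windows, 2*flank+1) float array."""
    if not windows:
        return np.empty((0, 0))
    return np.asarray([w.values for w in windows], dtype=float)


def write_drop_report(drops: Counter, path: str | Path) -> None:
    """Write the drop report as a two-column TSV (reason, count)."""
    with open(path, "w") as fh:
        fh.write("reason\tcount\n")
        for reason in sorted(drops):
            fh.write(f"{reason}\t{drops[reason]}\n")
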
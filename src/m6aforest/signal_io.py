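"""Readers and writers for per-position signal files and BED output.

Nanopore modification-detection preprocessing emits two per-position tracks:
a wiggle of fraction-modified values (the fraction of reads whose current
deviates from the canonical model at that base) and a bedgraph of read
coverage.  Wiggle positions are 1-based; bedgraph intervals are 0-based
half-open.  Everything is converted to 0-based positions at the file
boundary and kept 0-based internally.

Positions absent from a track are *missing*, not zero: no signal was
measured there, which is distinct from a measured 0.0 fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from m6aforest.predict import PredictionRecord


class ParseError(ValueError):
    """Malformed track file; message carries the offending line number."""


@dataclass
class SignalTrack:
    """Per-reference mapping from 0-based position to fraction-modified value.

    ``strand`` tags strand-split genomic tracks ('+' or '-'); cDNA-mode
    tracks leave it None.
    """

    values: dict[str, dict[int, float]] = field(default_factory=dict)
    strand: str | None = None

    def get(self, ref: str, pos: int) -> float | None:
        return self.values.get(ref, {}).get(pos)

    def set(self, ref: str, pos: int, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"fraction-modified value {value} outside [0, 1]")
        if pos < 0:
            raise ValueError(f"negative position {pos}")
        ref_map = self.values.setdefault(ref, {})
        if pos in ref_map:
            raise ValueError(f"duplicate position {pos} on {ref}")
        ref_map[pos] = value


@dataclass
class CoverageTrack:
    """Per-reference mapping from 0-based position to read count."""

    counts: dict[str, dict[int, int]] = field(default_factory=dict)
    strand: str | None = None

    def get(self, ref: str, pos: int) -> int | None:
        return self.counts.get(ref, {}).get(pos)


def read_wiggle(path: str | Path, strand: str | None = None) -> SignalTrack:
    """Parse a wiggle file (fixedStep or variableStep) into a SignalTrack.

    Wiggle positions are 1-based and are shifted to 0-based.  Values must
    lie in [0, 1]; anything else raises.  ``span`` greater than 1 expands to
    per-position values.
    """
    track = SignalTrack(strand=strand)
    chrom: str | None = None
    mode: str | None = None
    fixed_pos = 0
    step = 1
    span = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("variableStep") or line.startswith("fixedStep"):
                fields = dict(
                    kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                )
                if "chrom" not in fields:
                    raise ParseError(f"{path}:{lineno}: header missing chrom=")
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    try:
                        fixed_pos = int(fields["start"])
                    except KeyError:
                        raise ParseError(f"{path}:{lineno}: fixedStep missing start=")
                    step = int(fields.get("step", 1))
                else:
                    mode = "variable"
                continue
            if mode is None:
                raise ParseError(f"{path}:{lineno}: data before any step header")
            parts = line.split()
            try:
                if mode == "variable":
                    if len(parts) != 2:
                        raise ParseError(
                            f"{path}:{lineno}: variableStep line needs 2 fields"
                        )
                    start1 = int(parts[0])
                    value = float(parts[1])
                else:
                    if len(parts) != 1:
                        raise ParseError(
                            f"{path}:{lineno}: fixedStep line needs 1 field"
                        )
                    start1 = fixed_pos
                    fixed_pos += step
                    value = float(parts[0])
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if not 0.0 <= value <= 1.0:
                raise ParseError(
                    f"{path}:{lineno}: value {value} outside [0, 1]"
                )
            for offset in range(span):
                try:
                    track.set(chrom, start1 - 1 + offset, value)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return track


def write_wiggle(track: SignalTrack, path: str | Path) -> None:
    """Write a SignalTrack as variableStep wiggle (1-based positions)."""
    with open(path, "w") as fh:
        for ref in sorted(track.values):
            fh.write(f"variableStep chrom={ref}\n")
            for pos in sorted(track.values[ref]):
                fh.write(f"{pos + 1} {track.values[ref][pos]:.6g}\n")


def read_bedgraph(path: str | Path, strand: str | None = None) -> CoverageTrack:
    """Parse a 4-column bedgraph of read counts into a CoverageTrack.

    Intervals are 0-based half-open and expanded per position.  Overlapping
    intervals are rejected: coverage emitters produce disjoint intervals, so
    overlap indicates a corrupted file.
    """
    track = CoverageTrack(strand=strand)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            ref = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end {end} <= start {start}")
            count = int(round(value))
            if count < 0:
                raise ParseError(f"{path}:{lineno}: negative count {count}")
            ref_map = track.counts.setdefault(ref, {})
            for pos in range(start, end):
                if pos in ref_map:
                    raise ParseError(
                        f"{path}:{lineno}: overlapping interval at {ref}:{pos}"
                    )
                ref_map[pos] = count
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a CoverageTrack as a bedgraph, merging runs of equal counts."""
    with open(path, "w") as fh:
        for ref in sorted(track.counts):
            positions = sorted(track.counts[ref])
            i = 0
            while i < len(positions):
                j = i
                value = track.counts[ref][positions[i]]
                while (
                    j + 1 < len(positions)
                    and positions[j + 1] == positions[j] + 1
                    and track.counts[ref][positions[j + 1]] == value
                ):
                    j += 1
                fh.write(f"{ref}\t{positions[i]}\t{positions[j] + 1}\t{value}\n")
                i = j + 1


def write_bed(
    records: Sequence["PredictionRecord"],
    path: str | Path,
    positive_only: bool = False,
) -> None:
    """Write prediction records as BED6, sorted by (chrom, start).

    name = "<motif>:<call>"; score = round(1000 * probability).
    """
    rows = []
    for rec in records:
        if positive_only and rec.call != "m6A":
            continue
        s = rec.site
        rows.append(
            (
                s.ref_name,
                s.a_pos,
                s.a_pos + 1,
                f"{s.motif}:{rec.call}",
                int(round(1000 * rec.probability)),
                s.strand,
            )
        )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed_intervals(
    path: str | Path,
) -> list[tuple[str, int, int, str | None]]:
    """Read BED intervals as (ref, start, end, strand-or-None) tuples."""
    intervals: list[tuple[str, int, int, str | None]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else None
            intervals.append((parts[0], start, end, strand))
    return intervals
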
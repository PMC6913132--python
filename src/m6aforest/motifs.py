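"""DRACH motif enumeration and candidate-site scanning.

m6A deposition is strongly biased toward the degenerate 5-mer consensus
DRACH (D = A/G/T, R = A/G, H = A/C/T in DNA form), with the methylated
adenosine at the central position.  Restricting candidate sites to DRACH
occurrences keeps the search space small and specific to m6A rather than
other modifications.  The fully expanded family contains exactly 18 5-mers,
one classifier each.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from pyfaidx import Fasta

#: Degenerate alphabet of the DRACH consensus, position by position.
_DRACH_CLASSES = ("AGT", "AG", "A", "C", "ACT")

_DRACH_RE = re.compile(r"(?=([AGT][AG]AC[ACT]))")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_CHARS = frozenset("ACGTN")


def enumerate_drach() -> frozenset[str]:
    """Return the full set of 18 5-mers matching the DRACH consensus."""
    return frozenset("".join(p) for p in itertools.product(*_DRACH_CLASSES))


@dataclass(frozen=True, order=True)
class MotifSite:
    """One candidate adenosine: the central A of a DRACH occurrence.

    ``a_pos`` is the 0-based offset of the A on the reference sequence
    (genomic coordinates for minus-strand sites, i.e. the position of the
    complementary T on the plus strand).
    """

    ref_name: str
    a_pos: int
    motif: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.ref_name, self.a_pos, self.strand)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def normalize_sequence(sequence: str) -> str:
    """Uppercase, convert RNA U to DNA T, and validate the alphabet."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(
            f"sequence contains non-DNA characters: {sorted(bad)} "
            "(allowed: A, C, G, T, N, U)"
        )
    return seq


def scan_sequence(
    ref_name: str,
    sequence: str,
    strand: str = "+",
    motif_subset: Iterable[str] | None = None,
) -> list[MotifSite]:
    """Locate every DRACH occurrence on one strand of ``sequence``.

    Overlapping occurrences are all reported; windows containing N are not
    (N cannot be resolved to one of the 18 motifs).  For ``strand='-'`` the
    reverse complement is scanned and coordinates are reflected back so that
    ``a_pos`` is the plus-strand (genomic) position of the site.  Output is
    sorted by ``a_pos``.
    """
    seq = normalize_sequence(sequence)
    subset = frozenset(motif_subset) if motif_subset is not None else enumerate_drach()
    unknown = subset - enumerate_drach()
    if unknown:
        raise ValueError(f"motif_subset contains non-DRACH 5-mers: {sorted(unknown)}")

    if strand == "-":
        scanned = reverse_complement(seq)
    elif strand == "+":
        scanned = seq
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    n = len(seq)
    sites = []
    for m in _DRACH_RE.finditer(scanned):
        motif = m.group(1)
        if motif not in subset:
            continue
        a_scan = m.start() + 2
        a_pos = a_scan if strand == "+" else n - 1 - a_scan
        sites.append(MotifSite(ref_name, a_pos, motif, strand))
    sites.sort(key=lambda s: s.a_pos)
    return sites


def scan_fasta(
    path: str | Path,
    strands: Sequence[str] = ("+",),
    motif_subset: Iterable[str] | None = None,
) -> list[MotifSite]:
    """Scan every record of a FASTA file; returns sites grouped by record.

    cDNA (transcriptomic) references are scanned plus-strand only (the
    default); genomic references may request both strands.
    """
    fasta = Fasta(str(path), rebuild=True)
    sites: list[MotifSite] = []
    for record in fasta:
        seq = str(record)
        for strand in strands:
            sites.extend(scan_sequence(record.name, seq, strand, motif_subset))
    return sites


def sites_to_bed(sites: Sequence[MotifSite], path: str | Path) -> None:
    """Write candidate sites as BED6 (single-base intervals on the A)."""
    ordered = sorted(sites, key=lambda s: (s.ref_name, s.a_pos, s.strand))
    with open(path, "w") as fh:
        for s in ordered:
            fh.write(f"{s.ref_name}\t{s.a_pos}\t{s.a_pos + 1}\t{s.motif}\t0\t{s.strand}\n")
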
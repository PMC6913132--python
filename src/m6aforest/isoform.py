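"""Transcript-to-genome coordinate lifting and isoform-level classification.

Calls made against a cDNA (transcriptomic) reference are transcript-resolved.
Lifting each call's central A through the transcript's exon structure to a
genomic coordinate lets positions shared by several isoforms be compared:
a shared position can be never methylated, consistently methylated across
isoforms, or isoform-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gffutils

from m6aforest.predict import CALL_M6A, PredictionRecord

CATEGORY_NEVER = "never"
CATEGORY_CONSISTENT = "consistent"
CATEGORY_ISOFORM_SPECIFIC = "isoform_specific"


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript.

    ``exons`` are 0-based half-open genomic intervals ordered 5'->3' in
    transcript reading order: ascending starts on '+', descending on '-'.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.transcript_id}: empty exon ({start},{end})")
        genomic_order = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic_order, genomic_order[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        starts = [s for s, _ in self.exons]
        expected = sorted(starts, reverse=(self.strand == "-"))
        if starts != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not in 5'->3' order for {self.strand}"
            )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


def transcript_to_genome(
    tx: TranscriptModel, tx_pos: int
) -> tuple[str, int, str]:
    """Map a 0-based transcript offset to (chrom, genomic position, strand).

    Walks exons 5'->3'; on the minus strand transcript base 0 sits at the
    highest genomic coordinate of the first exon.
    """
    if not 0 <= tx_pos < tx.length:
        raise IndexError(
            f"{tx.transcript_id}: transcript position {tx_pos} outside "
            f"[0, {tx.length})"
        )
    remaining = tx_pos
    for start, end in tx.exons:
        size = end - start
        if remaining < size:
            if tx.strand == "+":
                return (tx.chrom, start + remaining, "+")
            return (tx.chrom, end - 1 - remaining, "-")
        remaining -= size
    raise AssertionError("unreachable: tx_pos bounds were checked")


def genome_to_transcript(tx: TranscriptModel, genomic_pos: int) -> int:
    """Inverse of :func:`transcript_to_genome`; raises if not exonic."""
    offset = 0
    for start, end in tx.exons:
        if start <= genomic_pos < end:
            if tx.strand == "+":
                return offset + (genomic_pos - start)
            return offset + (end - 1 - genomic_pos)
        offset += end - start
    raise IndexError(
        f"{tx.transcript_id}: genomic position {genomic_pos} not exonic"
    )


def spans_junction(tx: TranscriptModel, tx_pos: int, flank: int) -> bool:
    """True when the +/-flank window around tx_pos crosses an exon boundary.

    Junction-spanning windows see a signal context (contiguous transcript
    bases) that differs from the genomic context; they are flagged rather
    than excluded.
    """
    lo = max(0, tx_pos - flank)
    hi = min(tx.length - 1, tx_pos + flank)
    chrom_lo = transcript_to_genome(tx, lo)[1]
    chrom_hi = transcript_to_genome(tx, hi)[1]
    return abs(chrom_hi - chrom_lo) != hi - lo


def read_gtf(path: str | Path) -> dict[str, TranscriptModel]:
    """Load exon structures from a GTF, grouped by transcript_id.

    Exon features must carry transcript_id and gene_id attributes; exons are
    reordered into transcript 5'->3' order from their strand.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tx_id = exon.attributes["transcript_id"][0]
        gene_id = exon.attributes.get("gene_id", [tx_id])[0]
        entry = grouped.setdefault(
            tx_id,
            {"gene_id": gene_id, "chrom": exon.seqid, "strand": exon.strand, "exons": []},
        )
        # GTF is 1-based closed; convert to 0-based half-open.
        entry["exons"].append((exon.start - 1, exon.end))
    transcripts = {}
    for tx_id, entry in grouped.items():
        exons = sorted(entry["exons"], reverse=(entry["strand"] == "-"))
        transcripts[tx_id] = TranscriptModel(
            transcript_id=tx_id,
            gene_id=entry["gene_id"],
            chrom=entry["chrom"],
            strand=entry["strand"],
            exons=tuple(exons),
        )
    return transcripts


@dataclass
class SharedSiteClass:
    """One genomic position covered by >= 2 isoforms, with per-isoform calls."""

    chrom: str
    genomic_pos: int
    strand: str
    calls: dict[str, str] = field(default_factory=dict)
    category: str = ""


@dataclass
class GeneSummary:
    n_m6a_genes: int
    n_isoform_specific_genes: int
    n_genomic_positions: int
    n_shared_positions: int


def _categorize(calls: Sequence[str]) -> str:
    n_m6a = sum(1 for c in calls if c == CALL_M6A)
    if n_m6a == 0:
        return CATEGORY_NEVER
    if n_m6a == len(calls):
        return CATEGORY_CONSISTENT
    return CATEGORY_ISOFORM_SPECIFIC


def classify_shared_sites(
    predictions: Sequence[PredictionRecord],
    transcripts: Mapping[str, TranscriptModel],
    flank: int | None = None,
) -> tuple[list[SharedSiteClass], GeneSummary, list[str]]:
    """Lift transcript-space predictions and classify shared genomic sites.

    Predictions are grouped by lifted (chrom, genomic position, strand);
    motif identity may differ across isoforms at exon boundaries and is not
    required to match.  Positions covered by >= 2 isoforms are classified
    never / consistent / isoform_specific.  Returns the classified shared
    sites, a gene-level summary (genes with any m6A call; genes with any
    isoform-specific shared site), and the transcript ids of
    junction-spanning windows when ``flank`` is given.
    """
    unknown = {p.site.ref_name for p in predictions} - set(transcripts)
    if unknown:
        raise KeyError(
            f"predictions on transcripts with no model: {sorted(unknown)}"
        )

    groups: dict[tuple[str, int, str], dict[str, str]] = {}
    gene_calls: dict[str, list[str]] = {}
    gene_of_position: dict[tuple[str, int, str], set[str]] = {}
    junction_flagged: list[str] = []
    for pred in predictions:
        tx = transcripts[pred.site.ref_name]
        chrom, gpos, strand = transcript_to_genome(tx, pred.site.a_pos)
        key = (chrom, gpos, strand)
        groups.setdefault(key, {})[tx.transcript_id] = pred.call
        gene_calls.setdefault(tx.gene_id, []).append(pred.call)
        gene_of_position.setdefault(key, set()).add(tx.gene_id)
        if flank is not None and spans_junction(tx, pred.site.a_pos, flank):
            junction_flagged.append(tx.transcript_id)

    shared: list[SharedSiteClass] = []
    iso_specific_genes: set[str] = set()
    for (chrom, gpos, strand), calls in sorted(groups.items()):
        if len(calls) < 2:
            continue
        category = _categorize(list(calls.values()))
        shared.append(SharedSiteClass(chrom, gpos, strand, dict(calls), category))
        if category == CATEGORY_ISOFORM_SPECIFIC:
            iso_specific_genes.update(gene_of_position[(chrom, gpos, strand)])

    summary = GeneSummary(
        n_m6a_genes=sum(
            1 for calls in gene_calls.values() if any(c == CALL_M6A for c in calls)
        ),
        n_isoform_specific_genes=len(iso_specific_genes),
        n_genomic_positions=len(groups),
        n_shared_positions=len(shared),
    )
    return shared, summary, junction_flagged


def write_shared_sites(
    shared: Sequence[SharedSiteClass], path: str | Path
) -> None:
    """Write classified shared sites as a BED-style TSV."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcategory\tstrand\tisoform_calls\n")
        for s in shared:
            calls = ",".join(f"{tx}={call}" for tx, call in sorted(s.calls.items()))
            fh.write(
                f"{s.chrom}\t{s.genomic_pos}\t{s.genomic_pos + 1}\t"
                f"{s.category}\t{s.strand}\t{calls}\n"
            )
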
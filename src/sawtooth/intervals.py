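"""Strand-aware genomic intervals and elementary interval-set arithmetic.

All coordinates inside the package are 0-based half-open; conversion to and
from 1-based inclusive conventions (GTF, STAR junction tables) happens only
at file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region.

    ``strand`` is ``+`` or ``-``; ``.`` marks an unknown strand (kept for
    junction records whose strand the aligner could not assign).
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)

    def __lt__(self, other: "GenomicInterval") -> bool:
        return self.sort_key < other.sort_key

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


def merge_intervals(
    spans: Iterable[tuple[int, int]], merge_abutting: bool = True
) -> list[tuple[int, int]]:
    """Merge overlapping (and, by default, abutting) half-open spans.

    Abutting half-open spans represent contiguous sequence, so they merge
    unless ``merge_abutting`` is disabled. Idempotent.
    """
    spans = sorted(spans)
    if not spans:
        return []
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        last = merged[-1]
        joins = s <= last[1] if merge_abutting else s < last[1]
        if joins:
            last[1] = max(last[1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def subtract_spans(
    span: tuple[int, int], holes: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Remainder of ``span`` after removing every overlapping ``hole``."""
    pieces: list[tuple[int, int]] = []
    cursor = span[0]
    for hs, he in merge_intervals(holes, merge_abutting=True):
        if he <= span[0] or hs >= span[1]:
            continue
        if hs > cursor:
            pieces.append((cursor, hs))
        cursor = max(cursor, he)
    if cursor < span[1]:
        pieces.append((cursor, span[1]))
    return pieces


@dataclass
class GeneModel:
    """Exon structure of one gene: exons grouped per transcript.

    Exons of a transcript are kept sorted by genomic start and must not
    overlap one another; the gene span covers every exon.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    biotype: str = ""

    def add_exon(self, transcript_id: str, exon: GenomicInterval) -> None:
        self.transcripts.setdefault(transcript_id, []).append(exon)

    def finalize(self) -> None:
        for tx, exons in self.transcripts.items():
            exons.sort()
            for a, b in zip(exons, exons[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping exons in transcript {tx} of {self.gene_id}"
                    )

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for exons in self.transcripts.values() for e in exons]
        ends = [e.end for exons in self.transcripts.values() for e in exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    def exons(self) -> list[GenomicInterval]:
        """All exon intervals of the gene (duplicates across isoforms kept)."""
        return [e for exons in self.transcripts.values() for e in exons]

    def introns(self) -> list[GenomicInterval]:
        """Per-transcript gaps between consecutive exons."""
        out = []
        for exons in self.transcripts.values():
            for a, b in zip(exons, exons[1:]):
                if b.start > a.end:
                    out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out
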
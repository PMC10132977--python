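"""Splice-junction and chimeric (back-splice) junction tables.

Two columnar dialects are supported, both plain TSV:

* the STAR ``SJ.out.tab`` layout for linear splice junctions
  (chrom, 1-based intron start, 1-based intron end, strand code,
  motif, annotated flag, unique reads, multimapping reads, max overhang);
* a compact chimeric-junction table derived from STAR's chimeric output
  (chrom, donor position, acceptor position, strand, supporting reads),
  where donor/acceptor are the 0-based genomic breakpoints of the
  back-splice and reads counts supporting read pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .intervals import GenomicInterval

_STRAND_FROM_CODE = {0: ".", 1: "+", 2: "-"}
_CODE_FROM_STRAND = {".": 0, "+": 1, "-": 2}

SJ_COLUMNS = [
    "chrom",
    "intron_first",
    "intron_last",
    "strand_code",
    "motif",
    "annotated",
    "unique_reads",
    "multi_reads",
    "max_overhang",
]

CHIMERIC_COLUMNS = ["chrom", "donor_pos", "acceptor_pos", "strand", "reads"]


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction: the intron it excises plus its split-read support."""

    interval: GenomicInterval  # 0-based half-open intron span
    unique_reads: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.unique_reads < 0:
            raise ValueError("split-read count must be non-negative")


@dataclass(frozen=True)
class ChimericRecord:
    """One back-splice candidate junction with its supporting read count.

    For a genuine back-splice the acceptor precedes the donor in
    transcription direction (upstream acceptor joined to downstream donor).
    """

    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str
    reads: int


def read_star_junctions(path: str | Path, sample_id: str = "") -> list[JunctionRecord]:
    """Read a STAR ``SJ.out.tab``-style table.

    STAR reports the intron as 1-based first and last base; internally the
    intron becomes the 0-based half-open span (first-1, last). Strand code 0
    (undetermined) is kept with strand ``.``.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=SJ_COLUMNS, dtype={"chrom": str}
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != len(SJ_COLUMNS):
        raise ValueError(f"junction table must have {len(SJ_COLUMNS)} columns")
    records = []
    for row in df.itertuples():
        strand = _STRAND_FROM_CODE[int(row.strand_code)]
        iv = GenomicInterval(row.chrom, int(row.intron_first) - 1, int(row.intron_last), strand)
        records.append(JunctionRecord(iv, int(row.unique_reads), sample_id))
    return records


def write_star_junctions(records, path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.interval.chrom,
                "intron_first": r.interval.start + 1,
                "intron_last": r.interval.end,
                "strand_code": _CODE_FROM_STRAND[r.interval.strand],
                "motif": 0,
                "annotated": 0,
                "unique_reads": r.unique_reads,
                "multi_reads": 0,
                "max_overhang": 0,
            }
        )
    pd.DataFrame(rows, columns=SJ_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


def read_chimeric_table(path: str | Path) -> list[ChimericRecord]:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=CHIMERIC_COLUMNS, dtype={"chrom": str}
        )
    except pd.errors.EmptyDataError:
        return []
    return [
        ChimericRecord(r.chrom, int(r.donor_pos), int(r.acceptor_pos), r.strand, int(r.reads))
        for r in df.itertuples()
    ]


def write_chimeric_table(records, path: str | Path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "donor_pos": r.donor_pos,
            "acceptor_pos": r.acceptor_pos,
            "strand": r.strand,
            "reads": r.reads,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CHIMERIC_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )
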
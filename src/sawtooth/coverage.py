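"""Per-base read-depth extraction and coverage containers.

Coverage can come from three sources: SAM/BAM alignments (via pysam), a
simplified aligned-block table (DataFrame with chrom/start/end per aligned
block, the representation the simulator emits), or a bedGraph file (MNase
fragment-midpoint counts). All of them land in :class:`CoverageTrack`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .intervals import GenomicInterval

BLOCK_COLUMNS = ["chrom", "start", "end"]


@dataclass
class CoverageTrack:
    """Per-base depth over one interval. ``values[i]`` is depth at
    ``interval.start + i`` on the genomic axis (not transcription direction)."""

    interval: GenomicInterval
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.interval):
            raise ValueError("coverage length must equal interval length")
        if (self.values < 0).any():
            raise ValueError("coverage must be non-negative")

    def scaled(self, library_size: int) -> "CoverageTrack":
        """Reads-per-million scaling: raw depth x 1e6 / total mapped reads."""
        if library_size <= 0:
            raise ValueError("library size must be positive")
        return CoverageTrack(self.interval, self.values * 1e6 / library_size)

    def oriented_values(self) -> np.ndarray:
        """Depth ordered 5'->3' in transcription direction."""
        if self.interval.strand == "-":
            return self.values[::-1]
        return self.values


def _iter_alignments(path: str | Path, interval: GenomicInterval,
                     keep_secondary: bool = False, keep_duplicates: bool = True):
    """Yield primary aligned reads overlapping ``interval``.

    Falls back to a full scan when the file has no index (plain SAM).
    """
    with pysam.AlignmentFile(str(path)) as af:
        if interval.chrom not in af.references:
            raise ValueError(f"reference {interval.chrom!r} not in alignment header")
        ref_len = af.get_reference_length(interval.chrom)
        if interval.end > ref_len:
            raise ValueError(
                f"interval end {interval.end} beyond reference length {ref_len}"
            )
        try:
            reads = af.fetch(interval.chrom, interval.start, interval.end)
        except ValueError:  # no index: scan everything
            reads = af.fetch(until_eof=True)
        for read in reads:
            if read.is_unmapped:
                continue
            if not keep_secondary and (read.is_secondary or read.is_supplementary):
                continue
            if not keep_duplicates and read.is_duplicate:
                continue
            if read.reference_name != interval.chrom:
                continue
            yield read


def count_mapped_reads(path: str | Path) -> int:
    """Primary mapped reads in the file — the RPM denominator."""
    n = 0
    with pysam.AlignmentFile(str(path)) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            n += 1
    return n


def extract_coverage(
    alignments,
    interval: GenomicInterval,
    scale: str = "raw",
    library_size: int | None = None,
    keep_secondary: bool = False,
) -> CoverageTrack:
    """Per-base depth over ``interval``.

    ``alignments`` is a SAM/BAM path or an aligned-block DataFrame with
    columns chrom/start/end (one row per contiguous aligned block, so
    spliced reads contribute no depth inside their N gaps — with pysam
    input the same rule is enforced through ``get_blocks``).
    ``scale='rpm'`` divides by the library size (counted from the file when
    not given; required for table input).
    """
    depth = np.zeros(len(interval))
    if isinstance(alignments, pd.DataFrame):
        sub = alignments[
            (alignments["chrom"] == interval.chrom)
            & (alignments["end"] > interval.start)
            & (alignments["start"] < interval.end)
        ]
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            lo = max(int(s), interval.start) - interval.start
            hi = min(int(e), interval.end) - interval.start
            depth[lo:hi] += 1
        if scale == "rpm" and library_size is None:
            raise ValueError("library_size required for RPM scaling of a block table")
    else:
        for read in _iter_alignments(alignments, interval, keep_secondary=keep_secondary):
            for bs, be in read.get_blocks():
                lo = max(bs, interval.start) - interval.start
                hi = min(be, interval.end) - interval.start
                if hi > lo:
                    depth[lo:hi] += 1
        if scale == "rpm" and library_size is None:
            library_size = count_mapped_reads(alignments)
    track = CoverageTrack(interval, depth)
    if scale == "rpm":
        track = track.scaled(library_size)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    return track


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
            comment="t",  # skips "track ..." header lines
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])


def track_from_bedgraph(df: pd.DataFrame, interval: GenomicInterval) -> CoverageTrack:
    """Materialize bedGraph rows overlapping ``interval`` into a dense track."""
    depth = np.zeros(len(interval))
    sub = df[
        (df["chrom"] == interval.chrom)
        & (df["end"] > interval.start)
        & (df["start"] < interval.end)
    ]
    for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
        lo = max(int(s), interval.start) - interval.start
        hi = min(int(e), interval.end) - interval.start
        depth[lo:hi] += v
    return CoverageTrack(interval, depth)


def track_to_bedgraph(track: CoverageTrack) -> pd.DataFrame:
    """Run-length encode a dense track as bedGraph rows (zero runs dropped)."""
    v = track.values
    rows = []
    i = 0
    base = track.interval.start
    while i < len(v):
        j = i
        while j < len(v) and v[j] == v[i]:
            j += 1
        if v[i] != 0:
            rows.append((track.interval.chrom, base + i, base + j, float(v[i])))
        i = j
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
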
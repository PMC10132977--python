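"""Expression-normalized per-gene mismatch rates.

Single-read mismatches against the reference are treated as transcription
or sequencing errors once four filters have removed likely artefacts and
genetic variants: reads containing indels are excluded; mismatches closer
than five bases to either read end are excluded; genomic positions where
two or more reads mismatch (candidate SNPs or RNA editing) are excluded;
and only positions covered by at least 100 reads are kept. The per-gene
rate is passing mismatches divided by the number of gene positions meeting
the same coverage floor.

Input is either the simulator's two-table representation (reads +
mismatches) or a SAM/BAM file carrying MD tags, converted through
:func:`mismatch_tables_from_alignments`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

READ_COLUMNS = ["read_id", "chrom", "start", "length", "has_indel", "gene_id"]
MISMATCH_COLUMNS = ["read_id", "read_offset", "genome_pos", "ref", "alt"]

DEFAULT_MIN_DEPTH = 100
DEFAULT_END_DISTANCE = 4


@dataclass
class GeneMismatchRate:
    gene_id: str
    n_mismatches: int
    n_qualifying_bases: int

    @property
    def rate(self) -> float:
        if self.n_qualifying_bases == 0:
            return np.nan
        return self.n_mismatches / self.n_qualifying_bases


def collect_mismatches(
    reads: pd.DataFrame,
    mismatches: pd.DataFrame,
    end_distance: int = DEFAULT_END_DISTANCE,
) -> pd.DataFrame:
    """Apply the read-level and position-level filters, in order: drop
    indel-carrying reads, drop end-proximal mismatches (within
    ``end_distance`` of either read end, i.e. keep offsets >= end_distance+1
    from both ends), then drop positions mismatched in two or more reads.

    The coverage floor is applied later, in :func:`gene_mismatch_rate`,
    where depth is known.
    """
    missing = set(MISMATCH_COLUMNS) - set(mismatches.columns)
    if missing:
        raise ValueError(f"mismatch table lacks columns: {sorted(missing)}")
    clean_reads = reads[~reads["has_indel"].astype(bool)]
    mm = mismatches[mismatches["read_id"].isin(clean_reads["read_id"])]
    mm = mm.merge(clean_reads[["read_id", "length", "chrom"]], on="read_id")
    off = mm["read_offset"]
    dist_end = mm["length"] - 1 - off
    mm = mm[(off > end_distance) & (dist_end > end_distance)]
    pos_counts = mm.groupby(["chrom", "genome_pos"])["read_id"].nunique()
    unique_pos = pos_counts[pos_counts == 1].index
    keys = pd.MultiIndex.from_frame(mm[["chrom", "genome_pos"]])
    mm = mm[keys.isin(unique_pos)]
    return mm.drop(columns=["length", "chrom"]).reset_index(drop=True)


def gene_mismatch_rate(
    passing: pd.DataFrame,
    depth: np.ndarray,
    gene_id: str,
    gene_start: int = 0,
    min_depth: int = DEFAULT_MIN_DEPTH,
    denominator: str = "read_bases",
) -> GeneMismatchRate:
    """Per-gene expression-normalized mismatch rate.

    ``depth`` is per-base coverage over the gene (index 0 = ``gene_start``
    on the genome). Both numerator and denominator honour the same floor:
    the numerator counts passing mismatches at positions with depth >=
    ``min_depth``; the denominator is the total number of sequenced bases
    at those positions (sum of their depth — the default, which makes the
    rate a per-sequenced-base error frequency directly comparable to a
    per-base error rate and normalizes for expression level), or with
    ``denominator='positions'`` simply the number of qualifying positions.
    """
    depth = np.asarray(depth)
    qualifying = depth >= min_depth
    if denominator == "read_bases":
        n_bases = int(depth[qualifying].sum())
    elif denominator == "positions":
        n_bases = int(qualifying.sum())
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    idx = passing["genome_pos"].to_numpy(dtype=int) - gene_start
    in_gene = (idx >= 0) & (idx < len(depth))
    n_mm = int(qualifying[idx[in_gene]].sum())
    return GeneMismatchRate(gene_id, n_mm, n_bases)


def mismatch_tables_from_alignments(
    path: str | Path, gene_id: str = ""
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract the reads/mismatches tables from SAM/BAM records with MD
    tags (mismatched reference bases are reported lowercase by pysam's
    ``get_aligned_pairs(with_seq=True)``)."""
    read_rows, mm_rows = [], []
    with pysam.AlignmentFile(str(path)) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            has_indel = any(op in (1, 2) for op, _ in (read.cigartuples or []))
            read_rows.append(
                dict(
                    read_id=read.query_name,
                    chrom=read.reference_name,
                    start=read.reference_start,
                    length=read.query_length,
                    has_indel=has_indel,
                    gene_id=gene_id,
                )
            )
            if has_indel:
                continue
            if not read.has_tag("MD"):
                raise ValueError(
                    f"read {read.query_name!r} lacks the MD tag needed for "
                    "mismatch extraction"
                )
            seq = read.query_sequence
            for qpos, rpos, rbase in read.get_aligned_pairs(with_seq=True):
                if qpos is None or rpos is None or rbase is None:
                    continue
                if rbase.islower():
                    mm_rows.append(
                        dict(
                            read_id=read.query_name,
                            read_offset=qpos,
                            genome_pos=rpos,
                            ref=rbase.upper(),
                            alt=seq[qpos],
                        )
                    )
    reads = pd.DataFrame(read_rows, columns=READ_COLUMNS)
    mms = pd.DataFrame(mm_rows, columns=MISMATCH_COLUMNS)
    return reads, mms
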
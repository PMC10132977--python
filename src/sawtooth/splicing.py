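"""Transcript-fidelity metrics built on junction counts.

Three statistics: splicing efficiency (fraction of reads at a splice site
that are spliced rather than spanning the exon-intron boundary), the
per-gene fraction of rare exon-exon junctions (a junction is rare when it
carries <= 0.7% of the reads of its alternatively-excised intron cluster),
and the circRNA index

    CircRatio_i = BS_i / (BS_i + (S1_i + S2_i) / 2) * 100

where BS_i counts back-spliced reads of exon i and S1_i / S2_i count
linearly spliced reads at its 5' and 3' ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GeneModel
from .junctions import ChimericRecord, JunctionRecord

logger = logging.getLogger(__name__)

RARE_THRESHOLD = 0.007
DEFAULT_MIN_OVERHANG = 6


@dataclass
class JunctionCounts:
    """Read counts at one splice site / circularized exon."""

    chrom: str
    position: int
    strand: str
    spliced: int = 0
    unspliced: int = 0
    bs: int = 0   # back-spliced reads
    s1: int = 0   # linear spliced reads at the exon 5' end
    s2: int = 0   # linear spliced reads at the exon 3' end

    def __post_init__(self) -> None:
        for name in ("spliced", "unspliced", "bs", "s1", "s2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be non-negative")


@dataclass
class IntronCluster:
    """Junctions connected (transitively) through shared splice sites."""

    cluster_id: int
    junctions: list[JunctionRecord] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(j.unique_reads for j in self.junctions)


def splicing_efficiency(spliced: int, unspliced: int) -> float:
    """Fraction of reads at a splice site that are spliced. ``nan`` (site
    skipped) when no reads cover the site at all."""
    total = spliced + unspliced
    if total == 0:
        return np.nan
    return spliced / total


def gene_splicing_efficiency(
    site_table: pd.DataFrame, mode: str = "site_mean"
) -> pd.Series:
    """Per-gene efficiency from a table with gene_id/spliced/unspliced.

    ``site_mean`` (default) averages per-site efficiencies; ``pooled`` sums
    counts over sites first.
    """
    def per_gene(g: pd.DataFrame) -> float:
        if mode == "site_mean":
            eff = [
                splicing_efficiency(s, u)
                for s, u in zip(g["spliced"], g["unspliced"])
            ]
            eff = [e for e in eff if np.isfinite(e)]
            return float(np.mean(eff)) if eff else np.nan
        if mode == "pooled":
            return splicing_efficiency(int(g["spliced"].sum()), int(g["unspliced"].sum()))
        raise ValueError(f"unknown mode {mode!r}")

    return site_table.groupby("gene_id").apply(per_gene, include_groups=False)


def boundary_spanning_reads(
    blocks: pd.DataFrame, chrom: str, pos: int, min_overhang: int = DEFAULT_MIN_OVERHANG
) -> int:
    """Unspliced evidence at a splice site: aligned blocks continuously
    covering ``pos`` with at least ``min_overhang`` bases on each side."""
    sub = blocks[
        (blocks["chrom"] == chrom)
        & (blocks["start"] <= pos - min_overhang)
        & (blocks["end"] >= pos + min_overhang)
    ]
    return int(len(sub))


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def build_intron_clusters(junctions: list[JunctionRecord]) -> list[IntronCluster]:
    """Group junctions sharing a donor or acceptor coordinate into clusters
    (union-find over splice-site endpoints); isolated junctions form
    singleton clusters."""
    uf = _UnionFind()
    for i, j in enumerate(junctions):
        donor = (j.interval.chrom, "d", j.interval.start)
        acceptor = (j.interval.chrom, "a", j.interval.end)
        uf.union(("junc", i), donor)
        uf.union(("junc", i), acceptor)
    groups: dict = {}
    for i, j in enumerate(junctions):
        groups.setdefault(uf.find(("junc", i)), []).append(j)
    clusters = []
    for cid, (_, members) in enumerate(sorted(groups.items(), key=lambda kv: str(kv[0]))):
        clusters.append(IntronCluster(cid, members))
    return clusters


def rare_junction_fraction(
    clusters: list[IntronCluster],
    gene_of_junction: dict[tuple, str],
    threshold: float = RARE_THRESHOLD,
) -> pd.Series:
    """Per-gene fraction of rare junctions.

    A junction is rare when its reads are <= threshold x total reads of its
    cluster (inclusive comparison). ``gene_of_junction`` maps
    (chrom, start, end) of the excised intron to a gene id; unmapped
    junctions are skipped and counted in the log. Genes with zero assigned
    junctions produce no row.
    """
    rare_by_gene: dict[str, int] = {}
    all_by_gene: dict[str, int] = {}
    n_unassigned = 0
    for cluster in clusters:
        cutoff = threshold * cluster.total_reads
        for j in cluster.junctions:
            key = (j.interval.chrom, j.interval.start, j.interval.end)
            gene = gene_of_junction.get(key)
            if gene is None:
                n_unassigned += 1
                continue
            all_by_gene[gene] = all_by_gene.get(gene, 0) + 1
            if j.unique_reads <= cutoff:
                rare_by_gene[gene] = rare_by_gene.get(gene, 0) + 1
    if n_unassigned:
        logger.info("%d junctions had no gene assignment", n_unassigned)
    return pd.Series(
        {g: rare_by_gene.get(g, 0) / n for g, n in sorted(all_by_gene.items())},
        dtype=float,
    )


def circ_ratio(bs: int, s1: int, s2: int) -> float:
    """Percentage of transcripts from a locus that circularized:
    BS / (BS + (S1 + S2)/2) x 100. ``nan`` when every count is zero (locus
    skipped)."""
    if bs < 0 or s1 < 0 or s2 < 0:
        raise ValueError("counts must be non-negative")
    if bs + s1 + s2 == 0:
        return np.nan
    return bs / (bs + (s1 + s2) / 2.0) * 100.0


def assign_gene(
    chrom: str, start: int, end: int, strand: str, gene_models: dict[str, GeneModel]
) -> str | None:
    """Gene whose span contains both coordinates on the matching strand;
    ambiguous (multi-gene) assignments return None."""
    hits = []
    for gid, model in gene_models.items():
        span = model.span
        if (
            span.chrom == chrom
            and span.strand == strand
            and span.start <= start
            and end <= span.end
        ):
            hits.append(gid)
    return hits[0] if len(hits) == 1 else None


def extract_backsplices(
    chimeric: list[ChimericRecord],
    gene_models: dict[str, GeneModel],
    junctions: list[JunctionRecord] | None = None,
) -> list[JunctionCounts]:
    """Back-splice counts keyed to the circularized exon span.

    A chimeric record is a back-splice when both breakpoints fall in one
    gene and the acceptor precedes the donor in transcription direction
    (plus strand: acceptor position < donor position; mirrored on minus).
    When a linear junction table is supplied, S1 counts linear spliced
    reads whose acceptor coincides with the circRNA acceptor and S2 those
    whose donor coincides with the circRNA donor.
    """
    out = []
    for rec in chimeric:
        upstream = min(rec.donor_pos, rec.acceptor_pos)
        downstream = max(rec.donor_pos, rec.acceptor_pos)
        if rec.strand == "+":
            is_backsplice = rec.acceptor_pos < rec.donor_pos
        elif rec.strand == "-":
            is_backsplice = rec.acceptor_pos > rec.donor_pos
        else:
            continue
        if not is_backsplice:
            continue
        gene = assign_gene(rec.chrom, upstream, downstream, rec.strand, gene_models)
        if gene is None:
            continue
        s1 = s2 = 0
        if junctions is not None:
            for j in junctions:
                if j.interval.chrom != rec.chrom:
                    continue
                if j.interval.end == upstream:
                    s1 += j.unique_reads
                if j.interval.start == downstream:
                    s2 += j.unique_reads
        out.append(
            JunctionCounts(
                rec.chrom, upstream, rec.strand, bs=rec.reads, s1=s1, s2=s2
            )
        )
    return out
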
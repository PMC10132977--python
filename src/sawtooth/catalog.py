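"""Construction of the filtered intron catalog used for speed estimation.

The catalog pipeline removes exonic overlap, merges duplicated intronic
regions, subdivides introns around internal splice junctions (discarding
introns straddled by a junction), requires split-read support bridging each
intron in every condition of a comparison, and finally applies quality
floors. One shared catalog serves both conditions of a comparison, so the
same intron set is always contrasted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .intervals import GeneModel, GenomicInterval, merge_intervals, subtract_spans
from .junctions import JunctionRecord

logger = logging.getLogger(__name__)


@dataclass
class CatalogConfig:
    min_support: int = 5          # split reads bridging the intron, per condition
    min_length: int = 600         # bp floor for a usable slope fit
    min_mean_depth: float = 10.0  # raw depth floor, applied only when coverage given


@dataclass
class IntronRecord:
    interval: GenomicInterval
    gene_id: str
    support_by_condition: dict[str, int] = field(default_factory=dict)
    provenance: str = "original"  # original | subdivided | merged

    @property
    def intron_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"


@dataclass
class CatalogResult:
    """Catalog plus bookkeeping. ``empty`` is an explicit status so that an
    all-filtered outcome is never mistaken for success."""

    introns: list[IntronRecord]
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return len(self.introns) == 0


def subtract_exons(
    introns: list[IntronRecord], exons: list[GenomicInterval]
) -> list[IntronRecord]:
    """Remove every exon-overlapping part of each intron; an intron fully
    covered by exons disappears, a pierced intron yields flanking pieces."""
    exon_spans: dict[str, list[tuple[int, int]]] = {}
    for e in exons:
        exon_spans.setdefault(e.chrom, []).append((e.start, e.end))
    out = []
    for rec in introns:
        holes = exon_spans.get(rec.interval.chrom, [])
        pieces = subtract_spans((rec.interval.start, rec.interval.end), holes)
        for s, e in pieces:
            iv = GenomicInterval(rec.interval.chrom, s, e, rec.interval.strand)
            prov = rec.provenance if (s, e) == (rec.interval.start, rec.interval.end) else "subdivided"
            out.append(IntronRecord(iv, rec.gene_id, dict(rec.support_by_condition), prov))
    return out


def merge_overlapping(introns: list[IntronRecord]) -> list[IntronRecord]:
    """Merge overlapping or abutting introns on the same chromosome and
    strand (duplicated regions across isoforms collapse to one record)."""
    by_key: dict[tuple[str, str], list[IntronRecord]] = {}
    for rec in introns:
        by_key.setdefault((rec.interval.chrom, rec.interval.strand), []).append(rec)
    out = []
    for (chrom, strand), recs in sorted(by_key.items()):
        recs.sort(key=lambda r: r.interval.sort_key)
        spans = merge_intervals([(r.interval.start, r.interval.end) for r in recs])
        for s, e in spans:
            members = [r for r in recs if r.interval.start < e and r.interval.end > s]
            gene_ids = sorted({r.gene_id for r in members})
            prov = members[0].provenance if len(members) == 1 else "merged"
            out.append(
                IntronRecord(GenomicInterval(chrom, s, e, strand), ",".join(gene_ids), {}, prov)
            )
    return out


def subdivide_by_internal_junctions(
    introns: list[IntronRecord],
    junctions: list[JunctionRecord],
    min_reads: int = 5,
) -> list[IntronRecord]:
    """Split introns at junctions detected fully inside them; discard
    introns straddled by a junction (exactly one junction end inside).

    Only junctions meeting the support floor count as "detected".
    """
    usable = [j for j in junctions if j.unique_reads >= min_reads]
    out = []
    for rec in introns:
        iv = rec.interval
        cuts: list[tuple[int, int]] = []
        straddled = False
        for j in usable:
            if j.interval.chrom != iv.chrom:
                continue
            s_in = iv.start < j.interval.start < iv.end
            e_in = iv.start < j.interval.end < iv.end
            if s_in and e_in:
                cuts.append((j.interval.start, j.interval.end))
            elif s_in != e_in and j.interval.overlaps(iv):
                straddled = True
                break
        if straddled:
            continue
        if not cuts:
            out.append(rec)
            continue
        pieces = subtract_spans((iv.start, iv.end), cuts)
        for s, e in pieces:
            out.append(
                IntronRecord(
                    GenomicInterval(iv.chrom, s, e, iv.strand),
                    rec.gene_id,
                    {},
                    "subdivided",
                )
            )
    return out


def _bridging_support(
    intron: GenomicInterval, junctions: list[JunctionRecord]
) -> int:
    """Split reads bridging the intron: junctions whose excised span covers
    the (possibly merged or trimmed) intron piece. Support within a
    condition pools samples."""
    total = 0
    for j in junctions:
        if j.interval.chrom == intron.chrom and j.interval.start <= intron.start and j.interval.end >= intron.end:
            total += j.unique_reads
    return total


def filter_by_junction_support(
    introns: list[IntronRecord],
    junctions_by_condition: dict[str, list[JunctionRecord]],
    min_reads: int = 5,
) -> list[IntronRecord]:
    """Keep introns with >= ``min_reads`` bridging split reads in EVERY
    condition of the comparison, recording per-condition support."""
    if not junctions_by_condition:
        raise ValueError("at least one condition with junctions is required")
    out = []
    for rec in introns:
        support = {
            cond: _bridging_support(rec.interval, juncs)
            for cond, juncs in junctions_by_condition.items()
        }
        if all(v >= min_reads for v in support.values()):
            rec.support_by_condition = support
            out.append(rec)
    return out


def build_catalog(
    gene_models: dict[str, GeneModel],
    junctions_by_condition: dict[str, list[JunctionRecord]],
    config: CatalogConfig | None = None,
    coverage_by_sample: dict[str, dict[str, "object"]] | None = None,
) -> CatalogResult:
    """Run the full filter chain: subtract exons -> merge -> subdivide ->
    support filter -> length (and optional depth) floor.

    ``coverage_by_sample`` optionally maps sample -> {intron_id: CoverageTrack}
    for the mean-depth floor; when absent the depth floor is skipped.
    """
    cfg = config or CatalogConfig()
    introns = []
    exons = []
    for gid, model in gene_models.items():
        exons.extend(model.exons())
        for iv in model.introns():
            introns.append(IntronRecord(iv, gid))
    dropped: dict[str, int] = {}

    n0 = len(introns)
    introns = subtract_exons(introns, exons)
    introns = merge_overlapping(introns)
    dropped["exon_overlap_and_merge"] = n0 - len(introns)

    all_junctions = [j for js in junctions_by_condition.values() for j in js]
    n1 = len(introns)
    introns = subdivide_by_internal_junctions(introns, all_junctions, cfg.min_support)
    dropped["straddled"] = max(0, n1 - len(introns))

    n2 = len(introns)
    introns = filter_by_junction_support(introns, junctions_by_condition, cfg.min_support)
    dropped["unsupported"] = n2 - len(introns)

    n3 = len(introns)
    introns = [r for r in introns if len(r.interval) >= cfg.min_length]
    dropped["below_length_floor"] = n3 - len(introns)

    if coverage_by_sample:
        n4 = len(introns)
        kept = []
        for rec in introns:
            means = []
            for tracks in coverage_by_sample.values():
                tr = tracks.get(rec.intron_id)
                means.append(tr.values.mean() if tr is not None else 0.0)
            if all(m >= cfg.min_mean_depth for m in means):
                kept.append(rec)
        introns = kept
        dropped["below_depth_floor"] = n4 - len(introns)

    introns.sort(key=lambda r: r.interval.sort_key)
    result = CatalogResult(introns, dropped)
    if result.empty:
        logger.warning("intron catalog is empty after filtering: %s", dropped)
    return result
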
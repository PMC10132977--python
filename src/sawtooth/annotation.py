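"""Gene-annotation input: GTF reading and BED6 interval tables.

GTF is parsed through :mod:`gffutils` (in-memory database); coordinates are
converted from the 1-based inclusive GTF convention to the package-internal
0-based half-open convention at this boundary and nowhere else.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gffutils
import pandas as pd

from .intervals import GeneModel, GenomicInterval

_GTF_N_FIELDS = 9


def _validate_gtf_lines(path: str | Path) -> str:
    """Pre-scan a GTF file; return its content with unusable lines removed.

    Raises on a structurally malformed line (wrong field count), naming the
    line number. Lines lacking a ``gene_id`` attribute are skipped with a
    warning, as required records cannot be grouped without one.
    """
    kept: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != _GTF_N_FIELDS:
                raise ValueError(
                    f"malformed GTF line {lineno}: expected {_GTF_N_FIELDS} "
                    f"tab-separated fields, got {len(fields)}"
                )
            if "gene_id" not in fields[8]:
                warnings.warn(
                    f"GTF line {lineno} lacks gene_id; record skipped", stacklevel=2
                )
                continue
            kept.append(line)
    return "".join(kept)


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read exon features of a GTF file into :class:`GeneModel` objects.

    Returns a mapping from gene_id to model. GTF 1-based inclusive exon
    coordinates become 0-based half-open internally (start-1, end).
    """
    data = _validate_gtf_lines(path)
    models: dict[str, GeneModel] = {}
    if not data:
        return models
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    for feat in db.features_of_type("exon"):
        gene_id = feat.attributes["gene_id"][0]
        tx_ids = feat.attributes.get("transcript_id", [gene_id])
        biotype = (
            feat.attributes.get("gene_biotype") or feat.attributes.get("gene_type") or [""]
        )[0]
        model = models.get(gene_id)
        if model is None:
            model = GeneModel(gene_id, feat.seqid, feat.strand, biotype=biotype)
            models[gene_id] = model
        exon = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        for tx in tx_ids:
            model.add_exon(tx, exon)
    for model in models.values():
        model.finalize()
    return models


def write_bed6(intervals, path: str | Path, names=None, scores=None) -> None:
    """Write intervals as BED6 (0-based half-open, so no conversion)."""
    rows = []
    for i, iv in enumerate(intervals):
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "name": names[i] if names is not None else f"region_{i}",
                "score": scores[i] if scores is not None else 0,
                "strand": iv.strand,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> list[GenomicInterval]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]
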
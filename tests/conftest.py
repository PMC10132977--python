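import numpy as np
import pytest

from sawtooth import GeneModel, GenomicInterval
from sawtooth.junctions import JunctionRecord


def make_gene(gene_id, chrom, strand, exon_spans, tx_id=None):
    model = GeneModel(gene_id, chrom, strand)
    tx = tx_id or f"{gene_id}.t1"
    for s, e in exon_spans:
        model.add_exon(tx, GenomicInterval(chrom, s, e, strand))
    model.finalize()
    return model


@pytest.fixture
def toy_annotation():
    """Three genes / six introns exercising every catalog filter:

    gene A: two introns; a second-isoform exon pierces intron 1
            (exon subtraction); intron 2 is under-supported in one
            condition.
    gene B: one intron subdivided by an internal junction; one intron
            discarded for a straddling junction.
    gene C: minus strand, two cleanly supported introns (one at exactly
            the support threshold).
    """
    a = GeneModel("geneA", "chr1", "+")
    for s, e in [(0, 100), (200, 300), (400, 500)]:
        a.add_exon("geneA.t1", GenomicInterval("chr1", s, e, "+"))
    a.add_exon("geneA.t2", GenomicInterval("chr1", 130, 160, "+"))
    a.finalize()
    b = make_gene("geneB", "chr1", "+", [(1000, 1100), (2100, 2200)], "geneB.t1")
    b.add_exon("geneB.t2", GenomicInterval("chr1", 3000, 3100, "+"))
    b.add_exon("geneB.t2", GenomicInterval("chr1", 4100, 4200, "+"))
    b.finalize()
    c = make_gene("geneC", "chr2", "-", [(500, 600), (700, 800), (900, 1000)])
    return {"geneA": a, "geneB": b, "geneC": c}


def _j(chrom, start, end, reads, strand="+", sample=""):
    return JunctionRecord(GenomicInterval(chrom, start, end, strand), reads, sample)


@pytest.fixture
def toy_junctions():
    """Per-condition junction evidence matching ``toy_annotation``."""
    young = [
        _j("chr1", 100, 200, 7),
        _j("chr1", 300, 400, 7),
        _j("chr1", 1100, 2100, 8),
        _j("chr1", 1400, 1600, 9),   # internal -> subdivision
        _j("chr1", 3050, 3500, 6),   # straddles geneB intron 2
        _j("chr2", 600, 700, 10, "-"),
        _j("chr2", 800, 900, 5, "-"),
    ]
    old = [
        _j("chr1", 100, 200, 6),
        _j("chr1", 300, 400, 4),     # under-supported in old
        _j("chr1", 1100, 2100, 8),
        _j("chr1", 1400, 1600, 9),
        _j("chr1", 3050, 3500, 6),
        _j("chr2", 600, 700, 12, "-"),
        _j("chr2", 800, 900, 5, "-"),
    ]
    return {"young": young, "old": old}


EXPECTED_TOY_CATALOG = [
    ("chr1", 100, 130, "+"),
    ("chr1", 160, 200, "+"),
    ("chr1", 1100, 1400, "+"),
    ("chr1", 1600, 2100, "+"),
    ("chr2", 600, 700, "-"),
    ("chr2", 800, 900, "-"),
]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
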
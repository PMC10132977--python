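import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import sawtooth as st
from sawtooth.junctions import ChimericRecord, JunctionRecord
from sawtooth.splicing import (
    boundary_spanning_reads,
    build_intron_clusters,
    circ_ratio,
    extract_backsplices,
    gene_splicing_efficiency,
    rare_junction_fraction,
    splicing_efficiency,
)

from conftest import make_gene


def _j(start, end, reads, chrom="chr1"):
    return JunctionRecord(st.GenomicInterval(chrom, start, end, "+"), reads)


class TestSplicingEfficiency:
    @pytest.mark.parametrize(
        "spliced,unspliced,expected",
        [(30, 10, 0.75), (10, 0, 1.0), (0, 10, 0.0)],
    )
    def test_fraction_of_spliced_reads(self, spliced, unspliced, expected):
        assert splicing_efficiency(spliced, unspliced) == pytest.approx(expected)

    def test_zero_total_is_skipped_as_nan(self):
        assert np.isnan(splicing_efficiency(0, 0))

    @settings(derandomize=True, max_examples=50)
    @given(hst.integers(0, 1000), hst.integers(0, 1000), hst.integers(1, 20))
    def test_scale_invariance(self, s, u, c):
        if s + u == 0:
            return
        assert splicing_efficiency(s * c, u * c) == pytest.approx(
            splicing_efficiency(s, u)
        )

    def test_binomial_simulation_recovers_true_efficiency(self):
        cfg = st.SimulationConfig(seed=21, n_sites=100, site_depth=200,
                                  splicing_efficiency=0.8)
        sim = st.simulate_junction_counts(cfg)
        eff = gene_splicing_efficiency(sim.site_counts)
        assert abs(eff.mean() - 0.8) < 0.05

    def test_gene_modes_site_mean_vs_pooled(self):
        tab = pd.DataFrame(
            {"gene_id": ["g", "g"], "spliced": [90, 10], "unspliced": [10, 90]}
        )
        assert gene_splicing_efficiency(tab, mode="site_mean")["g"] == pytest.approx(0.5)
        assert gene_splicing_efficiency(tab, mode="pooled")["g"] == pytest.approx(0.5)

    def test_boundary_spanning_needs_min_overhang(self):
        blocks = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [94, 98], "end": [110, 110]}
        )
        # site at 100: first block has 6 bp on the left, second only 2
        assert boundary_spanning_reads(blocks, "chr1", 100, min_overhang=6) == 1


class TestIntronClusters:
    def test_shared_donor_clusters(self):
        clusters = build_intron_clusters([_j(100, 200, 5), _j(100, 300, 7)])
        assert len(clusters) == 1
        assert clusters[0].total_reads == 12

    def test_disjoint_junctions_are_singletons(self):
        clusters = build_intron_clusters([_j(100, 200, 5), _j(500, 600, 7)])
        assert len(clusters) == 2

    def test_transitive_chain_forms_one_cluster(self):
        chain = [_j(100, 200, 1), _j(100, 300, 2), _j(150, 300, 4)]
        clusters = build_intron_clusters(chain)
        assert len(clusters) == 1
        assert len(clusters[0].junctions) == 3

    def test_cluster_totals_conserve_read_sum(self):
        juncs = [_j(100, 200, 5), _j(100, 300, 7), _j(500, 600, 9), _j(550, 600, 1)]
        clusters = build_intron_clusters(juncs)
        assert sum(c.total_reads for c in clusters) == sum(j.unique_reads for j in juncs)


class TestRareJunctionFraction:
    def test_seven_permille_rule_on_cluster(self):
        # counts [1000, 5, 2]: threshold 0.007 * 1007 = 7.049 reads
        juncs = [_j(100, 200, 1000), _j(100, 300, 5), _j(100, 400, 2)]
        gmap = {("chr1", j.interval.start, j.interval.end): "g" for j in juncs}
        frac = rare_junction_fraction(build_intron_clusters(juncs), gmap)
        assert frac["g"] == pytest.approx(2 / 3)

    def test_balanced_cluster_has_no_rare_junctions(self):
        juncs = [_j(100, 200, 50), _j(100, 300, 50)]
        gmap = {("chr1", j.interval.start, j.interval.end): "g" for j in juncs}
        frac = rare_junction_fraction(build_intron_clusters(juncs), gmap)
        assert frac["g"] == 0.0

    def test_fraction_monotone_in_threshold(self):
        juncs = [_j(100, 200, 900), _j(100, 300, 60), _j(100, 400, 30), _j(100, 500, 10)]
        gmap = {("chr1", j.interval.start, j.interval.end): "g" for j in juncs}
        clusters = build_intron_clusters(juncs)
        fracs = [
            rare_junction_fraction(clusters, gmap, threshold=t).get("g", 0.0)
            for t in (0.001, 0.007, 0.05, 0.2)
        ]
        assert fracs == sorted(fracs)
        assert all(0 <= f <= 1 for f in fracs)

    def test_planted_rare_junction_recalled_from_simulation(self):
        cfg = st.SimulationConfig(seed=22, rare_abundance=0.001)
        sim = st.simulate_junction_counts(cfg)
        clusters = build_intron_clusters(sim.cluster_junctions)
        frac = rare_junction_fraction(clusters, sim.gene_of_junction)
        # each cluster gene has exactly one planted rare of two junctions
        assert np.allclose(frac.to_numpy(), 0.5)


class TestCircRatio:
    @pytest.mark.parametrize(
        "bs,s1,s2,expected",
        [(10, 20, 20, 100 / 3), (0, 15, 25, 0.0), (7, 0, 0, 100.0)],
    )
    def test_formula(self, bs, s1, s2, expected):
        assert circ_ratio(bs, s1, s2) == pytest.approx(expected)

    def test_all_zero_skipped(self):
        assert np.isnan(circ_ratio(0, 0, 0))

    @settings(derandomize=True, max_examples=50)
    @given(hst.integers(0, 500), hst.integers(0, 500), hst.integers(0, 500),
           hst.integers(1, 10))
    def test_scale_invariance(self, bs, s1, s2, c):
        if bs + s1 + s2 == 0:
            return
        assert circ_ratio(bs * c, s1 * c, s2 * c) == pytest.approx(circ_ratio(bs, s1, s2))


class TestExtractBacksplices:
    def _models(self):
        return {"g": make_gene("g", "chr1", "+", [(1000, 1500), (4000, 6000)])}

    def test_upstream_acceptor_is_backsplice(self):
        recs = [ChimericRecord("chr1", 5000, 2000, "+", 9)]
        out = extract_backsplices(recs, self._models())
        assert len(out) == 1
        assert out[0].bs == 9

    def test_forward_chimera_is_not_backsplice(self):
        recs = [ChimericRecord("chr1", 2000, 5000, "+", 9)]
        assert extract_backsplices(recs, self._models()) == []

    def test_cross_chromosome_discarded(self):
        models = self._models()
        models["g2"] = make_gene("g2", "chr2", "+", [(1000, 6000)])
        recs = [ChimericRecord("chr2", 5000, 2000, "+", 9)]
        out = extract_backsplices(recs, {"g": self._models()["g"]})
        assert out == []

    def test_simulated_circ_fraction_recovered_within_three_points(self):
        cfg = st.SimulationConfig(seed=23, circ_fraction=0.2, circ_linear_depth=500)
        sim = st.simulate_junction_counts(cfg)
        counts = extract_backsplices(sim.chimeric, sim.gene_models, sim.linear_junctions)
        ratios = [circ_ratio(c.bs, c.s1, c.s2) for c in counts]
        assert abs(np.mean(ratios) - 20.0) < 3.0
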
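import numpy as np
import pytest

import sawtooth as st
from sawtooth.junctions import read_star_junctions, write_star_junctions
from sawtooth.simulate import _expected_profile


class TestConfigValidation:
    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            st.SimulationConfig(initiation_rate=0.0)
        with pytest.raises(ValueError):
            st.SimulationConfig(speed_range=(0.0, 100.0))
        with pytest.raises(ValueError):
            st.SimulationConfig(noise="gaussian")


class TestDeterminism:
    def test_identical_seed_gives_bitwise_identical_outputs(self):
        a = st.simulate_sawtooth_sample(st.SimulationConfig(n_introns=20, seed=9))
        b = st.simulate_sawtooth_sample(st.SimulationConfig(n_introns=20, seed=9))
        assert a.truth.equals(b.truth)
        for iid in a.tracks:
            assert np.array_equal(a.tracks[iid].values, b.tracks[iid].values)
        assert [(j.interval, j.unique_reads) for j in a.junctions] == [
            (j.interval, j.unique_reads) for j in b.junctions
        ]

    def test_different_seed_differs(self):
        a = st.simulate_sawtooth_sample(st.SimulationConfig(n_introns=20, seed=9))
        b = st.simulate_sawtooth_sample(st.SimulationConfig(n_introns=20, seed=10))
        assert not a.truth.equals(b.truth)

    def test_condition_pair_samples_reproducible(self):
        cfg = st.SimulationConfig(n_introns=10, seed=9)
        p1 = st.simulate_condition_pair(cfg, 0.5, 1.5, 2)
        p2 = st.simulate_condition_pair(cfg, 0.5, 1.5, 2)
        t1 = p1.sample_tracks("B", 1)
        t2 = p2.sample_tracks("B", 1)
        for iid in t1:
            assert np.array_equal(t1[iid].values, t2[iid].values)


class TestSawtoothClosedForms:
    def test_noiseless_profile_is_exact_line(self):
        # depth 200 at the intron 5' end falling to baseline at the 3' end
        cfg = st.SimulationConfig(noise="none")
        prof = _expected_profile(10_000, k=1.0, n=0.02 / cfg.depth_scale, config=cfg)
        assert prof[0] == pytest.approx(cfg.baseline_depth + 0.02 * 10_000)
        assert prof[-1] == pytest.approx(cfg.baseline_depth + 0.02)
        diffs = np.diff(prof)
        assert np.allclose(diffs, -0.02)

    def test_infinite_speed_limit_is_flat_baseline(self):
        cfg = st.SimulationConfig(noise="none", baseline_depth=3.0)
        prof = _expected_profile(5_000, k=1e12, n=2.0, config=cfg)
        assert np.allclose(prof, 3.0, atol=1e-6)

    def test_minus_strand_coverage_is_genomically_mirrored(self):
        cfg = st.SimulationConfig(n_introns=40, noise="none", seed=14)
        sim = st.simulate_sawtooth_sample(cfg)
        minus = sim.truth[sim.truth.strand == "-"]
        assert len(minus) > 0
        for row in minus.itertuples():
            vals = sim.tracks[row.intron_id].values
            assert vals[-1] > vals[0]  # 5' end of a minus-strand gene sits right


class TestConditionPairBookkeeping:
    def test_effect_zero_shares_speeds(self):
        pair = st.simulate_condition_pair(
            st.SimulationConfig(n_introns=50, seed=15), effect=0.0, fold=2.0
        )
        assert np.array_equal(pair.truth["k_a"], pair.truth["k_b"])
        assert not pair.truth["affected"].any()

    def test_effect_one_doubles_every_speed(self):
        pair = st.simulate_condition_pair(
            st.SimulationConfig(n_introns=50, seed=15), effect=1.0, fold=2.0
        )
        assert np.allclose(np.log2(pair.truth["k_b"] / pair.truth["k_a"]), 1.0)

    def test_partial_effect_flags_expected_fraction(self):
        pair = st.simulate_condition_pair(
            st.SimulationConfig(n_introns=2_000, intron_length_range=(100, 200), seed=15),
            effect=0.7, fold=1.2,
        )
        assert pair.truth["affected"].mean() == pytest.approx(0.7, abs=0.03)

    def test_invalid_effect_rejected(self):
        with pytest.raises(ValueError):
            st.simulate_condition_pair(st.SimulationConfig(n_introns=5), 1.5, 2.0)


class TestGeneratedTablesRoundTrip:
    def test_junction_table_accepted_by_reader_unchanged(self, tmp_path):
        sim = st.simulate_sawtooth_sample(st.SimulationConfig(n_introns=15, seed=16))
        p = tmp_path / "SJ.out.tab"
        write_star_junctions(sim.junctions, p)
        back = read_star_junctions(p)
        assert [(r.interval, r.unique_reads) for r in back] == [
            (r.interval, r.unique_reads) for r in sim.junctions
        ]

    def test_nucleosome_bedgraph_round_trips_to_same_track(self, tmp_path):
        cfg = st.SimulationConfig(seed=17)
        region = st.GenomicInterval("chrN", 0, 3_000)
        sim = st.simulate_nucleosome_coverage(cfg, [region])
        p = tmp_path / "mnase.bedgraph"
        st.write_bedgraph(sim.bedgraph, p)
        dense = st.track_from_bedgraph(st.read_bedgraph(p), region)
        assert np.array_equal(dense.values, sim.tracks["chrN:0-3000"].values)


class TestJunctionCountSimulation:
    def test_efficiency_one_gives_zero_unspliced(self):
        cfg = st.SimulationConfig(seed=18, splicing_efficiency=1.0)
        sim = st.simulate_junction_counts(cfg)
        assert (sim.site_counts["unspliced"] == 0).all()

    def test_circ_fraction_zero_gives_no_chimeric_records(self):
        cfg = st.SimulationConfig(seed=18, circ_fraction=0.0)
        sim = st.simulate_junction_counts(cfg)
        assert sim.chimeric == []

    def test_planted_rare_abundance_below_rule(self):
        cfg = st.SimulationConfig(seed=18, rare_abundance=0.001)
        sim = st.simulate_junction_counts(cfg)
        planted = sim.rare_truth[sim.rare_truth["planted_rare"]]
        assert (planted["relative_abundance"] <= 0.007).all()


class TestNucleosomeSimulation:
    def test_zero_fuzziness_concentrates_counts_on_dyads(self):
        cfg = st.SimulationConfig(seed=19, nucleosome_fuzziness_sd=0.0)
        region = st.GenomicInterval("chrN", 0, 2_000)
        sim = st.simulate_nucleosome_coverage(cfg, [region])
        track = sim.tracks["chrN:0-2000"]
        nonzero = np.nonzero(track.values)[0]
        dyads = np.round(sim.truth.iloc[0]["dyad_positions"]).astype(int)
        assert sorted(nonzero) == sorted(set(dyads))
        assert np.all(track.values[nonzero] == cfg.fragments_per_nucleosome)

    def test_mean_planted_spacing_near_config(self):
        cfg = st.SimulationConfig(seed=19)
        regions = [st.GenomicInterval("chrN", i * 5_000, i * 5_000 + 4_000) for i in range(25)]
        sim = st.simulate_nucleosome_coverage(cfg, regions)
        assert np.nanmean(sim.truth["mean_spacing"]) == pytest.approx(185.0, abs=2.0)

    def test_halved_density_halves_dyad_count(self):
        cfg = st.SimulationConfig(seed=19)
        region = st.GenomicInterval("chrN", 0, 10_000)
        full = st.simulate_nucleosome_coverage(cfg, [region], density_per_kb=4.0)
        half = st.simulate_nucleosome_coverage(cfg, [region], density_per_kb=2.0)
        assert half.truth.iloc[0]["n_dyads"] * 2 == full.truth.iloc[0]["n_dyads"]


class TestFoursuSimulation:
    def test_time_zero_has_no_advanced_labelled_span(self):
        cfg = st.SimulationConfig(seed=20, noise="none")
        sim = st.simulate_foursu_timecourse(cfg)
        t0 = sim.reads[(sim.reads["time"] == 0) & sim.reads["labelled"]]
        assert (t0["offset"] == 0).all()

    def test_true_front_is_k_times_t(self):
        cfg = st.SimulationConfig(seed=20, noise="none")
        sim = st.simulate_foursu_timecourse(cfg)
        row = sim.truth.iloc[sim.truth["length"].idxmax()]
        reads = sim.reads[(sim.reads["gene_id"] == row["gene_id"]) & (sim.reads["time"] == 30)]
        assert reads["offset"].max() == pytest.approx(min(row["k"] * 30, row["length"]))
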
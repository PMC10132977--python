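import numpy as np
import pytest

import sawtooth as st
from sawtooth.catalog import IntronRecord
from sawtooth.speed import fit_intron_slope


def _track(values, strand="+", chrom="chr1", start=0):
    iv = st.GenomicInterval(chrom, start, start + len(values), strand)
    return st.CoverageTrack(iv, np.asarray(values, dtype=float))


def _catalog_records(truth):
    return [
        IntronRecord(st.GenomicInterval(r.chrom, r.start, r.end, r.strand), "g")
        for r in truth.itertuples()
    ]


class TestFitIntronSlope:
    def test_exact_line_recovers_slope_and_proxy(self):
        x = np.arange(10_000)
        est = fit_intron_slope(_track(200 - 0.02 * x))
        assert est.slope == pytest.approx(-0.02)
        assert est.speed_proxy == pytest.approx(50.0)
        assert est.r_squared == pytest.approx(1.0)
        assert est.valid

    def test_minus_strand_reversed_before_fitting(self):
        x = np.arange(10_000)
        plus = fit_intron_slope(_track(200 - 0.02 * x, "+"))
        minus = fit_intron_slope(_track((200 - 0.02 * x)[::-1], "-"))
        assert minus.slope == pytest.approx(plus.slope)
        assert minus.speed_proxy == pytest.approx(plus.speed_proxy)

    def test_flat_coverage_invalid_not_exception(self):
        est = fit_intron_slope(_track(np.full(1000, 5.0)))
        assert est.slope == pytest.approx(0.0)
        assert not est.valid
        assert np.isnan(est.speed_proxy)

    def test_all_zero_track_invalid(self):
        est = fit_intron_slope(_track(np.zeros(1000)))
        assert not est.valid

    def test_depth_scaling_halves_proxy(self):
        x = np.arange(5_000)
        base = 100 - 0.01 * x
        e1 = fit_intron_slope(_track(base))
        e2 = fit_intron_slope(_track(2 * base))
        assert e2.slope == pytest.approx(2 * e1.slope)
        assert e2.speed_proxy == pytest.approx(e1.speed_proxy / 2)


class TestEstimateSampleSpeeds:
    def test_noiseless_proxies_proportional_to_k_over_n(self):
        cfg = st.SimulationConfig(n_introns=30, noise="none", seed=7)
        sim = st.simulate_sawtooth_sample(cfg)
        recs = _catalog_records(sim.truth)
        est = st.estimate_sample_speeds(recs, sim.tracks)
        joined = est.join(sim.truth.set_index("intron_id"))
        expected = joined["k"] / (joined["n"] * cfg.depth_scale)
        assert np.allclose(joined["speed_proxy"], expected, rtol=1e-6)

    def test_missing_tracks_become_invalid_rows(self):
        cfg = st.SimulationConfig(n_introns=5, noise="none", seed=7)
        sim = st.simulate_sawtooth_sample(cfg)
        recs = _catalog_records(sim.truth)
        est = st.estimate_sample_speeds(recs, {})
        assert len(est) == 5
        assert not est["valid"].any()

    def test_rpm_rescaling_leaves_log2fc_unchanged(self):
        cfg = st.SimulationConfig(n_introns=40, seed=8)
        pair = st.simulate_condition_pair(cfg, effect=0.5, fold=1.5, n_replicates=1)
        recs = _catalog_records(pair.truth)
        a = [st.estimate_sample_speeds(recs, pair.sample_tracks("A", 0))]
        b = [st.estimate_sample_speeds(recs, pair.sample_tracks("B", 0))]
        cmp1 = st.compare_conditions(a, b)
        # scale both samples' coverage uniformly (same RPM factor)
        a2 = [df.assign(speed_proxy=df["speed_proxy"] / 3.0) for df in a]
        b2 = [df.assign(speed_proxy=df["speed_proxy"] / 3.0) for df in b]
        cmp2 = st.compare_conditions(a2, b2)
        assert np.allclose(
            cmp1.per_intron["log2fc"].dropna(), cmp2.per_intron["log2fc"].dropna()
        )


class TestCompareConditions:
    def _est(self, proxies):
        import pandas as pd

        return pd.DataFrame(
            {
                "speed_proxy": proxies,
                "valid": np.isfinite(proxies),
            },
            index=[f"i{j}" for j in range(len(proxies))],
        )

    def test_identical_conditions_zero_pseudomedian(self):
        a = self._est(np.linspace(1, 10, 20))
        cmp = st.compare_conditions([a], [a.copy()])
        assert np.allclose(cmp.per_intron["log2fc"], 0)
        assert cmp.summary.pseudo_median == pytest.approx(0.0)

    def test_uniform_doubling_gives_log2fc_one(self):
        a = self._est(np.linspace(1, 10, 20))
        b = self._est(np.linspace(1, 10, 20) * 2)
        cmp = st.compare_conditions([a], [b])
        assert np.allclose(cmp.per_intron["log2fc"], 1.0)
        assert cmp.summary.pseudo_median == pytest.approx(1.0)

    def test_consistent_flag_requires_sign_agreement_across_pairings(self):
        a1 = self._est(np.array([1.0, 1.0]))
        a2 = self._est(np.array([1.2, 1.2]))
        # intron 0: both B reps above all A reps; intron 1: B reps straddle A
        b1 = self._est(np.array([2.0, 1.1]))
        b2 = self._est(np.array([2.5, 1.3]))
        with pytest.warns(UserWarning, match="unreliable"):
            cmp = st.compare_conditions([a1, a2], [b1, b2])
        assert cmp.per_intron["consistent"].tolist() == [True, False]


class TestSpeedSignatureCluster:
    def _sim_estimates(self, seed, fold=1.0):
        cfg = st.SimulationConfig(n_introns=60, intron_length_range=(1000, 3000), seed=seed)
        pair = st.simulate_condition_pair(cfg, effect=1.0, fold=fold, n_replicates=2)
        recs = _catalog_records(pair.truth)
        out = {}
        for cond in ("A", "B"):
            for rep in range(2):
                out[f"{cond}{rep}"] = st.estimate_sample_speeds(
                    recs, pair.sample_tracks(cond, rep)
                )
        return out

    def test_conditions_partition_at_top_split(self):
        ests = self._sim_estimates(seed=11, fold=3.0)
        linkage, order = st.speed_signature_cluster(ests)
        # the top split separates A replicates from B replicates
        half = len(order) // 2
        sides = {tuple(sorted(order[:half])), tuple(sorted(order[half:]))}
        assert sides == {("A0", "A1"), ("B0", "B1")}

    def test_duplicated_sample_has_zero_distance(self):
        ests = self._sim_estimates(seed=12)
        ests["A0_twin"] = ests["A0"].copy()
        linkage, order = st.speed_signature_cluster(ests)
        i, j = order.index("A0"), order.index("A0_twin")
        assert abs(i - j) == 1  # twins are adjacent leaves
        assert linkage[:, 2].min() == pytest.approx(0.0, abs=1e-12)

    def test_two_samples_single_join(self):
        ests = self._sim_estimates(seed=13)
        two = {k: ests[k] for k in ("A0", "B0")}
        linkage, order = st.speed_signature_cluster(two)
        assert linkage.shape == (1, 4)
        assert sorted(order) == ["A0", "B0"]
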
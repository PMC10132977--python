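"""Compare elongation speed between two conditions (e.g. young vs old).

Simulates a paired design in which 70% of introns elongate 1.2-fold faster
in condition B, with three replicates per condition, then reports the
Hodges-Lehmann pseudo-median of per-intron log2 fold changes, its 95% CI
and the two-sided paired Wilcoxon signed-rank p-value.
"""

import sawtooth as st
from sawtooth.catalog import IntronRecord

cfg = st.SimulationConfig(n_introns=400, seed=2)
pair = st.simulate_condition_pair(cfg, effect=0.7, fold=1.2, n_replicates=3)
records = [
    IntronRecord(st.GenomicInterval(r.chrom, r.start, r.end, r.strand), "g")
    for r in pair.truth.itertuples()
]
est_a = [st.estimate_sample_speeds(records, pair.sample_tracks("A", i)) for i in range(3)]
est_b = [st.estimate_sample_speeds(records, pair.sample_tracks("B", i)) for i in range(3)]

cmp = st.compare_conditions(est_a, est_b)
s = cmp.summary
print(f"introns compared: {s.n}")
print(f"pseudo-median log2FC: {s.pseudo_median:.3f} (95% CI {s.ci_low:.3f}..{s.ci_high:.3f})")
print(f"paired Wilcoxon p: {s.p_value:.2e}")
cons = st.compare_conditions(est_a, est_b, consistent_only=True)
print(f"restricted to introns consistent across all replicate pairings "
      f"(n={cons.summary.n}): pseudo-median {cons.summary.pseudo_median:.3f}")
print("-> a positive pseudo-median means faster average elongation in B; "
      "log2(1.2)=0.263 is the planted per-intron effect.")
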
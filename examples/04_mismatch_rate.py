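"""Expression-normalized per-gene mismatch rate with error filters.

Simulates reads over a gene with a 5e-5 per-base error rate, planted SNP
positions (recurrent mismatches) and indel-carrying reads, then applies the
filter chain (indel reads out, end-proximal mismatches out, recurrent
positions out, coverage >= 100) and reports the recovered rate.
"""

import sawtooth as st
from sawtooth.mismatch import collect_mismatches, gene_mismatch_rate

cfg = st.SimulationConfig(seed=4, mismatch_error_rate=5e-5, mismatch_depth=200)
sim = st.simulate_mismatch_reads(cfg)
passing = collect_mismatches(sim.reads, sim.mismatches)
rate = gene_mismatch_rate(passing, sim.depth, "mmGene")

snp_leaked = set(passing["genome_pos"]) & set(sim.truth["snp_positions"])
print(f"planted per-base error rate: {cfg.mismatch_error_rate:.1e}")
print(f"passing mismatches: {rate.n_mismatches} over "
      f"{rate.n_qualifying_bases} sequenced bases -> rate {rate.rate:.2e}")
print(f"planted SNP positions leaking into the numerator: {len(snp_leaked)}")
print("-> the rate approximates the true error frequency (interior read "
      "positions only) while the recurrence filter removes genetic variants.")
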
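"""Absolute elongation rates (bp/min) from a 4sU/DRB release time course.

Simulates conversion-labelled reads at 0/15/30/45 min after transcription
release, classifies labelled read pairs (>= 3 T->C or A->G conversions),
tracks the 99th-percentile polymerase front per gene and time point, and
recovers rates with the linear-fit (genes >= 100 kb) estimator.
"""

import numpy as np

import sawtooth as st

cfg = st.SimulationConfig(seed=5)
sim = st.simulate_foursu_timecourse(cfg)
labelled = st.classify_labelled(sim.reads)
print(f"{len(labelled)} of {len(sim.reads)} read pairs classified as 4sU-labelled")

errs = []
example_shown = False
for row in sim.truth[sim.truth["length"] >= 100_000].itertuples():
    traj = st.rate_linear_fit(st.build_trajectory(labelled, row.gene_id, int(row.length)))
    if not traj.valid:
        continue
    errs.append(abs(traj.rate - row.k) / row.k)
    if not example_shown:
        fronts = {t: round(f) for t, f in sorted(traj.fronts.items())}
        print(f"{row.gene_id} ({row.length/1000:.0f} kb): fronts {fronts} bp")
        print(f"  fitted rate {traj.rate:.0f} bp/min (truth {row.k:.0f})")
        example_shown = True

print(f"median relative error over {len(errs)} genes >= 100 kb: "
      f"{np.median(errs):.1%}")
print("-> the front advances ~k bp per minute; the linear fit across four "
      "time points recovers the elongation rate.")
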
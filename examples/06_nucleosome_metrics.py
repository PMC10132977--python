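"""Nucleosome positioning metrics from MNase fragment-midpoint coverage.

Simulates phased nucleosome arrays (spacing 185 +- 10 bp), calls summits,
and reports density, sharpness and inter-summit distances; then shows the
PCA ordination separating two conditions that differ in fuzziness.
"""

import numpy as np
import pandas as pd

import sawtooth as st

regions = [st.GenomicInterval("chrN", i * 5_000, i * 5_000 + 4_000) for i in range(40)]
cfg = st.SimulationConfig(seed=6)
sim = st.simulate_nucleosome_coverage(cfg, regions)

dists, sharps, dens = [], [], []
for tr in sim.tracks.values():
    sig = st.feature_signatures(st.call_peaks(tr), [tr.interval])[0]
    dens.append(sig.density)
    if np.isfinite(sig.mean_summit_distance):
        dists.append(sig.mean_summit_distance)
    if np.isfinite(sig.mean_sharpness):
        sharps.append(sig.mean_sharpness)
print(f"mean nucleosome density: {np.mean(dens)*1000:.2f} peaks/kb")
print(f"mean inter-summit distance: {np.mean(dists):.1f} bp (planted 185)")
print(f"mean peak sharpness (height/width): {np.mean(sharps):.3f}")

# two conditions, three pseudo-samples each, differing in positioning fuzziness
rows = {}
for cond, fuzz in (("prolif", 15.0), ("senesc", 30.0)):
    for rep in range(3):
        c = st.SimulationConfig(seed=100 + rep, nucleosome_fuzziness_sd=fuzz)
        s = st.simulate_nucleosome_coverage(c, regions[:20])
        sig = [
            st.feature_signatures(st.call_peaks(tr), [tr.interval])[0].mean_sharpness
            for tr in s.tracks.values()
        ]
        rows[f"{cond}{rep}"] = sig
coords, evr, _ = st.signature_ordination(pd.DataFrame(rows).T)
print("\nPCA of per-sample sharpness signatures "
      f"(PC1 explains {evr[0]:.0%} of variance):")
print(coords.round(2))
print("-> fuzzier (senescent-like) samples separate from well-positioned "
      "ones along PC1; lower sharpness = less precise positioning.")
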
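# sawtooth

Transcription-kinetics analysis for bulk RNA-seq and companion assays:
estimate RNA polymerase II (Pol II) elongation speed, quantify transcript
fidelity, and measure nucleosome positioning — with a synthetic-data module
that generates every input with known ground truth.

## Who this is for

Groups studying how transcriptional elongation changes between conditions
(ageing, senescence, lifespan interventions, drug treatment) from standard
total/nascent RNA-seq, 4sU/DRB pulse time courses and MNase-seq — without
needing nascent-specific protocols like GRO-seq for the core readout.

## The models

**Intronic slope → relative speed.** Co-transcriptional splicing leaves a
"sawtooth" coverage profile in introns: nascent transcripts interrupted
mid-intron make read depth fall linearly 5′→3′. At steady state, with
initiation rate *n* (min⁻¹) and elongation speed *k* (bp min⁻¹), the slope
of depth versus position is

    s = −n / k        ⇒        k = −n / s

so −1/s is a relative speed proxy (∝ k/n). The package fits *s* by OLS over
each intron of a rigorously filtered catalog (exon-overlap subtraction,
merging, subdivision at internal junctions, discarding junction-straddled
introns, ≥5 bridging split reads per condition, length/depth floors) and
contrasts conditions on the same catalog with the Hodges–Lehmann
pseudo-median of per-intron log2 fold changes, its 95% signed-rank CI and a
two-sided paired Wilcoxon test.

**4sU/DRB front tracking → absolute rate.** DRB synchronizes Pol II at
promoters; after release, 4sU labels nascent RNA, read out as T→C (A→G)
conversions. Read pairs with ≥3 conversions are labelled; the wave front at
each time point (0/15/30/45 min) is the 99th percentile of labelled-read
positions. Rates come from an OLS fit of front vs time within the first
100 kb (genes ≥ 100 kb) or from two fronts 15 min apart (15/30 min for
30–100 kb genes, 30/45 min beyond 100 kb).

**Fidelity metrics.** Splicing efficiency = spliced / (spliced + unspliced)
reads at a splice site; rare junctions = junctions carrying ≤0.7% of their
alternatively-excised intron cluster's reads, summarized per gene; circRNA
index = BS/(BS + (S1+S2)/2) × 100 from back-spliced (BS) and flanking linear
(S1, S2) read counts; per-gene mismatch rate after filtering indel reads,
read-end-proximal calls, recurrent (SNP-like) positions and low-coverage
bases.

**Nucleosomes.** From MNase fragment-midpoint coverage: summit calling,
density (peaks/bp of exon or intron), sharpness (peak height / width),
inter-summit spacing, and PCA of per-sample signatures.

## Worked example

```bash
python examples/02_condition_comparison.py
```

```
introns compared: 400
pseudo-median log2FC: 0.237 (95% CI 0.135..0.259)
paired Wilcoxon p: 3.26e-54
restricted to introns consistent across all replicate pairings (n=291): pseudo-median 0.262
```

The simulation plants a 1.2-fold speed-up (log2 = 0.263) in 70% of introns;
the pseudo-median of per-intron log2 fold changes lands near the planted
mixture average, tightens to the planted value when restricted to introns
whose direction of change agrees across every replicate pairing, and the
paired Wilcoxon test rejects no-change decisively. The other examples
(`examples/01…06`) walk through slope fitting, fidelity metrics, mismatch
rates, 4sU rate recovery and nucleosome signatures the same way.

A minimal API session:

```python
import sawtooth as st

cfg = st.SimulationConfig(n_introns=200, seed=1)
sim = st.simulate_sawtooth_sample(cfg)          # tracks + junctions + truth
est = st.fit_intron_slope(next(iter(sim.tracks.values())))
print(est.slope, est.speed_proxy, est.valid)
```

Real data enter through the same containers: `read_gene_models` (GTF),
`read_star_junctions` (STAR `SJ.out.tab`), `extract_coverage` (SAM/BAM),
`read_chimeric_table`, `read_bedgraph`.

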
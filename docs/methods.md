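# Methods

This note records the models implemented in `sawtooth`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic data
do and do not emulate, and the numerical choices a maintainer would need to
know. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` compute.

## Steady-state slope model

An intron of length *L* is transcribed by polymerases moving at a common
speed *k* (bp/min) initiated at rate *n* (min⁻¹); premature termination
inside the intron is neglected. A polymerase needs Δt = L/k to traverse the
intron, so N = Δt·n polymerases are inside it at steady state, distributed
uniformly along it. Expected nascent-transcript depth therefore falls
linearly from (n/k)·L at the intron 5′ end to 0 at its 3′ end: the fitted
slope is s = −n/k and k = −n/s.

Consequences built into the API:

* **Only relative speeds are reported from slopes.** −1/s ∝ k/n; *n* is
  unknown, so absolute *k* is never derived from a slope. Condition ratios
  assume *n* is stable between conditions (logged at import of
  `sawtooth.speed`). Absolute rates come from the 4sU/DRB assay instead.
* **Slopes are fitted on linear depth** (raw or RPM — the choice cancels in
  ratios) over every base of the filtered intron, by ordinary least
  squares; the model is linear in depth, so log-transforming would bias it.
  Edges are not trimmed. Minus-strand tracks are reversed before fitting so
  slopes are always in transcription direction.
* A non-negative fitted slope, an all-zero track or a missing track yields
  an *invalid* estimate (flagged row), never an exception, so per-sample
  estimate tables stay aligned with the shared catalog.

## Intron catalog

Filter chain, in order: (1) subtract all annotated exons from per-transcript
introns; (2) merge overlapping — and abutting, since half-open abutting
spans are contiguous sequence — intronic regions per chromosome and strand;
(3) subdivide introns at junctions detected fully inside them and discard
introns straddled by a junction (one end inside); (4) keep introns with ≥5
bridging split reads (junction span covering the intron piece, samples
pooled within condition) in **every** condition of the comparison; (5) drop
pieces shorter than 600 bp and, when coverage is supplied, below mean raw
depth 10 in any sample. The order is fixed because subdivision must see
merged coordinates and support is only meaningful on final pieces. One
catalog is built per comparison and reused for both conditions, so the same
intron set is always contrasted; the build is symmetric in condition order.
The length/depth floors are explicit stand-ins for "reliable
quantification" quality criteria and are configurable (`CatalogConfig`).

## Paired condition statistics

Every condition contrast (speed proxies, splicing efficiency, circRNA
index, mismatch rate, nucleosome signatures) uses one machinery
(`sawtooth.stats`): the Hodges–Lehmann pseudo-median of paired differences
(median of Walsh averages), its 95% CI from order statistics of the Walsh
averages at signed-rank critical values (as in R's
`wilcox.test(conf.int=TRUE)`), and the two-sided paired Wilcoxon
signed-rank p (zeros dropped, average ranks for ties; exact null for small
tie-free samples, normal approximation otherwise). The signed-rank null CDF
is computed exactly by dynamic programming up to n = 500, beyond which the
normal approximation is used. Contrasts of speed proxies are on the log2
scale (fold changes); contrasts of absolute 4sU rates are on the
difference scale (bp/min). Fewer than 6 valid pairs triggers a
small-sample warning rather than a refusal. "Consistent" introns are those
whose B−A difference has the same sign for **every** cross-condition
replicate pairing — equivalently min(B) > max(A) or max(B) < min(A) — the
strictest reading of "always up or down". Replicates are aggregated by the
arithmetic mean of proxies.

## 4sU/DRB front tracking

Read pairs are labelled when they carry ≥3 T→C or A→G conversions (the two
orientations correspond to which mate reports the sense strand); other
substitutions never count, and unstranded input is rejected because
conversion orientation is undefined. The conversion-poor 5-min time point
is excluded by default. A no-conversion negative control should have a
labelled fraction ≲1% (`qc_negative_control`).

The polymerase front at a time point is the 99th percentile of
labelled-read 5′ offsets — a percentile of *positions*, not of the depth
distribution: the intent is a robust front location, and the last read
would be too noise-sensitive. Fronts need ≥20 labelled reads (configurable)
or are undefined. Rates: (a) OLS of front vs time over 0/15/30/45 min with
fronts capped at 100 kb, restricted to genes ≥100 kb (shorter genes finish
transcribing within the chase); a numerically flat fit (|slope| < 1e-9) is
snapped to zero and flagged invalid, as is any negative slope; (b) the
two-point estimator, (front_late − front_early)/15 min, using 15/30 min for
30–100 kb genes and 30/45 min above 100 kb; genes <30 kb are excluded.
Non-monotone front trajectories are logged, never silently repaired. In
noise-free simulation the true front is the labelled-read maximum, so
exactness checks use percentile 100; with noise the 99th percentile carries
a ~1% downward bias, negligible against the 15% recovery tolerance.

## Fidelity metrics

* **Splicing efficiency** = spliced/(spliced+unspliced) per site; zero
  totals are flagged and skipped. "Unspliced" evidence at a site counts
  reads continuously spanning the exon–intron boundary with ≥6 bp on each
  side (configurable; an explicit choice, since no overhang rule is
  standard). Per-gene values average site efficiencies by default; pooling
  counts first is available (`mode="pooled"`) since both readings of a
  per-gene summary are defensible.
* **Rare junctions**: intron clusters are connected components of junctions
  sharing a donor or acceptor coordinate (union–find); a junction is rare
  iff its reads ≤ 0.7% × cluster total (inclusive), and the per-gene
  fraction is rare/total junctions of that gene. Only cluster construction
  and this statistic are implemented — not a full alternative-splicing
  differential pipeline. Junctions are assigned to a gene when both ends
  fall inside exactly one gene span; ambiguous ones are dropped and
  counted.
* **circRNA index** = BS/(BS + (S1+S2)/2) × 100. A chimeric record is a
  back-splice iff both breakpoints lie in one gene and the acceptor
  precedes the donor in transcription direction. S1/S2 are linear spliced
  reads whose acceptor/donor coincides with the circularized exon
  boundaries. All-zero loci are skipped. Chimeric input is a compact
  5-column TSV (chrom, donor, acceptor, strand, reads) summarizing an
  aligner's per-read chimeric output.
* **Mismatch rate**: filters in order — drop indel-carrying reads; drop
  mismatches within 4 bp of either read end (kept iff offset ≥5 from both
  ends, in read coordinates after clipping); drop genomic positions
  (chromosome-aware) mismatched in ≥2 reads (candidate SNPs / editing);
  apply the depth ≥100 floor. The per-gene rate divides passing mismatches
  at qualifying positions by the **total sequenced bases** at those
  positions (sum of depth), making it a per-sequenced-base error frequency
  that is normalized for expression and directly comparable to a per-base
  error rate; counting qualifying *positions* instead is available via
  `denominator="positions"`. Extraction is native from MD-tagged
  alignments (pysam); no external mutation caller is wrapped.

## Nucleosome metrics

A deliberately minimal summit caller stands in for a full positioning
suite, because only three downstream statistics are in scope. Coverage is
Gaussian-smoothed (sd 20 bp ≈ linker scale); local maxima ≥25% of the
smoothed track maximum and ≥50 bp apart become summits; peak width is the
sd of raw-coverage-weighted positions within ±73 bp (half the 147-bp core
footprint); height is the smoothed depth at the summit. Sharpness is
height/width by default — the simplest combination that rises with height
and falls with width; height/width² is available and every constant is
configurable. Per-feature signatures: density = summits per bp, mean
sharpness, mean consecutive-summit distance (undefined under two summits,
flagged). Sample ordination is PCA on centred, unit-scaled signature
vectors with a deterministic sign convention (largest-magnitude loading
positive); constant or missing features are dropped, and <3 samples or <2
usable features raise an error.

## Synthetic data: what it emulates, and what it does not

The generator (`sawtooth.simulate`) reproduces the *data model* of each
assay with known truth; all randomness derives from one seed via numpy seed
sequences, so outputs are bitwise reproducible.

* **Sawtooth coverage**: expected depth baseline + scale·(n/k)·(L−x) along
  transcription direction, mirrored genomically on minus strands;
  independent per-base Poisson counting noise (fragment-level effects —
  read length, paired-end correlation, GC/PCR bias, isoform mixtures — are
  not modelled, so passing tests show estimator correctness under the
  counting model, not robustness to library artefacts). Defaults: 200
  introns of 1–20 kb, speed loguniform over the 5-fold range 500–2,500
  bp/min (physiological Pol II scale), constant initiation rate n = 2/min,
  depth scale 6 (interquartile mean intron depth ≈29–89×, median ≈53×),
  baseline 0.5. Initiation is held constant across introns so that the
  proxy −1/s ranks introns by k; consequently 5′ depth covaries with k and
  L, which is exactly the coupling the real assay has.
* **Condition pairs**: a fraction `effect` of introns gets k×`fold` in
  condition B; replicate noise independent; samples generated lazily and
  deterministically per (condition, replicate) so large designs hold one
  sample in memory at a time.
* **Junction counts**: binomial spliced/unspliced splits at depth ~200;
  circRNA loci as two-exon genes with back-splice counts at the planted
  circularization fraction; clusters of one dominant plus one planted rare
  junction (default 0.1% relative abundance, clearly below the 0.7% rule).
* **Mismatch reads**: errors at distinct genomic positions, one read each
  (so the recurrence filter removes only planted SNPs); SNP positions
  mismatching in every covering read; 2% of reads carry indels. The
  recoverable truth after end-trimming is the error rate × (read_length −
  10)/read_length.
* **4sU time course**: labelled offsets uniform on [0, k·t] plus
  Gaussian positional noise (sd 500 bp), conversions Binomial(30, 0.5) per
  pair assigned to the T→C or A→G column by mate orientation; background
  reads uniform over the gene with conversion probability 0.002 per
  eligible base. Gene lengths span <30 kb, 30–100 kb and >100 kb so every
  estimator branch is exercised.
* **Nucleosome arrays**: dyads advance by Normal(185, 10) bp steps;
  each dyad scatters 100 fragment midpoints with the fuzziness sd (default
  20 bp); a density parameter thins the array to a target dyads/kb.

## Problem sizes and numerical tolerances

The recovery checks run at desk scale: 500 introns for slope–speed rank
correlation, 300 introns (1–3 kb) × 100 seeded runs for null CI
calibration, 1,000 introns × 3 replicates for the planted-effect
detection, 60 genes for the 4sU bank, 500 regions for nucleosome spacing.
Signed-rank p-values agree with exact enumeration to <1e-12 on tie-free
samples up to n = 10. Ties in |differences| switch the p-value to the
normal approximation (scipy behaviour); zero differences are dropped.
Percentile computations use numpy's linear interpolation. OLS slopes use
closed-form centred sums, not iterative solvers.

## Known limitations

* Slope-based speeds are confounded with initiation rate if *n* changes
  between conditions; the package reports this assumption and offers the
  4sU assay as the absolute cross-check.
* The two-point 4sU estimator saturates when k·t exceeds gene length
  (fronts pinned at the 3′ end), biasing rates low for fast mid-length
  genes; the linear-fit estimator on ≥100 kb genes is the accurate one and
  is used for cross-method comparisons.
* The summit caller's relative height floor makes absolute peak counts
  depend on the strongest peak in a track; density comparisons should stay
  within tracks of similar dynamic range.
* The catalog's support rule pools samples within a condition; a
  per-sample support requirement would be stricter and is not implemented.
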
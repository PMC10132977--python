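"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the data model the analysis assumes, at desk scale:

* sawtooth coverage — intronic depth decreasing linearly 5'->3' with slope
  -n/k (initiation rate over elongation speed), Poisson counting noise per
  base, split-read junction support bridging each intron;
* paired conditions — a fraction of introns sped up by a fold in condition
  B, independent replicate noise;
* junction counts — binomial spliced/unspliced splits at splice sites,
  back-splice counts at planted circularization fractions, intron clusters
  with planted rare junctions;
* 4sU/DRB time courses — labelled-read offsets uniform between the TSS and
  the advancing polymerase front k*t, T->C conversion counts per read pair,
  unlabelled background;
* per-base mismatch errors (never recurrent) with planted SNP positions
  and indel-carrying reads;
* phased nucleosome arrays — dyads at normally distributed spacing,
  fragment midpoints scattered around each dyad by a fuzziness sd.

All randomness flows from the config seed through ``numpy`` seed
sequences, so identical configs give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import GeneModel, GenomicInterval
from .junctions import ChimericRecord, JunctionRecord

SIM_CHROM = "chrSim"
INTRON_GAP = 1_000  # bp of spacer between simulated introns


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the simulated experiment.

    Speeds are bp/min (Pol II travels roughly 0.5-4 kb/min in vivo),
    initiation rates 1/min, lengths bp. ``depth_scale`` converts nascent
    transcript counts into read depth (sequencing-depth dial);
    ``noise='none'`` reproduces expectations exactly.
    """

    # sawtooth coverage
    n_introns: int = 200
    intron_length_range: tuple[int, int] = (1_000, 20_000)
    speed_range: tuple[float, float] = (500.0, 2_500.0)  # 5-fold span
    initiation_rate: float = 2.0
    depth_scale: float = 6.0
    baseline_depth: float = 0.5
    junction_support_mean: float = 20.0
    frac_minus_strand: float = 0.5
    noise: str = "poisson"  # "poisson" | "none"
    # junction metrics
    n_sites: int = 100
    site_depth: float = 200.0
    splicing_efficiency: float = 0.8
    n_circ_loci: int = 50
    circ_fraction: float = 0.05
    circ_linear_depth: float = 500.0
    n_rare_clusters: int = 50
    rare_abundance: float = 0.001
    cluster_depth: float = 2_000.0
    # mismatch
    mismatch_gene_length: int = 5_000
    mismatch_depth: int = 200
    mismatch_error_rate: float = 5e-5
    n_snp_positions: int = 5
    indel_read_fraction: float = 0.02
    read_length: int = 75
    # 4sU/DRB
    foursu_rate_range: tuple[float, float] = (1_000.0, 3_000.0)
    conversion_rate: float = 0.5
    eligible_bases_per_pair: int = 30
    background_error_rate: float = 0.002
    labelled_reads_per_timepoint: int = 300
    background_reads_per_timepoint: int = 300
    front_noise_sd: float = 500.0
    # nucleosomes
    nucleosome_spacing_mean: float = 185.0
    nucleosome_spacing_sd: float = 10.0
    nucleosome_fuzziness_sd: float = 20.0
    fragments_per_nucleosome: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "initiation_rate", "depth_scale", "junction_support_mean",
            "site_depth", "circ_linear_depth", "cluster_depth",
            "nucleosome_spacing_mean", "fragments_per_nucleosome",
            "read_length",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("intron_length_range", "speed_range", "foursu_rate_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (low, high) pair")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")

    def rng(self, *stream: int) -> np.random.Generator:
        """Deterministic child generator for an independent stream."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, *stream)))


# ---------------------------------------------------------------------------
# sawtooth coverage


@dataclass
class SawtoothSample:
    tracks: dict[str, CoverageTrack]
    junctions: list[JunctionRecord]
    truth: pd.DataFrame


def _intron_layout(
    config: SimulationConfig,
    speeds: np.ndarray | None = None,
    lengths: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw the fixed genome layout and kinetic truth shared by all
    replicates: positions, strands, per-intron speed k, initiation rate n.
    Explicit ``speeds``/``lengths`` override the random draws (used to tie
    intronic-slope simulations to genes simulated elsewhere)."""
    rng = config.rng(0)
    n = config.n_introns if speeds is None else len(speeds)
    lo, hi = config.intron_length_range
    if lengths is None:
        lengths = rng.integers(lo, hi + 1, size=n)
    klo, khi = config.speed_range
    if speeds is None:
        speeds = np.exp(rng.uniform(np.log(klo), np.log(khi), size=n))
    minus = rng.random(n) < config.frac_minus_strand
    starts = np.concatenate([[INTRON_GAP], INTRON_GAP + np.cumsum(lengths + INTRON_GAP)[:-1]])
    rows = []
    for i in range(n):
        start, end = int(starts[i]), int(starts[i] + lengths[i])
        strand = "-" if minus[i] else "+"
        rows.append(
            dict(
                intron_id=f"{SIM_CHROM}:{start}-{end}({strand})",
                chrom=SIM_CHROM,
                start=start,
                end=end,
                strand=strand,
                length=int(lengths[i]),
                k=float(speeds[i]),
                n=config.initiation_rate,
            )
        )
    return pd.DataFrame(rows)


def _expected_profile(length: int, k: float, n: float, config: SimulationConfig) -> np.ndarray:
    """Expected depth along transcription direction: baseline plus the
    nascent-transcript gradient scale * (n/k) * (L - x)."""
    x = np.arange(length, dtype=float)
    return config.baseline_depth + config.depth_scale * (n / k) * (length - x)


def _sample_tracks(
    truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator,
    speeds: np.ndarray | None = None,
) -> dict[str, CoverageTrack]:
    tracks = {}
    ks = speeds if speeds is not None else truth["k"].to_numpy()
    for row, k in zip(truth.itertuples(), ks):
        expected = _expected_profile(row.length, k, row.n, config)
        if row.strand == "-":
            expected = expected[::-1]  # genomic axis: 5' end sits at the right
        if config.noise == "poisson":
            values = rng.poisson(expected).astype(float)
        else:
            values = expected
        iv = GenomicInterval(row.chrom, row.start, row.end, row.strand)
        tracks[row.intron_id] = CoverageTrack(iv, values)
    return tracks


def _support_junctions(
    truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator,
    sample_id: str = "",
) -> list[JunctionRecord]:
    juncs = []
    for row in truth.itertuples():
        reads = (
            int(rng.poisson(config.junction_support_mean))
            if config.noise == "poisson"
            else int(round(config.junction_support_mean))
        )
        iv = GenomicInterval(row.chrom, row.start, row.end, row.strand)
        juncs.append(JunctionRecord(iv, reads, sample_id))
    return juncs


def simulate_sawtooth_sample(
    config: SimulationConfig,
    speeds: np.ndarray | None = None,
    lengths: np.ndarray | None = None,
) -> SawtoothSample:
    """One sample of sawtooth intron coverage with bridging junction
    support and a truth table of per-intron k and n. ``speeds``/``lengths``
    optionally pin the kinetic truth instead of drawing it."""
    truth = _intron_layout(config, speeds=speeds, lengths=lengths)
    rng = config.rng(1)
    tracks = _sample_tracks(truth, config, rng)
    junctions = _support_junctions(truth, config, rng, sample_id="sim")
    truth = truth.assign(
        expected_slope=-config.depth_scale * truth["n"] / truth["k"]
    )
    return SawtoothSample(tracks, junctions, truth)


@dataclass
class ConditionPair:
    """Paired-condition simulation. Replicate samples are generated on
    demand (deterministically from the config seed) so that large designs
    never hold more than one sample in memory."""

    config: SimulationConfig
    effect: float
    fold: float
    n_replicates: int
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    CONDITIONS = ("A", "B")

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must be a fraction in [0, 1]")
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if len(self.truth) == 0:
            layout = _intron_layout(self.config)
            rng = self.config.rng(2)
            affected = rng.random(len(layout)) < self.effect
            layout["affected"] = affected
            layout["k_a"] = layout["k"]
            layout["k_b"] = np.where(affected, layout["k"] * self.fold, layout["k"])
            self.truth = layout

    def sample_tracks(self, condition: str, replicate: int) -> dict[str, CoverageTrack]:
        if condition not in self.CONDITIONS:
            raise ValueError(f"condition must be one of {self.CONDITIONS}")
        rng = self.config.rng(3, self.CONDITIONS.index(condition), replicate)
        speeds = self.truth["k_b" if condition == "B" else "k_a"].to_numpy()
        return _sample_tracks(self.truth, self.config, rng, speeds=speeds)

    def sample_junctions(self, condition: str, replicate: int) -> list[JunctionRecord]:
        rng = self.config.rng(4, self.CONDITIONS.index(condition), replicate)
        return _support_junctions(
            self.truth, self.config, rng, sample_id=f"{condition}{replicate}"
        )


def simulate_condition_pair(
    config: SimulationConfig, effect: float, fold: float, n_replicates: int = 3
) -> ConditionPair:
    """Two conditions sharing one intron layout; a fraction ``effect`` of
    introns runs ``fold`` times faster in condition B."""
    return ConditionPair(config, effect, fold, n_replicates)


# ---------------------------------------------------------------------------
# junction-level metrics


@dataclass
class JunctionSimulation:
    site_counts: pd.DataFrame          # gene_id, spliced, unspliced, true_efficiency
    chimeric: list[ChimericRecord]
    linear_junctions: list[JunctionRecord]  # S1/S2 evidence for circ loci
    gene_models: dict[str, GeneModel]
    cluster_junctions: list[JunctionRecord]
    gene_of_junction: dict[tuple, str]
    circ_truth: pd.DataFrame           # gene_id, true_circ_fraction
    rare_truth: pd.DataFrame           # junction key, relative abundance, is_rare


def simulate_junction_counts(config: SimulationConfig) -> JunctionSimulation:
    rng = config.rng(5)
    # splice-site spliced/unspliced splits
    site_rows = []
    for i in range(config.n_sites):
        depth = (
            rng.poisson(config.site_depth)
            if config.noise == "poisson"
            else int(round(config.site_depth))
        )
        if config.noise == "poisson":
            spliced = rng.binomial(depth, config.splicing_efficiency)
        else:
            spliced = int(round(depth * config.splicing_efficiency))
        site_rows.append(
            dict(
                gene_id=f"siteGene{i:04d}",
                spliced=int(spliced),
                unspliced=int(depth - spliced),
                true_efficiency=config.splicing_efficiency,
            )
        )
    site_counts = pd.DataFrame(site_rows)

    # circRNA loci: a two-exon gene per locus, linear junctions at the exon
    # boundaries and back-splice reads at the planted fraction
    chimeric: list[ChimericRecord] = []
    linear: list[JunctionRecord] = []
    gene_models: dict[str, GeneModel] = {}
    circ_rows = []
    cursor = 1_000
    for i in range(config.n_circ_loci):
        gid = f"circGene{i:04d}"
        exon1 = GenomicInterval(SIM_CHROM, cursor, cursor + 200, "+")
        exon2 = GenomicInterval(SIM_CHROM, cursor + 1_200, cursor + 1_400, "+")
        model = GeneModel(gid, SIM_CHROM, "+")
        model.add_exon(f"{gid}.t1", exon1)
        model.add_exon(f"{gid}.t1", exon2)
        model.finalize()
        gene_models[gid] = model
        # circularized exon = exon2: acceptor at its start, donor at its end
        acc, don = exon2.start, exon2.end
        s1 = int(rng.poisson(config.circ_linear_depth))
        s2 = int(rng.poisson(config.circ_linear_depth))
        linear.append(JunctionRecord(GenomicInterval(SIM_CHROM, exon1.end, acc, "+"), s1))
        linear.append(
            JunctionRecord(GenomicInterval(SIM_CHROM, don, don + 1_000, "+"), s2)
        )
        f = config.circ_fraction
        if f > 0:
            bs_mean = f / (1.0 - f) * (s1 + s2) / 2.0
            bs = int(rng.poisson(bs_mean)) if config.noise == "poisson" else int(round(bs_mean))
            if bs > 0:
                chimeric.append(ChimericRecord(SIM_CHROM, don, acc, "+", bs))
        circ_rows.append(dict(gene_id=gid, true_circ_fraction=f))
        cursor += 5_000
    circ_truth = pd.DataFrame(circ_rows)

    # intron clusters with planted rare junctions (shared donor)
    cluster_junctions: list[JunctionRecord] = []
    gene_of_junction: dict[tuple, str] = {}
    rare_rows = []
    cursor += 10_000
    for i in range(config.n_rare_clusters):
        gid = f"clustGene{i:04d}"
        donor = cursor
        major_acc = cursor + 2_000
        rare_acc = cursor + 3_000
        major = int(rng.poisson(config.cluster_depth)) if config.noise == "poisson" else int(config.cluster_depth)
        major = max(major, 1)
        rare = max(1, int(round(config.rare_abundance * major)))
        for acc, reads, planted_rare in ((major_acc, major, False), (rare_acc, rare, True)):
            iv = GenomicInterval(SIM_CHROM, donor, acc, "+")
            cluster_junctions.append(JunctionRecord(iv, reads))
            key = (SIM_CHROM, donor, acc)
            gene_of_junction[key] = gid
            total = major + rare
            rare_rows.append(
                dict(
                    chrom=SIM_CHROM, start=donor, end=acc, gene_id=gid,
                    relative_abundance=reads / total, planted_rare=planted_rare,
                )
            )
        cursor += 10_000
    rare_truth = pd.DataFrame(rare_rows)

    return JunctionSimulation(
        site_counts, chimeric, linear, gene_models,
        cluster_junctions, gene_of_junction, circ_truth, rare_truth,
    )


# ---------------------------------------------------------------------------
# mismatch reads


@dataclass
class MismatchSimulation:
    reads: pd.DataFrame
    mismatches: pd.DataFrame
    depth: np.ndarray
    truth: dict


def simulate_mismatch_reads(config: SimulationConfig) -> MismatchSimulation:
    """Reads tiling one gene with independent per-base errors (each true
    error at a distinct genomic position), planted SNP positions that
    mismatch in every covering read, and a fraction of indel reads."""
    rng = config.rng(6)
    L = config.mismatch_gene_length
    rl = config.read_length
    n_reads = int(np.ceil(config.mismatch_depth * L / rl))
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    has_indel = rng.random(n_reads) < config.indel_read_fraction
    reads = pd.DataFrame(
        dict(
            read_id=[f"r{i:06d}" for i in range(n_reads)],
            chrom=SIM_CHROM,
            start=starts,
            length=rl,
            has_indel=has_indel,
            gene_id="mmGene",
        )
    )
    depth = np.zeros(L)
    for s in starts:
        depth[s : s + rl] += 1

    bases = "ACGT"
    mm_rows = []
    # true errors: distinct genomic positions, one read each
    clean = reads[~reads["has_indel"]].reset_index(drop=True)
    n_covered = int(clean["length"].sum())
    n_errors = rng.binomial(n_covered, config.mismatch_error_rate)
    snp_pos = set()
    if config.n_snp_positions > 0:
        snp_pos = set(
            int(p) for p in rng.choice(np.arange(rl, L - rl), size=config.n_snp_positions, replace=False)
        )
    candidates = np.setdiff1d(np.arange(L), np.fromiter(snp_pos, dtype=int, count=len(snp_pos)))
    err_positions = rng.choice(candidates, size=min(n_errors, len(candidates)), replace=False)
    n_true_errors = 0
    for pos in err_positions:
        covering = clean[(clean["start"] <= pos) & (pos < clean["start"] + rl)]
        if covering.empty:
            continue
        read = covering.iloc[int(rng.integers(len(covering)))]
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        mm_rows.append(
            dict(
                read_id=read["read_id"],
                read_offset=int(pos - read["start"]),
                genome_pos=int(pos),
                ref=ref,
                alt=alt,
            )
        )
        n_true_errors += 1
    # SNPs: every covering read mismatches
    for pos in sorted(snp_pos):
        covering = reads[(reads["start"] <= pos) & (pos < reads["start"] + rl)]
        ref, alt = rng.choice(list(bases), size=2, replace=False)
        for _, read in covering.iterrows():
            mm_rows.append(
                dict(
                    read_id=read["read_id"],
                    read_offset=int(pos - read["start"]),
                    genome_pos=int(pos),
                    ref=ref,
                    alt=alt,
                )
            )
    mismatches = pd.DataFrame(
        mm_rows, columns=["read_id", "read_offset", "genome_pos", "ref", "alt"]
    )
    truth = dict(
        n_true_errors=n_true_errors,
        snp_positions=sorted(snp_pos),
        error_rate=config.mismatch_error_rate,
    )
    return MismatchSimulation(reads, mismatches, depth, truth)


# ---------------------------------------------------------------------------
# 4sU/DRB time course


@dataclass
class FoursuSimulation:
    reads: pd.DataFrame  # gene_id, time, offset, n_tc, n_ag, labelled(truth)
    truth: pd.DataFrame  # gene_id, length, k


def default_foursu_gene_lengths(rng: np.random.Generator, n_short=10, n_mid=20, n_long=30) -> np.ndarray:
    """Gene lengths spanning the three regimes the estimators distinguish:
    under 30 kb (excluded), 30-100 kb (two-point 15/30), over 100 kb."""
    short = rng.integers(15_000, 25_000, n_short)
    mid = rng.integers(35_000, 95_000, n_mid)
    long_ = rng.integers(110_000, 200_000, n_long)
    return np.concatenate([short, mid, long_])


def simulate_foursu_timecourse(
    config: SimulationConfig,
    time_points: tuple = (0, 15, 30, 45),
    gene_lengths: np.ndarray | None = None,
) -> FoursuSimulation:
    """Labelled and background reads per time point.

    At time t, labelled reads for a gene fall uniformly on
    [TSS, min(k*t, L)] plus positional noise, and carry conversions at the
    configured rate over the eligible (T on the sense strand) bases of the
    pair; background reads fall anywhere on the gene and only reach the
    conversion threshold through the sequencing error rate. Noise-free
    mode places labelled offsets on an exact grid whose maximum is the
    true front.
    """
    rng = config.rng(7)
    if gene_lengths is None:
        gene_lengths = default_foursu_gene_lengths(rng)
    klo, khi = config.foursu_rate_range
    speeds = rng.uniform(klo, khi, size=len(gene_lengths))
    truth = pd.DataFrame(
        dict(
            gene_id=[f"fsGene{i:04d}" for i in range(len(gene_lengths))],
            length=gene_lengths.astype(int),
            k=speeds,
        )
    )
    rows = []
    noiseless = config.noise == "none"
    for row in truth.itertuples():
        for t in time_points:
            front = min(row.k * t, float(row.length))
            m = config.labelled_reads_per_timepoint
            if noiseless:
                offsets = np.linspace(0.0, front, m)
            else:
                offsets = rng.uniform(0.0, max(front, 1.0), size=m)
                offsets = offsets + rng.normal(0.0, config.front_noise_sd, size=m)
                offsets = np.clip(offsets, 0.0, float(row.length))
            if noiseless:
                n_tc = np.full(m, int(config.eligible_bases_per_pair * config.conversion_rate))
                n_ag = np.zeros(m, dtype=int)
            else:
                eligible = config.eligible_bases_per_pair
                total = rng.binomial(eligible, config.conversion_rate, size=m)
                antisense = rng.random(m) < 0.5  # which mate reports the conversion
                n_ag = np.where(antisense, total, 0)
                n_tc = np.where(antisense, 0, total)
            for off, tc, ag in zip(offsets, n_tc, n_ag):
                rows.append(
                    dict(gene_id=row.gene_id, time=float(t), offset=float(off),
                         n_tc=int(tc), n_ag=int(ag), labelled=True)
                )
            nb = 0 if noiseless else config.background_reads_per_timepoint
            if nb:
                boff = rng.uniform(0.0, float(row.length), size=nb)
                btc = rng.binomial(
                    config.eligible_bases_per_pair, config.background_error_rate, size=nb
                )
                for off, tc in zip(boff, btc):
                    rows.append(
                        dict(gene_id=row.gene_id, time=float(t), offset=float(off),
                             n_tc=int(tc), n_ag=0, labelled=False)
                    )
    reads = pd.DataFrame(rows)
    return FoursuSimulation(reads, truth)


# ---------------------------------------------------------------------------
# nucleosome arrays


@dataclass
class NucleosomeSimulation:
    tracks: dict[str, CoverageTrack]
    bedgraph: pd.DataFrame
    truth: pd.DataFrame  # region, dyad count, mean planted spacing


def simulate_nucleosome_coverage(
    config: SimulationConfig,
    regions: list[GenomicInterval],
    density_per_kb: float | None = None,
) -> NucleosomeSimulation:
    """Fragment-midpoint counts over phased nucleosome arrays.

    Dyads advance by Normal(spacing mean, spacing sd) steps; each dyad
    receives ``fragments_per_nucleosome`` midpoints scattered by the
    fuzziness sd (zero fuzziness puts every count exactly on the dyad).
    ``density_per_kb`` thins the full array to a target dyad count.
    """
    rng = config.rng(8)
    tracks = {}
    truth_rows = []
    bg_rows = []
    for region in regions:
        length = len(region)
        dyads = []
        pos = float(config.nucleosome_spacing_mean) / 2.0
        while pos < length - config.nucleosome_spacing_mean / 2.0:
            dyads.append(pos)
            step = rng.normal(config.nucleosome_spacing_mean, config.nucleosome_spacing_sd)
            pos += max(step, 1.0)
        dyads = np.array(dyads)
        if density_per_kb is not None:
            n_target = min(len(dyads), int(round(density_per_kb * length / 1_000)))
            keep = np.sort(rng.choice(len(dyads), size=n_target, replace=False))
            dyads = dyads[keep]
        values = np.zeros(length)
        for dyad in dyads:
            if config.nucleosome_fuzziness_sd > 0:
                mids = rng.normal(dyad, config.nucleosome_fuzziness_sd,
                                  size=config.fragments_per_nucleosome)
            else:
                mids = np.full(config.fragments_per_nucleosome, dyad)
            idx = np.round(mids).astype(int)
            idx = idx[(idx >= 0) & (idx < length)]
            np.add.at(values, idx, 1.0)
        track = CoverageTrack(region, values)
        rid = f"{region.chrom}:{region.start}-{region.end}"
        tracks[rid] = track
        spacing = float(np.mean(np.diff(dyads))) if len(dyads) > 1 else np.nan
        truth_rows.append(
            dict(region=rid, n_dyads=len(dyads), mean_spacing=spacing,
                 dyad_positions=[float(region.start + d) for d in dyads])
        )
        nz = np.nonzero(values)[0]
        for i in nz:
            bg_rows.append((region.chrom, region.start + i, region.start + i + 1, values[i]))
    bedgraph = pd.DataFrame(bg_rows, columns=["chrom", "start", "end", "value"])
    truth = pd.DataFrame(truth_rows)
    return NucleosomeSimulation(tracks, bedgraph, truth)
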
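"""Absolute elongation rates (bp/min) from 4sU/DRB release time courses.

DRB stalls Pol II at promoters; upon release, polymerases advance as a
synchronized wave while 4sU labels nascent RNA. After thiouridine-to-
cytidine chemistry, labelled reads carry T->C (or A->G, depending on mate
orientation) conversions; a read pair with at least three such conversions
counts as labelled. The front of the polymerase wave at each time point is
the 99th percentile of labelled-read positions along the gene, and the
front's advance over time gives the elongation rate, via a linear fit over
all four time points (genes >= 100 kb, fronts capped at 100 kb) or via two
fronts 15 minutes apart (15/30 min for 30-100 kb genes, 30/45 min beyond
100 kb).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import PairedComparison, compare_paired

logger = logging.getLogger(__name__)

MIN_CONVERSIONS = 3
DEFAULT_PERCENTILE = 99.0
DEFAULT_MIN_READS = 20
LINEAR_FIT_CAP = 100_000
TWO_POINT_MIN_LENGTH = 30_000
EXCLUDED_TIMES = (5,)
QC_MAX_CONTROL_LABELLED_FRACTION = 0.01

LABELLED_READ_COLUMNS = ["gene_id", "time", "offset", "n_tc", "n_ag"]


@dataclass
class FrontTrajectory:
    gene_id: str
    gene_length: int
    fronts: dict[float, float] = field(default_factory=dict)  # time -> bp offset
    estimator: str = ""
    rate: float = np.nan
    valid: bool = False


def classify_labelled(
    reads: pd.DataFrame,
    min_conversions: int = MIN_CONVERSIONS,
    exclude_times: tuple = EXCLUDED_TIMES,
    stranded: bool = True,
) -> pd.DataFrame:
    """Keep read pairs with >= ``min_conversions`` T->C plus A->G
    conversions; other substitution types never count. Time points in
    ``exclude_times`` (default: the conversion-poor 5-min point) are
    dropped entirely."""
    if not stranded:
        raise ValueError(
            "conversion orientation is undefined on unstranded data; "
            "labelled-read classification needs gene strand"
        )
    missing = set(LABELLED_READ_COLUMNS) - set(reads.columns)
    if missing:
        raise ValueError(f"read table lacks columns: {sorted(missing)}")
    out = reads[~reads["time"].isin(exclude_times)]
    return out[(out["n_tc"] + out["n_ag"]) >= min_conversions].reset_index(drop=True)


def labelled_fraction(reads: pd.DataFrame, min_conversions: int = MIN_CONVERSIONS) -> float:
    """Fraction of read pairs classified as labelled; a no-conversion
    negative control should stay below ~1% (QC gate)."""
    if len(reads) == 0:
        return 0.0
    return float(((reads["n_tc"] + reads["n_ag"]) >= min_conversions).mean())


def qc_negative_control(reads: pd.DataFrame,
                        threshold: float = QC_MAX_CONTROL_LABELLED_FRACTION) -> bool:
    frac = labelled_fraction(reads)
    ok = frac <= threshold
    if not ok:
        logger.warning(
            "negative control labelled fraction %.3f exceeds QC threshold %.3f",
            frac, threshold,
        )
    return ok


def front_position(
    offsets: np.ndarray,
    percentile: float = DEFAULT_PERCENTILE,
    min_reads: int = DEFAULT_MIN_READS,
) -> float:
    """Wave-front location for one gene at one time point: the 99th
    percentile of labelled-read 5'-most offsets (transcription direction).
    Undefined (nan) below ``min_reads`` labelled reads."""
    offsets = np.asarray(offsets, dtype=float)
    if len(offsets) < min_reads:
        return np.nan
    return float(np.percentile(offsets, percentile))


def build_trajectory(
    labelled: pd.DataFrame,
    gene_id: str,
    gene_length: int,
    percentile: float = DEFAULT_PERCENTILE,
    min_reads: int = DEFAULT_MIN_READS,
) -> FrontTrajectory:
    traj = FrontTrajectory(gene_id, gene_length)
    sub = labelled[labelled["gene_id"] == gene_id]
    for t, grp in sub.groupby("time"):
        traj.fronts[float(t)] = front_position(
            grp["offset"].to_numpy(), percentile, min_reads
        )
    times = sorted(t for t, f in traj.fronts.items() if np.isfinite(f))
    fronts = [traj.fronts[t] for t in times]
    if any(b < a for a, b in zip(fronts, fronts[1:])):
        logger.warning("non-monotone front trajectory for gene %s", gene_id)
    return traj


def rate_linear_fit(
    traj: FrontTrajectory,
    cap: int = LINEAR_FIT_CAP,
    min_points: int = 3,
) -> FrontTrajectory:
    """OLS slope of front position against time, fronts capped at 100 kb.

    Restricted to genes of at least 100 kb, whose transcription cannot
    finish within the time course. A non-positive fitted slope is invalid.
    """
    traj.estimator = "linear_fit"
    if traj.gene_length < cap:
        traj.rate, traj.valid = np.nan, False
        return traj
    pts = [(t, min(f, cap)) for t, f in sorted(traj.fronts.items()) if np.isfinite(f)]
    if len(pts) < min_points:
        traj.rate, traj.valid = np.nan, False
        return traj
    t = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    slope = np.polyfit(t, f, 1)[0]
    if abs(slope) < 1e-9:  # numerically flat trajectory
        slope = 0.0
    traj.rate = float(slope)
    traj.valid = slope > 0
    return traj


def rate_two_point(traj: FrontTrajectory) -> FrontTrajectory:
    """Front advance between two time points 15 minutes apart, divided by
    15: the 15/30-min pair for genes of 30-100 kb, the 30/45-min pair for
    genes over 100 kb. Genes under 30 kb are excluded (fully transcribed
    too quickly)."""
    traj.estimator = "two_point"
    if traj.gene_length < TWO_POINT_MIN_LENGTH:
        traj.rate, traj.valid = np.nan, False
        return traj
    pair = (30.0, 45.0) if traj.gene_length > LINEAR_FIT_CAP else (15.0, 30.0)
    early = traj.fronts.get(pair[0], np.nan)
    late = traj.fronts.get(pair[1], np.nan)
    if not (np.isfinite(early) and np.isfinite(late)):
        traj.rate, traj.valid = np.nan, False
        return traj
    rate = (late - early) / (pair[1] - pair[0])
    traj.rate = float(rate)
    traj.valid = rate > 0
    return traj


def compare_rates(
    rates_a: pd.Series, rates_b: pd.Series
) -> PairedComparison:
    """Paired contrast of per-gene rates on the genes defined in both
    conditions (difference scale, bp/min)."""
    common = rates_a.index.intersection(rates_b.index)
    return compare_paired(rates_a.loc[common].to_numpy(), rates_b.loc[common].to_numpy())
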
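"""Pol II elongation-speed proxies from intronic coverage slopes.

At steady state, an intron of length L traversed at speed k (bp/min) with
initiation rate n (1/min) shows nascent-transcript coverage decreasing
linearly 5'->3'; the fitted slope is s = -n/k, so -1/s is proportional to
k/n and serves as a relative speed proxy. Absolute k is deliberately not
reported from slopes: n is unknown, and ratios between conditions only
assume n is stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import spearmanr

from .coverage import CoverageTrack
from .stats import PairedComparison, compare_paired

logger = logging.getLogger(__name__)
logger.info(
    "speed proxies (-1/slope) are relative measures proportional to k/n; "
    "absolute elongation rates require the initiation rate n"
)


@dataclass
class SlopeEstimate:
    intron_id: str
    slope: float
    intercept: float
    speed_proxy: float  # -1/slope, finite and > 0 only when slope < 0
    r_squared: float
    n_positions: int
    valid: bool


@dataclass
class SpeedComparison:
    """Condition contrast of per-intron speed proxies (B vs A)."""

    per_intron: pd.DataFrame  # intron_id, proxy_a, proxy_b, log2fc, consistent
    summary: PairedComparison
    consistent_only: bool


def fit_intron_slope(
    track: CoverageTrack, strand: str | None = None
) -> SlopeEstimate:
    """Ordinary least squares of depth against transcription-direction
    offset. Minus-strand tracks are reversed before fitting so the slope is
    always 5'->3'. A non-negative slope (or degenerate track) yields an
    invalid estimate rather than an exception."""
    strand = strand or track.interval.strand
    y = np.asarray(track.values, dtype=float)
    if strand == "-":
        y = y[::-1]
    m = len(y)
    intron_id = (
        f"{track.interval.chrom}:{track.interval.start}-{track.interval.end}({strand})"
    )
    if m < 2 or not np.any(y):
        return SlopeEstimate(intron_id, np.nan, np.nan, np.nan, np.nan, m, False)
    x = np.arange(m, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    sxy = float(xc @ yc)
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    syy = float(yc @ yc)
    r2 = (sxy * sxy) / (sxx * syy) if syy > 0 else np.nan
    valid = np.isfinite(slope) and slope < 0
    proxy = -1.0 / slope if valid else np.nan
    return SlopeEstimate(intron_id, slope, intercept, proxy, r2, m, valid)


def estimate_sample_speeds(
    catalog, tracks: dict[str, CoverageTrack]
) -> pd.DataFrame:
    """One slope estimate per catalog intron for one sample.

    ``tracks`` maps intron_id -> coverage (already on a uniform scale, raw
    or RPM, for the whole sample). Missing or unusable tracks produce
    invalid rows, never dropped rows, so catalogs stay aligned across
    samples.
    """
    rows = []
    for rec in catalog.introns if hasattr(catalog, "introns") else catalog:
        iid = rec.intron_id
        track = tracks.get(iid)
        if track is None:
            rows.append(
                dict(intron_id=iid, slope=np.nan, intercept=np.nan,
                     speed_proxy=np.nan, r_squared=np.nan, n_positions=0, valid=False)
            )
            continue
        est = fit_intron_slope(track, rec.interval.strand)
        rows.append(
            dict(intron_id=iid, slope=est.slope, intercept=est.intercept,
                 speed_proxy=est.speed_proxy, r_squared=est.r_squared,
                 n_positions=est.n_positions, valid=est.valid)
        )
    return pd.DataFrame(rows).set_index("intron_id")


def _proxy_matrix(estimates: list[pd.DataFrame]) -> pd.DataFrame:
    """Replicates as columns, introns as rows; invalid estimates become NaN."""
    cols = {}
    for i, df in enumerate(estimates):
        p = df["speed_proxy"].where(df["valid"])
        cols[i] = p
    return pd.DataFrame(cols)


def compare_conditions(
    estimates_a: list[pd.DataFrame],
    estimates_b: list[pd.DataFrame],
    consistent_only: bool = False,
) -> SpeedComparison:
    """Paired contrast of speed proxies between conditions.

    Per intron, the condition value is the mean of replicate proxies; only
    introns valid in every replicate of both conditions enter. The summary
    is the Hodges–Lehmann pseudo-median of log2 fold changes with its 95%
    CI and the two-sided paired Wilcoxon signed-rank p.

    ``consistent_only`` keeps introns whose B-vs-A difference has the same
    sign for every cross-condition replicate pairing (the strictest reading
    of "always up or down").
    """
    mat_a = _proxy_matrix(estimates_a)
    mat_b = _proxy_matrix(estimates_b)
    idx = mat_a.index.intersection(mat_b.index)
    mat_a, mat_b = mat_a.loc[idx], mat_b.loc[idx]
    ok = mat_a.notna().all(axis=1) & mat_b.notna().all(axis=1)
    mat_a, mat_b = mat_a[ok], mat_b[ok]
    mean_a = mat_a.mean(axis=1)
    mean_b = mat_b.mean(axis=1)
    # same sign across the full cartesian set of replicate pairings
    # <=> min(B) > max(A) or max(B) < min(A)
    consistent = (mat_b.min(axis=1) > mat_a.max(axis=1)) | (
        mat_b.max(axis=1) < mat_a.min(axis=1)
    )
    table = pd.DataFrame(
        {
            "proxy_a": mean_a,
            "proxy_b": mean_b,
            "log2fc": np.log2(mean_b / mean_a),
            "consistent": consistent,
        }
    )
    used = table[table["consistent"]] if consistent_only else table
    summary = compare_paired(
        np.log2(used["proxy_a"].to_numpy()), np.log2(used["proxy_b"].to_numpy())
    )
    return SpeedComparison(table, summary, consistent_only)


def speed_signature_cluster(
    estimates_by_sample: dict[str, pd.DataFrame],
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of samples on their speed signatures.

    The signature of a sample is its vector of speed proxies over the
    introns valid in every sample; distance is 1 - Spearman correlation,
    linkage is average. Returns the scipy linkage matrix and the leaf-order
    sample names (deterministic).
    """
    samples = sorted(estimates_by_sample)
    if len(samples) < 2:
        raise ValueError("clustering needs at least two samples")
    mat = pd.DataFrame(
        {s: estimates_by_sample[s]["speed_proxy"].where(estimates_by_sample[s]["valid"])
         for s in samples}
    ).dropna()
    if mat.empty:
        raise ValueError("no introns quantified in all samples")
    k = len(samples)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rho = spearmanr(mat.iloc[:, i], mat.iloc[:, j]).statistic
            dist[i, j] = dist[j, i] = 1.0 - rho
    condensed = dist[np.triu_indices(k, 1)]
    linkage = hierarchy.linkage(condensed, method="average")
    order = hierarchy.leaves_list(linkage)
    return linkage, [samples[i] for i in order]
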
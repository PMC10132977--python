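"""Nucleosome-positioning metrics from MNase fragment-midpoint coverage.

A minimal peak caller (Gaussian smoothing, local maxima above a relative
height floor, nearby-summit merging) supplies summits; on top of it three
statistics are computed per exon/intron feature: nucleosome density (peaks
per bp of feature), peak sharpness (height over width, width being the
standard deviation of coverage around the summit within one nucleosome
footprint), and the distance between consecutive summits (spacing
regularity). Per-sample signature vectors of these statistics are compared
by principal component analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from sklearn.decomposition import PCA

from .coverage import CoverageTrack
from .intervals import GenomicInterval

DEFAULT_BANDWIDTH = 20.0       # bp, Gaussian smoothing sd
DEFAULT_MIN_HEIGHT_FRAC = 0.25  # summit floor relative to track maximum
DEFAULT_MERGE_RADIUS = 50      # bp, minimum separation between summits
HALF_FOOTPRINT = 73            # bp, half of the 147-bp nucleosome core


@dataclass
class NucleosomePeak:
    summit: int        # genomic position
    height: float      # smoothed depth at the summit
    width: float       # sd (bp) of coverage-weighted positions around the summit

    @property
    def sharpness(self) -> float:
        return peak_sharpness(self)


def peak_sharpness(peak: NucleosomePeak, mode: str = "height_over_width") -> float:
    """Positioning precision of one nucleosome: grows with peak height and
    shrinks with peak width. Default is height/width; ``height_over_var``
    (height/width^2) is available as an alternative combination."""
    if peak.width <= 0:
        return np.nan
    if mode == "height_over_width":
        return peak.height / peak.width
    if mode == "height_over_var":
        return peak.height / peak.width**2
    raise ValueError(f"unknown sharpness mode {mode!r}")


def call_peaks(
    track: CoverageTrack,
    bandwidth: float = DEFAULT_BANDWIDTH,
    min_height_frac: float = DEFAULT_MIN_HEIGHT_FRAC,
    merge_radius: int = DEFAULT_MERGE_RADIUS,
) -> list[NucleosomePeak]:
    """Summit calling on a midpoint-count track.

    The track is Gaussian-smoothed (sd ``bandwidth`` bp); local maxima at
    least ``min_height_frac`` of the smoothed maximum and ``merge_radius``
    bp apart become summits. Width is the standard deviation of raw
    coverage-weighted positions within +-73 bp of the summit. A flat or
    empty track yields no peaks.
    """
    y = np.asarray(track.values, dtype=float)
    if not np.any(y) or np.all(y == y[0]):
        return []
    smooth = gaussian_filter1d(y, sigma=bandwidth, mode="constant")
    floor = min_height_frac * smooth.max()
    idx, _ = find_peaks(smooth, height=floor, distance=merge_radius)
    peaks = []
    for i in idx:
        lo = max(0, i - HALF_FOOTPRINT)
        hi = min(len(y), i + HALF_FOOTPRINT + 1)
        w = y[lo:hi]
        if w.sum() <= 0:
            continue
        pos = np.arange(lo, hi, dtype=float)
        mean = float((pos * w).sum() / w.sum())
        var = float(((pos - mean) ** 2 * w).sum() / w.sum())
        width = np.sqrt(var)
        if width <= 0:
            width = np.nan
        peaks.append(
            NucleosomePeak(track.interval.start + int(i), float(smooth[i]), width)
        )
    return peaks


@dataclass
class FeatureNucleosomeSignature:
    feature: GenomicInterval
    n_peaks: int
    density: float            # peaks per bp
    mean_sharpness: float
    mean_summit_distance: float  # nan when fewer than two summits


def feature_signatures(
    peaks: list[NucleosomePeak],
    features: list[GenomicInterval],
) -> list[FeatureNucleosomeSignature]:
    """Density, mean sharpness and mean consecutive-summit distance for
    each exon/intron feature; distances are only measured between summits
    inside the same feature."""
    out = []
    summits = np.array([p.summit for p in peaks])
    order = np.argsort(summits)
    for feat in features:
        inside = [
            peaks[i]
            for i in order
            if feat.contains_point(int(summits[i]))
        ]
        n = len(inside)
        sharp = [p.sharpness for p in inside if np.isfinite(p.sharpness)]
        if n >= 2:
            pos = np.array([p.summit for p in inside])
            dist = float(np.mean(np.diff(pos)))
        else:
            dist = np.nan
        out.append(
            FeatureNucleosomeSignature(
                feat,
                n,
                n / len(feat),
                float(np.mean(sharp)) if sharp else np.nan,
                dist,
            )
        )
    return out


def signature_ordination(
    signatures: pd.DataFrame, n_components: int = 2, scale: bool = True
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """PCA of per-sample signature vectors (samples x features).

    Columns with missing or constant values are dropped before centring
    (and unit-scaling). The sign of each component is fixed so its
    largest-magnitude loading is positive, making the ordination
    deterministic. Returns (coordinates, explained variance ratio,
    loadings).
    """
    mat = signatures.dropna(axis=1)
    keep = mat.std(axis=0) > 0
    mat = mat.loc[:, keep]
    if mat.shape[0] < 3:
        raise ValueError("ordination needs at least three samples")
    if mat.shape[1] < 2:
        raise ValueError("ordination needs at least two usable features")
    x = mat.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        x = x / x.std(axis=0)
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    loadings = pca.components_
    for c in range(n_components):
        j = np.argmax(np.abs(loadings[c]))
        if loadings[c, j] < 0:
            loadings[c] *= -1
            coords[:, c] *= -1
    coord_df = pd.DataFrame(
        coords,
        index=signatures.index,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    return coord_df, pca.explained_variance_ratio_, loadings
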
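"""Per-region model inputs.

Each region is summarized by (a) a 2000-point, base-pair-resolution signal
window centered on the region midpoint, max-normalized so the shape model is
depth-invariant, and (b) 11 enrichment ratios comparing the region's maximum
coverage against background means over 10-100 kb windows (10 kb increments)
plus the whole chromosome.  An optional Poisson upper-tail test against an
input-control track yields a per-region P-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from peakshaper.coverage_io import CoverageTrack, GenomicRegion

logger = logging.getLogger(__name__)

SIGNAL_WINDOW_BP = 2000
BACKGROUND_SIZES_BP = tuple(range(10_000, 110_000, 10_000))
N_ENRICHMENT_FEATURES = len(BACKGROUND_SIZES_BP) + 1  # + chromosome-wide
EPSILON = 0.1


@dataclass
class FeatureBundle:
    """Model inputs for one region."""

    region: GenomicRegion
    signal_window: np.ndarray  # length SIGNAL_WINDOW_BP, max-normalized
    enrichment_features: np.ndarray  # length N_ENRICHMENT_FEATURES, each > 0

    def __post_init__(self) -> None:
        if self.signal_window.size != SIGNAL_WINDOW_BP:
            raise ValueError("signal window must have exactly 2000 points")
        if self.enrichment_features.size != N_ENRICHMENT_FEATURES:
            raise ValueError("expected 11 enrichment features")


def encode_signal_window(track: CoverageTrack, region: GenomicRegion) -> np.ndarray:
    """Max-normalized per-base coverage over the 2 kb around the region midpoint.

    The window is ``[mid - 1000, mid + 1000)`` with ``mid =
    floor((start + end) / 2)``; bases beyond the chromosome contribute 0.
    An all-zero window stays all-zero.
    """
    signal = track.values[region.chrom]
    mid = (region.start + region.end) // 2
    half = SIGNAL_WINDOW_BP // 2
    lo, hi = mid - half, mid + half
    window = np.zeros(SIGNAL_WINDOW_BP, dtype=np.float64)
    src_lo, src_hi = max(lo, 0), min(hi, signal.size)
    if src_lo < src_hi:
        window[src_lo - lo : src_hi - lo] = signal[src_lo:src_hi]
    peak = window.max()
    if peak > 0:
        window = window / peak
    return window


def enrichment_features(track: CoverageTrack, region: GenomicRegion) -> np.ndarray:
    """11 max-vs-background coverage ratios for a region.

    Feature ``k`` (k = 0..9) is ``(max coverage in region + eps) /
    (mean coverage over the (k+1)*10 kb window centered on the region
    midpoint, clipped to the chromosome, + eps)`` with eps = 0.1; the last
    feature uses the whole-chromosome mean.
    """
    signal = track.values[region.chrom]
    peak_max = float(signal[region.start : region.end].max()) if region.end > region.start else 0.0
    mid = (region.start + region.end) // 2
    feats = np.empty(N_ENRICHMENT_FEATURES, dtype=np.float64)
    for i, size in enumerate(BACKGROUND_SIZES_BP):
        lo = max(mid - size // 2, 0)
        hi = min(mid + (size - size // 2), signal.size)
        bg_mean = float(signal[lo:hi].sum()) / (hi - lo)
        feats[i] = (peak_max + EPSILON) / (bg_mean + EPSILON)
    chrom_mean = float(signal.sum()) / signal.size
    feats[-1] = (peak_max + EPSILON) / (chrom_mean + EPSILON)
    return feats


def featurize(track: CoverageTrack, region: GenomicRegion) -> FeatureBundle:
    """Compute the full feature bundle for one region."""
    return FeatureBundle(
        region=region,
        signal_window=encode_signal_window(track, region),
        enrichment_features=enrichment_features(track, region),
    )


def pvalue_vs_input(
    track: CoverageTrack,
    input_track: CoverageTrack,
    region: GenomicRegion,
) -> float:
    """Poisson upper-tail P-value of region coverage versus an input control.

    observed = total treatment coverage in the region, rounded; lambda =
    total input coverage in the region scaled by the treatment/input
    chromosome depth ratio, floored at 0.1.  Returns P(X >= observed),
    always in (0, 1].
    """
    signal = track.values[region.chrom]
    control = input_track.values[region.chrom]
    observed = int(round(float(signal[region.start : region.end].sum())))
    input_total_chrom = float(control.sum())
    if input_total_chrom == 0:
        logger.warning(
            "input control has zero coverage on %s; lambda floored at %g",
            region.chrom,
            EPSILON,
        )
        lam = EPSILON
    else:
        depth_ratio = float(signal.sum()) / input_total_chrom
        lam = max(float(control[region.start : region.end].sum()) * depth_ratio, EPSILON)
    # P(X >= observed) = sf(observed - 1)
    return float(stats.poisson.sf(observed - 1, lam))
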
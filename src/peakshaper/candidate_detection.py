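"""Multi-scale enrichment mapping and candidate peak extraction.

A base is "enriched" under one definition — a (smoothing window, fold) pair —
when the rolling mean of coverage over that window strictly exceeds
fold x mean chromosome coverage.  With window sizes {100, 200, 400, 800,
1600} bp and folds {2, 4, 8, 16, 32} there are 25 definitions; the per-base
count of satisfied definitions forms the enrichment map.  Maximal runs with
at least 5 concurring definitions become candidate regions, subject to size
rules: runs under 50 bp are dropped, runs over 2 kb are re-segmented within
their own extent at an incremented requirement, recursively, until the size
fits or all 25 definitions are required (such "saturated" regions are kept
whatever their size).

Because every threshold is a multiple of the chromosome mean, the map — and
hence the candidate set — is invariant to rescaling the track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from peakshaper.coverage_io import CoverageTrack, GenomicRegion

DEFAULT_WINDOW_SIZES = (100, 200, 400, 800, 1600)
DEFAULT_FOLDS = (2, 4, 8, 16, 32)


@dataclass(frozen=True)
class EnrichmentParams:
    """Grids and size rules for the candidate detector."""

    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES
    folds: tuple[float, ...] = DEFAULT_FOLDS
    min_concurrence: int = 5
    min_width: int = 50
    max_width: int = 2000

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.window_sizes):
            raise ValueError("window sizes must be >= 1")
        if any(f <= 0 for f in self.folds):
            raise ValueError("folds must be positive")
        if not 1 <= self.min_concurrence <= self.n_definitions:
            raise ValueError("min_concurrence out of range")

    @property
    def n_definitions(self) -> int:
        return len(self.window_sizes) * len(self.folds)

    @property
    def definitions(self) -> list[tuple[int, float]]:
        """All (window, fold) pairs, window-major."""
        return [(w, f) for w in self.window_sizes for f in self.folds]


@dataclass
class EnrichmentMap:
    """Per-base count of satisfied enrichment definitions per chromosome."""

    chrom_names: list[str]
    counts: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            arr = self.counts[name]
            if arr.size and (arr.min() < 0):
                raise ValueError(f"{name}: negative definition count")


@dataclass(frozen=True)
class CandidatePeak:
    """A detector-emitted interval.

    ``n_definitions`` is the concurrence requirement at which the region was
    emitted; ``saturated`` marks regions enriched under every definition
    (exempt from the upper size bound); ``height`` is the maximum per-base
    coverage inside the region.
    """

    region: GenomicRegion
    n_definitions: int
    saturated: bool
    height: float


def rolling_mean(signal: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean with shrinking windows at the edges.

    The value at base ``i`` is the mean of ``signal`` over
    ``[i - floor(window/2), i + ceil(window/2))`` clipped to the array, so
    edge windows shrink rather than padding with phantom zeros.  Output
    length equals input length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValueError("signal must be non-empty")
    n = signal.size
    idx = np.arange(n)
    lo = np.maximum(idx - window // 2, 0)
    hi = np.minimum(idx + (window - window // 2), n)
    csum = np.concatenate(([0.0], np.cumsum(signal)))
    return (csum[hi] - csum[lo]) / (hi - lo)


def build_enrichment_map(track: CoverageTrack, params: EnrichmentParams | None = None) -> EnrichmentMap:
    """Count, per base, the enrichment definitions satisfied there.

    For each chromosome and each (window, fold) pair the test is strict:
    ``rolling_mean(signal, window)[i] > fold * mean(signal)`` with the mean
    taken over the whole chromosome including zero bases.
    """
    if params is None:
        params = EnrichmentParams()
    counts: dict[str, np.ndarray] = {}
    for chrom in track.chrom_names:
        signal = track.values[chrom]
        if signal.size == 0:
            counts[chrom] = np.zeros(0, dtype=np.int16)
            continue
        chrom_mean = float(np.sum(signal)) / signal.size
        total = np.zeros(signal.size, dtype=np.int16)
        for window in params.window_sizes:
            smoothed = rolling_mean(signal, window)
            for fold in params.folds:
                total += smoothed > fold * chrom_mean
        counts[chrom] = total
    return EnrichmentMap(list(track.chrom_names), counts)


def _runs_at_least(counts: np.ndarray, requirement: int, start: int, end: int):
    """Maximal runs of counts >= requirement within [start, end)."""
    mask = counts[start:end] >= requirement
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(start + edges[i], start + edges[i + 1]) for i in range(0, edges.size, 2)]


def _extract_chrom(
    counts: np.ndarray,
    signal: np.ndarray,
    chrom: str,
    params: EnrichmentParams,
) -> list[CandidatePeak]:
    max_req = params.n_definitions
    out: list[CandidatePeak] = []
    # (start, end, requirement) work stack; recursion stays within the parent run
    stack: list[tuple[int, int, int]] = [
        (s, e, params.min_concurrence)
        for s, e in _runs_at_least(counts, params.min_concurrence, 0, counts.size)
    ]
    while stack:
        s, e, req = stack.pop()
        width = e - s
        if width < params.min_width:
            continue
        if width <= params.max_width or req == max_req:
            out.append(
                CandidatePeak(
                    region=GenomicRegion(chrom, int(s), int(e)),
                    n_definitions=req,
                    saturated=req == max_req,
                    height=float(signal[s:e].max()),
                )
            )
            continue
        for s2, e2 in _runs_at_least(counts, req + 1, s, e):
            stack.append((s2, e2, req + 1))
    out.sort(key=lambda pk: pk.region.start)
    return out


def extract_candidates(
    emap: EnrichmentMap,
    track: CoverageTrack,
    params: EnrichmentParams | None = None,
) -> list[CandidatePeak]:
    """Extract candidate peaks from an enrichment map.

    Candidates are pairwise disjoint and sorted by (track chromosome order,
    start).
    """
    if params is None:
        params = EnrichmentParams()
    if list(emap.chrom_names) != list(track.chrom_names):
        raise ValueError("enrichment map and track cover different chromosomes")
    peaks: list[CandidatePeak] = []
    for chrom in track.chrom_names:
        peaks.extend(
            _extract_chrom(emap.counts[chrom], track.values[chrom], chrom, params)
        )
    return peaks


def detect(track: CoverageTrack, params: EnrichmentParams | None = None) -> list[CandidatePeak]:
    """Convenience: build the enrichment map and extract candidates."""
    if params is None:
        params = EnrichmentParams()
    return extract_candidates(build_enrichment_map(track, params), track, params)
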
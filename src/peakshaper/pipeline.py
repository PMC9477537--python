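"""End-to-end operating modes over track files.

Three modes: find-and-score (detect candidates, score them all), the same
with an input control (adds per-region Poisson P-values), and score-only
(no detection; score intervals supplied in a BED file).  All candidates are
written with their scores — the threshold only sets a pass/fail flag, so
nothing below it is hidden from the output.
"""

from __future__ import annotations

import logging
from pathlib import Path

from peakshaper.candidate_detection import EnrichmentParams, detect
from peakshaper.coverage_io import (
    CoverageTrack,
    ValidationError,
    read_coverage,
    read_regions,
    write_peaks,
)
from peakshaper.features import featurize, pvalue_vs_input
from peakshaper.model import PeakScorer, ScoredPeak, load_models, score_bundles

logger = logging.getLogger(__name__)


def _load_scorer(model_path) -> PeakScorer:
    path = Path(model_path)
    if not (path / "descriptor.json").exists():
        raise FileNotFoundError(
            f"no model bundle at {path}: train one with `peakshaper train` "
            "or point --model at an existing bundle directory"
        )
    return load_models(path)


def _score_candidates(
    track: CoverageTrack,
    scorer: PeakScorer,
    input_track: CoverageTrack | None = None,
    params: EnrichmentParams | None = None,
) -> list[ScoredPeak]:
    candidates = detect(track, params)
    bundles = [featurize(track, c.region) for c in candidates]
    scores = score_bundles(scorer, bundles)
    out = []
    for cand, row in zip(candidates, scores):
        pval = (
            pvalue_vs_input(track, input_track, cand.region)
            if input_track is not None
            else None
        )
        out.append(
            ScoredPeak(
                region=cand.region,
                shape_score=float(row[0]),
                enrichment_score=float(row[1]),
                peak_score=float(row[2]),
                height=cand.height,
                n_definitions=cand.n_definitions,
                saturated=cand.saturated,
                pvalue=pval,
            )
        )
    return out


def call_peaks(
    track_path,
    model_path,
    out_path,
    score_threshold: float = 0.5,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> list[ScoredPeak]:
    """Find-and-score mode: detect candidates, score all, write BED.

    Inference is deterministic; ``seed`` exists for interface symmetry with
    training commands and future stochastic extensions.
    """
    track = read_coverage(track_path, chrom_lengths=chrom_lengths)
    scorer = _load_scorer(model_path)
    peaks = _score_candidates(track, scorer)
    write_peaks(peaks, out_path, threshold=score_threshold, chrom_order=track.chrom_names)
    return peaks


def call_peaks_with_input(
    track_path,
    input_path,
    model_path,
    out_path,
    score_threshold: float = 0.5,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> list[ScoredPeak]:
    """Find-and-score with an input control track: adds a P-value column."""
    track = read_coverage(track_path, chrom_lengths=chrom_lengths)
    input_track = read_coverage(input_path, chrom_lengths=chrom_lengths)
    mismatched = [
        c
        for c in set(track.chrom_names) | set(input_track.chrom_names)
        if track.chrom_lengths.get(c) != input_track.chrom_lengths.get(c)
    ]
    if mismatched:
        raise ValidationError(
            "treatment and input disagree on chromosomes: " + ", ".join(sorted(mismatched))
        )
    scorer = _load_scorer(model_path)
    peaks = _score_candidates(track, scorer, input_track=input_track)
    write_peaks(peaks, out_path, threshold=score_threshold, chrom_order=track.chrom_names)
    return peaks


def score_bed(
    track_path,
    bed_path,
    model_path,
    out_path,
    chrom_lengths: dict[str, int] | None = None,
) -> int:
    """Score-only mode: featurize and score the supplied intervals.

    Input row order and original columns are preserved; the three score
    columns are appended.  Rows on unknown chromosomes are skipped with a
    warning; returns the number of rows skipped.
    """
    track = read_coverage(track_path, chrom_lengths=chrom_lengths)
    scorer = _load_scorer(model_path)
    lengths = track.chrom_lengths
    kept_lines: list[list[str]] = []
    bundles = []
    n_skipped = 0
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if chrom not in lengths or end > lengths[chrom] or start < 0 or start >= end:
                logger.warning("%s:%d: region off track chromosomes, skipping", bed_path, lineno)
                n_skipped += 1
                continue
            from peakshaper.coverage_io import GenomicRegion

            bundles.append(featurize(track, GenomicRegion(chrom, start, end)))
            kept_lines.append(fields)
    scores = score_bundles(scorer, bundles)
    with open(out_path, "w") as fh:
        for fields, row in zip(kept_lines, scores):
            fh.write(
                "\t".join(fields + [f"{row[2]:.4f}", f"{row[0]:.4f}", f"{row[1]:.4f}"]) + "\n"
            )
    return n_skipped


def read_scored_peaks(path) -> list[ScoredPeak]:
    """Read a BED written by :func:`peakshaper.coverage_io.write_peaks`."""
    from peakshaper.coverage_io import GenomicRegion

    out: list[ScoredPeak] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            pval = None
            if len(f) >= 8 and f[7] not in ("", "0", "1"):
                pval = float(f[7])
            out.append(
                ScoredPeak(
                    region=GenomicRegion(f[0], int(f[1]), int(f[2])),
                    peak_score=float(f[3]),
                    shape_score=float(f[4]),
                    enrichment_score=float(f[5]),
                    height=float(f[6]),
                    pvalue=pval,
                )
            )
    return out
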
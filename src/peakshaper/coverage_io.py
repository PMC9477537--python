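"""Reading and writing coverage tracks, region files and scored peak calls.

Coordinates are 0-based half-open throughout (BED / bigWig native).  bedGraph
is the dependency-light text format used by fixtures and tests; bigWig input
is supported when :mod:`pyBigWig` is installed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from peakshaper.model import ScoredPeak

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file could not be parsed in the named format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Per-base coverage values for a set of chromosomes.

    Attributes
    ----------
    chrom_names : list of str
        Ordered, unique chromosome identifiers.
    values : dict mapping chromosome name to ndarray
        One non-negative float64 array per chromosome, length equal to the
        chromosome length.
    """

    chrom_names: list[str]
    values: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("chromosome names must be unique")
        if set(self.chrom_names) != set(self.values):
            raise ValidationError("chrom_names and values keys differ")
        for name in self.chrom_names:
            arr = np.asarray(self.values[name], dtype=np.float64)
            if arr.ndim != 1:
                raise ValidationError(f"{name}: coverage must be 1-D")
            if arr.size and float(arr.min()) < 0:
                raise ValidationError(f"{name}: negative coverage value")
            self.values[name] = arr

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: int(self.values[name].size) for name in self.chrom_names}

    def chrom_length(self, chrom: str) -> int:
        return int(self.values[chrom].size)

    def scale(self, c: float) -> "CoverageTrack":
        """Return a copy with every value multiplied by ``c`` (c > 0)."""
        if c <= 0:
            raise ValidationError("scale factor must be positive")
        return CoverageTrack(
            list(self.chrom_names),
            {name: self.values[name] * c for name in self.chrom_names},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return self.chrom_names == other.chrom_names and all(
            np.array_equal(self.values[n], other.values[n]) for n in self.chrom_names
        )


def _read_bedgraph(path: Path, chrom_lengths: dict[str, int] | None) -> CoverageTrack:
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start_s, end_s, value_s = fields[:4]
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if value < 0:
                raise ValidationError(f"{path}:{lineno}: negative coverage {value}")
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: bad interval {start}-{end}")
            if chrom not in intervals:
                intervals[chrom] = []
                order.append(chrom)
            intervals[chrom].append((start, end, value))

    if chrom_lengths is not None:
        for chrom in chrom_lengths:
            if chrom not in intervals:
                intervals[chrom] = []
                order.append(chrom)
        order = [c for c in order if c in chrom_lengths]

    values: dict[str, np.ndarray] = {}
    for chrom in order:
        ivs = intervals[chrom]
        declared = chrom_lengths.get(chrom) if chrom_lengths else None
        length = declared if declared is not None else max((e for _, e, _ in ivs), default=0)
        arr = np.zeros(length, dtype=np.float64)
        for start, end, value in ivs:
            if end > length:
                raise ValidationError(
                    f"{path}: interval {chrom}:{start}-{end} exceeds length {length}"
                )
            arr[start:end] = value
        values[chrom] = arr
    return CoverageTrack(order, values)


def _read_bigwig(path: Path) -> CoverageTrack:
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            "bigWig support requires the optional pyBigWig dependency; "
            "install peakshaper[bigwig] or supply a bedGraph track"
        ) from exc
    bw = pyBigWig.open(str(path))  # pragma: no cover - optional dependency
    try:  # pragma: no cover
        order = list(bw.chroms())
        values = {}
        for chrom, length in bw.chroms().items():
            arr = np.nan_to_num(
                np.asarray(bw.values(chrom, 0, length), dtype=np.float64)
            )
            if arr.size and arr.min() < 0:
                raise ValidationError(f"{chrom}: negative coverage value")
            values[chrom] = arr
        return CoverageTrack(order, values)
    finally:  # pragma: no cover
        bw.close()


def read_coverage(
    path: str | Path,
    format: str | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> CoverageTrack:
    """Read a coverage track into per-base arrays.

    Parameters
    ----------
    path : path to a bigWig or bedGraph file.
    format : "bigwig" or "bedgraph"; inferred from the suffix when omitted.
    chrom_lengths : optional declared chromosome lengths for bedGraph input,
        whose header carries none.  Bases absent from the file are coverage 0.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = "bigwig" if path.suffix.lower() in {".bw", ".bigwig"} else "bedgraph"
    if format == "bigwig":
        return _read_bigwig(path)
    if format == "bedgraph":
        return _read_bedgraph(path, chrom_lengths)
    raise FormatError(f"unknown track format: {format!r}")


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, run-length encoding equal-valued spans.

    Zero runs are written too, so the chromosome length is recoverable from
    the file alone.  Values are written with ``repr`` so float64 round-trips
    exactly.
    """
    with open(path, "w") as fh:
        for chrom in track.chrom_names:
            arr = track.values[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{float(arr[s])!r}\n")


def read_regions(path: str | Path, chrom_lengths: dict[str, int] | None = None):
    """Read BED3+ intervals in file order; extra columns are ignored.

    Regions on chromosomes absent from ``chrom_lengths`` (when given) are
    skipped with a warning rather than aborting, so partial scoring works.
    Returns ``(regions, n_skipped)``.
    """
    regions: list[GenomicRegion] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            if chrom_lengths is not None and chrom not in chrom_lengths:
                logger.warning("%s:%d: unknown chromosome %s, skipping", path, lineno, chrom)
                n_skipped += 1
                continue
            regions.append(GenomicRegion(chrom, start, end))
    return regions, n_skipped


def write_peaks(
    peaks: Sequence["ScoredPeak"],
    path: str | Path,
    threshold: float | None = None,
    chrom_order: Iterable[str] | None = None,
) -> None:
    """Write scored peaks as tab-separated BED3+.

    Columns: chrom, start, end, peak_score, shape_score, enrichment_score,
    height, then a pvalue column (present only when peaks carry P-values),
    then a 0/1 pass flag when ``threshold`` is given.  Scores use fixed
    4-decimal precision.  Peaks must be sorted by (chromosome order, start).
    """
    order = {c: i for i, c in enumerate(chrom_order)} if chrom_order is not None else None
    has_pvals = any(pk.pvalue is not None for pk in peaks)
    last: tuple[int | str, int] | None = None
    lines = []
    for pk in peaks:
        r = pk.region
        key_chrom = order[r.chrom] if order is not None else r.chrom
        key = (key_chrom, r.start)
        if last is not None and key < last:
            raise ValidationError("peaks must be sorted by (chrom order, start)")
        last = key
        cols = [
            r.chrom,
            str(r.start),
            str(r.end),
            f"{pk.peak_score:.4f}",
            f"{pk.shape_score:.4f}",
            f"{pk.enrichment_score:.4f}",
            f"{pk.height:.4f}",
        ]
        if has_pvals:
            cols.append("" if pk.pvalue is None else f"{pk.pvalue:.4e}")
        if threshold is not None:
            cols.append("1" if pk.peak_score >= threshold else "0")
        lines.append("\t".join(cols))
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
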
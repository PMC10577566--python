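"""Genomic data model and plain-text I/O shared by all pipeline stages.

Coordinates are 0-based half-open throughout (BED/bedGraph native). The
containers are deliberately light: intervals are frozen records, coverage is
a dense numpy vector with an origin/step, and count matrices wrap a pandas
DataFrame plus optional per-sample size factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "CoverageTrack",
    "CountMatrix",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "bin_fragment_midpoints",
    "estimate_size_factors",
    "window_max_coverage",
]

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally with a summit."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    summit: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie within [start, end)")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end - 1) // 2

    @property
    def anchor(self) -> int:
        """Summit when present, interval midpoint otherwise."""
        return self.summit if self.summit is not None else self.midpoint

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def jaccard(self, other: "GenomicInterval") -> float:
        inter = self.overlap_length(other)
        union = len(self) + len(other) - inter
        return inter / union if union else 0.0


@dataclass
class CoverageTrack:
    """Dense per-position (or per-bin) nonnegative coverage on one chromosome."""

    chrom: str
    values: np.ndarray
    origin: int = 0
    step: int = 1
    strand: str = "."

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.values.size and self.values.min() < 0:
            raise ValueError("coverage values must be nonnegative")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    @property
    def end(self) -> int:
        return self.origin + self.step * self.values.size

    def slice_bp(self, start: int, end: int) -> np.ndarray:
        """Values over the bp window [start, end), zero-padded off-track."""
        if self.step != 1:
            raise ValueError("slice_bp requires a per-bp track (step == 1)")
        out = np.zeros(max(0, end - start), dtype=float)
        lo = max(start, self.origin)
        hi = min(end, self.end)
        if lo < hi:
            out[lo - start : hi - start] = self.values[lo - self.origin : hi - self.origin]
        return out


@dataclass
class CountMatrix:
    """Feature-by-sample nonnegative integer counts with optional size factors."""

    counts: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.size_factors is not None:
            sf = np.asarray(self.size_factors, dtype=float)
            if (sf <= 0).any():
                raise ValueError("size factors must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not estimated")
        return self.counts / self.size_factors

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df)


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6(+) records; track/browser/comment lines are skipped.

    An optional 7th column is interpreted as an absolute summit position.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
            summit = int(fields[6]) if len(fields) > 6 and fields[6] != "" else None
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand, name, summit)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name or ".", "0", iv.strand]
            if iv.summit is not None:
                fields.append(str(iv.summit))
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path, chrom: str | None = None) -> CoverageTrack:
    """Read a bedGraph into a dense per-bp track (zeros fill the gaps).

    Records must be non-overlapping and nonnegative. With more than one
    chromosome in the file, `chrom` selects which to load.
    """
    rows: list[tuple[int, int, float]] = []
    seen_chrom: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            c, s, e, v = line.split("\t")[:4]
            if chrom is not None and c != chrom:
                continue
            if seen_chrom is None:
                seen_chrom = c
            elif c != seen_chrom:
                raise ValueError(
                    f"{path}:{lineno}: multiple chromosomes; pass chrom= to select one"
                )
            start, end, value = int(s), int(e), float(v)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: empty interval")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage value")
            rows.append((start, end, value))
    if not rows:
        return CoverageTrack(chrom=chrom or "", values=np.zeros(0))
    rows.sort()
    for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping bedGraph records at {seen_chrom}:{s2}")
    origin = rows[0][0]
    values = np.zeros(rows[-1][1] - origin, dtype=float)
    for s, e, v in rows:
        values[s - origin : e - origin] = v
    return CoverageTrack(chrom=seen_chrom or "", values=values, origin=origin)


def write_bedgraph(track: CoverageTrack, path: str | Path, append: bool = False) -> None:
    """Write a track as run-length-collapsed bedGraph; zero runs are omitted."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        vals = track.values
        i = 0
        n = vals.size
        while i < n:
            j = i + 1
            while j < n and vals[j] == vals[i]:
                j += 1
            if vals[i] != 0:
                s = track.origin + i * track.step
                e = track.origin + j * track.step
                fh.write(f"{track.chrom}\t{s}\t{e}\t{vals[i]:g}\n")
            i = j


# ---------------------------------------------------------------------------
# Binning, normalization, coverage summaries
# ---------------------------------------------------------------------------

def fragment_midpoint(frag: GenomicInterval) -> int:
    return (frag.start + frag.end - 1) // 2


def bin_fragment_midpoints(
    fragments: Sequence[GenomicInterval],
    bin_size: int,
    chrom_length: int | None = None,
) -> tuple[np.ndarray, int]:
    """Count fragment midpoints in consecutive `bin_size` bp bins.

    Returns (counts, n_bins). Bins are [i*bin_size, (i+1)*bin_size) from
    position 0. Fragments on multiple chromosomes must be split by caller.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if chrom_length is None:
        chrom_length = max((f.end for f in fragments), default=0)
    n_bins = -(-chrom_length // bin_size) if chrom_length else 0
    counts = np.zeros(n_bins, dtype=np.int64)
    for f in fragments:
        b = fragment_midpoint(f) // bin_size
        if 0 <= b < n_bins:
            counts[b] += 1
    return counts, n_bins


def estimate_size_factors(cm: CountMatrix) -> CountMatrix:
    """Median-of-ratios size factors (the convention of count-based
    differential testing), computed over features with a positive geometric
    mean across samples."""
    counts = cm.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "fall back to total-count normalization"
        )
    log_geo = np.log(counts[positive]).mean(axis=1)
    ratios = np.log(counts[positive]) - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    sf = pd.Series(factors, index=cm.counts.columns, name="size_factor")
    return CountMatrix(counts=cm.counts, size_factors=sf)


def total_count_size_factors(cm: CountMatrix) -> CountMatrix:
    """Documented fallback: per-sample totals scaled to mean 1."""
    totals = cm.counts.sum(axis=0).astype(float)
    sf = totals / totals.mean()
    sf.name = "size_factor"
    return CountMatrix(counts=cm.counts, size_factors=sf)


def window_max_coverage(
    track: CoverageTrack,
    intervals: Sequence[GenomicInterval],
    width: int = 500,
) -> np.ndarray:
    """Maximum coverage in a `width` bp window centered on each summit.

    The window is [summit - width//2, summit - width//2 + width), i.e.
    left-closed for even widths, clipped to the track extent. Intervals
    fully off-track score 0 (with a warning).
    """
    out = np.zeros(len(intervals), dtype=float)
    half = width // 2
    for i, iv in enumerate(intervals):
        if iv.summit is None:
            raise ValueError(f"interval {iv.name or i} lacks a summit")
        lo = iv.summit - half
        window = track.slice_bp(lo, lo + width)
        if window.size == 0 or (iv.summit + width - half <= track.origin or lo >= track.end):
            warnings.warn(f"interval {iv.name or i} lies entirely off-track")
            out[i] = 0.0
        else:
            out[i] = window.max() if window.size else 0.0
    return out
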
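"""Genomic file I/O and the internal coordinate convention.

Everything downstream works in 0-based half-open (BED) coordinates. Inputs
in 1-based inclusive coordinates (HOMER-style peak tables) are converted at
the boundary by ``read_peaks(dialect="one_based")``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

H3_MARKS = ("H3K4me3", "H3K27me3", "H3K27ac")
KNOWN_MARKS = H3_MARKS + ("survivin", "other")


class ParseError(ValueError):
    """A malformed line in a genomic text file; the message names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genome location, 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Shared bases with ``other`` (0 when on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share at least one base."""
        return self.overlap_len(other) >= 1


@dataclass(frozen=True, order=True)
class Peak:
    """A called peak for one mark, with raw and library-normalized tag counts.

    ``norm_tags`` are tags per 10 million mapped reads. When a peak table
    carries no separate score column the score is taken equal to the
    normalized tag count.
    """

    interval: GenomicInterval
    mark: str
    raw_tags: float = 0.0
    norm_tags: float = 0.0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.raw_tags < 0 or self.norm_tags < 0 or self.score < 0:
            raise ValueError("tag counts and scores must be non-negative")


class GenomeLayout(Mapping[str, int]):
    """Chromosome name -> length (bp). Validates intervals against bounds."""

    def __init__(self, sizes: Mapping[str, int]):
        for name, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._sizes = dict(sizes)

    def __getitem__(self, key: str) -> int:
        return self._sizes[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def validate(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self._sizes:
            raise ValueError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self._sizes[interval.chrom]:
            raise ValueError(
                f"interval {interval} exceeds chromosome length "
                f"{self._sizes[interval.chrom]}"
            )

    def validate_peaks(self, peaks: Iterable[Peak]) -> None:
        for p in peaks:
            self.validate(p.interval)


def read_peaks(path, mark: str, dialect: str = "bed0") -> list[Peak]:
    """Read a BED3+ peak table into validated, sorted :class:`Peak` records.

    Columns: chrom, start, end[, tag_count[, score]]. ``dialect="one_based"``
    converts 1-based inclusive starts to the internal half-open convention.
    Missing tag/score columns default to 0 with a logged warning.
    """
    if dialect not in ("bed0", "one_based"):
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks: list[Peak] = []
    warned_cols = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}, line {lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: non-integer coordinate") from exc
            if dialect == "one_based":
                start -= 1
            tags = 0.0
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}, line {lineno}: bad score") from exc
            if len(fields) >= 4 and fields[3] not in (".", ""):
                try:
                    tags = float(fields[3])
                except ValueError as exc:
                    raise ParseError(f"{path}, line {lineno}: bad tag count") from exc
            else:
                warned_cols = True
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
            # score defaults to the normalized tag count when absent
            peaks.append(
                Peak(interval, mark, raw_tags=tags, norm_tags=tags,
                     score=tags if score is None else score)
            )
    if warned_cols:
        logger.warning("%s: missing tag/score columns defaulted to 0", path)
    peaks.sort()
    return peaks


def write_bed(peaks: Iterable[Peak], path) -> None:
    """Write peaks as sorted BED5 (chrom, start, end, tags, score), 0-based.

    The tag column carries the normalized tag count, which is what every
    downstream stage consumes; reading the file back therefore reproduces
    the peak set whenever raw and normalized tags coincide.
    """
    rows = sorted(peaks)
    with open(path, "w") as fh:
        for p in rows:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.norm_tags:g}\t{p.score:g}\n"
            )


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a two-column chrom.sizes TSV (name, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}, line {lineno}: expected 2 columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: non-integer length") from exc
            if name in sizes:
                raise ParseError(f"{path}, line {lineno}: duplicate chromosome {name!r}")
            sizes[name] = length
    return GenomeLayout(sizes)


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.items():
            fh.write(f"{name}\t{length}\n")


@dataclass
class ScoreTrack:
    """A genome-wide piecewise-constant score (bedGraph semantics).

    Positions not covered by any bedGraph interval score 0. Per chromosome
    the track is stored as breakpoints plus a cumulative integral so that
    interval means are O(log n).
    """

    _chroms: dict = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, records: Iterable[tuple[str, int, int, float]]) -> "ScoreTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if end <= start:
                raise ValueError(f"bedGraph interval with end <= start on {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        track = cls()
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            bounds = [0]
            vals: list[float] = []
            for start, end, value in ivs:
                if start < bounds[-1]:
                    raise ValueError(f"overlapping bedGraph intervals on {chrom}")
                if start > bounds[-1]:
                    bounds.append(start)
                    vals.append(0.0)
                bounds.append(end)
                vals.append(value)
            b = np.asarray(bounds, dtype=float)
            v = np.asarray(vals, dtype=float)
            cum = np.concatenate([[0.0], np.cumsum(v * np.diff(b))])
            track._chroms[chrom] = (b, v, cum)
        return track

    @classmethod
    def read_bedgraph(cls, path) -> "ScoreTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="t",
                         names=["chrom", "start", "end", "value"])
        return cls.from_intervals(df.itertuples(index=False, name=None))

    def _integral_at(self, chrom: str, x: np.ndarray) -> np.ndarray:
        if chrom not in self._chroms:
            return np.zeros_like(np.asarray(x, dtype=float))
        b, v, cum = self._chroms[chrom]
        x = np.clip(np.asarray(x, dtype=float), b[0], b[-1])
        idx = np.clip(np.searchsorted(b, x, side="right") - 1, 0, len(v) - 1)
        return cum[idx] + v[idx] * (x - b[idx])

    def mean(self, chrom: str, starts, ends) -> np.ndarray:
        """Mean score over [start, end) windows; uncovered bases count as 0."""
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        with np.errstate(invalid="ignore"):
            out = (self._integral_at(chrom, ends) - self._integral_at(chrom, starts)) / (
                ends - starts
            )
        return np.where(ends > starts, out, 0.0)
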
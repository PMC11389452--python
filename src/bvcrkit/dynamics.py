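"""Tag-deposition dynamics between conditions.

Covers library-size normalization (tags per 10 million mapped), the signed
fold change (ratio when >= 1, negative reciprocal otherwise, with a
pseudocount on both terms), percentage tag change per region and mark,
detection of "changeable" regions whose dominant H3 mark shifts after
treatment, and profile matrices of a score track around regions
(scale-regions and reference-point modes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .caller import BivalentRegion, assign_dominance
from .genomic_io import H3_MARKS, GenomicInterval, ScoreTrack

logger = logging.getLogger(__name__)


@dataclass
class TagChangeRecord:
    region_id: str
    mark: str
    pre_tags: float
    post_tags: float
    pct_change: float
    signed_fc: float


@dataclass
class ShiftRecord:
    region_id: str
    dominant_pre: str
    dominant_post: str

    @property
    def changeable(self) -> bool:
        return self.dominant_pre != self.dominant_post

    @property
    def transition(self) -> tuple[str, str]:
        return (self.dominant_pre, self.dominant_post)


def normalize_tags(raw, total_mapped) -> float:
    """Scale a raw tag count to a library of 10 million mapped reads."""
    if np.any(np.asarray(total_mapped) <= 0):
        raise ValueError("total_mapped must be positive")
    return raw * 1e7 / total_mapped


def signed_fold_change(a: float, b: float, pseudocount: float = 1.0) -> float:
    """Fold change a/b reported with magnitude >= 1 and a sign.

    ``r = (a+pc)/(b+pc)``; returns ``r`` when ``r >= 1`` and ``-1/r``
    otherwise, so the magnitude is always max/min and the sign says which
    argument is larger.
    """
    if a < 0 or b < 0:
        raise ValueError("signals must be non-negative")
    num, den = a + pseudocount, b + pseudocount
    if den == 0:
        if num == 0:
            raise ValueError("both terms zero with zero pseudocount")
        return np.inf
    r = num / den
    return r if r >= 1 else -1.0 / r


def tag_pct_change(region_id: str, mark: str, pre: float, post: float,
                   pseudocount: float = 1.0) -> TagChangeRecord:
    """Relative tag change in percent: 100 * (post - pre) / (pre + pc)."""
    pct = 100.0 * (post - pre) / (pre + pseudocount)
    return TagChangeRecord(region_id, mark, pre, post, pct,
                           signed_fold_change(post, pre, pseudocount))


def tag_share_change(tag_pct_pre: Mapping[str, float],
                     tag_pct_post: Mapping[str, float], mark: str) -> float:
    """Alternative change measure: difference in within-region tag-share points."""
    return tag_pct_post.get(mark, 0.0) - tag_pct_pre.get(mark, 0.0)


def detect_changeable(
    regions: Iterable[BivalentRegion],
    pre_tags: Mapping[str, Mapping[str, float]],
    post_tags: Mapping[str, Mapping[str, float]],
) -> list[ShiftRecord]:
    """Find regions whose dominant H3 mark differs between conditions.

    ``pre_tags`` and ``post_tags`` map region id -> mark -> normalized tag
    sum. Regions with zero total H3 tags in either condition are excluded
    with a warning; dominance is recomputed per condition with the same
    argmax/tie rules as the caller.
    """
    records: list[ShiftRecord] = []
    skipped = 0
    for r in regions:
        doms = []
        for tags in (pre_tags, post_tags):
            probe = BivalentRegion(interval=r.interval,
                                   tag_sum=dict(tags.get(r.region_id, {})))
            assign_dominance(probe)
            doms.append(probe.dominant)
        if doms[0] is None or doms[1] is None:
            skipped += 1
            continue
        records.append(ShiftRecord(r.region_id, doms[0], doms[1]))
    if skipped:
        warnings.warn(f"{skipped} regions with zero H3 tags in a condition excluded")
    return records


def collect_region_tags(
    regions: Iterable[BivalentRegion],
    peaks_by_mark: Mapping[str, Iterable],
) -> dict[str, dict[str, float]]:
    """Per-region normalized tag sums of the peaks overlapping each region.

    Used to re-quantify regions called in one condition against the peak
    set of another condition (>= 1 bp overlap assigns a peak to a region).
    """
    from intervaltree import IntervalTree

    regions = list(regions)
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.interval.chrom, IntervalTree()).addi(
            r.interval.start, r.interval.end, r.region_id)
    sums: dict[str, dict[str, float]] = {r.region_id: {} for r in regions}
    for mark, peaks in peaks_by_mark.items():
        for p in peaks:
            tree = trees.get(p.interval.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(p.interval.start, p.interval.end):
                d = sums[hit.data]
                d[mark] = d.get(mark, 0.0) + p.norm_tags
    return sums


def changeable_fraction(records: Iterable[ShiftRecord]) -> float:
    records = list(records)
    if not records:
        return float("nan")
    return sum(rec.changeable for rec in records) / len(records)


@dataclass
class ProfileMatrix:
    """Regions x bins matrix of a score track around regions."""

    values: np.ndarray
    region_ids: list
    mode: str
    body_width: int
    flank: int
    bin_size: int

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def row_summary(self, aggregate: str = "mean") -> np.ndarray:
        if aggregate == "mean":
            return self.values.mean(axis=1)
        if aggregate == "max":
            return self.values.max(axis=1)
        raise ValueError(f"unknown aggregate {aggregate!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_ids)


def profile_matrix(
    regions: Iterable[BivalentRegion],
    track: ScoreTrack,
    mode: str = "scale_regions",
    body_width: int = 500,
    flank: int = 2000,
    bin_size: int = 50,
) -> ProfileMatrix:
    """Bin a score track around regions, deepTools-computeMatrix style.

    ``scale_regions``: each region body, whatever its width, is rescaled
    onto ``body_width`` bases and binned, with ``flank`` bases of real
    coordinates binned on each side — (2*flank + body_width) / bin_size
    columns (90 with the defaults 500/2000/50). ``reference_point``: bins
    cover [center - flank, center + flank) around the region midpoint
    floor((start+end)/2). Bases with no track coverage score 0; windows
    reaching past a chromosome edge also read 0 there.
    """
    if mode not in ("scale_regions", "reference_point"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "scale_regions" and (2 * flank + body_width) % bin_size:
        raise ValueError("bin_size must divide 2*flank + body_width")
    if mode == "reference_point" and (2 * flank) % bin_size:
        raise ValueError("bin_size must divide 2*flank")

    regions = list(regions)
    n_flank_bins = flank // bin_size
    rows = []
    ids = []
    for r in regions:
        iv: GenomicInterval = r.interval if isinstance(r, BivalentRegion) else r
        chrom = iv.chrom
        if mode == "scale_regions":
            left = iv.start - flank + bin_size * np.arange(n_flank_bins + 1)
            body = iv.start + (iv.end - iv.start) * np.linspace(
                0.0, 1.0, body_width // bin_size + 1
            )
            right = iv.end + bin_size * np.arange(n_flank_bins + 1)
            edges = np.concatenate([left, body[1:], right[1:]])
        else:
            center = (iv.start + iv.end) // 2
            edges = center - flank + bin_size * np.arange(2 * n_flank_bins + 1)
        rows.append(track.mean(chrom, edges[:-1], edges[1:]))
        ids.append(getattr(r, "region_id", "") or f"{chrom}:{iv.start}-{iv.end}")
    values = np.vstack(rows) if rows else np.empty((0, 2 * n_flank_bins + body_width // bin_size))
    return ProfileMatrix(values, ids, mode, body_width, flank, bin_size)
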
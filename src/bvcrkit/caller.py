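"""Bivalent chromatin region (BvCR) calling and dominance statistics.

A BvCR is a merged footprint of mutually overlapping histone-mark peaks
(H3K4me3, H3K27me3 and — configurably — H3K27ac). Overlap means at least
one shared base in half-open coordinates; a maximum gap of zero bases is
enforced, so touching-but-not-overlapping peaks do not merge. Within each
region the H3 mark contributing the largest share of normalized tags is
the dominant mark, and regions overlapped by a survivin peak are flagged
survivin-positive (S+BvCR).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2
from statsmodels.stats.proportion import proportions_ztest

from .genomic_io import H3_MARKS, GenomicInterval, Peak

logger = logging.getLogger(__name__)

# fixed tie-break priority for the dominant mark
MARK_PRIORITY = {m: i for i, m in enumerate(H3_MARKS)}


@dataclass
class BivalentRegion:
    """A merged footprint with per-mark tag bookkeeping and flags."""

    interval: GenomicInterval
    member_peaks: dict = field(default_factory=dict)  # mark -> list[Peak]
    tag_sum: dict = field(default_factory=dict)       # mark -> normalized tags
    tag_pct: dict = field(default_factory=dict)       # H3 marks -> % of H3 total
    dominant: str | None = None
    tie_flag: bool = False
    survivin_positive: bool = False
    region_id: str = ""

    @property
    def has_h3_tags(self) -> bool:
        return sum(self.tag_sum.get(m, 0.0) for m in H3_MARKS) > 0


def merge_connected(peak_sets: Sequence[Iterable[Peak]]):
    """Connected components of the >=1-bp-overlap graph across peak sets.

    Returns a list of ``(footprint_interval, members)`` pairs where
    ``members`` maps each mark to its contributing peaks. Because overlap
    is an interval relation, components are exactly the maximal runs found
    by a sorted sweep that merges while the next start precedes the
    running maximum end (strictly — adjacency in half-open coordinates is
    a zero-base overlap and does not connect).
    """
    all_peaks: list[Peak] = sorted(p for ps in peak_sets for p in ps)
    footprints = []
    current: list[Peak] = []
    cur_chrom, cur_end = None, -1

    def _flush():
        if not current:
            return
        members: dict[str, list[Peak]] = {}
        for p in current:
            members.setdefault(p.mark, []).append(p)
        iv = GenomicInterval(cur_chrom,
                             min(p.interval.start for p in current),
                             max(p.interval.end for p in current))
        footprints.append((iv, members))

    for p in all_peaks:
        if p.interval.chrom != cur_chrom or p.interval.start >= cur_end:
            _flush()
            current = [p]
            cur_chrom, cur_end = p.interval.chrom, p.interval.end
        else:
            current.append(p)
            cur_end = max(cur_end, p.interval.end)
    _flush()
    return footprints


def assign_dominance(region: BivalentRegion) -> BivalentRegion:
    """Set ``tag_pct``, ``dominant`` and ``tie_flag`` from the H3 tag sums.

    The dominant mark is the argmax of the tag share; exact ties fall back
    to the fixed priority H3K4me3 > H3K27me3 > H3K27ac with the tie flag
    raised. Regions with zero H3 tags get ``dominant=None`` and are
    excluded from dominance statistics by callers.
    """
    sums = {m: float(region.tag_sum.get(m, 0.0)) for m in H3_MARKS}
    total = sum(sums.values())
    if total <= 0:
        region.tag_pct = {}
        region.dominant = None
        region.tie_flag = False
        return region
    region.tag_pct = {m: 100.0 * s / total for m, s in sums.items()}
    best = max(sums.values())
    winners = [m for m in H3_MARKS if sums[m] == best]
    region.dominant = min(winners, key=MARK_PRIORITY.__getitem__)
    region.tie_flag = len(winners) > 1
    return region


def call_bvcr(
    k4: Iterable[Peak],
    k27me3: Iterable[Peak],
    k27ac: Iterable[Peak],
    required_marks: Iterable[str] = H3_MARKS,
) -> list[BivalentRegion]:
    """Call BvCR: merged footprints containing every required mark.

    The default requires peaks of all three H3 marks; passing
    ``required_marks={"H3K4me3", "H3K27me3"}`` gives the two-methyl-mark
    definition of bivalency.
    """
    required = set(required_marks)
    if not required:
        raise ValueError("required_marks must not be empty")
    regions: list[BivalentRegion] = []
    for iv, members in merge_connected([k4, k27me3, k27ac]):
        if not required.issubset(members):
            continue
        region = BivalentRegion(
            interval=iv,
            member_peaks=members,
            tag_sum={m: sum(p.norm_tags for p in ps) for m, ps in members.items()},
        )
        assign_dominance(region)
        regions.append(region)
    for i, r in enumerate(regions):
        r.region_id = f"bvcr_{i:05d}"
    return regions


def flag_survivin(regions: Iterable[BivalentRegion],
                  survivin_peaks: Iterable[Peak]) -> list[BivalentRegion]:
    """Flag regions overlapped (>=1 bp) by any survivin peak."""
    trees: dict[str, IntervalTree] = {}
    for p in survivin_peaks:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end
        )
    out = []
    for r in regions:
        tree = trees.get(r.interval.chrom)
        r.survivin_positive = bool(tree.overlap(r.interval.start, r.interval.end)) if tree else False
        out.append(r)
    return out


def chi_square_homogeneity(counts: np.ndarray):
    """Pearson chi-square homogeneity test on a strata x categories table.

    Cells whose expected count is zero (an all-zero category column)
    contribute nothing to the statistic; degrees of freedom stay
    (rows-1)(cols-1). Returns ``(statistic, df, p)``.
    """
    counts = np.asarray(counts, dtype=float)
    row_tot = counts.sum(axis=1, keepdims=True)
    col_tot = counts.sum(axis=0, keepdims=True)
    total = counts.sum()
    if total <= 0 or (row_tot == 0).any():
        raise ValueError("every stratum needs at least one observation")
    expected = row_tot * col_tot / total
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = float(contrib.sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return stat, df, float(chi2.sf(stat, df))


def dominance_frequency_table(
    regions: Iterable[BivalentRegion], stratify_by_survivin: bool = True
):
    """Counts and percentages of the dominant mark, optionally per stratum.

    Returns ``(table, chi2_result)`` where the table has one row per
    stratum (survivin-negative / survivin-positive, or a single "all"
    row) with per-mark counts and percentages, and ``chi2_result`` is the
    ``(statistic, df, p)`` of the chi-square homogeneity test over the
    strata x marks count table (None when a stratum is empty or
    stratification is off).
    """
    regs = [r for r in regions if r.dominant is not None]
    if stratify_by_survivin:
        strata = {"S-": [r for r in regs if not r.survivin_positive],
                  "S+": [r for r in regs if r.survivin_positive]}
    else:
        strata = {"all": regs}
    rows = []
    for name, rs in strata.items():
        counts = {m: sum(1 for r in rs if r.dominant == m) for m in H3_MARKS}
        n = len(rs)
        row = {"stratum": name, "n": n}
        for m in H3_MARKS:
            row[f"count_{m}"] = counts[m]
            row[f"pct_{m}"] = 100.0 * counts[m] / n if n else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    result = None
    if stratify_by_survivin:
        counts = table[[f"count_{m}" for m in H3_MARKS]].to_numpy()
        if (counts.sum(axis=1) > 0).all():
            result = chi_square_homogeneity(counts)
        else:
            warnings.warn("empty stratum: chi-square homogeneity test skipped")
    return table, result


def compare_prevalence(hits_a: int, n_a: int, hits_b: int, n_b: int):
    """Two-proportion pooled z test without continuity correction.

    Returns ``(z, p_two_sided)`` comparing ``hits_a/n_a`` with
    ``hits_b/n_b`` — e.g. the prevalence of dominance shifts among
    survivin-positive vs survivin-negative BvCR.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= hits_a <= n_a and 0 <= hits_b <= n_b):
        raise ValueError("hit counts must lie in [0, n]")
    z, p = proportions_ztest([hits_a, hits_b], [n_a, n_b])
    return float(z), float(p)
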
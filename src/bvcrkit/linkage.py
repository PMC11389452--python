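"""Linking BvCR to genes through cis-regulatory elements, and aggregating
onto a hierarchical DNA-damage-response (DDR) network.

The element universe is the union of enhancer intervals (with their
curated gene links), gene bodies, and strand-aware 2-kb upstream
promoters. A BvCR is linked to a gene whenever it overlaps (>= 1 bp) an
element associated with that gene; links are then filtered to expressed
protein-coding genes (base mean > 1) and intersected with differential-
expression contrasts (nominal p < 0.05 flags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .caller import BivalentRegion
from .genomic_io import H3_MARKS, GenomicInterval

logger = logging.getLogger(__name__)

PROMOTER_WIDTH = 2000
DEG_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class RegulatoryElement:
    interval: GenomicInterval
    gene_id: str
    element_class: str  # enhancer | gene_body | promoter
    element_id: str


def build_element_universe(
    enhancers: pd.DataFrame | None,
    gene_models: pd.DataFrame,
    promoter_width: int = PROMOTER_WIDTH,
) -> list[RegulatoryElement]:
    """Union of enhancers, gene bodies and 2-kb upstream promoters.

    ``enhancers``: columns chrom, start, end, gene_id[, element_id].
    ``gene_models``: columns gene_id, chrom, start, end, strand, tss.
    Promoters extend ``promoter_width`` bp upstream of the TSS on the
    gene's strand, clipped at the chromosome start (a promoter that would
    be entirely off-chromosome is dropped).
    """
    elements: list[RegulatoryElement] = []
    if enhancers is not None and len(enhancers):
        for i, row in enumerate(enhancers.itertuples(index=False)):
            eid = getattr(row, "element_id", None) or f"enh_{i:05d}"
            elements.append(RegulatoryElement(
                GenomicInterval(row.chrom, int(row.start), int(row.end)),
                str(row.gene_id), "enhancer", str(eid)))
    for row in gene_models.itertuples(index=False):
        gid = str(row.gene_id)
        strand = getattr(row, "strand", None)
        if strand not in ("+", "-"):
            raise ValueError(f"gene {gid}: strand must be '+' or '-'")
        elements.append(RegulatoryElement(
            GenomicInterval(row.chrom, int(row.start), int(row.end)),
            gid, "gene_body", f"body_{gid}"))
        tss = int(row.tss)
        if strand == "+":
            p_start, p_end = max(0, tss - promoter_width), tss
        else:
            p_start, p_end = tss, tss + promoter_width
        if p_end > p_start:
            elements.append(RegulatoryElement(
                GenomicInterval(row.chrom, p_start, p_end),
                gid, "promoter", f"prom_{gid}"))
    return elements


def link_regions_to_genes(
    regions: Iterable[BivalentRegion],
    elements: Iterable[RegulatoryElement],
) -> pd.DataFrame:
    """One link per (region, element, gene) with >= 1 bp overlap.

    Genes reached through several elements or several BvCR keep every
    link. Returns a DataFrame with region/element/gene identities, the
    region's dominant mark, survivin flag, and per-mark tag percentages.
    """
    trees: dict[str, IntervalTree] = {}
    for el in elements:
        trees.setdefault(el.interval.chrom, IntervalTree()).addi(
            el.interval.start, el.interval.end, el)
    rows = []
    for r in regions:
        tree = trees.get(r.interval.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(r.interval.start, r.interval.end),
                          key=lambda h: (h.begin, h.end, h.data.element_id)):
            el: RegulatoryElement = hit.data
            row = {
                "region_id": r.region_id,
                "chrom": r.interval.chrom,
                "region_start": r.interval.start,
                "region_end": r.interval.end,
                "element_id": el.element_id,
                "element_class": el.element_class,
                "gene_id": el.gene_id,
                "dominant": r.dominant,
                "survivin_positive": r.survivin_positive,
            }
            for m in H3_MARKS:
                row[f"tag_pct_{m}"] = r.tag_pct.get(m, np.nan)
            rows.append(row)
    cols = ["region_id", "chrom", "region_start", "region_end", "element_id",
            "element_class", "gene_id", "dominant", "survivin_positive",
            *[f"tag_pct_{m}" for m in H3_MARKS]]
    return pd.DataFrame(rows, columns=cols)


def filter_expressed(
    links: pd.DataFrame,
    expression: pd.DataFrame,
    base_mean_min: float = 1.0,
    biotype: str = "protein_coding",
) -> pd.DataFrame:
    """Keep links to expressed protein-coding genes.

    ``expression``: columns gene_id, biotype, base_mean. Retains links
    whose gene has base_mean strictly greater than ``base_mean_min`` and
    the required biotype; genes absent from the table are dropped with a
    logged count. Idempotent.
    """
    expr = expression.drop_duplicates("gene_id").set_index("gene_id")
    known = links["gene_id"].isin(expr.index)
    if (~known).any():
        logger.info("dropping %d links to genes absent from the expression table",
                    int((~known).sum()))
    kept = links[known].copy()
    if not len(kept):
        return kept
    gene_ok = (expr.loc[kept["gene_id"], "base_mean"].to_numpy() > base_mean_min) & (
        expr.loc[kept["gene_id"], "biotype"].to_numpy() == biotype)
    return kept[gene_ok].reset_index(drop=True)


def flag_deg_contrasts(
    links: pd.DataFrame,
    contrasts: Mapping[str, pd.DataFrame],
    p_threshold: float = DEG_P_THRESHOLD,
) -> pd.DataFrame:
    """Attach per-contrast log2FC/p and a DEG flag (nominal p < threshold).

    ``contrasts`` maps a contrast label (e.g. "ifn", "ifn_ym155") to a
    table with columns gene_id, log2fc, pvalue; adds columns
    ``log2fc_<label>``, ``p_<label>`` and ``<label>_sensitive``.
    """
    out = links.copy()
    for label, tab in contrasts.items():
        t = tab.drop_duplicates("gene_id").set_index("gene_id")
        out[f"log2fc_{label}"] = out["gene_id"].map(t["log2fc"])
        out[f"p_{label}"] = out["gene_id"].map(t["pvalue"])
        out[f"{label}_sensitive"] = out[f"p_{label}"] < p_threshold
    return out


def annotate_ddr_network(
    links: pd.DataFrame,
    network_map: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate BvCR-gene links onto hierarchical network nodes.

    ``network_map``: columns gene_id, node_id[, parent]. Per node:
    connected-gene count and percentage of the node's genes reached by a
    BvCR, the mean of each H3 mark's tag percentage over the linked BvCR
    (each (region, gene) pair counted once), and the dominant mark as the
    argmax of those means. Genes mapped to several nodes contribute to
    every node. Nodes with no connected genes keep an undefined dominant
    mark.
    """
    pct_cols = [f"tag_pct_{m}" for m in H3_MARKS]
    uniq = links.drop_duplicates(["region_id", "gene_id"])
    rows = []
    for node_id, node in network_map.groupby("node_id", sort=True):
        genes = set(node["gene_id"])
        sub = uniq[uniq["gene_id"].isin(genes)]
        connected = sub["gene_id"].nunique()
        row = {
            "node_id": node_id,
            "parent": node["parent"].iloc[0] if "parent" in node else "",
            "n_genes": len(genes),
            "n_connected": connected,
            "pct_connected": 100.0 * connected / len(genes) if genes else 0.0,
        }
        if len(sub):
            means = sub[pct_cols].mean()
            for m, c in zip(H3_MARKS, pct_cols):
                row[f"mean_tag_pct_{m}"] = float(means[c])
            row["dominant_mark"] = H3_MARKS[int(np.argmax(means.to_numpy()))]
        else:
            for m in H3_MARKS:
                row[f"mean_tag_pct_{m}"] = np.nan
            row["dominant_mark"] = None
        rows.append(row)
    return pd.DataFrame(rows)
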
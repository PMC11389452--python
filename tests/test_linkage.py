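import numpy as np
import pandas as pd
import pytest

from bvcrkit.caller import BivalentRegion, call_bvcr, flag_survivin
from bvcrkit.genomic_io import H3_MARKS, GenomicInterval
from bvcrkit.linkage import (RegulatoryElement, annotate_ddr_network,
                             build_element_universe, filter_expressed,
                             flag_deg_contrasts, link_regions_to_genes)
from bvcrkit.simulate import SynthConfig, simulate_enhancer_links, simulate_peak_landscape


def gene_models(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "tss"])


def region(start, end, rid="r0", dominant="H3K4me3", pcts=(70, 20, 10),
           survivin=False):
    r = BivalentRegion(interval=GenomicInterval("c", start, end), region_id=rid)
    r.dominant = dominant
    r.tag_pct = dict(zip(H3_MARKS, pcts))
    r.survivin_positive = survivin
    return r


class TestElementUniverse:
    def test_plus_strand_promoter(self):
        els = build_element_universe(None, gene_models(
            [("g1", "c", 5000, 8000, "+", 5000)]))
        prom = [e for e in els if e.element_class == "promoter"][0]
        assert (prom.interval.start, prom.interval.end) == (3000, 5000)

    def test_minus_strand_promoter_downstream_of_body_end(self):
        els = build_element_universe(None, gene_models(
            [("g1", "c", 2000, 5000, "-", 5000)]))
        prom = [e for e in els if e.element_class == "promoter"][0]
        assert (prom.interval.start, prom.interval.end) == (5000, 7000)

    def test_promoter_clipped_at_chromosome_start(self):
        els = build_element_universe(None, gene_models(
            [("g1", "c", 500, 2000, "+", 500)]))
        prom = [e for e in els if e.element_class == "promoter"][0]
        assert (prom.interval.start, prom.interval.end) == (0, 500)

    def test_missing_strand_is_error(self):
        with pytest.raises(ValueError, match="strand"):
            build_element_universe(None, gene_models(
                [("g1", "c", 0, 100, ".", 0)]))

    def test_enhancers_keep_gene_association(self):
        enh = pd.DataFrame([{"chrom": "c", "start": 10, "end": 60,
                             "gene_id": "g9", "element_id": "e1"}])
        els = build_element_universe(enh, gene_models(
            [("g1", "c", 5000, 8000, "+", 5000)]))
        classes = {e.element_class for e in els}
        assert classes == {"enhancer", "gene_body", "promoter"}
        assert [e.gene_id for e in els if e.element_class == "enhancer"] == ["g9"]


class TestLinkRegions:
    def elements(self):
        return [
            RegulatoryElement(GenomicInterval("c", 0, 1000), "g1", "enhancer", "e1"),
            RegulatoryElement(GenomicInterval("c", 800, 1800), "g1", "enhancer", "e2"),
            RegulatoryElement(GenomicInterval("c", 5000, 6000), "g2", "enhancer", "e3"),
        ]

    def test_region_inside_enhancer_links_once(self):
        links = link_regions_to_genes([region(100, 200)], self.elements())
        assert len(links) == 1
        assert links.iloc[0]["gene_id"] == "g1"

    def test_two_elements_same_gene_two_links(self):
        links = link_regions_to_genes([region(700, 1100)], self.elements())
        assert len(links) == 2
        assert links["gene_id"].nunique() == 1

    def test_adjacent_region_not_linked(self):
        links = link_regions_to_genes([region(1800, 1900)], self.elements())
        assert links.empty

    def test_planted_linkage_recovered_exactly(self):
        cfg = SynthConfig(seed=13, n_bvcr=300, n_decoys_per_mark=50,
                          n_survivin_decoys=20, n_genes=120)
        peaks, truth = simulate_peak_landscape(cfg)
        genes, enhancers, _ = simulate_enhancer_links(cfg, truth)
        regions = call_bvcr(peaks["H3K4me3"], peaks["H3K27me3"], peaks["H3K27ac"])
        flag_survivin(regions, peaks["survivin"])
        els = build_element_universe(enhancers, genes)
        links = link_regions_to_genes(regions, els)
        # ground truth: the genes whose enhancer covers a planted locus
        locus_ivs = {(row.chrom, row.start, row.end) for row in
                     truth.itertuples(index=False)}
        enh_hits = set()
        for e in enhancers.itertuples(index=False):
            for c, s, t in locus_ivs:
                if e.chrom == c and e.start < t and e.end > s:
                    enh_hits.add(e.gene_id)
        assert set(links["gene_id"]) == enh_hits
        assert (links["element_class"] == "enhancer").all()


class TestFilterExpressed:
    def expression(self):
        return pd.DataFrame([
            {"gene_id": "g1", "biotype": "protein_coding", "base_mean": 0.5},
            {"gene_id": "g2", "biotype": "protein_coding", "base_mean": 1.0},
            {"gene_id": "g3", "biotype": "lincRNA", "base_mean": 100.0},
            {"gene_id": "g4", "biotype": "protein_coding", "base_mean": 7.0},
        ])

    def links(self, genes):
        return pd.DataFrame({"region_id": "r0", "gene_id": list(genes)})

    def test_threshold_biotype_and_strict_boundary(self):
        out = filter_expressed(self.links(["g1", "g2", "g3", "g4"]),
                               self.expression())
        assert list(out["gene_id"]) == ["g4"]

    def test_unknown_genes_dropped(self):
        out = filter_expressed(self.links(["g4", "gX"]), self.expression())
        assert list(out["gene_id"]) == ["g4"]

    def test_idempotent_and_order_independent(self):
        links = self.links(["g4", "g2", "g4", "g1"])
        once = filter_expressed(links, self.expression())
        twice = filter_expressed(once, self.expression())
        assert once.equals(twice)
        shuffled = filter_expressed(links.iloc[::-1].reset_index(drop=True),
                                    self.expression())
        assert sorted(shuffled["gene_id"]) == sorted(once["gene_id"])


class TestDegFlags:
    def test_nominal_p_threshold(self):
        links = pd.DataFrame({"region_id": ["r0", "r1"], "gene_id": ["g1", "g2"]})
        contrast = pd.DataFrame([
            {"gene_id": "g1", "log2fc": 1.5, "pvalue": 0.04},
            {"gene_id": "g2", "log2fc": -0.5, "pvalue": 0.06},
        ])
        out = flag_deg_contrasts(links, {"ifn": contrast})
        assert list(out["ifn_sensitive"]) == [True, False]


class TestDdrNetwork:
    def test_single_node_dominant_mark(self):
        links = link_regions_to_genes(
            [region(100, 200, pcts=(70, 20, 10))],
            [RegulatoryElement(GenomicInterval("c", 0, 1000), "g1", "enhancer", "e1")])
        nodes = annotate_ddr_network(links, pd.DataFrame(
            [{"gene_id": "g1", "node_id": "n1", "parent": "root"}]))
        assert nodes.iloc[0]["dominant_mark"] == "H3K4me3"
        assert nodes.iloc[0]["pct_connected"] == pytest.approx(100.0)

    def test_unconnected_node(self):
        links = pd.DataFrame(columns=["region_id", "gene_id",
                                      *[f"tag_pct_{m}" for m in H3_MARKS]])
        nodes = annotate_ddr_network(links, pd.DataFrame(
            [{"gene_id": "g1", "node_id": "n1", "parent": "root"}]))
        assert nodes.iloc[0]["pct_connected"] == 0.0
        assert nodes.iloc[0]["dominant_mark"] is None

    def test_node_averages_match_flat_recomputation(self):
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(30)]
        rows = []
        for i in range(60):
            pcts = rng.dirichlet([1, 1, 1]) * 100
            rows.append({"region_id": f"r{i}", "gene_id": genes[int(rng.integers(30))],
                         **{f"tag_pct_{m}": p for m, p in zip(H3_MARKS, pcts)}})
        links = pd.DataFrame(rows)
        net = pd.DataFrame([{"gene_id": g, "node_id": f"n{int(rng.integers(5))}",
                             "parent": "root"} for g in genes])
        nodes = annotate_ddr_network(links, net).set_index("node_id")
        for node_id, sub in net.groupby("node_id"):
            node_genes = set(sub["gene_id"])
            flat = links[links["gene_id"].isin(node_genes)]
            flat = flat.drop_duplicates(["region_id", "gene_id"])
            if len(flat):
                for m in H3_MARKS:
                    assert nodes.loc[node_id, f"mean_tag_pct_{m}"] == pytest.approx(
                        flat[f"tag_pct_{m}"].mean())
            assert nodes.loc[node_id, "n_connected"] == flat["gene_id"].nunique()
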
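"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the study system —
multi-mark peak landscapes with planted bivalent loci and decoys,
treatment-induced dominance shifts, survivin colocalization, expression
changes coupled to tag changes through a Gaussian copula, enhancer–gene
links with a toy hierarchical network, and a peptide array whose
intensities follow a planted composition rule plus noise. Every
generator is a pure function of (config, rng): identical outputs across
runs for the same seed.

Defaults follow the reported study conditions: 6000 bivalent loci, a
0.43/0.33/0.24 dominance mix, 65% survivin colocalization, an 8.5%
dominance-shift fraction, a planted Spearman correlation of 0.6 between
tag change and transcription change, and microarray intensity thresholds
at 30,000/10,000/1,000 fluorescence units.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import peptide as pep
from .genomic_io import H3_MARKS, GenomeLayout, GenomicInterval, Peak, write_bed

AA = pep.AMINO_ACIDS


@dataclass
class SynthConfig:
    """All knobs of the synthetic study, with the study conditions as defaults."""

    seed: int = 0
    # genome
    n_chromosomes: int = 5
    chrom_length: int = 6_000_000
    # peak landscape
    n_bvcr: int = 6000
    dominance_mix: tuple = (0.43, 0.33, 0.24)
    survivin_coloc_fraction: float = 0.65
    shift_fraction: float = 0.085
    n_decoys_per_mark: int = 500
    n_survivin_decoys: int = 500
    locus_width: tuple = (500, 1500)
    decoy_width: tuple = (200, 800)
    # negative-binomial tag model (overdispersed ChIP-seq counts)
    tag_mean_dominant: float = 120.0
    tag_mean_other: float = 25.0
    tag_mean_survivin: float = 50.0
    tag_dispersion: float = 10.0
    dominance_margin: float = 1.5   # dominant tags at least this multiple of runner-up
    treatment_noise_sd: float = 0.1  # lognormal sigma on unshifted tags
    # expression
    n_genes: int = 2000
    expression_rho: float = 0.6      # target Spearman between tag and transcription change
    deg_fraction: float = 0.3
    noncoding_fraction: float = 0.15
    low_expression_fraction: float = 0.1
    # enhancer links / network
    n_network_nodes: int = 10
    network_gene_fraction: float = 0.3
    linked_gene_fraction: float = 0.6
    # peptide array: 9 proteins and ~1500 tiles, the scale of the real
    # microarray covering the BRG1/SWI subunits
    n_proteins: int = 9
    protein_length: tuple = (300, 1200)
    min_aromatic: int = 3            # planted rule: tile binds iff >= this many ring groups
    intensity_base: float = 2000.0
    intensity_effect: float = 25000.0
    intensity_noise_sd: float = 0.4  # lognormal sigma
    n_replicates: int = 2

    def __post_init__(self):
        if abs(sum(self.dominance_mix) - 1.0) > 1e-9:
            raise ValueError("dominance_mix must sum to 1")
        for f in (self.survivin_coloc_fraction, self.shift_fraction,
                  self.deg_fraction, *self.dominance_mix):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")

    def genome(self) -> GenomeLayout:
        return GenomeLayout({f"chr{i + 1}": self.chrom_length
                             for i in range(self.n_chromosomes)})


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _nb(rng, mean: float, dispersion: float, size=None):
    """Negative-binomial draws with the given mean and size (dispersion)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _planted_tags(rng, cfg: SynthConfig, dominant_idx: int) -> np.ndarray:
    """Draw one tag triple and make ``dominant_idx`` the strict argmax.

    The largest of the three draws is swapped into the planted mark (which
    keeps the draw multiset) and then lifted to at least
    ``dominance_margin`` times the runner-up so dominance survives mild
    treatment noise.
    """
    means = np.full(3, cfg.tag_mean_other)
    means[dominant_idx] = cfg.tag_mean_dominant
    tags = np.array([_nb(rng, m, cfg.tag_dispersion) for m in means], dtype=float)
    top = int(np.argmax(tags))
    if top != dominant_idx:
        tags[top], tags[dominant_idx] = tags[dominant_idx], tags[top]
    runner_up = max(np.delete(tags, dominant_idx))
    tags[dominant_idx] = max(tags[dominant_idx],
                             np.ceil(cfg.dominance_margin * max(runner_up, 1.0)))
    return tags


#: top-of-chromosome span reserved for gene models and unlinked enhancers,
#: so peak loci never touch them and link ground truth stays exact
GENE_ZONE = 250_000


def _slots(cfg: SynthConfig, n_needed: int, rng) -> list[tuple[str, int]]:
    """Non-overlapping placement slots spread over the genome, shuffled.

    Slots cover only the span below the reserved gene zone at the top of
    each chromosome.
    """
    per_chrom = -(-n_needed // cfg.n_chromosomes)
    usable = cfg.chrom_length - GENE_ZONE
    if usable <= 0:
        raise ValueError("chromosomes shorter than the reserved gene zone")
    pitch = usable // per_chrom
    max_width = max(cfg.locus_width[1], cfg.decoy_width[1]) + 300
    if pitch <= max_width:
        raise ValueError("genome too small for the requested number of regions")
    slots = [(f"chr{c + 1}", s * pitch)
             for c in range(cfg.n_chromosomes) for s in range(per_chrom)]
    order = rng.permutation(len(slots))
    return [slots[i] for i in order]


def simulate_peak_landscape(cfg: SynthConfig, rng=None):
    """Pre-treatment peak landscape with planted bivalent loci and decoys.

    Returns ``(peaks, truth)`` where ``peaks`` maps mark -> list[Peak]
    (the three H3 marks plus survivin) and ``truth`` is one row per
    planted locus: interval, planted dominant mark, survivin flag and the
    per-mark tag values. Decoy single-mark peaks and decoy survivin peaks
    occupy their own slots, so no decoy touches a planted locus.
    """
    rng = _rng(cfg.seed if rng is None else rng)
    n_decoys = 3 * cfg.n_decoys_per_mark + cfg.n_survivin_decoys
    slots = _slots(cfg, cfg.n_bvcr + n_decoys, rng)
    peaks: dict[str, list[Peak]] = {m: [] for m in (*H3_MARKS, "survivin")}
    truth_rows = []
    dom_draw = rng.choice(3, size=cfg.n_bvcr, p=list(cfg.dominance_mix))
    coloc_draw = rng.random(cfg.n_bvcr) < cfg.survivin_coloc_fraction

    for i in range(cfg.n_bvcr):
        chrom, base = slots[i]
        width = int(rng.integers(*cfg.locus_width))
        start = base + int(rng.integers(0, 200))
        end = start + width
        tags = _planted_tags(rng, cfg, int(dom_draw[i]))
        row = {"locus_id": f"locus_{i:05d}", "chrom": chrom,
               "start": start, "end": end,
               "planted_dominant": H3_MARKS[int(dom_draw[i])],
               "survivin_positive": bool(coloc_draw[i])}
        for j, mark in enumerate(H3_MARKS):
            # each mark's peak jitters inside the locus but keeps the center
            j_l = int(rng.integers(0, max(1, width // 5)))
            j_r = int(rng.integers(0, max(1, width // 5)))
            iv = GenomicInterval(chrom, start + j_l, end - j_r)
            peaks[mark].append(Peak(iv, mark, raw_tags=tags[j],
                                    norm_tags=float(tags[j]), score=float(tags[j])))
            row[f"tags_{mark}"] = float(tags[j])
        if coloc_draw[i]:
            center = (start + end) // 2
            sv_tags = float(_nb(rng, cfg.tag_mean_survivin, cfg.tag_dispersion))
            iv = GenomicInterval(chrom, max(0, center - 100), center + 100)
            peaks["survivin"].append(Peak(iv, "survivin", raw_tags=sv_tags,
                                          norm_tags=sv_tags, score=sv_tags))
        truth_rows.append(row)

    cursor = cfg.n_bvcr
    for mark in H3_MARKS:
        for _ in range(cfg.n_decoys_per_mark):
            chrom, base = slots[cursor]
            cursor += 1
            width = int(rng.integers(*cfg.decoy_width))
            start = base + int(rng.integers(0, 200))
            t = float(_nb(rng, cfg.tag_mean_other, cfg.tag_dispersion))
            peaks[mark].append(Peak(GenomicInterval(chrom, start, start + width),
                                    mark, raw_tags=t, norm_tags=t, score=t))
    for _ in range(cfg.n_survivin_decoys):
        chrom, base = slots[cursor]
        cursor += 1
        width = int(rng.integers(*cfg.decoy_width))
        start = base + int(rng.integers(0, 200))
        t = float(_nb(rng, cfg.tag_mean_survivin, cfg.tag_dispersion))
        peaks["survivin"].append(Peak(GenomicInterval(chrom, start, start + width),
                                      "survivin", raw_tags=t, norm_tags=t, score=t))
    # H3 lists keep locus i at position i (decoys follow) so the treatment
    # generator can redraw tags positionally; writers sort on output and
    # readers sort on load.
    return peaks, pd.DataFrame(truth_rows)


def simulate_treatment(peaks, truth: pd.DataFrame, cfg: SynthConfig, rng=None):
    """Post-treatment H3 tag redraw with a planted dominance-shift fraction.

    A ``shift_fraction`` subset of loci is redrawn with a different
    dominant mark (chosen uniformly among the other two); the rest keep
    their tags up to multiplicative lognormal noise, so their dominance
    is preserved except for rare near-tie flips. Peak intervals are
    unchanged. Returns ``(post_peaks, post_truth)`` with a
    ``planted_shifted`` column.
    """
    rng = _rng(cfg.seed + 1 if rng is None else rng)
    post_peaks = {m: list(ps) for m, ps in peaks.items()}
    mark_idx = {m: j for j, m in enumerate(H3_MARKS)}
    shifted = rng.random(len(truth)) < cfg.shift_fraction
    post_truth = truth.copy()
    post_truth["planted_shifted"] = shifted

    # peaks for locus i occupy position i in each H3 mark's list (decoys follow)
    new_dominants = []
    for i, row in enumerate(truth.itertuples(index=False)):
        pre_dom = mark_idx[row.planted_dominant]
        if shifted[i]:
            others = [j for j in range(3) if j != pre_dom]
            new_dom = int(rng.choice(others))
            tags = _planted_tags(rng, cfg, new_dom)
        else:
            new_dom = pre_dom
            tags = np.array([getattr(row, f"tags_{m}") for m in H3_MARKS])
            tags = tags * np.exp(rng.normal(0.0, cfg.treatment_noise_sd, size=3))
        new_dominants.append(H3_MARKS[new_dom])
        for j, mark in enumerate(H3_MARKS):
            old = post_peaks[mark][i]
            post_peaks[mark][i] = Peak(old.interval, mark, raw_tags=float(tags[j]),
                                       norm_tags=float(tags[j]), score=float(tags[j]))
            post_truth.loc[post_truth.index[i], f"tags_{mark}"] = float(tags[j])
    post_truth["planted_dominant"] = new_dominants
    for mark in H3_MARKS:
        decoys = post_peaks[mark][len(truth):]
        noisy = []
        for p in decoys:
            t = p.norm_tags * float(np.exp(rng.normal(0.0, cfg.treatment_noise_sd)))
            noisy.append(Peak(p.interval, mark, raw_tags=t, norm_tags=t, score=t))
        post_peaks[mark] = sorted(post_peaks[mark][:len(truth)] + noisy)
    return post_peaks, post_truth


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation giving a target Spearman under a Gaussian copula."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def simulate_expression(cfg: SynthConfig, rng=None, tag_changes=None,
                        gene_ids=None) -> pd.DataFrame:
    """Expression table with a planted tag–transcription coupling.

    Per gene: a standardized tag-deposition change x (supplied or drawn
    N(0,1)), a transcription change (log2FC) drawn jointly with x under a
    Gaussian copula whose Pearson parameter is chosen so the population
    Spearman equals ``expression_rho``, a lognormal base mean (a
    ``low_expression_fraction`` pushed below 1), a biotype column, and
    p-values giving the planted DEG fraction nominal p < 0.05.
    """
    rng = _rng(cfg.seed + 2 if rng is None else rng)
    n = cfg.n_genes if tag_changes is None else len(tag_changes)
    if gene_ids is None:
        gene_ids = [f"gene_{i:05d}" for i in range(n)]
    x = rng.standard_normal(n) if tag_changes is None else np.asarray(tag_changes, float)
    r = spearman_to_pearson(cfg.expression_rho)
    y = r * x + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    base_mean = np.exp(rng.normal(3.0, 1.5, size=n))
    low = rng.random(n) < cfg.low_expression_fraction
    base_mean[low] = rng.uniform(0.0, 1.0, size=int(low.sum()))
    biotype = np.where(rng.random(n) < cfg.noncoding_fraction,
                       "lincRNA", "protein_coding")
    deg = rng.random(n) < cfg.deg_fraction
    pvals = np.where(deg, rng.uniform(0.0, 0.05, size=n),
                     rng.uniform(0.05, 1.0, size=n))
    return pd.DataFrame({
        "gene_id": gene_ids, "biotype": biotype, "base_mean": base_mean,
        "tag_change": x, "log2fc": y, "pvalue": pvals, "planted_deg": deg,
    })


def simulate_enhancer_links(cfg: SynthConfig, truth: pd.DataFrame, rng=None):
    """Gene models, enhancers linked to genes, and a toy hierarchical network.

    A ``linked_gene_fraction`` of genes get an enhancer that covers a
    planted bivalent locus (guaranteeing a BvCR–gene link); the rest get
    enhancers in the reserved top-of-chromosome gene zone, which no peak
    locus can reach, so the recovered link table equals the planted one
    exactly. Strands alternate and the TSS is the strand-appropriate body
    end. Returns ``(gene_models, enhancers, network_map)`` frames.
    """
    rng = _rng(cfg.seed + 3 if rng is None else rng)
    n = cfg.n_genes
    genome = cfg.genome()
    chroms = list(genome)
    rows_g, rows_e = [], []
    linked = rng.random(n) < cfg.linked_gene_fraction
    loci = truth.sample(n=n, replace=True, random_state=int(rng.integers(2**31)))
    for i in range(n):
        gid = f"gene_{i:05d}"
        strand = "+" if i % 2 == 0 else "-"
        chrom = chroms[i % len(chroms)]
        # bodies tucked high on the chromosome, clear of the peak slots
        start = genome[chrom] - 200_000 + (i // len(chroms)) % 100 * 1500
        end = start + 1200
        tss = start if strand == "+" else end
        rows_g.append({"gene_id": gid, "chrom": chrom, "start": start, "end": end,
                       "strand": strand, "tss": tss})
        if linked[i]:
            locus = loci.iloc[i]
            rows_e.append({"chrom": locus["chrom"],
                           "start": int(locus["start"]) - 50,
                           "end": int(locus["end"]) + 50,
                           "gene_id": gid, "element_id": f"enh_{i:05d}"})
        else:
            # unlinked enhancers live in the free band of the gene zone,
            # below the gene bodies and clear of every peak locus
            e_start = int(rng.integers(genome[chrom] - GENE_ZONE + 2_000,
                                       genome[chrom] - 210_000))
            rows_e.append({"chrom": chrom, "start": e_start, "end": e_start + 500,
                           "gene_id": gid, "element_id": f"enh_{i:05d}"})
    gene_models = pd.DataFrame(rows_g)
    enhancers = pd.DataFrame(rows_e)

    in_net = rng.random(n) < cfg.network_gene_fraction
    rows_n = []
    for i in np.flatnonzero(in_net):
        node = int(rng.integers(cfg.n_network_nodes))
        rows_n.append({"gene_id": f"gene_{i:05d}", "node_id": f"node_{node:02d}",
                       "parent": f"branch_{node % 3}"})
        if rng.random() < 0.2:  # some genes sit in two hierarchy nodes
            other = (node + 1 + int(rng.integers(cfg.n_network_nodes - 1))) \
                % cfg.n_network_nodes
            rows_n.append({"gene_id": f"gene_{i:05d}",
                           "node_id": f"node_{other:02d}",
                           "parent": f"branch_{other % 3}"})
    network_map = pd.DataFrame(rows_n)
    return gene_models, enhancers, network_map


def aromatic_rule(sequence: str, min_aromatic: int) -> bool:
    """Planted binding rule: a tile binds iff it carries at least
    ``min_aromatic`` aromatic ring groups (F/Y benzene rings plus the W
    indole)."""
    enc = pep.encode_cpos(sequence)
    per_pos = enc.reshape(pep.TILE_LENGTH, len(pep.GROUPS))
    idx = [pep.GROUPS.index("aromatic"), pep.GROUPS.index("indole")]
    return float(per_pos[:, idx].sum()) >= min_aromatic


def simulate_peptide_array(cfg: SynthConfig, rng=None):
    """Random proteins plus a microarray table following the planted rule.

    Intensity per tile is ``(base + effect * rule) * exp(sigma * Z)``
    averaged over ``n_replicates`` replicate spots, so with the default
    geometry rule-positive tiles land above the 10,000-unit moderate
    threshold and rule-negative tiles stay below it. Returns
    ``(proteins, array)`` — a protein_id -> sequence dict and a tile
    table with intensity, labels and the planted truth column.
    """
    rng = _rng(cfg.seed + 4 if rng is None else rng)
    proteins = {}
    rows = []
    for i in range(cfg.n_proteins):
        pid = f"prot_{i:02d}"
        L = int(rng.integers(*cfg.protein_length))
        seq = "".join(rng.choice(list(AA), size=L))
        proteins[pid] = seq
        for tile in pep.tile_protein(seq, pid):
            binds = aromatic_rule(tile.sequence, cfg.min_aromatic)
            mu = cfg.intensity_base + cfg.intensity_effect * binds
            reps = mu * np.exp(rng.normal(0.0, cfg.intensity_noise_sd,
                                          size=cfg.n_replicates))
            intensity = float(reps.mean())
            rows.append({"protein_id": pid, "start": tile.start,
                         "sequence": tile.sequence, "intensity": intensity,
                         "label": pep.label_intensity(intensity),
                         "planted_binds": binds})
    return proteins, pd.DataFrame(rows)


def simulate_all(cfg: SynthConfig, outdir) -> dict:
    """Run every generator and write the pipeline's input files.

    Emits peak BEDs (pre/post, per mark), survivin BED, chrom.sizes,
    expression/gene-model/enhancer/network TSVs, protein FASTA, the
    peptide-array TSV, ``truth/`` tables, and a JSON manifest recording
    the seed and config. Returns the in-memory objects.
    """
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    rng = _rng(cfg.seed)
    peaks, truth = simulate_peak_landscape(cfg, rng)
    post_peaks, post_truth = simulate_treatment(peaks, truth, cfg, rng)
    expression = simulate_expression(cfg, rng)
    gene_models, enhancers, network_map = simulate_enhancer_links(cfg, truth, rng)
    proteins, array = simulate_peptide_array(cfg, rng)

    from .genomic_io import write_chrom_sizes
    write_chrom_sizes(cfg.genome(), outdir / "genome.chrom.sizes")
    for mark, ps in peaks.items():
        write_bed(ps, outdir / f"pre_{mark}.bed")
    for mark in H3_MARKS:
        write_bed(post_peaks[mark], outdir / f"post_{mark}.bed")
    expression.drop(columns="planted_deg").to_csv(
        outdir / "expression.tsv", sep="\t", index=False)
    gene_models.to_csv(outdir / "gene_models.tsv", sep="\t", index=False)
    enhancers.to_csv(outdir / "enhancers.tsv", sep="\t", index=False)
    network_map.to_csv(outdir / "network_map.tsv", sep="\t", index=False)
    with open(outdir / "proteins.fasta", "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n{seq}\n")
    array.drop(columns="planted_binds").to_csv(
        outdir / "peptide_array.tsv", sep="\t", index=False)

    truth.to_csv(outdir / "truth" / "landscape.tsv", sep="\t", index=False)
    post_truth.to_csv(outdir / "truth" / "treatment.tsv", sep="\t", index=False)
    expression.to_csv(outdir / "truth" / "expression.tsv", sep="\t", index=False)
    array.to_csv(outdir / "truth" / "peptide_array.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"seed": cfg.seed, "config": dataclasses.asdict(cfg)}, fh,
                  indent=2, default=list)
    return {"peaks": peaks, "truth": truth, "post_peaks": post_peaks,
            "post_truth": post_truth, "expression": expression,
            "gene_models": gene_models, "enhancers": enhancers,
            "network_map": network_map, "proteins": proteins, "array": array}
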
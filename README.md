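# bvcrkit

Analysis toolkit for **bivalent chromatin regions (BvCR)** — genomic
regions where peaks of the activating mark H3K4me3 and the repressive
mark H3K27me3 (plus, per configuration, H3K27ac) mutually overlap — and
for the role of the inhibitor-of-apoptosis protein **survivin** in their
regulation. It is aimed at epigenomics analysts who have per-mark ChIP-seq
peak tables, expression contrasts, and (optionally) peptide-microarray
data, and who want the full downstream analysis without bespoke scripts:

* **BvCR calling** — connected components of the ≥1-bp-overlap graph
  across mark peak sets (maximum gap zero, half-open coordinates); each
  region's *dominant mark* is the H3 mark contributing the largest share
  of normalized tags (tags per 10 million mapped), and regions overlapped
  by a survivin peak are flagged S+BvCR.
* **Deposition dynamics** — signed fold change (the ratio `a/b` when ≥ 1,
  otherwise `−b/a`, with a pseudocount), percentage tag change, detection
  of *changeable* BvCR whose dominant mark shifts after treatment, and
  deepTools-style profile matrices (scale-regions and reference-point).
* **Colocalization enrichment** — observed overlap counts (≥10 % of the
  query interval) versus within-chromosome shuffles (default n = 15),
  two-tailed p per catalog, Benjamini–Yekutieli q-values, and the
  `overlaps > 5 & q < 0.05` filter.
* **Regulatory linkage** — BvCR → enhancer / gene-body / 2-kb-upstream
  promoter → gene, filtered to expressed protein-coding genes
  (base mean > 1), flagged by nominal differential-expression p < 0.05,
  and aggregated onto a hierarchical DNA-damage-response network.
* **Tag–transcription model** — the min–max quantile-anchored line: OLS
  through the three anchors pairing the (min, median, max) of the tag
  change with those of the transcription change, a one-standard-deviation
  residual inclusion rule, and subgroup Spearman correlations
  (up/down-regulated × all/S+ BvCR).
* **Peptide binding** — proteins tiled into 15-mers (step 5), C-Pos
  functional-group composition encoding, a two-hidden-unit MLP trained on
  microarray fluorescence labels (strong > 30 000 > moderate > 10 000 >
  low > 1 000), and the summaries R_bind (fraction of tiles predicted to
  bind) and M_bind(n) (fraction of the 19 substitutions at position n,
  over all covering tiles, still predicted to bind).
* **Synthetic data** — a generator that plants all of the above structure
  (dominance mix, colocalization, shifts, expression coupling, a
  composition binding rule) with exact ground truth, so every stage is
  testable without sequencing data.

## Worked example

Generate a synthetic study at the default conditions (6000 bivalent loci,
dominance mix 0.43/0.33/0.24, 65 % survivin colocalization, 8.5 % shift
fraction), then call and analyse it:

```python
from bvcrkit import (SynthConfig, call_bvcr, flag_survivin,
                     dominance_frequency_table, compare_prevalence)
from bvcrkit.simulate import simulate_peak_landscape

cfg = SynthConfig(seed=1)
peaks, truth = simulate_peak_landscape(cfg)
regions = call_bvcr(peaks["H3K4me3"], peaks["H3K27me3"], peaks["H3K27ac"])
flag_survivin(regions, peaks["survivin"])
table, chi = dominance_frequency_table(regions, stratify_by_survivin=False)
print(table[["n", "pct_H3K4me3", "pct_H3K27me3", "pct_H3K27ac"]].to_string(index=False))
z, p = compare_prevalence(325, 4068, 205, 2131)
print(f"shift prevalence S+ vs S-: z = {z:.2f}, p = {p:.3f}")
```

prints

```
   n  pct_H3K4me3  pct_H3K27me3  pct_H3K27ac
6000    41.616667         33.95    24.433333
shift prevalence S+ vs S-: z = -2.18, p = 0.029
```

— the caller recovers the planted dominance mix within sampling error of
43/33/24 %, and the two-proportion comparison of shift prevalence between
survivin-positive (325/4068) and survivin-negative (205/2131) regions
gives p ≈ 0.03: dominance shifts are *less* frequent where survivin is
bound.

The same pipeline is available from the shell:

```sh
bvcr simulate --out study --seed 3
bvcr call --k4 study/pre_H3K4me3.bed --k27me3 study/pre_H3K27me3.bed \
     --k27ac study/pre_H3K27ac.bed --survivin study/pre_survivin.bed \
     --genome study/genome.chrom.sizes --out bvcr.tsv
bvcr dynamics --regions bvcr.tsv --pre study --post study --out shifts.tsv
bvcr link --regions bvcr.tsv --enhancers study/enhancers.tsv \
     --gene-models study/gene_models.tsv --expression study/expression.tsv \
     --out links.tsv
bvcr pep-train --array study/peptide_array.tsv
```

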
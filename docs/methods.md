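# Methods

## Coordinates and region calling

All intervals are 0-based half-open (BED convention); 1-based inclusive
peak tables are converted on input. Two peaks are *connected* iff they
share at least one base — a maximum gap of zero — so touching intervals
(`end == start`) are separate. BvCR are the connected components of this
relation across the input mark peak sets, reported as the union interval
with members grouped by mark; a component becomes a BvCR only if it
contains at least one peak of every required mark. The default requires
all three H3 marks (H3K4me3, H3K27me3, H3K27ac) because H3K27ac-dominant
regions are a meaningful output class; `required_marks={"H3K4me3",
"H3K27me3"}` gives the classical two-methyl-mark definition of
bivalency. Both are exposed because the two definitions genuinely differ
and neither is privileged by the data model.

**Dominance.** Tag counts are normalized to a library of 10 million
mapped reads (`raw * 1e7 / total_mapped`). Within a region the per-mark
normalized tags are summed; percentages are taken over the three H3
marks, and the dominant mark is the argmax. Exact ties are broken by the
fixed priority H3K4me3 > H3K27me3 > H3K27ac with an explicit `tie_flag`;
regions with zero total H3 tags have undefined dominance and are
excluded from dominance statistics rather than assigned arbitrarily.

**Dominance homogeneity** across survivin strata is tested with a
Pearson chi-square on the strata × marks count table. Category columns
that are empty in both strata contribute nothing to the statistic but
degrees of freedom remain (rows−1)(cols−1), so degenerate tables are
still comparable. Shift prevalence between strata uses the pooled
two-proportion z test without continuity correction.

## Deposition dynamics

The signed fold change of two signals is `r = (a+pc)/(b+pc)` reported as
`r` when r ≥ 1 and as `−1/r` otherwise, with a pseudocount (default 1
normalized tag) on both terms; the magnitude is always max/min and the
sign says which condition is larger. Percentage tag change is the
relative change of per-region per-mark tag sums, `100·(post−pre)/(pre+pc)`;
an alternative measure — the difference in within-region tag-share
percentage points — is provided (`tag_share_change`) because the two
readings of "percentage tag change" cannot be distinguished from the
conventions alone; the relative change is the default.

A region is *changeable* when the dominant mark recomputed per condition
differs between conditions; zero-tag regions in either condition are
excluded with a warning.

**Profile matrices.** In scale-regions mode each region body is mapped
onto `body_width` = 500 bases and binned at 50 bp with 2000 bp of real
coordinates on each flank — 90 columns at the defaults. In
reference-point mode bins cover ±flank around the region midpoint
`floor((start+end)/2)`. The score track is a piecewise-constant
bedGraph; bases without coverage (including positions beyond a
chromosome end) contribute 0, and bin values are exact interval means of
the step function (cumulative-integral queries), making the matrix
linear in the track.

## Colocalization enrichment

A query region counts as overlapped by a catalog when some catalog
interval shares ≥ 10 % of the query's length (optionally also 10 % of
the catalog interval's length). The query set is shuffled n = 15 times,
each region placed uniformly at random on its own chromosome with its
length preserved, no exclusion mask, and every catalog is scored against
the same shuffles; results are bit-reproducible given the seed.

The observed count is studentized against the shuffle mean and sample
SD. The default p-value uses the exact small-sample reference for that
statistic — Student t on n−1 degrees of freedom after scaling by
√(1+1/n) — because the naive normal read-off of the z score is
anti-conservative at n = 15 (its true α at the nominal 0.05 is ≈ 0.079
even for perfectly normal counts); the normal mode is retained as
`p_mode="normal"` for parity with the upstream tool family, and an
empirical rank p (granularity 2/(n+1)) as `p_mode="empirical"`. With the
default mode the measured null rejection rate at α = 0.05 is ≈ 0.05.
When the shuffle SD is zero the p is 1 if the observed count equals the
shuffle mean and otherwise computed with a 0.5-count floor on the SD.

Catalog p-values are adjusted with the Benjamini–Yekutieli step-up
(harmonic factor c(m) = Σ 1/i), valid under arbitrary dependence between
catalogs; `q_significance = −log10(q)`, and a catalog passes the
reporting filter when observed overlaps > 5 and q < 0.05.

## Regulatory linkage

The element universe is the union of enhancer intervals (each carrying
its curated gene link), gene bodies, and strand-aware promoters spanning
the 2 kb upstream of the TSS, clipped at the chromosome start. A BvCR is
linked to a gene through every element it overlaps by ≥ 1 bp; genes
reached via several elements or several BvCR keep all links. Links are
then restricted to genes with base mean > 1 (strict) and protein-coding
biotype; genes absent from the expression table are dropped with a
logged count. Differential-expression flags use the nominal p < 0.05 per
contrast (configurable to adjusted p).

Network aggregation: per hierarchy node, the fraction of its genes
reached by a BvCR and the mean of each mark's within-region tag
percentage over the linked (region, gene) pairs, deduplicated so a gene
linked to one region through two elements is counted once; the node's
dominant mark is the argmax of those means. Genes assigned to several
nodes contribute to every node — the hierarchy is treated as
overlapping annotation, not a partition.

## Tag–transcription model

The line is anchored at three summary points pairing the order
statistics of the tag change x with those of the transcription change y:
(min x, min y), (median x, median y), (max x, max y), and fit by
ordinary least squares over the anchors. This *summary pairing* treats
the coupling as direct (monotone increasing); the alternative
`anchor_mode="argpoint"` uses the joint observations at the
argmin/argmedian/argmax of x and can represent inverse couplings
exactly. `fit_mode="chord"` draws the exact line through the min and max
anchors, ignoring the median. Residuals are computed in y by default
(`residual_direction="x"` back-projects through the line); a gene is
included iff its absolute residual is within k = 1 population SD of all
residuals (a 1e-12 absolute tolerance absorbs float noise on exactly
collinear data). Spearman correlations (tie-corrected, two-sided p) are
reported per direction of transcription change (up/down, or undirected
via `split_direction=False`) and per stratum (e.g. all vs
survivin-positive BvCR); cells with fewer than 3 genes are undefined.

## Peptide binding

Proteins are tiled into 15-residue peptides at a 5-residue step
(10-residue overlap); if the last regular tile stops short of the
C-terminus one extra tile anchored at L−14 is appended so every residue
is covered. Each tile is encoded position-by-position (C-Pos) as the
counts of side-chain functional groups — CH3, CH2, CH, aromatic ring,
hydroxyl, carboxyl, amide, sulfhydryl, thioether, guanidinium,
imidazole, indole, primary amine — plus the backbone amide common to
every residue: 15 × 14 = 210 features. The residue→group table lives in
`bvcrkit.peptide` and is this package's own chemically-motivated
assignment; the encoding contract (identical sequences → identical
vectors; a substitution changes exactly its position block) does not
depend on the particular table.

Fluorescence thresholds label tiles strong (> 30 000), moderate
(> 10 000), low (> 1 000) or none; the binary training label is
intensity strictly above 10 000 by default. Tiles ending in cysteine are
excluded from training (array-chemistry artifact) but still scored at
prediction. 90 % of eligible tiles train a pipeline of standard scaler
(statistics from the training split only) plus an MLP with a single
hidden layer of two units; the held-out 10 % gives the reported
accuracy. The net is optimized with L-BFGS under L2 penalty α = 0.1:
with only two hidden units the unregularized fit memorizes the training
tiles, while the penalty steers it to the low-complexity composition
rules the encoding exposes (held-out accuracy on the planted rule rises
from ~0.88–0.97 to ≥ 0.97).

R_bind is the fraction of a protein's tiles predicted to bind. M_bind(n)
mutates position n to each of the 19 other residues in every tile
covering n — the denominator is 19 × (covering tiles) — and reports the
fraction of mutants still predicted to bind: 1 means the region binds
regardless of mutation, 0 means no single substitution yields a binder.

## Synthetic data

The generator's defaults are the study conditions: 6000 bivalent loci
with dominance mix 0.43/0.33/0.24, survivin colocalization 0.65, shift
fraction 0.085, a planted Spearman coupling of 0.6 between tag change
and transcription change, and a peptide array of 9 proteins (~1400
tiles, the scale of the real subunit array) with intensity thresholds at
30 000/10 000/1 000. Quantities no convention fixes were chosen once as
realistic desk-scale values: a 5 × 6 Mb genome, locus widths 500–1500 bp,
negative-binomial tags (dispersion 10; overdispersed like ChIP-seq
counts) with mean 120 for the dominant mark versus 25 for the others,
500 single-mark decoy peaks per mark and 500 decoy survivin peaks,
2000 genes, and lognormal intensity noise σ = 0.4.

Placement uses non-overlapping slots so planted loci, decoys, and the
reserved gene zone never collide, which keeps every truth table exact:
the recovered link table equals the planted one, and no decoy can create
a spurious BvCR. Planted dominance is enforced by swapping the largest
of the three tag draws into the planted mark (preserving the draw
multiset) and lifting it to ≥ 1.5× the runner-up, so mild treatment
noise (lognormal σ = 0.1 on unshifted loci) almost never flips
dominance; shifted loci are redrawn with a different dominant mark. The
expression coupling is a Gaussian copula whose Pearson parameter
2·sin(πρ/6) yields the target population Spearman ρ. The peptide rule —
a tile binds iff it carries ≥ 3 aromatic ring groups (F/Y benzene or W
indole) — is linear-threshold in the encoding, hence learnable by the
two-unit net; intensities are (2000 + 25 000·rule)·exp(σZ) averaged over
two replicate spots.

What the generator does **not** emulate: mappability and GC bias, peak
width/tag correlation, spatial clustering of regulatory elements,
expression mean–variance structure, or homologous sequence between
proteins. Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration of its statistics under the planted
model, not performance on sequencing artifacts.

## Problem sizes

The test suite and the acceptance script run the landscape at the full
n = 6000 loci (5 seeds in the recovery test), the expression model at
n = 2000 genes, the null-calibration sweep at 100–200 simulated datasets
of 150 query regions × 5 catalogs on a 2 × 1 Mb toy genome, and the
peptide classifier on the ~1400-tile array across 10 seeds.

## Known limitations

* The summary anchor pairing cannot represent inverse tag–transcription
  couplings (use `argpoint`); this is inherent to pairing order
  statistics.
* The enrichment test's normal/student approximations assume the
  overlap counts are not severely discrete; for very sparse catalogs
  (shuffle SD 0) the p-value degrades to the documented floor rule.
* The peak "score" column of upstream peak callers is treated as an
  opaque input; when absent it defaults to the normalized tag count.
* M_bind aggregates over all covering tiles; a per-tile profile is
  available but the per-position summary is the default.
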
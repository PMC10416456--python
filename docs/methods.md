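# Methods

## Quantification model

MeRIP-seq measures methylation as enrichment of immunoprecipitated (IP)
coverage over input coverage within called peaks. Both libraries are
normalized to counts per million against whole-library totals; the m6A
level of a peak is the CPM ratio. Because the filter requiring input ≥ 5
reads in every sample guarantees finite ratios, no pseudocount is added —
a deliberate choice to avoid the shrinkage bias a pseudocount introduces at
low coverage.

Gene, region and sample levels are *pooled* ratios, `Σ ip_cpm / Σ input_cpm`
over the peaks involved, not means of per-peak ratios. Pooling weights each
peak by its input depth, reduces to the peak level for single-peak genes,
and keeps every aggregate within the min/max range of its peak levels.

Thresholds (all strict inequalities, configurable in `RunConfig`):

| constant | default | meaning |
|---|---|---|
| `min_input` | 5 reads | peak retention filter, applied per sample |
| `mod_threshold` | 1.5 | IP/input ratio above which a peak/gene is m6A-modified |
| `fc_threshold` | 1.2 | symmetric fold change defining a change between stages |
| `alpha` | 0.05 | chi-square significance for differential peaks |
| m6A groups | 1.5 / 4 | low / medium / high gene-level m6A |
| accessibility split | 10/80/10 | rank-based accessibility groups |
| correlation extremes | 5% | top/bottom classes of the PCC ranking |
| not-correlated band | ±0.1 | PCC interval labelled not_cor |

## Differential test

The differential call between two stages combines a fold-change gate on
normalized levels with a Pearson chi-square (1 df, no continuity
correction) on the count table `[[ip1, in1], [ip2, in2]]`. The raw table's
odds are only comparable when both stages have the same IP-to-input
library-size balance; the input column is therefore rescaled by each
stage's balance relative to the two stages' geometric mean before testing.
With equal balances this reduces exactly to the plain Pearson chi-square on
raw counts, and the construction keeps the test symmetric under stage
order. When any expected cell falls below 1 the peak is flagged
`low_count` and the p-value comes from Fisher's exact test on the rounded
table. Raw p-values drive classification (a Benjamini–Hochberg column is
emitted for reference only), matching the convention of reporting p < 0.05
per peak.

## Dynamics classification

The three consecutive transitions define change classes 0–3 (number of
differential transitions). The origin of a peak is the earliest stage with
level > 1.5, or `never`. Trajectory clustering z-scores each peak's
4-point profile and runs k-means (k-means++ init, 10 restarts, fixed
seed); constant profiles cannot be z-scored, are flagged, and are assigned
to the centroid nearest the zero profile. k defaults to 8; the true number
of shape families in real data is unknown, and k is exposed on the CLI.
Expression dispersion is the sample standard deviation (ddof = 1) of
log2(normalized expression + 1) across the four stages; the log scale keeps
the score from being dominated by highly expressed genes.

## Correlation-based target discovery

With only four stage points a Pearson correlation is extremely noisy — the
null distribution of r for two random 4-point vectors is uniform on
[−1, 1]. The module therefore never reports a per-gene correlation
p-value; genes are *ranked* and the top/bottom `floor(0.05·n)` form the
extreme classes, with ties broken lexicographically by gene id for
determinism. A gene in an extreme class keeps that label even if
|r| < 0.1. The hypergeometric universe for the target-overlap test is the
set of genes with defined correlations for both signals (the regulator's
own gene excluded); the analysis applies the 5% cut per regulator over all
such genes rather than over modified genes only.

## Chromatin integration

Rank-sum comparisons use the exact Mann–Whitney null when the smaller
group has ≤ 20 observations and the data are tie-free, otherwise the
tie-corrected normal approximation without continuity correction; the
exact branch agrees with full enumeration of rank splits. The five
co-dynamics categories are computed both over the whole trajectory (change
= any transition with fold change > 1.2; concordance = sign of the Pearson
correlation between the two 3-point change-ratio vectors, with zero or
undefined correlations falling to "discordant" with a degenerate flag) and
per transition (concordance = both ratios on the same side of 1), since
either reading of a stage "window" is defensible; stage-overlap analysis
uses the per-transition labels. PCC bins drop the top and bottom
`floor(0.05·n)` genes of the m6A-vs-accessibility correlation ranking and
split the rest into 18 bins whose sizes differ by at most one, reporting
the mean |log2 fold change| of m6A per bin and transition. Accessibility
"change" reuses the 1.2 fold threshold, as no separate criterion is
established for gene-level ATAC signal.

## Peak annotation and metagene coordinates

Peaks are assigned to the gene whose transcript interval contains the peak
midpoint; ties go to the longest peak/gene overlap, then lexicographic
gene id. The transcript model is interval-based (one interval per gene
with CDS bounds), as produced by the simplified transcript table or by a
GTF's gene + CDS features; intron structure is not modelled. Region labels
follow the midpoint's position relative to the CDS, with a stop-proximal
window of ±50 nt around the stop codon taking precedence — a conventional
metagene window, configurable via `io_formats.STOP_WINDOW`. Metagene
coordinates map midpoints to [0,1) over the 5′UTR, [1,2) over the CDS and
[2,3) over the 3′UTR by fractional position, histogrammed in 90 bins
(30 per segment) and area-normalized; genes lacking a UTR contribute to the
CDS segment only.

## Synthetic study generator

The generator plants every structure the pipeline measures, at study
conditions mirroring the scale of a desk-size experiment: 2000 genes, 3000
peaks, 70% of genes carrying peaks, 14% of trajectories unchanged with the
rest changing once/twice/thrice at 47/30/9%, 5% never modified, ~90% of
modified peaks already above threshold at D0, 60 planted targets per
regulator at coupling 0.9, and five co-dynamics categories at
6/8/46/20/20%.

Design points worth knowing:

* **Counts.** IP counts are Poisson with mean `depth · w(g,s) · μ(p,s) ·
  sizefactor`, input counts Poisson with mean `depth · w(g,s) ·
  sizefactor`, where `w` couples coverage to expression sublinearly
  (square root, clipped to [0.5, 3] around the median) so that the
  `depth_mean` parameter remains meaningful for every peak. Stage
  sizefactors are drawn log-uniform in [0.5, 2] to exercise normalization
  and cancel exactly in the level estimator. A negative-binomial size
  parameter is available (`dispersion`) for overdispersed counts; the
  default is the Poisson limit, the regime in which multiplexed-barcode
  MeRIP designs largely remove IP-efficiency variation and in which the
  per-peak chi-square is calibrated.
* **Consistent truth.** All peaks of a gene share the gene's methylation
  trajectory, so the pooled gene level equals the planted trajectory
  exactly. Truth labels (change class, origin, category) are always
  derived from the noiseless trajectories using the pipeline's own rules,
  so planted labels coincide with the infinite-depth pipeline output by
  construction.
* **Margins.** Planted changed transitions use fold changes in
  [1.35, 1.9], unchanged ones at most 1.03, and levels at origin-defining
  stages sit at least ~8% away from the 1.5 threshold, keeping labels
  recoverable under sequencing noise at realistic depth.
* **Identifiability of planted couplings.** Over four time points, random
  trajectory directions have uniform correlation with anything, so planted
  target couplings would drown in null extremes. Regulator expression
  trajectories are therefore fixed 4-point shapes chosen numerically so
  that their correlation with every single-transition change shape is at
  most 0.5 (pairwise regulator correlations ≤ 0.46) — notably they are
  *not* monotone, since any monotone 4-point curve correlates at ~0.9 with
  a middle-transition step. Non-target ("uncoupled") trajectory directions
  are rejection-sampled to |PCC| ≤ 0.55 against every regulator, and
  target directions are constructed so the noiseless sample PCC equals
  ±`r_plant` exactly. Real transcriptomes offer no such guarantees: the
  recovery results certify the pipeline's correctness, not the statistical
  power of 4-point correlation screens on real data.
* **What is not emulated.** Read-level artifacts (duplicates, mappability,
  antibody specificity), intron structure, overlapping genes, batch
  effects, and biological correlation between expression level and
  methylation beyond the planted couplings. The modified-gene share among
  peak-bearing genes is higher than in a full transcriptome, because the
  gene universe is sized so that the 5% correlation classes can hold the
  planted target sets.

## Problem sizes used in tests

The test suite and acceptance script run the generator at 150–2500 genes
and 300–10000 peaks, with expected input depths of 800–10000 reads per
peak: consistency, type-I and recovery checks use depth 10⁴ (three to
twenty seeds), the demo uses the default depth 10³. These sizes were
chosen as the smallest at which the binomial/multinomial tolerances of the
recovery checks are meaningful.

## Known limitations

* Gene-level accessibility and TF-binding matrices are taken as given;
  ATAC/ChIP read processing, peak calling and per-gene aggregation happen
  upstream, and any gene-level score matrix is accepted.
* The correlation screen is a ranking over four points; it finds the most
  extreme associations, not significant ones, and its output should be
  read as candidate lists.
* The balance-adjusted chi-square treats rescaled counts as counts; with
  extreme library imbalance it is anti-conservative on its own, and the
  fold-change gate is what keeps the combined call's type-I error
  controlled.
* GO/motif enrichment of gene sets and figure rendering are out of scope;
  outputs are TSV tables ready for downstream tools.
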
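# m6adyn

Quantitative analysis of N6-methyladenosine (m6A) dynamics across a
four-stage differentiation time course (D0 → D2 → D5 → D15, e.g. pluripotent
stem cells → mesoderm → cardiac progenitors → cardiomyocytes), built for
MeRIP-seq experiments with paired IP and input libraries. It is aimed at
epitranscriptomics analysts who already have peak-level count matrices
(peak calling and alignment happen upstream) and want the downstream
quantitative analysis: m6A levels, dynamic-peak classification,
writer/eraser target discovery, and integration with chromatin
accessibility.

## What it computes

**m6A levels.** For peak *p* at stage *s*, the m6A level is the ratio of
CPM-normalized IP to input coverage,

```
level(p, s) = [ip(p,s) / L_ip(s)] / [input(p,s) / L_input(s)]
```

with whole-library totals `L`. Gene, transcript-region and per-sample
levels are pooled ratios `Σ ip_cpm / Σ input_cpm` over the relevant peaks,
after removing peaks with input < 5 reads in any sample. A peak or gene
with level > 1.5 is called m6A-modified; its *origin* is the earliest stage
at which that happens.

**Dynamics.** A peak is differential between consecutive stages when its
symmetric fold change `max(r1,r2)/min(r1,r2) > 1.2` *and* a Pearson
chi-square test on the 2×2 table `[[ip1, in1], [ip2, in2]]` gives p < 0.05.
The number of differential transitions (0–3) defines the change classes;
k-means on z-scored level profiles groups trajectory shapes; a one-tailed
hypergeometric test scores gene-set overlaps.

**Regulator targets.** Each gene's m6A level and expression are correlated
(Pearson, over the 4 stage points) with the expression of m6A writers
(METTL14, RBM15) and erasers (ALKBH5). The top/bottom 5% of each ranking
form the positively/negatively correlated classes (|r| < 0.1 is "not
correlated"). Writer targets = (expression negatively correlated) ∩ (m6A
positively correlated); eraser targets have the signs reversed. Since m6A
destabilizes transcripts, a writer's genuine substrates should gain m6A and
lose expression as the writer rises.

**Chromatin co-dynamics.** Gene-level ATAC accessibility is compared with
m6A via Wilcoxon rank-sum tests (modified vs unmodified genes, 10/80/10
accessibility groups, TF-binding by m6A group <1.5 / 1.5–4 / >4) and each
gene is assigned one of five co-dynamics categories: (1) neither signal
changes, (2) accessibility only, (3) m6A only, (4) both change discordantly,
(5) both change concordantly.

A synthetic-data generator (`m6adyn.synthetic`) emits a complete study —
BED/GTF/TSV/FASTA — with planted truth for every structure above, so the
whole pipeline is testable without any sequencing data.

## Worked example

The `demo` subcommand simulates a default study (2000 genes, 3000 peaks,
~1000 input reads per peak) and analyzes it end to end:

```
$ m6adyn demo --out demo --seed 42
wrote 26 result tables to demo/results
  category_accuracy: 0.9907866761162296
  change_class_accuracy: 0.966
  frac_change_0: 0.142
  frac_origin_d0: 0.88
  median_level_rel_error: 0.027367648249101324
  n_targets_METTL14: 59
  target_precision_METTL14: 1.0
  target_recall_METTL14: 0.9833333333333333
  ...
```

Reading the numbers: 14.2% of peaks kept a constant m6A level (the rest
changed at least once), 88% of peaks were already modified at D0, and peak
levels were estimated to a median relative error of 2.7% at this depth. Of
the 60 planted METTL14 target genes, 59 were recovered with no false
positives, and the five co-dynamics categories were reassigned with 99%
accuracy against the planted truth. The full tables (per-peak levels and
dynamics, per-gene correlation classes and categories, metagene density,
DRACH counts, rank-sum comparisons) land in `demo/results/`, the simulated
study itself in `demo/study/`, and `demo/results/recovery.json` holds the
recovery metrics printed above.

The same analysis runs on real data via `m6adyn run-all` with a YAML config
or explicit paths (BED6 peaks, GTF annotation, count TSVs, library-size
table, expression/accessibility matrices).

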
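# Methods

## The single-sample predictor

The classifier assigns one of three NSCLC histologies (AC, SqCC, LCNEC) to a
single tumor sample from the expression of 11 diagnostic marker genes. It is
deliberately *rank-based*: the only information extracted from a sample is
the set of within-sample orderings among the panel genes. Writing
x<sub>g</sub> for the expression of gene g in the sample, each ordered pair
(a, b) yields a binary feature r<sub>ab</sub> = 1[x<sub>a</sub> < x<sub>b</sub>]
(strict; ties give 0 in both orientations, which is the deterministic choice
for integer count data). Any strictly increasing per-sample transform —
log, power, affine with positive slope, or a platform change that preserves
within-sample ordering — leaves every feature, and hence every prediction,
unchanged. This is the operational meaning of "platform independent", and it
is property-tested directly.

What rank rules cannot survive is *per-gene* rescaling that differs between
genes (e.g. transcript-length normalization differences between FPKM
pipelines), since that reorders genes within a sample. The synthetic
`gene_scale` transform exists to exhibit exactly this failure mode.

### Training

1. **Background correction** (NanoString counts only): per sample,
   b = mean(negative-control counts) + 2·SD (sample SD), then each
   endogenous count becomes max(count − b, floor) with floor 1. FPKM and
   microarray inputs are used untouched; correction would not commute with
   their scales and rank rules do not require it.
2. **Rule space**: all 110 ordered pairs over the 11 panel genes.
3. **Ranking**: per class c, rules are scored by
   |freq(r=1 | c) − freq(r=1 | not c)| and sorted descending, ties broken by
   enumeration order; within a class list the reverse orientation of a pair
   already listed is dropped (it carries no new information up to ties).
4. **Selection**: the top-ranked rules are taken round-robin across classes
   (alphabetical order) until k distinct pairs are held; a model never
   contains both orientations of one pair.
5. **Naive Bayes**: Laplace-smoothed Bernoulli conditionals
   p<sub>rc</sub> = (n<sub>rc</sub> + α)/(n<sub>c</sub> + 2α) with α = 1,
   which keeps every conditional strictly inside (0, 1). Priors are uniform
   by default: the rules are intended to be prototypic lineage contrasts, so
   cohort composition is deliberately kept out of the model (empirical
   priors are available by configuration).
6. **Choosing k**: stratified k-fold cross-validation (default 5 folds,
   reduced with a warning if the smallest class cannot support it) over a
   grid of rule counts (default 1–25). Ranking is redone inside each
   training fold so the selection is honestly cross-validated. k* is the
   smallest k attaining the maximum mean balanced accuracy — the tie-break
   prefers the simplest model. Everything is deterministic given the seed.

Posterior computation is done in log space and normalized; argmax ties
break to the first class in alphabetical order. A brute-force product of
Bernoulli likelihoods reproduces the posteriors to 1e-9 in tests.

### Evaluation protocol

The feasibility experiment partitions a cohort into stratified train/test
splits of fixed sizes (48/20 for the 68-sample development design; class
proportions preserved, remainder to train), trains a fresh model per
iteration and reports per-iteration accuracy, balanced accuracy (mean
per-class recall) and macro one-vs-rest AUC for both the reclassified
training split and the held-out test split, summarized as mean and SD over
10 iterations. Multiclass AUC is the macro average of per-class rank-based
(midrank-tied) one-vs-rest AUCs; this construction is recorded in the
report because other multiclass AUC definitions exist. For 2×2 concordance
tables the per-class table reports sensitivity, label-as-truth specificity
*and* precision, because published concordance statistics sometimes quote
the agreement of the assay's positive calls (precision) under the name
specificity — both directions are emitted, labeled.

## Fusion and MET exon-14 calling

A fusion places the kinase-side (3′) exons of the target gene under a
foreign promoter, so 3′ probes report higher counts than 5′ probes. For each
target gene the caller computes the imbalance ratio
mean(3′ counts)/mean(5′ counts) and the maximum variant-junction probe
count; a sample is positive iff ratio ≥ `ratio_min` **and** junction ≥
`junction_min` (the upper-right quadrant), with the best variant being the
argmax junction probe (ties to panel order). MET exon 14 skipping uses
x = mean(exon 3–4 and 20–21 counts)/exon-14 count (denominator floored at 1)
and y = exon 13–15 junction count, positive iff x ≥ `flank_ratio_min` and
y ≥ `junction_min`.

Defaults `ratio_min = 2`, `junction_min = 50` counts, `flank_ratio_min = 2`
encode the quadrant geometry; they are configuration, not biology, and were
chosen as round values that sit far from both the background distribution
(junction background ≈ a few counts) and the fused signal (hundreds to
thousands of counts) of the synthetic generator. Ratios are scale-free
(multiplying a sample's counts by c > 0 changes nothing); the junction
threshold is absolute in counts — a documented asymmetry, appropriate
because junction probes measure presence, not proportion.

QC gates every call: a sample fails with reason `low_total_counts` if its
total endogenous signal is below `total_count_min` (default 100) or
`low_positive_controls` if the geometric mean of positive-control probes is
below `poscon_min` (default 8, inclusive thresholds). A failing sample's
calls are *inconclusive*, never negative: degraded RNA must not be read as
fusion-absent. Calls are per-gene independent, so multi-positive samples are
representable. An optional trimmed 5′ mean (drop the highest 5′ probe)
guards against a single high-background probe; it is off by default.

## The synthetic generators

`simulate_histology_cohort` emulates the structure of a 68-tumor NanoString
development cohort: 27 AC, 30 SqCC and 11 LCNEC samples, each gene drawn
from a negative binomial (gamma–Poisson) with mean 2000 for a sample's
own-class markers and 50 for the rest, dispersion (NB size) 2 — heavy
overdispersion typical of count assays — plus six negative-control probes
at mean 10 for background correction. An optional `marker_null_fraction`
appends LCC-like samples expressing every marker at baseline, emulating the
"marker null" phenotype that a three-class model necessarily forces into
one of its classes.

`simulate_fusion_probes` draws a 131-sample screen in which the number of
positives per variant is fixed (1 + 3 + 1 EML4-ALK, 2 + 2 KIF5B-RET, 2
CD74-NRG1, 3 MET exon-14 skips) so the truth record is exact rather than
binomially noisy. Fusion-positive samples have their 3′ probe means
multiplied by 8 and the true variant's junction probe drawn at mean 2000;
MET-skip positives suppress exon 14 to 0.1× the flanking mean and light the
skip junction. Signal probes use a tighter dispersion (size 10) than the
background (size 2): the intent is that the assay geometry, not simulator
noise, determines the calls at default effect sizes, while shrinking the
effect (e.g. lowering the junction mean toward the 50-count threshold)
degrades sensitivity smoothly — both behaviors are tested.

What the generators do **not** model: probe-specific efficiencies, batch
and lane effects, RNA-quality gradients, partial tumor content, mixed
histology, and correlated marker co-expression within a class. Passing
tests therefore demonstrate that the algorithms are implemented correctly
and behave as designed under the stated noise model — not that the
classifier reaches any particular accuracy on real tumors. On these
well-separated synthetic cohorts the feasibility protocol lands near the
ceiling (test balanced accuracy ≈ 0.98–1.0) and cross-validation typically
keeps 5–8 rules; real cohorts, with noisier class boundaries, motivate
larger rule counts (on the order of 15).

## Numerical and design choices

- **Ties**: equal expression yields 0 for both rule orientations; argmax
  posterior ties break to alphabetical class order; variant ties to panel
  order; equal CV scores prefer smaller k. All deterministic.
- **Serialization**: models are versioned JSON (`schema_version`) with full
  provenance (seed, k-grid, CV record); a reload is posterior-identical.
- **RCC parsing** never alters counts (column sums equal the file's Count
  sums) and tolerates Windows line endings, blank trailing lines and
  sample-id collisions (suffixed by file stem).
- **Stratified partitioning** realizes "balanced for histology" as
  proportion-preserving sampling; remainder samples go to the training
  split.
- **Degenerate inputs** are hard errors, not warnings: negative or
  non-numeric cells, duplicate identifiers, missing panel genes (with the
  aliases that were tried), ambiguous alias resolution, classes with fewer
  than 3 training samples, mixed record types in call tables.
- Problem sizes in tests and the acceptance script (68-sample cohorts,
  131-sample screens, 10 iterations, 100 random matrices for the invariance
  property) match the study design the package emulates while keeping the
  default suite fast.

## Limitations

- The AIMS-style internals here (ranking statistic, round-robin selection,
  CV scheme) are one faithful, declared realization of the rule-based SSP
  idea; they are not guaranteed to be byte-compatible with other released
  implementations.
- "SFTPG" is not a current HGNC symbol; the panel keeps it and relies on
  the alias table (default alias SFTA2) for matrices using modern symbols.
- Fusion thresholds must be recalibrated for a real probe panel; the
  defaults are tuned to the synthetic generator's geometry.
- The three-class SSP cannot represent LCC / "marker null" or mixed
  histologies; such samples are forced into one of the trained classes.
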
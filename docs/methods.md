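# Methods

This note documents the models and procedures `polyas` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## PSI from transcript abundances

PSI is computed from transcript TPM and an ioe-style event catalog:
`PSI = 100 · Σ TPM(inclusion) / Σ TPM(total)`.  This is transcript-level
PSI (the Salmon/SUPPA route), not junction-read PSI; the two agree when
transcript quantification is accurate but respond differently to
quantification error.  A cell is NA exactly when the event's total TPM is
below `min_event_tpm` (default 1.0 TPM) — downstream of quantification this
is the only available proxy for "insufficient read coverage", and it is the
proxy used everywhere a denominator of "covered samples" is needed.

Reliability filtering keeps events whose replicate-mean PSI lies strictly
inside `(psi_reliable_low, psi_reliable_high)` = (5, 95) for at least one
(variety, stage/tissue) group.  Strict inequalities are used uniformly
(configurable); the window endpoints deliberately sit outside the common
(10, 90) convention to retain near-constitutive events, which the switched
bias category depends on.  An optional per-event p-value column (from an
external differential-splicing test) can additionally gate the filter at
`alpha`.

PanAS requires the fraction of non-NA samples with PSI strictly inside the
reliability window to strictly exceed `pan_fraction` (0.80) and at least
`min_defined_samples` (10) non-NA samples; VariantAS requires the non-NA
PSI range to exceed `variant_delta` (25 points).  The two labels are
independent.  Sample-level statements (PanAS, VariantAS) use individual
libraries; stage/tissue-level statements use replicate means.

## Triads, bias and dominance

Events are matched across subgenomes by lifting their genomic intervals
through pairwise UCSC chain files.  An A-subgenome event pairs with a
B-subgenome event only when (i) the lifted interval overlaps exactly one
same-type B event at `min_overlap_fraction` ≥ 0.5 of the shorter interval,
and (ii) the B event lifts back through the inverted chain onto exactly the
original A event.  Triads are seeded from the A→B and A→D matches; the B→D
chain is a consistency check by default (`require_all_chains` makes it a
hard filter).  One-to-many mappings on either side disqualify the event —
"perfect 1:1 orthology" is enforced structurally rather than by score.

Splicing bias per (triad, variety, stage) is the range of the three
replicate-mean homoeolog PSIs, partitioned half-open:
[0, 20) balanced, [20, 80) unbalanced, [80, 100] switched.  The source
ranges are quoted with overlapping bounds (0–20/20–80/80–100); the
half-open partition makes the assignment deterministic, and boundary mass
is negligible for continuous PSI.  Classification is exposed per stage;
a summary across stages can be formed by the caller (the choice between
per-stage and summary classification is genuinely open and both are
supported).

Dominance assigns a normalized (A, B, D) triple — gene TPM for GE bias, PSI
for AS bias — to the nearest of seven ideal centroids by Euclidean
distance: balanced (⅓,⅓,⅓), X-dominant (1 at X), X-suppressed (0 at X, ½
elsewhere), ties broken toward balanced.  "Balanced GE with biased AS"
intersects balanced GE dominance with an unbalanced/switched AS category
per stage, and additionally reports triads satisfying this at all seven
embryo stages.

## Specificity

Events are z-scored per row (sample standard deviation, n−1; constant and
incomplete rows dropped), clustered with k-means (k-means++, 10 restarts,
fixed seed; `k="auto"` maximizes mean silhouette over 2..`kmeans_max_k`,
default 24 — the magnitude of cluster counts reported for wheat subgenome
AS data).  For each cluster and sample group, the Pearson correlation
between the cluster centroid and the group's 0/1 indicator is computed; the
cluster is group-specific (positive or negative direction) when
|r| ≥ `specificity_r_min` (0.7) and p < `alpha`.  Member events inherit the
cluster's calls **only when their own z-profile correlates with the
centroid at r ≥ `specificity_r_min`**: hard k-means assignment places every
noise-dominated profile somewhere, and without the member gate such
profiles would inherit specificity calls they do not support.  All member
correlations are reported regardless.

Cultivar-divergent events (e.g. Chinese Spring vs AC Barrie) are called
directly: stage-matched replicate-mean PSI differing by more than
`variant_delta` in at least one shared stage, gated by a two-sided Welch
test across stage-matched means.  Welch's test is the unequal-variance-safe
default where the upstream description names only "a test".

## Correlation divergence and expression trees

Per triad, gene-level conservation is Pearson *r* on homoeolog gene-TPM
trajectories across the seven embryo stages (all three pairs > 0.8 ⇒
GE-conserved) and transcript-level divergence is Spearman *ρ* (average
ranks on ties) on PSI trajectories (any pair < 0.5 ⇒ AS-divergent); a
correlation needs ≥ 4 paired non-NA points, else it is NA and never
satisfies a flag.

Expression trees are classic Saitou–Nei neighbor joining (via scikit-bio)
on leaf = (cultivar × subgenome) PSI vectors over the triad events of one
stage.  The primary distance is `d = 1 − r` (pairwise-complete Pearson);
the Euclidean distance between rows of the leaf×leaf correlation matrix is
available as a flagged alternative, and outputs are labeled with the
definition used.  A leaf pair needs ≥ 20 shared defined events, else the
stage is skipped — bootstrap resampling makes smaller overlaps unstable.
Total tree length (sum of branch lengths) summarizes inter-subgenome
divergence; its distribution is obtained by resampling triad events with
replacement (`n_bootstrap` = 100), deterministically given a seed.  Both
3-leaves-per-cultivar and joint 6-leaf layouts are supported; the shipped
pipeline uses the joint 6-leaf tree.

Duncan's multiple range test compares group means (e.g. bootstrap length
distributions across stages) with the step-down studentized-range
procedure at Duncan's protection levels `alpha_p = 1 − (1−alpha)^(p−1)`,
critical values from the studentized-range distribution computed
numerically, harmonic-mean n for unbalanced groups, and a compact letter
display.  A stretch of ordered means inside a non-significant stretch is
never declared significant.  Under a complete null with k groups the
family-wise error of the procedure is the protected level
`1 − (1−alpha)^(k−1)` (≈ 9.75% for k = 3 at alpha = 0.05), which is what
the calibration test checks.  With zero within-group variance, any two
unequal means are significant — documented edge case.

PCA is plain SVD on column-centered data (samples as observations), kept as
light plumbing for sample-relatedness overviews; supervised ordination
(PLS-DA) is deliberately out of scope as an off-the-shelf wrapper that adds
no testable content.

## Polyploidization and phylostrata

Candidate triads are those whose diploid ancestors disagree: maximum
pairwise replicate-mean PSI difference among DV/SP/TA (DV vs SP for the
tetraploid path) of at least `diploid_delta` (50 points) in ≥ 1 stage.  For
candidates, the per-subgenome shift is the mean over stage-matched
differences PSI(polyploid) − PSI(matched diploid ancestor: A↔DV, B↔SP,
D↔TA), averaged over the two cultivars of the ploidy, with a two-sided
Welch test pooling per-(cultivar, stage) values against the diploid
per-stage values.  A subgenome is altered when |shift| > `polyploid_shift`
and p < `alpha`; the default shift threshold is 20 points (the operational
description), with 25 reachable by configuration where the stricter quoted
variant is wanted.  Per-stage shifts are reported alongside the pooled
test; testing per stage instead of pooling is a caller-side variation.
Tetraploid (diad) and hexaploid (triad) calls are made separately and
intersected per subgenome via the shared A-subgenome event.

Phylostratum levels PS1..PS14 are an input table (sequence-similarity-based
age assignment is external).  Eligible events (reliability-filtered) are
counted per gene, binned 1/2/3/4/5+, and the per-level proportions
reported; the young-vs-old contrast (PS13–14 vs PS1–6 mean events per gene)
is tested one-sided with Mann–Whitney.

## The synthetic dataset

The generator emits the full sampling design — varieties AC, CS (hexaploid
AABBDD), CM, ST (tetraploid AABB), DV (AA), SP (BB), TA (DD); stage/tissue
classes E01–E07 (embryo), E08–E09 (endosperm), E10 (pericarp); 2
replicates; 140 libraries — plus `n_triads` (default 300) triad gene models
with 2–8 isoforms per locus, one shared (triad-defining) AS event per
homoeolog and chained extra events on the remaining isoforms, the three
pairwise chain files relating the homoeolog coordinates, a phylostratum
table, and a `PlantedTruth` object.

Key construction choices:

- **PSI surfaces.**  Each triad draws a bias class from `bias_mixture`
  (default 0.60/0.30/0.10).  The within-triad spread is drawn per stage
  inside class-preserving bands with safety margins of several PSI points
  to every classification boundary, wider in E01–E03 than in E04–E07 —
  this single mechanism plants both the per-stage class labels and the
  larger early-embryo inter-subgenome divergence that the tree-length
  analysis detects.  All planted member PSIs stay strictly inside (5, 95)
  so the reliability filter never removes a planted triad member.
- **Isoform fractions.**  The planted event takes half the gene mass (all
  of it for 2-isoform genes, so gene TPM sums exactly to the planted
  trajectory); its inclusion isoform takes PSI/100 of that mass; the
  remainder is spread uniformly over the other isoforms, giving extra
  events a PSI of 50.
- **Noise.**  Replicate noise is a per-(gene, sample) multiplicative
  lognormal factor, which cancels in every PSI ratio — so PSI error is
  controlled solely by `noise_sd_psi` (additive Gaussian on the true PSI,
  clipped to [0, 100]), and at `noise_sd_psi = 0` computed PSI reproduces
  the truth surface exactly (construction inverse).
- **Polyploid null.**  Polyploid PSI surfaces copy the diploid ancestral
  surfaces except where structure is planted (alteration shifts of ±40 on
  the designated subgenomes, group-specific shifts of +45, cultivar shifts
  of +40), making the corresponding detectors' null hypotheses exact.
  Altered triads put their PSI extremes on the A and B homoeologs so the
  DV–SP contrast qualifies the diad for the tetraploid path as well.
- **Gene expression.**  Log-TPM trajectories are smooth random walks
  (start ~ N(3.0, 0.8), steps ~ N(0, 0.35), floored so event TPM stays
  measurable); conserved-GE/divergent-AS triads share one trajectory across
  homoeologs while their PSI trajectories are mutually reversed/permuted
  (Spearman ρ = −1 on one pair); a `fraction_ge_skewed` subset receives a
  ±2.5 log offset on one homoeolog to populate the dominant/suppressed
  dominance groups.
- **Gene age.**  PS levels are uniform over 1..14 per triad; genes at
  PS ≥ 13 draw isoform counts reweighted by `ps_young_isoform_boost^i`
  (default 1.6), which raises their event-per-gene counts and plants the
  young-gene trend.
- **Chains.**  One colinear chain per chromosome pair with randomly placed
  intergenic indels; homoeolog gene bodies lie wholly inside aligned
  blocks, so planted events lift exactly and the recovered triads equal the
  planted set at zero noise.  Extra events are staggered across subgenomes
  by more than the reciprocal-overlap threshold so they can never form
  spurious triads.  Inversions are off by default (`allow_inversions` is
  reserved); negative-strand targets are handled by the chain machinery
  itself.

What the generator does **not** emulate: read-level sampling error and its
coverage-dependence (TPMs are drawn, not estimated), quantification
ambiguity between near-identical homoeologs (the very problem the upstream
pipeline's Salmon step addresses), correlated replicate structure, partial
triads and homoeolog loss, multi-chromosome genomes, and sequence content.
Passing recovery tests therefore demonstrates correctness of the downstream
logic under the stated statistical structure, not robustness to
quantification artifacts in real wheat data.

## Problem sizes and determinism

The shipped analyses and tests run on 300-triad datasets (≈ 1,900 events ×
140 samples), 100 bootstrap replicates per stage, 1,000-replicate Duncan
calibration, and 10,000-point oracle checks; the acceptance script
re-simulates everything from a single seed in about a minute on one CPU.
Every stochastic step (simulation, k-means, bootstrap) takes an explicit
seed, and the end-to-end pipeline writes no timestamps, so identical
config + seed reproduces byte-identical outputs.

## Known limitations

- PSI is a ratio of estimated abundances; no uncertainty is propagated
  into downstream classifications beyond the TPM ≥ 1 definedness rule.
- The pooled Welch test for polyploidization treats stages as independent
  observations; stage-correlated PSI would inflate its nominal
  significance (a permutation variant is a natural extension).
- Bias categories are hard-thresholded on the PSI range; triads near a
  boundary flip classes under noise, which is why noisy-recovery accuracy
  is bounded at 95% rather than 100%.
- The silhouette-chosen k is data-dependent; specificity calls are robust
  to k only through the member-correlation gate.
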
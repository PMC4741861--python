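# Methods

## Data model and normalization

A `SignalMatrix` holds one feature's signal — the promoter-region read
level of one histone mark, or expression — for entities (genes or lncRNAs)
across cell-line samples, with an explicit normalization `state`:
`raw_counts → rpm → log2z` for chromatin (`fpkm` enters the expression
side), plus a `profile` state for already-standardized or simulated
profile-space data. ChIP-seq counts are converted to reads per million
mapped reads (RPM) by dividing each sample's counts by its total mapped
reads in millions. Transcript-level rows are collapsed to gene level by the
per-sample **maximum** over a gene's transcripts, on the reasoning that a
gene's promoter signal is carried by its most active TSS.

Entity filtering precedes standardization: chromatin entities need at
least one strictly positive value in any sample (a detectable mark in at
least one cell type); expression entities must be strictly positive in
**all** samples. Values are then log2(x + 1)-transformed and Z-scored per
entity row. Numerical choices the protocol leaves open, decided here once:

- **pseudocount 1** in log2(x + 1): monotone, exact at zero, standard for
  count-scale data;
- **sample standard deviation (ddof = 1)** in the Z-score, switchable via
  `RunConfig.zscore_ddof`;
- rows constant after log2 have an undefined Z-score; they are dropped and
  recorded on the matrix (`dropped_constant`) rather than emitting NaN.

## GO term preparation

Term memberships follow the true-path rule: a term's propagated gene set
is the union of its direct annotations and those of all DAG descendants
(`propagation="full"`; a `one_level` mode restricts to immediate children
for sensitivity analysis). Cycles are rejected. Terms are retained only
when their in-universe size n satisfies 20 < n < 2000 — both bounds
strict — where the **universe** is the intersection of the
chromatin-filtered and expression-filtered gene sets, so every
gold-standard gene has profiles on both sides.

Per retained term, the gold-standard positives (GSP) are the propagated
members in the universe, and each of the 100 gold-standard negative sets
(GSN) is a uniform sample without replacement from the remainder, size
matched to the GSP. Replicate r of term t is seeded by a deterministic
function of (master seed, t, r), so any replicate is reconstructible in
isolation.

## The centroid classifier

Profiles are compared in sample space via the distance difference
Δd(i) = ‖p(i) − GSP centroid‖₂ − ‖p(i) − GSN centroid‖₂. The protocol's
decision rule ("above the cutoff ⇒ positive") points in the opposite
direction from the raw Δd sign (positives have *smaller* distance to the
positive centroid, hence *negative* Δd), so the package defines the
decision score as −Δd and applies the ≥-cutoff rule to it; this preserves
both the distance formula and the stated decision direction. Points
exactly at the cutoff are classified positive.

Cross-validation folds each class **separately**: each class is shuffled
with the replicate seed and dealt round-robin into five approximately
equal parts; fold k's centroids are the per-sample means of the other four
folds' genes. Held-out decision scores from all five folds are pooled into
a single ROC (`cv_auc="pooled"`; a `mean` mode averages per-fold AUCs —
pooling is more stable for small terms). AUC is computed rank-based
(Mann–Whitney identity, ties counting ½), which equals the trapezoidal
area under the ROC swept over all distinct score cutoffs.

Per term, each feature's score is the mean CV AUC over the 100 GSN
replicates; the selected feature is the argmax, with exact ties broken
lexicographically on the feature label (logged). Final classifiers are
refit per replicate on the full GSP ∪ GSN in the selected feature's space.
The Youden cutoff is computed on the final classifier's training scores
(the protocol does not say which scores feed the cutoff; the full training
set matches the "refit on everything" spirit and uses all available
genes). Candidate thresholds are the observed scores only; ties on J are
broken toward higher specificity, then the lower threshold.

Missing entities: in `strict` mode (default) a feature is skipped for a
term if any gold-standard gene lacks a profile in it; `lenient` mode
restricts the gold standard to covered genes when ≥ 90% remain.

A lncRNA's confidence for a term is the fraction of the 100 replicate
classifiers calling it positive. Because the lncRNA's profile and the GSP
centroid are fixed while only the GSN replicate varies, confidence
measures robustness of the call against the choice of negatives — not a
calibrated probability. Records with confidence 0 are omitted from output.

## Similarity, TSS profiles, consistency

Within-term similarity is the mean Pearson r over all unordered member
pairs. Its significance is empirical: 100 same-size random gene sets are
drawn from the profile universe and the p-value is the proportion with
**strictly higher** similarity than observed — so p lies on the 1/100 grid
and can be exactly 0; an optional (+1)/(n+1) smoothing is available.
Benjamini–Hochberg adjustment is applied across terms.

TSS metagene profiles cover [−2000, +2000) bp in transcript orientation,
200 bins of 20 bp, with the TSS at the start of bin 101. A read increments
every bin it overlaps by ≥ 1 bp (`count="overlap"`, multicov-like; a
`fiveprime` mode assigns only the 5′-end bin — the exact assignment rule
is not fixed by the protocol). Minus-strand windows are reversed so bin 1
is always upstream; windows running off a chromosome start keep their
missing bins at zero and are flagged. Group profiles are per-bin means,
compared by Pearson r over the 200 bins.

Consistency with annotation transfer: a lncRNA's transferred term set is
every term sharing ≥ 1 gene with its target list (`min_overlap`
configurable); agreement between the model's terms (default: confidence
1.0) and the transferred terms is tested by the upper-tail hypergeometric
P(X ≥ overlap) over the universe of size-filtered terms, and a lncRNA
counts as consistent at p < 0.05. lncRNAs with no target data are excluded
from the denominator and reported separately.

## Synthetic data generator

`lncgo.synth.generate` emulates the structure the method assumes: per
term, member genes share one centroid per signal-carrying feature —
direction uniform on the sphere, norm δ in units of the within-class noise
sd — with background genes centred at the origin, and lncRNAs drawn from
either population. Defaults mirror the study conditions: 13 chromatin
samples, 9 expression samples, 10 features (9 marks + expression), signal
in H3K9ac, δ = 3, noise sd 1, 30 genes/term against 200 background genes.

Two deliberate design choices:

- **Centroids are drawn orthogonal to the all-ones vector.** Per-row
  standardization removes each profile's mean, so any signal component
  along the mean would be invisible downstream; planting it would only
  dilute the nominal δ.
- Profiles are generated in standardized space and emitted as strictly
  positive RPM/FPKM-scale values via x = 2^(g + 8), so the normalization
  path (log2(x + 1), row Z-score) approximately inverts the map. Row
  Z-scoring still **compresses** a planted location shift (a positive
  row's own sd includes the signal variance), so the end-to-end effective
  separation is smaller than the nominal δ — e.g. at δ = 3 in 13
  dimensions, measured planted-lncRNA confidence has median ≈ 0.96–1.0
  across seeds but only ~70% of planted lncRNAs exceed 0.9. Tests and the
  acceptance script assert the behaviour the pipeline actually exhibits.

What the generator does **not** emulate: correlated noise between cell
lines, mark-to-mark correlation, peak-shaped read distributions,
library-size variation, or incomplete annotation. Passing recovery tests
therefore demonstrates correctness of the machinery under the model's own
assumptions, not expected performance on real ENCODE-scale data.

The toy BED fixture contains six hand-placed reads around one plus- and
one minus-strand TSS with hand-computed bin assignments, exercising the
overlap rule, the two-bin spanning case and strand reversal.

## Problem sizes and determinism

Simulation studies use desk-scale sizes chosen to make the statistics
stable while keeping the full suite fast: 50 genes/class in 10 dimensions
for calibration and recovery (100 GSN replicates), 100 replicates for
feature recovery (10 GSN replicates each — the selection argmax is a mean
over replicates and is insensitive to the replicate count beyond ~10), and
1,000 random instances for the exact oracle-equivalence checks. Every
random draw descends from an explicit seed; the train/predict path is
bit-reproducible given the master seed, and rerunning the pipeline with
the same config yields byte-identical outputs.

## Known limitations

- Confidence scores are resampling frequencies, not probabilities; they
  should be thresholded (the reference protocol uses 1.0), not averaged.
- With strongly overlapping GO terms (e.g. a parent and its child), the
  same lncRNA is often predicted for both; no redundancy reduction is
  applied.
- The permutation p-value floor is 1/n_perm; with 100 permutations,
  multiple-testing control below q ≈ 0.01 is limited by the grid.
- FPKM estimation, read alignment and BAM handling are out of scope; the
  package starts from count/RPM/FPKM matrices and BED intervals.
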
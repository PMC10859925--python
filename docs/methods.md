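# Methods

This note records the model assumptions, numerical conventions and design
choices behind `statedetect`, at the level a maintainer or reviewer needs
to judge what the package does and does not establish.

## Problem model

A recording is a channels × samples matrix at a fixed sampling rate
(nominally 500 Hz, 38 scalp channels in the 10–20 convention, ear channels
excluded). The working assumption is piecewise stationarity over 1-s
epochs: the recording is a concatenation of "functional states", each a
time-contiguous run of epochs with a stationary joint feature
distribution, separated by change points. Nothing is assumed about the
number, lengths or ordering of states; non-adjacent states may coincide
(states can alternate), which is why all quality measures are defined on
*adjacent* state pairs only.

Epochs are 0-based; segments are half-open `[start, end)` intervals, so
partitions tile `[0, n_epochs)` exactly. After artifact rejection every
downstream index refers to the *retained* epoch sequence; the original
positions are carried only for reporting. The temporal connectivity radius
K is likewise counted over retained epochs — the rejected epochs' gaps are
closed — because the clustering operates on the cleaned sequence and a
contiguous index keeps the connectivity graph well-defined.

## Feature engineering

* **PSD** — adaptive-weight (Thomson) multitaper, full bandwidth 8 Hz on a
  1-s epoch (time-half-bandwidth 4, 7 DPSS tapers), via
  `mne.time_frequency.psd_array_multitaper(adaptive=True)`. Powers are
  averaged over frequency bins within each band, then over channels within
  each region. Band membership is half-open `[low, high)` with the top
  band closed at 40 Hz, so shared edges are never double-counted.
* **PSD ratios** — the 16 listed ratios per region, computed on linear
  (non-logged) powers; they are scale-invariant under common channel
  gains.
* **Coherence and PLV** — hand-built from DPSS-tapered cross-spectra
  (`scipy.signal.windows.dpss`), because only the estimator family was
  fixed, not a reference formula. For epoch *e* the cross-spectral density
  is averaged over the tapers and epochs of a 5-epoch window centred on
  *e*; coherence at a frequency is |mean CSD|² / (mean PSD_x · mean PSD_y)
  and PLV is the magnitude of the mean per-taper unit-normalized
  cross-spectrum, both then band-averaged. Edge windows truncate rather
  than drop, so every epoch keeps a feature row (the detector indexes rows
  by epoch). With 35 effective segments (5 epochs × 7 tapers) the null
  levels are ≈ 1/35 ≈ 0.03 for coherence and ≈ √(π/140) ≈ 0.15 for PLV;
  the test suite checks both against Monte-Carlo draws.
* **Connectivity indices** — per channel the count of other channels with
  synchrony ≥ P, thresholds {0.6, 0.7, 0.8}, averaged within regions: 3 ×
  5 × 15 = 225 columns per measure, hence 765 detector-input columns and
  1,815 analysis columns on the standard montage. Indices are monotone
  non-increasing in P, a property test.
* The 15-region map is shipped as an editable configuration; a merged
  9-region variant exists for display-style summaries.

## Preprocessing

Artifact rejection drops any epoch whose value in at least one band×region
PSD column deviates from that column's mean by more than 3 SD. Statistics
come from the full uncleaned table in a single pass (iteration is exposed
as an option but off: the single-pass reading is the simplest consistent
one). Zero-variance columns never flag an epoch. Note an interaction
worth knowing: rejection pools statistics across states, so recordings
with very strong planted power contrasts can see substantially more than
the 10–15% removal typical of real data — the boosted states' epochs sit
in the tail of the pooled distribution. This does not prevent boundary
recovery (the tests run the rejector in the loop) but it shortens states.

The reduction is log (PSD and ratio columns only — synchrony indices are
counts and stay linear) → per-column z-score → PCA to 15 components (20
for classifiers). Constant columns are dropped with a warning; a relative
tolerance absorbs floating-point roundoff in the mean of a constant
column. Each principal axis is sign-fixed so its largest-magnitude
loading is positive, making outputs platform-reproducible. The fitted
transform serializes to JSON so surrogate and rearranged variants can be
projected through the identical basis. Because fitting is row-order
invariant, permuting epochs before or after the reduction is equivalent;
the rearrangement analyses exploit this.

## The detector

Phase-1 clustering uses `sklearn.cluster.ward_tree` with a banded
connectivity matrix (|i − j| ≤ K); one linkage tree is built per K and cut
at every N, which is mathematically identical to running the constrained
agglomeration per (N, K) but ~19× cheaper across the N range. The test
suite proves the cut equal to a brute-force greedy Ward agglomeration on
small instances and equal to unconstrained Ward (scipy) when K ≥ n.

Merging conventions, where the underlying rule left room:

* short-segment merging processes the shortest offending segment first,
  ties leftmost; L = 0 skips the step;
* the close-segment loop recomputes D_avg over the *current* partition
  after every merge and stops when D_min > W·D_avg or one segment remains;
  with exactly two segments D_min = D_avg, so W < 1 never merges them;
* the relative rule makes pruning scale-free but means that with strongly
  *heterogeneous* adjacent contrasts the weakest real boundary can be
  merged away (its Ward distance falls under 0.3 × the average inflated by
  the strong pairs). This is a property of the method, not an
  implementation artifact; the synthetic default states are built with
  homogeneous contrasts (below) so recovery tests measure the detector,
  not this interplay.

Phase-2 conventions: candidate multisets keep duplicates (frequency is
stability); KMeans runs on raw indices (scale-invariant) with k-means++
and 10 seeded restarts; DBSCAN runs on indices normalized by the epoch
count — its radius values only make sense on a normalized scale — with
min_samples = 5, both exposed as configuration. Centers round half-up to
integer epochs; the mode tie-breaks to the smallest index. Candidate
lists are grouped by their deduplicated interior-boundary count, and each
count's winner maximizes the state-adapted silhouette, ties resolved by
the canonical enumeration order (L, N_max, K_max, method, parameter,
center type). Fixed-L pooling was chosen over pooling across L because
the subset definition enumerates (N_max, K_max, L) triples. The detector
never auto-selects "the" number of states; that is an expert decision made
from the reported measures.

Determinism: the only stochastic step is KMeans initialization, seeded
from `random_state`; identical inputs and seed give identical partitions.

## Quality measures

Silhouette, Calinski-Harabasz (with its two-cluster degrees-of-freedom
factors) and Davies-Bouldin are computed with scikit-learn on each
adjacent pair as a two-cluster dataset and averaged unweighted over pairs;
brute-force reimplementations in the tests pin them to 1e-10. Ward and
centroid distances between segment summaries complete the five measures.
Conventions for degenerate pairs: a singleton's silhouette is 0; coincident
centroids give Davies-Bouldin = ∞ (the similarity ratio diverges) and,
with zero scatter, Calinski-Harabasz = 0; two separated singletons give
Davies-Bouldin = 0 and Calinski-Harabasz = ∞. The standardized [−0.2, 1]
plotting scale sometimes used for display is reporting-only and never
enters selection.

## Information value

Features are binned into 10 quantile bins of the pooled distribution;
WoE = ln(event_share / nonevent_share) per bin and IV = Σ (event −
nonevent) · WoE. When any bin lacks a class, 0.5 is added to both counts
in every bin, keeping WoE finite while preserving exact textbook values on
zero-free tables. Quantile binning makes IV invariant under strictly
monotone feature transforms (property-tested). Binned IV has a positive
small-sample bias of order (bins − 1)(1/n_event + 1/n_nonevent); with
event classes under ~50 epochs it can reach 0.2–0.4 on pure noise, so
per-state averages are only meaningful for states of non-trivial size, and
the bin count is reduced (with a warning) when a class is smaller than the
bin count. The reporting threshold IV ≥ 0.4 ("medium or better") is kept
deliberately higher than credit-scoring convention because windowed
synchrony features are serially dependent across epochs.

## Significance testing

Mann-Whitney U (two-sided) between each unordered state pair and
one-sample Wilcoxon signed-rank (normal approximation) of each state
against the recording-wide feature median. The Bonferroni family is all
features within one comparison — the strictest per-analysis reading — and
reported entries are percentages of significant features at corrected
p < 0.01. All-tied samples get p = 1, so constant features are never
significant. The epoch-dependence caveat for windowed features is carried
in the report metadata rather than "corrected", matching the analysis
protocol the package implements.

## Predictive validation

Classifier scope is PSD + ratio columns only (315 on the standard
montage): windowed synchrony features leak across the train/test split.
The IV filter (≥ 0.4, one-vs-rest union for multiclass) and the 20-component
PCA are fitted on the training split only — refitting the filter on full
data demonstrably changes its support on small structured samples, which
the leakage test asserts. Splitting is epoch-level stratified with 40%
held out and 3-fold stratified CV for the grid search, exactly the
epoch-level protocol being replicated; a contiguous block-split option
exists and is off by default, because epoch-level splits inflate absolute
scores under temporal autocorrelation. Model families are kernel SVM,
L2 logistic regression and `HistGradientBoostingClassifier` as the
boosted-tree family, with small default grids (kernel/C; C/solver;
depth/learning-rate/iterations) exposed for extension. Binary tasks score
with decision functions where available. A state's one-vs-rest task may
be unrankable by a linear model when the state is "interior" in feature
space; the kernel family covers that case, and the tests exercise it.

## Synthetic data

Each channel is unit-variance 1/f background (flat below 1 Hz) plus five
band-limited Gaussian components synthesized by spectral masking of white
noise (exact band edges, no filter transition bands), scaled by the
state's (band, region) amplitude gain. Synchrony mixes a shared per-band
driver into all channels with amplitude weights √(1−s), √s, so `s` is the
driver's share of band power and maps monotonically onto coherence/PLV.
Generation is `numpy.random.default_rng`-seeded and bit-reproducible.

The default 8-state recipe matches the staged-protocol regime the detector
targets — 38 channels, 500 Hz, states of 60–180 one-second epochs — and
assigns each state one distinct (band, region) power boost of 4× amplitude
over baseline, rotating through the five bands and three equally sized
(3-channel) regions, with a common moderate beta synchrony. Two properties
of this construction are load-bearing: all states are pairwise distinct
(identical states that become adjacent after block rearrangement merge
into one — correctly — so rearrangement controls need distinct states),
and adjacent contrasts are homogeneous (see the merge-rule note above).
Earlier designs coding states by multi-band gain patterns produced 10–20×
spreads in adjacent Ward distances through the ratio features' pooled
denominators, and the relative merge rule then pruned true boundaries.

What the simulator does *not* model: volume conduction and field spread,
1/f slope changes, narrow-band oscillatory peaks with harmonics,
nonstationarity inside states, and realistic artifact topographies.
Passing recovery tests therefore show the algorithmic chain is correct
under its own assumptions, not that real recordings of any particular
paradigm contain such states.

## Test and acceptance problem sizes

Desk-scale sizes keep the suite and the acceptance script fast while
leaving every property scale-free: structural counts use the full
38-channel montage on 5–8 epochs; recovery runs an 8-state recording on a
6-channel / 3-region montage (~450 epochs) against the full 2,356-triple
grid; surrogate-contrast checks use 600-epoch feature tables with a
reduced grid preset (`SDAHyperGrid.small()`) over ≥10 seeds; the
acceptance script repeats the recovery-plus-rearrangement experiment
end-to-end on the reduced montage with the full grid. Monte-Carlo
tolerances (e.g. silhouette < 0.05 on surrogates, balanced accuracy
0.5 ± 0.05) were sized from the null distributions discussed above.

## Known limitations

* Surrogate-data detections can place boundary clusters at the recording
  edges, yielding length-1 states; downstream small-class statistics (IV
  especially) are then dominated by small-sample bias. Real structured
  data does not trigger this; reports flag tiny states via their
  dataset-share column.
* The candidate-selection silhouette is evaluated on the same data the
  candidates came from; the quality measures are therefore optimistically
  biased relative to an independent recording. The surrogate pipeline
  exists precisely to calibrate that bias.
* Wilcoxon uses the normal approximation throughout; for states under ~20
  epochs exact p-values would differ.
* EDF reading converts to microvolts assuming the file's physical units
  are volts as `mne` reports them; unusual EDF unit declarations are not
  special-cased.
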
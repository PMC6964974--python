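# Methods

## Grouped model reliance

`grouprely` implements grouped model reliance: a model-agnostic measure of
how much a fitted classifier depends on a named set of predictor columns.
Given a fitted model *f*, held-out data (*X*, **y**) and a group *J* of
column indices, the columns in *J* are randomly permuted across rows —
destroying their association with the outcome while preserving their
marginal distribution — and the accuracy drop is converted into a score.
With baseline accuracy ACC_bl and post-permutation accuracy ACC_perm(J),
the default (ratio-mode, size-normalized) score is

    MR(X_J) = (1/|J|) * ( (1 − ACC_perm(J)) / (1 − ACC_bl) − 1 )

The error *ratio* makes scores comparable across subjects whose absolute
decodability differs; the 1/|J| factor makes differently sized groups
comparable (a 20-frequency gamma band would otherwise be favored over a
5-frequency alpha band simply by surface area). Difference mode
(err_perm − err_bl, likewise optionally divided by |J|) is provided for
completeness. Scores can be negative — permutation can help by chance; only
large, consistent negative values are meaningful.

Estimation is embedded in stratified, shuffled k-fold cross-validation
(default k = 10). Per fold, the model is fitted on the training portion
only; the baseline accuracy is computed once on the validation portion and
reused for every group and permutation of that fold (it does not depend on
*J* — an exact optimization, not an approximation). Each group receives
`n_perm` (default 10) random permutations per fold, a plain Monte-Carlo
compromise between the prohibitive full average over all |fold|!
permutations and a noisy single draw. The reported per-group value is the
mean over permutations within fold, then over folds. No dispersion
estimates are attached: fold-level variances are not independent and we do
not pretend otherwise.

Reliance is computed on validation folds only — the question asked is which
variables a trained model relies on *to predict*, not to fit.

### Joint vs. independent group permutation

Permuting a group can mean one row permutation applied to all of its
columns simultaneously (preserving within-group covariance) or a separate
permutation per column. The grouped-permutation-importance literature uses
the joint scheme, which is the default here; `independent` is available and
recorded in the result settings. Both are exposed because either reading is
defensible and they answer subtly different questions (information in the
group vs. information in the group plus its internal structure).

### Degenerate baselines and exact identities

If a fold's baseline accuracy is 1, the error ratio is undefined. Such
records carry the difference-mode value instead, are flagged `degenerate`,
and trigger a warning — never a silent infinity.

The size-normalized score is the canonical per-record computation; the
un-normalized score is derived from it by multiplying back with |J|. This
makes the pair exactly consistent (`mr_unnormalized == mr_normalized * |J|`
bit-for-bit, which a direct double evaluation would violate about 10% of
the time at 1 ulp) while agreeing with direct evaluation of the
un-normalized formula to within one ulp.

### Cross-validation details

Fold assignment is a pure function of (labels, k, seed): per class, trials
are shuffled with the seeded generator and dealt round-robin, so per-fold
class counts differ by at most one and surplus trials land on the
lowest-indexed folds — a fixed, documented tie-break. This purity is what
makes "train on one group's columns only" exactly comparable with the full
model: `group_only_accuracy` over a group containing all columns reproduces
the standard CV accuracy bit-for-bit for the same seed.

Model factories construct fresh scikit-learn estimators; any estimator
built with `random_state=None` receives a seed derived from the master
seed, so whole runs are bit-reproducible. Defaults follow common practice
for this decoding problem: a 5000-tree random forest and an RBF-kernel SVM
with C = 1. The test suite uses 40–150 trees — the statistical behavior
under test does not depend on ensemble size, only the variance of
individual accuracy estimates does.

`leave_one_subject_out` implements between-subject decoding: each fold is
one subject; the model is fitted on all other subjects' pooled trials.

## Spectral predictors

Per trial and channel the signal is demeaned and linearly detrended, Hann
tapered, and Fourier transformed; squared magnitudes form the predictors.
Note one deliberate difference from session-based preprocessing pipelines:
detrending here is per epoch (epochs are the stored unit), not across a
session; a session-long detrend can be applied upstream when continuous
data are available.

Integer-frequency values (1–40 Hz) must be reduced from the native grid
(1/3 Hz for a 3 s epoch). Default: average native-bin power over
[f − 0.5, f + 0.5) Hz, which is robust to epoch length; `nearest_bin`
selects the single closest bin instead. The taper is not
amplitude-compensated — powers are in arbitrary units, and all downstream
statistics are contrasts across conditions, which normalization would not
change. Power is not log-transformed by default; a `log10` switch exists.

Band groups (delta 1–4, theta 5–7, alpha 8–12, beta 13–20, low gamma
21–40 Hz) partition the 1–40 Hz axis; nine ROIs
(left/central/right × frontal/central/occipital) partition the channels.
ROI membership is user configuration — electrode-to-region tables are
montage-specific and never hard-coded. With 122 channels the predictor
space is 40 × 122 = 4880 columns; each column belongs to exactly one band
and one ROI, so bands and ROIs overlap as groups, which is expected: every
group's reliance is evaluated independently.

## Cluster-based permutation test

Condition effects on (channel × frequency) power are tested with the
max-statistic cluster randomization approach. Pointwise statistic: the
one-way between-groups F across trials. (At the single-trial level the
condition groups are independent samples; the repeated-measures reading of
this test applies only to the across-subject variant, where the same F is
computed on per-subject condition means and condition labels are permuted
within subject.)

The cluster-forming threshold is the parametric F quantile at
`cluster_alpha` (default 0.05) for the map's degrees of freedom —
configurable, as is the cluster statistic (mass = sum of member F values,
or size). Connectivity joins same-channel points 1 Hz apart and
equal-frequency points on spatially adjacent channels; channel adjacency is
a Euclidean distance graph over the user-supplied 2-D layout, since the
true neighborhood template of any given montage is configuration. The null
distribution is the maximum cluster statistic over `n_perm` (default 1000)
label permutations, with 0 recorded when a permutation yields no cluster;
p = (b + 1)/(n_perm + 1), so p can never be 0 and is floored at
1/(n_perm + 1). A cluster is significant iff p ≤ alpha (default 0.05).

The permutation null is computed in batches: per-class indicator matrices
turn B relabelings into three matrix products, which keeps the
200-dataset × 500-permutation calibration study in the acceptance script at
a few seconds.

## Synthetic data

`simulate_subject` emulates the retention interval of a Sternberg
working-memory experiment: 3 sessions × 6 blocks × 54 trials = 972 trials,
loads 1/4/7 balanced within block (18 trials per load per block), 122
channels on a hexagonal montage, 3 s epochs at 512 Hz. Channels carry
1/f^1 colored noise plus a white floor (0.1); channels of the affected
ROI(s) additionally carry a sinusoid at a subject-specific integer peak
frequency (drawn in the configured band, default alpha 8–12 Hz) with random
phase per trial. Amplitude is `base * (1 + slope * load_rank)` with rank
0/1/2, clipped at zero, scaled by unit-mean lognormal trial-to-trial jitter
(σ = 0.4). The slope is signed — amplitude may rise or fall with load,
mirroring real inter-individual heterogeneity.

Defaults (base 0.6, slope 0.75, jitter 0.4) put single-subject decoding
accuracy in the realistic mid-range (≈0.45–0.65 on the reduced 27-channel
test montage) — high enough for planted-structure recovery to be reliable,
low enough that baselines are imperfect and the error ratio is well
defined.

What the generator does *not* emulate: volume conduction and realistic
cross-channel covariance, non-sinusoidal oscillations, ERP components,
artifacts, electrode drift, or probe/response phases. Passing tests
therefore demonstrate that the machinery is correct and calibrated on data
with the design's structure, not that any particular effect exists in real
recordings.

One genuine lesson from the heterogeneity simulation: flipping only the
*sign* of the load–amplitude slope across subjects does not drive
between-subject transfer to chance, because a nonlinear classifier can
exploit "extreme power in either direction = high load". Near-chance
generalization requires the fuller heterogeneity observed in real cohorts —
per-subject peak frequency and topography as well as sign — and that is
what the cohort test simulates.

`simulate_grouped_tabular` provides the minimal fixture for the reliance
engine itself: class-conditional Gaussian columns, a mean shift of
`effect × class_rank` in informative groups, optional within-group
equicorrelation via a shared factor.

## Problem sizes in tests and the acceptance script

Statistical checks run at reduced scale chosen for stable inference: the
27-channel / 108-trial montage for planted-recovery and heterogeneity
suites, 120-tree ensembles, 12 seeded replicate runs for the ≥95% recovery
check; the chance-calibration study uses 20 master seeds × 300 trials; the
type-I-error study uses 200 null datasets × 500 permutations on a
16-channel × 12-frequency grid. Each check states its own Monte-Carlo error
bound (3 standard errors unless noted) rather than a fixed tolerance.

## Known limitations

- Reliance is relative to the model: redundant groups can earn near-zero
  reliance while still decoding well alone (hence `group_only_accuracy`).
- The error-ratio form is undefined at perfect baselines; degenerate
  records are flagged rather than hidden, but folds with ACC_bl = 1 carry a
  different (difference-mode) scale.
- Permutation importance on correlated predictors extrapolates into
  off-manifold regions; conditional variants are out of scope.
- The trial-level cluster test assumes exchangeable trials within subject;
  session or block effects violate this if conditions are not balanced
  within block (the simulated design balances them).
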
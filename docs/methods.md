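# Methods

## Model and procedure

The analysis treats a continuous train of tactile stimuli as a sequence of
*triads*: stimulus *i* (for *i* ≥ 3) is characterised by its previous
interval *k* = t(i) − t(i−1) and penultimate interval *k−1* =
t(i−1) − t(i−2), in seconds. Triads are assigned to a 5 × 5 joint-interval
grid with upper bin edges 0.5, 1, 2, 4, 8 s. Membership is upper-bound
inclusive — interval *x* belongs to the smallest bin *b* with
*x* ≤ edge(*b*) — because the edges are defined as upper bounds; the first
bin is (0, 0.5] s (stimulation never produces intervals below 0.1 s, so the
open lower bound is inconsequential but defined). A triad is excluded when
*either* interval exceeds 8 s; exclusion counts are logged and every run
verifies that pooled trials + exclusions account for all stimuli. The axis
convention (row = penultimate, column = previous interval) is stamped into
output metadata because the 5 × 5 maps are orientation-sensitive.

Within each bin, the ERP is the mean of the pooled single-trial epochs
(−200…299 ms around onset, 1 kHz) of the selected electrode; a bin is valid
only with ≥ 10 trials. Grand averages are taken across subjects per bin; a
grand bin requires a configurable fraction (default 0.8) of subjects with a
valid bin — an addition this package makes explicit, since per-subject
missingness at grand averaging is otherwise undefined. Latency-wise
z-scoring standardises amplitudes across valid bins (sample SD, ddof = 1);
an all-equal latency yields z = 0 and a degeneracy flag.

**Statistics.** Per (bin, latency) cell, a two-sided one-sample t-test of
the subjects' z-scores against 0; cells with < 3 contributing subjects are
flagged untested, zero-variance cells get t = 0, p = 1. Multiple
comparisons are corrected once across all tested cells with
Benjamini–Hochberg (α = 0.05; Benjamini–Yekutieli optional). Latency
similarity uses Spearman rank correlation between the 25-value bin maps of
every latency pair; p-values use the t-approximation with n−2 df. Each
unordered pair enters the FDR pool exactly once (upper triangle), and pairs
within a ±25 ms diagonal band — trivially similar neighbours — are excluded
from the pool. The 25 ms figure is implemented as a *half*-width with a
switch for the full-width reading, since either reading is defensible.

**Factorization (starNNMF).** Post-stimulus magnitudes |amplitude| are
z-scored across valid bins per latency and shifted by the global minimum,
preserving all pairwise differences while making the 25 × 299 matrix
non-negative; invalid bins become excluded rows rather than being imputed
(imputation would fabricate modulation structure). Factorization uses
Lee–Seung multiplicative updates under the Frobenius objective
(epsilon-floor 1e−12, max 500 iterations, relative-change tolerance 1e−5;
the error history is recorded and checked non-increasing on every run).
Rank selection is Wold-style cross-validation: a random 10% of entries is
held out per fold (redrawn if a row/column would be fully masked), the
model is fitted on observed entries with masked updates (best of 5
restarts, judged on observed-entry fit), and held-out RMSE is averaged over
5 folds. The selected rank applies a one-standard-error rule on *paired*
per-fold differences toward the smaller rank: folds share holdout masks
across ranks, so pairing removes mask-to-mask variance and makes the
parsimony rule sharp even when the error curve is flat beyond the true
rank. Stability selection runs 100 (configurable) factorizations from
independent random initializations, scores every pair of runs by the mean
cosine similarity of optimally one-to-one-matched W columns (invariant to
the scale-permutation equivalence class of NNMF), and returns the medoid
run; its mean similarity to all other runs is the stability score.
"Most commonly visible across repetitions" is thus operationalised as a
deterministic, auditable medoid; a consensus-clustering selection would be
a drop-in alternative.

**Population clustering.** Meta-times are normalized to unit Euclidean
norm before pooling (the inverse scale is absorbed into the paired W
column, leaving W H unchanged): NNMF scale is arbitrary, so clustering raw
rows would group by amplitude rather than latency shape. All factors from
all subjects are pooled as individual points. k-means (Euclidean,
1000 random-initialization restarts) is run for k = 3…7 and the k with the
highest mean silhouette wins; Euclidean silhouette is the default (a
correlation distance would be the natural alternative for shape data, but
Euclidean on unit-norm vectors is monotonically related to cosine
distance). Cluster representatives are elementwise means of member
meta-times and their paired meta-JIERPs.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:
~600–1800 stimuli per train with i.i.d. intervals on [100, 10 000] ms
(log-uniform by default, so the quadratic bins receive roughly balanced
counts; uniform optional — the true sampling law of the original protocol
is exposed as a parameter, not asserted), a smooth evoked template built
from Gaussian-windowed components (peaks +5 μV at 50 ms, −5 at 75, +4 at
100, −3 at 150, +3 at 200 ms; 8 ms width; amplitudes are package choices at
a realistic SEP scale), multiplicative interval-conditioned gain applied
per processing-stage window, and additive i.i.d. Gaussian noise (default
1–2 μV; optional 1/f noise, off by default so noiseless oracles stay
exact). Overlapping responses sum linearly — the simplest defensible
superposition model. The first two events of a train have no triad and
receive unit gain.

The `early_late_suppression` preset multiplies the early and late windows
by a gain keyed to the previous interval (0.6 below 0.5 s, 1.0 up to 2 s,
1.3 beyond) and the intermediate window by the same profile keyed to the
*penultimate* interval, so the intermediate-stage bin pattern is
independent of the early/late pattern; the `diagonal` preset is monotone in
min(k, k−1). Gains are stored as per-window 5 × 5 tables evaluated at bin
level.

Not emulated: blink/muscle artifacts, volume conduction and electrode-cap
topography, background-state fluctuations (e.g. movie watching), and
impedance-driven channel loss. Passing tests therefore demonstrate that the
*analysis chain* recovers planted interval-dependent structure under
realistic noise, not that any particular neural effect exists in recorded
data. ICA blink removal and spherical channel interpolation are deliberately
out of scope; the pipeline accepts pre-cleaned recordings.

## Parameter defaults

| Parameter | Default | Notes |
|---|---|---|
| Epoch window | −200…299 ms | 500 samples at 1 kHz |
| Band-pass | 1–45 Hz (optionally preceded by 0.1–75 Hz) | zero-phase FIR, ~3.3 transition-width cycles (mne firwin defaults) |
| Rejection | strictly > 80 μV absolute | boundary epochs (exactly 80 μV) are retained: "beyond" denotes exceedance |
| Baseline | −200…−50 ms mean | per epoch and channel |
| Electrode selection | max positive peak, 25–75 ms | the P50 positivity; `absmax` optional, 150–300 ms window for central sites |
| Bin edges | 0.5, 1, 2, 4, 8 s | upper bounds, (lower, upper] membership |
| Min trials per bin | 10 | |
| Grand-average bin validity | ≥ 80% of subjects | package addition |
| α | 0.05, BH jointly across 25 × T | BY optional |
| Cross-correlation band | ±25 ms half-width | full-width reading switchable |
| NNMF | rank CV 2–10, 100 restarts, max_iter 500, tol 1e−5 | |
| k-means | k 3–7, 1000 restarts, random init | silhouette selection |

## Numerical choices and degenerate inputs

- Zero-phase (forward) FIR filtering keeps component latencies unshifted;
  filter length follows the mne firwin heuristic since the upstream
  toolbox's defaults are deferred to.
- Electrode-selection ties break to the lowest channel index (logged).
- Spearman ρ = ±1 maps to p = 0; constant bin maps make ρ undefined — such
  pairs are flagged and never enter the FDR pool.
- An all-zero NNMF input is an error; an all-zero meta-time is dropped at
  normalization (logged), reducing the effective rank.
- k-means with all-identical points raises (silhouette undefined); k values
  exceeding the point count are skipped and logged.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); a pipeline rerun under the same
  configuration is bit-identical, and every output container carries the
  configuration hash so stages from different configurations cannot be
  mixed silently.

## Test problem sizes

The suite exercises the chain at desk scale: trains of 80–1800 events,
12–30 simulated subjects, NNMF matrices of 25 × 299. The null-level check
of the FDR machinery uses 1000 global-null replicates in the suite and
3000 in `scripts/acceptance.py`; because Benjamini–Hochberg attains the
nominal level *exactly* for independent continuous p-values, the suite
tests level control one-sidedly at two Monte-Carlo standard errors of the
replicate mean — an estimator-precision allowance, not a relaxation of the
α = 0.05 criterion. Planted-pattern recovery (three (meta-JIERP, meta-time)
pairs, 8% Frobenius-norm noise, 20 subjects) uses 15–20 stability restarts
per factorization; results are insensitive to raising this to the
production default of 100.

## Known limitations

- Wold CV assumes missing-at-random holdouts; heavily structured matrices
  with near-collinear factors can still make neighbouring ranks
  statistically indistinguishable (the paired one-SE rule then prefers the
  smaller rank by design).
- The per-bin ERP ignores within-bin interval gradients; bins are treated
  as homogeneous contexts.
- Epoch overlap at short intervals (< 500 ms) mixes late components of the
  previous response into the current epoch's baseline and early window;
  the generator reproduces this honestly (linear summation), and the
  binning averages it within contexts, but it is not explicitly modeled.
- EDF export is not provided (HDF5 + TSV is the canonical on-disk pair);
  BrainVision and EDF are read-only inputs.
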
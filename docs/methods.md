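# Methods

This note documents the models, conventions and numerical choices behind
`spade-eeg`, in the spirit of a statistical-software methods appendix. It
states what the code computes and why each open design question was
resolved the way it was; every number quoted here is produced by the test
suite or by `scripts/acceptance.py`.

## Problem setting

Task-related EEG passes through a sequence of quasi-stable spatial
configurations (microstates). Classical microstate analysis clusters
scalp topographies at global-field-power (GFP) peaks, which works well
for resting-state rhythms but poorly for rapidly evolving task data. This
package instead represents each sliding window of the recording by its
spatial covariance matrix (SCM) — a symmetric positive definite (SPD)
matrix that captures the instantaneous spatial pattern of activity — and
clusters windows by the geometry of those SCMs.

## Pipeline

For a channels × samples record `X` with `n` channels:

1. **Windowing** (`segment`): sliding windows of length `t` samples and
   step `s` (defaults 200 ms, 1 sample), each zero-meaned per channel;
   `m = ⌊(T − t)/s⌋ + 1` windows.
2. **SCM estimation** (`covariance_set`): `C = X Xᵀ/(t−1)` per window,
   with shrinkage `C ← (1−γ)C + γ(tr C/n)I`. `γ = 0.05` is applied
   automatically when `t − 1 < n` (rank-deficient by construction) *or*
   when any raw SCM's condition number exceeds `1e8`. The second guard
   matters even for long windows: sources that are silent in a window
   push eigenvalues to the float-noise floor, and the affine-invariant
   metric then measures rounding error rather than signal. Shrinkage
   preserves the trace and bounds the log-spectrum.
3. **Two spatial-pattern distances** (`geometry`):
   * sensor space: the largest generalized eigenvalue `λmax` of
     `(Ci, Cj)` — the best variance ratio achievable by a spatial filter
     (the common-spatial-pattern objective). `λmax` is asymmetric, so the
     matrix entry is `max(λmax(Ci,Cj), λmax(Cj,Ci)) ≥ 1`, equal to 1 iff
     the SCMs coincide.
   * source space: the affine-invariant Riemannian distance
     `δ_R(Ci,Cj) = ‖logm(Ci^{-1/2} Cj Ci^{-1/2})‖_F = √Σ log²λ_e`,
     invariant to any invertible channel mixing, hence a property of the
     underlying sources. Both distances for one pair come from a single
     generalized eigendecomposition (the eigenvalues of one ordering are
     the reciprocals of the other), computed in batched chunks.
4. **Feature fusion** (`features`): three m × n blocks — log SCM
   diagonals (log channel variances), classical (Torgerson) MDS of
   `log D_sensor`, and classical MDS of `D_source` — each z-scored per
   column and concatenated into m × 3n features. The elementwise log of
   the sensor matrix maps its unit diagonal to the zero diagonal MDS
   requires and puts the eigenvalue ratios on the same log scale as
   `δ_R`. MDS keeps the top `n` eigenpairs; negative eigenvalues
   (non-Euclidean dissimilarities) are clipped to zero with a logged
   warning. Columns with (numerically) zero variance standardize to
   zeros rather than NaN.
5. **Deep embedded clustering** (`dec`): a mirrored fully connected
   autoencoder (3n → 64 → 32 → k, k = 5, tanh; linear bottleneck and
   output) is pretrained on mean-squared reconstruction (Adam 1e-3,
   800 epochs, batch 256); K-means (10 restarts) seeds `s` centroids in
   the bottleneck space; then encoder and centroids jointly minimize
   `KL(P‖Q)` where `Q` are Student-t soft assignments (α = 1) and `P` is
   the squared-and-renormalized target, refreshed every 30 iterations.
   Training stops when fewer than 0.1 % of hard labels change between
   refreshes (at most 2000 iterations). Empty clusters are reseeded at
   the least-confident point. Everything is plain numpy, so fixed seeds
   give bit-identical runs.
6. **Microstate sequence** (`pipeline`): each sample takes the label of
   the window whose center is nearest in time (ties toward the earlier
   window); runs are the maximal constant stretches. Each cluster's
   representative window minimizes the sum of squared Riemannian
   distances to its members — the member closest to the cluster's
   Fréchet mean.

### Encoder defaults

The encoder architecture is this package's own choice (the reference
design it follows does not print one). Widths (64, 32), latent dimension
5 and tanh were selected on a small sweep over simulated recordings for
reconstruction quality (relative MSE < 1 %) and run-to-run cluster
stability; all of it is configurable through `EncoderSpec`. The latent
dimension matches the usual cluster count.

## SPD geometry numerics

All matrix functions go through symmetric eigendecompositions with an
eigenvalue floor of 1e-12 applied only where the domain requires it
(log, inverse square root) — never to tangent matrices, whose negative
eigenvalues are meaningful. The Fréchet (Karcher) mean starts at the
arithmetic mean and iterates
`E ← E^{1/2} expm(ν·mean_i logm(E^{-1/2} C_i E^{-1/2})) E^{1/2}`,
halving the step ν whenever the gradient norm fails to decrease;
tolerance 1e-6 on the mean tangent norm, at most 50 iterations, and
non-convergence raises an error carrying the last iterate. Tangent-space
vectorization uses the upper triangle with √2 off-diagonal weighting so
Euclidean inner products equal Frobenius inner products (plain
flattening is available for strict parity with vector baselines).

## Synthetic EEG generator

`simulate` builds six unit sources over 1000 ms at 1000 Hz:

| source | design |
|---|---|
| 1 | Gaussian white noise, unit variance |
| 2 | linear chirp (10±5 → 30±5 Hz), amplitude 1 |
| 3 | linear chirp (30±5 → 10±5 Hz), amplitude 1 |
| 4–6 | sines at 30/20/10 ±5 Hz, amplitude 0.5, under Gaussian envelopes of 300 ms duration, peak 1, centered at 800/500/200 ±50 ms |

Conventions the reference description leaves open, fixed here once:

* **Envelope support**: "duration 300 ms" is read as 6σ (σ = 50 ms), so
  ≈99.7 % of the pulse mass lies within the nominal duration.
* **Phases**: with `random_phase=True` (default) chirps and sines draw a
  fresh initial phase every trial, so trial averaging attenuates the
  oscillatory carriers by ≈1/√n_trials while the envelopes' variance
  structure survives — the regime in which sample-level topography
  clustering is near chance but SCM-based methods succeed.
* **Jitters**: every "±j" fluctuation is Uniform(−j, j), drawn once per
  trial per parameter.
* **Mixing**: i.i.d. standard-normal n × n matrix, redrawn (≤100 times)
  until its condition number is below 1e3; one matrix per dataset,
  shared across its 50 trials. Separate named seeds control mixing and
  trials.
* **Ground truth**: state boundaries at the nominal pulse centers ± half
  the duration — 50/350/650/950 ms, giving S1–S5 with run lengths
  50/300/300/300/50 samples. Truth depends only on the configuration,
  never on the random streams.

`easy_config()` zeroes all jitters *and* fixes the phases, making every
trial identical up to noise; with identity mixing this is the natural
"parameter recovery" regime.

What the generator does **not** emulate: head geometry and volume
conduction beyond an arbitrary linear mix, 1/f background spectra,
artifacts, or inter-trial amplitude variability. Passing tests on this
generator therefore demonstrate correct geometry and clustering
mechanics under a known linear mixing model, not robustness to real
recording conditions.

## Evaluation conventions

Window-level clusterings are scored against the state at each window's
**center** sample. Note a structural consequence: with 200 ms windows on
the 1000 ms record, centers span 100–900 ms, so the 50 ms flanking
states S1/S5 own no window center and window-level truth has three
states. A five-cluster solution must then split true states, which caps
the attainable ARI for balanced splits near 0.77 — worth remembering
when reading absolute scores.

Sample-level algorithms (GFP, GMM) are scored per sample over the whole
record. The silhouette uses one common footing for all algorithms: the
Riemannian distance matrix of the 200 ms windows, with sample-level or
differently-windowed labelings read off at those windows' centers.

The GMM baseline defaults to a **tied** covariance (components differ by
mean topography only). A per-component full covariance would itself
discover the states' spatial covariance structure — at which point it is
no longer the intended "sample-level, mean-based" reference — and is
available via `covariance_type="full"`.

The soft-DTW baseline treats windows as multivariate series (time ×
channels) with squared-Euclidean ground cost and smoothing γ = 1,
assigns by the debiased divergence, and refines barycenters by L-BFGS on
the mean alignment cost using a ≤48-member random subsample per update
(4 alternation rounds). These sizes keep the quadratic dynamic programs
tractable at step-1 window counts on one CPU; they are the package's
own defaults and are configurable.

## Cluster validation

For every unordered cluster pair, 1000 within-cluster distances (pooled
equally over the two clusters; with replacement) and 1000 cross-cluster
distances are sampled from the precomputed Riemannian distance matrix; a
one-tailed Welch t-test asks whether within < between, with
Benjamini–Hochberg FDR across pairs at α = 0.05. Welch rather than
pooled-variance because the two distributions' spreads differ visibly in
practice. **Limitation**: resampling 1000 pairs from clusters with only
a handful of members recycles the same few distances and makes the
nominal test anti-conservative; the calibration property (≈5 % false
positives under random labels) holds at realistic cluster sizes
(dozens of members) and is tested there.

Cross-algorithm comparison: per metric, Shapiro–Wilk gates between
paired t-tests (all score vectors normal at α = 0.05) and Wilcoxon
signed-rank tests, with BH-FDR across the comparisons of that metric.
Zero-difference pairs are dropped per the Wilcoxon convention; an
all-zero difference vector reports p = 1.

## Problem sizes

The simulation study runs 30 datasets (one mixing matrix each, 50 trials
averaged), all seven algorithms, five clusters, 200 ms windows at step 1
(m = 801; the soft-DTW baseline uses its own 100 ms windows, m = 901).
One full study takes ≈10 minutes on one CPU; the reproduction script,
which runs the pipeline and the two targeted baselines, about half that.

## Known limitations

* The joint KL refinement reliably reaches a fixed point but rarely
  moves cluster boundaries far from the K-means initialization on these
  features; on data whose states form elongated trajectories (envelope
  waxing/waning inside a state) boundary placement, not cluster
  identity, is the dominant error source.
* Shrinkage γ is a single global constant per covariance set, not
  estimated per window (a Ledoit–Wolf-style estimate would be a natural
  extension).
* The statistical validation assumes the precomputed distance matrix is
  fixed; no uncertainty from SCM estimation propagates into it.
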
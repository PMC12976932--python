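# Methods

This note documents the models and procedures implemented in `hippogeom`,
the assumptions behind them, the defaults that matter, and the places where
the design was genuinely open and a choice had to be made.

## Task simulator (`synth`)

The simulator emulates a joystick pursuit game on a bounded 1800 × 1000 px
screen sampled at 60 Hz (frame = 16.67 ms).

**Agents and movement rules.**

* *Avatar (self)* — position clipped to the screen, displacement capped at
  23 px/frame (the joystick limit).  Real sessions have a human in the
  loop; the built-in stand-in policy is noisy proportional pursuit: head
  toward the chosen prey (the nearest prey at trial start) with von Mises
  heading noise.  The concentration parameter defaults to κ = 2 (≈ 45° SD),
  chosen once so that simulated behavior resembles real play — roughly 75%
  of trials end in capture, mean trial duration a few seconds, occasional
  predator captures — rather than the near-instant captures a noiseless
  pursuer produces.
* *Prey* — each frame, 15 candidate positions are placed uniformly on a
  circle of radius `prey_max_speed`; the minimum-cost candidate that stays
  on screen wins (off-screen candidates skipped in ascending cost order).
  The cost is a quadratic center bias,
  `center_bias_strength · (d_center / half_diagonal)²` with gain 0.3, plus
  a sigmoidal avatar repulsion `1 / (1 + exp(slope · (d − midpoint)))` with
  midpoint 200 px and slope 0.02/px, truncated to zero beyond 545 px (where
  it falls below 1e-3).  The shapes of both cost terms are qualitative
  descriptions in the literature without published constants; the values
  here were fixed once so that prey begin to flee within roughly the 400 px
  initial-separation scale.  Default prey speeds are 16 and 19 px/frame
  (slower than the avatar, so pursuit can succeed; fast enough that it
  takes seconds).
* *Predator* — single rule: move at `predator_speed` (16 px/frame) directly
  toward the avatar; present on 50% of trials when enabled.

**Trials.**  The avatar spawns at the center; prey spawn on cardinal points
450 px away (satisfying the ≥ 400 px separation rule).  A trial ends at
capture — center distance ≤ 22.5 px, i.e. avatar radius (7.5) + prey
half-side (15), a monotone proxy for circle–square tangency (the exact
tangency rule is available via `capture_rule="tangency"`) — or after 20 s.
Sessions concatenate trials with 30-frame inter-trial gaps marked invalid
for every variable; gaps and non-captured trials are excluded from all
analyses.  Chosen/unchosen prey labels are assigned post hoc from the
trial record (chosen = the prey eventually captured, or the pursuit target
on non-capture trials).

**Gaze** is simulated directly in screen coordinates: a Markov process
switches the followed target (weights over agents, switch rate 1/s),
isotropic Gaussian jitter (20 px) is added, and frames drop out with
probability 0.05 (modeling tracking failures).

**Spiking.**  Neurons are log-linear Poisson:
`rate(t) = exp(b_i + Σ_v w_{iv}[bin_v(t)])` Hz, counts drawn as
`Poisson(rate · dt)` with a 200 Hz ceiling purely as an overflow guard.
Frames where a tuned variable is invalid contribute baseline only.
Baselines are uniform on 2–8 Hz.  All randomness flows from one root seed
through `numpy.random.SeedSequence` spawns, with an independent stream per
neuron so that adding neurons never perturbs existing spike trains.

**Planted geometry.**  Per-variable weight-map matrices are constructed as
`M_v = map_gain · Q_v A_v + axis_gain · u_v c′ (+ noise)`, where the
`Q_v` are orthonormal neuron-space bases realizing requested principal
angles against the reference variable (constructed from one shared
orthonormal frame, so angles are exact by construction), the `A_v` are
smooth orthonormalized mixtures of low-frequency 2-D cosine modes over the
6×6 grid (equal latent norms make the planted subspace geometry exactly
recoverable from map covariances: with equal angles θ, the alignment index
equals cos²θ), `u_v` are planted left/right decoding axes (shared, negated
or orthogonal across variables), and `c` is the unit left/right bin
contrast.  When an axis is planted, the left/right contrast is projected
out of the latent patterns so that the axis term alone carries the
class signal.  An optional latent linear map ties two variables'
coordinates by `A_b = W_true A_a`, exactly before noise.

Angles are planted *relative to the first (reference) variable*; pairwise
angles between two non-reference variables are not directly controlled.

**Independent-trajectory sessions.**  `random_walk_session` produces
mutually independent reflected Gaussian random walks (default step SD
25 px/frame) segmented into pseudo-trials.  In pursuit behavior the agents'
positions are strongly correlated (the avatar chases the prey), so one
variable's tuning leaks into another variable's measured rate map through
behavior; the random-walk sessions remove that confound and are the
fixture for the statistical calibration tests.  This also defines what the
passing tests do and do not show: parameter-recovery results are exact on
independent trajectories, while on pursuit behavior cross-variable leakage
is real and is precisely what the GLM's joint model selection exists to
handle.

## Rate maps and population matrices (`maps`)

Positions are binned on a 6 × 6 grid (half-open bins, last bin closed,
row-major indices), restricted to valid frames of captured trials.  The
per-bin mean rate is total spikes / (occupancy · dt).  Unoccupied bins are
imputed before smoothing by the kernel-weighted mean of occupied bins
(truncated Gaussian, σ ≥ 0.5), with an imputation mask recorded — this
avoids NaN propagation into PCA while flagging unreliable bins.  Smoothing
uses σ = 0.5 bins with a truncated, per-source renormalized kernel: each
bin's mass is spread over its in-grid neighbors with the kernel
renormalized to the weight remaining on the grid.  This boundary rule is
linear and exactly mass-preserving (verified against a brute-force
kernel-sum oracle); no wraparound, since the screen is bounded.

Maps are smoothed, then vectorized, then z-scored per neuron (ddof = 1, so
each retained row has Σz = 0 and Σz² = 35).  Rows with SD < 1e-12 are
flagged as zero-variance and excluded from geometry analyses; when several
variables are analyzed together, a neuron flagged for any variable is
dropped from all matrices so that pairwise analyses share one neuron set.

## Poisson LN-GLM and forward selection (`glm`)

Design matrices are one-hot per variable (36 columns each) plus an
unpenalized intercept; frames missing any requested variable are excluded
(complete case).  The penalized log-likelihood is

```
Σ_t [y_t η_t − exp(η_t)] − Σ_v β_v w_v′ L w_v − 1e-8 b² − 1e-8 ‖w‖²
```

with `L` the 4-neighbor graph Laplacian of the 6×6 grid (sum of squared
first differences along both screen axes, no wraparound).  The intercept
ridge alone does not make the multi-variable problem strictly convex
(shifting mass between two variable blocks is likelihood- and
penalty-neutral), so a negligible ridge (1e-8) on the weights fixes
uniqueness and conditioning without measurably biasing the fit.

Two implementation choices matter for speed and are exact:

* **Design-row compression** — frames with identical one-hot rows are
  aggregated into (count, spike-sum) sufficient statistics; the Poisson
  likelihood depends only on these.  Single-variable fits become 36-row
  problems; two-variable fits at most 1296 rows.
* **Damped Newton optimization** — analytic gradient and Hessian, Armijo
  backtracking, adaptive Levenberg damping on stalls, convergence at
  gradient ∞-norm < 1e-6 or when the Newton decrement falls below the
  floating-point resolution of the objective.

**Cross-validation.**  Folds are ~10 s contiguous chunks (600 frames)
dealt round-robin to 10 folds — spike trains are autocorrelated, so
frame-level interleaving would leak information between train and test.
The per-fold score is the held-out log-likelihood increase over a null
model predicting the training-mean rate, divided by the held-out spike
count, in bits/spike (base 2; configurable).  The penalty grid is
{1, 10, 100, 1000}, shared across variables in a model, re-selected for
every candidate model.  Folds with zero held-out spikes are recorded as
NaN and excluded with a warning.

**Forward selection.**  All single-variable models are fit first (ties
broken by candidate order); then only supersets of the incumbent are
grown; a larger model is accepted only if a one-tailed Wilcoxon signed-rank
test across the 10 paired fold values is significant at α = 0.05 (exact
distribution at n = 10); the final model must additionally beat the null
in the same test, else the neuron is classified as untuned.  All candidate
models are evaluated on the common complete-case frame base of the full
candidate set, with one fold assignment, so fold values are genuinely
paired across models.  Under the null this procedure is conservative: the
measured false-tuning rate on constant-rate neurons is at or below the
nominal 5%.

**Prediction quality** is the Pearson correlation between predicted and
observed rate series after temporal Gaussian smoothing; the smoothing SD
is not dictated by the procedure and defaults to 250 ms (15 frames).

## Map similarity (`similarity`)

**SPAEF** is computed on smoothed, unnormalized maps (the
coefficient-of-variation ratio needs real scales); z-scoring happens only
inside the histogram component C, which uses 10 equal-width bins over the
union range of both z-scored maps, intersection normalized by the first
map's total.  With 36 values per map C is coarse; the bin count is
config-exposed and this caveat documented.  B is order-sensitive
(`cv(map_b)/cv(map_a)`).  The permutation test shuffles only the second
map's bins (preserving the first map's marginal exactly) and reports the
two-sided tail `(#{|null| ≥ |obs|} + 1)/(n + 1)` — under the null the rank
of |observed| among |shuffled| is uniform by exchangeability.  The noise
ceiling splits captured trials into two disjoint random halves (odd trial
dropped), builds maps per half, and averages SPAEF across splits.

**Agent preference index** — per neuron, the 95th−5th percentile range of
the unnormalized map (linear-interpolation percentiles), normalized by the
population-mean range per variable, differenced between two variables.
Neurons with zero range in both maps are excluded and counted.  Bimodality
is assessed with Hartigan's dip statistic, computed by the classical
greatest-convex-minorant / least-concave-majorant iteration (implemented
here in count units; validated to 1e-9 against an exact linear-programming
formulation of the dip's definition, including tied samples and the
atom-at-the-mode subtlety), with a uniform-bootstrap null (n = 2000).  On
Gaussian samples this calibration is conservative (measured type-I ≤ 0.07
at nominal 0.05, N = 200).

**Correlation structure** — N×N Pearson matrices of map rows per variable;
display order from centroid-linkage hierarchical clustering of the
reference matrix; similarity across variables as squared Pearson
correlation of upper-triangle vectors.

## Subspace geometry (`subspaces`)

Two covariance conventions are used deliberately, matching each formula's
dimensions: neuron-space `C_v = M_v M_v′/35` (N×N) for PCA, alignment and
subspace optimization; bin-space `M_v′ M_v/(N−1)` (36×36) for the
covariance-correlation analysis.

* **Alignment index** — `tr(D_a′ C_b D_a) / Σ_{i≤10} σ_b(i)` with `D_a`
  the top-10 eigenvectors of `C_a`.  The null draws k vectors
  `v_j = C_comb^{1/2} u_j` from the covariance of the variable-concatenated
  data and orthonormalizes them; the one-sided p is the fraction of random
  subspaces with *smaller* AI than observed, so small p means "more
  orthogonal than chance" — the direction is kept as stated even though it
  reads backwards from the usual convention.
* **Half-split covariance correlation** — per iteration, captured trials
  are split in two; the within baseline correlates variable a's covariance
  between halves, and the cross value correlates a's half-1 covariance
  with b's half-2 covariance over the same split, so both statistics face
  identical sampling noise and the self-pair reduces exactly to the
  baseline (ties broken at random, p ≈ 0.5).
* **Orthogonal subspaces** — the joint orthonormal frame
  `Q = [Q_1 … Q_V]` maximizing the equally weighted (1/V) sum of
  normalized captured variances is found by Riemannian gradient ascent on
  the Stiefel manifold: tangent-space projection of the gradient, QR
  retraction with sign correction, backtracking line search (monotone by
  construction), convergence at relative objective change < 1e-9 or
  gradient norm < 1e-6, five starts (eigenvector-seeded plus random), best
  objective kept.  The equal 1/V weighting generalizes the pairwise ½.
  Subspace dimensionality defaults to 4 per variable.
* **Cross-projection bootstrap** — neurons are resampled with replacement
  jointly in the map matrices and in the basis rows (the resampled basis
  re-orthonormalized); p is the fraction of replicates in which the
  cross-subspace capture reaches the own-subspace capture.  The resampling
  unit and null here are an interpretation: resampling neurons is the
  natural unit for a pseudo-population, and own-subspace capture the
  natural reference.
* **Linear maps** — ordinary least squares `W = argmin ‖X_b − W X_a‖_F`
  (no intercept; minimum-norm and flagged if `X_a` is rank-deficient),
  `R² = 1 − ‖X_b − W X_a‖²_F / ‖X_b‖²_F` on the full 36 conditions and by
  leave-one-bin-out cross-validation (verified to 1e-12 against a manual
  fold loop); the null permutes entries within each row of `X_a`
  independently per shuffle.

## CCGP (`ccgp`)

Concatenated captured trials are cut into non-overlapping 40 s chunks
(trailing remainder discarded and logged).  Left/right classes use grid
columns {0, 1} and {4, 5}; within each side the 6 bins with the highest
whole-session occupancy are kept (ties broken by ascending bin index; the
occupancy ranking is fixed across chunks so one bin set defines the
classes; a random-6-of-12 rule is available as an option).  Each
(chunk, selected bin) pair contributes one population rate vector; rows
whose bin was unvisited in a chunk are dropped and counted.

Per repetition (50 by default), the training design is split 70/30 with
class balance preserved, per-neuron z-scoring statistics come from the
training rows only and are applied unchanged to the test context, a linear
SVM (margin penalty C = 1) is fit, and accuracy is measured on the
test-context rows whose (chunk, bin) keys fall in the held-out part (all
test rows if the contexts share no keys).  The split is stratified over
classes only, not chunks, so rows of one chunk can appear on both sides of
a split; this matches the chunk-as-sample design but is noted as a
leakage risk at small chunk counts.  The label-shuffle null permutes
labels independently within each context and reruns the full repetition
procedure (500 shuffles by default); p is the tail in the direction of the
observed deviation from 0.5, with a +1 correction.

Decoding axes are unit-normalized SVM weight vectors per context on the
full z-scored design; pairwise cosines are converted to angles and to
distances `√(2(1−cos θ))`, embedded by classical (Torgerson) MDS — the 2-D
coordinates carry an arbitrary rotation/reflection.  Two numerical
caveats: a max-margin axis in a high-dimensional, nearly separable design
is determined by few support vectors and so carries irreducible direction
noise (~10° at a per-neuron amplitude SNR of 10 under the synthetic design
used in the tests); and with nearly noise-free designs, per-neuron
z-scoring is dominated by the signal itself, which can make cross-context
scaling degenerate — the calibration tests therefore use moderate noise.

## Problem sizes and benchmarks

The repository's calibration script (`scripts/acceptance.py`) uses:
100-trial pursuit sessions with 100 planted neurons for the CCGP null
calibration (100 shuffles × 20 repetitions); a 150-s random-walk session
for the SPAEF identity; 60 planted neurons for the alignment identity; and
150 pursuit trials (> 2×10⁴ analyzable frames) × 100 constant-rate neurons
with four candidate variables for the GLM false-tuning rate.  These sizes
were chosen as the smallest at which the Monte-Carlo error of each
statistic is comfortably below its acceptance band.

## Known limitations

* The avatar policy is a stand-in for human play; trial-duration and
  reward statistics are qualitatively, not quantitatively, matched.
* Prey cost-field and repulsion constants are plausible choices, not
  reconstructions; results that depend on fine behavioral statistics
  should be read accordingly.
* Planted principal angles are exact only for the stored weight maps; maps
  *measured* from spikes differ through the exponential nonlinearity,
  finite sampling, and (for pursuit behavior) cross-agent correlation.
* The dip test's uniform-null bootstrap is conservative for peaked
  unimodal alternatives.
* CCGP decodes only the binary left/right contrast; continuous position
  decoding and nonlinear decoders are out of scope.
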
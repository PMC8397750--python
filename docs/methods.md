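# Methods

This package analyzes chronic calcium-imaging responses to a repeated,
looped natural movie: single neurons fire in short, precisely timed
**spiking episodes** whose gain drifts across weekly sessions, yet the
population traces a stable low-dimensional **ring manifold** on which the
time within the movie can be decoded without supervision.  This note
describes the models and procedures, the synthetic data they are validated
on, the numerical choices, and the limitations.

## Data model and preprocessing

Activity is held as a dF/F tensor χ of shape neuron × time × trial
(N × T × K) with per-trial week labels; the default trial is 5 s of gray
screen followed by 30 s of movie at 10 Hz (T = 350, dt = 0.1 s), 30 trials
per weekly session, 6 weeks.

From raw fluorescence, the corrected trace is
`F_soma − α (F_neuropil − mean(F_neuropil))`, with α chosen on a 0.01 grid in
[0, 1] to minimize |corr(corrected, neuropil)| (a constant neuropil trace is
degenerate; α = 0 is returned with a warning).  dF/F is `(F − F0)/F0` with
the baseline F0 estimated as the mode of a Gaussian kernel-density estimate
(Silverman bandwidth, arg-max on a 512-point grid spanning the data range) —
the mode is the natural baseline for sparsely active neurons whose
fluorescence distribution is dominated by the resting level.

Before tensor decomposition every neuron is rescaled to unit root mean
square over all bins and trials, `sqrt(Σ x² / (T·K)) = 1`, so high-rate
neurons do not dominate the squared-error objective.  All-zero neurons have
no defined scale and are dropped with a warning.  Normalization is
idempotent and scale-equivariant.

**Week similarity** is the per-neuron Pearson correlation between
trial-averaged traces of a reference week and each other week, averaged over
neurons.  The across-week change statistic is the mean |Δ trial-averaged
trace| against week 1; its within-week baseline is the same statistic
between two random half-splits of week-1 trials, scaled by 1/√2 because a
half-week mean has twice the sampling variance of a full-week mean — without
the correction the baseline overstates within-week variability under
stationary noise (the supplementary statistic is not fully specified; this
is our calibration and the half-split scheme is a documented stand-in).

## Spiking episodes

Inferred spikes (deconvolved traces binarized at 3 SD above zero; for counts
the tensor is used directly) are summed across trials into a PSTH and
smoothed with a Gaussian kernel (bandwidth 0.2 s, reflective boundary,
mass-preserving).  A Bayesian adaptive regression-spline smoother would also
serve; only the smoothing role matters for peak finding, so a one-parameter
kernel is used and the bandwidth is exposed for sensitivity checks.
Episodes are peaks with topographic prominence > 3 (in smoothed summed-count
units — the prominence unit is a documented choice) whose window is the full
width at half maximum, half-max measured from the peak's prominence base
(scipy's convention); the window keeps the bins whose centers lie inside the
half-max interval.  Overlapping windows merge into one episode from the
first start to the last end.  Episode gain is the mean inferred rate in the
window per trial (Hz), aggregated to week means.

Gain-stability statistics: across-week CC correlates episode-rate vectors
between week pairs; within-week CC correlates even- vs odd-trial rate
vectors inside each week.  Episode-pair similarity is, per neuron with ≥ 2
episodes, the mean Pearson CC between week-gain trajectories of episode
pairs.  Its two references are (i) a Poisson control — one episode of the
neuron is selected at random and its weekly rates serve as the shared
trajectory from which all of that neuron's episodes draw independent
per-trial Poisson counts (count = rate × episode duration; per-trial,
per-episode draws are a documented reading since the original procedure
leaves bin- vs episode-level sampling open); and (ii) a week-shuffle chance
control that permutes each episode's week order independently.  Gaussian
summaries (mean, SD) are maximum-likelihood fits.

## Masked nonnegative tensor component analysis

χ is approximated by R rank-one nonnegative components,
`x̂_ntk = Σ_r W_nr B_tr A_kr`, minimizing ‖M ⋆ (χ − χ̂)‖²_F with binary mask
M zero exactly where dF/F is negative (noise below baseline carries no rate
information).  The optimizer is masked multiplicative updates with a 1e-9
denominator offset: factors stay nonnegative and the objective is
non-increasing.  Initialization is |Normal(0, 1)| scaled to the data, three
restarts by default (best objective kept; large pipeline fits use one
restart and float32 arithmetic — the update is identical, only BLAS
precision changes, and returned factors are float64).  Iteration stops at a
relative objective decrease below `tol` or at `max_iter` (returned flagged
as unconverged).

Rank selection masks out 50% of entries uniformly at random (resampling if a
fiber would lose all observations), fits on the rest, and reports the
normalized error ‖M⋆(χ−χ̂)‖²/‖M⋆χ‖² on held-out entries.  Ranks are fit in
ascending order with warm starts (previous factors padded by a small random
component): since the updates never increase the objective, training error
is non-increasing in rank by construction; a minimum of 60 iterations after
a warm start lets new components grow out of their small initialization.

Fit-to-fit **model similarity** matches components one-to-one by Hungarian
assignment on the product over modes of cosine similarities between
scale-normalized factor columns and averages the matched scores (the
original factor-matching score is not restated in our sources; this
permutation- and scale-invariant product-of-cosines version is the
documented substitute).  Trial factors are clustered by K-means (rows =
components, features = trial-factor values; 10 restarts); components are
ordered by cluster (clusters sorted by mean temporal time-to-peak) and
within cluster by time-to-peak.  Trial-factor stability averages Pearson
correlations of R-length factor vectors over within-week vs across-week
trial pairs.

The **factor-shuffle control** independently permutes each component's
neuron factor and circularly shifts its temporal and trial factors —
destroying coordination between components while preserving each factor's
marginal statistics and per-component reconstruction energy.

## Ring manifold (Isomap)

Each (time, trial) column of the (reconstructed) tensor is one point in
N-dimensional state space; time/trial labels are ignored during embedding
and recalled afterwards.  The embedding is classical Isomap: a k-nearest-
neighbor graph (k = 20; Euclidean edges; directed k-NN symmetrized by union;
distance ties broken toward the lower point index), all-pairs shortest-path
geodesics (repeated Dijkstra on the sparse graph; Floyd–Warshall retained as
a test oracle), and classical MDS of the geodesic matrix (double-center
−½ J D² J, top-d eigenpairs, coordinates = eigenvectors × √eigenvalue,
eigen-sign fixed so each dimension's first nonzero loading is positive).
Graphs that disconnect are restricted to the largest component with excluded
points flagged.  Embeddings of circular-shuffle controls use k = 100: the
shuffled activity has much higher intrinsic dimension and needs the larger
neighborhood for a connected, stable embedding.

At full scale the point cloud (63,000 points for 180 trials) would need a
63,000² geodesic matrix; the pipeline therefore embeds a week-balanced
random subset of whole trials, by default 18 trials = 6,300 points (about
288 MB of geodesics, a few minutes end to end on one core).  Subsampling
whole trials rather than scattered points keeps complete per-trial
trajectories for the stability analysis.  Trajectory stability is, per
embedding dimension, the mean Pearson correlation between the per-trial
time-courses over all trial pairs (computed on common time bins).

## Unsupervised time decoding (ring curve)

A closed piecewise-linear curve with 10 knots is fit to the embedded
training points (80/20 random split, all weeks pooled):

1. **Knots**: K-means centroids (10 restarts).
2. **Ring order**: each knot pair is scored by the data density *along* the
   connecting segment — the count of training points within a ball of radius
   ¼ × median nearest-knot spacing around each of five interior sample
   points, taking the minimum over samples, divided by segment length.  The
   minimum sends shortcut chords through empty interior to zero ("density in
   between" is not given a formula in our sources; this is our
   construction).  The ring is the greedy maximum-score Hamiltonian cycle.
   A second candidate orders knots by angle around their centroid; both
   candidates are optimized and the one with the lower final objective is
   kept — on uneven rings the greedy cycle occasionally shortcuts, and the
   objective itself is the unsupervised arbiter.  Degenerate inputs (no
   data near any segment) fall back to angular ordering with a warning.
3. **Optimization**: coordinate descent on the printed objective
   (Σ_i distance of point i to the curve) × (total curve length) — the
   product form exactly as stated, not a sum with a length penalty.
   Axis-aligned ± moves per knot, accepted only if the objective decreases
   (hence monotone); the step halves when a pass finds no improvement;
   stops at 50 passes, relative change < 1e-6, or step underflow.
4. **Coordinates**: each point takes the arc-length coordinate y ∈ [0, 1) of
   its nearest point on the curve (ties to the lower segment index);
   perpendicular offset is signed by the 2-D cross product (unsigned in
   higher dimensions).
5. **Alignment** (the only supervised step): a circular shift (grid of 350 =
   one per time bin; finer shifts are unresolvable at the sampling rate) ×
   flip minimizing the mean squared *circular* difference between the
   transformed coordinates and movie time rescaled to the unit circle.
   Circular (not linear) squared error is used throughout.  Alignment is
   estimated on the training set and applied unchanged to the test set.
6. Decoded time α = aligned coordinate × period (35 s); error =
   min(|t − α|, period − |t − α|) ∈ [0, 17.5 s]; uniform chance mean is
   period/4 = 8.75 s.

For shuffled-data comparisons, whose manifolds need not be rings, the
knots are instead the trial-averaged embedded points in ten movie-time
deciles, connected in time order, and the ring is kept fixed: on a collapsed
manifold the product objective pulls the curve along the per-time amplitude
filaments (the optimizer is doing its job on a question it was not designed
for), which would invert the very parallel/perpendicular comparison the
control probes.

Decoding works in 2–5 embedding dimensions; the default analyses use d = 2.

## Variance geometry

For each movie-time bin, the bin's points define a centroid; the curve point
nearest that centroid provides the local unit tangent (the coding
direction).  Parallel variance is the unbiased variance of tangent
projections of (point − centroid); perpendicular variance is the total
residual variance after removing the tangent component (in 2-D, the normal
direction; in d > 2 the sum over the d−1 normal directions).  The tangent is
taken once per bin at the centroid's foot, not per point (a per-point
variant would differ only when the bin's points straddle a knot).  Tangent
projections are used rather than arc-length differences; the two agree when
the perpendicular spread is small.  Three groupings: all trials pooled
(evaluated on held-out test points), per-week trial-averaged points
(week-to-week drift), and single trials within each week pooled over weeks.
The week-grouped modes use all embedded points so every (bin, week) cell
has enough points; the factor-shuffle control does the same (its ring is
pinned, so no leakage is possible), which matters because its
parallel-vs-perpendicular contrast is fragile: the collapsed control
manifold has per-time amplitude filaments nearly parallel to the time path,
the margin between the two medians is small, its sign can flip with the
generator seed, and the per-point tangent variant reverses it outright.  On
chronically imaged cortical data this control reportedly separates cleanly;
on this generator it does not, and the radius comparison (unambiguous,
p near 0) is the robust half of the control here.  The primary comparisons
on the original manifold are insensitive to all of these choices
(p between 1e-7 and 1e-25 across the three modes).  Comparisons use one-sided Wilcoxon signed-rank tests
across time bins.  Manifold shape is summarized by the distance of every
point to the coordinate-wise mean of the cloud; original vs factor-shuffle
radii are compared by a one-sided Mann–Whitney U test.

## Synthetic data generator

The generator is the ground truth against which every stage is validated.
Per neuron it plants 1–4 non-overlapping episodes (uniform count) inside the
movie window: durations are log-normal with median 0.6 s (σ = 0.4 in log
space, minimum 2 bins); starts are stratified over the movie with a random
per-neuron phase so pooled coverage tiles the movie evenly — the regime in
which every moment is represented by some group of neurons — with a minimum
gap of 5 bins so neighboring episodes stay separable.  Each episode draws a
base rate uniform in 5–15 Hz and one of 5 gain clusters whose week-gain
templates include stable (all ones), fading (geometric decay to 0.1),
emerging, transient, and slow-wobble profiles; per-trial gains are
log-normal with unit mean and CV 0.3.  Spike counts are Poisson(rate × dt)
inside episodes (background rate 0 by default so the planted structure is
exact).  dF/F is the spike train convolved with a causal
difference-of-exponentials kernel (rise 0.1 s, decay 1.5 s, peak-normalized)
plus Gaussian noise (SD 0.05).

Two convolution modes exist.  The default treats each weekly session as one
continuous looped recording: the session's trials are concatenated and
convolved circularly, so late-movie calcium tails decay through the next
trial's gray period — this looped structure is what closes the population
trajectory into a ring; with per-trial truncation (the alternative mode,
used in the unit tests of the impulse response) the trajectory is an open
path and no ring exists to decode from.  Nothing crosses week boundaries.

What the generator does **not** emulate: movie-frame-locked receptive-field
structure, gray-period onset/offset responses, eye movements or behavioral
state, imaging artifacts, correlated noise across neurons, or deconvolution
errors (the spike tensor is exact).  Consequently, passing tests show the
pipeline recovers planted episodic/gain/ring structure under Poisson and
Gaussian noise — not that real cortical data satisfies the generative
assumptions.

## Evaluation studies and problem sizes

The reference studies (`ringdrift.benchmarks`, re-run from scratch by
`scripts/acceptance.py`) use fixed sizes chosen to complete on one
workstation core: TCA recovery on 60×200×90 rank-3 tensors (10% noise, 20%
masking, 20 independent draws); episode recall on the default 100-neuron
series; geodesic/MDS oracles at 200 points; ring recovery on a 5,000-point
noisy circle isometrically embedded in 50 dimensions; the default study with
rank-24 TCA (150 iterations, float32) and 6,300 embedded points; the
across-week generalization study on stable-gain data (single all-ones
cluster) embedding 6 week-1 trials plus 3 per later week, training on
week-1 odd trials; calibrations at 10,000 draws.  The pipeline default rank
is 40 with cross-validation available to justify the choice; the studies use
rank 24, which is past the point where test error plateaus on the synthetic
data while keeping a full evaluation under a quarter hour.

## Known limitations

- Multiplicative updates converge slowly near optima; monotonicity holds to
  float32 rounding, and exact factor recovery is only checked on planted
  low-rank problems.
- Classical MDS on geodesics of an uneven ring concentrates variance
  unevenly across the two leading dimensions; the decoder tolerates this but
  the eigenvalue ratio is reported as a ring-quality diagnostic.
- The greedy Hamiltonian-cycle construction is heuristic; the angular
  candidate and objective-based selection make the failure mode (shortcut
  chords) rare but not impossible for strongly non-convex rings.
- Decoding of the gray-screen period relies entirely on decaying calcium
  tails and is intrinsically less precise than movie-period decoding.
- With 3 trials per week in the embedded subset, within-week variance per
  (bin, week) cell rests on few points; the Wilcoxon aggregation across 350
  bins is what carries the inference.
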
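# Methods

`diffpoint` infers, for every frame of a 2-D single-particle trajectory,
the generalised diffusion coefficient `K` (pixels²/frameᵅ), the anomalous
exponent `α`, and a discrete motion state `s ∈ {0 immobile, 1 confined,
2 free, 3 directed}`, and then locates the frames at which any of them
change.  This note records the model, the choices made where the design
was genuinely open, and what the desk-scale tests do and do not show.

## Trajectory model

Motion is piecewise fractional Brownian motion (fBM).  The 2-D ensemble
mean-square displacement obeys `MSD(t) = 4 K t^α`; per axis
`MSD_x(t) = 2 K t^α`.  Increments are fractional Gaussian noise with
Hurst exponent `H = α/2` and autocovariance

    γ(k) = σ²/2 (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}).

Sampling uses Davies–Harte circulant embedding (exact covariance,
O(n log n)) with a Cholesky fallback when the embedding is not positive
semi-definite.  Two conventions matter at the edges: `|0|^{2H}` is taken
as 0 for all `H ≥ 0` so that `α → 0` reaches the lag-1 correlation −1/2
continuously, and `α = 2` is special-cased to a single Gaussian draw
repeated (ballistic motion; the covariance matrix is singular there).

At every labelled changepoint the fGN memory is reset: each segment's
increments are drawn independently and appended at the current position.
This matches piecewise-process semantics; the alternative (one long
correlated draw re-scaled per segment) would correlate motion across
changepoints and make segment boundaries partially unidentifiable.

## The five simulated scenarios

Parameters are sampled per trajectory from the standard ranges:
`α ∈ [0, 2]`, `K ∈ [10⁻¹², 10⁶]`, trajectory length 20–200 frames,
field of view (FOV) 128×128 px with uniform initial positions.

* **Single state (SSM)** — one `(α, K)` pair, no changepoints; the
  sensitivity control for false-positive changepoints.
* **Multi state (MSM)** — a Markov chain over 2–3 free-diffusion states.
  The sampling law for the transition matrix is an open choice; uniform
  row-stochastic matrices would switch every ~2 frames and be destroyed
  by the 3-frame minimum dwell, so rows use a stay probability
  U[0.9, 0.99] with the remainder split randomly (mean dwell 10–100
  frames).  An explicit matrix can be supplied.
* **Quenched traps (QTM)** — 100–300 point traps of radius 0.5–2 px,
  uniformly placed (overlap allowed).  Binding on contact is certain;
  while trapped the position is frozen and `α = K = s = 0`; each trapped
  frame escapes with the unbinding probability (≤ 0.1, geometric dwell).
  A released particle must first leave its trap's disc before it can
  rebind, otherwise release would be unobservable.
* **Transient confinement (TCM)** — 30–50 non-overlapping compartments
  of radius 5–10 px (rejection-sampled placement; when geometry cannot
  fit the requested count the placed subset is used).  Inside, the
  confined `(α, K)` applies with `s = 1` and confined α is sampled below
  1.9 (a confined segment is never "directed").  A step crossing the
  wall outward passes with the transition probability (≤ 0.3), otherwise
  it is reflected radially back inside (reflections that would overshoot
  the centre are clamped to the disc).  Entry from outside is free, in
  line with the certain-binding convention of the other scenarios.
* **Dimerisation (DIM)** — two particles; when their separation falls
  within the interaction radius (0.5–5 px) they bind with certainty and
  share identical displacements drawn with the dimer `(α, K)`; each
  bound frame unbinds with probability ≤ 0.1.  After unbinding the pair
  must separate beyond the radius before rebinding.  Both particles are
  emitted as labelled trajectories.

`K` is sampled log-uniformly (uniform in `log₁₀(K+1)` over [0, ~6]):
the admissible range spans 18 decades and uniform sampling would never
produce biologically typical small diffusivities.  A trajectory is
truncated when it leaves the FOV and kept only if ≥ 20 frames remain;
failures retry with a new position and eventually fresh parameters.
This survival bias caps usable `K` near `log₁₀(K+1) ≈ 3`, which is also
why very large diffusivities are effectively absent from training data.

State labels follow the physical situation: `s = 0` iff trapped, `s = 1`
iff inside a compartment, otherwise `s = 3` when `α ≥ 1.9`, else 2.
Every label segment lasts ≥ 3 frames; shorter runs (possible when, e.g.,
a trap dwell lasts 2 frames) are merged into their predecessor, a short
leading run takes its successor's value.  Merging edits labels, not
coordinates, so a ≤ 2-frame physical event can survive in the positions
while being absorbed in the labels — the same compromise the 3-frame
challenge constraint forces on any labelling.

The dataset recipe mirrors the full-scale protocol at a configurable
scale: equal counts per scenario; a repeat with `α` restricted to
[1.9, 2] (over-samples the rare directed state); and MSM/DIM/TCM
variants in which only one of `α` or `K` changes across changepoints.
Counts divide deterministically (floor + remainder to the first groups);
the 60:20:20 train/val/test split is a seeded permutation.

## Features

Ten per-frame series derived from the coordinates: z-normalised `x̂, ŷ`
(population σ; a constant series maps to zeros — an immobile particle),
displacement from origin `d`, z-normalised step length, the signed
turning angle `ϑ` (two-argument arctangent of cross/dot; zero when a
step has zero length), two straightness measures `str, str₂` computed on
the normalised coordinates (1 = perfectly directed, 0 = returned to
origin; defined as 0 at t = 0), and log absolute differences
`F(k) = log|Δk|` of `x̂, ŷ` and the normalised step (|Δ| clamped at
1e-12 — immobile frames give Δ = 0).  Difference-based rows are shorter
than T and right-padded with zeros; the off-by-one alignment this
creates is accepted as the convention.  Note `str`/`str₂` are invariant
under axis flips but not under rotations (per-axis normalisation does
not commute with rotation); the step-based features are rotation
invariant.

Training-time augmentations, each applied independently with
probability 0.3 per instance and in a fixed order for reproducibility:
Gaussian localisation noise (σ = 0.1 px), rotation by a uniform angle,
axis flips, truncation to a random window of ≥ 20 frames (labels are
sliced to match).  Features are recomputed on the augmented coordinates.

## Network

One sequence-to-sequence network per output variable.  Three
bidirectional-LSTM blocks; blocks 1–2 stack two layers (10% inter-layer
dropout), block 3 one layer; every block emits 128 features per frame
(64 per direction), applies a rectified linear unit, concatenates with
its own input (skip connection) and layer-normalises, growing the frame
width 10 → 138 → 266 → 394.  A linear head maps to 1 output (α, or K in
`log₁₀(K+1)` space) or to 4 log-probabilities via log-softmax (state).
With 64 hidden units per direction the regression network has exactly
513,991 trainable parameters; the hidden size and the
concatenate-then-normalise wiring are corroborated by that count.  The
ReLU is applied to the LSTM output before concatenation so the skip path
stays linear.

The implementation is NumPy with hand-derived reverse-mode gradients
(LSTM, layer norm, linear, log-softmax), verified against central finite
differences to ~1e-10.  The backward-direction LSTM consumes sequences
reversed within their true lengths, so zero padding stays at the tail in
both directions and batched inference equals single-trajectory inference
to machine precision; losses mask padded frames (leaving them in would
bias every output toward zero targets).

Losses: per-trajectory mean absolute error over true frames (α, and K in
log space — the ground truth is converted once at data loading), then a
batch mean; class-weighted negative log-likelihood for the state, with
inverse-frequency weights normalised to mean 1 (absent classes get
weight 0).  Trapped frames train as-is with targets α = 0, log-K = 0.
The `λ Σθ²` regulariser is implemented once, as Adam weight decay
λ = 2e-6 (adding it to the loss as well would double-regularise).

Training: Adam, initial learning rate 1e-3, batch 32, ≤ 30 epochs.
Validation loss is evaluated before training (epoch-0 baseline) and
after every epoch; the best-validation weights are kept.  Five epochs
without improvement divide the learning rate by ten (plateau schedule).
A non-finite validation loss aborts with a diagnostic.

## Post-processing and changepoints

Predicted `α(t)` and `log₁₀(K+1)(t)` are smoothed by (1) replacing
greedy left-to-right maximal runs whose range is ≤ 0.01 with their mean
and (2) a centred window-3 median filter whose endpoints use shrunken
2-point windows (padding would invent boundary values and spurious edge
changepoints).  Predicted states obey a 3-frame minimum dwell: shorter
segments take the preceding state's value (a short leading segment the
following state's), iterated to a fixed point.

Changepoints in the smoothed continuous series come from penalized L2
segmentation (PELT): minimise the within-segment squared deviation plus
0.3 per changepoint, segments ≥ 3 frames, on the min-max-normalised
series (one penalty then serves both α and K; an exactly constant series
maps to zeros and yields no changepoints).  The PELT pruning rule is
delayed by the minimum segment size: a pruned candidate's replacement
only becomes admissible `min_size` frames later, and removing it earlier
can (and in testing did) break exactness.  With the delay the pruned
optimum equals exhaustive dynamic programming on every tested series.
State changepoints are simply the label changes.  Per-variable sets are
merged by keeping the K-derived points verbatim (empirically the
best-behaved series) and adding points from the other sets only when no
retained point lies within 5 frames; the default subset is α + K —
state-only changes are rare, and a nearest-retained-point suppression
resolves the (unspecified) tie-break.

One practical caveat the sensitivity analysis exposes: min-max
normalisation stretches *any* non-constant series to full range, so a
weakly-trained model whose output fluctuates by more than the 0.01
plateau band produces occasional false-positive changepoints on
homogeneous trajectories.  A well-trained model emits near-constant
output there, the plateau merge collapses it, and no changepoints
survive — which is the expected Jaccard-0 behaviour when nothing
physically changes.

## Metrics

MAE (α) and MALE (K, in log space) are two-level means: per-trajectory
over frames, then over trajectories, so lengths do not re-weight.  The
state report is a row-normalised confusion matrix over all frames with
average class accuracy the mean of its diagonal; rows for classes absent
from the ground truth are dropped.  Predicted and true changepoints are
paired by minimum-total-squared-distance Hungarian assignment; pairs
strictly closer than 5 frames are true positives, everything else
FN/FP.  Jaccard = TP/(TP+FN+FP), defined as 1 when both sets are empty.
RMSE is computed over paired points only and its denominator is the
paired count (dividing by all changepoints would mix in the miss rate
already measured by Jaccard); trajectories with no pairs are excluded
from RMSE averages.  These conventions are recorded in the report
metadata.

## Desk-scale conditions

The reference protocol trains on 3.12 M of 5.2 M simulated trajectories
for up to 30 epochs on GPUs.  This package's training loop is CPU NumPy,
so the shipped test suite and `scripts/acceptance.py` use desk-scale
runs: 2 000 trajectories of 20–100 frames, 6–8 epochs per variable.
At this scale the α-model recovers the anomalous exponent with held-out
Pearson r > 0.8 (per-trajectory mean α̂ vs truth) and clearly beats the
constant-mean baseline, and error decreases with trajectory length; but
absolute errors sit well above the full-scale figures, prediction series
are noisier, and changepoint Jaccard values are correspondingly low.
Passing desk-scale tests therefore demonstrates the correctness of the
machinery (simulation physics, gradients, segmentation optimality,
metric definitions) and the qualitative behaviours, not full-scale
accuracy.  The synthetic generator also idealises real data: no
localisation error outside the optional augmentation, no fluorophore
blinking or gaps, no motion blur, circular compartments, and exact
frame-synchronous dynamics.

## Numerical choices

* Population (not sample) standard deviation in z-normalisation;
  σ = 0 → zeros.
* `log|Δ|` guard at 1e-12; layer-norm ε = 1e-5; Adam (β₁, β₂, ε) =
  (0.9, 0.999, 1e-8).
* Changepoint index convention: a changepoint at frame c splits [0, c)
  from [c, T), 0-based, used uniformly by simulation, detection and
  scoring.
* Reflection overshoot at compartment walls clamps to the disc radius.
* All randomness flows through `numpy.random.Generator`; one seed
  reproduces datasets byte-for-byte and training runs exactly.
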
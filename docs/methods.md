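# Methods

## The model

Sleep is modelled as a discrete-time Markov process over posture states,
one label per fixed-length epoch (default 30 s).  Four in-bed postures are
distinguished — supine, prone, left lateral recumbent (LLR), right lateral
recumbent (RLR) — plus an optional OFFBED state used by the synthetic
generator.  Two anatomical assumptions constrain the chain: prone is
entered only from a lateral posture, and a lateral posture only from
supine.  These are *structural zeros*: the corresponding transition
probabilities are exactly zero regardless of data or smoothing.  Prone's
exits are not constrained by those assumptions; we allow prone → supine
(and self-persistence) only, which keeps the transition graph strongly
connected while respecting the rule that laterals are entered from supine.
OFFBED connects to and from supine only — one gets out of and back into
bed through lying on the back.

Prediction is sequential Bayes.  The fitted transition table supplies a
prior over the next posture given the last one (order 1) or two (order 2,
the default) postures; an observation likelihood — from the frame
classifier or from a physiological reading — multiplies the prior and the
product is renormalised.  A flat likelihood returns the transition row
itself.  Ties in the argmax are broken by the fixed label order
SUPINE < PRONE < LLR < RLR (< OFFBED) for reproducibility.  Histories
never seen during fitting fall back to a uniform distribution over allowed
targets so prediction is always defined; smoothing pseudo-counts
(`alpha`, default 1) are added to *allowed* targets only.

## Calibrated synthetic generator

The generator's defaults are the study conditions: stationary occupancies
54.1% lateral (split equally between LLR and RLR), 37.5% prone, 7.3%
supine, and 1.6 posture shifts per hour.  Those occupancies sum to 98.9%;
rather than renormalising, the 1.1% remainder is carried by the explicit
OFFBED state, so the quoted percentages are recovered exactly in
expectation.

Constructing a transition matrix with a prescribed stationary distribution
under this constraint mask is not a standard reversible-chain exercise:
the mask is irreversible (LLR → PRONE is allowed while PRONE → LLR is
forbidden), so any detailed-balance construction — Metropolis–Hastings
included — carries zero flow into prone.  We therefore build a
non-reversible chain from a jump chain plus holding rates:

1. the jump (embedded) chain `J` proposes uniformly over allowed non-self
   neighbours; its stationary distribution `ν` is computed exactly;
2. the target shift rate fixes the per-epoch shift probability
   `q = shifts_per_hour / epochs_per_hour`;
3. each state's exit rate is `r_i = q · ν_i / π_i` and the matrix is
   `P = diag(1−r) + diag(r)·J`.

Because the flow out of state *i* along edge *i→j* is `q·ν_i·J_ij` and `ν`
is stationary for `J`, flows balance at every state, so `π P = π` holds
*exactly* (verified internally, residual < 1e−9) and the expected shift
rate is exactly the target — no Monte-Carlo rescaling step is needed.
Infeasible requests (a disconnected mask, zero-mass states, or a shift
rate requiring an exit rate above 1) raise a calibration error.

Per-posture images are built from invented geometric templates — supine:
two vertically elongated bright-core lobes; prone: the same footprints
with a radially inverted profile (bright rims); LLR/RLR: a single
off-centre lobe, exact horizontal mirrors of each other; OFFBED: an empty
frame — plus additive Gaussian pixel noise (default sd 0.05), clipped to
[0, 1].  Heartbeat traces are Gaussian bpm draws with invented per-posture
means (60–75 bpm, sd 5), truncated to [30, 200].  Templates and bpm means
are generator parameters, never cohort claims, and every dataset manifest
records them as such.  What the generator does *not* emulate: real body
shapes and contact mechanics, respiration and heart-rate variability,
inter-subject variation, sensor drift and artefacts.  Passing tests
demonstrate that the pipeline's logic is correct under its stated
assumptions, not that these accuracy levels transfer to human data.

## Preprocessing conventions

* Standardisation min–max scales to [0, 1] (a constant image maps to
  zeros) and resamples by exact area overlap, which is deterministic and
  exact for any resize ratio.
* The intensity threshold is the mean over occupied (nonzero) points:
  total intensity divided by the count of nonzero pixels; an all-void
  image has no defined threshold and raises.  The filter's literal form
  keeps values *at or below* the threshold (`keep_low`); because that
  direction is the opposite of usual denoising, a `keep_high` mode is
  exposed as a flag.  Both are idempotent.  The default fixed threshold on
  standardised images is 0.5725.
* Gaussian smoothing uses a 5×5 sampled kernel, σ = 1 px by default,
  renormalised to sum to one (the continuous normaliser does not sum to 1
  on a truncated grid), convolved with reflect border handling so
  constants are fixed points and edge means are preserved.
* Rotation-PCA alignment treats pixels above the threshold as an
  intensity-weighted point cloud, takes the leading eigenvector of the
  2×2 coordinate covariance, and rotates (bilinear, zero fill) so that
  axis is vertical.  Angles are counter-clockwise positive in (−90°, 90°];
  the eigenvector's sign is fixed by a non-negative vertical component; a
  relative eigenvalue gap below 1e−9 is reported as degenerate (angle 0)
  rather than amplifying noise.

## Signals

Slow-time smoothing averages over the window j−R…j+R (default R = 2, a
five-sample window mirroring the 5×5 spatial unit), truncated and
renormalised at the boundaries — phantom zeros would bias edge means.  All
entries are updated simultaneously from the original matrix.  The
covariance uses the sample divisor M−1, which makes the eigenvalue /
singular-value identity λ = s²/(M−1) exact; eigenvector signs force the
largest-magnitude component non-negative.

## Features and classification

HOG uses central-difference gradients, unsigned orientations hard-binned
into 9 bins over [0°, 180°), 8×8-pixel cells, 2×2-cell blocks at stride
one cell, and per-block L2 normalisation with ε = 1e−6 (a constant image
yields an all-zero descriptor).  Pressure points are per-cell intensity
sums; a blank frame falls back to uniform weights with a warning, and a
zero first cell (common: image corners are background) sets the scale
factor to 0 rather than failing a batch.

The frame classifier is a nearest-centroid soft-max over the concatenated
(HOG, weights) descriptor, L2-normalised: `p(label) ∝ exp(−d²/T)`.  A
centroid classifier was chosen deliberately: it is deterministic, needs
no training hyper-parameters, and keeps the pipeline's testable
contribution — the Bayesian fusion — separate from classifier capacity;
it sits behind a small interface so a learned model can be plugged in.
The default temperature T = 0.05 makes the observation decisive against
the transition prior whenever the frame is unambiguous: the smallest
inter-class descriptor distance on noise-free frames (supine vs prone,
d² ≈ 0.41) gives observation odds exp(d²/T) ≈ 3.8×10³, comfortably above
the stay/move odds any fitted prior reaches at the problem sizes used
here, while noisy, ambiguous frames still let the prior arbitrate.

## Problem sizes and tolerances

The occupancy and shift-rate recovery runs use one million simulated
epochs (≈ 347 days of sleep; about two seconds of compute), compared to
targets within three Monte-Carlo standard errors estimated by batch
means (100 batches) — appropriate for a correlated chain whose episodes
last ~100–200 epochs.  Transition-probability recovery uses 2×10⁵ epochs
(±0.02 absolute on every allowed entry; structural zeros exact).  The
fusion check uses 5×10⁴ epochs: fusing the heartbeat likelihood with the
true transition prior cannot reduce the expected log-probability of the
truth (Gibbs' inequality), and the paired Monte-Carlo difference is
required to be non-negative within noise.  Chance-level behaviour under
label shuffling is asserted on the mean over 20 independent permutations,
because predictions from one shuffled classifier are correlated through
the shared centroids and single-shuffle accuracy is legitimately lumpy.
End-to-end runs use a few hundred epochs, enough for every posture to
appear while keeping the suite fast.

## Known limitations

* The transition model is first/second-order Markov in discrete time;
  real posture bout durations are not geometric.
* The constraint mask encodes idealised anatomy; observed violations in
  training data are skipped with a warning rather than modelled.
* The classifier has no notion of partial occlusion, limb articulation,
  or inter-subject shape variation — it recognises the generator's
  template geometry.
* `keep_low` threshold filtering (the literal rule) removes the
  *strongest* pressure points; whether that direction is intended is
  ambiguous at the source, which is why the mode is a flag.
* Heartbeat-based likelihoods assume per-posture Gaussian bpm with known
  means; on real data these would need per-subject estimation.
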
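# Methods

## Task model

Stimuli are drawn from a four-component Gaussian mixture in ℝᵈ.  Two
orthonormal axes μ₀, μ₁ define the geometry; a trial with label
y ∈ {0, 1} and component sign s ∈ {±1} is

    x = s · μ_y + σ · g,    g ~ 𝒩(0, 𝕀_d),

with y a fair coin and s a fair coin unless a curriculum restricts the
subset.  Labels follow the XOR rule — the two components of each class sit
diagonally opposite — so no linear readout solves the task.  Noise is
isotropic in all d coordinates even though only the 2-d span of (μ₀, μ₁)
carries signal; projections onto that span therefore look like four
clusters of width σ.  The Bayes rule reduces to "label 1 iff
|x·μ₁| > |x·μ₀|" (both class-conditional densities share the covariance,
so the likelihood ratio compares cosh(x·μ_y/σ²) terms); `bayes_accuracy`
estimates its accuracy by Monte Carlo and serves as an upper oracle for
any learner.

## Network and training

The learner is a two-layer ReLU network with K = 4 hidden units and *no
bias terms*: f(x) = Σ_k w2_k · relu(W1_k·x).  K = 4 is the smallest width
that can represent the XOR solution (one unit per mixture component); the
hand construction `xor_network` (units along ±μ₀, ±μ₁, readout
w2 = (1, 1, −1, −1)) computes |x·μ₁| − |x·μ₀|, i.e. exactly the Bayes
rule, and is used as a test oracle.  Without biases a stimulus that closes
every gate produces a logit of exactly 0; that outcome is a third response
("abstain") and scores as an error, which pushes the chance level of
dead or partially dead networks below 50%.  The abstention test is exact
floating-point equality with zero by design: live networks produce tiny
but nonzero logits, so any tolerance would misclassify them.

Training is strictly online SGD on binary cross-entropy: one fresh
stimulus per step, both layers updated (a config flag freezes the readout
for sensitivity checks), with the first-layer gradient using the
pre-update readout.  Time is measured in *time units* — steps divided by
d — and the per-step learning rate is η/d with η = 10.  This pairing is
the scaling under which online SGD has a well-defined high-dimensional
limit: per time unit the summed learning rate is η, alignment drift is
O(η), and the per-unit SGD heating of the weight norms is O(η²σ²),
independent of d.  A raw per-step rate of 10 diverges numerically
(verified), so the η/d convention is the only consistent reading of the
protocol.  The label convention is fixed: label 1 ⇔ positive logit.

Defaults: d = 100 (a config parameter everywhere; the protocol above does
not pin it), init std 0.05 on every weight entry, 10 time units of
training, test on fresh hard trials (σ = 0.65, both subsets,
n_test = 10,000 per network, binomial SE ≈ 0.5%).

## Curricula

All four schedules share the difficulty range σ ∈ [0.1, 0.65].  Ascending
ramps σ linearly over the T steps; hard pins σ = 0.65; random applies a
seeded permutation to the ascending multiset; bad uses the random order
and additionally crossfades feature-subset exposure: the probability of
drawing from the "+" subset {+μ₀, +μ₁} falls linearly from 1 at the first
step to 0 at the last.  The subsets pair one component per class — the
only grouping that keeps both labels present within a block and mirrors
the behavioral design of holding one (diagonal) feature dimension
constant.  The crossfade is stochastic per step (a Bernoulli draw at the
scheduled probability), matching a probability-of-exposure reading; a
`crossfade="blocked"` flag provides the deterministic half-split variant.
Within a population run the permutation is drawn once and shared by all
networks, so curriculum order is a population-level condition rather than
a per-network random effect.

## Populations, seeding, evaluation

A population run trains `n_networks` independent networks that share the
task geometry and schedule but have private init and stimulus streams.
Every network's stream is keyed by (master_seed, seed_id) with a fixed
documented draw order, so results are bit-reproducible and invariant to
chunked execution.  Accuracy is recorded at the end of every time unit on
a fresh batch (n_eval = 1,000) drawn from *that unit's* schedule
distribution — the σ and subset probability of the current step — because
training difficulty differs between curricula while the test phase does
not.  Random/bad trajectories therefore inherit the permutation's local
difficulty at each evaluation point, which makes their "final training
accuracy" a draw-dependent quantity; the hard-test evaluation is the
curriculum-independent comparison.  Long-term runs continue SGD on hard
trials (σ = 0.65, both subsets) to cumulative checkpoints and re-test.

## Finite-d simulation versus the mean-field regime

The headline population statistics (curriculum orderings, Cohen's d
values, achiever proportions) describe the *infinite-dimensional* limit
of these dynamics, where outcomes are a deterministic function of the
initialization.  Direct simulation at desk-scale d adds two finite-size
effects with opposite consequences: (i) per-unit diffusion of the
signal alignments of order η σ w2 /√d, which erodes solutions learned in
the easy phase once σ is large — this selectively hurts the ascending
curriculum, whose advantage rests on retaining early-phase alignment; and
(ii) gate statistics driven by the init norm |W1_k| = 0.05·√d, which
grows with d under entry-wise init and buries the signal at large d.
Consequently at d = 100 the simulated ordering places random above
ascending, while the ascending-above-hard/bad and random-above-hard
orderings and the random-curriculum achiever pattern reproduce.  Two
controls document the mechanism: averaging the gradient over a large
batch per step (removing SGD noise, keeping the schedule) restores the
ascending achiever fractions of the deterministic regime (~12% above
threshold in both final training and test), and with dimension-free init
(row norm 0.05) the ascending > random ordering emerges by d ≈ 1600 —
beyond a desk-scale 2,000-seed budget.  The package reports what the
simulation at its stated conditions actually produces; nothing is
calibrated to the limit values.  The same caveat applies to extended
hard training: at finite d all populations relax to a common SGD-heated
steady state (accuracy ≈ 0.46 at d = 50) instead of preserving a
persistent bad-curriculum deficit.

## Synthetic behavioral study

The RDK generator reproduces the behavioral design: per participant 100
training trials (motion coherence per curriculum: linear 1.00→0.40,
constant 0.40, or permutations thereof; the bad curriculum blocks feature
pairings through the same linear crossfade, holding one feature value
constant per subset) and 16 test trials at motion coherence 0.40 with all
four pairings × four color-coherence levels.  Color coherence is
counterbalanced over four evenly spaced levels in [0.66, 1.00] but never
curriculum-structured.  Response mapping and bad-subset identity are
counterbalanced across participants by id; render metadata (600 dots,
2 px radius, 1 px/frame) is carried for completeness but nothing is
rendered.

The synthetic responder is deliberately the same network model at d = 2:
the percept is (motion_sign·motion_coherence, color_sign·color_coherence)
plus 𝒩(0, ν²) perceptual noise, learned online through every training
trial and frozen during test.  Abstentions become fair guesses (humans
must answer) and with probability λ the intended response is inverted, so
λ = 0.5 makes every response a coin flip — the null responder for
false-positive checks.  Defaults ν = 0.1, λ = 0.02, per-trial rate 1.0,
init std 0.05 were chosen once to put mean test accuracies in the
human-plausible range (~0.62–0.77) with ascending highest and bad lowest.
In this responder family the expected ascending-vs-bad accuracy gap tops
out near 0.08–0.10: the 2-d learner partially relearns the second subset
during the crossfade, unlike larger-gap accounts of human blocking
deficits.  At that gap the fixed-effects contrast pipeline still detects
ascending-vs-bad at α = .05 with power > 0.9 at 50 participants per arm,
with a null false-positive rate at the nominal level.  What passing these
checks shows is that the *pipeline* is calibrated and sensitive; it does
not show that real human lapse/noise structure matches the generator
(real data have participant-level heterogeneity the fixed-effects model
ignores, and motivational/fatigue effects are absent).

## Statistics

Cohen's d uses the pooled-SD formula
s_p² = ((n_A−1)s_A² + (n_B−1)s_B²)/(n_A+n_B−2) and is reported as an
absolute value; a zero pooled SD yields d = 0 for equal means and ∞
otherwise.  Achiever splits use strict inequality ("exceeding 65%"), so
boundary values fall in the low group; with 16 test trials human accuracy
cannot tie the threshold and network ties have measure zero.  Training
trajectories are binned in 20-trial bins with a trailing partial bin
dropped.  Pairwise curriculum contrasts come from a cell-means binomial
logistic model fitted by IRLS in-repo (verified against closed-form 2×2
log-odds ratios and against an external GLM implementation in the test
suite); Wald z and two-sided p are reported per contrast, raw and
uncorrected.  The behavioral reference analysis used a random-intercept
hierarchical model; the fixed-effects fit targets the same pairwise
log-odds contrasts and agrees with the 2×2 closed forms exactly, but its
standard errors ignore between-participant overdispersion — acceptable
for the synthetic generator (whose trials are conditionally independent)
and for sign/significance patterns, not for publication-grade human
inference.  Perfect separation triggers a flagged ridge (1e-4) fallback
with finite estimates.

## Numerical choices and limitations

* Exact-zero logit defines abstention; no tolerance (see above).
* IRLS iterates Newton steps to a 1e-12 step-size tolerance, capped at
  200 iterations; the covariance is the inverse (penalized) Fisher
  information via pseudo-inverse.
* Population memory is bounded by chunking networks so pre-generated
  stimulus noise stays under ~200 MB; chunking cannot change results.
* Problem sizes in the test and acceptance suites (2,000 networks at
  d = 100 for distribution-level checks; 200 networks at d = 50 for
  long-term extensions; 100 replicate synthetic studies) are the
  package's desk-scale study conditions, chosen to keep full runs in the
  minutes range on a single CPU.
* Not implemented: the analytic mean-field evaluation itself, descending
  or mixed curricula, deep/wide architectures, momentum or minibatching,
  reaction-time modeling, stimulus rendering.
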
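# Methods

`ennflow` builds and evaluates *empirically-estimated neural networks*
(ENNs): layered network models whose units are measured cortical locations
("vertices") and whose inter-layer weights are estimated from resting-state
functional connectivity rather than trained.  The question the pipeline
answers is whether those rest-derived weights, applied to task activation
estimates, implement a context-dependent sensorimotor transformation —
producing the *correct* motor-response activation pattern for a given task
rule set and stimulus.  Everything runs against a synthetic cohort with
known ground truth, so each stage's claim is checked as a parameter-recovery
problem.

## The task

The C-PRO paradigm crosses 4 logic rules (both / not-both / either /
neither), 4 sensory rules (red, vertical, high-pitch, constant) and 4 motor
rules (left/right × middle/index) into 64 task contexts.  A trial presents
two consecutive audiovisual stimuli; the logic rule is applied to the
presence of the sensory rule's target feature in the two stimuli, and the
outcome maps to a button press: TRUE presses the motor rule's finger, FALSE
presses the other finger of the same hand ("either" is inclusive).  With 4
ordered feature pairs per dimension there are 256 stimulus sets and 16384
trial types; each response is correct in exactly 4096 of them.  A trial is
encoded on 28 binary input units (12 rules + 16 stimulus-pair conditions;
7 active per full trial).

**Counterbalanced pseudo-trials.**  Simulations use 15 stimulus samples per
context (960 pseudo-trials).  Random sampling alone leaves small per-response
imbalances, so the sampler enforces a per-(logic, sensory)-cell truth-count
quota matching the rules' truth rates (for n = 15: 4 TRUE for both/neither,
11 for not-both/either) and reuses the same per-cell stimulus multiset for
all four motor rules.  Consequences, by construction rather than on average:
each response is correct exactly 240 times, and the multiset of stimulus
conditions feeding each response is identical across responses — decodable
differences between predicted response patterns cannot come from input
imbalance.  A strict mode (even n, truth count n/2 per cell) additionally
equalizes per-response *context* mixtures; with rule-dependent truth rates
(1/4 vs 3/4) the default mode equalizes them only approximately, which is
exactly the trade-off the quota scheme navigates.

## The reference network

A feedforward network (28 → 1280 → 1280 → 4; ReLU hidden layers, sigmoid
output; Gaussian noise N(0, 1/1280) added to the first hidden layer's
activations) is trained on the task analog with Adam (lr 1e-4, default
moments), MSE loss against one-hot solver targets, mini-batches of 192
(each context three times with random stimuli), stopping when the trailing
1000-batch mean accuracy exceeds 99.5%.  Weights and biases initialize from
U(−√k, √k) with k = 1/(units in the next layer).  The implementation is
plain NumPy with a hand-rolled Adam; single-threaded BLAS trains the full
architecture in a few minutes.

Decisions the architecture description leaves open, resolved here: accuracy
is argmax over the four sigmoid outputs with ties to the lowest index;
probing runs with noise off (deterministic, replicable geometry); training
failure at max_batches (default 30000) raises instead of returning silently.

The network's only downstream role is representational: probing each input
unit alone yields a 28×28 Pearson RSM of second-hidden-layer responses, the
template for finding conjunction hubs in data.  A control RSM averages probe
RSMs over 10000 within-layer parameter shuffles — it preserves each layer's
weight distribution while destroying the trained structure, and its
off-diagonal variance is orders of magnitude smaller.

## The synthetic cohort

The generator emulates the data structures the real analysis consumes, at
desk scale, with known ground truth:

* **Teacher embedding.**  A compact teacher (28 → 64 → 4) from the same
  model family as the reference network (uniform fan-out init, hidden bias,
  sigmoid output, MSE/Adam) is trained on the composed-input task until it
  solves it exactly.  Its hidden bias is then folded into the input weights
  — exact because the context features always sum to 1 and exactly one
  stimulus unit is active — leaving a purely linear-weight network whose
  ReLU propagation activity-flow mapping can reproduce.  Rule and
  stimulus-pair conditions receive orthogonal spatial patterns over the
  input layers (stimulus patterns blocked by dimension, like segregated
  sensory cortices); each teacher hidden unit owns a disjoint set of
  conjunction-layer vertices with positive weights, so the vertex-space ReLU
  commutes exactly with the teacher's; response templates occupy disjoint
  left/right-hand motor blocks.  Zero-noise propagation therefore yields the
  solver-correct motor template for every trial type (verified exhaustively
  at build time; the constructor raises below 99%).  Internal template
  matching uses cosine similarity, which ranks responses exactly like the
  teacher's output units for equal-norm orthogonal templates at any motor
  size.
* **Rest.**  White-noise innovations (sd 1.0) at the context and stimulus
  layers propagate linearly through the ground-truth weights; conjunction
  vertices add *local* innovations (sd 0.7) that propagate onward to motor.
  The local term is a well-specifiedness requirement, not decoration:
  input-driven conjunction activity has rank ≤ 28 (the rank of the input
  weights), while the hidden→motor weights act on the full 64-dimensional
  unit space, so without local spontaneous activity those weights are
  structurally unidentifiable from rest at *any* noise level.  Independent
  observation noise (sd 0.2) covers every vertex; 10 distractor parcels of
  50 vertices carry AR(1) noise (φ = 0.8) uncorrelated with the layers.
  Default series length is 1065 TRs.
* **Betas.**  Condition activation estimates are group patterns plus
  per-subject Gaussian noise (sd 0.5).  Input layers carry their own
  condition patterns; conjunction vertices carry the propagated ReLU
  response to each single-condition probe (mirroring the network probe
  convention); motor vertices stay at baseline for the 28 encoding-phase
  conditions, because a single condition is not a completed trial and
  evokes no response-locked activity.  "Actual" motor patterns — the
  stand-in for response-period GLM estimates — are per-response averages of
  zero-noise propagation over a counterbalanced trial set, plus subject
  noise.

Defaults: V_context = V_stimulus = 200, V_hidden = 150, V_motor = 40 (two
20-vertex hand blocks), 17 parcels in total, 24 subjects for evaluation
cohorts.  All sizes and noise levels are configurable; every level is
deterministic given its seed.

What the generator does *not* emulate — hemodynamics, autocorrelated BOLD
noise, motion, spatial smoothness, surface geometry, behavioral variability
— bounds what passing tests show: they validate the *estimators and the
inference chain* (PCR FC recovers the true weights; RSM matching finds the
true conjunction parcel; activity flow + ReLU reproduces the transformation;
lesions abolish it), not robustness to fMRI artifacts.  Synthetic patterns
are also cleaner than GLM estimates from real data, so decoding accuracies
here sit near ceiling rather than at the modest levels typical of
cross-subject fMRI decoding.

## Connectivity estimation

Inter-layer weights come from principal-components regression on rest:
covariance PCA (per-vertex de-meaning, no variance normalization — amplitude
weighting is what activity flow propagates) reduces the source layer to
K = 500 components (silently capped at min(K, T−1, effective sources) and
logged; synthetic layers are smaller than 500); each target vertex is
regressed on the component time series with an intercept.  The loadings and
coefficients compose to vertex-space weights W = U·W_pc; source vertices
overlapping the target layer are excluded from the predictors and their
rows are zero.  Subject maps are averaged in composed vertex space —
subject-specific component bases are not alignable.  Intercepts are
estimated but never applied to activation patterns: activations are
baseline-relative, matching the ReLU's "below rest baseline" threshold
at exactly 0.

## Layer identification

Stimulus input vertices: parcels whose 4-way stimulus-pair decoding (per
dimension) survives BH-FDR across parcels (subject-level 12-fold
cross-validation, nearest-centroid Pearson classifier, one-sided binomial
test against chance; an optional logistic classifier mirrors the linear-
decoder robustness comparison).  Context input vertices: likewise from
12-way rule decoding.  Motor output vertices: per-hand two-sided paired t
contrasts (index − middle) across subjects with BH-FDR, giving signed
index-/middle-preferring masks; a bootstrap baseline decoder with
feature selection *inside* each training fold (p < 0.05 paired t) provides
the decodability ceiling — selecting on the full data is a leak, and a test
asserts the two paths differ.  Conjunction hubs: each parcel's 28-condition
RSM is compared with the reference network's via Spearman correlation of
Fisher-z-transformed upper triangles (diagonal excluded; z of r = 1
diverges); the hidden layer is the vertex union of the top-k parcels
(k ∈ {10, 20, 30, 40} supported; the synthetic default exercises k at the
scale of its 17-parcel brain).

## Simulation and evaluation

Per pseudo-trial, the context input is the mean of the three rule patterns
(additive compositionality) and the stimulus input is the relevant
dimension's pair-condition pattern (other dimensions contribute nothing).
Propagation is X_out = relu(X_ctx·W_c2h + X_stim·W_s2h)·W_h2m; outputs are
averaged by solver-correct response into four predicted prototypes per
subject.  Unique input combinations are forwarded once and prototype groups
are summed in a canonical sorted order, so responses with identical input
multisets get *bitwise identical* prototypes — the property behind the
exact-50% structural-chance results.

Evaluation trains a nearest-centroid (Pearson) decoder on predicted
prototypes of training subjects and tests on actual motor patterns of
held-out subjects (4 subject-folds, 3:1; per-hand 2-way restricted to the
hand's two classes and its output vertices, plus 4-way).  Training subjects
are bootstrap-resampled each of n_reps repetitions, each drawn subject
contributing one prototype per class — the reading of "resampled with
replacement" under which identical per-subject prototypes keep per-class
centroids exactly tied.  The permutation null shuffles the pooled
training-label vector (class counts preserved); p = (1 + #{null ≥ obs}) /
(1 + n_perm), averaged across repetitions, never exactly 0.

A caveat this implementation makes explicit: with perfectly separated test
patterns, per-hand 2-way fold outcomes under the null are all-or-none (every
test item in a fold shares the sign of the permuted centroid-difference's
alignment with the true class axis), so the null retains ≈ 1/16 probability
mass at 100% accuracy and the averaged per-hand p cannot fall below ≈ 0.066
in a 4-fold scheme — regardless of n_perm or SNR.  The 4-way null does not
have this floor.  Real data escape it because noisy items mix fold outcomes.
The acceptance suite asserts the per-hand threshold as specified and
documents this failure mode rather than retuning the generator around it.

Variants: `no_hidden` (direct input→motor FC), `random_hidden` (size-matched
random parcel unions, FC re-estimated per member), `no_relu`,
`context_lesion` (context→hidden weights zeroed), `shuffled_fc` (rows of
both input weight maps independently permuted — row permutation preserves
each target's weight distribution), `top_k`.  The two 1000-member families
report the full model's percentile within the family; desk-scale runs use
reduced family sizes and repetition counts (e.g., 50 members × 10 reps,
n_reps = 200) chosen to keep the whole suite around a minute on one core.

## Known limitations

- Rest dynamics are linear by design (the estimator's model class); the
  ReLU exists only in the task-evoked pathway.
- The generator's subject noise is i.i.d. Gaussian across vertices and
  subjects; no spatial covariance, sessions, or reliability structure.
- Group FC is a plain mean across subjects; no robust averaging.
- The bootstrap-by-subject and pooled-label-permutation choices are one
  consistent resolution of an underspecified scheme; alternatives (e.g.,
  per-pattern bootstrap) would break the exact-tie structural results.
- Runtime-driven scale choices (reduced family sizes, repetition counts,
  smoke-scale pipeline configs) are the package's defaults for desk use;
  all are configurable upward.
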
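# Methods

`arrowtime` implements an arrow-of-time self-supervised pretraining pipeline
for multivariate neural time courses — per-subject `T x N` matrices such as
ICA time courses from resting-state fMRI — together with a post-hoc
explainability layer built on integrated gradients. This note documents the
models, the parameter choices that matter, the numerics, and what the
synthetic experiments can and cannot show.

## The pretext task

Given a cohort of unlabeled subjects, every matrix `X` contributes two
training examples: `(X, y=0)` and `(reverse_time(X), y=1)`, where
`reverse_time` flips the row (time) order. A binary classifier trained with
cross-entropy on this balanced set must exploit temporal dependencies —
time-reversal preserves every static marginal, so the only usable signal is
the asymmetry of the dynamics. Two contrastive baselines are provided for
comparison:

* **OCP** (order-contrastive): pairs of non-overlapping segments from one
  trajectory; half are presented misordered as negatives. Negatives are
  always misordered.
* **PCL** (permutation-contrastive): positives are adjacent windows in
  order; negatives are random same-trajectory window pairs that may, by
  chance, be correctly ordered — a deliberately weaker order signal.

Pair examples are presented to the same architecture as the time-axis
concatenation `[segment_a ; segment_b]` (a `2L x N` sequence). The pair
presentation is this package's choice; a two-tower scorer would be an
alternative.

## Architecture

A unidirectional LSTM (optionally GRU) encoder maps the sequence to hidden
states `h_1..h_T`. A concatenation attention head scores each step as
`linear2(tanh(linear1([h_t ; h_T])))`, softmax-normalises the scores over
time, and forms the context vector as the weighted sum of hidden states; with
attention disabled the context is `h_T` itself. The decoder is two linear
layers with (inverted) dropout between them — no hidden nonlinearity — ending
in a sigmoid that emits the probability of the positive class ("reversed"
during pretraining, "patient" downstream; 0.5 threshold for accuracy-type
metrics). All weight matrices are drawn Xavier-normal
(`std = sqrt(2/(fan_in+fan_out))`) under the config seed; biases start at
zero.

Defaults (`lstm_hidden=64`, one layer, `attention_hidden=64`,
`decoder_hidden=32`, `dropout_rate=0.3`) keep the model trainable on a
single CPU at the problem sizes used here. The forward and backward passes
are written directly in NumPy (float64); the backward pass is verified
against central finite differences for every architecture variant in the
test suite, which is what the integrated-gradients implementation leans on.

## Training

Adam (lr `7e-4`, batch 32) with a reduce-on-plateau schedule (factor 0.5
after 10 stagnant epochs, floor 1e-6) and early stopping (patience 20
epochs) on the loss of a stratified validation split (`val_fraction=0.2` by
default); the best-validation parameters are returned. Up to 1000 epochs.
Gradient norms are clipped at 5.0 — a stability guard for backpropagation
through hundreds of recurrent steps, applied before every update. Training
is bit-reproducible given the config seed on a fixed platform and thread
count. Downstream evaluation uses stratified k-fold cross-validation
(scikit-learn `StratifiedKFold`, 10 folds by default) reporting per-fold
AUC (Mann–Whitney rank form with midrank ties), accuracy and balanced
accuracy. Weight transfer copies all parameters from a structurally
identical donor; `reinit_head=True` re-draws only the decoder.

## Synthetic cohorts

**Chirp cohort (pretraining).** Each component is a concatenation of linear
up-chirps, `sin(2*pi*(f0*u + (f1-f0)*u^2/2))` with `u` in `[0,1)` per
segment, `f0 ~ U(1,5)` and `f1 ~ U(20,60)` cycles per segment (`f1 > f0`
enforced), plus Gaussian noise of sd 0.1. Frequency rises with time, so the
time direction is identifiable in every component; the full-scale default
(53 components, 1200 time points) matches the dimensions used with real
ICA time courses, and all experiments here reduce `T` and `N` for CPU-scale
runs. Note that at short `T` the upper default frequencies exceed the
Nyquist limit and alias; operations that inspect short windows (e.g. OCP
segments) should lower `f1_range` accordingly.

**Episodic cohort (downstream).** Controls are per-component AR(1) noise
(coefficient 0.5, innovation sd 1.0). Patients add `n_events`
non-overlapping oscillatory bursts — a half-sine envelope times a sinusoid
(3 cycles per event by default), peak amplitude `event_amplitude`, length
`event_length` — to a fixed random subset of components at patient-specific
uniformly drawn onsets. The burst is oscillatory rather than a constant
offset so that the class signal is a localized variance/frequency anomaly,
matching the intuition of transient, episodic disease activity, and so that
a sliding-window variance detector can verify event placement
independently. What this generator does **not** emulate: spatial covariance
between components, 1/f spectra, scanner drift, subject-level amplitude
heterogeneity, or label noise. Passing tests on these cohorts show the
pipeline's mechanics are correct at desk scale, not that the effect sizes
transfer to real fMRI.

## Interpretability

**Integrated gradients.** `IG(X) = (X - b) * mean_k dF/dx` evaluated at the
midpoints `b + (k-1/2)/steps * (X-b)`, with `b = 0` by default and `F` the
model's sigmoid probability in evaluation mode. Midpoint Riemann
integration converges at `O(steps^-2)` for smooth paths; default 64 steps.
The exactness on linear scorers and the completeness axiom (attributions
sum to `F(X) - F(b)`) are asserted in the tests on a moderately trained
model. **Caveat:** for a classifier trained to saturation on a separable
task, the output along the straight path can switch in an interval narrower
than any practical step grid (the recurrent dynamics amplify an input-scale
bifurcation), and completeness then fails at any fixed step count; saliency
maps of such models concentrate at the earliest time steps in both temporal
directions — an artifact of recurrence, not a feature of the data. See the
alignment discussion below.

**Alignment.** Reverse-input maps are flipped along time
(`flip_time_saliency`, guarded by an `aligned` flag) and compared with the
forward map via Pearson correlation of the flattened absolute attributions.
Absolute values are used because salience magnitude, not sign, is what the
vertical-bar visualisation encodes; a `signed=True` flag is exposed. The
correlation uses the full map rather than per-time marginals — the stricter
of the plausible readings.

**EMD spikiness.** The top `ceil(fraction * T * N)` entries by absolute
attribution (default 5%; ties at the cutoff broken by earlier time, then
lower component index) are kept, collapsed onto the time axis by summing
absolute values, and normalised to a distribution. Its 1-Wasserstein
distance to the uniform reference over the `T` indices — computed by the
exact CDF formula `sum_t |CDF1(t) - CDF2(t)|`, validated against an LP
transport solver — is the spikiness score: 0 for evenly spread saliency,
`(T-1)/2` for a single endpoint spike. The uniform reference is the choice
that makes "concentrated = high, scattered = low" hold; scores are in
time-index units with an optional `/(T-1)` normalisation for cross-length
comparison.

**Submodular pick.** With `W` the stack of flattened absolute maps and
feature importance `I_j = sqrt(sum_i W_ij)`, subjects are picked greedily to
maximise the importance-weighted coverage of features with `W_ij > 0`, ties
to the lower index. The greedy trace is tested against an exhaustive
per-step oracle.

## Numerical and degenerate-input conventions

* Probabilities are clamped to `[1e-7, 1-1e-7]` inside the BCE loss, and to
  `(1e-12, 1-1e-12)` in single-sequence inference output.
* An all-zero masked saliency marginal raises a degenerate-distribution
  error rather than returning a silent NaN; zero-variance maps make the
  alignment correlation undefined and raise.
* Early-stopping improvement is any validation-loss decrease larger than
  1e-6; with patience 0 the first non-improving epoch stops training.
* Cohort I/O writes floats with 17 significant digits, so a
  write/read round trip is bitwise exact.

## Problem sizes used in the shipped experiments

The bundled study runs (acceptance script and heavy tests) use 200 chirp
subjects with 8 components and 200 time points for pretraining (80/20
subject split), and small episodic cohorts — 20 subjects, 6 components, 80
time points, burst peak 4x the innovation sd — across 5 repetition seeds
for the pretrained-vs-scratch comparison; these sizes were chosen so the
full suite runs on one CPU in minutes while keeping every qualitative
phenomenon of interest measurable. In the small-cohort regime the
pretrained and scratch arms differ most in what their saliency looks like;
with more subjects or stronger bursts both arms learn the task and the
saliency-concentration contrast shrinks.

## Known limitations

* The alignment analysis is meaningful only for models whose confidence is
  moderate; at desk scale the chirp pretext task is nearly separable and
  the trained model saturates, which suppresses forward/reverse alignment
  (see the IG caveat above). Real, noisy cohorts — where accuracy tops out
  below 100% — are the intended regime.
* Transfer from chirp dynamics to burst detection is a stand-in for
  transfer between real resting-state cohorts; the synthetic source and
  target tasks are farther apart than two fMRI datasets, so the transfer
  benefit measured here is conservative — in the shipped experiments a
  fully chirp-pretrained encoder can in fact start from a worse basin than
  a random initialization (negative transfer). A closer synthetic analog —
  pretraining on the downstream cohort's own control process — is not
  available, because a stationary Gaussian AR(1) is time-reversible in
  distribution and the time-reversal task carries no signal on it. By
  contrast, the saliency-concentration effect of pretraining (higher EMD
  spikiness on patient maps) is reproduced robustly at desk scale.
* OCP/PCL results depend on segment/window lengths, which the user must
  keep meaningful relative to the signal's frequency content.
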
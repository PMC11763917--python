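# arrowtime

Self-supervised **arrow-of-time pretraining** and saliency-based
explainability for multivariate neural time courses — per-subject `T x N`
matrices (T time points, N components) such as ICA time courses extracted
from resting-state fMRI.

Deep classifiers for clinical neuroimaging are data-starved and opaque.
This package addresses both problems with one pretext task: train a
recurrent attention model to tell whether a sequence runs forward or
backward in time. Reversal preserves every static statistic of the data, so
the only way to win is to encode the temporal dynamics — and those learned
dynamics transfer to downstream diagnosis tasks. The explainability layer
then asks *what* the model looked at, and *how concentrated in time* that
evidence is.

## What is implemented

- **Time-reversal (TR) pretraining** — for each subject matrix `X`, the pair
  `(X, y=0)` and `(X_reverse, y=1)` with `X_reverse[t, n] = X[T-t-1, n]`;
  binary cross-entropy loss
  `L = -mean[ y log f(X) + (1-y) log(1-f(X)) ]`.
- **Model** — unidirectional LSTM (or GRU) encoder; concatenation attention
  `a_t = softmax_t( w2' tanh(W1 [h_t ; h_T]) )`, context `c = sum_t a_t h_t`;
  two-linear-layer decoder with dropout and a sigmoid output. Xavier-normal
  initialization; Adam (lr 7e-4, batch 32), reduce-on-plateau scheduling and
  early stopping on validation loss; stratified 10-fold cross-validation
  with AUC / accuracy / balanced accuracy; weight transfer to downstream
  tasks. Entirely NumPy — forward and backward passes are hand-written and
  finite-difference checked.
- **Baselines** — order-contrastive pretraining (OCP) and permutation
  contrastive learning (PCL) over segment pairs.
- **Explainability** — integrated gradients
  `IG(X) = (X-b) . (1/m) sum_k dF/dx |_{b+(k-1/2)(X-b)/m}`;
  forward/flipped-reverse saliency alignment by Pearson correlation;
  top-5% masking; time-marginal saliency distributions; 1-Wasserstein
  ("earth mover's") spikiness against a uniform reference,
  `EMD(p, u) = sum_t |CDF_p(t) - CDF_u(t)|`; greedy submodular pick of
  representative subjects.
- **Synthetic cohorts** — up-chirp pretraining cohorts (rising instantaneous
  frequency makes the arrow of time identifiable) and two-class "episodic"
  cohorts (AR(1) controls; patients with short oscillatory bursts), so every
  stage runs with no data download.

## Worked example

```python
from arrowtime import (ChirpParams, ModelConfig, TrainConfig,
                       generate_chirp_cohort, pretrain)

cohort = generate_chirp_cohort(40, ChirpParams(n_components=6, n_timepoints=80, seed=100))
model, acc = pretrain(
    "tr", cohort,
    ModelConfig(input_size=6, lstm_hidden=32, attention_hidden=32, decoder_hidden=16, seed=100),
    TrainConfig(seed=100, max_epochs=150, early_stop_patience=30),
)
print(acc)
```

prints `1.0`: on held-out chirp subjects the model separates forward from
time-reversed sequences perfectly — the pretext task is solvable only by
reading temporal structure, and the chirps' rising frequency makes that
structure unambiguous. The `examples/` directory walks through every
capability (simulation, pretraining, transfer + cross-validation, saliency
alignment, EMD spikiness and submodular pick); each script prints what it
computes and what the numbers mean, e.g. `examples/05_spikiness_and_pick.py`:

```
 flat: EMD spikiness = 4.53 (max possible 19.5)
spiky: EMD spikiness = 13.27 (max possible 19.5)
```

— a saliency map dominated by one time point scores close to the
single-spike maximum `(T-1)/2`, while evenly scattered saliency scores low.

There is also a thin CLI over the same pipeline:

```bash
arrowtime simulate --data-dir data --seed 0 --n-components 8 --n-timepoints 160
arrowtime pretrain --data-dir data --output-dir out --seed 0 --method tr
arrowtime finetune --data-dir data --output-dir out --seed 0
arrowtime explain  --data-dir data --output-dir out --seed 0
arrowtime report   --data-dir data --output-dir out --seed 0
```

See `docs/methods.md` for the model, the synthetic-data assumptions, and
numerical conventions.

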
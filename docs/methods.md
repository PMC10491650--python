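# Methods

## Problem and model

`ictalnet` classifies single-channel EEG segments into epileptic states. The
data layout is the five-subset benchmark format: subsets Z and O are scalp
recordings from healthy subjects, N and F are interictal (between-seizure)
intracranial recordings from epilepsy patients, and S is continuous ictal
(during-seizure) activity; each record is one 23.6 s segment sampled at
173.61 Hz. Tasks are expressed as ordered groups of subsets; the headline
task is the ternary discrimination {F/N} (interictal) vs {O/Z} (healthy) vs
{S} (ictal), alongside eight standard binary tasks such as {Z} vs {S}.

The classifier is a hybrid convolutional-recurrent network:

    input (1 × T) → [conv(k) → ReLU → max-pool(p)] × 3 → dropout(P)
                  → time-major reshape → LSTM(H) → dropout(P)
                  → dense softmax

The three conv+pool blocks extract local (spatial/morphological) features —
spikes, rhythmic bursts — while the LSTM consumes the pooled feature map as
a time sequence (each pooled time step becomes one input vector of channel
activations) and summarizes its temporal evolution in the final hidden
state. Convolution uses the cross-correlation convention with valid padding
and stride 1. The LSTM cell operates on the concatenation z = [h_{t−1}, x_t]:

    f_t = σ(W_f z + b_f)      i_t = σ(W_i z + b_i)
    C̃_t = tanh(W_C z + b_C)   C_t = f_t ∘ C_{t−1} + i_t ∘ C̃_t
    o_t = σ(W_o z + b_o)      h_t = o_t ∘ tanh(C_t)

Dropout (inverted scaling) applies at two sites — after the pooling stack
and after the LSTM — only during training; inference is deterministic.

Two implementations of the forward pass coexist deliberately.
`ictalnet.reference` is an executable specification written as naive
per-channel loops; `ictalnet.network` is the trainable realization
(im2col/GEMM convolutions, batched LSTM, manual backpropagation, Adam).
Tests require the two routes to agree on exported parameters, which pins the
whole architecture wiring (channel ordering, the pooled-map-to-sequence
reshape, gate layout). Training arithmetic is float32; inference is float64.

## Default hyperparameters

| parameter | default | rationale |
|---|---|---|
| conv channels | 16 / 32 / 32 | small-footprint feature pyramid for 4096-sample inputs |
| kernel length | 5 (≈29 ms at 173.61 Hz) | matches interictal spike half-width |
| pool size / stride | 4 / 4 per block | 4096 → 62 LSTM steps; see below |
| LSTM hidden units | 64 | enough capacity for three rhythm classes |
| dropout P | 0.5, both sites | standard heavy regularization for small corpora |
| optimizer | Adam, lr 1e-3, batch 32 | conventional defaults |
| epochs | 100 (max) | with early stop when mean epoch cross-entropy < 1e-3 |
| loss | categorical cross-entropy | softmax head; the fold error e_q is computed separately |

The pool size of 4 (rather than 2) per block is a deliberate design choice:
with pools of 2 the LSTM would unroll over 508 time steps, through which
backpropagated gradients decay badly and computation grows ~8-fold; 62 steps
of 32-channel vectors train reliably. Every value above is overridable via
`ModelConfig` / the CLI config file.

Weight initialization: He-normal conv kernels, Glorot-uniform LSTM and dense
matrices, zero biases except the forget-gate offset, initialized to 1 so the
cell state is retained by default early in training.

## Cross-validation and error formulas

`tenfold_split` produces a seeded shuffled partition into 10 folds
(stratified by default — the ictal group has half the segment count of the
other ternary groups, and unstratified folds can miss it entirely). Each
fold trains a fresh model whose seed derives from the global seed and the
fold index. The per-fold error is the multiclass Brier score

    e_q = (1/m) Σ_n ‖ŷ_n − onehot(y_n)‖²,     CVe = (1/10) Σ_q e_q,

where ŷ_n is the predicted probability vector; for a scalar 0/1 prediction
this reduces to the plain mean squared error. Mean test accuracy across
folds is reported as the headline figure. Because normalization is per
segment, no statistics flow from test folds into training.

## Evaluation indices

The confusion table A is indexed rows = real class, columns = predicted.
Group sensitivity and specificity use the three-group formulas
SEN_g = A_gg/A_g and SPE_g = (Σ_{i≠g, j≠g} A_ij)/(Σ_{i≠g} A_i), which equal
the one-vs-rest recall and true-negative rate of group g (verified exactly
against independent computations in the tests) and reduce to TP/(TP+FN),
TN/(TN+FP) for binary tasks. ROC curves sweep all distinct thresholds of a
class's predicted probability one-vs-rest; AUC is the trapezoid area over
tie-grouped points, equal to the Mann-Whitney ranking probability with ties
credited ½. Macro AUC is the unweighted mean over classes. Precision-recall
curves record one point per distinct threshold. Reports key per-group values
by group label (e.g. `"{F/N}"`), so group ordering is explicit everywhere.

## Synthetic data

The generator emulates the five-subset layout with three signal classes,
each built on unit-RMS 1/f^β background noise (β = 1) synthesized in the
frequency domain with random phases:

- **healthy** (Z, O): background + an alpha-band (8–13 Hz) sinusoid of
  random frequency/phase, amplitude 1× background RMS;
- **interictal** (N, F): the healthy signal + Poisson-timed biphasic spikes
  (derivative-of-Gaussian, ≈70 ms wide, amplitude 4× RMS, rate 0.5 Hz);
- **ictal** (S): background + a sustained 3–5 Hz oscillation at 5× RMS.

Records are scaled to span roughly ±1000 and rounded to integers, matching
the integer ASCII storage format. Per-record random streams derive from
(seed, subset code, record index), so any record is individually
reproducible and the whole corpus is byte-identical under a fixed seed.

These are learnable fixtures, not physiology: real EEG has nonstationary
artifacts, inter-subject variability, broadband ictal dynamics and
multichannel structure that the generator does not attempt. Passing tests
therefore demonstrate that the pipeline's mechanics are correct and that the
network can learn genuinely separable rhythm/transient classes — not that
the reported synthetic accuracies transfer to clinical recordings. Running
the CLI on the real downloaded corpus is supported via the Bonn-layout
loader but is outside the test suite.

## Numerical choices and degenerate inputs

- Band-pass: 4th-order Butterworth, 0.5–50 Hz, zero-phase forward-backward
  (`sosfiltfilt`), which squares the magnitude response; applied before
  segmentation so window edges carry no filter transients.
- Segmentation truncates a trailing partial window (a 4097-line record
  yields one 4096-sample segment); z-normalization uses the population
  standard deviation and rejects constant segments explicitly.
- Softmax is computed max-subtracted; AUC tie-handling is exact (grouped
  thresholds), not sample-order dependent (stable mergesort).
- Max-pool drops a trailing partial window; pooling supports the optional
  per-channel affine (scale/offset) form, defaulting to plain max.
- A class with fewer members than the fold count makes stratification
  impossible: a warning is emitted and a plain shuffled split is used.
- Training divergence (non-finite loss) raises immediately, naming the fold.

## Scale of the shipped experiments

The full-scale validation run uses the benchmark's own layout — 100 records
per subset, i.e. 500 ternary segments of 4096 samples — with training capped
at 30 epochs per fold (the separable synthetic classes converge well within
the cap; the early-stop criterion usually ends training sooner). The same
conditions are used by `scripts/acceptance.py`, which also runs the binary
{Z} vs {S} task on the corresponding 200 records.

## Known limitations

- The LSTM is unidirectional; a bidirectional variant is not implemented
  (a config flag is reserved for it).
- No GPU path: the numpy implementation targets CPU-scale experiments
  (minutes per 10-fold run at the shipped sizes).
- The CNN-only and LSTM-only ablations are not built in; the nearest
  equivalent is configuring a 1-unit LSTM or 1-channel conv stack.
- Only single-channel, fixed-rate records are supported (no EDF/BrainVision,
  no montages); mixed sampling rates are rejected rather than resampled.
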
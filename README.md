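# ictalnet

Hybrid CNN-LSTM recognition of epileptic EEG states.

`ictalnet` is a library + CLI for classifying single-channel EEG segments in
the five-subset benchmark layout (Z, O = healthy scalp; N, F = interictal
intracranial; S = ictal intracranial; one 23.6 s record per ASCII text file,
173.61 Hz). It covers nine standard tasks — eight binary, plus the ternary
discrimination of interictal {F/N} vs healthy {O/Z} vs ictal {S} — and is
aimed at researchers who want a fully inspectable, retrainable baseline for
seizure-state classification rather than a framework black box.

## The model

Each preprocessed segment x (band-passed 0.5–50 Hz, z-normalized) passes
through three convolution + max-pooling blocks, a dropout site, one LSTM
layer, a second dropout site, and a dense softmax head:

    u_m = Σ_{n∈p} corr(x_n, H_mn) + b_m ,  x_m = ReLU(u_m),  then a·down(x_m)+b

for each conv block (valid cross-correlation, windowed max `down`), and for
each pooled time step t, with z = [h_{t−1}, x_t],

    f_t = σ(W_f z + b_f),  i_t = σ(W_i z + b_i),  C̃_t = tanh(W_C z + b_C),
    C_t = f_t ∘ C_{t−1} + i_t ∘ C̃_t,  o_t = σ(W_o z + b_o),  h_t = o_t ∘ tanh(C_t).

The class posterior is softmax(w h_T + b). Evaluation is 10-fold
cross-validation with the Brier-style fold error
e_q = (1/m) Σ ‖ŷ − onehot(y)‖² and CVe = mean(e_q), plus a multi-index
report: accuracy, confusion table (rows = real class), per-group
sensitivity SEN_g = A_gg/A_g and specificity
SPE_g = Σ_{i≠g,j≠g} A_ij / Σ_{i≠g} A_i, one-vs-rest ROC/AUC (Mann-Whitney
tie convention) and precision-recall curves. The forward pass exists twice —
a naive loop-based reference and a vectorized trainable implementation with
manual backpropagation — and the test suite requires them to agree.

A seeded synthetic generator emulates the benchmark layout with three
separable signal classes (alpha rhythm + 1/f noise; the same plus sparse
biphasic spikes; sustained 3–5 Hz high-amplitude rhythm), so the whole
pipeline is testable without downloading the real corpus. See
`docs/methods.md` for what these fixtures do and do not demonstrate.

## Worked example

```bash
# 1) write a synthetic corpus: 5 subset directories x 100 records
ictalnet simulate --out-dir data/synth --n-per-class 100 --seed 1

# 2) ternary 10-fold CV with a 30-epoch training cap
cat > config.yaml <<EOF
model: {epochs: 30}
EOF
ictalnet run --config config.yaml --data-root data/synth --task ternary \
         --seed 1 --out runs/ternary

# 3) figures (confusion heat map, ROC, PRC) + markdown summary
ictalnet report runs/ternary
```

The `run` step prints (and writes to `runs/ternary/summary.txt`):

```
task: ternary ({F/N}-{O/Z}-{S})
mean 10-fold ACC: 99.80%
CVe (Brier): 0.0045
group {F/N}: SEN 99.50%  SPE 100.00%  AUC 100.00%
group {O/Z}: SEN 100.00%  SPE 99.67%  AUC 100.00%
group {S}: SEN 100.00%  SPE 100.00%  AUC 100.00%
macro one-vs-rest AUC: 100.00%
```

Reading: each fold holds out 50 of the 500 segments; the mean held-out
accuracy is 99.8%, the mean Brier error of the probability forecasts is
0.0045, and every group's one-vs-rest ranking is near-perfect — the three
synthetic classes are separable by design, so this is a pipeline
correctness check, not a clinical claim. The same commands run on the real
downloaded corpus by pointing `--data-root` at its directory tree (`SET A`
… `SET E` directory aliases are accepted).

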
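# Methods

This document records the model definition, the synthetic-data generator,
the numerical and protocol choices, and the known limitations of
`toxtransfer`. The study conditions used by the acceptance suite were fixed
before the runs (see *Acceptance protocol* below) and are never adjusted in
response to individual pass/fail outcomes.

## Problem setting

Three assay domains measure the expression of the same gene panel after
compound exposure:

| domain         | time grid (h) | replicates | role                      |
|----------------|---------------|------------|---------------------------|
| rat in vitro   | 2, 8, 24      | 2          | source inputs             |
| rat in vivo    | 3, 6, 9, 24   | 3 (2 kept) | source targets            |
| human in vitro | 2, 8, 24      | 2          | target inputs, unlabelled |

Expression values live on a normalized [0, 1] scale. An *input vector*
flattens one in vitro series gene-major to length `3·G`; a *target vector*
flattens one in vivo series to length `4·G`. Pairing each non-control
in vitro series with each kept in vivo replicate yields 16 source learning
examples per compound (3 non-control doses × 2 in vitro replicates × 2 kept
in vivo replicates, plus the control dose's pairings), and symmetrically 16
unlabelled target examples per compound from human in vitro series. The
default 45-compound design therefore yields exactly 720 source and 720
target examples. The third in vivo replicate is deliberately dropped
(`VIVO_KEPT = 2`) to keep source and target example counts balanced.

Normalization is per-gene min–max, fit **only** on training compounds
(`normalize_dataset(ds, fit_scope=...)`); held-out compounds are transformed
with the training statistics and clipped to [0, 1], so no fold ever leaks
its own scale.

## Synthetic study generator

The generator (`toxtransfer.simulate`) produces datasets with a fully known
ground truth so every downstream stage can be tested against an exact
answer. Scope and mechanics:

- Each compound-gene response is a gamma-shaped impulse
  `w_dose · A_cg · (t/τ_cg) · exp(1 − t/τ_cg)` added to a gene baseline;
  dose scales amplitude (`control = 0`, `low = 1/3`, `medium = 2/3`,
  `high = 1`), and τ is the peak time.
- The rat in vivo trajectory is the same latent response with a 2 h onset
  delay and a gene-specific gain, evaluated on the in vivo grid — a smooth,
  learnable transform.
- Human in vitro data are the rat latent response passed through a
  systematic gene-wise affine shift (offset + gain) whose size is
  `domain_shift_magnitude`. The shift is *systematic*, not noise: exactly
  the situation adversarial adaptation addresses.
- Replicates differ only by i.i.d. Gaussian noise (`noise_sd`), truncated to
  [0, 1]. An optional `discordant_fraction` flips the response sign of
  random compound-dose pairs to emulate non-reproducible exposures.
- Optional toxicity labels: `assign_toxicity_labels` marks a chosen fraction
  of compounds positive and perturbs their response parameters by
  `perturbation_magnitude`, creating a latent-detectable class signal.

The generator is **not** a biological model: it makes no claim about real
transcriptional kinetics, uses a single impulse per compound-gene, and its
domain shift is affine. It exists to give the pipeline a controlled,
regenerable ground truth.

## Network and training

Architecture (`ArchitectureSpec`, defaults for a 76-gene panel):

- trunk: input `3·G = 228` → hidden widths (135, 90, 64, 120, 190), ReLU;
  sigmoid output head of width `4·G = 304`;
- the **latent layer** is hidden index 2 (width 64), the bottleneck shared
  by both domains;
- the **domain arm** reads the latent layer through a gradient-reversal
  layer (identity forward; backward multiplies by −λ) into an 8-unit hidden
  layer and a 2-class softmax.

Losses: prediction = sum of absolute errors over source examples; domain =
softmax cross-entropy over all examples (target examples contribute domain
loss only). λ follows the schedule `2/(1 + exp(−γp)) − 1` with γ = 10 over
training progress `p`, and the domain-loss weight warms up linearly from a
0.1 floor over the first 25 % of epochs.

Optimization is momentum SGD (lr 0.02, momentum 0.9, 400 epochs, batch 32),
implemented in NumPy with manual backpropagation; all gradients are verified
against central finite differences in the test suite.

### Adversary stabilization

A naive single-step adversary either collapses (the domain classifier
predicts one class everywhere) or destabilizes the trunk. The package
defaults use a critic-style recipe, chosen on training diagnostics (loss
traces, collapse counts) before the acceptance runs:

- the arm uses leaky ReLU (slope 0.1) so its gradients cannot die;
- per trunk step the arm takes 5 plain-SGD updates at 10× the learning rate
  with weight decay 0.02, keeping the domain classifier near-optimal;
- the reversed gradient entering the trunk is scaled by
  `adversary_gradient_scale = 0.5` and the prediction gradient is normalized
  per output dimension, balancing the two objectives;
- a mode-collapse detector (window of domain-accuracy history; single-class
  prediction check) triggers seeded restarts (`train_with_restarts`), with
  the replacement seed derived deterministically.

### Numerical precision

The training loop runs in float32 (`TrainingConfig.precision = "single"`,
~1.5× faster on one CPU); parameters are cast back to float64 at the end,
and checkpoints store float64. Exact-equivalence tests (for example
"λ = 0 trunk updates equal adaptation-off updates") use
`precision="double"`, because float32 GEMM rounds shared rows differently
when the batch carries extra target rows. Determinism is unaffected: all
randomness flows from `numpy.random.SeedSequence(seed).spawn(...)` children
(init, arm init, source shuffle, target shuffle), and same-seed runs are
byte-identical.

## Evaluation protocol

**LOOCV.** One fold per compound: normalization refit on the training
compounds, model retrained from scratch, and the 16 held-out source
instances scored by MAE between predicted and measured in vivo matrices
(`G × 4`). `overall_mae` averages instance MAEs; `compare_with_without_da`
repeats the identical folds and seeds with the adversarial arm disabled and
pairs the per-instance MAEs (two-tailed paired t-test; zero-variance
non-zero differences are flagged degenerate).

**Domain mixing.** The headline mixing diagnostic trains on the *full*
study, embeds every in vitro example at the latent layer, and fits a fresh
logistic-regression probe on a stratified 50/50 train/test split of those
embeddings (`probe_accuracy`); reported accuracy is on the probe's held-out
half. Accuracy near 0.5 means the latent space no longer encodes species;
the adaptation-off model stays near 1.0. A stricter variant probes only the
embeddings of LOOCV held-out compounds; with 32 embeddings per fold it is
noisy and typically lands between the two extremes (≈0.8 at the acceptance
study scale). It is reported as a secondary diagnostic
(`loocv_summary.json: heldout_probe_accuracy`) but not gated on.

**Latent classifier.** For each labelled compound a fold model is trained
without it; latent features of the remaining labelled compounds train a
class-weighted linear SVM; the held-out compound is called by majority vote
over its embeddings (ties → positive, the conservative call). Folds whose
training labels contain one class are skipped with a warning. The SVM
default is strongly regularized (C = 0.1): with tens of compounds the
classifier sees few effective samples in a 64-dimensional latent space, and
C = 1 was observed to fit the training records perfectly while losing
compound-level generalization. The C value was selected on tuning seeds
disjoint from the acceptance seed (feature standardization was also tried
and did not help).

## Acceptance protocol (fixed a priori)

Study conditions: 10 compounds × 20 genes, `domain_shift_magnitude = 0.3`,
`noise_sd = 0.02`; package-default architecture and training config.
Seeds: mixing uses seeds 0–9, the LOOCV comparison seeds 101–110, parameter
recovery seed 13 (with `noise_sd = 0`), the classifier seed 21 with 20
label permutations reusing the label-free fold models.

The classifier's *separable case* (15 labelled compounds, label fraction
0.5, perturbation 0.5) is defined by a generator-level oracle, not by the
classifier under test: a linear SVM on the noise-free raw ground-truth
trajectories must reach 100 % compound-level LOOCV accuracy across multiple
seeds. Perturbation 0.3 fails that oracle (labels are then not
compound-separable and the criterion's precondition is unmet); perturbation
0.5 saturates it at both 15 and 20 compounds.

`scripts/acceptance.py` re-derives all
seeds (< 2³¹) from a single `--seed` via `SeedSequence` children, so the
report tests the same properties on fresh seeds.

Checks: 720/720 example counts and 16-instance folds; reversal gradients
equal −λ × finite differences (rel. 1e-4); λ-schedule closed form and
monotonicity; median mixing probe ≤ 0.65 (adaptation on) and ≥ 0.9
(adaptation off) over 10 seeds; median LOOCV MAE with adaptation ≤ without
over 10 seeds; the model beats a per-gene training-mean baseline on ≥ 90 %
of noise-free held-out instances; separable-label validation accuracy
≥ 0.9 with mean permuted accuracy within ±0.15 of the majority prior;
zero-weight forward = 0.5, adaptation-off ≡ arm-free, same-seed
byte-identity.

## Limitations

- The generator's affine domain shift and impulse dynamics are far simpler
  than real cross-species biology; results quantify the pipeline, not
  biological transfer.
- The adaptation benefit on held-out MAE is within seed noise at desk
  scale: single seeds, very small studies (see `examples/02`), and even
  10-seed medians on an independent seed set can favor either arm (observed
  mean paired difference ~6e-5 against a between-seed sd of ~1.3e-3 in one
  acceptance-script run). The desk-scale claim is "adaptation does not hurt
  translation while it removes the species signal", not a robust MAE win.
- The strict held-out-compound probe stays well above 0.5: with 32-point
  probe sets and unseen compounds, domain mixing generalizes only
  partially.
- Sum-of-absolute-error training on [0, 1] sigmoid outputs converges
  slowly; 400 epochs were kept after 200-epoch runs showed clear
  under-convergence (prediction-loss plateaus not reached, erratic probe
  values).
- No GPU path and no minibatch parallelism; the NumPy implementation
  targets clarity and testability over speed.
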
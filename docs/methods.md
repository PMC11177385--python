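# Methods

## Model

`neurostitch` classifies subjects as ill (label 1) vs control (label 0)
from resting-state fMRI ROI time-series. Each subject is a matrix
x ∈ R^{T×N} (T time nodes × N brain regions). Each acquisition site is
treated as one task; D sites are learned jointly.

**Positional encoding.** Temporal order is injected once, before the first
layer, as x̃ = x + PE with

    PE[t, 2n]   = sin(t / 10000^(2n/N)),
    PE[t, 2n+1] = cos(t / 10000^(2n/N)),   t = 0 … T−1.

The exponent uses the brain-region count N (the feature axis), not a
separate model width. For odd N the final unpaired column uses the sine
form. Consequently adjacent even/odd columns share an angle, giving the
exact identity PE(t,2n)² + PE(t,2n+1)² = 1, which the tests assert.

**Attention layer.** Each of D columns applies, per layer,

    Q = f W_Q + b_Q,  K = f W_K + b_K   (N → ⌊N/2⌋),
    V = f W_V + b_V                     (N → N),
    f̂ = softmax(Q Kᵀ) V,               (row-normalised T×T scores)
    f̄ = f̂ + f,                         (residual fusion)
    f̃ = ReLU(f̄ W_f + b_f).             (position-wise feed-forward, N → N)

Q and K halve the channel count to cut the inner-product cost; V keeps
width N so the residual sum is well-typed. There is no 1/√d temperature by
default (`scaled_attention: true` enables 1/√⌊N/2⌋). Single head; no
dropout or layer normalisation — the layer is deliberately this minimal.

**Cross-stitch sharing.** After every one of the L layers the D column
outputs are linearly recombined by a learnable D×D matrix M:

    f_d^{l+1} = Σ_j M[j,d] · f̃_j^l .

Every sample is forwarded through all D columns simultaneously, so
prediction works for a lone test subject; the alternative reading (mixing
features of different samples drawn per site) would make single-sample
inference ill-defined, and was rejected for that reason. One sharing matrix
is kept per layer, applied after each of the L layers including the last;
the task-d head therefore consumes column d's final post-sharing features.
M is initialised at 0.9 on the diagonal and 0.1/(D−1) off-diagonal —
near single-task, letting training discover how much to share. With M = I
at every layer the multi-task forward is *exactly* (bitwise) equal to D
independent single-task forwards with the same weights; this
identity-reduction property is asserted in the tests and is what makes the
single-task ablation arm a controlled comparison: `single_task=true` simply
freezes every M at I and removes it from the optimizer.

**Prediction head and objective.** Per task, column d's final T×N features
are flattened and passed through three fully-connected layers
(T·N → 4096 → 2048 → 2 by default, ReLU between, softmax at the end). The
joint objective is the sum over tasks and samples of the negative log
probability of the true class (binary cross-entropy in its NLL form),
with probabilities clamped at ε = 1e-12 inside the loss. A predicted tie
(0.5, 0.5) resolves to class 0 (control), a deterministic choice that
favours specificity.

**Optimization.** Adam, initial learning rate 1e-5 halved every 30 epochs,
120 epochs, batch size 16, stratified 8:2 train/test split — the package
defaults. "Every 30 iterations" is implemented as epochs: a 30-step decay
period would end the schedule inside the first epoch at realistic site
sizes. Each optimizer step accumulates one mini-batch from *every* task
(the shorter site's samples are cycled within the epoch), realising the
summed-over-tasks loss exactly. No early stopping, weight decay or
gradient clipping by default; `grad_clip` (max global norm) is available
because summed losses can produce large steps. All randomness — weight
init, split membership, batch order — derives from the single config seed
via named substreams, so (weights, history) are bit-reproducible on fixed
hardware in single-threaded mode.

The network and its gradients are implemented directly in NumPy as
handwritten reverse-mode differentiation; the test suite validates every
gradient path against central finite differences at relative tolerance
1e-4.

## Synthetic data generator

The generator emulates D sites of labelled T×N matrices. A unit-norm
region pattern u (drawn once per spec seed, shared by all sites) and a
site-private unit-norm pattern v_d carry the class signal: class-1 samples
receive `shared_effect · u + private_effect · v_d` added to every time row
(optionally modulated by 1 + 0.5 sin(2πt/T)); all entries carry i.i.d.
Gaussian noise of sd `noise_sd`. Generation is a pure function of
(spec, task_index).

Defaults mirror a two-site autism-classification setting: site sizes
172 (74/98) and 120 (47/73); N = 116 regions (the AAL atlas convention)
and T = 176 time nodes — both conventions, since real scan parameters vary
by site; `shared_effect = 0.6`, `private_effect = 0.3`, `noise_sd = 1.0`
(signals below the per-entry noise floor but well above the per-sample
projection noise ≈ noise_sd/√T, i.e. moderate, realistic separability).

What the generator does **not** emulate: haemodynamic/BOLD autocorrelation
and spectra, atlas geometry and spatial smoothness, motion artifacts,
site-specific preprocessing differences, age/sex structure. Tests passing
on this generator therefore demonstrate that the architecture, sharing
mechanism and training loop behave as specified — not that any particular
accuracy transfers to real rs-fMRI data.

## Desk-scale studies

The canonical studies in `neurostitch.experiments` use T=30, N=20 and a
reduced architecture (L=2, 128/32/2 head, Adam at 1e-3 — the standard
from-scratch rate at this scale), chosen so each study completes in
minutes on one CPU:

* **Strong-signal learning** — 2 sites × 200 balanced samples,
  shared_effect 1.2: per-sample projected class separation is ≈ 6.6× the
  projection noise, so a correct implementation should reach ≥ 90%
  held-out accuracy within 60 epochs in nearly every seed.
* **Null signal** — both effects 0: pooled held-out accuracy must fall in
  the 99% binomial chance interval around 0.5.
* **Sharing ablation** — 2 sites × 60 samples, shared_effect 0.5, private
  0.1, 15 epochs, 10 paired seeds (same splits and init per seed in both
  arms). The regime was calibrated by a Monte-Carlo study: with scarce
  data the 600-dimensional flattened head memorises training noise in both
  arms, so the arm difference expresses itself early in training, where
  cross-stitch columns — receiving gradient from both sites' losses —
  learn the shared pattern roughly twice as fast as identity-frozen
  columns. 15 epochs sits in that window; the measured advantage is small
  (≈ +1 to +3 accuracy points) but directionally stable across master
  seeds, matching the modest improvements multi-task sharing yields in
  practice.

## Numerical choices and edge cases

* Softmax is computed with row-max subtraction; attention raises on
  non-finite scores rather than propagating NaN.
* Undefined metrics (zero denominators) are reported as `null` with a
  reason string, never coerced to 0, to avoid silently biasing arm
  comparisons.
* Length harmonization truncates from the end or zero-pads at the end —
  the simplest deterministic policy; resampling is intentionally not
  implemented.
* Stratified splits take ⌈0.8·n_class⌉ per class for training; a class
  absent from either side at tiny n warns instead of raising.
* Checkpoints are versioned `.npz` archives carrying all weights plus the
  model configuration.

## Known limitations

* Binary labels only; no task weighting in the objective beyond the
  unweighted sum.
* Single attention head; no dropout/normalisation, so very deep stacks
  (L ≫ 5) may train poorly.
* The training loop is CPU-bound NumPy: fine at desk scale, not intended
  for full-size imaging studies.
* The per-sample-through-all-columns sharing semantics is an interpretive
  choice (see above); other couplings (e.g. batch-paired cross-site
  mixing) are possible but break single-sample inference.
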
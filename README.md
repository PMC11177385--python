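# neurostitch

Multi-task transformer with cross-stitch feature sharing for binary
disorder classification from resting-state fMRI ROI time-series.

## The problem

Classifying a neurodevelopmental condition (e.g. autism spectrum disorder
vs typical controls) from rs-fMRI is hard partly because any single
acquisition site has few subjects. Sites, however, share the underlying
discriminative signal. `neurostitch` treats each site as one *task*: each
subject is a T×N matrix x (T time nodes × N atlas brain regions, label 1 =
illness, 0 = control), and D per-site networks are trained jointly so that
what one site's data teaches about the shared signal benefits the others.

## The model

Each site has its own column of L attention layers. The input is
position-encoded once, x̃ = x + PE with PE(t,2n) = sin(t/10000^(2n/N)),
PE(t,2n+1) = cos(t/10000^(2n/N)). Per layer, a column computes single-head
softmax attention over time nodes with a residual connection and a
position-wise feed-forward map:

    f̂ = softmax(Q Kᵀ) V,   f̄ = f̂ + f,   f̃ = ReLU(f̄ W_f + b_f)

where Q, K project the region axis N → ⌊N/2⌋ and V keeps width N. After
every layer the D columns' features are linearly recombined by a learnable
D×D cross-stitch matrix M:

    f_d^{l+1} = Σ_j M[j,d] · f̃_j^l

so M = I decouples the columns *exactly* — that identity is the controlled
"single-task" ablation arm. A per-task 3-layer FC head
(T·N → 4096 → 2048 → 2, softmax) predicts the label; the joint objective is
the summed cross-entropy over tasks and samples, optimised with Adam
(lr 1e-5 halved every 30 epochs, 120 epochs, batch 16, stratified 8:2
split). The network and its reverse-mode gradients are implemented directly
in NumPy and validated against finite differences in the test suite.

A seeded multi-site synthetic generator (shared + site-private rank-1 class
patterns in Gaussian noise) makes every stage testable end-to-end without
any imaging downloads. See `docs/methods.md` for assumptions, parameter
defaults, and what the synthetic studies do and do not demonstrate.

## Worked example

Simulate two sites with a strong shared class signal, train the multi-task
model, and evaluate on the held-out 20%:

```sh
cat > cfg.yaml <<'EOF'
synthetic:
  n_tasks: 2
  class_counts: [[100, 100], [100, 100]]
  T: 30
  N: 20
  shared_effect: 1.2
  private_effect: 0.2
  noise_sd: 1.0
  task_names: [siteA, siteB]
model:
  L: 2
  head_dims: [128, 32]
train:
  initial_lr: 0.001
  epochs: 60
EOF

neurostitch simulate --spec cfg.yaml --out data --seed 0
neurostitch train    --config cfg.yaml --data data --out run --seed 0
neurostitch evaluate --checkpoint run/checkpoint.npz --data data \
                     --out report.json --splits run/splits.json
```

which prints

```
wrote 2 task dataset(s) to data
trained 60 epochs; checkpoint at run/checkpoint.npz
siteA: accuracy=1.0000 sensitivity=1.0 specificity=1.0
siteB: accuracy=1.0000 sensitivity=1.0 specificity=1.0
```

With a class signal this far above the per-sample noise floor the model
separates the held-out subjects perfectly: accuracy is the fraction of the
40 test subjects per site classified correctly, sensitivity the recall on
ill subjects, specificity the recall on controls. `ablate --seeds K` runs
the paired single-task (M frozen at identity) vs multi-task comparison on
the same splits. Every run writes a `run_manifest.json` (config, seed,
input checksums, version) sufficient to reproduce it.

The library mirrors the CLI: `SyntheticSpec` / `generate_task_data`,
`MultiTaskModel`, `train`, `confusion` / `metrics`, `ablation_compare`.

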
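# hgdiag — disease diagnosis on heterogeneous patient–drug–procedure graphs

`hgdiag` classifies patients into disease categories from the structure
of an electronic-health-record graph with three node types — patients
(P), drugs (D) and procedures (O) — and four directed relations (P-D,
D-P, P-O, O-P). It is aimed at clinical-informatics researchers who
want a self-contained, CPU-friendly reference implementation of
meta-path graph learning with diffusion-based denoising, plus a
synthetic-cohort generator for controlled experiments when access to
real EHR databases is restricted.

## Model

Two branches produce complementary patient representations:

1. **k-hop hierarchical Transformer.** For each patient, 32 neighbors
   are sampled per hop from the exact k-hop frontiers (k = 1..4) along
   the meta-path templates P-D-P and P-O-P. Each hop's sequence is
   encoded by its own Transformer layer; hop attention
   α⁽ᵏ⁾(v,u) = softmax((h_v W_Q)(h_u W_K)ᵀ/√d) summarizes every hop into
   z_v⁽ᵏ⁾ = Σ_u α·(h_u W_V), and a hierarchical Transformer plus
   multi-head hop attention β_k fuses the hop sequence into h_v^HHGAT.
2. **Dual-view latent diffusion.** Auxiliary patient–patient graphs are
   built from the P-D-P and P-D-P-O-P meta-path adjacencies (binarized
   relation-matrix products, zero diagonal). A shallow GCN encodes each
   view into clean latents h₀; the forward process corrupts them as
   h_t = √ᾱ_t·h₀ + √(1−ᾱ_t)·ε, and a shared 3-layer GCN noise predictor
   — conditioned on the other view's noisy state and the time step —
   reverses it with a 10-step deterministic DDIM sampler. The two
   reconstructions are averaged into h^diff.

The branches are fused as h^final = LayerNorm(λ·h^HHGAT + (1−λ)·h^diff)
and classified by softmax(W_c h^final + b_c). Training minimizes
KL(label-smoothed targets ‖ predictions) + the diffusion noise-matching
MSE, with Adam (lr 0.003), label smoothing μ = 0.3, embedding dimension
128, 4 attention heads and stratified 50/30/20 splits. Micro-F1
(= accuracy here) and Macro-F1 are reported. Four ablation variants are
config toggles (`my_gcn`, `my_onlytrans`, `my_onesub`, `my_onlydiff`).

Everything — including the reverse-mode autodiff the model trains
with — runs on numpy/scipy; no GPU framework is required. See
`docs/methods.md` for assumptions, parameter semantics and limitations.

## Worked example

```python
from hgdiag import SyntheticSpec, generate, TrainConfig, train_model
from hgdiag.hetgraph import graph_stats

spec = SyntheticSpec(seed=111)            # 600 patients, 3 classes,
graph, labels, truth = generate(spec)     # signal 0.9, 5% noise rates
print(round(graph_stats(graph).sparsity, 4))

cfg = TrainConfig(max_epochs=50, patience=12, seed=0)
params, report, log = train_model(graph, labels, cfg)
print(round(report.micro_f1, 4), round(report.macro_f1, 4))
```

Output:

```
0.9338
0.9583 0.9577
```

The first number is the realized sparsity of the simulated cohort
(fraction of empty patient-event slots). The F1 pair is test-set
performance at the best-validation checkpoint: with strong planted
class-conditional prescribing (signal 0.9) and 5% edge/label noise the
model recovers the planted disease labels almost perfectly; the gap to
1.0 is mostly the 5% of patients whose labels were flipped by the noise
channel.

The same pipeline is scriptable from the shell:

```bash
hgdiag simulate --seed 1 --out data/cohort
hgdiag stats data/cohort
hgdiag train data/cohort --seed 1 --out runs/full
hgdiag ablate data/cohort --seed 1 --max-epochs 20
```

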
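# Methods

`hgdiag` performs single-label disease classification for patients in a
heterogeneous clinical graph with three node types — patients (P), drugs
(D) and procedures (O) — and four directed relations (P-D, D-P, P-O,
O-P), each stored as a binary adjacency matrix. Two components produce
complementary patient representations that are fused for classification.

## Graph model and meta-paths

Meta-paths (P-D-P, P-O-P, P-D-P-O-P) act as semantic templates. A
meta-path adjacency is the product of the relation matrices along the
path, binarized, with the diagonal zeroed: entry (i, j) is 1 iff at least
one template walk connects patient i to a *different* patient j.
Meta-path *instance* counts keep walk multiplicity (each choice of
intermediate nodes is a separate instance) and exclude self-walks; this
convention is documented here because published cohort tables do not
state one.

Cohort sparsity is reported as the bipartite-density complement

    1 − (E_PD + E_DP + E_PO + E_OP) / (2 · |P| · (|D| + |O|)),

the fraction of possible directed patient-event slots left empty. This
formula reproduces the ≈0.9875 value reported for both reference cohorts
from their printed counts. Opposite relations are stored independently —
real extraction pipelines yield unequal directed counts — so transposed
consistency is supported but never assumed.

k-hop neighborhoods are exact shortest-path-distance shells on the
undirected union of all relations. Because every edge joins a patient to
an event node, template-constrained expansion (patients to events at odd
hops, events to patients at even hops) coincides with plain
breadth-first distance, which is what the sampler caches.

## Structural branch: k-hop hierarchical Transformer

For each patient the sampler draws a fixed number of neighbors
(default 32) **with replacement** from each exact-k-hop frontier,
k = 1..4; empty frontiers produce masked slots. With-replacement draws
keep the arrays rectangular; masking guarantees padded slots can neither
attend nor be attended to. Draws are refreshed every epoch (seeded by
epoch index), so the encoder sees a different subgraph sample each pass.

Encoding proceeds in three stages:

1. **Intra-hop encoding.** Each hop's neighbor sequence passes through
   that hop's own Transformer encoder layer (4 heads, feed-forward width
   2d, residuals, per-row normalization). One layer per hop is the
   minimal reading of "an independent Transformer per hop".
2. **Hop attention.** Scaled dot-product attention between the target
   patient embedding and the encoded neighbors of each hop produces one
   summary vector z_k per hop; weights over unmasked slots sum to 1 and
   an empty hop contributes a zero vector. A single projection triple
   (d × d) is shared across hops.
3. **Hierarchical fusion.** The length-K hop sequence is contextualized
   by a hop-level Transformer encoder layer, then multi-head attention
   between the patient embedding and the contextualized hops weights the
   hops (per-head weights sum to 1 over hops). Head outputs
   (d/H each) are concatenated, projected by W_out (d × d), and added to
   the patient embedding through a single residual. Folding the residual
   to one post-projection addition (rather than one per head) keeps the
   printed projection shapes consistent; the degenerate behaviors are
   preserved: all-zero hop summaries return the patient embedding
   unchanged, and identical hop vectors receive uniform weights 1/K.

**Node features.** The cohorts carry no intrinsic node attributes.
Drug and procedure nodes receive free learnable embedding rows (they are
shared across data splits, so they receive gradient from training
patients). Patient rows are *projections of their drug⊕procedure
incidence vectors* (row-L2-normalized, optionally compressed to 256
dimensions by a seeded Gaussian projection) through a learnable matrix.
A free per-patient embedding table was rejected: held-out patients'
rows would never receive gradient, so validation performance stays at
chance while training accuracy climbs — the feature projection restores
generalization without information leakage.

Softmax computations subtract the row-wise maximum before
exponentiation; fully masked rows are defined as exactly zero.

## Denoising branch: dual-view latent diffusion

Two auxiliary patient-patient views are built from the P-D-P and
P-D-P-O-P meta-path adjacencies. Both share the incidence feature matrix
X; a single shallow graph convolution f0 (symmetric normalization
D^{-1/2}(A+I)D^{-1/2}, one linear layer, rows L2-normalized afterwards)
encodes each view into clean latents h0.

The forward process follows the standard closed form
h_t = √ᾱ_t·h0 + √(1−ᾱ_t)·ε with ᾱ_t = Π(1−β_i). The schedule is linear
with β running from 0.1·s to s over T = 50 steps, where the noise scale
s defaults to 1e-5; the published description gives neither T nor the
schedule shape, so the terminal-β reading preserves the intended
low-noise regime (‖h_T − h0‖/‖h0‖ ≪ 0.1 at the default scale).

The noise predictor ε_θ is one 3-layer GCN (hidden width 128) **shared
by both views**; its input concatenates the view's own noisy state, the
*other* view's noisy state (cross-view conditioning) and a 16-dim
sinusoidal embedding of t. A per-node linear skip connects the input
directly to the output: graph convolutions average over neighborhoods,
and on the dense meta-path views the self-loop weight scales like
1/degree, so without the skip the predictor cannot see the node's own
noisy value and node-specific noise is unrecoverable — the skip is what
lets reconstruction actually beat the un-denoised state. Reverse sampling uses deterministic DDIM
(σ_t = 0) over a 10-step subsequence; the published update formula mixes
indices and a product-of-products α̃, and is implemented here as the
standard DDIM update (erratum reading). The two reconstructions are
averaged into h^diff.

The diffusion loss draws one uniform step t and per-view Gaussian noise
and penalizes the mean squared error between predicted and injected
noise, averaged over all entries and both views (a zero predictor scores
≈ 1 under this convention).

## Fusion, objective, training

h^final = LayerNorm(λ·h^HHGAT + (1−λ)·h^diff) with learnable affine and
variance floored at 1e-5; λ defaults to 0.5 (no published value).
A linear softmax classifier produces class probabilities; targets are
label-smoothed, q = (1−μ)·onehot + μ/C with μ = 0.3, and the
classification loss is mean KL(q ‖ p̂). The total loss is the unweighted
sum of classification and diffusion objectives.

Optimization uses Adam at learning rate 0.003 for up to 300 epochs with
a 5-epoch linear learning-rate warmup and global gradient-norm clipping
at 5 — both standard stabilizers for attention stacks that remove an
otherwise long chance-level plateau at small cohort sizes. Each epoch:
neighbor draws are resampled, the denoised table h^diff is refreshed by
one 10-step DDIM pass and then treated as constant for the classifier
loss (the diffusion branch learns through its own loss term, which is
added to every mini-batch objective; backpropagating through the full
sampling chain would multiply the epoch cost by the step count for
little benefit). The checkpoint with the best validation macro-F1 is
kept (early stopping patience 30 by default), and the test report is
computed at that checkpoint. Splits are stratified 50/30/20 with
largest-remainder rounding per class; classes with fewer than three
members always contribute one member to training (with a warning).
Argmax ties break toward the lowest class index. All randomness (splits,
draws, noise) derives from the configured seed.

Micro-F1 pools TP/FP/FN over classes — in this single-label setting it
equals plain accuracy — and Macro-F1 averages per-class F1 with the
0/0 := 0 convention. Validation checkpoint selection is used because the
stopping rule is otherwise unspecified.

Ablation variants are configuration toggles: `my_gcn` replaces the
structural branch with a two-layer GCN over the full typed graph;
`my_onlytrans` removes the diffusion branch (λ = 1, no diffusion loss);
`my_onesub` restricts diffusion to the P-D-P view (the cross-view
condition degenerates to self-conditioning); `my_onlydiff` removes the
structural branch (λ = 0).

## Synthetic cohorts

The generator plants recoverable class structure: each patient gets one
uniform class label (coverage of every class is forced); drug/procedure
event counts are Poisson (means 8 and 3, floored at 1 so no patient is
edgeless before noise); each event comes from the class's preferred
subset with probability `signal_strength`, else uniformly. Preferred
subsets default to |items|/(2C) per class and are disjoint when they
fit. Three noise channels follow: spurious edges added uniformly over
non-edges (count = rate × surviving edges), edges dropped independently,
and labels flipped to a uniformly random other class *after* edge
generation, so features reflect the true class — the harder,
diagnostic-label-error regime. Defaults (600 patients, 90 drugs, 45
procedures, 3 classes, signal 0.9, all noise rates 0.05) give realized
sparsity ≈ 0.92, in the regime of real cohorts though not as extreme.

What the generator does **not** emulate: temporal admission structure,
class imbalance of real disease prevalence, code hierarchies and
correlated co-prescription patterns. Passing tests therefore demonstrate
correct mechanics and recoverability of planted structure, not clinical
performance.

## Problem sizes used by the test suite

Heavier checks are scaled to finish on one CPU: planted-structure
recovery uses the full default cohort (600 patients, 3 seeds, ≤50
epochs, early-stopping patience 12); the ablation comparison uses 240
patients / 36 drugs / 18 procedures at signal 0.6 with all noise rates
0.15 (5 seeds, ≤30 epochs); the denoiser-utility check fits the noise
predictor on 70% of a 240-patient cohort under the default low-noise
schedule and compares reconstruction against the noised state on the
held-out patients. The recoverability-monotonicity check uses two
signal levels and reduced cohorts for the same reason.

## Numerical choices and limitations

* Everything runs in float32 except losses (float64 accumulation); the
  automatic-differentiation engine is an in-repo reverse-mode tape over
  numpy arrays (no external framework dependency).
* Masked softmax adds −1e9 to masked logits and post-multiplies by the
  mask, so fully-masked rows are exactly zero rather than uniform.
* KL computations clamp log arguments at 1e-12.
* Degenerate inputs: empty frontiers mask whole hops; zero-variance rows
  in LayerNorm are floored; graphs without event nodes report sparsity 1
  with a warning.
* The model is transductive with respect to drug/procedure nodes (their
  embeddings are learned from training patients' neighborhoods); unseen
  *event* vocabularies would require retraining.
* Micro/macro-F1 are the only metrics; no calibration or uncertainty
  quantification is attempted.
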
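"""End-to-end training: fusion, classifier, losses, splits and evaluation.

The structural branch (k-hop hierarchical Transformer, or a plain GCN in
the ablation) and the diffusion branch are fused as
``LayerNorm(lambda * h_struct + (1 - lambda) * h_diff)`` and fed to a
linear softmax classifier.  The classification objective is the KL
divergence between label-smoothed targets and predictions; the total loss
adds the diffusion noise-prediction MSE.  Optimization uses Adam with the
denoised embeddings refreshed once per epoch by deterministic DDIM
sampling (the classifier gradient does not propagate through the sampling
chain; the diffusion branch learns through its own loss term).

Ablation variants:

* ``full`` -- both branches (default).
* ``my_gcn`` -- structural branch replaced by a two-layer GCN.
* ``my_onlytrans`` -- diffusion branch removed (lambda forced to 1).
* ``my_onesub`` -- diffusion restricted to the P-D-P view.
* ``my_onlydiff`` -- structural branch removed (lambda forced to 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix

from .autodiff import Adam, Tensor, clip_global_norm, layer_norm, softmax
from .diffusion import (
    AuxiliaryView,
    DenoiserParams,
    NoiseSchedule,
    ViewEncoderParams,
    build_views,
    ddim_reverse,
    diffusion_loss,
    encode_view,
    fuse_views,
    make_schedule,
)
from .hetgraph import HetGraph
from .sampler import KHopIndex, SampledBatch, SamplerConfig, make_batches
from .transformer import (
    EncoderParams,
    GCNEncoderParams,
    encode_batch,
    gcn_encode,
)

VARIANTS = ("full", "my_gcn", "my_onlytrans", "my_onesub", "my_onlydiff")


@dataclass
class TrainConfig:
    learning_rate: float = 0.003
    max_epochs: int = 300
    embed_dim: int = 128
    gcn_layers: int = 3
    heads: int = 4
    label_smoothing: float = 0.3
    noise_strength: float = 1e-5
    diffusion_steps: int = 50
    ddim_steps: int = 10
    k_max: int = 4
    per_hop: int = 32
    batch_size: int = 256
    fusion_lambda: float = 0.5
    split_fractions: Tuple[float, float, float] = (0.5, 0.3, 0.2)
    patience: int = 30
    warmup_epochs: int = 5
    grad_clip: float = 5.0
    feature_dim: int = 256
    seed: int = 0
    variant: str = "full"

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not (0.0 <= self.label_smoothing <= 1.0):
            raise ValueError("label smoothing must lie in [0, 1]")
        if not (0.0 <= self.fusion_lambda <= 1.0):
            raise ValueError("fusion lambda must lie in [0, 1]")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class ClassifierParams:
    """Linear classifier; ``w`` is stored (d, C), the transpose of W_c."""

    w: Tensor
    b: Tensor

    @classmethod
    def create(cls, rng: np.random.Generator, d: int, n_classes: int):
        w = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, n_classes))
        return cls(
            w=Tensor(w.astype(np.float32), requires_grad=True),
            b=Tensor(np.zeros(n_classes, np.float32), requires_grad=True),
        )

    def params(self) -> List[Tensor]:
        return [self.w, self.b]


@dataclass
class EvalReport:
    confusion: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    micro_f1: float
    macro_f1: float
    per_class_f1: np.ndarray
    n: int

    def to_dict(self) -> dict:
        return {
            "micro_f1": float(self.micro_f1),
            "macro_f1": float(self.macro_f1),
            "per_class_f1": [float(x) for x in self.per_class_f1],
        }


# ---------------------------------------------------------------------------
# losses and metrics
def fuse_final(h_struct, h_diff, lam: float,
               ln_gamma: Tensor, ln_beta: Tensor) -> Tensor:
    """Per-row normalized convex combination of the two branches."""
    h_struct = h_struct if isinstance(h_struct, Tensor) else Tensor(h_struct)
    h_diff = h_diff if isinstance(h_diff, Tensor) else Tensor(h_diff)
    mix = h_struct * float(lam) + h_diff * float(1.0 - lam)
    return layer_norm(mix, ln_gamma, ln_beta)


def classify(h_final, params: ClassifierParams) -> Tensor:
    """Row-stochastic class probabilities softmax(h W + b)."""
    h = h_final if isinstance(h_final, Tensor) else Tensor(h_final)
    return softmax(h @ params.w + params.b, axis=-1)


def predict_classes(probs: np.ndarray) -> np.ndarray:
    """Argmax with ties broken toward the lowest class index."""
    return np.argmax(probs, axis=-1)


def smooth_labels(y, mu: float, n_classes: int) -> np.ndarray:
    """(1 - mu) * onehot(y) + mu / C; accepts a scalar or a vector."""
    ys = np.atleast_1d(np.asarray(y, dtype=np.int64))
    out = np.full((len(ys), n_classes), mu / n_classes, dtype=np.float64)
    out[np.arange(len(ys)), ys] += 1.0 - mu
    return out[0] if np.isscalar(y) or np.ndim(y) == 0 else out


def classification_loss(predicted, smoothed: np.ndarray) -> Tensor:
    """Mean KL(smoothed || predicted) over patients."""
    p = predicted if isinstance(predicted, Tensor) else Tensor(predicted)
    q = np.atleast_2d(np.asarray(smoothed, dtype=np.float64))
    # target entropy term is constant; guard 0*log(0)
    qlogq = np.where(q > 0, q * np.log(np.maximum(q, 1e-300)), 0.0).sum()
    if p.ndim == 1:
        p = p.reshape(1, -1)
    cross = (Tensor(q) * (p + 1e-12).log()).sum()
    return (Tensor(np.float64(qlogq)) - cross) * (1.0 / q.shape[0])


def total_loss(cls_loss, diff_loss):
    """Unweighted sum of classification and diffusion objectives."""
    return cls_loss + diff_loss


def split_patients(
    labels: Sequence[int],
    fractions: Tuple[float, float, float] = (0.5, 0.3, 0.2),
    seed: int = 0,
) -> Tuple[List[int], List[int], List[int]]:
    """Deterministic stratified train/val/test split.

    Within each class the per-split sizes follow largest-remainder
    rounding, so each split's class proportions are within one member of
    the global proportions.  Classes with fewer than three members always
    contribute at least one member to the training split (with a warning).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    labels = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(seed)
    splits: Tuple[List[int], ...] = ([], [], [])
    for c in np.unique(labels):
        members = rng.permutation(np.flatnonzero(labels == c))
        n_c = len(members)
        raw = np.array(fractions) * n_c
        base = np.floor(raw).astype(int)
        order = np.argsort(-(raw - base))
        for i in range(n_c - base.sum()):
            base[order[i]] += 1
        if n_c < 3:
            warnings.warn(
                f"class {c} has only {n_c} member(s); forcing one into train"
            )
        if base[0] == 0 and n_c > 0:
            donor = int(np.argmax(base))
            base[donor] -= 1
            base[0] += 1
        cuts = np.cumsum(base)[:-1]
        for part, chunk in zip(splits, np.split(members, cuts)):
            part.extend(int(i) for i in chunk)
    return splits[0], splits[1], splits[2]


def evaluate(y_true: Sequence[int], y_pred: Sequence[int],
             n_classes: int) -> EvalReport:
    """Confusion counts plus pooled (micro) and averaged (macro) F1.

    With single-label predictions the pooled F1 equals plain accuracy.
    Per-class F1 is defined as 0 when its denominator vanishes.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    tp = np.diag(cm).astype(np.int64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    micro_den = 2 * tp.sum() + fp.sum() + fn.sum()
    micro = 2.0 * tp.sum() / micro_den if micro_den else 0.0
    den = 2 * tp + fp + fn
    per_class = np.where(den > 0, 2.0 * tp / np.maximum(den, 1), 0.0)
    return EvalReport(
        confusion=cm, tp=tp, fp=fp, fn=fn,
        micro_f1=float(micro), macro_f1=float(per_class.mean()),
        per_class_f1=per_class, n=n_classes,
    )


# ---------------------------------------------------------------------------
# model assembly
@dataclass
class ModelParams:
    encoder: Optional[EncoderParams]
    gcn_embedding: Optional["NodeEmbeddingParams"]
    gcn_encoder: Optional[GCNEncoderParams]
    view_encoder: Optional[ViewEncoderParams]
    denoiser: Optional[DenoiserParams]
    classifier: ClassifierParams
    ln_gamma: Tensor
    ln_beta: Tensor

    def params(self) -> List[Tensor]:
        out: List[Tensor] = []
        if self.encoder is not None:
            out += self.encoder.params()
        if self.gcn_embedding is not None:
            out += self.gcn_embedding.params()
        if self.gcn_encoder is not None:
            out += self.gcn_encoder.params()
        if self.view_encoder is not None:
            out += self.view_encoder.params()
        if self.denoiser is not None:
            out += self.denoiser.params()
        out += self.classifier.params()
        out += [self.ln_gamma, self.ln_beta]
        return out

    def snapshot(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def restore(self, snap: List[np.ndarray]) -> None:
        for p, s in zip(self.params(), snap):
            p.data[...] = s


def _effective_lambda(config: TrainConfig) -> float:
    if config.variant == "my_onlydiff":
        return 0.0
    if config.variant == "my_onlytrans":
        return 1.0
    return config.fusion_lambda


@dataclass
class TrainState:
    """Static per-run context shared across epochs."""

    graph: HetGraph
    labels: np.ndarray
    n_classes: int
    khop: Optional[KHopIndex]
    views: Optional[Tuple[AuxiliaryView, AuxiliaryView]]
    schedule: Optional[NoiseSchedule]
    adj_norm_union: Optional[object]
    model: ModelParams
    sampler_cfg: Optional[SamplerConfig]


def _build_state(graph: HetGraph, labels: Sequence[int],
                 config: TrainConfig) -> TrainState:
    labels = np.asarray(labels, dtype=np.int64)
    n_classes = int(labels.max()) + 1
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    d = config.embed_dim
    uses_diffusion = config.variant != "my_onlytrans"
    uses_transformer = config.variant in ("full", "my_onlytrans", "my_onesub")
    uses_gcn = config.variant == "my_gcn"

    from .diffusion import patient_incidence_features

    feats = patient_incidence_features(
        graph, max_dim=config.feature_dim, seed=config.seed
    )
    encoder = khop = sampler_cfg = None
    gcn_embedding = gcn_encoder = adj_norm_union = None
    if uses_transformer:
        encoder = EncoderParams.create(
            rng, graph.n_nodes, d=d, heads=config.heads, k_max=config.k_max,
            n_patients=graph.n_patients, patient_features=feats,
        )
        sampler_cfg = SamplerConfig(
            k_max=config.k_max, per_hop=config.per_hop,
            batch_size=config.batch_size, seed=config.seed,
        )
        khop = KHopIndex(graph, config.k_max)
    elif uses_gcn:
        from .diffusion import _sym_normalize
        from .transformer import NodeEmbeddingParams

        gcn_embedding = NodeEmbeddingParams.create(
            rng, graph.n_nodes, graph.n_patients, d, feats
        )
        gcn_encoder = GCNEncoderParams.create(rng, d)
        adj_norm_union = _sym_normalize(graph.union_adjacency())

    views = schedule = view_encoder = denoiser = None
    if uses_diffusion:
        v1, v2 = build_views(
            graph, feature_dim=config.feature_dim, seed=config.seed
        )
        if config.variant == "my_onesub":
            v2 = v1
        views = (v1, v2)
        schedule = make_schedule(
            T=config.diffusion_steps,
            noise_strength=config.noise_strength,
            ddim_steps=config.ddim_steps,
        )
        view_encoder = ViewEncoderParams.create(
            rng, v1.features.shape[1], d
        )
        denoiser = DenoiserParams.create(rng, d)

    classifier = ClassifierParams.create(rng, d, n_classes)
    model = ModelParams(
        encoder=encoder, gcn_embedding=gcn_embedding, gcn_encoder=gcn_encoder,
        view_encoder=view_encoder, denoiser=denoiser, classifier=classifier,
        ln_gamma=Tensor(np.ones(d, np.float32), requires_grad=True),
        ln_beta=Tensor(np.zeros(d, np.float32), requires_grad=True),
    )
    return TrainState(
        graph=graph, labels=labels, n_classes=n_classes, khop=khop,
        views=views, schedule=schedule, adj_norm_union=adj_norm_union,
        model=model, sampler_cfg=sampler_cfg,
    )


def _refresh_h_diff(state: TrainState, config: TrainConfig,
                    rng: np.random.Generator) -> Optional[np.ndarray]:
    """Encode views and run DDIM to produce this epoch's denoised table."""
    if state.views is None:
        return None
    v1, v2 = state.views
    encode_view(v1, state.model.view_encoder)
    if v2 is not v1:
        encode_view(v2, state.model.view_encoder)
    r1 = ddim_reverse(v1, v2, state.schedule, state.model.denoiser, rng)
    if v2 is v1:
        return r1
    r2 = ddim_reverse(v2, v1, state.schedule, state.model.denoiser, rng)
    return fuse_views(r1, r2)


def _struct_embed(state: TrainState, config: TrainConfig,
                  batch: Optional[SampledBatch],
                  patient_rows: np.ndarray) -> Optional[Tensor]:
    if state.model.encoder is not None:
        return encode_batch(batch, state.model.encoder)
    if state.model.gcn_encoder is not None:
        return gcn_encode(
            state.adj_norm_union, state.model.gcn_embedding.full_table(),
            patient_rows, state.model.gcn_encoder,
        )
    return None


def _forward_logits(state: TrainState, config: TrainConfig,
                    batch: Optional[SampledBatch],
                    patient_rows: np.ndarray,
                    h_diff: Optional[np.ndarray]) -> Tensor:
    lam = _effective_lambda(config)
    d = config.embed_dim
    h_s = _struct_embed(state, config, batch, patient_rows)
    if h_s is None:
        h_s = Tensor(np.zeros((len(patient_rows), d), np.float32))
    if h_diff is None:
        h_d = Tensor(np.zeros((len(patient_rows), d), np.float32))
    else:
        h_d = Tensor(h_diff[patient_rows].astype(np.float32))
    h_final = fuse_final(h_s, h_d, lam,
                         state.model.ln_gamma, state.model.ln_beta)
    return classify(h_final, state.model.classifier)


def _eval_split(state: TrainState, config: TrainConfig,
                idx: Sequence[int], h_diff, rng) -> EvalReport:
    idx = np.asarray(idx, dtype=np.int64)
    preds = np.empty(len(idx), dtype=np.int64)
    if state.model.encoder is not None:
        batches = make_batches(state.khop, idx, state.sampler_cfg,
                               rng=rng, shuffle=False)
        pos = 0
        for b in batches:
            probs = _forward_logits(
                state, config, b, b.patient_indices, h_diff
            ).data
            preds[pos : pos + len(b.patient_indices)] = predict_classes(probs)
            pos += len(b.patient_indices)
    else:
        probs = _forward_logits(state, config, None, idx, h_diff).data
        preds[:] = predict_classes(probs)
    return evaluate(state.labels[idx], preds, state.n_classes)


def train_model(
    graph: HetGraph, labels: Sequence[int], config: TrainConfig
) -> Tuple[ModelParams, EvalReport, List[Dict]]:
    """Fit the model and return (params, test report, training log).

    Per epoch: resample neighbor draws, refresh the denoised embedding
    table by DDIM, then take one Adam step per mini-batch on
    L_cls + L_diff.  The checkpoint with the best validation macro-F1 is
    selected (patience-based early stopping); the test report is computed
    at that checkpoint.  Deterministic given ``config.seed``.
    """
    state = _build_state(graph, labels, config)
    train_idx, val_idx, test_idx = split_patients(
        state.labels, config.split_fractions, seed=config.seed
    )
    opt = Adam(state.model.params(), lr=config.learning_rate)
    uses_diffusion = state.views is not None

    log: List[Dict] = []
    best_val, best_snap, best_epoch = -1.0, None, -1
    for epoch in range(config.max_epochs):
        ep_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1000 + epoch])
        )
        # linear learning-rate warmup stabilizes the first Adam steps
        if config.warmup_epochs > 0:
            opt.lr = config.learning_rate * min(
                1.0, (epoch + 1) / config.warmup_epochs
            )
        h_diff = _refresh_h_diff(state, config, ep_rng)

        if state.model.encoder is not None:
            batches = make_batches(
                state.khop, train_idx, state.sampler_cfg, rng=ep_rng
            )
        else:
            perm = ep_rng.permutation(np.asarray(train_idx, dtype=np.int64))
            batches = [
                perm[i : i + config.batch_size]
                for i in range(0, len(perm), config.batch_size)
            ]

        ep_cls, ep_diff, n_b = 0.0, 0.0, 0
        for b in batches:
            rows = b.patient_indices if isinstance(b, SampledBatch) else b
            sampled = b if isinstance(b, SampledBatch) else None
            probs = _forward_logits(state, config, sampled, rows, h_diff)
            targets = smooth_labels(
                state.labels[rows], config.label_smoothing, state.n_classes
            )
            l_cls = classification_loss(probs, targets)
            if uses_diffusion:
                v1, v2 = state.views
                encode_view(v1, state.model.view_encoder)
                if v2 is not v1:
                    encode_view(v2, state.model.view_encoder)
                l_diff = diffusion_loss(
                    v1, v2, state.schedule, state.model.denoiser, ep_rng
                )
            else:
                l_diff = Tensor(np.float64(0.0))
            loss = total_loss(l_cls, l_diff)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            if config.grad_clip > 0:
                clip_global_norm(state.model.params(), config.grad_clip)
            opt.step()
            ep_cls += float(l_cls.data)
            ep_diff += float(l_diff.data)
            n_b += 1

        eval_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 900_000 + epoch])
        )
        val_report = _eval_split(state, config, val_idx, h_diff, eval_rng)
        log.append({
            "epoch": epoch,
            "loss_cls": ep_cls / max(n_b, 1),
            "loss_diff": ep_diff / max(n_b, 1),
            "val_macro_f1": val_report.macro_f1,
        })
        if val_report.macro_f1 > best_val:
            best_val = val_report.macro_f1
            best_snap = state.model.snapshot()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break

    if best_snap is not None:
        state.model.restore(best_snap)
    final_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 424242])
    )
    h_diff = _refresh_h_diff(state, config, final_rng)
    test_report = _eval_split(state, config, test_idx, h_diff, final_rng)
    return state.model, test_report, log
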
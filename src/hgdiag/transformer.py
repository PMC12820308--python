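"""K-hop hierarchical Transformer over sampled neighborhoods.

Three stages per batch of patients:

1. *Intra-hop encoding* -- each hop's fixed-width neighbor sequence passes
   through that hop's own Transformer encoder layer (masked multi-head
   self-attention + position-wise feed-forward, residuals and per-row
   normalization).  Masked slots neither attend nor are attended to.
2. *Hop attention* -- scaled dot-product attention between the target
   patient embedding and the encoded neighbors of each hop produces one
   summary vector z_k per hop; weights over unmasked slots sum to 1 and an
   empty hop yields z_k = 0.
3. *Hierarchical fusion* -- the length-K hop sequence is contextualized by
   a hop-level Transformer encoder layer, then multi-head attention between
   the patient embedding and the contextualized hops weights the hops
   (per-head weights sum to 1 over hops); head outputs are concatenated,
   linearly projected, and added residually to the patient embedding.

All learnable arrays live in :class:`EncoderParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .autodiff import Tensor, concat, layer_norm, softmax
from .sampler import SampledBatch

NEG_BIG = 1e9


def _init(rng: np.random.Generator, shape, scale: float = None) -> Tensor:
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return Tensor(
        rng.normal(0.0, scale, size=shape).astype(np.float32),
        requires_grad=True,
    )


@dataclass
class TransformerLayerParams:
    """One encoder layer: multi-head self-attention + feed-forward."""

    wq: Tensor
    wk: Tensor
    wv: Tensor
    wo: Tensor
    ff1: Tensor
    ff1_b: Tensor
    ff2: Tensor
    ff2_b: Tensor
    ln1_g: Tensor
    ln1_b: Tensor
    ln2_g: Tensor
    ln2_b: Tensor
    heads: int

    @classmethod
    def create(cls, rng, d: int, heads: int, ff_mult: int = 2):
        return cls(
            wq=_init(rng, (d, d)), wk=_init(rng, (d, d)),
            wv=_init(rng, (d, d)), wo=_init(rng, (d, d)),
            ff1=_init(rng, (d, ff_mult * d)),
            ff1_b=Tensor(np.zeros(ff_mult * d, np.float32), requires_grad=True),
            ff2=_init(rng, (ff_mult * d, d)),
            ff2_b=Tensor(np.zeros(d, np.float32), requires_grad=True),
            ln1_g=Tensor(np.ones(d, np.float32), requires_grad=True),
            ln1_b=Tensor(np.zeros(d, np.float32), requires_grad=True),
            ln2_g=Tensor(np.ones(d, np.float32), requires_grad=True),
            ln2_b=Tensor(np.zeros(d, np.float32), requires_grad=True),
            heads=heads,
        )

    def params(self) -> List[Tensor]:
        return [self.wq, self.wk, self.wv, self.wo, self.ff1, self.ff1_b,
                self.ff2, self.ff2_b, self.ln1_g, self.ln1_b,
                self.ln2_g, self.ln2_b]


def encoder_layer(x: Tensor, p: TransformerLayerParams,
                  mask: np.ndarray = None) -> Tensor:
    """Apply one Transformer encoder layer to (..., S, d) sequences.

    ``mask`` is a boolean (..., S) array; masked slots are excluded as keys
    and their outputs are zeroed.
    """
    *lead, S, d = x.shape
    H = p.heads
    dh = d // H

    def split_heads(t: Tensor) -> Tensor:
        t = t.reshape(*lead, S, H, dh)
        axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
        return t.transpose(*axes)              # (..., H, S, dh)

    q = split_heads(x @ p.wq)
    k = split_heads(x @ p.wk)
    v = split_heads(x @ p.wv)
    kt_axes = tuple(range(len(lead) + 1)) + (len(lead) + 2, len(lead) + 1)
    scores = (q @ k.transpose(*kt_axes)) * (1.0 / np.sqrt(dh))  # (...,H,S,S)
    key_mask = None
    if mask is not None:
        key_mask = np.broadcast_to(
            mask[..., None, None, :], scores.shape
        )
    att = softmax(scores, axis=-1, mask=key_mask)
    ctx = att @ v                               # (..., H, S, dh)
    inv_axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
    ctx = ctx.transpose(*inv_axes).reshape(*lead, S, d)
    h = layer_norm(x + ctx @ p.wo, p.ln1_g, p.ln1_b)
    ff = ((h @ p.ff1 + p.ff1_b).relu()) @ p.ff2 + p.ff2_b
    out = layer_norm(h + ff, p.ln2_g, p.ln2_b)
    if mask is not None:
        out = out * mask[..., None].astype(np.float32)
    return out


@dataclass
class NodeEmbeddingParams:
    """Shared node representations for the whole typed node universe.

    Patient rows are projections of their drug/procedure incidence
    features through a learnable matrix, so held-out patients receive
    meaningful embeddings; drug and procedure nodes, which are shared
    between splits, keep free embedding-table rows.  When
    ``patient_features`` is None patients also get free table rows.
    """

    n_patients: int
    patient_features: Optional[np.ndarray]    # (N_p, d_x) constant or None
    w_feat: Optional[Tensor]                  # (d_x, d)
    table: Tensor                             # (n_nodes - N_p or n_nodes, d)

    @classmethod
    def create(cls, rng: np.random.Generator, n_nodes: int, n_patients: int,
               d: int, patient_features: Optional[np.ndarray] = None):
        if patient_features is None:
            return cls(n_patients=n_patients, patient_features=None,
                       w_feat=None, table=_init(rng, (n_nodes, d), scale=0.1))
        feats = np.ascontiguousarray(patient_features, dtype=np.float32)
        return cls(
            n_patients=n_patients,
            patient_features=feats,
            w_feat=_init(rng, (feats.shape[1], d)),
            table=_init(rng, (n_nodes - n_patients, d), scale=0.1),
        )

    def full_table(self) -> Tensor:
        if self.patient_features is None:
            return self.table
        patient_rows = Tensor(self.patient_features) @ self.w_feat
        return concat([patient_rows, self.table], axis=0)

    def params(self) -> List[Tensor]:
        return [self.table] if self.w_feat is None else [self.w_feat,
                                                         self.table]


@dataclass
class EncoderParams:
    """All learnable weights of the hierarchical k-hop encoder."""

    d: int
    heads: int
    k_max: int
    embedding: NodeEmbeddingParams
    intra: List[TransformerLayerParams]       # one layer per hop
    hop_wq: Tensor                            # (d, d) hop-level attention
    hop_wk: Tensor
    hop_wv: Tensor
    hier_layer: TransformerLayerParams        # hop-sequence contextualizer
    hier_wq: Tensor                           # (d, d) split into H heads
    hier_wk: Tensor
    hier_wv: Tensor
    w_out: Tensor                             # (H*dh, d) final projection

    @classmethod
    def create(cls, rng: np.random.Generator, n_nodes: int,
               d: int = 128, heads: int = 4, k_max: int = 4,
               n_patients: int = 0,
               patient_features: Optional[np.ndarray] = None):
        if d % heads:
            raise ValueError("embedding dim must be divisible by head count")
        return cls(
            d=d, heads=heads, k_max=k_max,
            embedding=NodeEmbeddingParams.create(
                rng, n_nodes, n_patients, d, patient_features
            ),
            intra=[TransformerLayerParams.create(rng, d, heads)
                   for _ in range(k_max)],
            hop_wq=_init(rng, (d, d)),
            hop_wk=_init(rng, (d, d)),
            hop_wv=_init(rng, (d, d)),
            hier_layer=TransformerLayerParams.create(rng, d, heads),
            hier_wq=_init(rng, (d, d)),
            hier_wk=_init(rng, (d, d)),
            hier_wv=_init(rng, (d, d)),
            w_out=_init(rng, (d, d)),
        )

    def params(self) -> List[Tensor]:
        out = self.embedding.params() + [
            self.hop_wq, self.hop_wk, self.hop_wv,
            self.hier_wq, self.hier_wk, self.hier_wv, self.w_out,
        ]
        for layer in self.intra:
            out += layer.params()
        out += self.hier_layer.params()
        return out


def intra_hop_encode(batch: SampledBatch, params: EncoderParams,
                     table: Optional[Tensor] = None) -> Tensor:
    """Encode each hop's neighbor sequence with its own Transformer layer.

    Returns a (B, k_max, per_hop, d) tensor; masked slots are zero.
    """
    if table is None:
        table = params.embedding.full_table()
    outs = []
    B, K, S = batch.mask.shape
    for h in range(params.k_max):
        outs.append(
            encoder_layer(
                table.take_rows(batch.neighbor_indices[:, h]),
                params.intra[h],
                mask=batch.mask[:, h],
            )
        )
    return concat([o.reshape(B, 1, S, params.d) for o in outs], axis=1)


def hop_attention(target: Tensor, encoded: Tensor, mask: np.ndarray,
                  params: EncoderParams) -> Tensor:
    """Attention-weighted hop summaries z_k (B, k_max, d).

    ``target`` is (B, d); ``encoded`` is (B, k_max, per_hop, d).  Weights
    are a masked softmax over the per-hop slots; an empty hop gives zeros.
    """
    d = params.d
    q = (target @ params.hop_wq).reshape(-1, 1, 1, d)          # B,1,1,d
    keys = encoded @ params.hop_wk                             # B,K,S,d
    vals = encoded @ params.hop_wv
    scores = (q * keys).sum(axis=-1) * (1.0 / np.sqrt(d))      # B,K,S
    alpha = softmax(scores, axis=-1, mask=mask)
    z = (alpha.reshape(*alpha.shape, 1) * vals).sum(axis=2)    # B,K,d
    return z


def hierarchical_fuse(target: Tensor, z: Tensor,
                      params: EncoderParams) -> Tensor:
    """Fuse the hop sequence into the final structural embedding (B, d)."""
    B, K, d = z.shape
    H = params.heads
    dh = d // H
    zc = encoder_layer(z, params.hier_layer)                   # B,K,d
    q = (target @ params.hier_wq).reshape(B, H, 1, dh)
    keys = (zc @ params.hier_wk).reshape(B, K, H, dh).transpose(0, 2, 1, 3)
    vals = (zc @ params.hier_wv).reshape(B, K, H, dh).transpose(0, 2, 1, 3)
    beta = softmax(
        (q * keys).sum(axis=-1, keepdims=True) * (1.0 / np.sqrt(dh)), axis=2
    )                                                           # B,H,K,1
    heads = (beta * vals).sum(axis=2)                           # B,H,dh
    fused = heads.reshape(B, d) @ params.w_out
    return target + fused


def encode_batch(batch: SampledBatch, params: EncoderParams) -> Tensor:
    """Full pipeline: sampled batch -> structural patient embeddings (B, d)."""
    table = params.embedding.full_table()
    target = table.take_rows(batch.patient_indices)
    enc = intra_hop_encode(batch, params, table=table)
    z = hop_attention(target, enc, batch.mask, params)
    return hierarchical_fuse(target, z, params)


# ---------------------------------------------------------------------------
# Plain-GCN structural encoder (ablation: replaces the k-hop Transformer)
@dataclass
class GCNEncoderParams:
    w1: Tensor
    w2: Tensor

    @classmethod
    def create(cls, rng, d: int):
        return cls(w1=_init(rng, (d, d)), w2=_init(rng, (d, d)))

    def params(self) -> List[Tensor]:
        return [self.w1, self.w2]


def gcn_encode(adj_norm, embedding: Tensor, patient_rows: np.ndarray,
               params: GCNEncoderParams) -> Tensor:
    """Two-layer graph convolution over the full typed graph union."""
    from .autodiff import spmm

    h = spmm(adj_norm, embedding @ params.w1).relu()
    h = spmm(adj_norm, h @ params.w2)
    return h.take_rows(patient_rows)
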
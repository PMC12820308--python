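"""Dual-view latent diffusion denoiser over meta-path auxiliary subgraphs.

Two patient-patient auxiliary views are built from the shared-drug
(``P-D-P``) and drug-then-procedure (``P-D-P-O-P``) meta-paths.  A shallow
graph convolution encodes each view into clean latent embeddings h0.  The
forward process corrupts h0 with Gaussian noise following a variance
schedule (h_t = sqrt(abar_t) h0 + sqrt(1-abar_t) eps); a single shared
3-layer GCN denoiser, conditioned on the *other* view's noisy state and a
sinusoidal time embedding, predicts the injected noise.  Deterministic DDIM
sampling over a short step subsequence reconstructs denoised embeddings,
and the two reconstructions are averaged into the final denoised patient
representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, concat, l2_normalize_rows, spmm
from .hetgraph import PDP, PDPOP, HetGraph, compose_metapath

TIME_EMBED_DIM = 16


def _sym_normalize(adj: sp.spmatrix) -> sp.csr_matrix:
    """D^{-1/2} (A + I) D^{-1/2} graph-convolution propagation matrix."""
    a = sp.csr_matrix(adj, dtype=np.float32)
    a = a + sp.eye(a.shape[0], dtype=np.float32, format="csr")
    deg = np.asarray(a.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    dmat = sp.diags(dinv.astype(np.float32))
    return (dmat @ a @ dmat).tocsr()


@dataclass
class AuxiliaryView:
    view_id: int
    adjacency: sp.csr_matrix            # binary, symmetric, zero diagonal
    adj_norm: sp.csr_matrix             # propagation matrix
    features: np.ndarray                # (N, d_x) row-L2-normalized
    prop_features: np.ndarray           # adj_norm @ features, precomputed
    h0: Optional[Tensor] = None         # clean embeddings, set by encode_view


def patient_incidence_features(
    graph: HetGraph, max_dim: int = 256, seed: int = 0
) -> np.ndarray:
    """Row-L2-normalized binary incidence of patients over drugs+procedures.

    When the raw dimension exceeds ``max_dim`` a seeded Gaussian random
    projection compresses it (the cohorts carry no intrinsic attributes, so
    incidence is the natural content-bearing feature).
    """
    x = sp.hstack(
        [graph.relation_adjacency["P-D"], graph.relation_adjacency["P-O"]]
    ).toarray().astype(np.float32)
    if x.shape[1] > max_dim:
        rng = np.random.default_rng(seed)
        proj = rng.normal(
            0.0, 1.0 / np.sqrt(max_dim), size=(x.shape[1], max_dim)
        ).astype(np.float32)
        x = x @ proj
    norms = np.sqrt((x * x).sum(axis=1, keepdims=True))
    return x / np.maximum(norms, 1e-12)


def build_views(
    graph: HetGraph, feature_dim: int = 256, seed: int = 0
) -> Tuple[AuxiliaryView, AuxiliaryView]:
    """Construct the P-D-P and P-D-P-O-P auxiliary patient views."""
    if graph.n_patients < 1:
        raise ValueError("no patients")
    x = patient_incidence_features(graph, max_dim=feature_dim, seed=seed)
    views = []
    for vid, path in ((1, PDP), (2, PDPOP)):
        a = compose_metapath(graph, path)
        an = _sym_normalize(a)
        views.append(
            AuxiliaryView(
                view_id=vid, adjacency=a, adj_norm=an, features=x,
                prop_features=(an @ x),
            )
        )
    return views[0], views[1]


@dataclass
class ViewEncoderParams:
    """Shallow GCN f0 shared by both auxiliary views."""

    w: Tensor

    @classmethod
    def create(cls, rng: np.random.Generator, d_x: int, d: int):
        w = rng.normal(0.0, 1.0 / np.sqrt(d_x), size=(d_x, d))
        return cls(w=Tensor(w.astype(np.float32), requires_grad=True))

    def params(self) -> List[Tensor]:
        return [self.w]


def encode_view(view: AuxiliaryView, enc: ViewEncoderParams) -> Tensor:
    """h0 = row-normalized shallow graph convolution of the view features."""
    h0 = l2_normalize_rows(Tensor(view.prop_features) @ enc.w)
    view.h0 = h0
    return h0


@dataclass
class NoiseSchedule:
    """Linear beta schedule with cumulative signal fractions abar."""

    T: int
    beta: np.ndarray
    alpha_bar: np.ndarray
    sigma: np.ndarray
    ddim_steps: int

    def ddim_subsequence(self) -> np.ndarray:
        """Descending step subsequence T = t_1 > ... > t_m >= 1."""
        steps = np.unique(
            np.round(np.linspace(self.T, 1, self.ddim_steps)).astype(int)
        )[::-1]
        return steps


def make_schedule(
    T: int = 50, noise_strength: float = 1e-5, ddim_steps: int = 10
) -> NoiseSchedule:
    """Betas linearly spaced from 0.1*noise_strength to noise_strength."""
    if T < 1:
        raise ValueError("invalid schedule")
    if not (0.0 < noise_strength < 1.0):
        raise ValueError("invalid schedule")
    beta = np.linspace(0.1 * noise_strength, noise_strength, T)
    alpha_bar = np.cumprod(1.0 - beta)
    return NoiseSchedule(
        T=T, beta=beta, alpha_bar=alpha_bar,
        sigma=np.zeros(T), ddim_steps=min(ddim_steps, T),
    )


def _abar(schedule: NoiseSchedule, t: int) -> float:
    if not (1 <= t <= schedule.T):
        raise ValueError(f"step {t} outside schedule 1..{schedule.T}")
    return float(schedule.alpha_bar[t - 1])


def forward_diffuse(
    h0, t: int, schedule: NoiseSchedule,
    rng: Optional[np.random.Generator] = None,
    noise: Optional[np.ndarray] = None,
):
    """Closed-form noising h_t = sqrt(abar) h0 + sqrt(1-abar) eps.

    Works on Tensors (differentiable w.r.t. h0) and plain arrays.  Pass
    ``noise`` to fix the Gaussian draw; otherwise it is drawn from ``rng``.
    Returns ``(h_t, eps)``.
    """
    ab = _abar(schedule, t)
    data = h0.data if isinstance(h0, Tensor) else np.asarray(h0)
    if noise is None:
        if rng is None:
            raise ValueError("either rng or noise must be given")
        noise = rng.standard_normal(data.shape).astype(data.dtype)
    h_t = h0 * np.sqrt(ab) + noise * np.sqrt(1.0 - ab)
    return h_t, noise


def time_embedding(t: int, dim: int = TIME_EMBED_DIM) -> np.ndarray:
    """Sinusoidal embedding of a diffusion step."""
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)]).astype(np.float32)


@dataclass
class DenoiserParams:
    """Shared 3-layer GCN noise predictor eps_theta (hidden dim 128).

    A per-node linear skip from the network input to the output lets the
    predictor use its *own* noisy value directly: graph convolutions
    average over (often dense) neighborhoods, so without the skip the
    self-contribution shrinks like 1/degree and node-specific noise is
    unrecoverable.
    """

    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor
    w3: Tensor
    b3: Tensor
    w_skip: Tensor

    @classmethod
    def create(cls, rng: np.random.Generator, d: int,
               hidden: int = 128, t_dim: int = TIME_EMBED_DIM):
        d_in = 2 * d + t_dim

        def mk(fan_in, fan_out):
            w = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out))
            return Tensor(w.astype(np.float32), requires_grad=True)

        def bias(n):
            return Tensor(np.zeros(n, np.float32), requires_grad=True)

        return cls(
            w1=mk(d_in, hidden), b1=bias(hidden),
            w2=mk(hidden, hidden), b2=bias(hidden),
            w3=mk(hidden, d), b3=bias(d),
            w_skip=Tensor(np.zeros((d_in, d), np.float32),
                          requires_grad=True),
        )

    def params(self) -> List[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3,
                self.w_skip]


def predict_noise(
    h_t_own, t: int, h_t_other, view: AuxiliaryView, params: DenoiserParams
) -> Tensor:
    """eps_hat from the shared GCN, conditioned on the cross view and t."""
    own = h_t_own if isinstance(h_t_own, Tensor) else Tensor(h_t_own)
    other = h_t_other if isinstance(h_t_other, Tensor) else Tensor(h_t_other)
    n = own.shape[0]
    temb = np.broadcast_to(time_embedding(t), (n, TIME_EMBED_DIM))
    x = concat([own, other, Tensor(np.ascontiguousarray(temb))], axis=-1)
    a = view.adj_norm
    h = spmm(a, x @ params.w1 + params.b1).relu()
    h = spmm(a, h @ params.w2 + params.b2).relu()
    return spmm(a, h @ params.w3 + params.b3) + x @ params.w_skip


NoisePredictor = Callable[[np.ndarray, int, np.ndarray], np.ndarray]


def ddim_reverse(
    view: AuxiliaryView,
    other_view: AuxiliaryView,
    schedule: NoiseSchedule,
    params: Optional[DenoiserParams],
    rng: np.random.Generator,
    predictor: Optional[NoisePredictor] = None,
    initial_noise: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Deterministic DDIM reconstruction of the clean embeddings.

    Starts from the fully-noised state h_T of both views and iterates the
    sigma=0 update over the step subsequence; returns the final clean-state
    estimate x0_hat for ``view``.  ``predictor`` overrides the learned
    denoiser (used by the algebraic-inversion check).
    """
    if view.h0 is None or other_view.h0 is None:
        raise ValueError("views must be encoded first")
    h0_own = view.h0.data
    h0_oth = other_view.h0.data
    T = schedule.T
    ht, _ = forward_diffuse(h0_own, T, schedule, rng=rng, noise=initial_noise)
    ht_oth, _ = forward_diffuse(h0_oth, T, schedule, rng=rng)

    def _eps(h, t, h_other):
        if predictor is not None:
            return np.asarray(predictor(h, t, h_other))
        return predict_noise(h, t, h_other, view, params).data

    steps = schedule.ddim_subsequence()
    x0 = h0_own  # overwritten below; placeholder for the t-loop result
    for i, t in enumerate(steps):
        ab = _abar(schedule, int(t))
        eps = _eps(ht, int(t), ht_oth)
        x0 = (ht - np.sqrt(1.0 - ab) * eps) / np.sqrt(ab)
        if i + 1 < len(steps):
            ab_next = _abar(schedule, int(steps[i + 1]))
            ht = np.sqrt(ab_next) * x0 + np.sqrt(1.0 - ab_next) * eps
    return x0


def diffusion_loss(
    view1: AuxiliaryView,
    view2: AuxiliaryView,
    schedule: NoiseSchedule,
    params: DenoiserParams,
    rng: np.random.Generator,
    t: Optional[int] = None,
    fixed_noise: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> Tensor:
    """Noise-prediction MSE, averaged over entries and both views.

    A single step t is drawn uniformly from 1..T; each view gets its own
    Gaussian draw.  The mean is per coordinate (mean squared error over all
    N*d entries), so a zero predictor scores about 1.  ``t`` and
    ``fixed_noise`` pin the random draws (deterministic replay in tests).
    """
    if t is None:
        t = int(rng.integers(1, schedule.T + 1))
    losses = []
    pairs = ((view1, view2), (view2, view1))
    noisy = {}
    for i, (v, _) in enumerate(pairs):
        noise = None if fixed_noise is None else fixed_noise[i]
        noisy[v.view_id], noise = forward_diffuse(
            v.h0, t, schedule, rng=rng, noise=noise
        )
        noisy[v.view_id] = (noisy[v.view_id], noise)
    for v, other in pairs:
        h_t, eps = noisy[v.view_id]
        h_t_oth, _ = noisy[other.view_id]
        eps_hat = predict_noise(h_t, t, h_t_oth.detach()
                                if isinstance(h_t_oth, Tensor) else h_t_oth,
                                v, params)
        diff = eps_hat - Tensor(eps)
        losses.append((diff * diff).mean())
    return (losses[0] + losses[1]) * 0.5


def fuse_views(h0_hat_1: np.ndarray, h0_hat_2: np.ndarray) -> np.ndarray:
    """Final denoised embedding: elementwise mean of both reconstructions."""
    a, b = np.asarray(h0_hat_1), np.asarray(h0_hat_2)
    if a.shape != b.shape:
        raise ValueError("shape mismatch between view reconstructions")
    return 0.5 * (a + b)
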
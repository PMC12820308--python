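"""Auxiliary views, noise schedule, forward/reverse diffusion."""

import numpy as np
import pytest
import scipy.sparse as sp

from hgdiag.autodiff import Adam, Tensor
from hgdiag.diffusion import (
    AuxiliaryView,
    DenoiserParams,
    ViewEncoderParams,
    _sym_normalize,
    build_views,
    ddim_reverse,
    diffusion_loss,
    encode_view,
    forward_diffuse,
    fuse_views,
    make_schedule,
    predict_noise,
)
from hgdiag.hetgraph import build_graph

from conftest import brute_force_metapath_matrix
from hgdiag.hetgraph import PDPOP


def make_view(h0: np.ndarray, adj=None, view_id=1) -> AuxiliaryView:
    n = h0.shape[0]
    if adj is None:
        adj = sp.csr_matrix((n, n))
    an = _sym_normalize(adj)
    x = np.eye(n, dtype=np.float32)
    v = AuxiliaryView(view_id=view_id, adjacency=sp.csr_matrix(adj),
                      adj_norm=an, features=x, prop_features=an @ x)
    v.h0 = Tensor(h0)
    return v


class TestBuildViews:
    def test_shared_drug_view(self):
        g = build_graph([("p1", "d1"), ("p2", "d1")], [])
        v1, v2 = build_views(g)
        np.testing.assert_array_equal(
            v1.adjacency.toarray(), [[0, 1], [1, 0]]
        )

    def test_no_sharing_yields_empty_views(self):
        g = build_graph([("p1", "d1"), ("p2", "d2")], [("p1", "o1")])
        v1, v2 = build_views(g)
        assert v1.adjacency.nnz == 0 and v2.adjacency.nnz == 0

    def test_long_view_matches_walk_enumeration(self):
        g = build_graph(
            [("p1", "d1"), ("p2", "d1"), ("p3", "d2")],
            [("p2", "o1"), ("p3", "o1")],
        )
        _, v2 = build_views(g)
        np.testing.assert_array_equal(
            v2.adjacency.toarray(), brute_force_metapath_matrix(g, PDPOP)
        )

    def test_features_are_row_normalized(self):
        g = build_graph([("p1", "d1"), ("p1", "d2"), ("p2", "d1")],
                        [("p2", "o1")])
        v1, _ = build_views(g)
        norms = np.linalg.norm(v1.features, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)


class TestEncodeView:
    def test_zero_adjacency_uses_self_loop_only(self):
        rng = np.random.default_rng(0)
        enc = ViewEncoderParams.create(rng, 4, 6)
        h0 = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0], [0, 0, 1.0, 0]],
                      np.float32)
        v = make_view(np.zeros((3, 6), np.float32))
        v.features = h0
        v.prop_features = v.adj_norm @ h0
        out = encode_view(v, enc).data
        expected = h0 @ enc.w.data
        expected /= np.linalg.norm(expected, axis=1, keepdims=True)
        np.testing.assert_allclose(out, expected, rtol=1e-5, atol=1e-6)

    def test_identical_patients_encode_identically(self):
        g = build_graph([("p1", "d1"), ("p2", "d1")], [])
        v1, _ = build_views(g)
        enc = ViewEncoderParams.create(np.random.default_rng(1), 1, 6)
        out = encode_view(v1, enc).data
        np.testing.assert_allclose(out[0], out[1], rtol=1e-5)

    def test_hand_computed_propagation(self):
        adj = sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]]))
        x = np.array([[1.0, 2.0], [0.5, -1.0], [2.0, 0.0]], np.float32)
        w = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, -1.0]], np.float32)
        v = make_view(np.zeros((3, 3), np.float32), adj=adj)
        v.features = x
        an = _sym_normalize(adj).toarray()
        v.prop_features = (an @ x).astype(np.float32)
        enc = ViewEncoderParams(w=Tensor(w, requires_grad=True))
        out = encode_view(v, enc).data
        ref = an @ x @ w
        ref /= np.linalg.norm(ref, axis=1, keepdims=True)
        np.testing.assert_allclose(out, ref, rtol=1e-5, atol=1e-6)


class TestSchedule:
    def test_single_step_product(self):
        s = make_schedule(T=1, noise_strength=0.2)
        assert s.alpha_bar[0] == pytest.approx(1.0 - s.beta[0])

    def test_alpha_bar_strictly_decreasing(self):
        s = make_schedule(T=50, noise_strength=1e-5)
        assert np.all(np.diff(s.alpha_bar) < 0)
        assert s.alpha_bar[-1] > 0

    def test_low_noise_limit_matches_exponential(self):
        s = make_schedule(T=50, noise_strength=1e-5)
        assert s.alpha_bar[-1] == pytest.approx(
            np.exp(-s.beta.sum()), abs=1e-8
        )

    @pytest.mark.parametrize("bad", [1.0, 1.5, 0.0, -0.1])
    def test_invalid_noise_strength_rejected(self, bad):
        with pytest.raises(ValueError, match="invalid schedule"):
            make_schedule(T=10, noise_strength=bad)

    def test_ddim_subsequence_descends_from_T_to_1(self):
        s = make_schedule(T=50, noise_strength=1e-5, ddim_steps=10)
        sub = s.ddim_subsequence()
        assert sub[0] == 50 and sub[-1] == 1
        assert np.all(np.diff(sub) < 0)


class TestForwardDiffuse:
    def test_zero_noise_scales_by_sqrt_alpha_bar(self):
        s = make_schedule(T=10, noise_strength=0.3)
        h0 = np.random.default_rng(0).normal(size=(4, 3))
        ht, _ = forward_diffuse(h0, 7, s, noise=np.zeros_like(h0))
        np.testing.assert_allclose(ht, np.sqrt(s.alpha_bar[6]) * h0)

    def test_step_out_of_range_rejected(self):
        s = make_schedule(T=10, noise_strength=0.3)
        with pytest.raises(ValueError):
            forward_diffuse(np.zeros((2, 2)), 11, s,
                            rng=np.random.default_rng(0))

    def test_moments_match_marginal(self):
        # closed form must have mean sqrt(abar)*h0 and variance (1-abar)
        s = make_schedule(T=5, noise_strength=0.5)
        h0 = np.full((1, 1), 2.0)
        rng = np.random.default_rng(1)
        draws = np.array(
            [forward_diffuse(h0, 5, s, rng=rng)[0][0, 0]
             for _ in range(10_000)]
        )
        ab = s.alpha_bar[-1]
        se_mean = np.sqrt((1 - ab) / len(draws))
        assert abs(draws.mean() - np.sqrt(ab) * 2.0) < 3 * se_mean
        se_var = (1 - ab) * np.sqrt(2.0 / (len(draws) - 1))
        assert abs(draws.var() - (1 - ab)) < 3 * se_var


class TestPredictNoise:
    def test_zero_weights_give_zero(self):
        rng = np.random.default_rng(2)
        params = DenoiserParams.create(rng, d=6)
        for p in params.params():
            p.data[...] = 0.0
        v = make_view(rng.normal(size=(3, 6)).astype(np.float32))
        out = predict_noise(v.h0.data, 3, v.h0.data, v, params)
        assert np.all(out.data == 0.0)

    def test_output_shape(self):
        rng = np.random.default_rng(3)
        params = DenoiserParams.create(rng, d=6)
        for n in (1, 5, 17):
            v = make_view(rng.normal(size=(n, 6)).astype(np.float32))
            out = predict_noise(v.h0.data, 2, v.h0.data, v, params)
            assert out.shape == (n, 6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        params = DenoiserParams.create(rng, d=6)
        n = 5
        adj = sp.csr_matrix(
            (np.random.default_rng(5).random((n, n)) < 0.4).astype(np.int8)
        )
        adj = ((adj + adj.T) > 0).astype(np.int8)
        adj.setdiag(0)
        h = rng.normal(size=(n, 6)).astype(np.float32)
        v = make_view(h, adj=adj)
        out = predict_noise(h, 2, h, v, params).data
        perm = np.array([3, 0, 4, 1, 2])
        adj_p = adj.toarray()[perm][:, perm]
        v_p = make_view(h[perm], adj=sp.csr_matrix(adj_p))
        out_p = predict_noise(h[perm], 2, h[perm], v_p, params).data
        np.testing.assert_allclose(out_p, out[perm], rtol=1e-4, atol=1e-5)


class TestDdimReverse:
    def test_oracle_denoiser_recovers_h0(self):
        rng = np.random.default_rng(6)
        h0 = rng.normal(size=(5, 4))
        v1, v2 = make_view(h0), make_view(rng.normal(size=(5, 4)), view_id=2)
        s = make_schedule(T=20, noise_strength=0.4, ddim_steps=5)
        eps = rng.normal(size=h0.shape)
        rec = ddim_reverse(v1, v2, s, None, np.random.default_rng(7),
                           predictor=lambda h, t, other: eps,
                           initial_noise=eps)
        rel = np.linalg.norm(rec - h0) / np.linalg.norm(h0)
        assert rel <= 1e-5

    def test_zero_predictor_rescales_terminal_state(self):
        rng = np.random.default_rng(8)
        h0 = rng.normal(size=(3, 4))
        v1, v2 = make_view(h0), make_view(h0, view_id=2)
        s = make_schedule(T=10, noise_strength=0.3, ddim_steps=1)
        eps = rng.normal(size=h0.shape)
        rec = ddim_reverse(v1, v2, s, None, np.random.default_rng(9),
                           predictor=lambda h, t, other: np.zeros_like(h),
                           initial_noise=eps)
        ht, _ = forward_diffuse(h0, 10, s, noise=eps)
        np.testing.assert_allclose(rec, ht / np.sqrt(s.alpha_bar[-1]),
                                   rtol=1e-6)

    def test_single_step_equals_direct_formula(self):
        rng = np.random.default_rng(10)
        h0 = rng.normal(size=(4, 3))
        v1, v2 = make_view(h0), make_view(h0, view_id=2)
        s = make_schedule(T=8, noise_strength=0.2, ddim_steps=1)
        eps_hat = rng.normal(size=h0.shape)
        eps0 = rng.normal(size=h0.shape)
        rec = ddim_reverse(v1, v2, s, None, np.random.default_rng(11),
                           predictor=lambda h, t, other: eps_hat,
                           initial_noise=eps0)
        ab = s.alpha_bar[-1]
        ht = np.sqrt(ab) * h0 + np.sqrt(1 - ab) * eps0
        np.testing.assert_allclose(
            rec, (ht - np.sqrt(1 - ab) * eps_hat) / np.sqrt(ab), rtol=1e-6
        )


class TestDiffusionLoss:
    def test_zero_predictor_scores_near_one(self):
        # zero net output -> loss is the mean square of standard noise
        rng = np.random.default_rng(12)
        params = DenoiserParams.create(rng, d=8)
        for p in params.params():
            p.data[...] = 0.0
        h0 = rng.normal(size=(40, 8)).astype(np.float32)
        v1 = make_view(h0)
        v2 = make_view(rng.normal(size=(40, 8)).astype(np.float32), view_id=2)
        s = make_schedule(T=10, noise_strength=0.3)
        vals = [
            float(diffusion_loss(v1, v2, s, params,
                                 np.random.default_rng(i)).data)
            for i in range(30)
        ]
        n_coords = 40 * 8 * 2 * len(vals)
        se = np.sqrt(2.0 / n_coords)
        assert abs(np.mean(vals) - 1.0) < 3 * se

    def test_loss_invariant_under_patient_permutation(self):
        rng = np.random.default_rng(13)
        params = DenoiserParams.create(rng, d=6)
        n = 7
        adj = (np.random.default_rng(20).random((n, n)) < 0.5)
        adj = sp.csr_matrix(((adj | adj.T) & ~np.eye(n, dtype=bool))
                            .astype(np.int8))
        h0 = rng.normal(size=(n, 6)).astype(np.float32)
        h0b = rng.normal(size=(n, 6)).astype(np.float32)
        eps = (rng.normal(size=(n, 6)), rng.normal(size=(n, 6)))
        s = make_schedule(T=6, noise_strength=0.4)
        l1 = diffusion_loss(make_view(h0, adj=adj),
                            make_view(h0b, adj=adj, view_id=2), s,
                            params, np.random.default_rng(99),
                            t=4, fixed_noise=eps).data
        perm = np.random.default_rng(14).permutation(n)
        adj_p = sp.csr_matrix(adj.toarray()[perm][:, perm])
        eps_p = (eps[0][perm], eps[1][perm])
        l2 = diffusion_loss(make_view(h0[perm], adj=adj_p),
                            make_view(h0b[perm], adj=adj_p, view_id=2), s,
                            params, np.random.default_rng(99),
                            t=4, fixed_noise=eps_p).data
        assert l1 == pytest.approx(l2, rel=1e-5)

    def test_shared_denoiser_couples_views(self):
        rng = np.random.default_rng(15)
        params = DenoiserParams.create(rng, d=6)
        h0 = rng.normal(size=(5, 6)).astype(np.float32)
        v1 = make_view(h0)
        v2 = make_view(h0[::-1].copy(), view_id=2)
        s = make_schedule(T=6, noise_strength=0.4)
        v1.h0, v2.h0 = Tensor(h0), Tensor(h0[::-1].copy())
        before = predict_noise(h0, 3, h0, v2, params).data.copy()
        params.w1.data += 0.5
        after = predict_noise(h0, 3, h0, v2, params).data
        assert not np.allclose(before, after)


class TestFuseViews:
    def test_identical_inputs_unchanged(self):
        a = np.random.default_rng(16).normal(size=(3, 4))
        np.testing.assert_array_equal(fuse_views(a, a), a)

    def test_elementwise_mean(self):
        rng = np.random.default_rng(17)
        a, b = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        np.testing.assert_allclose(fuse_views(a, b), (a + b) / 2)
        np.testing.assert_allclose(fuse_views(a, np.zeros_like(a)), a / 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_views(np.zeros((2, 2)), np.zeros((3, 2)))


class TestTrainedDenoiserUtility:
    def test_training_improves_noise_prediction(self):
        # Adam steps should beat the untrained net on a paired eval set
        rng = np.random.default_rng(18)
        n, d = 12, 8
        ring = np.zeros((n, n), np.int8)
        for i in range(n):
            ring[i, (i + 1) % n] = ring[(i + 1) % n, i] = 1
        ring = sp.csr_matrix(ring)
        h0 = rng.normal(size=(n, d)).astype(np.float32)
        h0 /= np.linalg.norm(h0, axis=1, keepdims=True)
        v1 = make_view(h0, adj=ring)
        v2 = make_view(h0[::-1].copy(), adj=ring, view_id=2)
        s = make_schedule(T=10, noise_strength=0.3)
        params = DenoiserParams.create(rng, d=d)

        eval_set = [
            (int(r.integers(1, 11)),
             (r.normal(size=(n, d)), r.normal(size=(n, d))))
            for r in [np.random.default_rng(777)] for _ in range(30)
        ]

        def eval_loss():
            return np.mean([
                float(diffusion_loss(v1, v2, s, params,
                                     np.random.default_rng(0),
                                     t=t, fixed_noise=eps).data)
                for t, eps in eval_set
            ])

        before = eval_loss()
        opt = Adam(params.params(), lr=0.01)
        for i in range(300):
            loss = diffusion_loss(v1, v2, s, params,
                                  np.random.default_rng(1000 + i))
            opt.zero_grad()
            loss.backward()
            opt.step()
        after = eval_loss()
        assert after < before
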
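"""Contextual synergy inference: each refinement stage against brute-force
oracles, plus the composite-identity reduction of the whole chain."""

import numpy as np
import pytest

from dualscope.csi import (
    CsiConfig,
    CsiModule,
    SaliencyBlock,
    affinity_propagate,
    box_blur3,
    build_class_graph,
    csi_fuse,
    graph_propagate,
    prior_normalize,
    saliency_recalibrate,
    sharpen_logits,
    sparsify_graph,
)
from dualscope.decoder import decode_mask
from dualscope.nn import Tensor, softmax
from dualscope.phantoms import make_csi_fixture


def loop_affinity(u, e, tau):
    """O(P^2) double-loop oracle on (C, H, W) logits / (D, H, W) embeddings."""
    c, h, w = u.shape
    d = e.shape[0]
    uf = u.reshape(c, -1).T
    ef = e.reshape(d, -1).T
    p = uf.shape[0]
    out = np.zeros_like(uf)
    for i in range(p):
        logits = np.array([-np.sum((ef[i] - ef[j]) ** 2) / tau**2
                           for j in range(p)])
        wgt = np.exp(logits - logits.max())
        wgt /= wgt.sum()
        out[i] = sum(wgt[j] * uf[j] for j in range(p))
    return out.T.reshape(c, h, w)


def loop_class_graph(u):
    c = u.shape[0]
    s = np.exp(u - u.max(axis=0, keepdims=True))
    s /= s.sum(axis=0, keepdims=True)
    flat = s.reshape(c, -1)
    p = flat.shape[1]
    w = np.zeros((c, c))
    for i in range(c):
        for j in range(c):
            w[i, j] = np.mean([flat[i, k] * flat[j, k] for k in range(p)])
    return w


class TestAffinity:
    def test_matches_double_loop_oracle_on_8x8(self):
        u, e, _, _ = make_csi_fixture(8, 8, 3, 4, seed=5)
        out, _ = affinity_propagate(u[None], e[None], tau=1.3, stride=1)
        np.testing.assert_allclose(out.data[0], loop_affinity(u, e, 1.3),
                                   atol=1e-6)

    def test_rows_stochastic_and_output_within_extrema(self):
        u, e, _, _ = make_csi_fixture(8, 8, 4, 4, seed=3)
        out, attn = affinity_propagate(u[None], e[None], tau=0.7, stride=1)
        np.testing.assert_allclose(attn.data.sum(axis=2), 1.0, atol=1e-6)
        for c in range(4):
            assert out.data[0, c].min() >= u[c].min() - 1e-5
            assert out.data[0, c].max() <= u[c].max() + 1e-5

    def test_identical_embeddings_give_spatial_mean(self):
        u = np.random.default_rng(0).standard_normal((1, 2, 4, 4)).astype(np.float32)
        e = np.ones((1, 3, 4, 4), np.float32)
        out, _ = affinity_propagate(u, e, tau=1.0, stride=1)
        mean = u.mean(axis=(2, 3), keepdims=True)
        np.testing.assert_allclose(out.data, np.broadcast_to(mean, u.shape),
                                   atol=1e-6)

    def test_tiny_tau_with_separated_embeddings_is_identity(self):
        u = np.random.default_rng(1).standard_normal((1, 3, 3, 3))
        e = np.arange(9, dtype=np.float64).reshape(1, 1, 3, 3)  # distances >= 1
        out, _ = affinity_propagate(u, e, tau=1e-6, stride=1)
        np.testing.assert_allclose(out.data, u, atol=1e-6)

    def test_two_pixel_hand_computed_weights(self):
        u = np.array([[1.0, 0.0], [0.0, 1.0]]).T.reshape(1, 2, 1, 2)
        e = np.array([0.0, 1.0]).reshape(1, 1, 1, 2)
        out, _ = affinity_propagate(u, e, tau=1.0, stride=1)
        w0 = np.exp(0.0) / (np.exp(0.0) + np.exp(-1.0))
        np.testing.assert_allclose(out.data[0, :, 0, 0],
                                   [w0, 1 - w0], atol=1e-6)
        np.testing.assert_allclose(out.data[0, 0, 0, 0], 0.7311, atol=1e-4)

    def test_invalid_tau_and_oversized_grid_rejected(self):
        u = np.zeros((1, 2, 4, 4), np.float32)
        e = np.zeros((1, 2, 4, 4), np.float32)
        with pytest.raises(ValueError):
            affinity_propagate(u, e, tau=0.0)
        with pytest.raises(ValueError, match="stride"):
            affinity_propagate(u, e, tau=1.0, stride=1, max_pixels=8)

    def test_strided_path_pools_then_upsamples(self):
        u, e, _, _ = make_csi_fixture(8, 8, 2, 3, seed=9)
        out, _ = affinity_propagate(u[None], e[None], tau=1.0, stride=2)
        assert out.shape == (1, 2, 8, 8)
        pooled_u = u.reshape(2, 4, 2, 4, 2).mean(axis=(2, 4))
        pooled_e = e.reshape(3, 4, 2, 4, 2).mean(axis=(2, 4))
        ref_coarse = loop_affinity(pooled_u, pooled_e, 1.0)
        coarse, _ = affinity_propagate(pooled_u[None], pooled_e[None],
                                       tau=1.0, stride=1)
        np.testing.assert_allclose(coarse.data[0], ref_coarse, atol=1e-6)


class TestPairwiseLogitsNode:
    def test_fused_gradient_matches_finite_differences(self):
        from dualscope.csi import _pairwise_logits

        rng = np.random.default_rng(0)
        e0 = rng.standard_normal((2, 5, 3))
        x = Tensor(e0.copy(), requires_grad=True)
        (_pairwise_logits(x, 0.8) ** 2).sum().backward()
        eps = 1e-6
        ng = np.zeros_like(e0)
        it = np.nditer(e0, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            e0[i] += eps
            fp = float((_pairwise_logits(Tensor(e0), 0.8).data ** 2).sum())
            e0[i] -= 2 * eps
            fm = float((_pairwise_logits(Tensor(e0), 0.8).data ** 2).sum())
            e0[i] += eps
            ng[i] = (fp - fm) / (2 * eps)
        np.testing.assert_allclose(x.grad, ng, atol=1e-5)


class TestSaliencyStages:
    def test_zero_weight_block_outputs_half(self):
        block = SaliencyBlock(4, np.random.default_rng(0))
        for conv in (block.conv1, block.conv2):
            conv.weight.data[...] = 0.0
        m = block(Tensor(np.random.default_rng(1)
                         .random((1, 4, 5, 5)).astype(np.float32)))
        np.testing.assert_allclose(m.data, 0.5, atol=1e-7)

    def test_saliency_always_in_open_interval(self):
        block = SaliencyBlock(2, np.random.default_rng(2))
        m = block(Tensor(np.random.default_rng(3)
                         .standard_normal((1, 2, 6, 6)).astype(np.float32)))
        assert np.all(m.data > 0.0) and np.all(m.data < 1.0)

    def test_recalibration_identities_and_scaling(self):
        u = Tensor(np.random.default_rng(0).standard_normal((1, 3, 4, 4)))
        m = Tensor(np.ones((1, 1, 4, 4)))
        np.testing.assert_array_equal(saliency_recalibrate(u, m, 0.0).data, u.data)
        np.testing.assert_allclose(saliency_recalibrate(u, m, 0.5).data,
                                   1.5 * u.data, atol=1e-7)
        with pytest.raises(ValueError):
            saliency_recalibrate(u, m, -0.1)

    def test_recalibration_never_reorders_channels(self):
        rng = np.random.default_rng(4)
        u = Tensor(rng.standard_normal((1, 4, 6, 6)))
        m = Tensor(rng.random((1, 1, 6, 6)))
        out = saliency_recalibrate(u, m, 2.0)
        np.testing.assert_array_equal(
            np.argsort(out.data, axis=1), np.argsort(u.data, axis=1)
        )


class TestPriorNormalize:
    def test_zero_coefficient_is_identity(self):
        u = Tensor(np.random.default_rng(0).standard_normal((1, 2, 3, 3)))
        alpha = Tensor(np.array([[0.7, 0.3]]))
        np.testing.assert_array_equal(prior_normalize(u, alpha, 0.0).data, u.data)

    def test_concentrated_prior_doubles_one_channel(self):
        u = Tensor(np.ones((1, 2, 2, 2)))
        alpha = Tensor(np.array([[1.0, 0.0]]))
        out = prior_normalize(u, alpha, 1.0).data
        np.testing.assert_allclose(out[0, 0], 2.0, atol=1e-7)
        np.testing.assert_allclose(out[0, 1], 1.0, atol=1e-7)

    def test_uniform_prior_preserves_decoding(self):
        rng = np.random.default_rng(1)
        u = Tensor(rng.standard_normal((1, 4, 5, 5)))
        alpha = Tensor(np.full((1, 4), 0.25))
        out = prior_normalize(u, alpha, 0.8)
        np.testing.assert_array_equal(decode_mask(out), decode_mask(u))


class TestClassGraph:
    def test_matches_double_loop_oracle_on_8x8(self):
        u, _, _, _ = make_csi_fixture(8, 8, 4, 2, seed=7)
        w = build_class_graph(u[None]).data[0]
        np.testing.assert_allclose(w, loop_class_graph(u.astype(np.float64)),
                                   atol=1e-6)

    def test_one_hot_activation_concentrates_mass(self):
        u = np.zeros((1, 3, 4, 4), np.float32)
        u[0, 1] = 60.0  # softmax ~ one-hot on class 1 everywhere
        w = build_class_graph(u).data[0]
        np.testing.assert_allclose(w[1, 1], 1.0, atol=1e-6)
        assert w.sum() - w[1, 1] < 1e-6

    def test_single_pixel_even_split(self):
        u = np.zeros((1, 2, 1, 1))
        w = build_class_graph(u).data[0]
        np.testing.assert_allclose(w, 0.25, atol=1e-9)

    def test_mass_one_and_symmetry(self):
        u = np.random.default_rng(2).standard_normal((3, 5, 6, 6))
        w = build_class_graph(u).data
        np.testing.assert_allclose(w.sum(axis=(1, 2)), 1.0, atol=1e-9)
        np.testing.assert_allclose(w, np.swapaxes(w, 1, 2), atol=1e-12)
        assert w.min() >= 0


class TestSparsify:
    def test_full_keep_is_identity(self):
        w = build_class_graph(
            np.random.default_rng(0).standard_normal((1, 4, 4, 4))).data[0]
        np.testing.assert_array_equal(sparsify_graph(w, 3), w)
        np.testing.assert_array_equal(sparsify_graph(w, 10), w)

    def test_diagonal_always_retained_and_topk_matches_sort(self):
        w = build_class_graph(
            np.random.default_rng(5).standard_normal((1, 4, 6, 6))).data[0]
        out = sparsify_graph(w, 1)
        assert np.all(np.diag(out) == np.diag(w))
        # brute-force: entry survives iff top-1 off-diagonal of row i or j
        keep = np.zeros_like(w, dtype=bool)
        for i in range(4):
            off = w[i].copy()
            off[i] = -np.inf
            keep[i, np.argmax(off)] = True
        expected = np.where(keep | keep.T | np.eye(4, dtype=bool), w, 0.0)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_invalid_keep_rejected(self):
        with pytest.raises(ValueError):
            sparsify_graph(np.eye(3), 0)


class TestGraphPropagate:
    def test_identity_and_zero_graphs(self):
        n = Tensor(np.random.default_rng(0).standard_normal((1, 3, 4, 4)))
        np.testing.assert_allclose(graph_propagate(n, np.eye(3)).data, n.data,
                                   atol=1e-7)
        np.testing.assert_allclose(graph_propagate(n, np.zeros((3, 3))).data,
                                   0.0, atol=1e-12)

    def test_single_pixel_matrix_vector_product(self):
        w = np.array([[0.5, 0.3, 0.2], [0.3, 0.4, 0.1], [0.2, 0.1, 0.6]])
        n = np.array([1.0, -2.0, 3.0]).reshape(1, 3, 1, 1)
        out = graph_propagate(Tensor(n), w).data.ravel()
        np.testing.assert_allclose(out, w @ n.ravel(), atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            graph_propagate(Tensor(np.zeros((1, 3, 2, 2))), np.eye(4))


class TestSharpen:
    def test_zero_eta_identity_and_constant_fixed_point(self):
        u = Tensor(np.random.default_rng(0).standard_normal((1, 2, 5, 5)))
        np.testing.assert_array_equal(sharpen_logits(u, 0.0).data, u.data)
        const = Tensor(np.full((1, 2, 5, 5), 3.3))
        np.testing.assert_allclose(sharpen_logits(const, 2.0).data, 3.3,
                                   atol=1e-6)

    def test_step_edge_overshoot_matches_hand_blur(self):
        u = np.zeros((1, 1, 6, 6))
        u[:, :, :, 3:] = 1.0
        hand = np.zeros((6, 6))
        pad = np.pad(u[0, 0], 1, mode="reflect")
        for i in range(6):
            for j in range(6):
                hand[i, j] = pad[i:i+3, j:j+3].mean()
        expected = u[0, 0] + 1.0 * (u[0, 0] - hand)
        out = sharpen_logits(Tensor(u), 1.0).data[0, 0]
        np.testing.assert_allclose(out, expected, atol=1e-6)
        assert out.max() > 1.0 and out.min() < 0.0  # overshoot at the edge


class TestFusion:
    def test_degenerate_theta_selects_branch(self):
        rng = np.random.default_rng(0)
        r = Tensor(rng.standard_normal((1, 3, 4, 4)))
        n = Tensor(rng.standard_normal((1, 3, 4, 4)))
        s = Tensor(rng.standard_normal((1, 3, 4, 4)))
        fused, mask = csi_fuse(r, n, s, [1.0, 0.0, 0.0])
        np.testing.assert_array_equal(mask, decode_mask(r))
        np.testing.assert_allclose(fused.data, r.data, atol=1e-7)

    def test_equal_inputs_fixed_point_for_any_theta(self):
        x = Tensor(np.random.default_rng(1).standard_normal((1, 2, 3, 3)))
        fused, _ = csi_fuse(x, x, x, [0.2, 0.5, 0.3])
        np.testing.assert_allclose(fused.data, x.data, atol=1e-6)

    def test_uniform_theta_average_oracle(self):
        a = np.array([[2.0, 0.0], [0.0, 1.0]]).reshape(1, 2, 2, 1)
        b = np.array([[1.0, 1.0], [1.0, 0.0]]).reshape(1, 2, 2, 1)
        c = np.array([[0.0, 2.0], [2.0, 2.0]]).reshape(1, 2, 2, 1)
        fused, mask = csi_fuse(Tensor(a), Tensor(b), Tensor(c),
                               [1/3, 1/3, 1/3])
        np.testing.assert_allclose(fused.data, (a + b + c) / 3, atol=1e-7)
        np.testing.assert_array_equal(mask, decode_mask((a + b + c) / 3))


class TestCompositeChain:
    def test_neutral_configuration_is_identity_on_logits(self):
        # tau -> 0 with pairwise-separated embeddings, lam = lam_prior = 0,
        # eta = 0, no graph mixing, theta picks the untouched branch
        h = w = 6
        u = np.random.default_rng(3).standard_normal((1, 3, h, w)).astype(np.float64)
        emb = np.arange(h * w, dtype=np.float64).reshape(1, 1, h, w)
        feat = np.random.default_rng(4).random((1, 4, h, w)).astype(np.float32)
        cfg = CsiConfig(tau=1e-4, lam=0.0, lam_prior=0.0, eta=0.0, stride=1,
                        graph=False)
        module = CsiModule(4, 3, cfg, np.random.default_rng(0)).eval()
        module.set_theta([0.0, 1.0, 0.0])
        alpha = Tensor(np.full((1, 3), 1 / 3))
        state = module(Tensor(u), Tensor(emb), Tensor(feat), alpha)
        np.testing.assert_allclose(state.fused.data, u, atol=1e-5)
        np.testing.assert_array_equal(state.mask, decode_mask(u))

    def test_module_runs_all_stages_and_reports_state(self):
        u, e, _, _ = make_csi_fixture(8, 8, 3, 4, seed=1)
        feat = np.random.default_rng(2).random((1, 5, 8, 8)).astype(np.float32)
        cfg = CsiConfig(stride=2)
        module = CsiModule(5, 3, cfg, np.random.default_rng(0)).eval()
        alpha = Tensor(np.full((1, 3), 1 / 3))
        state = module(Tensor(u[None]), Tensor(e[None]), Tensor(feat), alpha)
        assert state.saliency is not None and state.graph is not None
        np.testing.assert_allclose(state.theta.data.sum(), 1.0, atol=1e-6)
        np.testing.assert_allclose(state.graph.data[0].sum(), 1.0, atol=1e-6)
        assert state.mask.shape == (1, 8, 8)

    def test_boundary_supervised_saliency_concentrates_on_edges(self):
        # toy training: the saliency block, supervised by a boundary band
        # around a disk, should weight the band above the far background
        from dualscope.nn import AdamW
        from dualscope.objectives import (
            boundary_band_target,
            saliency_supervision_loss,
        )

        yy, xx = np.mgrid[:32, :32]
        disk = (((yy - 16) ** 2 + (xx - 16) ** 2) <= 8**2)
        mask = disk.astype(np.uint8)[None]
        image = (0.25 + 0.45 * disk).astype(np.float32)
        feats = Tensor(np.stack([image, np.gradient(image)[0],
                                 np.gradient(image)[1]])[None])
        block = SaliencyBlock(3, np.random.default_rng(0))
        opt = AdamW(block.parameters(), lr=1e-2)
        target = boundary_band_target(mask, radius=2)
        for _ in range(200):
            m = block(feats)
            loss = saliency_supervision_loss(m, target)
            block.zero_grad()
            loss.backward()
            opt.step()
        m = block(feats).data[0, 0]
        band = target[0, 0] > 0
        far_background = (~band) & (~disk)
        assert m[band].mean() > m[far_background].mean()

    def test_ema_graph_accumulates_only_in_training(self):
        u, e, _, _ = make_csi_fixture(8, 8, 3, 4, seed=1)
        feat = np.random.default_rng(2).random((1, 5, 8, 8)).astype(np.float32)
        cfg = CsiConfig(stride=2, ema_decay=0.5)
        module = CsiModule(5, 3, cfg, np.random.default_rng(0))
        alpha = Tensor(np.full((1, 3), 1 / 3))
        before = module.running_graph.copy()
        module.eval()(Tensor(u[None]), Tensor(e[None]), Tensor(feat), alpha)
        np.testing.assert_array_equal(module.running_graph, before)
        module.train()
        module.drop.rng = np.random.default_rng(1)
        module(Tensor(u[None]), Tensor(e[None]), Tensor(feat), alpha)
        assert not np.array_equal(module.running_graph, before)
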
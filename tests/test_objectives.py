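"""Loss terms: analytic spot values, brute-force pair oracles, reductions."""

import numpy as np
import pytest

from dualscope.nn import AdamW, Parameter, Tensor
from dualscope.objectives import (
    LossConfig,
    affinity_loss,
    boundary_band_target,
    embedding_discriminability,
    relational_consistency_loss,
    saliency_focal_loss,
    smoothed_cross_entropy,
    total_loss,
)


def logits_for_prob(p, n_pixels=1):
    """2-class logits whose softmax gives (p, 1-p)."""
    z = np.log(p / (1 - p))
    return np.stack([np.full((1, n_pixels, 1), z),
                     np.zeros((1, n_pixels, 1))], axis=1)


class TestAffinityLoss:
    def test_identical_embeddings_same_label_zero(self):
        e = Tensor(np.ones((4, 3)))
        out = affinity_loss(e, np.zeros(4, int), margin=1.0, lambda_a=1.0,
                            exhaustive=True)
        assert float(out.data) == 0.0

    def test_coincident_pair_different_labels_hits_full_margin(self):
        e = Tensor(np.zeros((2, 3)))
        out = affinity_loss(e, np.array([0, 1]), margin=1.5, lambda_a=1.0,
                            exhaustive=True)
        np.testing.assert_allclose(float(out.data), 1.5**2, atol=1e-5)

    def test_six_pixel_fixture_matches_all_pairs_loop(self):
        rng = np.random.default_rng(0)
        e = rng.standard_normal((6, 4))
        labels = np.array([0, 0, 1, 1, 2, 0])
        m, lam = 1.2, 0.7
        total, count = 0.0, 0
        for i in range(6):
            for j in range(i + 1, 6):
                d2 = np.sum((e[i] - e[j]) ** 2)
                d = np.sqrt(d2 + 1e-12)
                if labels[i] == labels[j]:
                    total += d2
                else:
                    total += lam * max(0.0, m - d) ** 2
                count += 1
        out = affinity_loss(Tensor(e), labels, m, lam, exhaustive=True)
        np.testing.assert_allclose(float(out.data), total / count, atol=1e-6)

    def test_single_pixel_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            out = affinity_loss(Tensor(np.zeros((1, 2))), np.array([0]),
                                1.0, 1.0)
        assert float(out.data) == 0.0

    def test_gradient_step_contracts_same_class_pair(self):
        e = Parameter(np.array([[0.0, 0.0], [3.0, 4.0]], np.float32))
        opt = AdamW([e], lr=0.1, weight_decay=0.0)
        d_before = np.linalg.norm(e.data[0] - e.data[1])
        loss = affinity_loss(e, np.array([1, 1]), 1.0, 1.0, exhaustive=True)
        loss.backward()
        opt.step()
        d_after = np.linalg.norm(e.data[0] - e.data[1])
        assert d_after < d_before


class TestSaliencyFocal:
    def test_perfect_prediction_zero_loss(self):
        logits = np.zeros((1, 2, 2, 2))
        logits[:, 0] = 60.0
        m = np.ones((1, 1, 2, 2))
        out = saliency_focal_loss(Tensor(logits), m, np.zeros((1, 2, 2), int),
                                  gamma=2.0)
        np.testing.assert_allclose(float(out.data), 0.0, atol=1e-12)

    def test_half_probability_analytic_values(self):
        logits = Tensor(np.zeros((1, 2, 1, 1)))  # softmax = (0.5, 0.5)
        y = np.zeros((1, 1, 1), int)
        m = np.ones((1, 1, 1, 1))
        ce = saliency_focal_loss(logits, m, y, gamma=0.0)
        np.testing.assert_allclose(float(ce.data), np.log(2), atol=1e-6)
        focal = saliency_focal_loss(logits, m, y, gamma=2.0)
        np.testing.assert_allclose(float(focal.data), 0.25 * np.log(2),
                                   atol=1e-6)
        np.testing.assert_allclose(float(focal.data), 0.1733, atol=1e-4)

    def test_reduces_to_cross_entropy_at_gamma_zero(self):
        rng = np.random.default_rng(1)
        logits = rng.standard_normal((2, 3, 4, 4))
        y = rng.integers(0, 3, (2, 4, 4))
        m = np.ones((2, 1, 4, 4))
        out = saliency_focal_loss(Tensor(logits), m, y, gamma=0.0)
        # independent cross-entropy
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        idx = np.indices(y.shape)
        ce = -np.mean(np.log(p[idx[0], y, idx[1], idx[2]]))
        np.testing.assert_allclose(float(out.data), ce, atol=1e-7)

    def test_zero_mass_warns_and_returns_zero(self):
        logits = Tensor(np.zeros((1, 2, 2, 2)))
        with pytest.warns(UserWarning):
            out = saliency_focal_loss(logits, np.zeros((1, 1, 2, 2)),
                                      np.zeros((1, 2, 2), int), 2.0)
        assert float(out.data) == 0.0

    def test_saliency_weight_takes_no_gradient(self):
        m = Parameter(np.full((1, 1, 2, 2), 0.5, np.float32))
        logits = Tensor(np.random.default_rng(0)
                        .standard_normal((1, 2, 2, 2)).astype(np.float32),
                        requires_grad=True)
        out = saliency_focal_loss(logits, m, np.zeros((1, 2, 2), int), 2.0)
        out.backward()
        assert m.grad is None
        assert logits.grad is not None


class TestRelationalKL:
    def test_equal_distributions_zero(self):
        n = Tensor(np.random.default_rng(0).standard_normal((1, 3, 4, 4)))
        out = relational_consistency_loss(n, n, eps=0.0)
        np.testing.assert_allclose(float(out.data), 0.0, atol=1e-9)

    def test_single_pixel_analytic_kl(self):
        n = Tensor(np.array([60.0, -60.0]).reshape(1, 2, 1, 1))  # ~ (1, 0)
        r = Tensor(np.zeros((1, 2, 1, 1)))  # (0.5, 0.5)
        out = relational_consistency_loss(n, r, eps=0.0)
        np.testing.assert_allclose(float(out.data), np.log(2), atol=1e-5)

    def test_matches_per_pixel_loop(self):
        rng = np.random.default_rng(2)
        n = rng.standard_normal((1, 2, 4, 4))
        r = rng.standard_normal((1, 2, 4, 4))
        eps = 1e-6

        def sm(x):
            e = np.exp(x - x.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)

        p, q = sm(n), sm(r)
        expected = 0.0
        for i in range(4):
            for j in range(4):
                for c in range(2):
                    expected += p[0, c, i, j] * np.log(
                        p[0, c, i, j] / (q[0, c, i, j] + eps))
        expected /= 16
        out = relational_consistency_loss(Tensor(n), Tensor(r), eps=eps)
        np.testing.assert_allclose(float(out.data), expected, atol=1e-7)

    def test_epsilon_bias_bounded_at_equality(self):
        n = Tensor(np.random.default_rng(3).standard_normal((1, 4, 3, 3)))
        eps = 1e-3
        out = relational_consistency_loss(n, n, eps=eps)
        assert abs(float(out.data)) <= eps * 4


class TestEmbeddingDiscriminability:
    def test_per_class_constant_embeddings_zero_intra(self):
        e = np.array([[0, 0], [0, 0], [5, 5], [5, 5]], float)
        labels = np.array([0, 0, 1, 1])
        d_intra, d_inter, _ = embedding_discriminability(
            Tensor(e), labels, exhaustive=True)
        assert d_intra == 0.0

    def test_mean_distance_two_gives_inter_four(self):
        e = np.array([[0.0, 0.0], [2.0, 0.0]])
        _, d_inter, _ = embedding_discriminability(
            Tensor(e), np.array([0, 1]), exhaustive=True)
        np.testing.assert_allclose(d_inter, 4.0, atol=1e-9)

    def test_eight_pixel_fixture_matches_brute_force(self):
        rng = np.random.default_rng(4)
        e = rng.standard_normal((8, 3))
        labels = np.array([0, 0, 0, 1, 1, 2, 2, 2])
        margin = 1.4
        d_intra, d_inter, loss = embedding_discriminability(
            Tensor(e), labels, margin_mu=margin, exhaustive=True)
        per_class = []
        for c in range(3):
            idx = np.flatnonzero(labels == c)
            ds = [np.sum((e[i] - e[j]) ** 2)
                  for k, i in enumerate(idx) for j in idx[k + 1:]]
            per_class.append(np.mean(ds))
        np.testing.assert_allclose(d_intra, np.mean(per_class), atol=1e-9)
        mus = [e[labels == c].mean(axis=0) for c in range(3)]
        inter, hinge = 0.0, 0.0
        for a in range(3):
            for b in range(a + 1, 3):
                d2 = np.sum((mus[a] - mus[b]) ** 2)
                inter += d2
                hinge += max(0.0, margin - np.sqrt(d2)) ** 2
        np.testing.assert_allclose(d_inter, inter, atol=1e-9)
        np.testing.assert_allclose(float(loss.data), np.mean(per_class) + hinge,
                                   atol=1e-7)

    def test_single_class_batch_has_zero_inter(self):
        e = np.random.default_rng(5).standard_normal((4, 2))
        _, d_inter, _ = embedding_discriminability(
            Tensor(e), np.zeros(4, int), exhaustive=True)
        assert d_inter == 0.0


class TestTotalObjective:
    def make_terms(self):
        rng = np.random.default_rng(6)
        return {
            "final_ce": Tensor(np.array(1.3)),
            "affinity": Tensor(np.array(0.4)),
            "focal": Tensor(np.array(0.9)),
        }

    def test_only_ce_when_aux_weights_zero(self):
        rng = np.random.default_rng(7)
        logits = Tensor(rng.standard_normal((1, 3, 4, 4)))
        y = rng.integers(0, 3, (1, 4, 4))
        ce = smoothed_cross_entropy(logits, y, 0.1)
        cfg = LossConfig(w_deep_supervision=0, w_affinity=0, w_focal=0,
                         w_relational=0, w_embedding=0)
        total, logged = total_loss({"final_ce": ce}, cfg)
        np.testing.assert_allclose(float(total.data), float(ce.data), atol=1e-9)

    def test_linearity_in_term_weights(self):
        terms = self.make_terms()
        t1, _ = total_loss(terms, LossConfig(w_affinity=0.1))
        t2, _ = total_loss(terms, LossConfig(w_affinity=0.2))
        np.testing.assert_allclose(float(t2.data) - float(t1.data),
                                   0.1 * 0.4, atol=1e-7)

    def test_all_zero_weights_rejected(self):
        cfg = LossConfig(w_deep_supervision=0, w_affinity=0, w_focal=0,
                         w_relational=0, w_embedding=0, w_final_ce=0)
        with pytest.raises(ValueError):
            total_loss(self.make_terms(), cfg)

    def test_unknown_term_rejected(self):
        with pytest.raises(KeyError):
            total_loss({"bogus": Tensor(np.array(1.0))}, LossConfig())

    def test_smoothed_ce_floor_above_zero(self):
        # with smoothing the optimum is strictly positive
        logits = np.zeros((1, 3, 1, 1))
        logits[0, 0] = 80.0
        out = smoothed_cross_entropy(Tensor(logits), np.zeros((1, 1, 1), int),
                                     0.1)
        assert float(out.data) > 0.0

    def test_invalid_config_values_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(margin=0.0)
        with pytest.raises(ValueError):
            LossConfig(gamma_focal=-1.0)
        with pytest.raises(ValueError):
            LossConfig(label_smoothing=1.0)


class TestBoundarySupervision:
    def test_band_marks_foreground_edges(self):
        mask = np.zeros((1, 16, 16), int)
        mask[0, 4:12, 4:12] = 1
        band = boundary_band_target(mask, radius=1)[0, 0]
        assert band[4, 4] == 1.0  # corner of the square
        assert band[8, 8] == 0.0  # deep interior
        assert band[0, 0] == 0.0  # far background
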
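"""Losses and forward-pass properties of the prototype graph transformer."""

import numpy as np
import pytest

from mogt import (
    LossConfig,
    ModelConfig,
    MOGTModule,
    PrototypeSet,
    SimGraphConfig,
    focal_loss,
    prototype_contrastive_loss,
    prototype_similarity,
    simulate_gene_graph,
    total_loss,
)
from mogt.nn import Tensor
from mogt.training import sample_subgraph


class TestPrototypeSimilarity:
    def test_zero_distance_gives_log_inverse_epsilon(self):
        v = np.ones(8)
        assert prototype_similarity(v, v, 1e-4) == pytest.approx(np.log(1e4), abs=1e-9)

    def test_unit_distance_closed_form(self):
        # D = 1 → g = ln(2 / 1.0001)
        v_n = np.zeros(4)
        v_p = np.array([1.0, 0.0, 0.0, 0.0])
        assert prototype_similarity(v_n, v_p, 1e-4) == pytest.approx(
            np.log(2.0 / 1.0001), abs=1e-9
        )
        assert prototype_similarity(v_n, v_p, 1e-4) == pytest.approx(0.69305, abs=1e-5)

    @pytest.mark.parametrize("eps", [1e-6, 1e-4, 0.5, 0.999])
    def test_strictly_decreasing_in_distance(self, eps):
        v = np.zeros(3)
        d1 = np.array([1.0, 0.0, 0.0])       # D = 1
        d2 = np.array([2.0, 0.0, 0.0])       # D = 4
        assert prototype_similarity(v, d1, eps) > prototype_similarity(v, d2, eps)

    def test_nonnegative_for_epsilon_below_one(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 5))
            assert prototype_similarity(a, b, 1e-4) >= 0.0

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            prototype_similarity(np.array([np.nan, 0.0]), np.zeros(2))


def _protoset(vectors, classes):
    return PrototypeSet(
        vectors=Tensor(np.asarray(vectors, dtype=float), requires_grad=True),
        class_of=np.asarray(classes),
    )


class TestContrastiveLoss:
    def test_single_node_hand_case(self):
        """One positive prototype with g=2, one negative with g=0, T=1 → −2."""
        # distances chosen so g(v, p_pos) = 2 and g(v, p_neg) = 0 exactly:
        # g = ln((D+1)/(D+eps)); eps→ pick D to invert at eps = 1e-4
        eps = 1e-4
        def d_for(g):
            return (1.0 - eps * np.exp(g)) / (np.exp(g) - 1.0)
        emb = np.zeros((1, 1))
        d_pos = d_for(2.0)
        protos = _protoset(
            [[np.sqrt(d_pos)], [1e8]], [1, 0]  # far prototype: g ≈ 0
        )
        loss = prototype_contrastive_loss(
            Tensor(emb), np.array([1]), protos, temperature=1.0, epsilon=eps
        )
        assert loss.item() == pytest.approx(-2.0, abs=1e-6)

    def test_equal_similarity_gives_zero(self):
        protos = _protoset([[1.0, 0.0], [-1.0, 0.0]], [0, 1])
        emb = Tensor(np.array([[0.0, 0.5]]))  # equidistant from both prototypes
        loss = prototype_contrastive_loss(emb, np.array([0]), protos, temperature=0.7)
        assert loss.item() == pytest.approx(0.0, abs=1e-9)

    def test_duplicating_a_node_leaves_loss_unchanged(self, rng):
        protos = _protoset(rng.normal(size=(4, 3)), [0, 0, 1, 1])
        e = rng.normal(size=(1, 3))
        l1 = prototype_contrastive_loss(Tensor(e), np.array([1]), protos)
        l2 = prototype_contrastive_loss(
            Tensor(np.vstack([e, e])), np.array([1, 1]), protos
        )
        assert l1.item() == pytest.approx(l2.item(), abs=1e-12)

    def test_moving_toward_own_prototype_decreases_loss(self):
        protos = _protoset([[2.0, 0.0], [-2.0, 0.0]], [1, 0])
        far = prototype_contrastive_loss(
            Tensor(np.array([[0.0, 0.0]])), np.array([1]), protos
        )
        near = prototype_contrastive_loss(
            Tensor(np.array([[1.5, 0.0]])), np.array([1]), protos
        )
        assert near.item() < far.item()

    def test_denominator_all_option_differs(self, rng):
        protos = _protoset(rng.normal(size=(4, 3)), [0, 0, 1, 1])
        emb = Tensor(rng.normal(size=(2, 3)))
        labels = np.array([0, 1])
        l_nonclass = prototype_contrastive_loss(emb, labels, protos)
        l_all = prototype_contrastive_loss(emb, labels, protos, denominator="all")
        assert l_all.item() > l_nonclass.item()  # denominator grows

    def test_empty_batch_rejected(self):
        protos = _protoset([[0.0], [1.0]], [0, 1])
        with pytest.raises(ValueError):
            prototype_contrastive_loss(
                Tensor(np.zeros((0, 1))), np.array([], dtype=int), protos
            )

    def test_missing_class_prototypes_rejected(self):
        protos = _protoset([[0.0], [1.0]], [0, 0])
        with pytest.raises(ValueError):
            prototype_contrastive_loss(Tensor(np.zeros((1, 1))), np.array([1]), protos)


class TestFocalLoss:
    def test_confident_correct_prediction_is_near_zero(self):
        assert focal_loss(1 - 1e-7, 1) == pytest.approx(0.0, abs=1e-12)

    def test_half_probability_closed_form(self):
        # α(1−p_t)^γ ln 2 with α=0.25, γ=2, p_t=0.5
        expected = 0.25 * 0.25 * np.log(2.0)
        assert focal_loss(0.5, 1, 0.25, 2.0) == pytest.approx(expected, abs=1e-9)
        assert focal_loss(0.5, 1, 0.25, 2.0) == pytest.approx(0.043322, abs=1e-6)

    @pytest.mark.parametrize("p,y", [(0.3, 1), (0.9, 0), (0.5, 0), (0.99, 1)])
    def test_gamma_zero_reduces_to_weighted_cross_entropy(self, p, y):
        alpha = 0.25
        p_t = p if y == 1 else 1 - p
        alpha_t = alpha if y == 1 else 1 - alpha
        assert focal_loss(p, y, alpha, 0.0) == pytest.approx(
            -alpha_t * np.log(p_t), abs=1e-12
        )

    def test_nonnegative_and_monotone_in_pt(self, rng):
        ps = np.sort(rng.uniform(0.01, 0.99, 25))
        losses = [focal_loss(p, 1) for p in ps]
        assert all(l >= 0 for l in losses)
        assert all(a >= b for a, b in zip(losses, losses[1:]))

    def test_downweights_easy_examples_at_gamma_two(self):
        """The easy/hard loss ratio shrinks far beyond the plain CE ratio."""
        ratio_focal = focal_loss(0.9, 1, 0.25, 2.0) / focal_loss(0.5, 1, 0.25, 2.0)
        ratio_ce = np.log(0.9) / np.log(0.5)
        assert ratio_focal < (0.1 / 0.5) ** 2 * ratio_ce * 1.001

    def test_batched_mean(self, rng):
        p = rng.uniform(0.05, 0.95, 10)
        y = rng.integers(0, 2, 10)
        singles = np.mean([focal_loss(pi, yi) for pi, yi in zip(p, y)])
        assert focal_loss(p, y) == pytest.approx(singles, abs=1e-12)


class TestTotalLoss:
    def test_unweighted_sum(self):
        assert total_loss(0.1, 0.2) == pytest.approx(0.3)
        assert total_loss(0.7, 0.0) == pytest.approx(0.7)

    def test_gradient_reaches_prototypes(self):
        """Finite-difference check of d(total)/d(prototype)."""
        protos = _protoset([[1.0, 0.0], [-1.0, 1.0]], [1, 0])
        emb = Tensor(np.array([[0.3, 0.2]]))
        labels = np.array([1])

        def value():
            return prototype_contrastive_loss(
                emb, labels, protos, temperature=0.5
            ).item()

        loss = prototype_contrastive_loss(emb, labels, protos, temperature=0.5)
        loss.backward()
        eps = 1e-6
        orig = protos.vectors.data[0, 0]
        protos.vectors.data[0, 0] = orig + eps
        up = value()
        protos.vectors.data[0, 0] = orig - eps
        down = value()
        protos.vectors.data[0, 0] = orig
        num = (up - down) / (2 * eps)
        assert protos.vectors.grad[0, 0] == pytest.approx(num, abs=1e-5)
        assert abs(num) > 0


class TestForward:
    @pytest.fixture()
    def module_and_batch(self):
        graph, _ = simulate_gene_graph(SimGraphConfig(n_genes=40, n_features=6, seed=3))
        cfg = ModelConfig(hidden_dim=16, n_heads=2)
        module = MOGTModule(graph.n_features, cfg, seed=11)
        batch = sample_subgraph(graph, np.arange(12))
        return graph, module, batch

    def test_probabilities_finite_in_unit_interval(self, module_and_batch):
        _, module, batch = module_and_batch
        out = module.forward(batch, training=False)
        p = out.probabilities.data
        assert np.isfinite(p).all() and (p >= 0).all() and (p <= 1).all()
        np.testing.assert_allclose(
            p, 1 / (1 + np.exp(-out.logits.data)), atol=1e-12
        )

    def test_evaluation_mode_is_deterministic(self, module_and_batch):
        _, module, batch = module_and_batch
        p1 = module.forward(batch, training=False).probabilities.data
        p2 = module.forward(batch, training=False).probabilities.data
        np.testing.assert_array_equal(p1, p2)

    def test_permutation_equivariance(self):
        """Relabeling nodes permutes center outputs identically."""
        graph, _ = simulate_gene_graph(SimGraphConfig(n_genes=30, n_features=5, seed=9))
        cfg = ModelConfig(hidden_dim=16, n_heads=2)
        module = MOGTModule(graph.n_features, cfg, seed=4)
        perm = np.random.default_rng(0).permutation(graph.n_nodes)
        inv = np.argsort(perm)
        permuted = type(graph)(
            node_ids=[graph.node_ids[perm[i]] for i in range(graph.n_nodes)],
            features=graph.features[perm],
            edges=[],
            labels=graph.labels[perm],
            masks=graph.masks[perm],
        )
        # rebuild edges under the permutation, keeping weights
        from mogt import GeneEdge

        id_of = {g: i for i, g in enumerate(graph.node_ids)}
        permuted.edges = [
            GeneEdge(
                permuted.node_ids[inv[id_of[e.gene_a]]],
                permuted.node_ids[inv[id_of[e.gene_b]]],
                e.weight,
            )
            for e in graph.edges
        ]
        centers = np.arange(8)
        out1 = module.forward(sample_subgraph(graph, centers), training=False)
        # centers in the permuted graph that correspond to original centers
        centers_p = np.array([inv[c] for c in centers])
        batch_p = sample_subgraph(permuted, centers_p)
        out2 = module.forward(batch_p, training=False)
        order1 = {int(c): i for i, c in enumerate(sample_subgraph(graph, centers).centers)}
        got1 = np.array([out1.probabilities.data[order1[int(c)]] for c in centers])
        order2 = {int(c): i for i, c in enumerate(batch_p.centers)}
        got2 = np.array([out2.probabilities.data[order2[int(inv[c])]] for c in centers])
        np.testing.assert_allclose(got1, got2, atol=1e-5)

    def test_feature_dimension_mismatch_rejected(self, module_and_batch):
        graph, module, batch = module_and_batch
        bad = type(batch)(
            node_index=batch.node_index,
            features=batch.features[:, :3],
            src=batch.src,
            dst=batch.dst,
            edge_bias=batch.edge_bias,
            centers=batch.centers,
            member_node=batch.member_node,
            member_center=batch.member_center,
        )
        with pytest.raises(ValueError):
            module.forward(bad)

    def test_checkpoint_round_trip(self, module_and_batch, tmp_path):
        _, module, batch = module_and_batch
        path = tmp_path / "ckpt.npz"
        module.save(path)
        loaded = MOGTModule.load(path)
        p1 = module.forward(batch, training=False).probabilities.data
        p2 = loaded.forward(batch, training=False).probabilities.data
        np.testing.assert_array_equal(p1, p2)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_dim=30, n_heads=4)
        with pytest.raises(ValueError):
            LossConfig(temperature=0.0)
        with pytest.raises(ValueError):
            LossConfig(epsilon=0.0)
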
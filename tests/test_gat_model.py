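import numpy as np
import pytest

from gatmerip import (
    GATConfig,
    attention_coefficients,
    forward,
    forward_logits,
    init_parameters,
    load_checkpoint,
    save_checkpoint,
)
from gatmerip._autodiff import masked_bce_with_logits
from gatmerip.ppi_graph import PPINetwork

from conftest import net_from_pairs


def leaky(x, s=0.2):
    return x if x > 0 else s * x


class TestConfig:
    def test_default_dimensioning(self):
        dims = GATConfig().layer_dims()
        assert dims == [(2, 2, 16), (2, 32, 16), (1, 32, 1)]

    def test_invalid_dropout(self):
        with pytest.raises(ValueError, match="dropout"):
            GATConfig(dropout=1.0)


class TestInit:
    def test_seed_reproducibility(self):
        a = init_parameters(GATConfig(), seed=3)
        b = init_parameters(GATConfig(), seed=3)
        for k in a.tensors:
            assert np.array_equal(a.tensors[k].data, b.tensors[k].data)
        c = init_parameters(GATConfig(), seed=4)
        assert any(
            not np.array_equal(a.tensors[k].data, c.tensors[k].data)
            for k in a.tensors
        )

    def test_shapes_validate(self):
        params = init_parameters(GATConfig(n_edge_types=3), seed=0)
        params.validate_shapes()
        params.tensors["W1_0"].data = np.zeros((5, 5))
        with pytest.raises(ValueError, match="shapes"):
            params.validate_shapes()


class TestAttention:
    def test_weights_sum_to_one_every_layer_and_head(self, small_synth, rng):
        net, feats, _ = small_synth
        cfg = GATConfig(n_edge_types=1)
        params = init_parameters(cfg, seed=1)
        X1 = rng.normal(size=(net.n_nodes, 2))
        X2 = rng.normal(size=(net.n_nodes, 32))
        for layer, X in ((1, X1), (2, X2), (3, X2)):
            heads = cfg.layer_dims()[layer - 1][0]
            for head in range(heads):
                alpha, _, edst = attention_coefficients(layer, head, X, net, params)
                assert np.all(alpha >= 0)
                sums = np.zeros(net.n_nodes)
                np.add.at(sums, edst, alpha)
                assert np.allclose(sums, 1.0, atol=1e-6)

    def test_isolated_node_attends_only_to_itself(self):
        net = PPINetwork(["A", "B", "LONE"], np.array([0, 1]),
                         np.array([1, 0]), np.array([0, 0]), ["ppi"])
        params = init_parameters(GATConfig(), seed=0)
        alpha, esrc, edst = attention_coefficients(
            1, 0, np.random.default_rng(2).normal(size=(3, 2)), net, params
        )
        i = net.node_index["LONE"]
        (k,) = np.where((edst == i))
        assert esrc[k[0]] == i and np.isclose(alpha[k[0]], 1.0)

    def test_identical_neighbors_share_attention(self):
        """Star with all-equal features: self-loop and both neighbor edges
        get 1/3 each (edge projections are zero at initialization)."""
        net = net_from_pairs([("HUB", "L1"), ("HUB", "L2")])
        params = init_parameters(GATConfig(), seed=5)
        X = np.tile([0.4, -1.3], (3, 1))
        alpha, _, edst = attention_coefficients(1, 0, X, net, params)
        hub = net.node_index["HUB"]
        assert np.allclose(alpha[edst == hub], 1 / 3)

    def test_matches_scalar_reimplementation(self, rng):
        """Independent per-edge scalar computation of
        softmax(LeakyReLU(a_dst.Wh_i + a_src.Wh_j + P.g(type)))."""
        net = net_from_pairs([("A", "B"), ("B", "C")])
        cfg = GATConfig(n_edge_types=1)
        params = init_parameters(cfg, seed=7)
        params.tensors["P1_0"].data = rng.normal(size=32)  # exercise edge term
        X = rng.normal(size=(3, 2))

        W = params.tensors["W1_0"].data
        a_src = params.tensors["a_src1_0"].data
        a_dst = params.tensors["a_dst1_0"].data
        P = params.tensors["P1_0"].data
        embed = params.tensors["embed1"].data
        H = X @ W
        edges = [(s, d, t) for s, d, t in
                 zip(net.edge_src, net.edge_dst, net.edge_type)]
        edges += [(i, i, 1) for i in range(3)]  # self-loops, reserved type
        expected = {}
        for i in range(3):
            incoming = [(s, d, t) for s, d, t in edges if d == i]
            logits = [leaky(a_dst @ H[i] + a_src @ H[s] + P @ embed[t])
                      for s, _, t in incoming]
            ez = np.exp(np.array(logits) - max(logits))
            for (s, _, t), a in zip(incoming, ez / ez.sum()):
                expected[(s, i)] = a

        alpha, esrc, edst = attention_coefficients(1, 0, X, net, params)
        for a, s, d in zip(alpha, esrc, edst):
            assert np.isclose(a, expected[(s, d)], atol=1e-12)


class TestForward:
    def test_zeroed_output_layer_gives_half_everywhere(self, triangle_net):
        params = init_parameters(GATConfig(), seed=0)
        params.tensors["W3_0"].data[:] = 0.0
        params.tensors["b3"].data[:] = 0.0
        scores = forward(triangle_net, np.ones((3, 2)), params)
        assert np.allclose(scores, 0.5)

    def test_interchangeable_nodes_score_identically(self):
        net = net_from_pairs([("HUB", "L1"), ("HUB", "L2")])
        params = init_parameters(GATConfig(), seed=2)
        X = np.array([[0.5, -0.5], [1.0, 2.0], [1.0, 2.0]])  # L1 == L2
        scores = forward(net, X, params)
        i1, i2 = net.node_index["L1"], net.node_index["L2"]
        assert scores[i1] == scores[i2]

    def test_permutation_equivariance(self, rng):
        pairs = [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D"), ("B", "D")]
        net = net_from_pairs(pairs)
        mapping = {"A": "W", "B": "Q", "C": "Z", "D": "M"}
        pnet = net_from_pairs([(mapping[a], mapping[b]) for a, b in pairs])
        params = init_parameters(GATConfig(), seed=6)
        X = rng.normal(size=(4, 2))
        pX = np.empty_like(X)
        for g, i in net.node_index.items():
            pX[pnet.node_index[mapping[g]]] = X[i]
        scores = forward(net, X, params)
        pscores = forward(pnet, pX, params)
        for g, i in net.node_index.items():
            assert scores[i] == pscores[pnet.node_index[mapping[g]]]

    def test_eval_forward_is_pure(self, small_synth):
        net, feats, _ = small_synth
        from gatmerip import align_all

        X = align_all(net, feats)["SYN1"][0]
        params = init_parameters(GATConfig(n_edge_types=1), seed=1)
        s1 = forward(net, X, params)
        s2 = forward(net, X, params)
        assert np.array_equal(s1, s2)
        assert np.all((s1 > 0) & (s1 < 1))

    def test_shape_mismatch_rejected(self, triangle_net):
        params = init_parameters(GATConfig(), seed=0)
        with pytest.raises(ValueError, match="features must be"):
            forward(triangle_net, np.ones((3, 5)), params)

    def test_nan_features_rejected(self, triangle_net):
        params = init_parameters(GATConfig(), seed=0)
        X = np.ones((3, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            forward(triangle_net, X, params)


class TestGradients:
    def test_analytic_matches_central_differences(self, rng):
        """Loss gradients vs finite differences on a 5-node fixture."""
        net = net_from_pairs(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("A", "E"),
             ("B", "D")]
        )
        cfg = GATConfig(dropout=0.0, n_edge_types=1)
        params = init_parameters(cfg, seed=4)
        X = rng.normal(size=(5, 2))
        y = np.array([1, 0, 1, 0, 1], dtype=float)
        mask = np.ones(5)

        def loss_value():
            logits = forward_logits(net, X, params, mode="train",
                                    rng=np.random.default_rng(0))
            return masked_bce_with_logits(logits, y, mask)

        loss = loss_value()
        loss.backward()
        grads = {k: t.grad.copy() for k, t in params.tensors.items()
                 if t.grad is not None}

        eps = 1e-6
        checked = 0
        for name in sorted(grads):
            t = params.tensors[name]
            flat = t.data.reshape(-1)
            for j in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                up = loss_value().data
                flat[j] = orig - eps
                down = loss_value().data
                flat[j] = orig
                fd = (up - down) / (2 * eps)
                an = grads[name].reshape(-1)[j]
                denom = max(abs(fd), abs(an), 1e-8)
                assert abs(fd - an) / denom < 1e-4, (name, j, fd, an)
                checked += 1
        assert checked >= 30


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        params = init_parameters(GATConfig(n_edge_types=2), seed=8)
        p = tmp_path / "model.json"
        save_checkpoint(params, p)
        back = load_checkpoint(p)
        assert back.config == params.config and back.seed == params.seed
        for k in params.tensors:
            assert np.array_equal(back.tensors[k].data, params.tensors[k].data)
        for k in params.running:
            assert np.array_equal(back.running[k], params.running[k])

    def test_corrupt_shapes_rejected(self, tmp_path):
        import json

        params = init_parameters(GATConfig(), seed=0)
        p = tmp_path / "model.json"
        save_checkpoint(params, p)
        payload = json.loads(p.read_text())
        payload["tensors"]["W1_0"] = [[0.0, 0.0]]
        p.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="shapes"):
            load_checkpoint(p)
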
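import numpy as np
import pytest
import scipy.sparse as sp

from sgcd import autodiff as ad
from sgcd.graph_io import GeneNetwork, LabelSet, symmetric_normalize
from sgcd.model import (
    GeneScores,
    ModelConfig,
    bce_loss,
    bimodal_extract,
    forward,
    graph_encoder,
    init_params,
    load_checkpoint,
    model_logp,
    predict,
    rs_layer,
    save_checkpoint,
)

from conftest import make_network
from dense_oracle import dense_forward_logp


def weights_of(params):
    return {k: v.data for k, v in params.tensors.items()}


class TestInitParams:
    def test_same_seed_bitwise_identical(self):
        cfg = ModelConfig()
        a = init_params(cfg, f=8, n=5, seed=3)
        b = init_params(cfg, f=8, n=5, seed=3)
        for k in a.tensors:
            assert np.array_equal(a[k].data, b[k].data)

    def test_different_seeds_differ(self):
        cfg = ModelConfig()
        a = init_params(cfg, f=8, n=5, seed=1)
        b = init_params(cfg, f=8, n=5, seed=2)
        assert any(not np.array_equal(a[k].data, b[k].data) for k in a.tensors)

    def test_shape_ledger_default_dims(self):
        cfg = ModelConfig()  # L=2, d=d_h=64
        p = init_params(cfg, f=64, n=10, seed=0)
        assert p["Wprime"].shape == (128, 2)
        assert p["W1"].shape == (128, 64)
        assert p["W2"].shape == (256, 64)

    @pytest.mark.parametrize("L", [1, 2, 3])
    @pytest.mark.parametrize("d", [4, 64])
    def test_shape_ledger_sweep(self, L, d):
        cfg = ModelConfig(hidden_dim=d, head_dim=d, num_layers=L)
        p = init_params(cfg, f=6, n=7, seed=0)
        assert p["W0"].shape == (6, d)
        for layer in range(1, L + 1):
            assert p[f"W{layer}"].shape == ((2**layer) * d, d)
        assert p["Wprime"].shape == (L * d, 2)
        # forward pass respects the ledger end to end
        net = make_network([(0, 1), (1, 2), (3, 4)], n=7, f=6)
        logp = model_logp(symmetric_normalize(net), net.adjacency,
                          net.features, p, cfg)
        assert logp.shape == (7, 2)


class TestRSLayer:
    def test_isolated_node_duplicates_value(self):
        net = make_network([], n=1, f=1)
        out = rs_layer(symmetric_normalize(net), np.array([[2.5]]))
        assert np.allclose(out.data, [[2.5, 2.5]])

    def test_single_edge_hand_computed(self):
        net = make_network([(0, 1)], n=2, f=1)
        out = rs_layer(symmetric_normalize(net), np.array([[1.0], [0.0]]))
        assert np.allclose(out.data, [[0.5, 0.5], [0.5, 0.5]])

    def test_negative_input_zeroed_by_relu(self):
        net = make_network([(0, 1)], n=2, f=1)
        out = rs_layer(symmetric_normalize(net), -np.ones((2, 1)))
        assert np.all(out.data == 0.0)

    def test_width_doubles(self):
        net = make_network([(0, 1), (1, 2)], n=3, f=1)
        out = rs_layer(symmetric_normalize(net), np.ones((3, 5)))
        assert out.shape == (3, 10)

    def test_dimension_mismatch_reports_sizes(self):
        net = make_network([(0, 1)], n=2, f=1)
        with pytest.raises(ValueError, match="2"):
            rs_layer(symmetric_normalize(net), np.ones((3, 1)))


class TestGraphEncoder:
    def test_zero_everything_gives_zero(self):
        cfg = ModelConfig(hidden_dim=3, head_dim=3, num_layers=2)
        net = make_network([(0, 1)], n=2, f=4)
        p = init_params(cfg, f=4, n=2, seed=0)
        p["W0"].data[:] = 0.0
        out = graph_encoder(symmetric_normalize(net), np.zeros((2, 4)), p, cfg)
        assert np.allclose(out.data, 0.0)

    def test_single_layer_is_one_head_projection(self):
        cfg = ModelConfig(hidden_dim=2, head_dim=3, num_layers=1)
        net = make_network([(0, 1), (1, 2)], n=3, f=2)
        p = init_params(cfg, f=2, n=3, seed=1)
        h = graph_encoder(symmetric_normalize(net), net.features, p, cfg)
        r = rs_layer(symmetric_normalize(net),
                     net.features @ p["W0"].data)
        assert np.allclose(h.data, r.data @ p["W1"].data, atol=1e-12)


class TestBimodalExtract:
    def test_zero_coefficients_zero_output(self, toy_net):
        cfg = ModelConfig(alpha=0.0, beta=0.0, hidden_dim=3, head_dim=3)
        p = init_params(cfg, f=4, n=4, seed=0)
        out = bimodal_extract(toy_net.adjacency, toy_net.features, p, cfg)
        assert np.allclose(out.data, 0.0)

    def test_alpha_one_returns_topology_branch(self, toy_net):
        cfg = ModelConfig(alpha=1.0, beta=0.0, hidden_dim=3, head_dim=3)
        p = init_params(cfg, f=4, n=4, seed=0)
        out = bimodal_extract(toy_net.adjacency, toy_net.features, p, cfg)
        A = toy_net.adjacency.toarray()
        h_A = np.maximum(A @ p["A_W1"].data + p["A_b1"].data, 0) \
            @ p["A_W2"].data + p["A_b2"].data
        assert np.abs(out.data - h_A).max() < 1e-12

    def test_hand_computed_tiny_net(self):
        # n=2, all weights one, no bias, alpha=beta=0.5
        cfg = ModelConfig(alpha=0.5, beta=0.5, hidden_dim=2, head_dim=1,
                          num_layers=1)
        net = make_network([(0, 1)], n=2, f=2,
                           features=np.array([[1.0, 2.0], [3.0, 4.0]]))
        p = init_params(cfg, f=2, n=2, seed=0)
        for k in ("A_W1", "A_W2", "X_W1", "X_W2"):
            p[k].data[:] = 1.0
        for k in ("A_b1", "A_b2", "X_b1", "X_b2"):
            p[k].data[:] = 0.0
        # h_A rows: sum of adjacency row = 1 -> hidden (1,1) -> output 2
        # h_X rows: feature sums 3 and 7 -> hidden (s,s) -> output 2s
        out = bimodal_extract(net.adjacency, net.features, p, cfg)
        expected = 0.5 * np.array([[2.0], [2.0]]) + 0.5 * np.array([[6.0], [14.0]])
        assert np.abs(out.data - expected).max() < 1e-12


class TestPredictAndLoss:
    def test_equal_logits_give_half(self):
        cfg = ModelConfig(hidden_dim=2, head_dim=2, num_layers=1)
        p = init_params(cfg, f=2, n=1, seed=0)
        p["Wprime"].data[:] = 0.0
        scores = predict(np.ones((3, 2)), np.zeros((3, 2)), p)
        assert np.allclose(scores.driver_prob, 0.5)

    def test_shift_invariance(self):
        logp = GeneScores(logp=np.log(np.array([[0.25, 0.75]])))
        # direct check on the softmax identity: logits (0, ln3) -> p=0.75
        z = np.array([[0.0, np.log(3.0)]])
        soft = np.exp(z) / np.exp(z).sum()
        assert soft[0, 1] == pytest.approx(0.75)
        zc = z + 7.3
        softc = np.exp(zc - zc.max()) / np.exp(zc - zc.max()).sum()
        assert np.allclose(soft, softc)

    def test_rows_exponentiate_to_simplex(self, toy_net, small_config):
        p = init_params(small_config, f=4, n=4, seed=0)
        logp = model_logp(symmetric_normalize(toy_net), toy_net.adjacency,
                          toy_net.features, p, small_config)
        assert np.allclose(np.exp(logp.data).sum(axis=1), 1.0, atol=1e-6)

    def test_bce_closed_forms(self):
        n = 7
        half = GeneScores(logp=np.full((n, 2), np.log(0.5)))
        y = np.array([1, 0, 1, 0, 1, 1, 0])
        assert bce_loss(half, y) == pytest.approx(n * np.log(2), rel=1e-12)
        single = GeneScores(logp=np.log(np.array([[0.75, 0.25]])))
        assert bce_loss(single, np.array([1])) == pytest.approx(-np.log(0.25))

    def test_bce_perfect_fit_limit(self):
        eps = 1e-9
        sc = GeneScores(logp=np.log(np.array([[eps, 1 - eps], [1 - eps, eps]])))
        assert bce_loss(sc, np.array([1, 0])) < 1e-6

    def test_bce_decreases_toward_truth(self):
        y = np.array([1])
        losses = [bce_loss(GeneScores(logp=np.log([[1 - p, p]])), y)
                  for p in (0.2, 0.5, 0.9)]
        assert losses[0] > losses[1] > losses[2] >= 0


class TestFullForward:
    def test_matches_dense_loop_oracle(self, small_config):
        rng = np.random.default_rng(0)
        worst = 0.0
        for trial in range(20):
            n = int(rng.integers(2, 11))
            f = int(rng.integers(1, 5))
            mask = rng.random((n, n)) < 0.4
            A = np.triu(mask, 1)
            A = (A + A.T).astype(float)
            X = rng.random((n, f))
            net = GeneNetwork(gene_ids=[f"G{i}" for i in range(n)],
                              adjacency=sp.csr_matrix(A), features=X)
            p = init_params(small_config, f=f, n=n, seed=trial)
            got = model_logp(symmetric_normalize(net), net.adjacency, X,
                             p, small_config).data
            want = dense_forward_logp(A, X, weights_of(p), small_config)
            worst = max(worst, np.abs(got - want).max())
        assert worst < 1e-6

    def test_eq5_logsoftmax_variant_matches_oracle(self):
        cfg = ModelConfig(hidden_dim=3, head_dim=3, num_layers=2,
                          eq5_logsoftmax=True)
        rng = np.random.default_rng(5)
        n, f = 6, 3
        A = np.triu(rng.random((n, n)) < 0.5, 1)
        A = (A + A.T).astype(float)
        X = rng.random((n, f))
        net = GeneNetwork(gene_ids=[f"G{i}" for i in range(n)],
                          adjacency=sp.csr_matrix(A), features=X)
        p = init_params(cfg, f=f, n=n, seed=0)
        got = model_logp(symmetric_normalize(net), net.adjacency, X, p, cfg).data
        want = dense_forward_logp(A, X, weights_of(p), cfg)
        assert np.abs(got - want).max() < 1e-6

    def test_forward_deterministic(self, toy_net, toy_labels, small_config):
        p = init_params(small_config, f=4, n=4, seed=0)
        s1, l1 = forward(toy_net, toy_labels, p, small_config)
        s2, l2 = forward(toy_net, toy_labels, p, small_config)
        assert np.array_equal(s1.logp, s2.logp)
        assert l1 == l2

    def test_permutation_equivariance(self, small_config):
        rng = np.random.default_rng(11)
        n, f = 8, 4
        A = np.triu(rng.random((n, n)) < 0.4, 1)
        A = (A + A.T).astype(float)
        X = rng.random((n, f))
        net = GeneNetwork(gene_ids=[f"G{i}" for i in range(n)],
                          adjacency=sp.csr_matrix(A), features=X)
        p = init_params(small_config, f=f, n=n, seed=0)
        base = model_logp(symmetric_normalize(net), net.adjacency, X,
                          p, small_config).data

        perm = rng.permutation(n)
        Ap = A[perm][:, perm]
        Xp = X[perm]
        netp = GeneNetwork(gene_ids=[f"G{i}" for i in range(n)],
                           adjacency=sp.csr_matrix(Ap), features=Xp)
        pp = p.copy()
        # MLP_A consumes adjacency rows, so its input weights permute too
        pp["A_W1"].data = p["A_W1"].data[perm]
        got = model_logp(symmetric_normalize(netp), netp.adjacency, Xp,
                         pp, small_config).data
        assert np.abs(got - base[perm]).max() < 1e-6


def test_checkpoint_round_trip(tmp_path, small_config):
    p = init_params(small_config, f=4, n=4, seed=9)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, p)
    q = load_checkpoint(path)
    assert q.config == small_config
    for k in p.tensors:
        assert np.array_equal(p[k].data, q[k].data)
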
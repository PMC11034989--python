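"""Topology, two-step convolution layers, heads, and checkpoints."""

import numpy as np
import pytest

from gpgnet import _nn
from gpgnet.exceptions import ContractViolationError, InvalidParameterError
from gpgnet.gpg_core import build_gpg
from gpgnet.graph_model import (
    AblationModel,
    GPGCNModel,
    LayerWeights,
    ModelConfig,
    ablation_forward,
    build_topology,
    classify,
    gcn_embed,
    graphs_to_arrays,
    layer_forward,
)

from conftest import random_dna


def dense_layer_oracle(H_u, H_v, w: LayerWeights, k: int):
    """Reference two-step layer that materializes neighbor lists explicitly."""
    n = 4**k
    H_u1 = np.zeros((n, w.B1.shape[0]))
    for u in range(n):
        neigh = [s * n + t for s in range(n) for t in range(n) if s == u or t == u]
        mean = np.mean([H_v[p] for p in neigh], axis=0)
        H_u1[u] = np.maximum(w.B1 @ H_u[u] + w.W1 @ mean, 0.0)
    H_v1 = np.zeros((n * n, w.B2.shape[0]))
    for s in range(n):
        for t in range(n):
            p = s * n + t
            neigh = [s] if s == t else [s, t]
            mean = np.mean([H_u1[u] for u in neigh], axis=0)
            H_v1[p] = np.maximum(w.B2 @ H_v[p] + w.W2 @ mean, 0.0)
    return H_u1, H_v1


class TestTopology:
    def test_k1_neighbor_counts(self):
        topo = build_topology(1)
        assert topo.n_kmers == 4 and topo.n_pairs == 16
        # self-pair (A,A) = index 0 has a single k-mer neighbor
        assert list(topo.kmer_neighbors_of_pair(0)) == [0]
        # vertex A appears in pairs (A,*) and (*,A): 2*4 - 1 = 7 of them
        assert len(topo.pair_neighbors_of_kmer(0)) == 7
        expected = {topo.pair_index(0, t) for t in range(4)} | {
            topo.pair_index(s, 0) for s in range(4)
        }
        assert set(topo.pair_neighbors_of_kmer(0)) == expected

    def test_k3_sizes(self):
        topo = build_topology(3)
        assert topo.n_kmers == 64 and topo.n_pairs == 4096

    def test_deterministic_construction(self):
        a, b = build_topology(2), build_topology(2)
        assert (a.agg_kmer_to_pair != b.agg_kmer_to_pair).nnz == 0
        assert (a.agg_pair_to_kmer != b.agg_pair_to_kmer).nnz == 0

    def test_aggregation_rows_are_means(self):
        topo = build_topology(2)
        np.testing.assert_allclose(
            np.asarray(topo.agg_kmer_to_pair.sum(axis=1)).ravel(), 1.0
        )
        np.testing.assert_allclose(
            np.asarray(topo.agg_pair_to_kmer.sum(axis=1)).ravel(), 1.0
        )

    @pytest.mark.parametrize("bad", [0, 9])
    def test_k_out_of_range(self, bad):
        with pytest.raises(InvalidParameterError):
            build_topology(bad)


class TestLayerForward:
    def _weights(self, rng, h, c_u, c_v):
        return LayerWeights(
            W1=rng.normal(size=(h, c_v)),
            B1=rng.normal(size=(h, c_u)),
            W2=rng.normal(size=(h, h)),
            B2=rng.normal(size=(h, c_v)),
        )

    def test_identity_case(self, rng):
        """Zero messages + identity self-weights pass features through ReLU."""
        topo = build_topology(1)
        H_u = np.abs(rng.random((4, 2)))
        H_v = np.abs(rng.random((16, 2)))
        w = LayerWeights(
            W1=np.zeros((2, 2)), B1=np.eye(2), W2=np.zeros((2, 2)), B2=np.eye(2)
        )
        H_u1, H_v1 = layer_forward(H_u, H_v, w, topo)
        np.testing.assert_allclose(H_u1, H_u)
        np.testing.assert_allclose(H_v1, H_v)

    def test_mean_of_constant_neighbors(self):
        """With pure message weights, a constant field stays constant."""
        topo = build_topology(1)
        c = 0.7
        H_u = np.full((4, 1), c)
        H_v = np.full((16, 1), c)
        w = LayerWeights(
            W1=np.eye(1), B1=np.zeros((1, 1)), W2=np.eye(1), B2=np.zeros((1, 1))
        )
        H_u1, H_v1 = layer_forward(H_u, H_v, w, topo)
        np.testing.assert_allclose(H_u1, c)
        np.testing.assert_allclose(H_v1, c)

    def test_matches_dense_oracle(self, rng):
        """Vectorized layer equals the explicit neighbor-list reference,
        including the use of updated k-mer features in the pair step."""
        topo = build_topology(1)
        H_u = rng.normal(size=(4, 2))
        H_v = rng.normal(size=(16, 3))
        w = self._weights(rng, 5, 2, 3)
        got_u, got_v = layer_forward(H_u, H_v, w, topo)
        exp_u, exp_v = dense_layer_oracle(H_u, H_v, w, 1)
        np.testing.assert_allclose(got_u, exp_u, rtol=1e-5)
        np.testing.assert_allclose(got_v, exp_v, rtol=1e-5)

    def test_uses_updated_kmer_features(self, rng):
        """The pair update must see h_u^{l+1}, not h_u^l: with B2=0 and the
        k-mer step saturated to zero, pair outputs are zero even though the
        *old* k-mer features are not."""
        topo = build_topology(1)
        H_u = np.abs(rng.random((4, 1))) + 1.0
        H_v = np.abs(rng.random((16, 1)))
        w = LayerWeights(
            W1=np.zeros((1, 1)),
            B1=-np.eye(1),  # forces h_u' = relu(-h_u) = 0
            W2=np.eye(1),
            B2=np.zeros((1, 1)),
        )
        _, H_v1 = layer_forward(H_u, H_v, w, topo)
        np.testing.assert_allclose(H_v1, 0.0)

    def test_neighbor_order_invariance(self, rng):
        """Mean aggregation is invariant to neighbor enumeration order."""
        import scipy.sparse as sp

        topo = build_topology(1)
        H_v = rng.normal(size=(1, 16, 3))
        perm = rng.permutation(16)
        A = topo.agg_pair_to_kmer
        A_perm = sp.csr_matrix(A.toarray()[:, perm])
        out1 = A @ H_v[0]
        out2 = A_perm @ H_v[0][perm]
        np.testing.assert_allclose(out1, out2)

    def test_shape_mismatch_rejected(self, rng):
        topo = build_topology(1)
        w = self._weights(rng, 4, 2, 3)
        with pytest.raises(ContractViolationError):
            layer_forward(rng.random((4, 9)), rng.random((16, 3)), w, topo)


TINY = ModelConfig(
    k=1, d=1, n_layers=2, hidden=3, conv_channels=(3, 2), conv_kernel=4,
    conv_stride=2, embed_dim=5, mlp_hidden=(4,), n_classes=3, seed=11,
)


def tiny_graphs(rng, n=4, L=60):
    return [build_gpg(random_dna(rng, L), k=1, d=1) for _ in range(n)]


class TestGPGCNModel:
    def test_embedding_shape_and_determinism(self, rng):
        model = GPGCNModel(TINY)
        graphs = tiny_graphs(rng)
        e1, e2 = model.embed(graphs), model.embed(graphs)
        assert e1.shape == (4, TINY.embed_dim)
        np.testing.assert_array_equal(e1, e2)

    def test_identical_graphs_identical_embeddings(self, rng):
        model = GPGCNModel(TINY)
        g = tiny_graphs(rng, n=1)[0]
        e = model.embed([g, g.copy()])
        np.testing.assert_array_equal(e[0], e[1])

    def test_probabilities_normalized(self, rng):
        model = GPGCNModel(TINY)
        p = model.predict_proba(tiny_graphs(rng))
        assert p.shape == (4, 3)
        assert (p >= 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_logits_give_uniform(self):
        np.testing.assert_allclose(_nn.softmax(np.zeros((1, 2))), 0.5)

    def test_aux_fusion_matches_plain_model_when_empty(self, rng):
        graphs = tiny_graphs(rng)
        m0 = GPGCNModel(TINY)
        p0 = m0.predict_proba(graphs)
        assert p0.shape == (4, 3)  # aux_dim=0 works without aux input

    def test_aux_mismatch_rejected(self, rng):
        import dataclasses

        cfg = dataclasses.replace(TINY, aux_dim=3)
        model = GPGCNModel(cfg)
        graphs = tiny_graphs(rng)
        with pytest.raises(ContractViolationError):
            model.predict_proba(graphs, aux=None)
        with pytest.raises(ContractViolationError):
            model.predict_proba(graphs, aux=rng.random((4, 2)))

    def test_config_graph_mismatch_rejected(self, rng):
        model = GPGCNModel(TINY)
        wrong = [build_gpg(random_dna(rng, 50), k=2, d=1)]
        with pytest.raises(ContractViolationError):
            model.predict_proba(wrong)

    def test_end_to_end_oracle_composition(self, rng):
        """Model GCN layers match the dense oracle applied layer by layer
        (with enrichment input scaling replicated)."""
        model = GPGCNModel(TINY)
        g = tiny_graphs(rng, n=1)[0]
        H_u, H_v = graphs_to_arrays([g], TINY)
        s_u, s_v = TINY.scale_factors()
        hu, hv = H_u[0] * s_u, H_v[0] * s_v
        for l in range(TINY.n_layers):
            hu, hv = dense_layer_oracle(hu, hv, model.layer_weights(l), 1)
        logits, cache = model.forward(H_u, H_v)
        # compare the cached final pair features against the oracle
        final_Hv = cache[0][-1][6] * (  # mask_v * Z_v is the layer output
            cache[0][-1][5] @ model.layer_weights(TINY.n_layers - 1).W2.T
            + cache[0][-1][1] @ model.layer_weights(TINY.n_layers - 1).B2.T
        )
        np.testing.assert_allclose(final_Hv[0], hv, rtol=1e-5, atol=1e-10)

    def test_gradients_match_finite_differences(self, rng):
        import dataclasses

        cfg = dataclasses.replace(TINY, aux_dim=2)
        model = GPGCNModel(cfg)
        N = 3
        Hu = rng.random((N, 4, 1))
        Hv = rng.random((N, 16, 2))
        aux = rng.random((N, 2))
        y = np.array([0, 1, 2])

        def loss():
            logits, cache = model.forward(Hu, Hv, aux)
            l, dl = _nn.softmax_cross_entropy(logits, y)
            return l, dl, cache

        _, dl, cache = loss()
        grads = model.backward(dl, cache)
        eps = 1e-6
        for name, P in model.params.items():
            for _ in range(3):
                ix = tuple(rng.integers(0, s) for s in P.shape)
                old = P[ix]
                P[ix] = old + eps
                lp, _, _ = loss()
                P[ix] = old - eps
                lm, _, _ = loss()
                P[ix] = old
                num = (lp - lm) / (2 * eps)
                assert grads[name][ix] == pytest.approx(num, rel=1e-3, abs=1e-7)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        model = GPGCNModel(TINY)
        graphs = tiny_graphs(rng)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = GPGCNModel.load(path)
        assert loaded.config == model.config
        np.testing.assert_array_equal(
            model.predict_proba(graphs), loaded.predict_proba(graphs)
        )

    def test_functional_wrappers(self, rng):
        model = GPGCNModel(TINY)
        g = tiny_graphs(rng, n=1)[0]
        np.testing.assert_array_equal(gcn_embed(g, model), model.embed([g])[0])
        np.testing.assert_array_equal(classify(g, model), model.predict_proba([g])[0])


class TestAblationModel:
    def test_probabilities_and_determinism(self, rng):
        model = AblationModel(TINY)
        graphs = tiny_graphs(rng)
        p1, p2 = model.predict_proba(graphs), model.predict_proba(graphs)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(p1, p2)
        g = graphs[0]
        np.testing.assert_array_equal(ablation_forward(g, model), p1[0])
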
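"""Graph-convolutional architecture over gapped pattern graphs.

Every edge of a gapped pattern graph is reified as a *k-mer-pair vertex* so
that edge features can take part in message passing.  The resulting
bipartite topology — 4^(2k) pair vertices, each linked to its two
constituent k-mer vertices — depends only on ``k`` and is shared by all
sequences; only the features differ.

One convolution level performs a two-step update with mean aggregation:
first every k-mer vertex u is updated from its pair neighbors,

    h_u' = sigma(B1 h_u + W1 · mean{h_v : v in N(u)})

then every pair vertex v is updated from the *freshly updated* k-mer
vertices,

    h_v' = sigma(B2 h_v + W2 · mean{h_u' : u in N(v)}).

After ``l`` levels the pair features are concatenated in lexicographic
pair-index order and reduced by a small 1-D CNN head to a fixed-size
embedding; a softmax MLP (optionally fused with auxiliary per-sequence
features at its first layer) produces class probabilities.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _nn
from .exceptions import ContractViolationError, InvalidParameterError
from .gpg_core import GapBinning, GappedPatternGraph


# ---------------------------------------------------------------------------
# topology


class BipartiteTopology:
    """Fixed adjacency between pair vertices and k-mer vertices for one k.

    Pair vertex ``p = s * 4^k + t`` connects to k-mer vertices ``s`` and
    ``t`` (one neighbor when ``s == t``); k-mer vertex ``u`` connects to
    the ``2*4^k - 1`` pairs containing it.  Mean aggregation in each
    direction is materialized as a row-stochastic sparse matrix.
    """

    def __init__(self, k: int):
        if not 1 <= k <= 8:
            raise InvalidParameterError(f"k must be in [1, 8], got {k}")
        self.k = k
        n = 4**k
        self.n_kmers = n
        self.n_pairs = n * n

        s = np.repeat(np.arange(n), n)
        t = np.tile(np.arange(n), n)
        p = np.arange(n * n)

        # pair -> k-mer neighbors (mean over {s, t})
        w = np.where(s == t, 1.0, 0.5)
        rows = np.concatenate([p, p[s != t]])
        cols = np.concatenate([s, t[s != t]])
        dat = np.concatenate([w, w[s != t]])
        self.agg_kmer_to_pair = sp.csr_matrix(
            (dat, (rows, cols)), shape=(self.n_pairs, n)
        )

        # k-mer -> pair neighbors (mean over all pairs containing u)
        deg = 2 * n - 1
        rows = np.concatenate([s, t[s != t]])
        cols = np.concatenate([p, p[s != t]])
        self.agg_pair_to_kmer = sp.csr_matrix(
            (np.full(rows.size, 1.0 / deg), (rows, cols)), shape=(n, self.n_pairs)
        )

        self._agg_k2p_T = self.agg_kmer_to_pair.T.tocsr()
        self._agg_p2k_T = self.agg_pair_to_kmer.T.tocsr()

    def kmer_neighbors_of_pair(self, pair_index: int) -> np.ndarray:
        """Indices of the k-mer vertices adjacent to one pair vertex."""
        return self.agg_kmer_to_pair[pair_index].indices.copy()

    def pair_neighbors_of_kmer(self, kmer_index: int) -> np.ndarray:
        """Indices of the pair vertices adjacent to one k-mer vertex."""
        return self.agg_pair_to_kmer[kmer_index].indices.copy()

    def pair_index(self, s: int, t: int) -> int:
        return s * self.n_kmers + t


def build_topology(k: int) -> BipartiteTopology:
    return BipartiteTopology(k)


def _agg(A: sp.csr_matrix, H: np.ndarray) -> np.ndarray:
    """Apply a (n_out, n_in) aggregation matrix along axis 1 of (N, n_in, c)."""
    N, n_in, c = H.shape
    out = A @ H.transpose(1, 0, 2).reshape(n_in, N * c)
    return out.reshape(A.shape[0], N, c).transpose(1, 0, 2)


# ---------------------------------------------------------------------------
# configuration and weights


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the full model.

    ``window`` > 0 cuts sequences into non-overlapping windows of that
    length, each encoded as its own graph; 0 encodes whole sequences.
    """

    k: int = 3
    d: int = 2
    bin_edges: tuple[int, ...] | None = None  # None -> identity binning
    n_layers: int = 2
    hidden: int = 16
    conv_channels: tuple[int, int] = (16, 8)
    conv_kernel: int = 8
    conv_stride: int = 4
    embed_dim: int = 64
    mlp_hidden: tuple[int, ...] = (64, 32)
    n_classes: int = 2
    aux_dim: int = 0
    window: int = 0
    activation: str = "relu"
    input_scale: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1:
            raise InvalidParameterError("n_layers must be >= 1")
        if self.n_classes < 2:
            raise InvalidParameterError("n_classes must be >= 2")
        for name in ("k", "hidden", "embed_dim"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be positive")
        if self.d < 0:
            raise InvalidParameterError("d must be >= 0")
        if self.activation != "relu":
            raise InvalidParameterError("only the relu activation is supported")

    @property
    def binning(self) -> GapBinning:
        if self.bin_edges is None:
            return GapBinning.identity(self.d)
        return GapBinning.from_edges(self.d, self.bin_edges)

    @property
    def n_bins(self) -> int:
        return self.binning.n_bins

    def scale_factors(self) -> tuple[float, np.ndarray]:
        """Enrichment scaling of the inputs to O(1) magnitude.

        Normalized frequencies have uniform-background expectation 1/4^k
        per vertex and bin_width/4^(2k) per pair bin; dividing by these
        expectations (i.e. feeding enrichment ratios to the network) keeps
        inputs on a unit scale regardless of k, d or binning.
        """
        n = 4**self.k
        widths = np.array([hi - lo + 1 for lo, hi in self.binning.bins], dtype=np.float64)
        return float(n), (n * n) / widths

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        data = dict(data)
        for key in ("bin_edges", "conv_channels", "mlp_hidden"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class LayerWeights:
    """Learned matrices of one two-step convolution level."""

    W1: np.ndarray  # (hidden, c_v_in)   pair -> k-mer message
    B1: np.ndarray  # (hidden, c_u_in)   k-mer self term
    W2: np.ndarray  # (hidden, hidden)   k-mer -> pair message
    B2: np.ndarray  # (hidden, c_v_in)   pair self term


# ---------------------------------------------------------------------------
# spec-level operations


def layer_forward(
    H_u: np.ndarray,
    H_v: np.ndarray,
    weights: LayerWeights,
    topology: BipartiteTopology,
) -> tuple[np.ndarray, np.ndarray]:
    """One two-step convolution level (k-mer update first, then pairs).

    Accepts batched ``(N, n, c)`` or single ``(n, c)`` feature arrays.
    The pair update deliberately consumes the already-updated k-mer
    features.
    """
    single = H_u.ndim == 2
    if single:
        H_u, H_v = H_u[None], H_v[None]
    if H_u.shape[1] != topology.n_kmers or H_v.shape[1] != topology.n_pairs:
        raise ContractViolationError(
            f"features ({H_u.shape}, {H_v.shape}) do not match topology k={topology.k}"
        )
    if weights.B1.shape[1] != H_u.shape[2] or weights.W1.shape[1] != H_v.shape[2]:
        raise ContractViolationError("weight shapes do not match feature widths")
    M_u = _agg(topology.agg_pair_to_kmer, H_v)
    H_u1 = np.maximum(H_u @ weights.B1.T + M_u @ weights.W1.T, 0.0)
    M_v = _agg(topology.agg_kmer_to_pair, H_u1)
    H_v1 = np.maximum(H_v @ weights.B2.T + M_v @ weights.W2.T, 0.0)
    if single:
        return H_u1[0], H_v1[0]
    return H_u1, H_v1


def graphs_to_arrays(
    graphs: list[GappedPatternGraph], config: ModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Stack graph features into ``(N, 4^k, 1)`` and ``(N, 4^2k, B)`` arrays."""
    n = 4**config.k
    for g in graphs:
        if g.k != config.k or g.binning.n_bins != config.n_bins:
            raise ContractViolationError(
                f"graph (k={g.k}, B={g.binning.n_bins}) does not match config "
                f"(k={config.k}, B={config.n_bins})"
            )
    H_u = np.stack([g.vertex for g in graphs])[:, :, None].astype(np.float64)
    # lexicographic pair order: index (s, t) -> s * 4^k + t
    H_v = np.stack([g.pairs.reshape(n * n, -1) for g in graphs]).astype(np.float64)
    return H_u, H_v


# ---------------------------------------------------------------------------
# full model


class GPGCNModel:
    """Gapped-pattern-graph convolutional classifier.

    Holds all parameters in a flat name -> array dict (deterministically
    initialized from ``config.seed``), with explicit forward/backward passes
    so training needs no autodiff framework.
    """

    def __init__(self, config: ModelConfig, topology: BipartiteTopology | None = None):
        self.config = config
        self.topology = topology if topology is not None else build_topology(config.k)
        if self.topology.k != config.k:
            raise ContractViolationError("topology k does not match config")
        self.params: dict[str, np.ndarray] = {}
        self._init_params()

    # -- parameters ---------------------------------------------------------

    def _head_dims(self) -> tuple[int, int, int]:
        cfg = self.config
        c1, c2 = cfg.conv_channels
        t1 = (self.topology.n_pairs - cfg.conv_kernel) // cfg.conv_stride + 1
        t2 = (t1 - cfg.conv_kernel) // cfg.conv_stride + 1
        if t2 < 1:
            raise InvalidParameterError("CNN head reduces the pair axis to nothing")
        return t1, t2, c2 * t2 + c2  # flattened + max-pooled

    def _init_params(self):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        h, B = cfg.hidden, cfg.n_bins
        p = self.params
        c_u, c_v = 1, B
        for l in range(cfg.n_layers):
            p[f"gcn{l}.W1"], _ = _nn.init_linear(rng, h, c_v)
            p[f"gcn{l}.B1"], _ = _nn.init_linear(rng, h, c_u)
            p[f"gcn{l}.W2"], _ = _nn.init_linear(rng, h, h)
            p[f"gcn{l}.B2"], _ = _nn.init_linear(rng, h, c_v)
            c_u = c_v = h
        c1, c2 = cfg.conv_channels
        k_, s_ = cfg.conv_kernel, cfg.conv_stride
        W, b = _nn.init_linear(rng, c1, k_ * h)
        p["conv1.W"], p["conv1.b"] = W.reshape(c1, k_, h), b
        W, b = _nn.init_linear(rng, c2, k_ * c1)
        p["conv2.W"], p["conv2.b"] = W.reshape(c2, k_, c1), b
        _, _, head_in = self._head_dims()
        p["head.W"], p["head.b"] = _nn.init_linear(rng, cfg.embed_dim, head_in)
        dims = (cfg.embed_dim + cfg.aux_dim, *cfg.mlp_hidden, cfg.n_classes)
        for i in range(len(dims) - 1):
            p[f"mlp{i}.W"], p[f"mlp{i}.b"] = _nn.init_linear(rng, dims[i + 1], dims[i])

    def layer_weights(self, level: int) -> LayerWeights:
        p = self.params
        return LayerWeights(
            W1=p[f"gcn{level}.W1"],
            B1=p[f"gcn{level}.B1"],
            W2=p[f"gcn{level}.W2"],
            B2=p[f"gcn{level}.B2"],
        )

    # -- forward ------------------------------------------------------------

    def forward(self, H_u, H_v, aux=None):
        """Logits for a batch; returns ``(logits, cache)`` for backprop."""
        cfg, p = self.config, self.params
        N = H_u.shape[0]
        if cfg.aux_dim:
            if aux is None or aux.shape != (N, cfg.aux_dim):
                raise ContractViolationError(
                    f"expected aux features of shape ({N}, {cfg.aux_dim})"
                )
        if cfg.input_scale:
            s_u, s_v = cfg.scale_factors()
            H_u = H_u * s_u
            H_v = H_v * s_v
        gcn_caches = []
        for l in range(cfg.n_layers):
            w = self.layer_weights(l)
            M_u = _agg(self.topology.agg_pair_to_kmer, H_v)
            Z_u = H_u @ w.B1.T + M_u @ w.W1.T
            mask_u = Z_u > 0
            H_u1 = Z_u * mask_u
            M_v = _agg(self.topology.agg_kmer_to_pair, H_u1)
            Z_v = H_v @ w.B2.T + M_v @ w.W2.T
            mask_v = Z_v > 0
            H_v1 = Z_v * mask_v
            gcn_caches.append((H_u, H_v, M_u, mask_u, H_u1, M_v, mask_v))
            H_u, H_v = H_u1, H_v1

        y1, cache_c1 = _nn.conv1d_forward(H_v, p["conv1.W"], p["conv1.b"], cfg.conv_stride)
        a1, mask_c1 = _nn.relu_forward(y1)
        y2, cache_c2 = _nn.conv1d_forward(a1, p["conv2.W"], p["conv2.b"], cfg.conv_stride)
        a2, mask_c2 = _nn.relu_forward(y2)
        mp, cache_mp = _nn.maxpool_forward(a2)
        flat = a2.reshape(N, -1)
        head_in = np.concatenate([mp, flat], axis=1)
        emb, cache_head = _nn.linear_forward(head_in, p["head.W"], p["head.b"])

        x = emb if not cfg.aux_dim else np.concatenate([emb, aux], axis=1)
        mlp_caches = []
        n_mlp = len(cfg.mlp_hidden) + 1
        for i in range(n_mlp):
            z, cache_l = _nn.linear_forward(x, p[f"mlp{i}.W"], p[f"mlp{i}.b"])
            if i < n_mlp - 1:
                x, mask = _nn.relu_forward(z)
            else:
                x, mask = z, None
            mlp_caches.append((cache_l, mask))
        logits = x
        cache = (
            gcn_caches,
            (cache_c1, mask_c1, cache_c2, mask_c2, cache_mp, a2.shape, cache_head),
            mlp_caches,
        )
        return logits, cache

    def backward(self, dlogits, cache) -> dict[str, np.ndarray]:
        """Parameter gradients from the upstream logits gradient."""
        cfg, p = self.config, self.params
        gcn_caches, head_cache, mlp_caches = cache
        grads: dict[str, np.ndarray] = {}

        g = dlogits
        n_mlp = len(cfg.mlp_hidden) + 1
        for i in reversed(range(n_mlp)):
            cache_l, mask = mlp_caches[i]
            if mask is not None:
                g = _nn.relu_backward(g, mask)
            g, grads[f"mlp{i}.W"], grads[f"mlp{i}.b"] = _nn.linear_backward(
                g, cache_l, p[f"mlp{i}.W"]
            )
        if cfg.aux_dim:
            g = g[:, : cfg.embed_dim]

        cache_c1, mask_c1, cache_c2, mask_c2, cache_mp, a2_shape, cache_head = head_cache
        g, grads["head.W"], grads["head.b"] = _nn.linear_backward(
            g, cache_head, p["head.W"]
        )
        N = a2_shape[0]
        c2 = a2_shape[2]
        d_mp, d_flat = g[:, :c2], g[:, c2:]
        d_a2 = _nn.maxpool_backward(d_mp, cache_mp) + d_flat.reshape(a2_shape)
        g = _nn.relu_backward(d_a2, mask_c2)
        g, grads["conv2.W"], grads["conv2.b"] = _nn.conv1d_backward(
            g, cache_c2, p["conv2.W"], cfg.conv_stride
        )
        g = _nn.relu_backward(g, mask_c1)
        dH_v, grads["conv1.W"], grads["conv1.b"] = _nn.conv1d_backward(
            g, cache_c1, p["conv1.W"], cfg.conv_stride
        )

        dH_u = np.zeros_like(gcn_caches[-1][4])
        for l in reversed(range(cfg.n_layers)):
            w = self.layer_weights(l)
            H_u_in, H_v_in, M_u, mask_u, H_u1, M_v, mask_v = gcn_caches[l]
            dZ_v = dH_v * mask_v
            g2 = dZ_v.reshape(-1, dZ_v.shape[-1])
            grads[f"gcn{l}.B2"] = g2.T @ H_v_in.reshape(-1, H_v_in.shape[-1])
            grads[f"gcn{l}.W2"] = g2.T @ M_v.reshape(-1, M_v.shape[-1])
            dH_v_in = dZ_v @ w.B2
            dM_v = dZ_v @ w.W2
            dH_u1 = dH_u + _agg(self.topology._agg_k2p_T, dM_v)
            dZ_u = dH_u1 * mask_u
            g2 = dZ_u.reshape(-1, dZ_u.shape[-1])
            grads[f"gcn{l}.B1"] = g2.T @ H_u_in.reshape(-1, H_u_in.shape[-1])
            grads[f"gcn{l}.W1"] = g2.T @ M_u.reshape(-1, M_u.shape[-1])
            dH_u = dZ_u @ w.B1
            dM_u = dZ_u @ w.W1
            dH_v = dH_v_in + _agg(self.topology._agg_p2k_T, dM_u)
        return grads

    # -- inference ----------------------------------------------------------

    def embed_arrays(self, H_u, H_v) -> np.ndarray:
        logits_cache = self.forward(H_u, H_v, aux=np.zeros((H_u.shape[0], self.config.aux_dim)) if self.config.aux_dim else None)
        # re-run up to the embedding only: cheaper to recompute from cache
        _, cache = logits_cache
        cache_head = cache[1][6]
        emb = cache_head @ self.params["head.W"].T + self.params["head.b"]
        return emb

    def embed(self, graphs: list[GappedPatternGraph], batch_size: int = 32) -> np.ndarray:
        """Embedding vectors, one row per graph."""
        out = []
        for i in range(0, len(graphs), batch_size):
            H_u, H_v = graphs_to_arrays(graphs[i : i + batch_size], self.config)
            out.append(self.embed_arrays(H_u, H_v))
        return np.concatenate(out) if out else np.empty((0, self.config.embed_dim))

    def predict_proba(
        self,
        graphs: list[GappedPatternGraph],
        aux: np.ndarray | None = None,
        batch_size: int = 32,
    ) -> np.ndarray:
        """Class probabilities, one row per graph (rows sum to 1)."""
        cfg = self.config
        if cfg.aux_dim:
            if aux is None or aux.shape != (len(graphs), cfg.aux_dim):
                raise ContractViolationError(
                    f"expected aux features of shape ({len(graphs)}, {cfg.aux_dim})"
                )
        out = []
        for i in range(0, len(graphs), batch_size):
            H_u, H_v = graphs_to_arrays(graphs[i : i + batch_size], cfg)
            a = aux[i : i + batch_size] if cfg.aux_dim else None
            logits, _ = self.forward(H_u, H_v, a)
            out.append(_nn.softmax(logits))
        return np.concatenate(out) if out else np.empty((0, cfg.n_classes))

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: config JSON + every weight tensor, round-trips bit-exactly."""
        arrays = {f"param::{k}": v for k, v in self.params.items()}
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
            ),
            __class__=np.frombuffer(b"GPGCNModel", dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "GPGCNModel":
        with np.load(path, allow_pickle=False) as z:
            config = ModelConfig.from_dict(json.loads(bytes(z["__config__"]).decode()))
            model = cls(config)
            for key in z.files:
                if key.startswith("param::"):
                    model.params[key[len("param::") :]] = z[key].copy()
        return model

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


class AblationModel:
    """No-GCN control: flattened pair features into a fully connected net.

    Consumes the same gapped pattern graphs; the gapped-pattern frequency
    tensor is flattened and fed directly to an MLP, skipping both the graph
    convolutions and the CNN head.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        n = 4**config.k
        rng = np.random.default_rng(config.seed)
        dims = (n * n * config.n_bins + config.aux_dim, *config.mlp_hidden, config.n_classes)
        self.params: dict[str, np.ndarray] = {}
        for i in range(len(dims) - 1):
            W, b = _nn.init_linear(rng, dims[i + 1], dims[i])
            self.params[f"fc{i}.W"], self.params[f"fc{i}.b"] = W, b

    def forward(self, H_u, H_v, aux=None):
        cfg, p = self.config, self.params
        N = H_v.shape[0]
        if cfg.input_scale:
            _, s_v = cfg.scale_factors()
            H_v = H_v * s_v
        x = H_v.reshape(N, -1)
        if cfg.aux_dim:
            if aux is None or aux.shape != (N, cfg.aux_dim):
                raise ContractViolationError("aux features missing or mis-shaped")
            x = np.concatenate([x, aux], axis=1)
        caches = []
        n_fc = len(cfg.mlp_hidden) + 1
        for i in range(n_fc):
            z, cache_l = _nn.linear_forward(x, p[f"fc{i}.W"], p[f"fc{i}.b"])
            if i < n_fc - 1:
                x, mask = _nn.relu_forward(z)
            else:
                x, mask = z, None
            caches.append((cache_l, mask))
        return x, caches

    def backward(self, dlogits, caches):
        cfg, p = self.config, self.params
        grads = {}
        g = dlogits
        for i in reversed(range(len(cfg.mlp_hidden) + 1)):
            cache_l, mask = caches[i]
            if mask is not None:
                g = _nn.relu_backward(g, mask)
            g, grads[f"fc{i}.W"], grads[f"fc{i}.b"] = _nn.linear_backward(
                g, cache_l, p[f"fc{i}.W"]
            )
        return grads

    def predict_proba(self, graphs, aux=None, batch_size: int = 64) -> np.ndarray:
        cfg = self.config
        out = []
        for i in range(0, len(graphs), batch_size):
            H_u, H_v = graphs_to_arrays(graphs[i : i + batch_size], cfg)
            a = aux[i : i + batch_size] if cfg.aux_dim else None
            logits, _ = self.forward(H_u, H_v, a)
            out.append(_nn.softmax(logits))
        return np.concatenate(out) if out else np.empty((0, cfg.n_classes))

    def copy_params(self):
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params):
        for k in self.params:
            self.params[k] = params[k].copy()


# ---------------------------------------------------------------------------
# thin functional wrappers


def gcn_embed(graph: GappedPatternGraph, model: GPGCNModel) -> np.ndarray:
    """Embedding of a single graph."""
    return model.embed([graph])[0]


def classify(
    graph: GappedPatternGraph,
    model: GPGCNModel,
    aux: np.ndarray | None = None,
) -> np.ndarray:
    """Class probabilities for a single graph."""
    a = aux[None] if aux is not None else None
    return model.predict_proba([graph], a)[0]


def ablation_forward(
    graph: GappedPatternGraph,
    model: AblationModel,
    aux: np.ndarray | None = None,
) -> np.ndarray:
    a = aux[None] if aux is not None else None
    return model.predict_proba([graph], a)[0]


def export_embeddings(ids, embeddings: np.ndarray, path) -> None:
    """TSV export (id + embedding values), one row per sequence."""
    import pandas as pd

    df = pd.DataFrame(embeddings, columns=[f"e{i}" for i in range(embeddings.shape[1])])
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)
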
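"""Gapped pattern graph construction.

A DNA sequence is summarized by the frequencies of its k-mers (vertex
features) and of its gapped k-mer pairs ``s·x·t`` with ``|x| <= d`` (edge
features, resolved by gap length).  All 4^k vertices and 4^(2k) ordered
pairs are always materialized, zeros where absent, so every sequence maps
to tensors of a fixed shape for a given ``(k, d, binning)``.

Counting is windowed: any window that overlaps a non-ACGT character (N and
other ambiguity codes) contributes nothing, while normalization denominators
are computed from the full sequence length (``L - k + 1`` for vertices and
``L - 2k - g + 1`` for pairs at gap ``g``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlreadyNormalizedError,
    InvalidParameterError,
)

ALPHABET = "ACGT"

#: byte -> base code; -1 marks every non-ACGT character (case-insensitive)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA string to int8 codes (A=0, C=1, G=2, T=3, other=-1)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


@dataclass(frozen=True)
class KmerIndexer:
    """Bijection between the 4^k k-mer strings and ``[0, 4^k)``.

    The order is lexicographic with A < C < G < T, read as base-4 digits
    (most significant first), so e.g. ``AAA -> 0`` and ``TTT -> 4^k - 1``.
    """

    k: int

    def __post_init__(self):
        if self.k < 1:
            raise InvalidParameterError(f"k must be >= 1, got {self.k}")

    @property
    def n_kmers(self) -> int:
        return 4**self.k

    def index(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise InvalidParameterError(
                f"expected a {self.k}-mer, got {kmer!r}"
            )
        idx = 0
        for ch in kmer:
            code = _CODE[ord(ch)]
            if code < 0:
                raise InvalidParameterError(f"non-ACGT character in {kmer!r}")
            idx = idx * 4 + int(code)
        return idx

    def inverse(self, index: int) -> str:
        if not 0 <= index < self.n_kmers:
            raise InvalidParameterError(
                f"k-mer index {index} out of range [0, {self.n_kmers})"
            )
        chars = []
        for _ in range(self.k):
            chars.append(ALPHABET[index % 4])
            index //= 4
        return "".join(reversed(chars))

    def all_kmers(self) -> Iterable[str]:
        return ("".join(p) for p in itertools.product(ALPHABET, repeat=self.k))


@dataclass(frozen=True)
class GapBinning:
    """Partition of the gap lengths ``{0, ..., d}`` into contiguous bins.

    ``bins`` holds inclusive ``(lo, hi)`` ranges; they must be ordered,
    disjoint and cover ``{0, ..., d}`` exactly.  The identity binning (one
    gap length per bin) is the default for small ``d``.
    """

    d: int
    bins: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.d < 0:
            raise InvalidParameterError(f"d must be >= 0, got {self.d}")
        expect = 0
        for lo, hi in self.bins:
            if lo != expect or hi < lo:
                raise InvalidParameterError(
                    f"bins {self.bins} do not tile {{0,...,{self.d}}}"
                )
            expect = hi + 1
        if expect != self.d + 1:
            raise InvalidParameterError(
                f"bins {self.bins} do not cover {{0,...,{self.d}}}"
            )

    @classmethod
    def identity(cls, d: int) -> "GapBinning":
        return cls(d=d, bins=tuple((g, g) for g in range(d + 1)))

    @classmethod
    def from_edges(cls, d: int, upper_edges: Sequence[int]) -> "GapBinning":
        """Build bins from inclusive upper edges, e.g. d=4, (2, 4) -> {0..2},{3,4}."""
        bins, lo = [], 0
        for hi in upper_edges:
            bins.append((lo, hi))
            lo = hi + 1
        return cls(d=d, bins=tuple(bins))

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def is_identity(self) -> bool:
        return all(lo == hi for lo, hi in self.bins)

    def bin_of(self, gap: int) -> int:
        for b, (lo, hi) in enumerate(self.bins):
            if lo <= gap <= hi:
                return b
        raise InvalidParameterError(
            f"gap {gap} outside the binning range [0, {self.d}]"
        )

    def gap_to_bin(self) -> np.ndarray:
        out = np.empty(self.d + 1, dtype=np.int64)
        for b, (lo, hi) in enumerate(self.bins):
            out[lo : hi + 1] = b
        return out


@dataclass
class GappedPatternGraph:
    """Fixed-topology feature container for one sequence.

    ``vertex`` has shape ``(4^k,)`` (per-k-mer frequency); ``pairs`` has
    shape ``(4^k, 4^k, B)`` where entry ``(s, t, b)`` is the frequency of
    the gapped pattern ``s·x·t`` with ``|x|`` falling in bin ``b``.
    """

    k: int
    binning: GapBinning
    vertex: np.ndarray
    pairs: np.ndarray
    length: int
    mode: str = "absolute"  # "absolute" | "normalized"

    def __post_init__(self):
        n = 4**self.k
        if self.vertex.shape != (n,):
            raise InvalidParameterError(
                f"vertex features must have shape ({n},), got {self.vertex.shape}"
            )
        if self.pairs.shape != (n, n, self.binning.n_bins):
            raise InvalidParameterError(
                f"pair features must have shape ({n},{n},{self.binning.n_bins}), "
                f"got {self.pairs.shape}"
            )
        if self.mode not in ("absolute", "normalized"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")

    @property
    def n_kmers(self) -> int:
        return 4**self.k

    def copy(self) -> "GappedPatternGraph":
        return replace(self, vertex=self.vertex.copy(), pairs=self.pairs.copy())


def _window_ids(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 ids of all length-k windows plus a validity mask."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    ids = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        ids = ids * 4 + np.where(c < 0, 0, c).astype(np.int64)
        valid &= c >= 0
    return ids, valid


def count_kmers(sequence: str, k: int) -> np.ndarray:
    """Absolute k-mer counts as a length-4^k vector.

    Windows containing any non-ACGT character are skipped.  A sequence
    shorter than ``k`` (including the empty one) yields all zeros.
    """
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    ids, valid = _window_ids(encode_sequence(sequence), k)
    return np.bincount(ids[valid], minlength=4**k).astype(np.int64)


def count_gapped_pairs(sequence: str, k: int, d: int) -> np.ndarray:
    """Gap-resolved pair counts as a ``(4^k, 4^k, d+1)`` tensor.

    Entry ``(s, t, g)`` counts occurrences of ``s·x·t`` with ``|x| = g``.
    ``d = 0`` reproduces the pattern-graph edges (exact concatenations).
    """
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    if d < 0:
        raise InvalidParameterError(f"d must be >= 0, got {d}")
    n = 4**k
    codes = encode_sequence(sequence)
    ids, valid = _window_ids(codes, k)
    out = np.zeros((n, n, d + 1), dtype=np.int64)
    for g in range(d + 1):
        m = codes.size - 2 * k - g + 1
        if m <= 0:
            continue
        left, right = ids[:m], ids[k + g : k + g + m]
        ok = valid[:m] & valid[k + g : k + g + m]
        # the gap itself may contain ambiguity characters only if the two
        # k-mer windows are clean -- the paper's pattern s·x·t puts no
        # constraint on x, but we require the gap characters to be clean as
        # well so that the whole window s·x·t is a genuine substring
        if g > 0:
            gapok = np.ones(m, dtype=bool)
            for j in range(k, k + g):
                gapok &= codes[j : j + m] >= 0
            ok &= gapok
        pair_idx = left[ok] * n + right[ok]
        out[:, :, g] += np.bincount(pair_idx, minlength=n * n).reshape(n, n)
    return out


def normalize(graph: GappedPatternGraph) -> GappedPatternGraph:
    """Convert absolute counts to normalized frequencies.

    Vertex counts are divided by the total number of k-mer windows
    ``L - k + 1``; pair counts at gap ``g`` by ``max(1, L - 2k - g + 1)``.
    Requires identity binning (normalization is defined per gap length and
    applied before any binning).
    """
    if graph.mode == "normalized":
        raise AlreadyNormalizedError("graph is already normalized")
    if not graph.binning.is_identity:
        raise InvalidParameterError(
            "normalize requires identity binning; normalize before bin_gaps"
        )
    L, k = graph.length, graph.k
    if L < k:
        raise InvalidParameterError(
            f"normalization requires L >= k (L={L}, k={k})"
        )
    vertex = graph.vertex / (L - k + 1)
    denom = np.array(
        [max(1, L - 2 * k - g + 1) for g in range(graph.binning.d + 1)],
        dtype=np.float64,
    )
    pairs = graph.pairs / denom
    return replace(graph, vertex=vertex, pairs=pairs, mode="normalized")


def bin_gaps(pair_tensor: np.ndarray, binning: GapBinning) -> np.ndarray:
    """Collapse an identity-binned ``(., ., d+1)`` tensor to ``B`` bins.

    Each binned entry is the sum of the per-gap entries in its range, so the
    total mass is conserved.
    """
    if pair_tensor.shape[-1] != binning.d + 1:
        raise InvalidParameterError(
            f"tensor has {pair_tensor.shape[-1]} gap slots but binning "
            f"covers {{0,...,{binning.d}}}"
        )
    if binning.is_identity:
        return pair_tensor.copy()
    out = np.empty(pair_tensor.shape[:-1] + (binning.n_bins,), pair_tensor.dtype)
    for b, (lo, hi) in enumerate(binning.bins):
        out[..., b] = pair_tensor[..., lo : hi + 1].sum(axis=-1)
    return out


def build_gpg(
    sequence: str,
    k: int = 3,
    d: int = 2,
    binning: GapBinning | None = None,
    normalized: bool = True,
) -> GappedPatternGraph:
    """Build the gapped pattern graph of one sequence.

    Counting, normalization (if requested) and gap binning are composed;
    normalization uses per-gap denominators and happens before binning.
    Runtime is O(dL) at fixed k.
    """
    if binning is None:
        binning = GapBinning.identity(d)
    elif binning.d != d:
        raise InvalidParameterError(
            f"binning covers gaps up to {binning.d} but d={d}"
        )
    L = len(sequence)
    vertex = count_kmers(sequence, k).astype(np.float64)
    pairs = count_gapped_pairs(sequence, k, d).astype(np.float64)
    graph = GappedPatternGraph(
        k=k,
        binning=GapBinning.identity(d),
        vertex=vertex,
        pairs=pairs,
        length=L,
        mode="absolute",
    )
    if normalized and L >= k:
        graph = normalize(graph)
    elif normalized:  # empty/too-short sequence: all-zero features, keep flag
        graph = replace(graph, mode="normalized")
    return replace(graph, pairs=bin_gaps(graph.pairs, binning), binning=binning)


# ---------------------------------------------------------------------------
# serialization


def graph_to_tsv(graph: GappedPatternGraph, path) -> None:
    """Write the nonzero entries to TSV for inspection.

    One row per nonzero entry with columns kmer_s, kmer_t, gap_bin, value;
    vertex entries use ``kmer_t='.'`` and ``gap_bin=-1``.
    """
    idx = KmerIndexer(graph.k)
    rows = []
    for i in np.flatnonzero(graph.vertex):
        rows.append((idx.inverse(int(i)), ".", -1, graph.vertex[i]))
    s_idx, t_idx, b_idx = np.nonzero(graph.pairs)
    for s, t, b in zip(s_idx, t_idx, b_idx):
        rows.append(
            (idx.inverse(int(s)), idx.inverse(int(t)), int(b), graph.pairs[s, t, b])
        )
    pd.DataFrame(rows, columns=["kmer_s", "kmer_t", "gap_bin", "value"]).to_csv(
        path, sep="\t", index=False
    )


def graph_to_npz(graph: GappedPatternGraph, path) -> None:
    np.savez_compressed(
        path,
        k=graph.k,
        d=graph.binning.d,
        bin_lo=np.array([lo for lo, _ in graph.binning.bins]),
        bin_hi=np.array([hi for _, hi in graph.binning.bins]),
        vertex=graph.vertex,
        pairs=graph.pairs,
        length=graph.length,
        mode=graph.mode,
    )


def graph_from_npz(path) -> GappedPatternGraph:
    with np.load(path, allow_pickle=False) as z:
        binning = GapBinning(
            d=int(z["d"]),
            bins=tuple(zip(z["bin_lo"].tolist(), z["bin_hi"].tolist())),
        )
        return GappedPatternGraph(
            k=int(z["k"]),
            binning=binning,
            vertex=z["vertex"],
            pairs=z["pairs"],
            length=int(z["length"]),
            mode=str(z["mode"]),
        )
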
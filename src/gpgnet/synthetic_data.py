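"""Synthetic labeled sequence sets with planted gapped-pattern signatures.

The generator emulates the structure of small genome-classification tasks:
i.i.d. background sequences, class-specific gapped-pattern (or IUPAC motif)
signatures overwritten into them at random non-overlapping positions, SNP
and indel noise, and optional class-conditional Bernoulli auxiliary
features (mimicking protein presence/absence profiles).

The default configuration is a two-class *pair-swap* design: both classes
plant the same left and right 3-mers with a gap of exactly 2, but pair
them differently (class 0: ACG··TGA and GTC··CAT; class 1: ACG··CAT and
GTC··TGA).  Marginal k-mer frequencies and junction contexts are identical
across classes by construction, so the label is carried only by *which*
left k-mer co-occurs with *which* right k-mer at gap 2 — invisible to a
gap-free encoding, by design.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import InvalidParameterError
from .gpg_core import ALPHABET
from .interpret import GappedPattern, expand_iupac
from .training import LabeledDataset, split_dataset

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_signatures() -> dict:
    """Pair-swap planted signatures: classes differ only in gap-2 pairing."""
    return {
        0: [(GappedPattern("ACG", 2, "TGA"), 4), (GappedPattern("GTC", 2, "CAT"), 4)],
        1: [(GappedPattern("ACG", 2, "CAT"), 4), (GappedPattern("GTC", 2, "TGA"), 4)],
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    ``signatures`` maps a class label to a list of ``(pattern_or_motif,
    copies_per_sequence)`` pairs; a pattern is a GappedPattern, a motif an
    IUPAC string.  ``aux_probs`` (K, aux_dim) gives per-class Bernoulli
    presence probabilities for the auxiliary features.
    """

    n_classes: int = 2
    n_per_class: int = 100
    length_range: tuple[int, int] = (1000, 1000)
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    signatures: dict = field(default_factory=default_signatures)
    snp_rate: float = 0.01
    indel_rate: float = 0.0
    aux_dim: int = 0
    aux_probs: np.ndarray | None = None
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise InvalidParameterError("n_per_class must be >= 1")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise InvalidParameterError(f"bad length range {self.length_range}")
        comp = np.asarray(self.composition, dtype=np.float64)
        if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
            raise InvalidParameterError(f"composition {self.composition} must sum to 1")
        for rate in (self.snp_rate, self.indel_rate):
            if not 0 <= rate < 1:
                raise InvalidParameterError("noise rates must be in [0, 1)")
        if self.aux_dim and self.aux_probs is None:
            raise InvalidParameterError("aux_dim > 0 requires aux_probs")

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["signatures"] = {
            str(c): [[str(p), int(m)] for p, m in sigs]
            for c, sigs in self.signatures.items()
        }
        if self.aux_probs is not None:
            d["aux_probs"] = np.asarray(self.aux_probs).tolist()
        return d


def generate_background(
    n: int, length_range, composition, seed_or_rng
) -> list[str]:
    """n i.i.d. background sequences, lengths uniform in the range."""
    comp = np.asarray(composition, dtype=np.float64)
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
        raise InvalidParameterError(f"composition {composition} must sum to 1")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    lo, hi = length_range
    out = []
    for _ in range(n):
        L = int(rng.integers(lo, hi + 1))
        codes = rng.choice(4, size=L, p=comp)
        out.append(_BASES[codes].tobytes().decode("ascii"))
    return out


def _realize(signature, rng: np.random.Generator) -> str:
    """Concrete string for one planted copy of a pattern or IUPAC motif."""
    if isinstance(signature, GappedPattern):
        gap = _BASES[rng.integers(0, 4, size=signature.g)].tobytes().decode("ascii")
        return signature.s + gap + signature.t
    concretes = expand_iupac(signature)
    return concretes[int(rng.integers(0, len(concretes)))]


def plant_signature(
    sequences, signature, copies: int, seed_or_rng
) -> list[str]:
    """Overwrite ``copies`` occurrences of the signature into each sequence.

    Placement is by substitution at random non-overlapping positions, so
    sequence lengths are unchanged.  Each planted copy of a gapped pattern
    uses an independently random gap string.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if copies == 0:
        return list(sequences)
    out = []
    for seq in sequences:
        arr = bytearray(seq.encode("ascii"))
        occupied: list[tuple[int, int]] = []
        for _ in range(copies):
            ins = _realize(signature, rng)
            span = len(ins)
            if span > len(arr):
                raise InvalidParameterError(
                    f"sequence of length {len(arr)} too short for {signature}"
                )
            placed = False
            for _attempt in range(200):
                pos = int(rng.integers(0, len(arr) - span + 1))
                if all(pos + span <= a or pos >= b for a, b in occupied):
                    arr[pos : pos + span] = ins.encode("ascii")
                    occupied.append((pos, pos + span))
                    placed = True
                    break
            if not placed:
                raise InvalidParameterError(
                    f"could not place {copies} non-overlapping copies of {signature}"
                )
        out.append(arr.decode("ascii"))
    return out


def apply_noise(
    sequences, snp_rate: float, indel_rate: float, seed_or_rng
) -> list[str]:
    """Per-position substitution and insertion/deletion noise.

    Each position independently mutates to a uniformly different base with
    probability ``snp_rate``; with probability ``indel_rate`` it suffers an
    indel (equally likely a deletion of the base or an insertion of one
    random base before it).
    """
    for rate in (snp_rate, indel_rate):
        if not 0 <= rate < 1:
            raise InvalidParameterError("noise rates must be in [0, 1)")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out = []
    for seq in sequences:
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        L = codes.size
        if snp_rate > 0:
            hit = np.flatnonzero(rng.random(L) < snp_rate)
            base_idx = np.searchsorted(_BASES, codes[hit])
            # add 1..3 (mod 4) so the substituted base is always different
            shift = rng.integers(1, 4, size=hit.size)
            codes[hit] = _BASES[(base_idx + shift) % 4]
        if indel_rate > 0:
            pieces = []
            hit = rng.random(L) < indel_rate
            is_del = rng.random(L) < 0.5
            prev = 0
            for i in np.flatnonzero(hit):
                if is_del[i]:
                    pieces.append(codes[prev:i])
                    prev = i + 1
                else:
                    pieces.append(codes[prev:i])
                    pieces.append(_BASES[rng.integers(0, 4, size=1)])
                    prev = i
            pieces.append(codes[prev:])
            codes = np.concatenate(pieces)
        out.append(codes.tobytes().decode("ascii"))
    return out


def generate_dataset(config: SimConfig, outdir=None) -> LabeledDataset:
    """Full synthetic dataset: background + signatures + noise + aux + splits.

    When ``outdir`` is given, writes ``sequences.fasta``, ``aux.tsv`` (if
    aux features are configured) and a ``manifest.json`` recording the
    configuration and seed, sufficient for exact regeneration.
    """
    rng = np.random.default_rng(config.seed)
    ids, seqs, labels = [], [], []
    for c in range(config.n_classes):
        batch = generate_background(
            config.n_per_class, config.length_range, config.composition, rng
        )
        for signature, copies in config.signatures.get(c, []):
            batch = plant_signature(batch, signature, copies, rng)
        batch = apply_noise(batch, config.snp_rate, config.indel_rate, rng)
        for i, seq in enumerate(batch):
            ids.append(f"class{c}_seq{i}")
            seqs.append(seq)
            labels.append(c)
    labels = np.asarray(labels, dtype=np.int64)

    aux = None
    if config.aux_dim:
        probs = np.asarray(config.aux_probs, dtype=np.float64)
        if probs.shape != (config.n_classes, config.aux_dim):
            raise InvalidParameterError(
                f"aux_probs must have shape ({config.n_classes}, {config.aux_dim})"
            )
        aux = (rng.random((len(ids), config.aux_dim)) < probs[labels]).astype(np.float64)

    dataset = split_dataset(
        ids, seqs, labels,
        ratios=config.split_ratios,
        seed=config.seed,
        stratified=True,
        aux=aux,
    )
    if outdir is not None:
        _write_dataset(dataset, config, outdir)
    return dataset


def _write_dataset(dataset: LabeledDataset, config: SimConfig, outdir) -> None:
    from pathlib import Path

    from .cli_io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "sequences.fasta"
    write_fasta(zip(dataset.ids, dataset.sequences), fasta)
    labels_path = outdir / "labels.tsv"
    with open(labels_path, "w") as fh:
        fh.write("id\tlabel\tsplit\n")
        for i, sid in enumerate(dataset.ids):
            fh.write(f"{sid}\t{dataset.labels[i]}\t{dataset.split[i]}\n")
    if dataset.aux is not None:
        with open(outdir / "aux.tsv", "w") as fh:
            cols = "\t".join(f"f{j}" for j in range(dataset.aux.shape[1]))
            fh.write(f"id\t{cols}\n")
            for i, sid in enumerate(dataset.ids):
                vals = "\t".join(f"{v:g}" for v in dataset.aux[i])
                fh.write(f"{sid}\t{vals}\n")
    digest = hashlib.sha256(fasta.read_bytes()).hexdigest()
    manifest = {
        "config": config.to_manifest(),
        "seed": config.seed,
        "n_records": len(dataset),
        "fasta_sha256": digest,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
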
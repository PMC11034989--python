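"""Occlusion-based contribution scores for gapped patterns and motifs.

A set of gapped patterns is "removed" by zeroing the corresponding
pair-feature entries of each graph (the features the model actually
consumes); the contribution score is the mean absolute change this causes
in the predicted class probabilities, averaged over an evaluation set.
Each score is compared against a baseline obtained by removing the same
number of uniformly random patterns; a target is *informative* when its
contribution strictly exceeds its baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ContractViolationError, InvalidParameterError
from .gpg_core import KmerIndexer, GappedPatternGraph

#: IUPAC nucleotide ambiguity codes
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True, order=True)
class GappedPattern:
    """A gapped pattern s·x·t: two k-mers separated by a gap of length g."""

    s: str
    g: int
    t: str

    def __post_init__(self):
        if len(self.s) != len(self.t):
            raise InvalidParameterError("s and t must be k-mers of the same k")
        if self.g < 0:
            raise InvalidParameterError("gap length must be >= 0")

    @property
    def k(self) -> int:
        return len(self.s)

    def __str__(self) -> str:
        return f"{self.s}({self.g}){self.t}"


@dataclass
class ContributionReport:
    target: str
    n_patterns: int
    contribution: float
    baseline: float

    @property
    def informative(self) -> bool:
        return self.contribution > self.baseline


def remove_patterns(
    graph: GappedPatternGraph, patterns
) -> GappedPatternGraph:
    """Zero the pair-feature entries addressed by each pattern.

    Vertex features and all other entries are untouched; no renormalization
    is performed, keeping the occlusion local.
    """
    idx = KmerIndexer(graph.k)
    out = graph.copy()
    for pat in patterns:
        if pat.k != graph.k:
            raise InvalidParameterError(
                f"pattern {pat} has k={pat.k}, graph has k={graph.k}"
            )
        if pat.g > graph.binning.d:
            raise InvalidParameterError(
                f"pattern {pat} gap exceeds the graph's range d={graph.binning.d}"
            )
        out.pairs[idx.index(pat.s), idx.index(pat.t), graph.binning.bin_of(pat.g)] = 0.0
    return out


def contribution_score(model, graphs, patterns, aux=None) -> float:
    """Mean absolute probability shift caused by removing the patterns.

    For each graph the class probabilities are predicted before and after
    ``remove_patterns``; the score is the mean over graphs of the mean
    absolute difference of the two probability vectors.
    """
    if not graphs:
        raise InvalidParameterError("empty evaluation set")
    patterns = list(patterns)
    p0 = model.predict_proba(graphs, aux)
    if not patterns:
        return 0.0
    occluded = [remove_patterns(g, patterns) for g in graphs]
    p1 = model.predict_proba(occluded, aux)
    return float(np.mean(np.abs(p0 - p1)))


def pattern_universe(k: int, d: int):
    """All 4^(2k) * (d+1) gapped patterns for the given (k, d)."""
    idx = KmerIndexer(k)
    kmers = [idx.inverse(i) for i in range(idx.n_kmers)]
    return [
        GappedPattern(s, g, t)
        for s, t, g in itertools.product(kmers, kmers, range(d + 1))
    ]


def baseline_score(
    model, graphs, n_patterns: int, repeats: int = 10, seed: int = 0, aux=None
) -> float:
    """Expected contribution of removing ``n_patterns`` random patterns.

    Mean over ``repeats`` of the contribution score for pattern sets drawn
    uniformly without replacement from the full (k, d) pattern universe.
    """
    if not graphs:
        raise InvalidParameterError("empty evaluation set")
    k, d = graphs[0].k, graphs[0].binning.d
    universe = pattern_universe(k, d)
    if n_patterns > len(universe):
        raise InvalidParameterError(
            f"n_patterns={n_patterns} exceeds the universe size {len(universe)}"
        )
    if n_patterns == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(repeats):
        chosen = rng.choice(len(universe), size=n_patterns, replace=False)
        scores.append(
            contribution_score(model, graphs, [universe[i] for i in chosen], aux)
        )
    return float(np.mean(scores))


def expand_iupac(consensus: str):
    """All concrete ACGT strings matching an IUPAC consensus."""
    try:
        choices = [IUPAC[c] for c in consensus.upper()]
    except KeyError as exc:
        raise InvalidParameterError(
            f"invalid IUPAC character {exc.args[0]!r} in {consensus!r}"
        ) from None
    return ["".join(p) for p in itertools.product(*choices)]


def motif_to_patterns(motif: str, k: int, d: int):
    """Every gapped pattern contained in an IUPAC consensus motif.

    Enumerates every start position and gap length g <= d such that
    ``s·x·t`` (|s| = |t| = k) fits inside the motif, expanding ambiguity
    codes in the two k-mer windows only (the gap characters are free).
    Returns a deduplicated set.
    """
    motif = motif.strip().upper()
    if len(motif) < k:
        raise InvalidParameterError(
            f"motif {motif!r} is shorter than k={k}"
        )
    patterns = set()
    for g in range(d + 1):
        span = 2 * k + g
        for start in range(len(motif) - span + 1):
            left = motif[start : start + k]
            right = motif[start + k + g : start + span]
            for s in expand_iupac(left):
                for t in expand_iupac(right):
                    patterns.add(GappedPattern(s, g, t))
    return patterns


def score_motifs(
    model, graphs, motifs: dict, repeats: int = 10, seed: int = 0, aux=None
):
    """Contribution vs. matched random baseline for each motif.

    ``motifs`` maps a motif id to its IUPAC consensus.  Each motif's
    contribution comes from removing all gapped patterns it contains; its
    baseline removes the same number of random patterns.  Returns one
    ContributionReport per motif.
    """
    if not graphs:
        raise InvalidParameterError("empty evaluation set")
    k, d = graphs[0].k, graphs[0].binning.d
    reports = []
    for i, (motif_id, consensus) in enumerate(motifs.items()):
        patterns = motif_to_patterns(consensus, k, d)
        contrib = contribution_score(model, graphs, patterns, aux)
        base = baseline_score(
            model, graphs, len(patterns), repeats=repeats, seed=seed + i, aux=aux
        )
        reports.append(
            ContributionReport(
                target=str(motif_id),
                n_patterns=len(patterns),
                contribution=contrib,
                baseline=base,
            )
        )
    return reports


def reports_to_tsv(reports, path) -> None:
    pd.DataFrame(
        [
            {
                "motif_id": r.target,
                "n_patterns": r.n_patterns,
                "contribution": r.contribution,
                "baseline": r.baseline,
                "informative": r.informative,
            }
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False)
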
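import itertools

import numpy as np
import pytest

from gpgnet.gpg_core import KmerIndexer

ACGT = "ACGT"


def oracle_count_kmers(seq: str, k: int) -> np.ndarray:
    """Brute-force k-mer tally by enumerating every substring."""
    idx = KmerIndexer(k)
    counts = np.zeros(4**k, dtype=np.int64)
    for i in range(len(seq) - k + 1):
        sub = seq[i : i + k]
        if all(c in ACGT for c in sub):
            counts[idx.index(sub)] += 1
    return counts


def oracle_count_gapped_pairs(seq: str, k: int, d: int) -> np.ndarray:
    """Brute-force gapped-pair tally: enumerate substrings of length 2k+g
    and decompose each into (left k-mer, gap, right k-mer)."""
    idx = KmerIndexer(k)
    n = 4**k
    out = np.zeros((n, n, d + 1), dtype=np.int64)
    for g in range(d + 1):
        span = 2 * k + g
        for i in range(len(seq) - span + 1):
            sub = seq[i : i + span]
            if all(c in ACGT for c in sub):
                out[idx.index(sub[:k]), idx.index(sub[k + g :]), g] += 1
    return out


def random_dna(rng: np.random.Generator, length: int, with_ambiguity: bool = False) -> str:
    alphabet = ACGT + ("N" if with_ambiguity else "")
    probs = None
    if with_ambiguity:
        probs = [0.24, 0.24, 0.24, 0.24, 0.04]
    return "".join(rng.choice(list(alphabet), size=length, p=probs))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
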
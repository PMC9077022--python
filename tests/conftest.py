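"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's alignment backend: pairwise
identity for the clustering fixtures is computed by strand-aware Hamming
comparison (the fixtures are equal-length and substitution-only, where the
column-wise alignment is optimal), and the brute-force greedy clusterer
re-evaluates the published greedy rule directly.
"""

from __future__ import annotations

import numpy as np
import pytest

from dietbarcode import synthetic
from dietbarcode.amplicon import MergedRead, UniqueSeq

_COMP = str.maketrans("ACGT", "TGCA")


def oracle_revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_identity(a: str, b: str) -> float:
    """Strand-aware identity for equal-length, substitution-only sequences:
    1 - hamming/L, maximized over orientation."""
    assert len(a) == len(b)
    ham = sum(x != y for x, y in zip(a, b))
    ham_rc = sum(x != y for x, y in zip(a, oracle_revcomp(b)))
    return 1.0 - min(ham, ham_rc) / len(a)


def oracle_greedy_partition(
    uniques: list[UniqueSeq], otu_identity: float = 0.97
) -> list[tuple[str, int]]:
    """Exhaustive re-evaluation of the greedy centroid rule (no chimera
    step needed: fixtures contain no spliced sequences).  Returns
    (centroid, accumulated abundance) per cluster in creation order."""
    centroids: list[str] = []
    sizes: list[int] = []
    for u in uniques:
        best_i, best_identity = -1, -1.0
        for i, c in enumerate(centroids):
            ident = oracle_identity(u.seq, c)
            if ident > best_identity:
                best_i, best_identity = i, ident
        if best_i >= 0 and best_identity >= otu_identity:
            sizes[best_i] += u.abundance
        else:
            centroids.append(u.seq)
            sizes.append(u.abundance)
    return list(zip(centroids, sizes))


def mutate_seq(seq: str, positions: list[int], rng: np.random.Generator) -> str:
    """Substitute the given positions with a different base."""
    bases = "ACGT"
    out = list(seq)
    for p in positions:
        out[p] = bases[(bases.index(out[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def make_merged(seq: str, q: int = 40, read_id: str = "r1") -> MergedRead:
    return MergedRead(id=read_id, seq=seq, qual=np.full(len(seq), q, dtype=np.int16))


@pytest.fixture(scope="session")
def small_library():
    return synthetic.generate_reference_library(6, 2, 2, seed=1)


@pytest.fixture(scope="session")
def community(small_library):
    library, _ = small_library
    return synthetic.generate_mock_diet(library, 8, 1.0, seed=2)
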
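"""Shared fixtures and independent reference oracles.

The oracles here are deliberately plain-Python (explicit loops, stdlib
math) and never call the scanning/correlation code paths they check.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pytest

from regnominate.genome_io import PromoterRegion

DATA_DIR = Path(__file__).parent / "data"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


@pytest.fixture
def toy_genome_paths():
    return DATA_DIR / "toy_genome.fa", DATA_DIR / "toy_genome.gff3"


def make_promoter(sequence: str, gene_id: str = "g1", strand: str = "+",
                  contig_id: str = "ctg1", start: int = 0) -> PromoterRegion:
    return PromoterRegion(
        gene_id=gene_id, contig_id=contig_id, start=start,
        end=start + len(sequence), sequence=sequence, strand=strand,
        truncated=False,
    )


def brute_consensus_hits(seq: str, pattern: str) -> list[tuple[int, str]]:
    """Enumerate every window on both strands and test IUPAC membership.

    A window containing any base outside {A,C,G,T} never matches.
    Returns (offset, strand_relative) pairs.
    """
    L = len(pattern)
    hits = []
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        if any(b not in "ACGT" for b in window):
            continue
        if all(b in IUPAC[p] for b, p in zip(window, pattern)):
            hits.append((off, "same"))
        if all(b in IUPAC[p] for b, p in zip(rc(window), pattern)):
            hits.append((off, "opposite"))
    return hits


def brute_matrix_hits(
    seq: str,
    counts: np.ndarray,
    threshold_frac: float,
    background: np.ndarray,
    pseudocount: float = 0.5,
) -> list[tuple[int, str]]:
    """Log-odds scan by explicit enumeration, independent of the package.

    Scores every window on both strands against a pseudocounted
    frequency matrix over the given background; a window is a hit when
    its score reaches threshold_frac of the maximum attainable score
    (1e-9 cutoff tolerance, part of the scan contract).
    """
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = counts.shape[1]
    pssm = [[0.0] * L for _ in range(4)]
    for j in range(L):
        col_total = sum(counts[i][j] for i in range(4)) + 4 * pseudocount
        for i in range(4):
            p = (counts[i][j] + pseudocount) / col_total
            pssm[i][j] = math.log2(p / background[i])
    max_score = sum(max(pssm[i][j] for i in range(4)) for j in range(L))
    cutoff = threshold_frac * max_score - 1e-9

    hits = []
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        if any(b not in base_idx for b in window):
            continue
        fwd = sum(pssm[base_idx[b]][j] for j, b in enumerate(window))
        rev = sum(pssm[base_idx[b]][j] for j, b in enumerate(rc(window)))
        if fwd >= cutoff:
            hits.append((off, "same"))
        if rev >= cutoff:
            hits.append((off, "opposite"))
    return hits


def brute_pearson(x, y) -> float:
    """Pearson r by the raw sum formula, plain Python."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


@pytest.fixture
def cascade_fixture():
    from regnominate.synthetic_data import make_cascade_benchmark

    return make_cascade_benchmark()


def random_dna(rng: np.random.Generator, n: int, with_n: float = 0.0) -> str:
    alphabet = "ACGTN" if with_n > 0 else "ACGT"
    if with_n > 0:
        p = [(1 - with_n) / 4] * 4 + [with_n]
        return "".join(rng.choice(list(alphabet), size=n, p=p))
    return "".join(rng.choice(list(alphabet), size=n))
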
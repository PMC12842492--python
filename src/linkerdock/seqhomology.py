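"""Pairwise global sequence alignment for domain-homology comparisons.

Needleman–Wunsch with affine gaps (Gotoh's three-state recursion).  A gap of
length L costs ``gap_open + L * gap_extend``, i.e. opening a gap costs
open + extend and each further gap position costs extend.  Defaults follow
the EMBOSS needle convention: BLOSUM62, gap_open 10, gap_extend 0.5.
Traceback ties are resolved diagonal > up (gap in b) > left (gap in a).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

_NEG = -1e30


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_fraction: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped sequences must have equal length")


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    """Load a published substitution matrix as a plain dict."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(name)
    table: dict[tuple[str, str], float] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


def _validate(seq: str, matrix: dict[tuple[str, str], float], label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    alphabet = {a for a, _ in matrix}
    unknown = sorted(set(seq) - alphabet)
    if unknown:
        raise ValueError(f"{label}: residues {unknown} not in the substitution matrix")


def needleman_wunsch(seq_a: str, seq_b: str,
                     matrix: dict[tuple[str, str], float] | None = None,
                     gap_open: float = 10.0, gap_extend: float = 0.5) -> AlignmentResult:
    """Optimal global alignment score with affine gap penalties, plus one
    deterministic optimal traceback."""
    matrix = matrix if matrix is not None else load_matrix("BLOSUM62")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    _validate(seq_a, matrix, "seq_a")
    _validate(seq_b, matrix, "seq_b")
    n, m = len(seq_a), len(seq_b)
    open_cost = gap_open + gap_extend

    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in seq_b (consume a)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in seq_a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + j * gap_extend)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[(seq_a[i - 1], seq_b[j - 1])]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - open_cost,
                           Ix[i - 1, j] - gap_extend,
                           Iy[i - 1, j] - open_cost)
            Iy[i, j] = max(M[i, j - 1] - open_cost,
                           Iy[i, j - 1] - gap_extend,
                           Ix[i, j - 1] - open_cost)

    end_scores = (M[n, m], Ix[n, m], Iy[n, m])
    score = max(end_scores)

    # traceback; state preference diagonal (M) > up (Ix) > left (Iy)
    state = int(np.argmax(end_scores))  # 0=M, 1=Ix, 2=Iy
    i, j = n, m
    out_a: list[str] = []
    out_b: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            s = matrix[(seq_a[i - 1], seq_b[j - 1])]
            target = M[i, j] - s
            i, j = i - 1, j - 1
            if abs(M[i, j] - target) <= eps:
                state = 0
            elif abs(Ix[i, j] - target) <= eps:
                state = 1
            else:
                state = 2
        elif state == 1:
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            cur = Ix[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - open_cost - cur) <= eps:
                state = 0
            elif abs(Ix[i, j] - gap_extend - cur) <= eps:
                state = 1
            else:
                state = 2
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            cur = Iy[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - open_cost - cur) <= eps:
                state = 0
            elif abs(Iy[i, j] - gap_extend - cur) <= eps:
                state = 2
            else:
                state = 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    return AlignmentResult(aligned_a=aligned_a, aligned_b=aligned_b,
                           score=float(score),
                           identity_fraction=matches / len(aligned_a))


def read_fasta(path) -> tuple[str, str]:
    """Read the first record of a FASTA file; returns (id, sequence)."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq)
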
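"""Internal pairwise local aligner with a Karlin–Altschul-style e-value.

A self-contained, deterministic surrogate for an external BLASTP search:
affine-gap Smith–Waterman (Gotoh) over BLOSUM62, with the raw score mapped
to a bit score and an e-value over a declared effective search space. The
thresholding semantics (e-value <= cut AND identity >= cut) are identical to
what an ingested precomputed hit table would receive, so the two backends
are interchangeable.

Conventions
-----------
* Gap of length L costs ``gap_open + L * gap_extend`` (NCBI-style 11/1).
* Identity % = identical columns / alignment columns of the local alignment
  (gap columns count in the denominator; a local alignment has no end-gaps).
* Traceback is deterministic: the optimal cell with the smallest (i, j) in
  row-major order is chosen, and at each step ties break diagonal first,
  then gap-in-subject (up), then gap-in-query (left).
* Bit score S' = (lambda * S - ln K) / ln 2 with the gapped BLOSUM62
  constants lambda = 0.267, K = 0.041; E = m * n * 2**(-S') where m and n
  are the summed query and subject set lengths (the declared search space).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import log

from Bio.Align import substitution_matrices

GAP_OPEN = 11
GAP_EXTEND = 1
KA_LAMBDA = 0.267
KA_K = 0.041
_LN2 = log(2.0)

NEG_INF = float("-inf")


@lru_cache(maxsize=1)
def _blosum62() -> dict[tuple[str, str], int]:
    mat = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], int] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = int(mat[a, b])
    return table


@dataclass(frozen=True)
class LocalAlignment:
    """Result of one Smith–Waterman alignment (1-based inclusive coords)."""

    score: int
    n_columns: int
    n_identical: int
    n_gap_columns: int
    n_gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int

    @property
    def identity_pct(self) -> float:
        if self.n_columns == 0:
            return 0.0
        return 100.0 * self.n_identical / self.n_columns

    @property
    def n_mismatches(self) -> int:
        return self.n_columns - self.n_identical - self.n_gap_columns


def smith_waterman(
    query: str,
    subject: str,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> LocalAlignment:
    """Affine-gap local alignment of two protein sequences over BLOSUM62.

    Returns the empty alignment (score 0) when no positive-scoring local
    alignment exists.
    """
    if not query or not subject:
        raise ValueError("cannot align an empty sequence")
    sub = _blosum62()
    n, m = len(query), len(subject)

    # H: best score ending at (i, j); E: ending with gap in query (left move);
    # F: ending with gap in subject (up move). Integer scores -> exact ties.
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]

    best, best_i, best_j = 0, 0, 0
    for i in range(1, n + 1):
        qi = query[i - 1]
        Hi, Him1 = H[i], H[i - 1]
        Ei = E[i]
        Fi, Fim1 = F[i], F[i - 1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] - gap_open - gap_extend, Ei[j - 1] - gap_extend)
            f = max(Him1[j] - gap_open - gap_extend, Fim1[j] - gap_extend)
            d = Him1[j - 1] + sub[(qi, subject[j - 1])]
            h = max(0, d, f, e)
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
            if h > best:  # strict: keeps smallest (i, j) in row-major order
                best, best_i, best_j = h, i, j

    if best == 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0, 0, 0)

    # deterministic traceback: diagonal > up (gap in subject) > left
    i, j = best_i, best_j
    state = "H"
    n_cols = n_ident = n_gap = n_gap_opens = 0
    while True:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            d = H[i - 1][j - 1] + sub[(query[i - 1], subject[j - 1])]
            if h == d:
                n_cols += 1
                if query[i - 1] == subject[j - 1]:
                    n_ident += 1
                i -= 1
                j -= 1
            elif h == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in subject: consume query residue
            n_cols += 1
            n_gap += 1
            from_open = H[i - 1][j] - (gap_open + gap_extend)
            if F[i][j] == from_open:
                n_gap_opens += 1
                state = "H"
            i -= 1
        else:  # state == "E": gap in query: consume subject residue
            n_cols += 1
            n_gap += 1
            from_open = H[i][j - 1] - (gap_open + gap_extend)
            if E[i][j] == from_open:
                n_gap_opens += 1
                state = "H"
            j -= 1

    return LocalAlignment(
        score=best,
        n_columns=n_cols,
        n_identical=n_ident,
        n_gap_columns=n_gap,
        n_gap_opens=n_gap_opens,
        q_start=i + 1,
        q_end=best_i,
        s_start=j + 1,
        s_end=best_j,
    )


def bit_score(raw_score: float) -> float:
    """Karlin–Altschul bit score from a raw alignment score."""
    return (KA_LAMBDA * raw_score - log(KA_K)) / _LN2


def evalue(raw_score: float, search_space: float) -> float:
    """Expected number of chance alignments at this score.

    ``search_space`` is the declared effective space: the product of the
    summed query-set and subject-set lengths.
    """
    if search_space <= 0:
        raise ValueError("search_space must be positive")
    return search_space * 2.0 ** (-bit_score(raw_score))
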
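"""Pairwise global alignment of repeats and the internal-identity statistic.

The per-protein *internal sequence identity* summarises how alike a WD40
protein's repeats are.  All repeat pairs are globally aligned
(Needleman–Wunsch, affine gaps) and the identity of a pair is the count of
identical aligned residue pairs divided by the length of the shorter repeat.
The protein-level statistic is then::

    max over windows W of 8 contiguous repeats
        max over 6-repeat subsets S of W
            min pairwise identity within S

For proteins of exactly 6 or 7 repeats the window constraint is dropped and
all repeats form the single window.  A protein has internal identity >= X
iff some window contains six repeats that are all mutually >= X identical,
which makes the continuous value returned here the largest such threshold.

Proteins with fewer than six repeats have no defined value (``None``), which
is distinct from a low value.

Classification: HR (highly repetitive) at >= 0.7, MR (moderately repetitive)
at >= 0.4 below 0.7, "other" below 0.4, "undefined" when absent.  HR
proteins are read as products of recent repeat duplication.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices

from .model import (
    AlignmentResult,
    IdentityMatrix,
    RepeatScopeError,
    ValidationError,
    WD40Protein,
)

__all__ = [
    "AlignParams",
    "needleman_wunsch",
    "pairwise_identity",
    "repeat_identity_matrix",
    "internal_identity",
    "classify_repetitiveness",
    "HR_CUTOFF",
    "MR_CUTOFF",
]

HR_CUTOFF = 0.7
MR_CUTOFF = 0.4

_NEG_INF = float("-inf")


@lru_cache(maxsize=None)
def _load_matrix(name: str) -> dict[tuple[str, str], float]:
    """Substitution matrix as a plain dict; any pair involving X scores 0."""
    arr = substitution_matrices.load(name)
    scores: dict[tuple[str, str], float] = {}
    for a in arr.alphabet:
        for b in arr.alphabet:
            scores[(a, b)] = float(arr[a, b])
    for a in arr.alphabet:
        scores[(a, "X")] = 0.0
        scores[("X", a)] = 0.0
    scores[("X", "X")] = 0.0
    return scores


@dataclass(frozen=True)
class AlignParams:
    """Alignment parameters (positive-penalty convention).

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def scores(self) -> dict[tuple[str, str], float]:
        return _load_matrix(self.matrix)


DEFAULT_PARAMS = AlignParams()

# Traceback state codes
_M, _IX, _IY = 0, 1, 2  # diagonal / gap-in-b ("up") / gap-in-a ("left")


def needleman_wunsch(
    a: str, b: str, params: AlignParams = DEFAULT_PARAMS
) -> AlignmentResult:
    """Optimal global alignment with affine gaps and deterministic traceback.

    Ties between co-optimal moves resolve diagonal > up > left, making the
    reported alignment (and hence the identity count) reproducible.
    """
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    sub = params.scores()
    for seq in (a, b):
        for r in seq:
            if (r, r) not in sub:
                raise ValidationError(f"residue {r!r} not in alignment alphabet")
    go, ge = params.gap_open, params.gap_extend
    n, m = len(a), len(b)

    M = np.full((n + 1, m + 1), _NEG_INF)
    Ix = np.full((n + 1, m + 1), _NEG_INF)
    Iy = np.full((n + 1, m + 1), _NEG_INF)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(go + (i - 1) * ge)
        ptr[_IX, i, 0] = _M if i == 1 else _IX
    for j in range(1, m + 1):
        Iy[0, j] = -(go + (j - 1) * ge)
        ptr[_IY, 0, j] = _M if j == 1 else _IY

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub[(ai, b[j - 1])]
            # M: consume both; source preference M > Ix > Iy on ties
            best, src = M[i - 1, j - 1], _M
            if Ix[i - 1, j - 1] > best:
                best, src = Ix[i - 1, j - 1], _IX
            if Iy[i - 1, j - 1] > best:
                best, src = Iy[i - 1, j - 1], _IY
            M[i, j] = best + s
            ptr[_M, i, j] = src
            # Ix: gap in b (move up)
            best, src = M[i - 1, j] - go, _M
            if Ix[i - 1, j] - ge > best:
                best, src = Ix[i - 1, j] - ge, _IX
            if Iy[i - 1, j] - go > best:
                best, src = Iy[i - 1, j] - go, _IY
            Ix[i, j] = best
            ptr[_IX, i, j] = src
            # Iy: gap in a (move left)
            best, src = M[i, j - 1] - go, _M
            if Ix[i, j - 1] - go > best:
                best, src = Ix[i, j - 1] - go, _IX
            if Iy[i, j - 1] - ge > best:
                best, src = Iy[i, j - 1] - ge, _IY
            Iy[i, j] = best
            ptr[_IY, i, j] = src

    # Final state preference mirrors the move preference.
    state, score = _M, M[n, m]
    if Ix[n, m] > score:
        state, score = _IX, Ix[n, m]
    if Iy[n, m] > score:
        state, score = _IY, Iy[n, m]

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        src = ptr[state, i, j]
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == _IX:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        state = src

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    n_identical = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    return AlignmentResult(aligned_a, aligned_b, float(score), n_identical)


def pairwise_identity(aln: AlignmentResult, len_a: int, len_b: int) -> float:
    """Identical aligned pairs divided by the shorter ungapped length."""
    shorter = min(len_a, len_b)
    if shorter <= 0:
        raise ValidationError("identity undefined for zero-length sequence")
    return aln.n_identical / shorter


def repeat_identity_matrix(
    protein: WD40Protein, params: AlignParams = DEFAULT_PARAMS
) -> IdentityMatrix:
    """All-against-all repeat identities within one protein."""
    reps = protein.repeats
    if len(reps) < 2:
        raise ValidationError(
            f"{protein.accession}: need >= 2 repeats for an identity matrix"
        )
    k = len(reps)
    m = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        aln = needleman_wunsch(reps[i].sequence, reps[j].sequence, params)
        ident = pairwise_identity(aln, len(reps[i]), len(reps[j]))
        m[i, j] = m[j, i] = ident
    return IdentityMatrix(protein.accession, m)


def internal_identity(im: IdentityMatrix) -> Optional[float]:
    """Max over 8-repeat windows of the best min-identity 6-clique.

    Returns ``None`` for proteins with fewer than six repeats.
    """
    n = im.n_repeats
    if n < 6:
        return None
    m = im.m
    if n <= 7:
        windows = [tuple(range(n))]
    else:
        windows = [tuple(range(s, s + 8)) for s in range(n - 7)]
    best = 0.0
    for window in windows:
        for subset in itertools.combinations(window, 6):
            lo = min(
                m[i, j] for i, j in itertools.combinations(subset, 2)
            )
            if lo > best:
                best = lo
    return float(best)


def classify_repetitiveness(v: Optional[float]) -> str:
    """HR at >= 0.7, MR at >= 0.4 (below 0.7), other below 0.4; undefined
    when the statistic is absent (fewer than six repeats)."""
    if v is None:
        return "undefined"
    if v >= HR_CUTOFF:
        return "HR"
    if v >= MR_CUTOFF:
        return "MR"
    return "other"
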
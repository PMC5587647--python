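"""Alignment and internal-sequence-identity statistic."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices
from hypothesis import given, strategies as st

from repeatscope.identity import (
    AlignParams,
    classify_repetitiveness,
    internal_identity,
    needleman_wunsch,
    pairwise_identity,
    repeat_identity_matrix,
)
from repeatscope.model import IdentityMatrix, ValidationError
from repeatscope.simulate import SimConfig, simulate_wd40_gene

from conftest import make_protein


# ---------------------------------------------------------------------------
# Needleman-Wunsch


def _bio_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    matrix = substitution_matrices.load(params.matrix)
    arr = np.array(matrix)
    # mirror the in-package convention: X scores 0 against everything
    idx = matrix.alphabet.index("X")
    arr[idx, :] = 0.0
    arr[:, idx] = 0.0
    aligner.substitution_matrix = substitution_matrices.Array(
        alphabet=matrix.alphabet, dims=2, data=arr
    )
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = "global"
    return aligner


def test_self_alignment_is_ungapped_and_fully_identical():
    aln = needleman_wunsch("ACDE", "ACDE")
    assert aln.aligned_a == aln.aligned_b == "ACDE"
    assert aln.n_identical == 4


def test_single_residue_scores_matrix_entry():
    matrix = substitution_matrices.load("BLOSUM62")
    aln = needleman_wunsch("W", "W")
    assert aln.score == matrix["W", "W"]


def test_deletion_is_placed_opposite_the_missing_residue():
    aln = needleman_wunsch("ACDE", "ADE")
    assert aln.aligned_a == "ACDE"
    assert aln.aligned_b == "A-DE"
    assert aln.n_identical == 3


def test_empty_sequence_rejected():
    with pytest.raises(ValidationError):
        needleman_wunsch("", "ACD")


@given(
    st.lists(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12),
        min_size=2,
        max_size=2,
    )
)
def test_optimal_score_matches_independent_aligner(pair):
    """The in-package aligner reaches the same optimum as Bio.Align."""
    a, b = pair
    params = AlignParams()
    ours = needleman_wunsch(a, b, params)
    assert ours.score == pytest.approx(_bio_aligner(params).score(a, b))


def _enumerate_alignments(a: str, b: str):
    """All global alignments as (row_a, row_b) pairs (exponential; tiny n)."""
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for ra, rb in _enumerate_alignments(a[:-1], b[:-1]):
            yield ra + a[-1], rb + b[-1]
    if a:
        for ra, rb in _enumerate_alignments(a[:-1], b):
            yield ra + a[-1], rb + "-"
    if b:
        for ra, rb in _enumerate_alignments(a, b[:-1]):
            yield ra + "-", rb + b[-1]


def _score_alignment(ra: str, rb: str, params: AlignParams) -> float:
    sub = params.scores()
    score = 0.0
    in_gap = None
    for x, y in zip(ra, rb):
        if x != "-" and y != "-":
            score += sub[(x, y)]
            in_gap = None
        else:
            which = "a" if x == "-" else "b"
            score -= params.gap_extend if in_gap == which else params.gap_open
            in_gap = which
    return score


@pytest.mark.parametrize(
    "a,b",
    [("ACDE", "ADE"), ("WW", "W"), ("ACD", "MNP"), ("AAAA", "AA"), ("KR", "KRED")],
)
def test_optimal_score_matches_exhaustive_enumeration(a, b):
    params = AlignParams()
    best = max(
        _score_alignment(ra, rb, params) for ra, rb in _enumerate_alignments(a, b)
    )
    assert needleman_wunsch(a, b, params).score == pytest.approx(best)


# ---------------------------------------------------------------------------
# pairwise identity


def test_identity_uses_shorter_length_denominator():
    aln = needleman_wunsch("ACDEFGHIK", "ACDEFGH")
    assert pairwise_identity(aln, 9, 7) == pytest.approx(7 / 7)
    # constructed: 5 identical pairs over shorter length 7
    from repeatscope.model import AlignmentResult

    manual = AlignmentResult("ACDEFGHIK", "ACDEF--YK", 0.0, 7)
    manual_5 = AlignmentResult("ACDEFGHIK", "ACDEW--YF", 0.0, 5)
    assert pairwise_identity(manual_5, 9, 7) == pytest.approx(5 / 7)


def test_identity_of_repeat_with_itself_is_one(gene_diverged):
    protein, _ = gene_diverged
    for rep in protein.repeats:
        aln = needleman_wunsch(rep.sequence, rep.sequence)
        assert pairwise_identity(aln, len(rep), len(rep)) == 1.0


# ---------------------------------------------------------------------------
# identity matrix and the internal-identity statistic


def test_identity_matrix_of_identical_repeats_is_all_ones():
    im = repeat_identity_matrix(make_protein(n_repeats=3))
    assert np.allclose(im.m, 1.0)


def test_identity_matrix_requires_two_repeats():
    from repeatscope.model import WD40Protein

    lonely = WD40Protein(
        accession="X", gene_id="g", organism_id="o", category="Bacteria",
        sequence="ACDE", repeats=[],
    )
    with pytest.raises(ValidationError):
        repeat_identity_matrix(lonely)


def _oracle_internal_identity(m: np.ndarray):
    """Independent route: largest threshold X (over observed values) such
    that some 8-window holds a 6-clique in the >=X identity graph."""
    n = m.shape[0]
    if n < 6:
        return None
    windows = (
        [tuple(range(n))] if n <= 7 else [tuple(range(s, s + 8)) for s in range(n - 7)]
    )
    candidates = sorted({m[i, j] for i in range(n) for j in range(i + 1, n)} | {0.0})
    best = 0.0
    for x in candidates:
        feasible = any(
            all(m[i, j] >= x for i, j in itertools.combinations(sub, 2))
            for w in windows
            for sub in itertools.combinations(w, 6)
        )
        if feasible:
            best = max(best, x)
    return best


@given(st.integers(min_value=0, max_value=2**32 - 1), st.integers(6, 12))
def test_internal_identity_matches_clique_threshold_oracle(seed, n):
    rng = np.random.default_rng(seed)
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    im = IdentityMatrix("r", m)
    assert internal_identity(im) == pytest.approx(_oracle_internal_identity(m))


def test_internal_identity_small_protein_drops_window_constraint():
    # 7 repeats, all pairwise 0.5: value is the min over any 6-subset
    m = np.full((7, 7), 0.5)
    np.fill_diagonal(m, 1.0)
    assert internal_identity(IdentityMatrix("r", m)) == pytest.approx(0.5)


def test_internal_identity_finds_planted_clique():
    # only repeats 2-7 (0-based 1..6) form a 0.8 clique; others <= 0.3
    n = 10
    m = np.full((n, n), 0.3)
    clique = range(1, 7)
    for i in clique:
        for j in clique:
            m[i, j] = 0.8
    m = np.triu(m) + np.triu(m, 1).T
    np.fill_diagonal(m, 1.0)
    assert internal_identity(IdentityMatrix("r", m)) == pytest.approx(0.8)


def test_internal_identity_undefined_below_six_repeats():
    m = np.eye(5)
    assert internal_identity(IdentityMatrix("r", m)) is None


@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_raising_an_entry_never_decreases_internal_identity(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 11))
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    before = internal_identity(IdentityMatrix("r", m.copy()))
    i, j = rng.integers(n), rng.integers(n)
    while i == j:
        j = rng.integers(n)
    bumped = m.copy()
    bumped[i, j] = bumped[j, i] = min(1.0, bumped[i, j] + rng.random())
    after = internal_identity(IdentityMatrix("r", bumped))
    assert after >= before - 1e-12


def test_identity_declines_with_divergence_time():
    """Expected internal identity is non-increasing in divergence time."""
    levels = []
    for t in (0.0, 0.1, 0.3, 1.0):
        vals = []
        for seed in range(30):
            protein, _ = simulate_wd40_gene(
                SimConfig(n_repeats=7, t=t, omega_sim=0.2, seed=3000 + seed)
            )
            vals.append(internal_identity(repeat_identity_matrix(protein)))
        levels.append(np.mean(vals))
    assert all(a >= b - 1e-9 for a, b in zip(levels, levels[1:]))
    assert levels[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "value,label",
    [
        (0.72, "HR"),
        (0.7, "HR"),
        (0.55, "MR"),
        (0.4, "MR"),
        (0.39, "other"),
        (None, "undefined"),
    ],
)
def test_hr_mr_classification_boundaries(value, label):
    assert classify_repetitiveness(value) == label
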
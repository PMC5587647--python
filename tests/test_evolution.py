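"""NG86 substitution counting against an independent brute-force oracle."""

from __future__ import annotations

import itertools

import pytest
from Bio.Data import CodonTable

from repeatscope.evolution import (
    count_pair_differences,
    median_repeat_ds,
    median_repeat_omega,
    ng86,
    purifying_subset,
    synonymous_site_fraction,
    thread_codon_alignment,
    translate_cds,
)
from repeatscope.identity import needleman_wunsch
from repeatscope.model import (
    AlignmentResult,
    CodonAlignment,
    SubstitutionEstimate,
    ValidationError,
)


# ---------------------------------------------------------------------------
# Independent brute-force oracle (written directly from first principles,
# no caching, Biopython tables accessed on every call).


def _oracle_sites(codon: str, code: int) -> float:
    table = CodonTable.unambiguous_dna_by_id[code]
    syn_total = 0.0
    for pos in range(3):
        neighbours = [
            codon[:pos] + nt + codon[pos + 1 :]
            for nt in "ACGT"
            if nt != codon[pos]
        ]
        usable = [n for n in neighbours if n not in table.stop_codons]
        syn = [n for n in usable if table.forward_table[n] == table.forward_table[codon]]
        if usable:
            syn_total += len(syn) / len(usable)
    return syn_total


def _oracle_differences(ca: str, cb: str, code: int) -> tuple[float, float]:
    table = CodonTable.unambiguous_dna_by_id[code]
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    outcomes = []
    for order in itertools.permutations(positions):
        current, syn, nonsyn, blocked = ca, 0, 0, False
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1 :]
            if nxt in table.stop_codons:
                blocked = True
                break
            if table.forward_table[current] == table.forward_table[nxt]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if not blocked:
            outcomes.append((syn, nonsyn))
    assert outcomes, "oracle found no stop-free path"
    return (
        sum(o[0] for o in outcomes) / len(outcomes),
        sum(o[1] for o in outcomes) / len(outcomes),
    )


def _oracle_ng86(ca: CodonAlignment):
    import math

    pairs = ca.codon_pairs()
    S = sum(
        (_oracle_sites(a, ca.genetic_code) + _oracle_sites(b, ca.genetic_code)) / 2
        for a, b in pairs
    )
    N = 3 * len(pairs) - S
    Sd = Nd = 0.0
    for a, b in pairs:
        s, n = _oracle_differences(a, b, ca.genetic_code)
        Sd += s
        Nd += n
    pS, pN = Sd / S, Nd / N
    def jc(p):
        arg = 1 - 4 * p / 3
        return None if arg <= 0 else -0.75 * math.log(arg)
    return S, N, Sd, Nd, jc(pS), jc(pN)


# A fixed battery of <= 3-codon alignments covering 0/1/2/3-difference
# codon pairs, a stop-adjacent path, and the saturated error path.
_BATTERY = [
    ("GGTGGT", "GGCGGT", 1),   # single synonymous difference
    ("GGTGGT", "GGCGGT", 11),  # same under the bacterial table
    ("TTATTG", "CTACTG", 1),   # Leu synonymous first-position changes
    ("AAAGGG", "AGAGGC", 1),   # mixed syn/nonsyn
    ("TGGTAC", "TGCTAT", 11),  # path adjacent to stop codons (TGA/TAA)
    ("ATGATGATG", "ATAATCACA", 1),  # 3 codons incl. a 2-difference pair
    ("TTTACGGAT", "TTCACGGAC", 11),
    ("AAATTTCCC", "GGGAAATTT", 1),  # all three positions differ per codon
]


@pytest.mark.parametrize("cds_a,cds_b,code", _BATTERY)
def test_ng86_matches_brute_force_oracle(cds_a, cds_b, code):
    ca = CodonAlignment(cds_a, cds_b, code)
    est = ng86(ca)
    S, N, Sd, Nd, dS, dN = _oracle_ng86(ca)
    assert est.S == pytest.approx(S)
    assert est.N == pytest.approx(N)
    assert est.Sd == pytest.approx(Sd)
    assert est.Nd == pytest.approx(Nd)
    if dS is None or dN is None:
        assert est.status == "saturated"
    else:
        assert est.dS == pytest.approx(dS)
        assert est.dN == pytest.approx(dN)
    # sites invariant: N + S = 3 x ungapped codon pairs
    assert est.N + est.S == pytest.approx(3 * len(ca.codon_pairs()))


@pytest.mark.parametrize("cds_a,cds_b,code", _BATTERY)
def test_ng86_is_symmetric_in_its_sequences(cds_a, cds_b, code):
    fwd = ng86(CodonAlignment(cds_a, cds_b, code))
    rev = ng86(CodonAlignment(cds_b, cds_a, code))
    assert fwd.status == rev.status
    for attr in ("N", "S", "Nd", "Sd", "dN", "dS"):
        x, y = getattr(fwd, attr), getattr(rev, attr)
        if x is None or y is None:
            assert x is None and y is None
        else:
            assert x == pytest.approx(y)


def test_ng86_known_worked_example():
    """Gly-Gly pair: third position 4-fold degenerate, one synonymous hit."""
    est = ng86(CodonAlignment("GGTGGT", "GGCGGT", 1))
    assert est.S == pytest.approx(2.0)
    assert est.Sd == pytest.approx(1.0)
    assert est.pS == pytest.approx(0.5)
    assert est.dS == pytest.approx(0.8239, abs=5e-4)
    assert est.dN == 0.0
    assert est.omega == 0.0


def test_ng86_identical_pair_and_saturation():
    same = ng86(CodonAlignment("GGTGGT", "GGTGGT", 1))
    assert same.Sd == same.Nd == 0.0
    assert same.dS == same.dN == 0.0
    assert same.omega is None  # dS = 0: ratio undefined
    sat = ng86(CodonAlignment("GGT", "GGC", 1))
    assert sat.status == "saturated"
    assert sat.dS is None and sat.omega is None


def test_ng86_requires_ungapped_codons():
    with pytest.raises(ValidationError):
        ng86(CodonAlignment("---", "---", 1))


def test_standard_and_bacterial_tables_count_sites_identically():
    """NCBI tables 1 and 11 differ only in initiation codons, so per-codon
    synonymous site counts must agree everywhere."""
    table = CodonTable.unambiguous_dna_by_id[1]
    for codon in table.forward_table:
        assert synonymous_site_fraction(codon, 1) == pytest.approx(
            synonymous_site_fraction(codon, 11)
        )


def test_genetic_code_with_different_degeneracy_changes_sites():
    """Under the vertebrate-mitochondrial table AGA is a stop and ATA
    recodes to Met, so Arg/Ile codons count different synonymous sites."""
    assert synonymous_site_fraction("CGA", 2) != pytest.approx(
        synonymous_site_fraction("CGA", 1)
    )
    assert synonymous_site_fraction("ATT", 2) != pytest.approx(
        synonymous_site_fraction("ATT", 1)
    )


# ---------------------------------------------------------------------------
# codon-alignment threading


def test_threading_ungapped_and_gapped():
    aln = AlignmentResult("MKV", "MKV", 0.0, 3)
    ca = thread_codon_alignment(aln, "ATGAAAGTT", "ATGAAAGTA", 1)
    assert len(ca.codons_a) == 9

    gapped = AlignmentResult("MKV", "M-V", 0.0, 2)
    ca = thread_codon_alignment(gapped, "ATGAAAGTT", "ATGGTA", 1)
    assert ca.codons_b[3:6] == "---"
    assert ca.codon_pairs() == [("ATG", "ATG"), ("GTT", "GTA")]


def test_threading_rejects_wrong_length_or_translation():
    aln = AlignmentResult("MKV", "MKV", 0.0, 3)
    with pytest.raises(ValidationError):
        thread_codon_alignment(aln, "ATGAAA", "ATGAAAGTA", 1)
    with pytest.raises(ValidationError):
        # CDS translates to MKL, alignment says MKV
        thread_codon_alignment(aln, "ATGAAACTT", "ATGAAAGTA", 1)


def test_translate_rejects_internal_stops():
    with pytest.raises(ValidationError):
        translate_cds("ATGTAAGTT", 1)


# ---------------------------------------------------------------------------
# medians and the purifying subset


def _est(ds, omega=0.1, status="ok"):
    return SubstitutionEstimate(
        N=10, S=5, Nd=1, Sd=1, pN=0.1, pS=0.2,
        dN=None if status != "ok" else (omega * ds if ds else 0.0),
        dS=None if status != "ok" else ds,
        omega=None if status != "ok" or not ds else omega,
        status=status,
    )


def test_median_ds_excludes_saturated_and_averages_even_counts():
    assert median_repeat_ds([_est(0.0), _est(0.824), _est(0.824)]) == pytest.approx(0.824)
    assert median_repeat_ds(
        [_est(0.1), _est(None, status="saturated"), _est(0.3)]
    ) == pytest.approx(0.2)
    assert median_repeat_ds([_est(0.0), _est(0.0), _est(0.0)]) == 0.0
    assert median_repeat_ds([_est(None, status="saturated")]) is None


def test_purifying_subset_window_boundaries():
    ds = {"low": 0.5, "in": 1.2, "high": 2.5, "lo_edge": 1.0, "hi_edge": 2.0}
    omega = {k: 0.19 for k in ds}
    subset, med = purifying_subset(ds, omega)
    assert subset == ["in", "lo_edge"]
    assert med == pytest.approx(0.19)
    subset, med = purifying_subset({}, {})
    assert subset == [] and med is None


def test_median_omega_over_usable_estimates():
    assert median_repeat_omega(
        [_est(1.2, omega=0.1), _est(1.4, omega=0.3), _est(None, status="saturated")]
    ) == pytest.approx(0.2)
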
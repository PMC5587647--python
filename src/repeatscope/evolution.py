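"""Codon-level divergence between repeats: NG86 dN/dS with JC correction.

The number of synonymous substitutions per synonymous site (dS) between two
repeat coding sequences approximates neutral divergence and hence the time
since the repeats duplicated; the ratio omega = dN/dS measures selective
pressure (omega << 1: purifying selection).

The estimator is the Nei–Gojobori (1986) counting method:

* per codon, each of the 9 single-nucleotide neighbours is classified as
  synonymous or nonsynonymous under the declared genetic code; mutations to
  stop codons are excluded from the denominator.  Summing the synonymous
  fractions over positions gives the codon's synonymous site count; sites
  are averaged over the two sequences.
* observed differences at codon pairs with 2 or 3 changed positions are
  averaged over all minimal mutation paths with equal weights, discarding
  paths that pass through a stop codon.
* proportions are corrected for multiple hits with the Jukes–Cantor
  formula d = -(3/4) ln(1 - (4/3) p).  When the log argument is
  non-positive the estimate is *saturated* and no rate is reported,
  mirroring the exclusion of undefined estimates rather than clamping.

Genetic codes are NCBI translation tables (1 standard, 11
bacterial/archaeal — note these two assign identical amino acids and so
give identical site counts; they differ only in initiation codons).
"""

from __future__ import annotations

import itertools
import logging
import math
from functools import lru_cache
from statistics import median
from typing import Mapping, Optional, Sequence

from Bio.Data import CodonTable

from .model import (
    AlignmentResult,
    CodonAlignment,
    SubstitutionEstimate,
    ValidationError,
    WD40Protein,
)

__all__ = [
    "genetic_code_table",
    "translate_cds",
    "synonymous_site_fraction",
    "count_pair_differences",
    "thread_codon_alignment",
    "ng86",
    "repeat_pair_estimates",
    "median_repeat_ds",
    "median_repeat_omega",
    "purifying_subset",
    "PURIFYING_DS_MIN",
    "PURIFYING_DS_MAX",
]

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"

#: dS window in which omega is analysed: small dS means too few synonymous
#: changes, dS >= 2 cannot be estimated reliably.
PURIFYING_DS_MIN = 1.0
PURIFYING_DS_MAX = 2.0


@lru_cache(maxsize=None)
def genetic_code_table(code: int) -> tuple[Mapping[str, str], frozenset[str]]:
    """(codon -> amino acid, stop codons) for an NCBI translation table."""
    try:
        table = CodonTable.unambiguous_dna_by_id[code]
    except KeyError as exc:
        raise ValidationError(f"unknown NCBI genetic code table {code}") from exc
    return dict(table.forward_table), frozenset(table.stop_codons)


def translate_cds(cds: str, code: int = 1) -> str:
    """Translate an in-frame CDS (no stop codon) to protein."""
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS length {len(cds)} not divisible by 3")
    forward, stops = genetic_code_table(code)
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in stops:
            raise ValidationError(f"internal stop codon {codon} at nt {i + 1}")
        try:
            out.append(forward[codon])
        except KeyError as exc:
            raise ValidationError(f"unrecognised codon {codon!r} at nt {i + 1}") from exc
    return "".join(out)


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str, code: int = 1) -> float:
    """Synonymous site count of one codon (0..3).

    Per position, the fraction of non-stop single-nucleotide neighbours
    that conserve the amino acid; summed over the three positions.
    """
    forward, stops = genetic_code_table(code)
    if codon in stops or codon not in forward:
        raise ValidationError(f"cannot count sites of non-sense codon {codon!r}")
    aa = forward[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in stops:
                continue
            non_stop += 1
            if forward[mutant] == aa:
                syn += 1
        if non_stop:
            total += syn / non_stop
    return total


@lru_cache(maxsize=None)
def count_pair_differences(
    codon_a: str, codon_b: str, code: int = 1
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Multi-substitution pairs are averaged over all minimal mutation paths
    with equal weights; paths traversing a stop codon are discarded.  In the
    (theoretical) event that every path is blocked by stops, all paths are
    used so that the count is still defined.
    """
    forward, stops = genetic_code_table(code)
    for codon in (codon_a, codon_b):
        if codon in stops or codon not in forward:
            raise ValidationError(f"non-sense codon {codon!r} in alignment")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: Sequence[int]) -> Optional[tuple[float, float]]:
        syn = nonsyn = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in stops:
                return None
            if forward[current] == forward[nxt]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        return syn, nonsyn

    paths = [walk(order) for order in itertools.permutations(diff_positions)]
    valid = [p for p in paths if p is not None]
    if not valid:  # defensive fallback; cannot occur for 1-2 diffs
        valid = [
            _walk_through_stops(codon_a, codon_b, order, forward)
            for order in itertools.permutations(diff_positions)
        ]
    syn = sum(p[0] for p in valid) / len(valid)
    nonsyn = sum(p[1] for p in valid) / len(valid)
    return syn, nonsyn


def _walk_through_stops(codon_a, codon_b, order, forward):
    syn = nonsyn = 0.0
    current = codon_a
    for pos in order:
        nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
        same = forward.get(current) is not None and forward.get(current) == forward.get(nxt)
        if same:
            syn += 1
        else:
            nonsyn += 1
        current = nxt
    return syn, nonsyn


def thread_codon_alignment(
    protein_aln: AlignmentResult,
    cds_a: str,
    cds_b: str,
    genetic_code: int = 1,
) -> CodonAlignment:
    """Thread a protein alignment onto the two coding sequences.

    Each aligned residue pair becomes a codon pair; each protein gap becomes
    a whole-codon gap.  CDS lengths must be exactly 3x the ungapped protein
    lengths and must translate to the aligned residues.
    """
    for cds, length, name in (
        (cds_a, protein_aln.len_a, "a"),
        (cds_b, protein_aln.len_b, "b"),
    ):
        if len(cds) != 3 * length:
            raise ValidationError(
                f"CDS {name} length {len(cds)} != 3 x protein length {length}"
            )
    prot_a = translate_cds(cds_a, genetic_code)
    prot_b = translate_cds(cds_b, genetic_code)
    rows = []
    for aligned, prot, cds in (
        (protein_aln.aligned_a, prot_a, cds_a),
        (protein_aln.aligned_b, prot_b, cds_b),
    ):
        out = []
        i = 0
        for residue in aligned:
            if residue == "-":
                out.append("---")
                continue
            if prot[i] != residue:
                raise ValidationError(
                    f"CDS translates to {prot[i]!r} where alignment has "
                    f"{residue!r} (residue {i + 1})"
                )
            out.append(cds[3 * i : 3 * i + 3])
            i += 1
        rows.append("".join(out))
    return CodonAlignment(rows[0], rows[1], genetic_code)


def _jc_correct(p: float) -> Optional[float]:
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg) + 0.0  # + 0.0 normalises -0.0


def ng86(ca: CodonAlignment) -> SubstitutionEstimate:
    """Nei–Gojobori counting estimate for one codon alignment."""
    pairs = ca.codon_pairs()
    if not pairs:
        raise ValidationError("no ungapped codon pairs to estimate from")
    code = ca.genetic_code
    S_a = sum(synonymous_site_fraction(a, code) for a, _ in pairs)
    S_b = sum(synonymous_site_fraction(b, code) for _, b in pairs)
    S = (S_a + S_b) / 2.0
    N = 3.0 * len(pairs) - S
    Sd = Nd = 0.0
    for a, b in pairs:
        syn, nonsyn = count_pair_differences(a, b, code)
        Sd += syn
        Nd += nonsyn
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    if dS is None or dN is None:
        return SubstitutionEstimate(
            N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS,
            dN=None, dS=None, omega=None, status="saturated",
        )
    omega = dN / dS if dS > 0 else None
    return SubstitutionEstimate(
        N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS,
        dN=dN, dS=dS, omega=omega, status="ok",
    )


def repeat_pair_estimates(
    protein: WD40Protein, genetic_code: int = 1
) -> dict[tuple[int, int], SubstitutionEstimate]:
    """NG86 estimates for every pair of repeats within one protein.

    Repeat CDS segments are cut from the gene CDS by residue coordinates
    (codon i..j for residues i..j; repeats share the reading frame by
    construction).  Repeat pairs are compared ungapped when equal length,
    otherwise threaded through their protein alignment.
    """
    from .identity import needleman_wunsch  # local import avoids cycle at import time

    if protein.cds is None:
        raise ValidationError(f"{protein.accession}: no CDS for rate estimation")
    reps = protein.repeats
    out: dict[tuple[int, int], SubstitutionEstimate] = {}
    for i, j in itertools.combinations(range(len(reps)), 2):
        cds_i = protein.repeat_cds(reps[i])
        cds_j = protein.repeat_cds(reps[j])
        aln = needleman_wunsch(reps[i].sequence, reps[j].sequence)
        ca = thread_codon_alignment(aln, cds_i, cds_j, genetic_code)
        out[(reps[i].index, reps[j].index)] = ng86(ca)
    return out


def median_repeat_ds(
    estimates: Sequence[SubstitutionEstimate],
) -> Optional[float]:
    """Median dS over the usable (non-saturated) repeat-pair estimates.

    ``None`` (with a log message) when every estimate saturated.
    """
    ok = [e.dS for e in estimates if e.status == "ok" and e.dS is not None]
    if not ok:
        logger.warning("median dS unavailable: all repeat-pair estimates saturated")
        return None
    return float(median(ok))


def median_repeat_omega(
    estimates: Sequence[SubstitutionEstimate],
) -> Optional[float]:
    """Median omega over usable estimates that define one (dS > 0)."""
    omegas = [e.omega for e in estimates if e.status == "ok" and e.omega is not None]
    if not omegas:
        return None
    return float(median(omegas))


def purifying_subset(
    median_ds: Mapping[str, Optional[float]],
    median_omega: Mapping[str, Optional[float]],
) -> tuple[list[str], Optional[float]]:
    """Proteins whose median repeat dS falls in [1.0, 2.0) and their median omega.

    dS below 1 carries too little synonymous signal to constrain omega and
    dS of 2 or more is unreliable; within the window, a small median omega
    across proteins indicates purifying selection holding old repeats alike.
    """
    subset = sorted(
        acc
        for acc, ds in median_ds.items()
        if ds is not None and PURIFYING_DS_MIN <= ds < PURIFYING_DS_MAX
    )
    omegas = [
        median_omega[acc]
        for acc in subset
        if median_omega.get(acc) is not None
    ]
    if not omegas:
        if subset:
            logger.warning("purifying subset has no usable omega values")
        else:
            logger.warning("no proteins with median dS in [1.0, 2.0)")
        return subset, None
    return subset, float(median(omegas))
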
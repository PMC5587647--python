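"""Canonical blade template, tetrad calling, and sequence-logo matrices.

Repeats are projected onto a fixed coordinate system — the canonical blade
template — so that positions are comparable across repeats and proteins.
Strand residues (Sa–Sd) are placed positionally, left-anchored into strand
slots of canonical width; loop residues are first multiple-aligned across
the supplied context of repeats and the top 6, 5, 3, and 4 most-occupied
columns are kept for Lda, Lab, Lbc, and Lcd respectively.

The DH[S/T]W *tetrad* is a side-chain hydrogen-bond network (Asp, His,
Ser/Thr, Trp) associated with blade thermal stability; at most one can occur
per repeat.  Its four anchor positions on the template default to the Asp of
the SPDG motif on Lab, the His site on Lda, the final Sb site (Ser/Thr), and
the Trp at template position 37 on Sc; all four are configurable since
different predictors may anchor them slightly differently.

Tetrad density of a protein is complete tetrads divided by repeat count.
Logo matrices are per-position residue counts with Shannon information
content (log2 20 minus column entropy, no small-sample correction).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AMINO_ACIDS,
    BladeTemplate,
    ConfigError,
    LogoMatrix,
    RepeatUnit,
    TemplateMap,
    TetradCall,
    ValidationError,
    WD40Protein,
)
from .identity import AlignParams, DEFAULT_PARAMS, needleman_wunsch

__all__ = [
    "CANONICAL_TEMPLATE",
    "DEFAULT_TETRAD_SITES",
    "LOOP_KEEP",
    "map_repeat_to_template",
    "map_protein",
    "call_tetrad",
    "tetrad_density",
    "logo_matrix",
    "information_content",
    "logo_table",
]

logger = logging.getLogger(__name__)

#: Kept (most conserved) loop sites per loop.
LOOP_KEEP = {"Lda": 6, "Lab": 5, "Lbc": 3, "Lcd": 4}

_SEGMENTS: list[tuple[str, str]] = [
    ("Lda", "GAEHLG"),
    ("Sa", "TLLATGS"),
    ("Lab", "SPDGR"),
    ("Sb", "LLASGST"),
    ("Lbc", "GQL"),
    ("Sc", "AKVNTVRLW"),
    ("Lcd", "DTSN"),
    ("Sd", "VRTLA"),
]

#: Canonical 46-residue blade with the tetrad occupied: His on Lda (4), Asp
#: of the SPDG motif on Lab (16), Thr closing Sb (25), Trp on Sc (37).
CANONICAL_TEMPLATE = BladeTemplate(
    sequence="".join(seq for _, seq in _SEGMENTS),
    labels=tuple(tag for tag, seq in _SEGMENTS for _ in seq),
    tetrad_sites={"H": 4, "D": 16, "ST": 25, "W": 37},
)

DEFAULT_TETRAD_SITES = dict(CANONICAL_TEMPLATE.tetrad_sites)

#: Residues accepted at each tetrad anchor.
_TETRAD_ALLOWED = {"D": {"D"}, "H": {"H"}, "ST": {"S", "T"}, "W": {"W"}}


def _segment_spans(template: BladeTemplate) -> dict[str, tuple[int, int]]:
    """1-based inclusive template span of each structural element."""
    spans: dict[str, tuple[int, int]] = {}
    pos = 1
    for tag, length in template.segment_lengths().items():
        spans[tag] = (pos, pos + length - 1)
        pos += length
    return spans


def _star_msa(segments: Sequence[str], params: AlignParams) -> list[str]:
    """Centre-star multiple alignment of short same-loop segments.

    The longest segment (first on ties) is the star centre; every other
    segment is pairwise-aligned to it and the pairwise alignments are merged
    on centre coordinates, taking the maximum insertion run observed before
    each centre position.
    """
    non_empty = [s for s in segments if s]
    if not non_empty:
        return ["" for _ in segments]
    if len(set(len(s) for s in non_empty)) == 1 and all(segments):
        return list(segments)  # equal lengths: positional alignment
    centre = max(non_empty, key=len)
    c_len = len(centre)
    # Per sequence: residues inserted before centre position p (0..c_len).
    alignments: list[tuple[list[str], str]] = []
    max_ins = [0] * (c_len + 1)
    for seg in segments:
        if not seg:
            alignments.append(([""] * (c_len + 1), ""))
            continue
        if seg == centre:
            alignments.append(([""] * (c_len + 1), centre))
            continue
        aln = needleman_wunsch(centre, seg, params)
        ins = [""] * (c_len + 1)
        matched = [""] * c_len  # residue of seg aligned to each centre pos
        cpos = 0
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if x == "-":
                ins[cpos] += y
            else:
                matched[cpos] = y if y != "-" else "-"
                cpos += 1
        alignments.append((ins, "".join(matched)))
        for p in range(c_len + 1):
            max_ins[p] = max(max_ins[p], len(ins[p]))
    rows: list[str] = []
    for (ins, matched) in alignments:
        if not matched and not any(ins):
            rows.append("-" * (sum(max_ins) + c_len))
            continue
        row = []
        body = matched if matched else "-" * c_len
        for p in range(c_len):
            row.append(ins[p].rjust(max_ins[p], "-"))
            row.append(body[p] if body is not centre else centre[p])
        row.append(ins[c_len].ljust(max_ins[c_len], "-"))
        rows.append("".join(row))
    return rows


def _rank_loop_columns(rows: Sequence[str], k: int) -> list[int]:
    """Top-k columns by occupancy, ties by max single-residue frequency,
    then leftmost; returned in left-to-right order."""
    if not rows or not rows[0]:
        return []
    width = len(rows[0])
    ranked = []
    for col in range(width):
        column = [r[col] for r in rows]
        occ = sum(1 for c in column if c != "-")
        top = max(Counter(c for c in column if c != "-").values(), default=0)
        ranked.append((-occ, -top, col))
    ranked.sort()
    keep = sorted(col for _, _, col in ranked[:k])
    return keep


def map_repeat_to_template(
    repeat: RepeatUnit,
    loop_msa_context: Sequence[RepeatUnit],
    template: BladeTemplate = CANONICAL_TEMPLATE,
    params: AlignParams = DEFAULT_PARAMS,
) -> TemplateMap:
    """Place one repeat onto template coordinates.

    ``loop_msa_context`` supplies the repeats whose loops are aligned
    together (normally all repeats of the same protein, including this one).
    """
    maps = map_protein_repeats([repeat], loop_msa_context, template, params)
    return maps[0]


def map_protein_repeats(
    repeats: Sequence[RepeatUnit],
    loop_msa_context: Sequence[RepeatUnit],
    template: BladeTemplate = CANONICAL_TEMPLATE,
    params: AlignParams = DEFAULT_PARAMS,
) -> list[TemplateMap]:
    """Template maps for several repeats sharing one loop-MSA context."""
    context = list(loop_msa_context)
    for rep in repeats:
        if not any(c is rep or c == rep for c in context):
            context.append(rep)
    spans = _segment_spans(template)

    # Loop placements are computed once per loop over the whole context.
    loop_cols: dict[str, dict[int, list[int]]] = {}
    loop_rows: dict[str, list[str]] = {}
    for tag, k in LOOP_KEEP.items():
        segs = [rep.segment(tag) for rep in context]
        rows = _star_msa(segs, params)
        keep = _rank_loop_columns(rows, k)
        loop_rows[tag] = rows
        loop_cols[tag] = {i: keep for i in range(len(context))}

    out: list[TemplateMap] = []
    for rep in repeats:
        ctx_idx = next(
            i for i, c in enumerate(context) if c is rep or c == rep
        )
        residues: dict[int, str] = {}
        flagged = False
        for tag, (lo, hi) in spans.items():
            slot = hi - lo + 1
            seg = rep.segment(tag)
            if not seg:
                flagged = True
                continue
            if tag in LOOP_KEEP:
                row = loop_rows[tag][ctx_idx]
                keep = loop_cols[tag][ctx_idx]
                chosen = [row[c] if c < len(row) else "-" for c in keep]
                for offset, resi in enumerate(chosen[:slot]):
                    if resi != "-":
                        residues[lo + offset] = resi
            else:
                for offset, resi in enumerate(seg[:slot]):  # left-anchored
                    residues[lo + offset] = resi
        if flagged:
            logger.warning(
                "%s repeat %d: missing labelled run; partial template map",
                rep.parent_id,
                rep.index,
            )
        out.append(TemplateMap(repeat=rep, residues=residues, flagged=flagged))
    return out


def call_tetrad(
    tm: TemplateMap,
    config_sites: Optional[dict[str, int]] = None,
    template: BladeTemplate = CANONICAL_TEMPLATE,
) -> TetradCall:
    """Check the four tetrad anchors of one template-mapped repeat."""
    sites = dict(DEFAULT_TETRAD_SITES if config_sites is None else config_sites)
    for key, pos in sites.items():
        if key not in _TETRAD_ALLOWED:
            raise ConfigError(f"unknown tetrad anchor {key!r}")
        if not 1 <= pos <= len(template):
            raise ConfigError(
                f"tetrad site {key} at position {pos} outside template 1..{len(template)}"
            )
    present = {
        key: tm.residue_at(pos) in _TETRAD_ALLOWED[key]
        for key, pos in sites.items()
    }
    return TetradCall(
        repeat=tm.repeat,
        site_D=sites["D"],
        site_H=sites["H"],
        site_ST=sites["ST"],
        site_W=sites["W"],
        present_D=present["D"],
        present_H=present["H"],
        present_ST=present["ST"],
        present_W=present["W"],
    )


def tetrad_density(protein: WD40Protein, calls: Sequence[TetradCall]) -> float:
    """Complete tetrads per repeat for one protein, in [0, 1]."""
    if protein.n_repeats == 0:
        raise ValidationError(f"{protein.accession}: no repeats")
    if len(calls) != protein.n_repeats:
        raise ValidationError(
            f"{protein.accession}: {len(calls)} tetrad calls for "
            f"{protein.n_repeats} repeats"
        )
    return sum(1 for c in calls if c.complete) / protein.n_repeats


def logo_matrix(
    maps: Sequence[TemplateMap], template: BladeTemplate = CANONICAL_TEMPLATE
) -> LogoMatrix:
    """Residue counts per template position over a set of mapped repeats."""
    L = len(template)
    counts = np.zeros((L, len(AMINO_ACIDS)))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for tm in maps:
        for pos, resi in tm.residues.items():
            idx = aa_index.get(resi)
            if idx is not None:
                counts[pos - 1, idx] += 1
    return LogoMatrix(counts=counts, positions=list(range(1, L + 1)))


def information_content(lm: LogoMatrix) -> list[Optional[float]]:
    """Per-position information in bits: log2(20) minus column entropy.

    Positions with no observed residues (all-gap columns) yield ``None``.
    """
    out: list[Optional[float]] = []
    max_bits = math.log2(len(AMINO_ACIDS))
    for row in lm.counts:
        total = row.sum()
        if total == 0:
            out.append(None)
            continue
        p = row[row > 0] / total
        entropy = float(-(p * np.log2(p)).sum())
        out.append(max_bits - entropy)
    return out


def logo_table(lm: LogoMatrix) -> pd.DataFrame:
    """Logo matrix as a position x residue count table with information."""
    df = pd.DataFrame(lm.counts, columns=list(AMINO_ACIDS))
    df.insert(0, "position", lm.positions)
    info = information_content(lm)
    df["information_bits"] = [np.nan if v is None else v for v in info]
    return df
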
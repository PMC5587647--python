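"""Domain types for WD40 repeat-level analysis.

A WD40 β-propeller is built from ~40–60-residue repeat units (blades), each
folding into four antiparallel β-strands.  Strands are conventionally named
``Sa``–``Sd`` and the connecting loops ``Lda``, ``Lab``, ``Lbc``, ``Lcd``
(``Lda`` precedes ``Sa`` in the sequence repeat, reflecting the one-strand
"Velcro" offset between sequence repeats and structural blades).

These dataclasses are deliberately thin: they validate their own structural
invariants on construction and carry no behaviour beyond that.  All
coordinates are 1-based inclusive, matching GFF3 convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LABEL_TAGS",
    "CATEGORIES",
    "RepeatScopeError",
    "FormatError",
    "ValidationError",
    "ConfigError",
    "RepeatUnit",
    "WD40Protein",
    "GeneRecord",
    "GeneCluster",
    "OrthologPair",
    "ProteomeRecord",
    "CategorySummary",
    "AlignmentResult",
    "IdentityMatrix",
    "BladeTemplate",
    "TemplateMap",
    "TetradCall",
    "LogoMatrix",
    "CodonAlignment",
    "SubstitutionEstimate",
]

#: Structural element tags in canonical blade order (sequence repeats start
#: with the loop preceding strand a).
LABEL_TAGS = ("Lda", "Sa", "Lab", "Sb", "Lbc", "Sc", "Lcd", "Sd")

#: Taxonomic categories used throughout.
CATEGORIES = (
    "Animalia",
    "Plantae",
    "Fungi",
    "Protista",
    "Archaea",
    "Bacteria",
    "Virus",
    "Other",
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class RepeatScopeError(Exception):
    """Base class for package errors."""


class FormatError(RepeatScopeError):
    """A file or string does not conform to its declared format."""


class ValidationError(RepeatScopeError):
    """Data violates a structural invariant (named object where possible)."""


class ConfigError(RepeatScopeError):
    """Invalid configuration or parameterisation."""


def _check_label_runs(labels: Sequence[str]) -> None:
    """Labels must form contiguous runs following the cyclic blade order,
    permitted to start mid-cycle."""
    runs: list[str] = []
    for tag in labels:
        if tag not in LABEL_TAGS:
            raise FormatError(f"unknown structural label tag {tag!r}")
        if not runs or runs[-1] != tag:
            runs.append(tag)
    for prev, nxt in zip(runs, runs[1:]):
        i = LABEL_TAGS.index(prev)
        if LABEL_TAGS[(i + 1) % len(LABEL_TAGS)] != nxt:
            raise ValidationError(
                f"label run {nxt!r} does not follow {prev!r} in blade order"
            )


@dataclass(frozen=True)
class RepeatUnit:
    """One WD40 repeat: coordinates within its parent protein, per-residue
    structural labels, and a WDSP-style prediction score."""

    parent_id: str
    index: int  # 1-based ordinal within the protein
    start: int  # 1-based inclusive residue coordinate
    end: int
    sequence: str
    labels: tuple[str, ...]
    score: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"{self.parent_id} repeat {self.index}: end {self.end} < start {self.start}"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"{self.parent_id} repeat {self.index}: sequence length "
                f"{len(self.sequence)} does not match span {self.start}..{self.end}"
            )
        if len(self.labels) != len(self.sequence):
            raise ValidationError(
                f"{self.parent_id} repeat {self.index}: {len(self.labels)} labels "
                f"for {len(self.sequence)} residues"
            )
        if self.score < 0:
            raise ValidationError(
                f"{self.parent_id} repeat {self.index}: negative score {self.score}"
            )
        _check_label_runs(self.labels)

    def __len__(self) -> int:
        return len(self.sequence)

    def segment(self, tag: str) -> str:
        """Residues carrying a given structural label (contiguous by invariant)."""
        return "".join(r for r, t in zip(self.sequence, self.labels) if t == tag)


@dataclass
class WD40Protein:
    """A WD40 protein with its ordered repeat annotation and optional CDS.

    ``cds`` excludes the stop codon, so ``len(cds) == 3 * len(sequence)``.
    """

    accession: str
    gene_id: str
    organism_id: str
    category: str
    sequence: str
    repeats: list[RepeatUnit] = field(default_factory=list)
    cds: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"{self.accession}: unknown category {self.category!r}"
            )
        self.repeats = sorted(self.repeats, key=lambda r: r.start)
        prev_end = 0
        for rep in self.repeats:
            if rep.start <= prev_end:
                raise ValidationError(
                    f"{self.accession}: repeat {rep.index} (start {rep.start}) "
                    f"overlaps previous repeat ending at {prev_end}"
                )
            if rep.end > len(self.sequence):
                raise ValidationError(
                    f"{self.accession}: repeat {rep.index} ends at {rep.end} "
                    f"beyond sequence length {len(self.sequence)}"
                )
            prev_end = rep.end
        if self.cds is not None and len(self.cds) != 3 * len(self.sequence):
            raise ValidationError(
                f"{self.accession}: CDS length {len(self.cds)} is not 3x protein "
                f"length {len(self.sequence)}"
            )

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def mean_repeat_score(self) -> float:
        if not self.repeats:
            raise ValidationError(f"{self.accession}: no scored repeats")
        return float(np.mean([r.score for r in self.repeats]))

    def repeat_cds(self, repeat: RepeatUnit) -> str:
        """CDS segment coding for a repeat (codon i..j for residues i..j)."""
        if self.cds is None:
            raise ValidationError(f"{self.accession}: no CDS attached")
        return self.cds[3 * (repeat.start - 1) : 3 * repeat.end]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: location, transcription direction, product text."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass
class GeneCluster:
    """A same-strand run of genes with small intergenic gaps (operon proxy)."""

    cluster_id: str
    contig: str
    strand: str
    members: list[GeneRecord]

    def __post_init__(self) -> None:
        self.members = sorted(self.members, key=lambda g: g.start)
        for g in self.members:
            if g.contig != self.contig or g.strand != self.strand:
                raise ValidationError(
                    f"cluster {self.cluster_id}: member {g.gene_id} on "
                    f"{g.contig}/{g.strand}, cluster is {self.contig}/{self.strand}"
                )

    def __len__(self) -> int:
        return len(self.members)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.members]


@dataclass(frozen=True)
class OrthologPair:
    """A bidirectional best hit between two proteomes."""

    id_a: str
    id_b: str
    score: float
    identity: float


@dataclass(frozen=True)
class ProteomeRecord:
    """Per-organism WD40 content of one complete proteome."""

    organism_id: str
    category: str
    n_proteins: int
    n_wd40: int

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValidationError(
                f"{self.organism_id}: proteome size must be positive"
            )
        if not 0 <= self.n_wd40 <= self.n_proteins:
            raise ValidationError(
                f"{self.organism_id}: n_wd40 {self.n_wd40} outside "
                f"[0, {self.n_proteins}]"
            )


@dataclass(frozen=True)
class CategorySummary:
    """Abundance summary for one taxonomic category (one table row)."""

    category: str
    n_proteomes: int
    n_with_wd40: int
    pct_with_wd40: float
    mean_abundance_pct: float

    def __post_init__(self) -> None:
        if self.n_with_wd40 > self.n_proteomes:
            raise ValidationError(
                f"{self.category}: n_with_wd40 exceeds n_proteomes"
            )
        if not 0.0 <= self.pct_with_wd40 <= 100.0:
            raise ValidationError(f"{self.category}: pct_with_wd40 out of range")


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise global alignment: gapped rows, score, identical-pair count."""

    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValidationError("gapped rows differ in length")
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" and y == "-":
                raise ValidationError("alignment column with gap in both rows")

    @property
    def len_a(self) -> int:
        return sum(1 for c in self.aligned_a if c != "-")

    @property
    def len_b(self) -> int:
        return sum(1 for c in self.aligned_b if c != "-")


@dataclass
class IdentityMatrix:
    """Symmetric matrix of pairwise repeat identities for one protein."""

    accession: str
    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError(f"{self.accession}: identity matrix not square")
        if not np.allclose(m, m.T):
            raise ValidationError(f"{self.accession}: identity matrix not symmetric")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValidationError(f"{self.accession}: identities outside [0, 1]")
        np.fill_diagonal(m, 1.0)
        self.m = m

    @property
    def n_repeats(self) -> int:
        return self.m.shape[0]


@dataclass(frozen=True)
class BladeTemplate:
    """A canonical blade: template sequence, per-residue labels, and the
    template positions (1-based) of the DH[S/T]W tetrad anchors."""

    sequence: str
    labels: tuple[str, ...]
    tetrad_sites: dict  # keys "D", "H", "ST", "W" -> 1-based template position

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequence):
            raise ConfigError("template labels/sequence length mismatch")
        _check_label_runs(self.labels)
        for key in ("D", "H", "ST", "W"):
            if key not in self.tetrad_sites:
                raise ConfigError(f"template missing tetrad site {key!r}")
            pos = self.tetrad_sites[key]
            if not 1 <= pos <= len(self.sequence):
                raise ConfigError(f"tetrad site {key} at {pos} outside template")

    def __len__(self) -> int:
        return len(self.sequence)

    def segment_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for tag in self.labels:
            out[tag] = out.get(tag, 0) + 1
        return out


@dataclass
class TemplateMap:
    """A repeat's residues placed on the canonical template positions.

    ``residues[p]`` is the residue at 1-based template position ``p`` or
    ``'-'`` where the repeat contributes nothing.  ``flagged`` marks repeats
    missing a whole labelled strand run (partial maps).
    """

    repeat: RepeatUnit
    residues: dict[int, str]
    flagged: bool = False

    def residue_at(self, pos: int) -> str:
        return self.residues.get(pos, "-")


@dataclass(frozen=True)
class TetradCall:
    """Presence of the DH[S/T]W hydrogen-bond tetrad in one repeat."""

    repeat: RepeatUnit
    site_D: int
    site_H: int
    site_ST: int
    site_W: int
    present_D: bool
    present_H: bool
    present_ST: bool
    present_W: bool

    @property
    def complete(self) -> bool:
        return self.present_D and self.present_H and self.present_ST and self.present_W


@dataclass
class LogoMatrix:
    """Position x residue counts over the 20-letter alphabet plus per-position
    information content in bits (0 .. log2 20)."""

    counts: "np.ndarray"  # shape (L, 20), column order AMINO_ACIDS
    positions: list[int]  # 1-based template positions

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != len(AMINO_ACIDS):
            raise ValidationError("logo counts must be (L, 20)")
        if (c < 0).any():
            raise ValidationError("negative logo counts")
        self.counts = c


@dataclass(frozen=True)
class CodonAlignment:
    """A codon-level pairwise alignment threaded from a protein alignment.

    Rows are gapped nucleotide strings whose gaps occur in whole-codon
    triples; ``genetic_code`` is an NCBI translation table id (1 standard,
    11 bacterial/archaeal).
    """

    codons_a: str
    codons_b: str
    genetic_code: int = 1

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValidationError("codon alignment rows differ in length")
        if len(self.codons_a) % 3 != 0:
            raise ValidationError("codon alignment length not divisible by 3")
        for row in (self.codons_a, self.codons_b):
            for i in range(0, len(row), 3):
                codon = row[i : i + 3]
                if "-" in codon and codon != "---":
                    raise ValidationError(
                        f"gap not aligned to codon boundary at column {i}: {codon!r}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.codons_a) // 3

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Ungapped aligned codon pairs."""
        out = []
        for i in range(0, len(self.codons_a), 3):
            ca, cb = self.codons_a[i : i + 3], self.codons_b[i : i + 3]
            if ca != "---" and cb != "---":
                out.append((ca, cb))
        return out


@dataclass(frozen=True)
class SubstitutionEstimate:
    """Nei–Gojobori counting estimate for one codon-aligned pair.

    ``N``/``S`` are expected nonsynonymous/synonymous site counts, ``Nd``/``Sd``
    the (fractionally averaged) observed differences; ``dN``/``dS`` carry the
    Jukes–Cantor correction and are ``None`` when the correction saturates.
    ``omega`` is dN/dS, ``None`` when dS is 0 or unavailable.
    """

    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: Optional[float]
    dS: Optional[float]
    omega: Optional[float]
    status: str  # "ok" | "saturated"

    def __post_init__(self) -> None:
        if self.status not in ("ok", "saturated"):
            raise ValidationError(f"unknown status {self.status!r}")
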
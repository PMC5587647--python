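"""Synthetic WD40 genes, proteomes, and genomes with known ground truth.

The generators operationalise the repeat-duplication model of β-propeller
formation: an ancestral blade-coding segment is duplicated in place and the
copies then diverge by point mutation.  Everything the pipeline consumes can
be produced here with the planted structure recorded in truth logs, so every
downstream statistic can be checked against what was actually simulated.

Gene model (:func:`simulate_wd40_gene`)
    The blade template is back-translated (uniform choice among synonymous
    codons), duplicated ``n_repeats`` times, and each repeat copy evolves
    independently on a star phylogeny: a Poisson(t x 3 x codons) number of
    candidate point mutations, target nucleotides weighted ``kappa``:1 for
    transitions vs transversions, mutations creating stop codons rejected,
    nonsynonymous changes accepted with probability ``omega_sim``
    (purifying selection), synonymous changes always accepted.  ``t`` is the
    expected number of candidate substitutions per nucleotide site.

Proteome model (:func:`simulate_proteomes`)
    Per organism, the WD40 count is Binomial(proteome size, abundance) — or
    a deterministic rounding in exact mode.

Genome model (:func:`simulate_gene_table`)
    Genes are laid along a contig with planted same-strand clusters at
    controlled intragenic gaps and decoys separated by at least a stated
    distance, so neighbourhood clustering has an exactly known answer.

All generators are deterministic functions of their configuration and seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    AMINO_ACIDS,
    BladeTemplate,
    ConfigError,
    GeneRecord,
    ProteomeRecord,
    RepeatUnit,
    WD40Protein,
)
from .evolution import genetic_code_table, synonymous_site_fraction
from .template import CANONICAL_TEMPLATE

__all__ = [
    "SimConfig",
    "MutationEvent",
    "GeneTruth",
    "simulate_wd40_gene",
    "CategorySpec",
    "TABLE1_SPECS",
    "simulate_proteomes",
    "PlantedCluster",
    "GenomeTruth",
    "simulate_gene_table",
    "GenomePair",
    "simulate_genome_pair",
]

logger = logging.getLogger(__name__)

_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_NTS = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the repeat duplication–divergence simulator.

    ``t`` is the expected candidate substitutions per nucleotide site per
    repeat lineage (dimensionless divergence time); ``kappa`` the
    transition/transversion rate ratio; ``omega_sim`` the acceptance
    probability of nonsynonymous changes (1 = neutral, 0 = perfectly
    conserved protein).
    """

    n_repeats: int = 7
    template: BladeTemplate = CANONICAL_TEMPLATE
    t: float = 0.1
    kappa: float = 2.0
    omega_sim: float = 0.2
    seed: int = 0
    genetic_code: int = 11

    def __post_init__(self) -> None:
        if self.n_repeats < 6:
            raise ConfigError("n_repeats must be at least 6 (WD40 propeller)")
        if self.t < 0:
            raise ConfigError("divergence time t must be >= 0")
        if self.kappa <= 0:
            raise ConfigError("kappa must be positive")
        if not 0.0 <= self.omega_sim <= 1.0:
            raise ConfigError("omega_sim must lie in [0, 1]")


@dataclass(frozen=True)
class MutationEvent:
    """One accepted point mutation in one repeat's CDS (0-based nt site)."""

    repeat_index: int  # 1-based, matching RepeatUnit.index
    site: int
    nt_from: str
    nt_to: str
    synonymous: bool


@dataclass
class GeneTruth:
    """Ground truth of one simulated WD40 gene.

    Sufficient to recompute every planted quantity: the ancestral repeat
    CDS, all accepted mutations per repeat, repeat boundaries, and the
    template's tetrad sites.
    """

    config: SimConfig
    ancestral_cds: str  # one repeat unit, pre-duplication
    events: list[list[MutationEvent]]  # per repeat
    boundaries: list[tuple[int, int]]  # 1-based residue spans per repeat
    tetrad_sites: dict  # template tetrad anchor positions
    syn_sites_ancestral: float = field(init=False)

    def __post_init__(self) -> None:
        code = self.config.genetic_code
        self.syn_sites_ancestral = sum(
            synonymous_site_fraction(self.ancestral_cds[i : i + 3], code)
            for i in range(0, len(self.ancestral_cds), 3)
        )

    def syn_substitutions(self, repeat_index: int) -> int:
        """Accepted synonymous mutations on one repeat lineage (1-based)."""
        return sum(1 for e in self.events[repeat_index - 1] if e.synonymous)

    def pair_syn_divergence(self, i: int, j: int) -> float:
        """Synonymous substitutions per synonymous site separating repeats
        i and j (1-based): accepted synonymous events on both star branches
        over the ancestral synonymous site count."""
        return (
            self.syn_substitutions(i) + self.syn_substitutions(j)
        ) / self.syn_sites_ancestral

    def mean_pair_syn_divergence(self) -> float:
        n = len(self.events)
        pairs = list(itertools.combinations(range(1, n + 1), 2))
        return float(
            np.mean([self.pair_syn_divergence(i, j) for i, j in pairs])
        )


def _back_translate(
    protein: str, code: int, rng: np.random.Generator
) -> str:
    forward, stops = genetic_code_table(code)
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(forward.items()):
        by_aa.setdefault(aa, []).append(codon)
    out = []
    for aa in protein:
        options = by_aa.get(aa)
        if not options:
            raise ConfigError(f"residue {aa!r} has no codon under table {code}")
        out.append(options[rng.integers(len(options))])
    return "".join(out)


def _evolve_repeat(
    cds: str,
    cfg: SimConfig,
    repeat_index: int,
    rng: np.random.Generator,
) -> tuple[str, list[MutationEvent]]:
    forward, stops = genetic_code_table(cfg.genetic_code)
    seq = list(cds)
    events: list[MutationEvent] = []
    n_candidates = rng.poisson(cfg.t * len(cds))
    for _ in range(n_candidates):
        site = int(rng.integers(len(seq)))
        current = seq[site]
        others = [nt for nt in _NTS if nt != current]
        weights = np.array(
            [cfg.kappa if _TRANSITIONS[current] == nt else 1.0 for nt in others]
        )
        target = others[rng.choice(len(others), p=weights / weights.sum())]
        codon_start = 3 * (site // 3)
        old_codon = "".join(seq[codon_start : codon_start + 3])
        new_codon = (
            old_codon[: site % 3] + target + old_codon[site % 3 + 1 :]
        )
        if new_codon in stops:
            continue  # lethal; candidate rejected
        synonymous = forward[new_codon] == forward[old_codon]
        if not synonymous and rng.random() >= cfg.omega_sim:
            continue  # purged by purifying selection
        seq[site] = target
        events.append(
            MutationEvent(
                repeat_index=repeat_index,
                site=site,
                nt_from=current,
                nt_to=target,
                synonymous=synonymous,
            )
        )
    return "".join(seq), events


def simulate_wd40_gene(cfg: SimConfig) -> tuple[WD40Protein, GeneTruth]:
    """Simulate one WD40 gene by repeat duplication then codon divergence.

    Returns the protein (with CDS attached) and the ground-truth log.
    Deterministic under a fixed configuration (the seed is part of it).
    """
    rng = np.random.default_rng(cfg.seed)
    template = cfg.template
    forward, stops = genetic_code_table(cfg.genetic_code)
    for aa in template.sequence:
        if aa not in set(forward.values()):
            raise ConfigError(
                f"template residue {aa!r} untranslatable under table {cfg.genetic_code}"
            )
    ancestral = _back_translate(template.sequence, cfg.genetic_code, rng)
    L = len(template)
    repeat_cds: list[str] = []
    events: list[list[MutationEvent]] = []
    for k in range(1, cfg.n_repeats + 1):
        evolved, ev = _evolve_repeat(ancestral, cfg, k, rng)
        repeat_cds.append(evolved)
        events.append(ev)
    cds = "".join(repeat_cds)
    protein_seq = "".join(
        forward[cds[i : i + 3]] for i in range(0, len(cds), 3)
    )
    accession = f"SIMWD40_{cfg.seed:08d}"
    repeats = []
    boundaries = []
    for k in range(cfg.n_repeats):
        start, end = k * L + 1, (k + 1) * L
        boundaries.append((start, end))
        repeats.append(
            RepeatUnit(
                parent_id=accession,
                index=k + 1,
                start=start,
                end=end,
                sequence=protein_seq[start - 1 : end],
                labels=template.labels,
                score=75.0,
            )
        )
    protein = WD40Protein(
        accession=accession,
        gene_id=f"simgene_{cfg.seed:08d}",
        organism_id="SIMORG",
        category="Bacteria",
        sequence=protein_seq,
        repeats=repeats,
        cds=cds,
    )
    truth = GeneTruth(
        config=cfg,
        ancestral_cds=ancestral,
        events=events,
        boundaries=boundaries,
        tetrad_sites=dict(template.tetrad_sites),
    )
    return protein, truth


# ---------------------------------------------------------------------------
# Proteome collections


@dataclass(frozen=True)
class CategorySpec:
    """Target WD40 abundance and sampling frame for one taxonomic category."""

    category: str
    n_proteomes: int
    abundance_pct: float
    proteome_size: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.abundance_pct <= 100.0:
            raise ConfigError("abundance_pct must lie in [0, 100]")
        if self.n_proteomes <= 0 or self.proteome_size <= 0:
            raise ConfigError("counts must be positive")


#: Default study conditions: category sizes and mean abundances as reported
#: for complete proteomes (Animalia..Bacteria), with representative proteome
#: sizes (eukaryotes ~10-30k proteins, prokaryotes ~2.5-3.5k).
TABLE1_SPECS = (
    CategorySpec("Animalia", 100, 0.98, 20000),
    CategorySpec("Plantae", 27, 0.77, 30000),
    CategorySpec("Fungi", 198, 1.21, 9000),
    CategorySpec("Protista", 55, 1.08, 12000),
    CategorySpec("Archaea", 134, 0.08, 2500),
    CategorySpec("Bacteria", 1679, 0.06, 3200),
)


def simulate_proteomes(
    specs: Sequence[CategorySpec] = TABLE1_SPECS,
    seed: int = 0,
    exact: bool = False,
) -> list[ProteomeRecord]:
    """Proteome records with WD40 counts Binomial(size, abundance).

    In exact mode every organism gets round(size * abundance) WD40s
    (deterministic, no sampling noise).
    """
    rng = np.random.default_rng(seed)
    records: list[ProteomeRecord] = []
    for spec in specs:
        p = spec.abundance_pct / 100.0
        for i in range(spec.n_proteomes):
            if exact:
                n_wd40 = round(spec.proteome_size * p)
            else:
                n_wd40 = int(rng.binomial(spec.proteome_size, p))
            records.append(
                ProteomeRecord(
                    organism_id=f"{spec.category[:3].upper()}_{i + 1:04d}",
                    category=spec.category,
                    n_proteins=spec.proteome_size,
                    n_wd40=n_wd40,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Genomes with planted gene clusters


@dataclass(frozen=True)
class PlantedCluster:
    """A same-strand gene run to plant: size, intragenic gap, strand."""

    size: int
    intra_gap: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ConfigError("cluster size must be >= 1")
        if self.intra_gap < 0:
            raise ConfigError("intra_gap must be >= 0 (gaps are non-negative)")
        if self.strand not in ("+", "-"):
            raise ConfigError("strand must be '+' or '-'")


@dataclass
class GenomeTruth:
    """Planted memberships of one simulated gene table."""

    planted: list[list[str]]  # gene ids per planted cluster, in order
    decoys: list[str]


def simulate_gene_table(
    planted: Sequence[PlantedCluster],
    n_decoys: int = 0,
    contig: str = "chr",
    decoy_gap: int = 300,
    gene_length: tuple[int, int] = (300, 1500),
    seed: int = 0,
    id_prefix: str = "g",
) -> tuple[list[GeneRecord], GenomeTruth]:
    """Lay planted clusters and decoy genes along one contig.

    Planted clusters appear consecutively with their configured intragenic
    gaps; decoys (and cluster-to-cluster separations) are spaced by at least
    ``decoy_gap`` bases so they never join a planted cluster under a
    max-gap threshold of ``decoy_gap`` or less.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    truth = GenomeTruth(planted=[], decoys=[])
    pos = 1
    counter = itertools.count(1)

    def place(strand: str, product: str) -> GeneRecord:
        nonlocal pos
        length = int(rng.integers(gene_length[0], gene_length[1] + 1))
        g = GeneRecord(
            gene_id=f"{id_prefix}{next(counter):04d}",
            contig=contig,
            start=pos,
            end=pos + length - 1,
            strand=strand,
            product=product,
        )
        genes.append(g)
        pos = g.end + 1
        return g

    def separate() -> None:
        nonlocal pos
        pos += decoy_gap + int(rng.integers(0, 500))

    units: list[tuple[str, object]] = [("cluster", pc) for pc in planted]
    units += [("decoy", None)] * n_decoys
    # Interleave decoys between clusters deterministically.
    order = np.arange(len(units))
    rng.shuffle(order)
    for idx in order:
        kind, payload = units[idx]
        if kind == "cluster":
            pc = payload
            member_ids = []
            for m in range(pc.size):
                g = place(pc.strand, f"planted cluster member {m + 1}")
                member_ids.append(g.gene_id)
                if m < pc.size - 1:
                    pos += pc.intra_gap
            truth.planted.append(member_ids)
            separate()
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            g = place(strand, "decoy gene")
            truth.decoys.append(g.gene_id)
            separate()
    return genes, truth


@dataclass
class GenomePair:
    """Two synthetic genomes sharing (or not) a planted WD40 neighbourhood."""

    genes_a: list[GeneRecord]
    genes_b: list[GeneRecord]
    proteins_a: list[tuple[str, str]]
    proteins_b: list[tuple[str, str]]
    wd40_ids: set[str]
    truth_a: GenomeTruth
    truth_b: GenomeTruth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    letters = np.array(list(AMINO_ACIDS))
    return "".join(rng.choice(letters, size=length))


def simulate_genome_pair(
    cluster_size: int = 3,
    intra_gap: int = 50,
    n_decoys: int = 3,
    shared: bool = True,
    protein_length: int = 120,
    seed: int = 0,
) -> GenomePair:
    """Two genomes, each with one planted cluster; when ``shared`` the
    cluster members carry identical protein sequences across genomes (a
    conserved neighbourhood), otherwise the second genome's members are
    unrelated random proteins (lineage-specific)."""
    rng = np.random.default_rng(seed)
    pc = PlantedCluster(size=cluster_size, intra_gap=intra_gap)
    genes_a, truth_a = simulate_gene_table(
        [pc], n_decoys=n_decoys, contig="contigA", seed=int(rng.integers(2**31)),
        id_prefix="A_",
    )
    genes_b, truth_b = simulate_gene_table(
        [pc], n_decoys=n_decoys, contig="contigB", seed=int(rng.integers(2**31)),
        id_prefix="B_",
    )
    cluster_prots = [_random_protein(rng, protein_length) for _ in range(cluster_size)]
    proteins_a: list[tuple[str, str]] = []
    proteins_b: list[tuple[str, str]] = []
    for genes, truth, prots in (
        (genes_a, truth_a, cluster_prots),
        (
            genes_b,
            truth_b,
            cluster_prots
            if shared
            else [_random_protein(rng, protein_length) for _ in range(cluster_size)],
        ),
    ):
        members = truth.planted[0]
        seqs = dict(zip(members, prots))
        target = proteins_a if genes is genes_a else proteins_b
        for g in genes:
            target.append(
                (g.gene_id, seqs.get(g.gene_id) or _random_protein(rng, protein_length))
            )
    wd40_ids = {truth_a.planted[0][0], truth_b.planted[0][0]}
    return GenomePair(
        genes_a=genes_a,
        genes_b=genes_b,
        proteins_a=proteins_a,
        proteins_b=proteins_b,
        wd40_ids=wd40_ids,
        truth_a=truth_a,
        truth_b=truth_b,
    )
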
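"""Gene-neighbourhood clustering, BBH orthology, and conserved clusters.

Prokaryotic genes that sit close together on the same strand frequently form
one transcriptional unit (operon), so the neighbourhood of a WD40 gene is a
cheap proxy for its functional context.  A *gene cluster* here is a maximal
run of same-contig, same-strand genes whose intergenic gaps are all below a
threshold (default < 300 bp, counting the bases strictly between the genes;
overlapping genes have a negative gap and always cluster).

Orthology between two proteomes uses the bidirectional-best-hit (BBH)
heuristic on global-alignment scores.  Two clusters from different species
are a *conserved neighbourhood* when they contain a BBH pair of WD40
proteins and every other member of the smaller cluster also has a BBH
partner of sufficient identity in the other cluster; clusters without such
a partner are lineage- or species-specific.

Annotation term frequencies over cluster members (minus uninformative
phrases such as "hypothetical protein") summarise what WD40 genes sit next
to, and are the input one would feed a word-cloud renderer.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .identity import AlignParams, DEFAULT_PARAMS, needleman_wunsch, pairwise_identity
from .model import GeneCluster, GeneRecord, OrthologPair

__all__ = [
    "DEFAULT_MAX_GAP",
    "DEFAULT_MIN_IDENTITY",
    "DEFAULT_STOPLIST",
    "intergenic_gap",
    "cluster_genes",
    "bbh_pairs",
    "match_conserved_clusters",
    "term_frequencies",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 300
DEFAULT_MIN_IDENTITY = 0.3

#: Annotation phrases carrying no functional information (case-insensitive).
DEFAULT_STOPLIST = (
    "hypothetical protein",
    "uncharacterized protein",
    "unknown function",
    "wd40 repeat",
    "wd40 repeat protein",
    "wd-40 repeat protein",
    "wd repeat protein",
)


def intergenic_gap(prev: GeneRecord, nxt: GeneRecord) -> int:
    """Bases strictly between two genes (negative when they overlap)."""
    return nxt.start - prev.end - 1


def cluster_genes(
    genes: Sequence[GeneRecord], max_gap: int = DEFAULT_MAX_GAP
) -> list[GeneCluster]:
    """Chain same-contig, same-strand genes with gaps below ``max_gap``.

    Singletons come back as size-1 clusters; the output partitions the
    input.  Cluster ids are deterministic, named after the leftmost member.
    """
    groups: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        groups.setdefault((g.contig, g.strand), []).append(g)
    clusters: list[GeneCluster] = []
    for (contig, strand), members in sorted(groups.items()):
        members = sorted(members, key=lambda g: (g.start, g.end, g.gene_id))
        run: list[GeneRecord] = []
        for g in members:
            if run and intergenic_gap(run[-1], g) < max_gap:
                run.append(g)
            else:
                if run:
                    clusters.append(_make_cluster(contig, strand, run))
                run = [g]
        if run:
            clusters.append(_make_cluster(contig, strand, run))
    clusters.sort(key=lambda c: (c.contig, c.members[0].start, c.strand))
    logger.info(
        "clustered %d genes into %d neighbourhoods (max gap %d bp)",
        len(genes),
        len(clusters),
        max_gap,
    )
    return clusters


def _make_cluster(contig: str, strand: str, members: list[GeneRecord]) -> GeneCluster:
    return GeneCluster(
        cluster_id=f"nb_{members[0].gene_id}",
        contig=contig,
        strand=strand,
        members=list(members),
    )


def _best_hits(
    queries: Sequence[tuple[str, str]],
    targets: Sequence[tuple[str, str]],
    params: AlignParams,
) -> dict[str, tuple[str, float, float]]:
    """Best target per query by score; ties by higher identity then
    lexicographically smaller target id."""
    best: dict[str, tuple[str, float, float]] = {}
    for qid, qseq in queries:
        chosen: Optional[tuple[str, float, float]] = None
        for tid, tseq in targets:
            aln = needleman_wunsch(qseq, tseq, params)
            ident = pairwise_identity(aln, len(qseq), len(tseq))
            cand = (tid, aln.score, ident)
            if (
                chosen is None
                or cand[1] > chosen[1]
                or (cand[1] == chosen[1] and cand[2] > chosen[2])
                or (cand[1] == chosen[1] and cand[2] == chosen[2] and cand[0] < chosen[0])
            ):
                chosen = cand
        assert chosen is not None
        best[qid] = chosen
    return best


def bbh_pairs(
    proteome_a: Sequence[tuple[str, str]],
    proteome_b: Sequence[tuple[str, str]],
    params: AlignParams = DEFAULT_PARAMS,
) -> list[OrthologPair]:
    """Bidirectional best hits between two proteomes of (id, sequence).

    Scores come from the package's global aligner, which is sufficient for
    desk-scale proteome pairs; precomputed score tables can be fed to a BBH
    directly when inputs are large.
    """
    if not proteome_a or not proteome_b:
        return []
    fwd = _best_hits(proteome_a, proteome_b, params)
    rev = _best_hits(proteome_b, proteome_a, params)
    pairs = []
    for id_a, (id_b, score, ident) in sorted(fwd.items()):
        if rev[id_b][0] == id_a:
            pairs.append(OrthologPair(id_a=id_a, id_b=id_b, score=score, identity=ident))
    return pairs


def match_conserved_clusters(
    clusters_a: Sequence[GeneCluster],
    clusters_b: Sequence[GeneCluster],
    pairs: Sequence[OrthologPair],
    wd40_ids: Iterable[str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[list[tuple[GeneCluster, GeneCluster]], list[GeneCluster], list[GeneCluster]]:
    """Cross-species conserved WD40 neighbourhoods.

    Returns (matched pairs, lineage-specific clusters of a, lineage-specific
    clusters of b).  Only clusters containing a WD40 gene participate;
    clusters without any WD40 member are ignored entirely.

    A match requires (i) a BBH pair of WD40 genes, one in each cluster, and
    (ii) every other member of the smaller cluster to have a BBH partner
    with identity >= ``min_identity`` located in the other cluster.
    """
    wd40 = set(wd40_ids)
    by_a: dict[str, OrthologPair] = {p.id_a: p for p in pairs}
    matched: list[tuple[GeneCluster, GeneCluster]] = []
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    for ca in clusters_a:
        if not any(g in wd40 for g in ca.gene_ids):
            continue
        for cb in clusters_b:
            if not any(g in wd40 for g in cb.gene_ids):
                continue
            if _clusters_match(ca, cb, by_a, wd40, min_identity):
                matched.append((ca, cb))
                matched_a.add(ca.cluster_id)
                matched_b.add(cb.cluster_id)
    specific_a = [
        c
        for c in clusters_a
        if c.cluster_id not in matched_a and any(g in wd40 for g in c.gene_ids)
    ]
    specific_b = [
        c
        for c in clusters_b
        if c.cluster_id not in matched_b and any(g in wd40 for g in c.gene_ids)
    ]
    return matched, specific_a, specific_b


def _clusters_match(
    ca: GeneCluster,
    cb: GeneCluster,
    by_a: Mapping[str, OrthologPair],
    wd40: set[str],
    min_identity: float,
) -> bool:
    members_b = set(cb.gene_ids)
    anchor = None
    for gid in ca.gene_ids:
        pair = by_a.get(gid)
        if (
            pair is not None
            and gid in wd40
            and pair.id_b in wd40
            and pair.id_b in members_b
        ):
            anchor = pair
            break
    if anchor is None:
        return False
    if len(ca) <= len(cb):
        smaller_ids, other_members, forward = ca.gene_ids, members_b, True
    else:
        smaller_ids, other_members, forward = cb.gene_ids, set(ca.gene_ids), False
        by_b = {p.id_b: p for p in by_a.values()}
    for gid in smaller_ids:
        if gid in (anchor.id_a, anchor.id_b):
            continue
        if forward:
            pair = by_a.get(gid)
            partner = pair.id_b if pair else None
        else:
            pair = by_b.get(gid)
            partner = pair.id_a if pair else None
        if pair is None or partner not in other_members or pair.identity < min_identity:
            return False
    return True


def term_frequencies(
    clusters: Sequence[GeneCluster],
    stoplist: Sequence[str] = DEFAULT_STOPLIST,
) -> pd.DataFrame:
    """Annotation phrase counts across cluster members, stoplist removed.

    Phrases are compared case-insensitively against the stoplist; counts are
    sorted descending, ties broken lexicographically.
    """
    stop = {s.lower() for s in stoplist}
    counter: Counter[str] = Counter()
    for cluster in clusters:
        for gene in cluster.members:
            phrase = gene.product.strip()
            if not phrase or phrase.lower() in stop:
                continue
            counter[phrase] += 1
    rows = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["phrase", "count"])
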
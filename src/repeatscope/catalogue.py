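"""Candidate filtering, deduplication, and proteome abundance statistics.

WD40 candidates come in with WDSP-style per-repeat scores.  A protein is
kept when it has at least 6 repeats and a mean repeat score of at least 48;
retained proteins with mean score in [48, 60) are additionally flagged for
review (the band that would be cross-checked against domain databases).
Redundancy within an organism is removed by keeping the single longest
protein per gene.

Abundance of WD40 proteins in a complete proteome is the simple percentage
100 * n_wd40 / n_proteins.  Category summaries report the share of proteomes
containing any WD40 and the unweighted mean abundance over proteomes; group
differences are assessed with a one-sided Wilcoxon rank-sum (Mann-Whitney)
test and expressed as fold changes of mean abundances.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    CategorySummary,
    ProteomeRecord,
    ValidationError,
    WD40Protein,
)

__all__ = [
    "MIN_REPEATS",
    "MIN_MEAN_SCORE",
    "REVIEW_SCORE_MAX",
    "filter_wd40_candidates",
    "dedupe_longest_per_gene",
    "proteome_abundance",
    "summarize_category",
    "fold_change",
    "category_share",
    "rank_sum_test",
    "distribution_table",
]

logger = logging.getLogger(__name__)

MIN_REPEATS = 6
MIN_MEAN_SCORE = 48.0
REVIEW_SCORE_MAX = 60.0

#: exact/asymptotic switch for the rank-sum test
_EXACT_MAX_N = 12


def filter_wd40_candidates(
    proteins: Sequence[WD40Protein],
) -> tuple[list[WD40Protein], list[WD40Protein], list[WD40Protein]]:
    """Partition candidates into (retained, review_flagged, rejected).

    Retained: >= 6 repeats and mean repeat score >= 48.  Review-flagged is a
    subset of retained with mean score in [48, 60) — kept, but marked as the
    band one would double-check against external domain annotations.
    """
    retained: list[WD40Protein] = []
    flagged: list[WD40Protein] = []
    rejected: list[WD40Protein] = []
    for p in proteins:
        if p.n_repeats >= MIN_REPEATS and p.mean_repeat_score >= MIN_MEAN_SCORE:
            retained.append(p)
            if p.mean_repeat_score < REVIEW_SCORE_MAX:
                flagged.append(p)
        else:
            rejected.append(p)
    logger.info(
        "candidate filter: %d in -> %d retained (%d review-flagged), %d rejected",
        len(proteins),
        len(retained),
        len(flagged),
        len(rejected),
    )
    return retained, flagged, rejected


def dedupe_longest_per_gene(
    proteins: Iterable[WD40Protein],
) -> list[WD40Protein]:
    """Keep one protein per (organism, gene): the longest, ties broken by
    lexicographically smallest accession."""
    groups: dict[tuple[str, str], WD40Protein] = {}
    n_in = 0
    for p in proteins:
        n_in += 1
        key = (p.organism_id, p.gene_id)
        cur = groups.get(key)
        if (
            cur is None
            or len(p.sequence) > len(cur.sequence)
            or (len(p.sequence) == len(cur.sequence) and p.accession < cur.accession)
        ):
            groups[key] = p
    out = list(groups.values())
    logger.info("dedupe: %d in -> %d out", n_in, len(out))
    return out


def proteome_abundance(record: ProteomeRecord) -> float:
    """Percentage of WD40 proteins in one complete proteome."""
    # n_proteins > 0 is a ProteomeRecord invariant
    return 100.0 * record.n_wd40 / record.n_proteins


def summarize_category(
    records: Sequence[ProteomeRecord], category: str
) -> CategorySummary:
    """Category row: proteome count, share containing WD40s, and the
    unweighted mean abundance over proteomes."""
    sub = [r for r in records if r.category == category]
    if not sub:
        raise ValidationError(f"no proteome records for category {category!r}")
    n_with = sum(1 for r in sub if r.n_wd40 > 0)
    return CategorySummary(
        category=category,
        n_proteomes=len(sub),
        n_with_wd40=n_with,
        pct_with_wd40=100.0 * n_with / len(sub),
        mean_abundance_pct=float(np.mean([proteome_abundance(r) for r in sub])),
    )


def fold_change(a: CategorySummary, b: CategorySummary) -> float:
    """Ratio of mean WD40 abundances between two categories (a over b)."""
    if b.mean_abundance_pct <= 0:
        raise ValidationError(
            f"fold change undefined: {b.category} mean abundance is 0"
        )
    return a.mean_abundance_pct / b.mean_abundance_pct


def category_share(counts: dict[str, int], categories: Sequence[str]) -> float:
    """Percentage of the whole catalogue contributed by some categories."""
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("empty catalogue")
    return 100.0 * sum(counts.get(c, 0) for c in categories) / total


def rank_sum_test(
    a: Sequence[float], b: Sequence[float], alternative: str = "greater"
) -> float:
    """One-sided Wilcoxon rank-sum p-value for sample ``a`` versus ``b``.

    ``alternative="greater"`` tests whether values in ``a`` tend to exceed
    those in ``b`` (and symmetrically for ``"less"``).  Small untied samples
    (n_a + n_b <= 12) use the exact null distribution; larger or tied
    samples use the normal approximation with tie and continuity
    corrections.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("rank-sum test needs two non-empty samples")
    if alternative not in ("greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    pooled = list(a) + list(b)
    has_ties = len(set(pooled)) < len(pooled)
    if len(pooled) <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


def distribution_table(
    values: Sequence[float], bins: Optional[Sequence[float] | int] = None
) -> pd.DataFrame:
    """Histogram table (bin, count, fraction); fractions sum to 1.

    With ``bins=None`` the values are treated as discrete (e.g. repeat
    counts) and each distinct value gets its own row; otherwise bins are
    passed to :func:`numpy.histogram` (e.g. for tetrad densities in [0, 1]).
    """
    if len(values) == 0:
        logger.warning("distribution_table: no values; returning empty table")
        return pd.DataFrame(columns=["bin", "count", "fraction"])
    arr = np.asarray(values, dtype=float)
    if bins is None:
        uniq, counts = np.unique(arr, return_counts=True)
        labels = [int(u) if float(u).is_integer() else float(u) for u in uniq]
    else:
        counts, edges = np.histogram(arr, bins=bins)
        labels = [
            f"[{edges[i]:g}, {edges[i + 1]:g}{']' if i == len(counts) - 1 else ')'}"
            for i in range(len(counts))
        ]
    total = counts.sum()
    return pd.DataFrame(
        {
            "bin": labels,
            "count": counts.astype(int),
            "fraction": counts / total,
        }
    )
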
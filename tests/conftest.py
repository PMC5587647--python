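"""Shared fixtures: synthetic proteins built from the canonical blade."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from repeatscope.model import RepeatUnit, WD40Protein
from repeatscope.simulate import SimConfig, simulate_wd40_gene
from repeatscope.template import CANONICAL_TEMPLATE

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_protein(
    accession: str = "P1",
    n_repeats: int = 7,
    scores: list[float] | None = None,
    gene_id: str = "gene1",
    organism_id: str = "org1",
    category: str = "Bacteria",
) -> WD40Protein:
    """A protein of identical canonical-blade repeats with given scores."""
    if scores is None:
        scores = [75.0] * n_repeats
    assert len(scores) == n_repeats
    L = len(CANONICAL_TEMPLATE)
    seq = CANONICAL_TEMPLATE.sequence * n_repeats
    repeats = [
        RepeatUnit(
            parent_id=accession,
            index=k + 1,
            start=k * L + 1,
            end=(k + 1) * L,
            sequence=CANONICAL_TEMPLATE.sequence,
            labels=CANONICAL_TEMPLATE.labels,
            score=scores[k],
        )
        for k in range(n_repeats)
    ]
    return WD40Protein(
        accession=accession,
        gene_id=gene_id,
        organism_id=organism_id,
        category=category,
        sequence=seq,
        repeats=repeats,
    )


@pytest.fixture(scope="session")
def gene_t0():
    """A simulated gene with zero divergence: all repeats identical."""
    return simulate_wd40_gene(SimConfig(n_repeats=7, t=0.0, seed=11))


@pytest.fixture(scope="session")
def gene_diverged():
    """A moderately diverged simulated gene with CDS and truth log."""
    return simulate_wd40_gene(SimConfig(n_repeats=8, t=0.15, omega_sim=0.1, seed=5))
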
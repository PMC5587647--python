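# Methods

This note documents the models, parameter choices, and numerical
conventions behind `repeatscope`, and what the synthetic-data tests do and
do not establish about real data.

## Internal sequence identity

Repeat pairs within a protein are aligned with global Needleman–Wunsch
under affine gaps. The aligner is implemented in-package so the traceback
is fully deterministic: co-optimal moves resolve diagonal > up (gap in the
second sequence) > left. Determinism matters because the *identity count*
of an alignment — identical aligned residue pairs divided by the shorter
ungapped length — can differ between co-optimal alignments, and the
downstream statistic must be reproducible. Default parameters are BLOSUM62,
gap open 10, gap extend 0.5 (a gap of length k costs open + (k−1)·extend);
`X` scores 0 against everything. No alignment parameters are canonical for
this statistic, so they are configurable and echoed in CLI output headers;
identity values shift by a few percent under other standard matrices.

The protein-level statistic is the largest threshold X such that some
window of 8 contiguous repeats (all repeats when only 6 or 7 exist)
contains 6 repeats whose pairwise identities all reach X. It is computed
directly as max over windows of max over C(8,6) subsets of the subset's
minimum pairwise identity. "Reach" is inclusive (≥): this makes the HR
cutoff "at least 0.7" exact and the statistic a well-defined maximum; a
strict reading differs only on ties of measure zero. Proteins with fewer
than six repeats get no value (`None` → "undefined"), never 0, so absence
is not conflated with low identity. HR ≥ 0.7, MR ∈ [0.4, 0.7); reports
flooring values to a 0.1 grid reproduce layered-plot style summaries.

## Candidate filtering and abundance

Filtering keeps proteins with ≥ 6 repeats and mean repeat score ≥ 48;
retained proteins with mean score in [48, 60) are flagged for review but
kept (the manual cross-check that band would receive cannot be automated
here; a strict mode drops them). Deduplication keeps the longest protein
per (organism, gene), ties to the lexicographically smallest accession.

Category summaries report the percentage of proteomes containing any WD40
and the *unweighted* mean over proteomes of 100·n_wd40/n_proteins; fold
changes are ratios of those means. An overall prokaryote-vs-eukaryote fold
change is deliberately not computed, because the averaging weights such a
single number would need are not well defined across very unequal category
sizes.

The one-sided Wilcoxon rank-sum test uses scipy's Mann–Whitney U: the
exact null when n_a + n_b ≤ 12 with no ties (cheap and oracle-checkable by
full enumeration), otherwise the normal approximation with tie and
continuity corrections. The switch point and corrections are documented
choices, not inferences about any published analysis.

## Blade template, tetrads, and logos

The canonical blade template is 46 residues: L_da(6) S_a(7) L_ab(5) S_b(7)
L_bc(3) S_c(9) L_cd(4) S_d(5), with a complete tetrad planted at His 4
(L_da), Asp 16 (the SPDG motif on L_ab), Thr 25 (closing S_b), and Trp 37
(on S_c). Strand residues are placed positionally (left-anchored into the
strand slots); loop residues are multiple-aligned across the protein's
repeats with a centre-star strategy (longest segment as centre, pairwise
alignments merged on centre coordinates) and the top 6/5/3/4 columns kept
for L_da/L_ab/L_bc/L_cd. Column ranking is by non-gap occupancy, ties by
maximum single-residue frequency, then leftmost — "most conserved" needs a
concrete metric and this is it.

Tetrad calling checks the four anchor positions for {D}, {H}, {S, T}, {W};
a repeat is tetrad-complete iff all four match, so tetrad count ≤ repeat
count by construction and tetrad density = complete/repeats ∈ [0, 1]. The
H and S/T anchors are template choices of this package, configurable per
call — external predictors may anchor them differently, and the defaults
are not a claim about any particular predictor's geometry.

Logo matrices count residues per template position; information content is
log₂20 − Shannon entropy of the empirical column distribution, with a
uniform 20-letter background, no gap penalty, and no small-sample
correction (counts are emitted alongside bits so alternative renderings
remain possible).

## Gene neighbourhoods

Intergenic distance is the number of bases strictly between two genes
(next.start − prev.end − 1); overlapping genes have negative distance and
always cluster, as operonic genes often overlap. Clusters are maximal
same-contig, same-strand runs with all consecutive distances < 300 bp
(strict), computed by chaining genes sorted by start — provably equal to
connected components of the adjacency graph, which the tests verify
against a graph oracle. The end-to-start convention is configurable.

BBH orthology scores proteome pairs with the package's global aligner
(score ordering is all BBH needs at desk scale; a precomputed score table
can replace it for large inputs). Best hits tie-break by higher identity,
then lexicographically smaller id. Conserved neighbourhoods require a BBH
pair of WD40 genes, one per cluster, plus a BBH partner with identity
≥ 0.3 (configurable; remote WD40 homologs at ~32% identity motivate the
default) in the other cluster for every remaining member of the smaller
cluster. The WD40 gene itself must be a cluster member.

## NG86 dN/dS

Synonymous site counts enumerate each codon's nine single-nucleotide
neighbours under the declared NCBI code; mutations to stops are excluded
from the per-position denominator. Sites are averaged over the two
sequences. Observed differences at 2–3-difference codon pairs average over
all minimal mutation paths with equal weights, discarding paths through
stops (with an all-paths fallback should every path be blocked — not
reachable for valid codon pairs with ≤ 2 differences). Jukes–Cantor
correction d = −¾ ln(1 − 4/3·p) is applied to both proportions; a
non-positive log argument marks the estimate *saturated* and no rate is
reported (exclusion, not clamping). ω = dN/dS when dS > 0, absent at
dS = 0. Per-protein summaries take the median over non-saturated repeat
pairs; the purifying subset is median dS ∈ [1.0, 2.0) — below 1.0 the
synonymous signal is too weak to constrain ω, at 2.0 and above dS itself
is unreliable.

NCBI tables 1 (standard) and 11 (bacterial/archaeal) assign identical
amino acids to all 64 codons — they differ only in initiation codons — so
site counts agree between them by construction; the regression test for
genetic-code sensitivity therefore uses the vertebrate-mitochondrial table,
where degeneracy genuinely changes. A counting estimator was chosen over
maximum-likelihood codon models because it is exactly specified,
brute-force checkable, and sufficient for repeat-pair dating; the module
interface leaves room for other estimators.

## Synthetic-data generators

`simulate_wd40_gene` embodies the repeat-duplication model: the blade
template is back-translated (uniform synonymous codon choice), duplicated
n_repeats times, and each copy evolves independently — a star phylogeny,
matching the pairwise (non-phylogenetic) statistics computed downstream;
a ladder-duplication mode is a possible extension, not implemented.
Candidate mutations number Poisson(t × 3 × codons) per repeat with target
nucleotides weighted κ:1 (transitions:transversions, default κ = 2, a
typical bacterial value); stop-creating changes are rejected, nonsynonymous
changes accepted with probability ω_sim (default 0.2, moderate purifying
selection), synonymous always. Defaults: 7 repeats (the modal propeller),
t = 0.1, bacterial code. Truth logs record every accepted event, so
pair-level synonymous divergence is recomputable as (events_i + events_j) /
ancestral synonymous sites without re-running the generator.

Parameter recovery is validated at pair-level synonymous divergences of
roughly 0.05, 0.2, and 0.5 (per-branch t of half that), 50 seeds per
level, 8 repeats of 46 codons each (~1,300 usable pairs per level): mean
NG86 dS tracks the truth-log divergence within 2–7%. A known limitation:
at pair divergences ≳ 1 the equal-rate site counting of NG86 interacts
with transition bias (κ > 1 concentrates synonymous changes on a subset of
sites) and the estimator overshoots by ~15–20%; estimates there should be
read as upper bounds, which is also why the ω analysis caps dS at 2.

`simulate_proteomes` draws per-organism WD40 counts Binomial(size,
abundance) at the default category conditions (Animalia 100 proteomes /
0.98%, Plantae 27 / 0.77%, Fungi 198 / 1.21%, Protista 55 / 1.08%, Archaea
134 / 0.08%, Bacteria 1,679 / 0.06%; proteome sizes 2.5–30k). A
single-parameter binomial reproduces the mean abundances but *not*,
simultaneously, the low fraction of prokaryotic proteomes containing any
WD40 — real prokaryotic WD40s are concentrated in a few lineages
(overdispersion the model omits). Worked-example statistics on the
published tallies therefore use the tallies directly.

`simulate_gene_table` plants same-strand clusters at exact intragenic gaps
with decoys separated by ≥ 300 bp (plus jitter), and
`simulate_genome_pair` gives two genomes whose planted clusters carry
identical (or deliberately unrelated) member proteins, making
conserved-neighbourhood calls exactly checkable. No indel process acts
within repeats, and genome simulation is layout-only — planted-structure
tests validate the clustering and matching logic, not robustness to
annotation noise.

## What the tests show — and don't

Oracle suites (alignment enumeration, clique-threshold identity oracle,
brute-force NG86, rank-sum enumeration, union-find clustering) establish
algorithmic correctness exactly. Simulator-based tests establish
statistical behaviour *under the generators' assumptions*: no indels
within repeats, star-shaped duplication history, uniform codon usage,
single-lineage genomes. Real WD40 data violate each of these to some
degree (repeat-length variation, nested duplications, codon bias, operon
rearrangement), so passing tests bound implementation error, not biological
inference error. All generators are deterministic under their seeds; every
stochastic test fixes its seeds or derives them from the test runner's.
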
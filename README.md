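# repeatscope

Repeat-level comparative analysis of WD40 β-propeller proteins.

WD40 domains are ~7-bladed β-propellers built from tandem repeats of 40–60
residues (strands S_a–S_d, loops L_da/L_ab/L_bc/L_cd). They dominate
eukaryotic scaffolding proteins but also occur, far more rarely, in bacteria
and archaea. Two questions drive this package: **how abundant are WD40
proteins across taxa**, and **how recently were individual propellers
assembled by intra-gene repeat duplication?** The second is answered from
sequence alone: repeats that duplicated recently are still nearly identical
at both protein and synonymous-DNA level.

`repeatscope` is a library (plus a thin CLI) for researchers studying
tandem-repeat protein evolution. It implements:

* **Internal sequence identity** — for a protein with repeats
  r₁…r_n and pairwise Needleman–Wunsch identities
  I(rᵢ, rⱼ) = (identical aligned pairs) / min(|rᵢ|, |rⱼ|), the statistic

  > max over windows *W* of 8 contiguous repeats (all repeats when n ∈ {6, 7})
  > of max over 6-repeat subsets *S* ⊆ *W* of min₍ᵢ,ⱼ₎∈S I(rᵢ, rⱼ)

  Proteins with value ≥ 0.7 are **Highly-Repetitive (HR)**: recent
  duplications. Values in [0.4, 0.7) are **Moderately-Repetitive (MR)**.
* **Candidate filtering and abundance statistics** — WDSP-style score
  filtering (≥ 6 repeats, mean score ≥ 48, review band [48, 60)),
  longest-isoform deduplication, per-proteome WD40 percentages, one-sided
  Wilcoxon rank-sum tests, and fold changes of category means.
* **DH[S/T]W tetrad calling** — the Asp–His–Ser/Thr–Trp hydrogen-bond
  network that stabilises a blade, anchored on a canonical template (Asp of
  the L_ab SPDG motif, His on L_da, Ser/Thr closing S_b, Trp at template
  position 37 on S_c), plus tetrad density (tetrads / repeats) and
  sequence-logo matrices with per-position information content.
* **Gene-neighbourhood analysis** — operon-proxy clusters (same strand,
  intergenic gaps < 300 bp), bidirectional-best-hit orthology, conserved
  vs lineage-specific WD40 neighbourhoods, and annotation term counts.
* **Repeat-pair dS/ω** — Nei–Gojobori (1986) counting with Jukes–Cantor
  correction under any NCBI genetic code (tables 1 and 11 built in),
  dS = −¾ ln(1 − 4/3·pS); per-protein median dS dates the duplication, and
  ω = dN/dS over proteins with median dS ∈ [1.0, 2.0) separates "young"
  from "ancient but conserved under purifying selection".
* **Synthetic data with ground truth** — a duplication–divergence gene
  simulator (codon-level, κ-weighted mutations, selection via ω_sim),
  proteome collections with set abundances, and genomes with planted gene
  clusters; every planted quantity is recomputable from the truth logs.

## Worked example

```bash
python examples/01_internal_identity.py
```

```
protein SIMWD40_00000042: 7 repeats
min/max pairwise repeat identity: 0.913 / 1.000
internal sequence identity: 0.935 -> HR
```

A gene simulated at divergence t = 0.05 still has repeats ≥ 91% identical;
the best 6-repeat clique reaches 0.935, so the protein classifies as
Highly-Repetitive — exactly the signature of a recent repeat duplication.
Dating the same signal at the DNA level:

```bash
python examples/05_repeat_ds_omega.py
```

```
young gene (t=0.05): 21/21 usable repeat pairs, median dS = 0.053
ancient gene (t=0.55): 20/21 usable repeat pairs, median dS = 1.217
purifying subset (1.0 <= median dS < 2.0): ['ancient']
median omega in subset = 0.073
```

The young gene's median synonymous divergence is near zero (duplication
just happened); the ancient gene reaches dS ≈ 1.2, and its ω ≈ 0.07 shows
strong purifying selection — the regime in which high protein-level repeat
identity can persist despite an old duplication.

The other examples cover abundance tables (`02`), tetrad density and logos
(`03`), and conserved gene neighbourhoods (`04`). The same operations are
available as CLI subcommands (`repeatscope identity|classify|tetrad|
abundance|neighbourhood|evolve-rates|logo|simulate`).

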
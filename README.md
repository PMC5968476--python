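# syntad

Annotating putative topological association domains (TADs) and CTCF binding
motifs in a target genome from cross-species synteny, and testing whether
regulatory variation — boundary hallmarks, allele-specific expression (ASE)
and cis-QTLs — is confined by those annotations.

TADs are chromosomal segments whose interiors contact each other far more
often than the outside; they are conserved across cell types and species, so
domains called from Hi-C in well-studied genomes can be projected onto a
genome that lacks Hi-C data. Projecting megabase-scale domains through
coordinate conversion shatters them into fragments, and the core of this
package is the chain that turns fragment mappings back into credible domains
and then asks whether the resulting annotation behaves like the real thing.

## What the package computes

**TAD recovery and filtering** (`syntad.tad_mapping`). For each query TAD,
fragments on one chromosome separated by gaps ≤ *w* (the minimum input-TAD
width of the set) are merged back into one span; fragments of different
queries are never merged. A consensus profile *aᵢ* counts, at every genomic
position *i*, how many of the TAD sets cover it; a stage-1 TAD survives iff
it is ≥ 200 kb wide and reaches *aᵢ* ≥ 4 somewhere. Finally, TADs overlapping
by more than 1 bp are merged, preserving exact 1-bp "TAD1.TAD2" touches.

**Boundaries, motif sets and CTCF gaps** (`syntad.annotation`). A boundary is
the ≤ 400 kb interval between adjacent TADs of a set; an exact touch (a
"knot") contributes a 400-kb window centred on the shared coordinate.
FIMO-style motif hits are filtered into a less stringent set (P ≤ 10⁻⁵) and
a more stringent set (score ≥ 80, P ≤ 10⁻⁸, overlapping same-strand hits
merged); CTCF gaps are the intervals strictly between consecutive
strand-flattened stringent blocks.

**Circular-permutation enrichment** (`syntad.enrichment`). The null model
rotates features along each chromosome by M ~ Uniform{1..L} with
wrap-around, preserving sizes and spacing. With observed statistic *n*
(overlapping bp, or points inside regions) and permuted values *m*:
fold change = n / mean(m), rank R = 1 + #(m ≥ n), P = R/(n_perm+1)
(reported as "<0.0001" when n beats all 10,000 permutations); enrichment is
declared when n exceeds 95% (bp) or 99% (points) of the m values.

**ASE ANOVA** (`syntad.ase`). Each heterozygous exonic site scores
Y = log₁₀((P+1)/(M+1)) from paternal/maternal read counts. Regulatory units
are TADs, CTCF gaps, or their intersection cells (≥ 5 SNPs each); a one-way
ANOVA partitions score variance between units (R² = SSB/SST), a genome-wide
score shuffle supplies the cohort null, and a unit shows significant ASE
when |mean score| beats 99% of its shuffled means and a one-sample t-test
gives P ≤ 10⁻⁶.

**cis-QTL colocalization** (`syntad.qtl`). Per eGene the most significant
passing cis-QTL is selected, ties broken by the linearly furthest SNP. With
N eGenes overlapping a TAD, M̄ the maximum eSNPs tested on one chromosome
and threshold p, the expected same-TAD count is E = N·M̄·p and the departure
is χ² = (E−O)²/E (1 df, significant at P < 0.001).

**Synthetic inputs** (`syntad.synthetic`) generate every table above with
known ground truth, so the whole chain is testable without any download.

## Worked example

```
python analysis/01_simulate_inputs.py --seed 1   # inputs under results/
python analysis/02_map_tads.py --seed 1
python analysis/04_boundary_enrichment.py --seed 1
```

The mapping driver prints, per set, the recovery → filter → refinement
counts, e.g.

```
tadset1: stage1 42 -> stage2 42 (>=200 kb & 4-of-6 consensus) -> final 38; final widths 303-2100 kb
classification matches generator ground truth: True
```

42 recovered spans pass the width/consensus filter and local refinement
merges rearrangement-induced overlaps down to 38 final TADs. The enrichment
driver then reports

```
66 analyses (6 boundary sets x 11 signals)
enriched at the 95% quantile: 66/66; mean fold change 2.04
calibration: uniform signal fold 0.965 (enriched=False); 10x signal fold 4.14 (P <0.0001, enriched=True)
```

signals placed 3× denser inside boundaries are detected in every one of the
66 boundary-set × hallmark analyses, a uniformly placed signal is correctly
not called (fold ≈ 1), and a 10× signal hits the permutation resolution
bound. The remaining drivers (`05`–`07`) fit the three ASE ANOVA models and
run the 32-analysis QTL-motif and 96-test colocalization grids.

A `syntad` console command exposes the same steps
(`simulate`, `map-tads`, `boundaries`, `motifs`, `enrich`, `ase`,
`qtl-coloc`, `run-all`) for file-based runs.

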
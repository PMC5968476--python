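# Methods

This note records the models implemented in `syntad`, the parameters that
matter, the generative model behind the synthetic data, and the numerical
and design choices that were genuinely open.

## Coordinates and interval arithmetic

All coordinates are 0-based half-open (BED convention); widths are
`end − start`. The source descriptions of the procedures never state a
convention, so every printed width rule (200 kb, 400 kb) is interpreted on
that scale, and conversion shims for 1-based inclusive motif coordinates
are a reader option rather than a core change. Strand is carried on
intervals but ignored by all overlap arithmetic except stringent-motif
merging, which is per strand by definition.

Two merge primitives coexist deliberately:

* `flatten` — union semantics, overlapping *or touching* blocks become one
  (used for coverage, gaps, and all overlap counting);
* `merge_intervals(ivs, k)` — merges only when the pairwise overlap is
  *strictly greater* than `k` bp. With `k = 1` (local refinement) two TADs
  sharing exactly 1 bp stay separate, preserving the "TAD1.TAD2" knot
  structure that the boundary definition later depends on.

## TAD recovery, consensus and refinement

The recovery gap rule is inclusive: fragments of one query merge when the
gap between consecutive sorted fragments is ≤ *w*, where *w* is the minimum
input-TAD width of that set ("no more than w away"). Gaps are measured from
fragment end to next fragment start; fragment strand is ignored (coordinate
conversion strand flips are treated as plain intervals).

The consensus count *aᵢ* includes the set being filtered — the filtering
description counts "TAD sets" without excluding the candidate's own — and
both the 200-kb width threshold and the 4-of-6 agreement threshold are
inclusive ("no less than"). Both are configurable
(`TADMappingConfig(min_tad_width, min_agreement)`).

Multi-step conversions through intermediate assemblies are not chained
internally; each step's recovery can be invoked successively (the CLI takes
one mapping table at a time), and query ids propagate unchanged.

Mapping classification counts, per set, queries with exactly one fragment
(single location), queries whose fragments stayed on one chromosome, and
queries with any fragment; queries with no fragments appear in none of the
three counts.

## Boundaries, motif stringency, CTCF gaps

Adjacent TADs with gap in (0, 400 kb] contribute the gap itself as a
boundary. A knot (gap = 0) contributes a 400-kb window centred on the
shared coordinate; windows are clipped at chromosome edges and kept rather
than dropped, which preserves the boundary count. A residual 1-bp overlap
left by refinement yields no boundary; overlaps deeper than 1 bp violate
the precondition and raise.

The stringent motif set realises "non-overlapping" as merging — overlapping
same-strand hits become one block — rather than discarding. CTCF gaps are
computed on cross-strand-flattened blocks: only that reading makes the gap
count one less than the block count per chromosome, matching a motif set
whose gap count is roughly half its stranded motif count. Chromosome-end
segments are excluded because gaps are intervals *between* motifs;
consequently every gap has width ≥ 1 bp.

## Circular-shift permutation tests

One offset M ~ Uniform{1..L} is drawn per chromosome per permutation, as a
single (n_perm × n_chrom) block in genome order, so results do not depend
on chromosome iteration order. Rotated intervals that run past the
chromosome end are split into a tail and a head piece (recycling, not
discarding), which makes per-chromosome covered bp and point counts exact
invariants of the null — a property the test suite checks over 10,000
rotations.

The permuted statistic is computed without materialising shifted tracks: a
prefix-sum coverage index over the fixed track gives `cum(x)` = covered bp
in `[0, x)`, and the overlap of a rotated interval is `cum` evaluated at
its (possibly wrapped) endpoints, vectorised over permutations ×
intervals. A test asserts this equals overlap after an explicit shift.

For hallmark tests the regions (boundaries) rotate; for QTL tests the
points rotate, deduplicated by position first (a cis-QTL associated with
several eGenes counts once). Which object moves is an explicit argument.

Rank handling: R = 1 + #(m ≥ n); ties count against enrichment, since the
source defines no tie rule. When R = 1 the P-value is reported as the
resolution bound "<1/(n_perm+1)" ("<0.0001" at 10,000 permutations);
otherwise P = R/(n_perm+1). "Larger than 95% (or 99%) of all m values" is
implemented as a strict count: #(m < n) ≥ ⌈q·n_perm⌉. A fold change with
mean(m) = 0 is reported as infinite with a warning rather than raising.

## ASE ANOVA

The score Y = log₁₀((P+1)/(M+1)) is defined for every record because of the
pseudocount, so "valid ASE score" is any record with P + M ≥ 1 read (a
configurable minimum-depth filter defaults to 1). Units keep ≥ 5 scored
SNPs; under the nested TAD+CTCF model a unit is an (containing TAD,
containing gap) intersection cell, and records outside all regions are
excluded rather than pooled into a background unit — the models describe
innermost regions only. Tissues are analysed independently, and the cohort
shuffle permutes scores within the tissue being fitted.

The one-way ANOVA is computed from the variance decomposition
(SSB, SSW, R² = SSB/SST, F with (k−1, N−k) df) and is cross-checked against
`scipy.stats.f_oneway` in the tests. The cohort is permutation-significant
when the observed R² exceeds all shuffled R² values.

The per-unit rule "P-value for n ≤ 10⁻⁶" cannot be an empirical rank from
10,000 shuffles (resolution 10⁻⁴), so it is implemented as a one-sample
t-test of the unit's scores against zero, combined with the empirical
criterion |mean| larger than 99% of the unit's shuffled |means|. This is an
interpretation, documented as such, not an assertion about the original
analysis.

## QTL colocalization

Tie-break distance is from the SNP to the nearest gene edge (0 inside the
gene); remaining ties fall to the lowest coordinate for determinism —
neither rule is defined at the source. "eGene overlapping a TAD" means
≥ 1 bp overlap, not containment. The chi-square uses 1 df (single-cell
goodness of fit). The threshold p entering E = N·M̄·p is configurable
independently of the selection threshold because the published worked table
is arithmetically consistent with p = 10⁻⁷ while its caption states 10⁻⁸;
the tests reproduce the printed E and χ² values with 10⁻⁷. One published
row (mm10:liver, white blood, aseQTL) prints an O/χ² pair that no parse of
the closed form reproduces and is excluded from the frozen expectations.

## Synthetic data: what it emulates and what it does not

The default instance is 2 chromosomes × 20 Mb, 6 TAD sets, 18
pseudo-tissues — large enough for every factorial design (66 boundary
analyses, 32 QTL-motif analyses, 96 colocalization tests) at desk scale.

* **Mappings.** One "true" TAD landscape (widths 300 kb–1.2 Mb, gaps
  50–350 kb, 10% exact knots) tiles each chromosome; each set jitters it by
  ±20 kb so the 4-of-6 consensus retains real domains. Queries split as
  unique / intra-chromosomal / inter-chromosomal with probabilities
  (0.8, 0.15, 0.05); intra splits insert a gap below *w* so recovery
  reconstitutes the span, inter splits place the tail on another
  chromosome. The jitter destroys exact knot coordinates in the mapped
  sets, so knot boundaries are exercised by fixtures rather than by the
  default instance.
* **Motifs.** One hit per grid slot (40/Mb) with jitter, so hits never
  overlap and the constructed stringent subset (30%; score ≥ 80,
  P ∈ [10⁻¹², 10⁻⁹]) survives the stringent filter exactly; the rest draw
  P > 10⁻⁸ and can never pass it.
* **Signal tracks.** 400 intervals of 500 bp placed wholly inside a
  boundary or background block, with inside-probability f·B/(f·B+U); f = 1
  is exactly uniform and f = 0 gives provably zero boundary overlap.
* **ASE.** Per (unit, tissue): δ_u ~ Normal(0, σ_u) on the log-odds scale;
  per SNP: depth ~ NegBin(mean 50, dispersion 5), paternal ~
  Binomial(depth, logistic(δ_u)). The logistic link makes unit mean scores
  monotone in δ_u (recovery correlation > 0.99 at the defaults), and the
  negative-binomial depth keeps mono-allelic sites present, exercising the
  pseudocount.
* **QTLs.** Genes sit inside TADs; each receives 30 background associations
  (P ≥ 10⁻³) and, for half the genes, one top QTL (P ∈ [10⁻¹², 10⁻⁹])
  placed in the gene's TAD with probability 0.8 and snapped into a motif
  with probability 0.5; realised placements are recorded as truth.

Not emulated: sequence content, mapping bias, linkage disequilibrium,
realistic chromosome counts or real motif position-weight matrices,
correlated tissues, or multi-step assembly chains. Passing tests therefore
demonstrate that the procedures implement their stated rules and recover
known structure — not that real cross-species annotations would reach any
particular enrichment level.

## Problem sizes and determinism

Permutation defaults are 10,000 rotations (enrichment) and the test suite
exercises them at full scale where the quantity under test is a
conservation law; calibration and ASE analyses in the drivers use 1,000
shuffles, which already resolves P ≤ 10⁻³ ranks and keeps a full run in
seconds. All generators and tests derive randomness from explicit seeds
(`numpy.random.SeedSequence` with stream ids), so reruns are byte-identical;
the acceptance script threads a single `--seed` through every stage.

## Known limitations

* The consensus profile is exact run-length encoding; genomes with tens of
  millions of distinct breakpoints would need a coarser representation.
* `fit_anova` raises on the degenerate N = k design (one SNP per unit)
  rather than returning R² = 1.
* The CLI chains one conversion step at a time; orchestration of
  multi-assembly chains is left to the caller.
* Enrichment against nulls that match GC content or assembly gaps
  (shuffle-with-exclusions) is out of scope; the circular rotation
  preserves spacing but not local sequence context.
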
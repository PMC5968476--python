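#!/usr/bin/env python
"""Derive TAD boundaries (with 400-kb knot windows), the two CTCF motif
stringency sets, and the CTCF gaps between stringent motif blocks."""

import argparse
from pathlib import Path

from syntad import core_io, synthetic as syn
from syntad.annotation import ctcf_gaps, extract_boundaries, filter_motifs
from syntad.tad_mapping import map_all_sets

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results/annotations"))
args = ap.parse_args()

cfg = syn.SimulationConfig(seed=args.seed)
genome = syn.make_genome(cfg)
queries, mappings, _ = syn.make_fragment_mappings(cfg, genome)
stages = map_all_sets(mappings, syn.recovery_widths(queries))
args.outdir.mkdir(parents=True, exist_ok=True)

for set_id, tracks in stages.items():
    bnd = extract_boundaries(tracks["final"], genome=genome)
    core_io.write_bed(bnd, args.outdir / f"{set_id}.boundaries.bed")
    knots = sum(1 for b in bnd if b.width == 400_000)
    print(f"{set_id}: {len(bnd)} boundaries (<=400 kb), of which {knots} knot windows")

hits = syn.make_motif_hits(cfg, genome)
less = filter_motifs(hits, "less")
more = filter_motifs(hits, "more")
gaps = ctcf_gaps(more, genome)
core_io.write_bed(less, args.outdir / "ctcf_less_stringent.bed", six_column=True)
core_io.write_bed(more, args.outdir / "ctcf_stringent.bed", six_column=True)
core_io.write_bed(gaps, args.outdir / "ctcf_gaps.bed")
gap_widths = [g.width for g in gaps]
print(f"motif hits: {len(hits)} -> less stringent (P<=1e-5): {len(less)}; "
      f"stringent (score>=80 & P<=1e-8, merged per strand): {len(more)}")
print(f"CTCF gaps: {len(gaps)}, widths {min(gap_widths)}-{max(gap_widths)} bp")
print(f"written to {args.outdir}/")
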
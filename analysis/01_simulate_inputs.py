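#!/usr/bin/env python
"""Generate the simulated study inputs (fragment mappings, motif hits, signal
tracks, ASE read counts, cis-QTL associations) into results/simulated_inputs/.

Every downstream driver regenerates what it needs from the same seed, so this
script exists to materialise the files a reader can inspect."""

import argparse
from pathlib import Path

from syntad import core_io, synthetic as syn
from syntad.cli import _write_genome

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results/simulated_inputs"))
args = ap.parse_args()

cfg = syn.SimulationConfig(seed=args.seed)
out = args.outdir
out.mkdir(parents=True, exist_ok=True)

genome = syn.make_genome(cfg)
_write_genome(genome, out / "genome.tsv")
queries, mappings, truth = syn.make_fragment_mappings(cfg, genome)
queries.to_csv(out / "queries.tsv", sep="\t", index=False)
mappings.to_csv(out / "fragment_mappings.tsv", sep="\t", index=False)
truth.to_csv(out / "truth_mappings.tsv", sep="\t", index=False)
hits = syn.make_motif_hits(cfg, genome)
hits.to_csv(out / "motif_hits.tsv", sep="\t", index=False)
units = syn.make_units(cfg, genome)
core_io.write_bed(units, out / "units.bed")
records, ase_truth = syn.make_ase_records(cfg, units)
records.to_csv(out / "ase_records.tsv", sep="\t", index=False)
ase_truth.to_csv(out / "truth_ase.tsv", sep="\t", index=False)

print(f"genome: {len(genome.chroms)} chromosomes x {genome.chroms[0][1]/1e6:.0f} Mb")
print(f"query TADs: {len(queries)} across {cfg.n_tad_sets} sets "
      f"-> {len(mappings)} target fragments")
print("split categories:", truth.category.value_counts().to_dict())
print(f"motif hits: {len(hits)} ({int(hits.is_stringent.sum())} stringent by construction)")
print(f"ASE records: {len(records)} over {cfg.n_tissues} tissues, "
      f"{len(units)} regulatory units")
print(f"written to {out}/")
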
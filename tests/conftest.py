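"""Shared fixtures: toy genomes, the mini simulated instance, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from syntad import synthetic as syn
from syntad import tad_mapping as tm
from syntad.core_io import Genome, GenomicInterval, Track


@pytest.fixture(scope="session")
def mini_cfg() -> syn.SimulationConfig:
    return syn.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def mini_genome(mini_cfg) -> Genome:
    return syn.make_genome(mini_cfg)


@pytest.fixture(scope="session")
def mini_mappings(mini_cfg, mini_genome):
    queries, mappings, truth = syn.make_fragment_mappings(mini_cfg, mini_genome)
    return queries, mappings, truth


@pytest.fixture(scope="session")
def mini_stages(mini_mappings):
    queries, mappings, _ = mini_mappings
    return tm.map_all_sets(mappings, syn.recovery_widths(queries))


@pytest.fixture(scope="session")
def mini_motif_hits(mini_cfg, mini_genome):
    return syn.make_motif_hits(mini_cfg, mini_genome)


# ---------------------------------------------------------------------------
# brute-force per-base oracles used across modules


def coverage_mask(track: Track, genome: Genome) -> dict[str, np.ndarray]:
    """Per-chromosome boolean membership array (only safe on toy genomes)."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in genome.chroms}
    for iv in track:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def brute_overlap_bp(a: Track, b: Track, genome: Genome) -> int:
    ma, mb = coverage_mask(a, genome), coverage_mask(b, genome)
    return int(sum((ma[c] & mb[c]).sum() for c in ma))


def random_toy_track(rng: np.random.Generator, genome: Genome, n_intervals: int = 5) -> Track:
    out = []
    for _ in range(n_intervals):
        chrom, length = genome.chroms[int(rng.integers(len(genome.chroms)))]
        start = int(rng.integers(0, length - 1))
        end = int(rng.integers(start + 1, length + 1))
        out.append(GenomicInterval(chrom, start, end))
    return Track("toy", out)
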
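"""Recovery, consensus filtering and local refinement of cross-species TADs.

Cross-assembly coordinate conversion of megabase-scale TADs shatters each
query domain into fragments on the target genome.  The chain here turns a
fragment-mapping table (one row per fragment: set, query id, target
chromosome, start, end) into final putative TAD sets:

stage 1 (recovery)
    Fragments of one query on one chromosome whose gaps are no more than
    ``w`` (the minimum input-TAD width of the set) are merged into a
    single TAD spanning them.  Fragments of the same query on different
    chromosomes stay separate; fragments of different queries are never
    merged even when they overlap.

stage 2 (consensus filter)
    For each genomic position i, a_i counts how many TAD sets cover i.
    A stage-1 TAD survives iff it is at least ``min_tad_width`` (200 kb)
    wide and contains at least one position with a_i >= ``min_agreement``
    (4 of 6 sets).

final (local refinement)
    Stage-2 TADs overlapping by more than 1 bp are merged; exact 1-bp
    touches ('TAD1.TAD2' knots) are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GenomicInterval, Track, merge_intervals

__all__ = [
    "TADMappingConfig",
    "ConsensusProfile",
    "recover_stage1",
    "consensus_profile",
    "consensus_filter",
    "local_refinement",
    "classify_mapping",
    "map_all_sets",
]

MAPPING_SCHEMA = {"set_id": str, "query_id": str, "chrom": str, "start": int, "end": int}


@dataclass
class TADMappingConfig:
    w: int  # minimum width of input TADs in the set; recovery merge distance
    min_tad_width: int = 200_000
    min_agreement: int = 4
    refine_min_overlap: int = 1

    def __post_init__(self) -> None:
        for name in ("w", "min_tad_width", "min_agreement", "refine_min_overlap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def recover_stage1(mappings: pd.DataFrame, config: TADMappingConfig) -> Track:
    """Merge per-query fragments with inter-fragment gap <= w into TADs.

    ``mappings`` has columns set_id, query_id, chrom, start, end and must
    describe a single TAD set.  The merged TAD spans from the first
    fragment start to the last fragment end ("no more than w away" is
    inclusive: gap == w merges).
    """
    missing = set(MAPPING_SCHEMA) - set(mappings.columns)
    if missing:
        raise ValueError(f"mapping table missing columns {sorted(missing)}")
    sets = mappings["set_id"].unique()
    if len(sets) > 1:
        raise ValueError(f"recover_stage1 expects one set, got {list(sets)}")
    out: list[GenomicInterval] = []
    for (_, chrom), grp in mappings.groupby(["query_id", "chrom"], sort=True):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= config.w:  # gap <= w merges (negative gap = overlap)
                cur_e = max(cur_e, int(e))
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    label = str(sets[0]) if len(sets) else "stage1"
    return Track(label, sorted(out))


@dataclass
class ConsensusProfile:
    """Run-length encoded per-position count a_i of TAD sets covering i.

    Per chromosome: ``breaks`` are the segment boundaries and
    ``counts[k]`` holds a_i on ``[breaks[k], breaks[k+1])``.
    """

    segments: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def count_at(self, chrom: str, pos: int) -> int:
        if chrom not in self.segments:
            return 0
        breaks, counts = self.segments[chrom]
        k = int(np.searchsorted(breaks, pos, side="right")) - 1
        if k < 0 or k >= len(counts):
            return 0
        return int(counts[k])

    def max_over(self, chrom: str, start: int, end: int) -> int:
        """Maximum a_i over [start, end)."""
        if chrom not in self.segments:
            return 0
        breaks, counts = self.segments[chrom]
        lo = max(int(np.searchsorted(breaks, start, side="right")) - 1, 0)
        hi = int(np.searchsorted(breaks, end, side="left"))
        window = counts[lo:hi]
        return int(window.max()) if len(window) else 0


def consensus_profile(stage1_sets: list[Track]) -> ConsensusProfile:
    """Count, per genomic position, how many sets cover it (flattened)."""
    if not stage1_sets:
        raise ValueError("need at least one TAD set")
    events: dict[str, list[tuple[int, int]]] = {}
    for track in stage1_sets:
        for iv in track.flattened():
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    profile = ConsensusProfile()
    for chrom, evts in events.items():
        evts.sort()
        pos = np.array([p for p, _ in evts], dtype=np.int64)
        delta = np.array([d for _, d in evts], dtype=np.int64)
        breaks, inverse = np.unique(pos, return_inverse=True)
        per_break = np.bincount(inverse, weights=delta).astype(np.int64)
        counts = np.cumsum(per_break)[:-1]  # a_i on [breaks[k], breaks[k+1])
        profile.segments[chrom] = (breaks, counts)
    return profile


def consensus_filter(
    stage1_set: Track, profile: ConsensusProfile, config: TADMappingConfig
) -> Track:
    """Keep TADs that are >= min_tad_width wide with max a_i >= min_agreement."""
    kept = [
        iv
        for iv in stage1_set.intervals
        if iv.width >= config.min_tad_width
        and profile.max_over(iv.chrom, iv.start, iv.end) >= config.min_agreement
    ]
    return Track(stage1_set.label, kept)


def local_refinement(stage2_set: Track, config: TADMappingConfig) -> Track:
    """Merge TADs overlapping by more than ``refine_min_overlap`` (1 bp)."""
    return Track(
        stage2_set.label, merge_intervals(stage2_set.intervals, config.refine_min_overlap)
    )


def classify_mapping(mappings: pd.DataFrame) -> pd.DataFrame:
    """Per-set query counts in the three nested mapping categories.

    Columns mirror the classic summary: queries that mapped to a single
    location (no split), queries whose fragments stayed on one target
    chromosome (no split or intra-chromosomal split only), and queries
    that mapped at all.  Queries with no fragments never appear in the
    table, so they are excluded from all three counts.
    """
    rows = []
    for set_id, grp in mappings.groupby("set_id", sort=True):
        per_query = grp.groupby("query_id").agg(
            n_frag=("chrom", "size"), n_chrom=("chrom", "nunique")
        )
        unique = int((per_query["n_frag"] == 1).sum())
        same_chrom = int((per_query["n_chrom"] == 1).sum())
        mapped = int(len(per_query))
        rows.append(
            {
                "set_id": set_id,
                "n_queries_mapped": mapped,
                "unique_location": unique,
                "same_chromosome": same_chrom,
                "any_location": mapped,
            }
        )
    return pd.DataFrame(rows)


def map_all_sets(
    mappings: pd.DataFrame, widths: dict[str, int], config: TADMappingConfig | None = None
) -> dict[str, dict[str, Track]]:
    """Run the full stage1 -> stage2 -> final chain for every set.

    ``widths`` maps set_id to that set's recovery distance w (the minimum
    input-TAD width).  Returns, per set, the three stages as Tracks.
    """
    stage1: dict[str, Track] = {}
    for set_id, grp in mappings.groupby("set_id", sort=True):
        cfg = TADMappingConfig(
            w=widths[set_id],
            **(
                {}
                if config is None
                else {
                    "min_tad_width": config.min_tad_width,
                    "min_agreement": config.min_agreement,
                    "refine_min_overlap": config.refine_min_overlap,
                }
            ),
        )
        stage1[set_id] = recover_stage1(grp, cfg)
    profile = consensus_profile(list(stage1.values()))
    out: dict[str, dict[str, Track]] = {}
    for set_id, s1 in stage1.items():
        cfg = TADMappingConfig(
            w=widths[set_id],
            **(
                {}
                if config is None
                else {
                    "min_tad_width": config.min_tad_width,
                    "min_agreement": config.min_agreement,
                    "refine_min_overlap": config.refine_min_overlap,
                }
            ),
        )
        s2 = consensus_filter(s1, profile, cfg)
        final = local_refinement(s2, cfg)
        out[set_id] = {"stage1": s1, "stage2": s2, "final": final}
    return out
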
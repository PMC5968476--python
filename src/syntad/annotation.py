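"""TAD boundaries (with knots), stringency-filtered CTCF motif sets, CTCF gaps.

A boundary is the interval between adjacent TADs of one set when that
interval is no larger than 400 kb.  When consecutive TADs touch exactly
(a 'knot': previous end == next start) the boundary is a 400-kb window
centred on the shared coordinate, clipped to the chromosome.  Motif hits
come in FIMO-style rows (interval + strand, score, P-value) and are
filtered into a less stringent set (P <= 1e-5) and a more stringent set
(score >= 80 and P <= 1e-8, overlapping same-strand hits merged).  CTCF
gaps are the intervals strictly between consecutive strand-flattened
stringent-motif blocks; chromosome-end segments are not gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Genome, GenomicInterval, Track, flatten, merge_intervals

__all__ = [
    "BoundaryConfig",
    "extract_boundaries",
    "filter_motifs",
    "ctcf_gaps",
    "motif_track",
    "LESS_STRINGENT_P",
    "STRINGENT_P",
    "STRINGENT_SCORE",
]

LESS_STRINGENT_P = 1e-5
STRINGENT_P = 1e-8
STRINGENT_SCORE = 80.0

MOTIF_SCHEMA = {"chrom": str, "start": int, "end": int, "strand": str, "score": float, "p_value": float, "motif_id": str}


@dataclass
class BoundaryConfig:
    max_gap: int = 400_000
    knot_window: int = 400_000
    include_knots: bool = True

    def __post_init__(self) -> None:
        if self.max_gap <= 0 or self.knot_window <= 0:
            raise ValueError("max_gap and knot_window must be positive")


def extract_boundaries(
    tads: Track, config: BoundaryConfig | None = None, genome: Genome | None = None
) -> Track:
    """Boundaries between adjacent TADs of one (refined) set.

    Gap in (0, max_gap] -> the gap interval is a boundary; gap == 0 (knot)
    with ``include_knots`` -> a knot_window interval centred on the shared
    coordinate, clipped to the chromosome when a genome is given; gaps
    larger than max_gap (or 1-bp touches left by refinement) yield no
    boundary.  Input TADs overlapping by more than 1 bp are a
    precondition violation.
    """
    config = config or BoundaryConfig()
    out: list[GenomicInterval] = []
    for chrom, (starts, ends) in tads.by_chrom().items():
        for k in range(len(starts) - 1):
            gap = int(starts[k + 1] - ends[k])
            if gap < -1:
                raise ValueError(
                    f"TADs overlap by {-gap} bp on {chrom}; refine the set first"
                )
            if gap == 0 and config.include_knots:
                knot = int(ends[k])
                half = config.knot_window // 2
                lo, hi = knot - half, knot + (config.knot_window - half)
                if genome is not None:
                    lo = max(lo, 0)
                    hi = min(hi, genome.length(chrom))
                elif lo < 0:
                    lo = 0
                if hi > lo:
                    out.append(GenomicInterval(chrom, lo, hi))
            elif 0 < gap <= config.max_gap:
                out.append(GenomicInterval(chrom, int(ends[k]), int(starts[k + 1])))
    return Track(f"{tads.label}.boundaries", sorted(out))


def motif_track(hits: pd.DataFrame, label: str = "motifs") -> Track:
    """FIMO-style hit table -> stranded Track."""
    intervals = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        for r in hits.itertuples()
    ]
    return Track(label, intervals)


def filter_motifs(hits: pd.DataFrame, mode: str) -> Track:
    """Stringency-filter motif hits.

    mode='less': keep P <= 1e-5, no merging (stranded hits as given).
    mode='more': keep score >= 80 AND P <= 1e-8, then merge overlapping
    (>= 1 bp) hits per strand.
    """
    if mode not in ("less", "more"):
        raise ValueError("mode must be 'less' or 'more'")
    if mode == "less":
        kept = hits[hits["p_value"] <= LESS_STRINGENT_P]
        return motif_track(kept, "ctcf_less_stringent")
    kept = hits[(hits["score"] >= STRINGENT_SCORE) & (hits["p_value"] <= STRINGENT_P)]
    merged: list[GenomicInterval] = []
    for strand in ("+", "-", "."):
        sub = kept[kept["strand"] == strand]
        if sub.empty:
            continue
        ivs = [
            GenomicInterval(r.chrom, int(r.start), int(r.end), strand)
            for r in sub.itertuples()
        ]
        # min_overlap_bp=0: any >= 1 bp overlap merges; merged blocks keep strand
        for block in merge_intervals(ivs, 0):
            merged.append(GenomicInterval(block.chrom, block.start, block.end, strand))
    return Track("ctcf_stringent", sorted(merged))


def ctcf_gaps(stringent: Track, genome: Genome) -> Track:
    """Intervals strictly between consecutive strand-flattened motif blocks.

    Motifs on both strands are flattened into unstranded blocks first; a
    chromosome with k >= 2 blocks yields exactly k - 1 gaps.  Segments
    between a chromosome end and its first/last block are not gaps.
    """
    out: list[GenomicInterval] = []
    blocks = stringent.flattened().by_chrom()
    for chrom in genome.names:
        if chrom not in blocks:
            continue
        starts, ends = blocks[chrom]
        for k in range(len(starts) - 1):
            out.append(GenomicInterval(chrom, int(ends[k]), int(starts[k + 1])))
    return Track("ctcf_gaps", out)
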
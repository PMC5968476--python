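"""Synthetic inputs with the statistical structure the pipeline assumes.

Every table the analysis consumes — fragment mappings from cross-species
coordinate conversion, FIMO-style motif hits, hallmark signal tracks,
per-tissue allelic read counts, and cis-QTL association tables — can be
generated here from a single seeded configuration, together with
ground-truth side tables that let downstream modules run oracle
comparisons.  The default configuration is a "paper-scale mini" instance:
2 chromosomes x 20 Mb, 6 TAD sets, 18 pseudo-tissues.

Generative choices (documented, not claims about real data):

* One "true" TAD landscape tiles each chromosome; each of the 6 sets is
  a jittered copy, so the 4-of-6 consensus filter retains real TADs.
* A query TAD maps without splitting, with an intra-chromosomal split
  (two fragments separated by a gap below the recovery distance w, so
  recovery reconstitutes the span), or with an inter-chromosomal split.
* Allelic imbalance is modelled on the log-odds scale: each regulatory
  unit draws a bias delta_u ~ Normal(0, sigma_u) per tissue, read depth
  is negative-binomial (mono-allelic sites exercise the +1 pseudocount),
  and paternal counts are Binomial(depth, logistic(delta_u)).
* Significant cis-QTLs are placed inside CTCF motifs and inside the
  eGene's TAD with configurable fractions; realised placements are
  recorded as truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_io import Genome, GenomicInterval, Track, flatten

__all__ = ["SimulationConfig", "make_genome", "make_fragment_mappings",
           "make_motif_hits", "make_signal_track", "make_units",
           "make_ase_records", "make_qtl_table", "recovery_widths"]


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length_bp: int = 20_000_000
    # TAD landscape and mappings
    n_tad_sets: int = 6
    tad_width_range: tuple[int, int] = (300_000, 1_200_000)
    tad_gap_range: tuple[int, int] = (50_000, 350_000)
    knot_prob: float = 0.1
    jitter_bp: int = 20_000
    split_probs: tuple[float, float, float] = (0.8, 0.15, 0.05)  # unique/intra/inter
    # motifs
    motif_density_per_mb: float = 40.0
    motif_width_range: tuple[int, int] = (15, 40)
    stringent_fraction: float = 0.3
    # hallmark signal
    n_signal_intervals: int = 400
    signal_width_bp: int = 500
    boundary_enrichment_factor: float = 3.0
    # ASE
    n_tissues: int = 18
    units_per_chrom: int = 25
    snps_per_unit: int = 20
    read_depth_mean: float = 50.0
    read_depth_dispersion: float = 5.0
    sigma_unit: float = 1.0
    # QTL
    n_genes: int = 300
    gene_width_bp: int = 20_000
    n_assoc_per_gene: int = 30
    cis_window_bp: int = 1_000_000
    frac_significant_genes: float = 0.5
    frac_in_motif: float = 0.5
    frac_same_tad: float = 0.8
    qtl_types: tuple[str, ...] = ("aseQTL", "eQTL")
    cell_types: tuple[str, ...] = ("white_blood", "milk")

    def __post_init__(self) -> None:
        if abs(sum(self.split_probs) - 1.0) > 1e-9:
            raise ValueError("split_probs must sum to 1")
        for p in (*self.split_probs, self.frac_in_motif, self.frac_same_tad,
                  self.frac_significant_genes, self.knot_prob, self.stringent_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.sigma_unit < 0:
            raise ValueError("sigma_unit must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def make_genome(config: SimulationConfig) -> Genome:
    return Genome.from_lengths(
        [(f"chr{i + 1}", config.chrom_length_bp) for i in range(config.n_chroms)]
    )


def _true_landscape(config: SimulationConfig, genome: Genome, rng: np.random.Generator) -> list[GenomicInterval]:
    """Tile each chromosome with the 'true' TAD spans all sets agree on."""
    out = []
    for chrom, length in genome.chroms:
        pos = int(rng.integers(50_000, 200_000))
        while True:
            width = int(rng.integers(*config.tad_width_range))
            if pos + width > length - 50_000:
                break
            out.append(GenomicInterval(chrom, pos, pos + width))
            if rng.random() < config.knot_prob:
                gap = 0
            else:
                gap = int(rng.integers(*config.tad_gap_range))
            pos += width + gap
    return out


def make_fragment_mappings(
    config: SimulationConfig, genome: Genome
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Query TAD sets and their target-genome fragment mappings.

    Returns (queries, mappings, truth):
    queries  — set_id, query_id, chrom, start, end on the query genome;
    mappings — set_id, query_id, chrom, start, end fragments on the target;
    truth    — set_id, query_id, category in {unique, intra, inter} and the
               intended target span.
    """
    rng = config.rng(1)
    landscape = _true_landscape(config, genome, rng)
    queries, mappings, truth = [], [], []
    chrom_names = genome.names
    for s in range(config.n_tad_sets):
        set_id = f"tadset{s + 1}"
        spans = []
        for iv in landscape:
            j1 = int(rng.integers(-config.jitter_bp, config.jitter_bp + 1))
            j2 = int(rng.integers(-config.jitter_bp, config.jitter_bp + 1))
            start = max(iv.start + j1, 0)
            end = min(iv.end + j2, genome.length(iv.chrom))
            if end - start >= 50_000:
                spans.append(GenomicInterval(iv.chrom, start, end))
        w = min(sp.width for sp in spans)
        for q, span in enumerate(spans):
            query_id = f"{set_id}.q{q}"
            queries.append((set_id, query_id, span.chrom, span.start, span.end))
            category = ("unique", "intra", "inter")[
                int(rng.choice(3, p=config.split_probs))
            ]
            frags: list[GenomicInterval] = []
            if category == "unique":
                frags = [span]
            elif category == "intra":
                gap = int(rng.integers(max(w // 10, 1), max(int(0.8 * w), 2)))
                gap = min(gap, max(span.width // 3, 1))
                cut = span.start + int((span.width - gap) * rng.uniform(0.3, 0.7))
                frags = [
                    GenomicInterval(span.chrom, span.start, cut),
                    GenomicInterval(span.chrom, cut + gap, span.end),
                ]
            else:  # inter-chromosomal: tail lands on another chromosome
                half = span.width // 2
                other = chrom_names[
                    (chrom_names.index(span.chrom) + 1 + int(rng.integers(len(chrom_names) - 1)))
                    % len(chrom_names)
                ] if len(chrom_names) > 1 else span.chrom
                ostart = int(rng.integers(0, genome.length(other) - (span.width - half)))
                frags = [
                    GenomicInterval(span.chrom, span.start, span.start + half),
                    GenomicInterval(other, ostart, ostart + (span.width - half)),
                ]
            for f in frags:
                mappings.append((set_id, query_id, f.chrom, f.start, f.end))
            truth.append((set_id, query_id, category, span.chrom, span.start, span.end))
    qdf = pd.DataFrame(queries, columns=["set_id", "query_id", "chrom", "start", "end"])
    mdf = pd.DataFrame(mappings, columns=["set_id", "query_id", "chrom", "start", "end"])
    tdf = pd.DataFrame(
        truth, columns=["set_id", "query_id", "category", "span_chrom", "span_start", "span_end"]
    )
    return qdf, mdf, tdf


def recovery_widths(queries: pd.DataFrame) -> dict[str, int]:
    """Per set, the recovery distance w = minimum query-TAD width."""
    widths = queries["end"] - queries["start"]
    return queries.assign(width=widths).groupby("set_id")["width"].min().astype(int).to_dict()


def make_motif_hits(config: SimulationConfig, genome: Genome) -> pd.DataFrame:
    """FIMO-style motif-hit table.

    Hits are laid on an even grid with jitter (one hit per slot), so no
    two hits overlap and the constructed stringent subset (score >= 80,
    P <= 1e-9..1e-12) survives the stringent filter unchanged; the rest
    draw P in (1e-7.9, 1e-4] and can never pass it.  Column
    ``is_stringent`` is generator truth.
    """
    rng = config.rng(2)
    rows = []
    wlo, whi = config.motif_width_range
    for chrom, length in genome.chroms:
        n = int(round(config.motif_density_per_mb * length / 1e6))
        if n == 0:
            continue
        slot = length // n
        for k in range(n):
            width = int(rng.integers(wlo, whi + 1))
            lo = k * slot
            hi = min((k + 1) * slot, length) - width
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            stringent = rng.random() < config.stringent_fraction
            if stringent:
                score = float(rng.uniform(80.0, 100.0))
                p = 10.0 ** rng.uniform(-12.0, -9.0)
            else:
                score = float(rng.uniform(40.0, 95.0))
                p = 10.0 ** rng.uniform(-7.9, -4.0)
            rows.append((chrom, start, start + width, strand, f"motif_{1 + int(rng.integers(8))}",
                         round(score, 3), p, stringent))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "motif_id", "score", "p_value", "is_stringent"],
    )


def make_signal_track(
    config: SimulationConfig,
    boundaries: Track,
    genome: Genome,
    enrichment_factor: float | None = None,
    seed_stream: int = 3,
) -> Track:
    """A hallmark signal track placed at rate f x higher per bp inside boundaries.

    With f = 1 placement is uniform over the genome; with f = 0 the signal
    never touches a boundary.  Intervals are short (``signal_width_bp``)
    and placed wholly within the chosen stratum, so the rate statement is
    exact.
    """
    f = config.boundary_enrichment_factor if enrichment_factor is None else enrichment_factor
    if f < 0:
        raise ValueError("enrichment factor must be >= 0")
    rng = config.rng(seed_stream)
    inside_blocks = [iv for iv in boundaries.flattened() if iv.width > 0]
    from .core_io import complement

    outside_blocks = list(complement(boundaries, genome).intervals)
    b_mass = sum(iv.width for iv in inside_blocks)
    u_mass = sum(iv.width for iv in outside_blocks)
    p_inside = 0.0 if (f * b_mass + u_mass) == 0 else f * b_mass / (f * b_mass + u_mass)
    out = []
    for _ in range(config.n_signal_intervals):
        blocks = inside_blocks if rng.random() < p_inside else outside_blocks
        if not blocks:
            continue
        weights = np.array([iv.width for iv in blocks], dtype=float)
        block = blocks[int(rng.choice(len(blocks), p=weights / weights.sum()))]
        width = min(config.signal_width_bp, block.width)
        start = block.start + int(rng.integers(0, block.width - width + 1))
        out.append(GenomicInterval(block.chrom, start, start + width))
    return Track(f"signal_f{f:g}", sorted(out))


def make_units(config: SimulationConfig, genome: Genome) -> Track:
    """Contiguous, disjoint regulatory units tiling each chromosome."""
    out = []
    for chrom, length in genome.chroms:
        edges = np.linspace(0, length, config.units_per_chrom + 1).astype(np.int64)
        for k in range(config.units_per_chrom):
            out.append(GenomicInterval(chrom, int(edges[k]), int(edges[k + 1])))
    return Track("units", out)


def make_ase_records(
    config: SimulationConfig, units: Track, tissues: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue allelic read counts at heterozygous exonic positions.

    Per (unit, tissue): delta_u ~ Normal(0, sigma_unit) on the log-odds
    scale; per SNP: depth ~ NegBin(mean, dispersion), paternal ~
    Binomial(depth, logistic(delta_u)).  Returns (records, truth) where
    truth carries the drawn delta per unit and tissue.
    """
    rng = config.rng(4)
    tissues = tissues or [f"tissue{t + 1}" for t in range(config.n_tissues)]
    mu, r = config.read_depth_mean, config.read_depth_dispersion
    nb_p = r / (r + mu)
    rows, truth = [], []
    for tissue in tissues:
        for u, iv in enumerate(units.intervals):
            delta = float(rng.normal(0.0, config.sigma_unit))
            truth.append((tissue, u, iv.chrom, iv.start, iv.end, delta))
            pos = np.sort(rng.integers(iv.start, iv.end, size=config.snps_per_unit))
            depth = rng.negative_binomial(r, nb_p, size=config.snps_per_unit)
            pat = rng.binomial(depth, expit(delta))
            for x, d, p in zip(pos, depth, pat):
                rows.append((iv.chrom, int(x), tissue, int(p), int(d - p)))
    records = pd.DataFrame(rows, columns=["chrom", "pos", "tissue", "paternal", "maternal"])
    truth_df = pd.DataFrame(
        truth, columns=["tissue", "unit_index", "chrom", "start", "end", "delta"]
    )
    return records, truth_df


def _place_outside(rng, length: int, avoid: tuple[int, int], width_hint: int = 0) -> int:
    """A position on [0, length) outside the avoided interval."""
    for _ in range(200):
        pos = int(rng.integers(0, length))
        if not avoid[0] <= pos < avoid[1]:
            return pos
    return 0 if avoid[0] > 0 else avoid[1]


def make_qtl_table(
    config: SimulationConfig, tads: Track, motifs: Track, genome: Genome
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """cis-QTL association tables for every (qtl_type, cell_type) combination.

    Genes are placed inside TADs; each gene receives a background of
    non-significant associations, and with probability
    ``frac_significant_genes`` one strictly most-significant QTL
    (P ~ 10^U(-12, -9)) placed inside the gene's TAD with probability
    ``frac_same_tad`` and snapped into a CTCF motif with probability
    ``frac_in_motif``.  Truth records realised placements.
    """
    rng = config.rng(5)
    tad_list = sorted(tads.intervals)
    if not tad_list:
        raise ValueError("need a non-empty TAD track to place genes")
    motif_by_chrom = motifs.flattened().by_chrom() if len(motifs) else {}
    genes = []
    for g in range(config.n_genes):
        tad = tad_list[int(rng.integers(len(tad_list)))]
        start = tad.start + int(rng.integers(0, max(tad.width - config.gene_width_bp, 1)))
        genes.append((f"gene{g}", tad, GenomicInterval(tad.chrom, start, start + config.gene_width_bp)))
    rows, truth = [], []
    for qtl_type in config.qtl_types:
        for cell_type in config.cell_types:
            for gene_id, tad, gene in genes:
                L = genome.length(gene.chrom)
                lo = max(gene.start - config.cis_window_bp, 0)
                hi = min(gene.end + config.cis_window_bp, L)
                n_bg = config.n_assoc_per_gene
                bg_pos = rng.integers(lo, hi, size=n_bg)
                bg_p = rng.uniform(1e-3, 1.0, size=n_bg)
                for x, p in zip(bg_pos, bg_p):
                    rows.append((qtl_type, cell_type, gene.chrom, int(x), gene_id,
                                 gene.chrom, gene.start, gene.end, float(p)))
                if rng.random() >= config.frac_significant_genes:
                    truth.append((qtl_type, cell_type, gene_id, False, None, None, None))
                    continue
                same_tad = rng.random() < config.frac_same_tad
                if same_tad:
                    pos = tad.start + int(rng.integers(0, tad.width))
                else:
                    pos = _place_outside(rng, L, (tad.start, tad.end))
                in_motif = False
                if rng.random() < config.frac_in_motif and gene.chrom in motif_by_chrom:
                    starts, ends = motif_by_chrom[gene.chrom]
                    if same_tad:
                        ok = (starts >= tad.start) & (ends <= tad.end)
                    else:
                        ok = (ends <= tad.start) | (starts >= tad.end)
                    cand = np.flatnonzero(ok)
                    if len(cand):
                        k = int(cand[int(rng.integers(len(cand)))])
                        pos = int(rng.integers(starts[k], ends[k]))
                        in_motif = True
                p_sig = 10.0 ** rng.uniform(-12.0, -9.0)
                rows.append((qtl_type, cell_type, gene.chrom, int(pos), gene_id,
                             gene.chrom, gene.start, gene.end, float(p_sig)))
                truth.append((qtl_type, cell_type, gene_id, True, same_tad, in_motif, int(pos)))
    assoc = pd.DataFrame(
        rows,
        columns=["qtl_type", "cell_type", "snp_chrom", "snp_pos", "egene_id",
                 "gene_chrom", "gene_start", "gene_end", "p_value"],
    )
    truth_df = pd.DataFrame(
        truth,
        columns=["qtl_type", "cell_type", "egene_id", "significant", "same_tad", "in_motif", "top_pos"],
    )
    return assoc, truth_df
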
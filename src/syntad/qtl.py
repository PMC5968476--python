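"""cis-QTL / eGene TAD colocalization: top-QTL selection, expected count, chi-square.

For every eGene the most significant passing cis-QTL is selected; when
several associations tie at the minimal P-value, the one linearly
furthest from the gene is chosen (distance from the SNP to the nearest
gene edge, 0 inside the gene; remaining ties broken by lower coordinate).
The observed count O is the number of eGenes whose selected QTL lies in a
TAD that the gene overlaps.  The expected count under independence is

    E = N * Mbar * p

with N the number of eGenes overlapping any TAD, Mbar the maximum number
of eSNPs tested on one chromosome, and p the significance threshold; the
departure is scored as chi2 = (E - O)^2 / E with a 1-df chi-square
P-value.  ``run_grid`` evaluates the full factorial of QTL type x cell
type x threshold x TAD set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomicInterval, Track

__all__ = [
    "QTL_SCHEMA",
    "ColocationTest",
    "top_qtl_per_gene",
    "observed_colocation",
    "expected_colocation",
    "chi_square_test",
    "genes_overlapping_tads",
    "max_esnps_per_chromosome",
    "run_grid",
]

QTL_SCHEMA = {
    "qtl_type": str,
    "cell_type": str,
    "snp_chrom": str,
    "snp_pos": int,
    "egene_id": str,
    "gene_chrom": str,
    "gene_start": int,
    "gene_end": int,
    "p_value": float,
}


@dataclass
class ColocationTest:
    qtl_type: str
    cell_type: str
    threshold: float
    tad_set: str
    n_genes_in_tad: int
    max_esnps: int
    expected: float
    observed: int
    chi2: float
    chi2_p: float


def _gene_distance(snp_pos: np.ndarray, gene_start: np.ndarray, gene_end: np.ndarray) -> np.ndarray:
    """Linear distance from SNP to the nearest gene edge; 0 inside the gene."""
    before = np.maximum(gene_start - snp_pos, 0)
    after = np.maximum(snp_pos - (gene_end - 1), 0)
    return np.maximum(before, after)


def top_qtl_per_gene(associations: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """One row per eGene: the most significant passing cis-QTL.

    Among associations at the minimal P-value, the linearly furthest SNP
    is kept; residual ties fall to the lowest (chrom, position).  eGenes
    without a passing association are excluded.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    passing = associations[associations["p_value"] <= p_threshold].copy()
    if passing.empty:
        return passing
    passing["_dist"] = _gene_distance(
        passing["snp_pos"].to_numpy(),
        passing["gene_start"].to_numpy(),
        passing["gene_end"].to_numpy(),
    )
    passing = passing.sort_values(
        ["egene_id", "p_value", "_dist", "snp_chrom", "snp_pos"],
        ascending=[True, True, False, True, True],
        kind="stable",
    )
    top = passing.groupby("egene_id", sort=True).head(1).drop(columns="_dist")
    return top.reset_index(drop=True)


def observed_colocation(top_qtls: pd.DataFrame, tads: Track) -> int:
    """Count eGenes whose selected QTL sits in a TAD overlapping the gene."""
    by_chrom = tads.by_chrom()
    count = 0
    for row in top_qtls.itertuples():
        if row.snp_chrom != row.gene_chrom or row.snp_chrom not in by_chrom:
            continue
        starts, ends = by_chrom[row.snp_chrom]
        # TADs containing the SNP position
        holds = (starts <= row.snp_pos) & (row.snp_pos < ends)
        # ... that overlap the gene by >= 1 bp
        overlaps = (starts < row.gene_end) & (ends > row.gene_start)
        if np.any(holds & overlaps):
            count += 1
    return count


def expected_colocation(n_genes: int, max_esnps: int, p: float) -> float:
    """E = N x Mbar x p."""
    if n_genes <= 0 or max_esnps <= 0 or p <= 0:
        raise ValueError("N, Mbar and p must all be positive")
    return n_genes * max_esnps * p


def chi_square_test(expected: float, observed: float) -> tuple[float, float]:
    """chi2 = (E - O)^2 / E with a 1-df chi-square P-value."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    chi2 = (expected - observed) ** 2 / expected
    return chi2, float(stats.chi2.sf(chi2, df=1))


def genes_overlapping_tads(associations: pd.DataFrame, tads: Track) -> int:
    """Number of distinct eGenes whose interval overlaps any TAD (>= 1 bp)."""
    genes = associations[["egene_id", "gene_chrom", "gene_start", "gene_end"]].drop_duplicates(
        "egene_id"
    )
    by_chrom = tads.by_chrom()
    n = 0
    for row in genes.itertuples():
        if row.gene_chrom not in by_chrom:
            continue
        starts, ends = by_chrom[row.gene_chrom]
        if np.any((starts < row.gene_end) & (ends > row.gene_start)):
            n += 1
    return n


def max_esnps_per_chromosome(associations: pd.DataFrame) -> int:
    """Mbar: the maximum number of distinct tested eSNP positions on one chromosome."""
    per = associations.drop_duplicates(["snp_chrom", "snp_pos"]).groupby("snp_chrom").size()
    return int(per.max()) if len(per) else 0


def run_grid(
    associations: pd.DataFrame,
    tad_sets: dict[str, Track],
    thresholds: tuple[float, ...] = (1e-5, 1e-6, 1e-7, 1e-8),
    expectation_p: float | None = None,
) -> pd.DataFrame:
    """Full factorial colocalization table.

    One chi-square test per (qtl_type, cell_type, threshold, TAD set)
    cell; paper-shaped input (2 x 2 x 4 x 6) yields 96 rows.  By default
    the threshold itself enters the expectation E = N*Mbar*p; pass
    ``expectation_p`` to decouple the two.
    """
    if associations.empty:
        warnings.warn("empty association table: no colocalization tests")
        return pd.DataFrame(
            columns=[
                "qtl_type", "cell_type", "threshold", "tad_set", "n_genes_in_tad",
                "max_esnps", "expected", "observed", "chi2", "chi2_p",
            ]
        )
    rows = []
    for (qtl_type, cell_type), sub in associations.groupby(["qtl_type", "cell_type"], sort=True):
        mbar = max_esnps_per_chromosome(sub)
        for threshold in thresholds:
            top = top_qtl_per_gene(sub, threshold)
            for set_id, tads in tad_sets.items():
                n_genes = genes_overlapping_tads(sub, tads)
                e = expected_colocation(n_genes, mbar, expectation_p or threshold)
                o = observed_colocation(top, tads)
                chi2, chi2_p = chi_square_test(e, o)
                rows.append(
                    {
                        "qtl_type": qtl_type,
                        "cell_type": cell_type,
                        "threshold": threshold,
                        "tad_set": set_id,
                        "n_genes_in_tad": n_genes,
                        "max_esnps": mbar,
                        "expected": e,
                        "observed": o,
                        "chi2": chi2,
                        "chi2_p": chi2_p,
                    }
                )
    return pd.DataFrame(rows)
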
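"""Allele-specific expression scoring, regulatory-unit ANOVA and permutation nulls.

Each heterozygous exonic position contributes a score
``Y = log10((P + 1) / (M + 1))`` from its paternal (P) and maternal (M)
read counts; the pseudocount keeps mono-allelic sites scorable.  Positive
scores favour the paternal allele.  Regulatory units are defined by TADs
(model 1), by CTCF gaps (model 2), or by their intersection cells
(model 3, gaps nested within TADs); units retain at least 5 scored SNPs.
A one-way ANOVA partitions score variance between and within units:

    SSB = sum_u n_u (ybar_u - ybar)^2      SSW = sum_u sum (y - ybar_u)^2
    R^2 = SSB / (SSB + SSW)                F = (SSB/(k-1)) / (SSW/(N-k))

The cohort-level null shuffles scores across all retained records and
refits; the cohort is significant when the observed R^2 exceeds every
shuffled value.  A unit displays significant ASE when its |mean score|
exceeds 99% of the shuffled per-unit |means| (FDR < 0.01) and a
one-sample t-test of its scores against zero gives P <= 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Track

__all__ = [
    "ase_score",
    "assign_units",
    "fit_anova",
    "permute_cohort",
    "unit_significance",
    "AnovaResult",
    "UnitAssignment",
    "CohortPermutation",
    "ASE_SCHEMA",
]

ASE_SCHEMA = {"chrom": str, "pos": int, "tissue": str, "paternal": int, "maternal": int}

MODELS = ("tad", "ctcf", "tad+ctcf")


def ase_score(paternal, maternal):
    """log10((P+1)/(M+1)); vectorised; counts must be non-negative."""
    p = np.asarray(paternal)
    m = np.asarray(maternal)
    if np.any(p < 0) or np.any(m < 0):
        raise ValueError("read counts must be non-negative")
    out = np.log10((p + 1.0) / (m + 1.0))
    return float(out) if out.ndim == 0 else out


def _locate(chrom: np.ndarray, pos: np.ndarray, track: Track) -> np.ndarray:
    """Index of the containing interval per record, -1 when outside.

    Intervals are taken in sorted order per chromosome; with disjoint
    regions the containing interval is unique.  A position inside a
    residual 1-bp overlap is assigned to the later-starting interval.
    """
    labels = np.full(len(pos), -1, dtype=np.int64)
    order = sorted(range(len(track.intervals)), key=lambda i: track.intervals[i])
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c in set(iv.chrom for iv in track.intervals):
        idx = [i for i in order if track.intervals[i].chrom == c]
        starts = np.array([track.intervals[i].start for i in idx], dtype=np.int64)
        ends = np.array([track.intervals[i].end for i in idx], dtype=np.int64)
        per_chrom[c] = (starts, ends, np.array(idx, dtype=np.int64))
    for c, (starts, ends, idx) in per_chrom.items():
        mask = chrom == c
        if not mask.any():
            continue
        p = pos[mask]
        k = np.searchsorted(starts, p, side="right") - 1
        ok = k >= 0
        safe = np.maximum(k, 0)
        ok &= p < ends[safe]
        res = np.where(ok, idx[safe], -1)
        labels[mask] = res
    return labels


@dataclass
class UnitAssignment:
    """Record -> regulatory-unit mapping for one cohort (one tissue)."""

    model: str
    unit_of: np.ndarray  # per-record unit label index, -1 = unassigned/dropped
    unit_names: list[str]

    @property
    def n_units(self) -> int:
        return len(self.unit_names)

    @property
    def retained(self) -> np.ndarray:
        return self.unit_of >= 0


def assign_units(
    records: pd.DataFrame,
    tads: Track | None = None,
    gaps: Track | None = None,
    model: str = "tad",
    min_snps: int = 5,
) -> UnitAssignment:
    """Assign each record to its regulatory unit under one model.

    Records outside every region are unassigned; units with fewer than
    ``min_snps`` scored records are dropped together with their records.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if model in ("tad", "tad+ctcf") and tads is None:
        raise ValueError("model requires a TAD track")
    if model in ("ctcf", "tad+ctcf") and gaps is None:
        raise ValueError("model requires a CTCF-gap track")
    chrom = records["chrom"].to_numpy(dtype=object)
    pos = records["pos"].to_numpy(dtype=np.int64)
    parts = []
    if model in ("tad", "tad+ctcf"):
        parts.append(("t", _locate(chrom, pos, tads)))
    if model in ("ctcf", "tad+ctcf"):
        parts.append(("g", _locate(chrom, pos, gaps)))
    inside = np.ones(len(pos), dtype=bool)
    for _, lab in parts:
        inside &= lab >= 0
    keys = np.where(
        inside,
        np.array(["|".join(f"{tag}{lab[i]}" for tag, lab in parts) for i in range(len(pos))], dtype=object),
        None,
    )
    # enforce the minimum-SNP rule per unit
    counts: dict[str, int] = {}
    for k in keys:
        if k is not None:
            counts[k] = counts.get(k, 0) + 1
    kept_names = sorted(k for k, c in counts.items() if c >= min_snps)
    name_index = {k: i for i, k in enumerate(kept_names)}
    unit_of = np.array([name_index.get(k, -1) if k is not None else -1 for k in keys], dtype=np.int64)
    return UnitAssignment(model, unit_of, kept_names)


@dataclass
class AnovaResult:
    model: str
    r_squared: float
    f_statistic: float
    p_value: float
    n_snps: int
    n_units: int
    unit_means: np.ndarray
    unit_counts: np.ndarray
    grand_mean: float


def fit_anova(scores: np.ndarray, assignment: UnitAssignment) -> AnovaResult:
    """One-way ANOVA of scores on the regulatory-unit factor."""
    y = np.asarray(scores, dtype=float)[assignment.retained]
    g = assignment.unit_of[assignment.retained]
    k = assignment.n_units
    n = len(y)
    if k < 2:
        raise ValueError("need at least 2 regulatory units")
    counts = np.bincount(g, minlength=k)
    sums = np.bincount(g, weights=y, minlength=k)
    means = sums / counts
    grand = y.mean()
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((y - means[g]) ** 2))
    sst = ssb + ssw
    if sst == 0:
        r2, f, p = 0.0, 0.0, 1.0
    else:
        r2 = ssb / sst
        if n == k:
            raise ValueError("degenerate ANOVA: one observation per unit")
        if ssw == 0:
            f, p = float("inf"), 0.0
        else:
            f = (ssb / (k - 1)) / (ssw / (n - k))
            p = float(stats.f.sf(f, k - 1, n - k))
    return AnovaResult(assignment.model, r2, f, p, n, k, means, counts, float(grand))


@dataclass
class CohortPermutation:
    """Shuffle null for one cohort: R^2 values and per-unit mean scores."""

    r2_null: np.ndarray  # (n_perm,)
    unit_means_null: np.ndarray  # (n_perm, n_units)
    observed: AnovaResult
    significant: bool  # observed R^2 larger than every shuffled R^2


def permute_cohort(
    scores: np.ndarray,
    assignment: UnitAssignment,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> CohortPermutation:
    """Genome-wide score shuffle null (unit assignments fixed)."""
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = fit_anova(scores, assignment)
    y = np.asarray(scores, dtype=float)[assignment.retained]
    g = assignment.unit_of[assignment.retained]
    k = assignment.n_units
    n = len(y)
    counts = np.bincount(g, minlength=k).astype(float)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_null = np.empty(n_perm)
    means_null = np.empty((n_perm, k))
    for it in range(n_perm):
        perm = rng.permutation(y)
        sums = np.bincount(g, weights=perm, minlength=k)
        means = sums / counts
        ssb = float(np.sum(counts * (means - perm.mean()) ** 2))
        r2_null[it] = 0.0 if sst == 0 else ssb / sst
        means_null[it] = means
    significant = observed.r_squared > float(r2_null.max())
    return CohortPermutation(r2_null, means_null, observed, significant)


def unit_significance(
    scores: np.ndarray,
    assignment: UnitAssignment,
    permutations: CohortPermutation,
    fdr_quantile: float = 0.99,
    t_threshold: float = 1e-6,
) -> pd.DataFrame:
    """Per-unit ASE calls within a significant cohort.

    A unit is called when |mean score| is larger than ``fdr_quantile`` of
    its shuffled |means| AND a one-sample t-test of its scores against 0
    gives P <= ``t_threshold``.
    """
    y = np.asarray(scores, dtype=float)[assignment.retained]
    g = assignment.unit_of[assignment.retained]
    abs_null = np.abs(permutations.unit_means_null)
    n_perm = abs_null.shape[0]
    rows = []
    for u, name in enumerate(assignment.unit_names):
        vals = y[g == u]
        obs = float(np.mean(vals))
        exceed = int(np.sum(abs_null[:, u] < abs(obs)))
        empirical = exceed >= int(np.ceil(fdr_quantile * n_perm))
        if np.allclose(vals, vals[0]):
            t_p = 0.0 if vals[0] != 0 else 1.0
        else:
            t_p = float(stats.ttest_1samp(vals, 0.0).pvalue)
        rows.append(
            {
                "unit": name,
                "n_snps": len(vals),
                "mean_score": obs,
                "empirical_pass": empirical,
                "t_pvalue": t_p,
                "significant": empirical and t_p <= t_threshold,
            }
        )
    return pd.DataFrame(rows)
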
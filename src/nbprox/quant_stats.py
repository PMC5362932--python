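"""Tabular statistics: grouped Spearman correlation, qPCR relative
quantification, dual-reporter normalization and promoter/peak interval
overlap.

These are the quantitative companions to the imaging pipeline: rank
correlation of two genes' expression across sample groups, relative
expression by the efficiency-corrected ddCq method with a
geometric-mean multi-reference normalizer, firefly/Renilla reporter
folds, and closed-interval arithmetic in promoter-relative coordinates
(TSS = 0).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "RelativeExpression",
    "GenomicInterval",
    "spearman",
    "correlate_groups",
    "qpcr_relative_quantity",
    "dual_reporter_fold",
    "interval_intersection",
    "interval_to_bed",
]

#: sample-size cutoff below which the Spearman p-value is computed by
#: exact permutation rather than the t approximation
EXACT_P_MAX_N = 10


@dataclass
class CorrelationResult:
    """Spearman correlation for one sample group.

    ``rho`` and/or ``p_value`` are NaN when undefined (fewer than the
    required samples, or a constant variable).
    """

    group: str
    gene_x: str
    gene_y: str
    n: int
    rho: float
    p_value: float


@dataclass
class RelativeExpression:
    gene: str
    condition: str
    fold_change: float
    fold_sd: float
    n_replicates: int


@dataclass(frozen=True)
class GenomicInterval:
    """Closed interval in promoter-relative coordinates (TSS = 0)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval {self.name}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-ranks (tie-aware Spearman rho)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = math.sqrt((sx ** 2).sum() * (sy ** 2).sum())
    if denom == 0:
        return math.nan
    return float((sx * sy).sum() / denom)


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p: enumerate all orderings of y's ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx - rx.mean()
    norm_x = math.sqrt((sx ** 2).sum())
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        sy = np.asarray(perm) - ry.mean()
        rho = (sx * sy).sum() / (norm_x * math.sqrt((sy ** 2).sum()))
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x, y, group: str = "", gene_x: str = "x", gene_y: str = "y") -> CorrelationResult:
    """Spearman rank correlation with a split p-value strategy.

    rho is the Pearson correlation of mid-ranks (handles ties).  The
    two-sided p-value is exact (full permutation enumeration) for
    ``3 <= n < 10`` and the classical t approximation for ``n >= 10``.
    ``n = 2`` with distinct values returns rho = +/-1 with an undefined
    (NaN) p; constant input or ``n < 2`` returns NaN for both.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1D, got {x.shape} vs {y.shape}")
    n = int(x.size)
    if n < 2:
        return CorrelationResult(group, gene_x, gene_y, n, math.nan, math.nan)
    rho = _spearman_rho(x, y)
    if math.isnan(rho) or n == 2:
        return CorrelationResult(group, gene_x, gene_y, n, rho, math.nan)
    if n < EXACT_P_MAX_N:
        p = _exact_permutation_p(x, y, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho ** 2))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(group, gene_x, gene_y, n, rho, float(min(p, 1.0)))


def correlate_groups(
    table: pd.DataFrame,
    gene_x: str,
    gene_y: str,
    group_col: str = "group",
    pooled_label: str = "All",
) -> list[CorrelationResult]:
    """Per-group Spearman correlation of two genes, plus a pooled row.

    ``table`` has one row per sample with a group-label column and one
    column per gene.  Samples missing either gene's value are dropped
    pairwise.  Groups with too few samples are reported with NaN
    rho/p rather than dropped, so the output mirrors the input's group
    structure.  The pooled row combines all groups.
    """
    for col in (group_col, gene_x, gene_y):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in expression table")
    results: list[CorrelationResult] = []

    def _one(label: str, sub: pd.DataFrame) -> CorrelationResult:
        cols = [gene_x] if gene_x == gene_y else [gene_x, gene_y]
        pair = sub[cols].dropna()
        return spearman(
            pair[gene_x].to_numpy(), pair[gene_y].to_numpy(),
            group=label, gene_x=gene_x, gene_y=gene_y,
        )

    results.append(_one(pooled_label, table))
    for label, sub in table.groupby(group_col, sort=True):
        results.append(_one(str(label), sub))
    return results


def correlations_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(r) for r in results],
        columns=["group", "gene_x", "gene_y", "n", "rho", "p_value"],
    )


def qpcr_relative_quantity(
    cq: pd.DataFrame,
    calibrator: str,
    reference_genes: list[str],
    efficiency: float | dict[str, float] = 2.0,
) -> list[RelativeExpression]:
    """Relative expression by efficiency-corrected ddCq.

    For gene *g* in condition *c*, the relative quantity is
    ``RQ_g(c) = E_g ** (mean Cq_g(calibrator) - mean Cq_g(c))``; the
    normalized fold change divides by the geometric mean of the
    reference genes' RQs in the same condition.  The calibrator
    condition's folds are 1 by construction.  Replicate dispersion is
    the standard deviation of per-replicate folds (replicate Cq against
    the calibrator mean, normalized by the condition-level reference
    factor).

    ``cq`` columns: condition, gene, replicate, cq.  Amplification
    efficiency defaults to 2.0 (perfect doubling) and may be a per-gene
    mapping.
    """
    required = {"condition", "gene", "cq"}
    if missing := required - set(cq.columns):
        raise ValueError(f"Cq table missing columns {sorted(missing)}")
    if not reference_genes:
        raise ValueError("at least one reference gene is required")
    if (cq["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")

    def eff(gene: str) -> float:
        e = efficiency.get(gene, 2.0) if isinstance(efficiency, dict) else efficiency
        if not 1.0 < e <= 2.2:
            raise ValueError(f"amplification efficiency {e} for {gene} outside (1, 2.2]")
        return float(e)

    conditions = list(dict.fromkeys(cq["condition"]))
    if calibrator not in conditions:
        raise ValueError(f"calibrator condition {calibrator!r} not in table")
    mean_cq = cq.groupby(["gene", "condition"])["cq"].mean()
    for ref in reference_genes:
        for cond in conditions:
            if (ref, cond) not in mean_cq.index:
                raise ValueError(f"reference gene {ref!r} missing in condition {cond!r}")

    def rq(gene: str, cond: str) -> float:
        return eff(gene) ** (mean_cq[(gene, calibrator)] - mean_cq[(gene, cond)])

    out: list[RelativeExpression] = []
    for gene in dict.fromkeys(cq["gene"]):
        for cond in conditions:
            if (gene, cond) not in mean_cq.index:
                continue
            norm = stats.gmean([rq(ref, cond) for ref in reference_genes])
            reps = cq[(cq["gene"] == gene) & (cq["condition"] == cond)]["cq"].to_numpy()
            rep_folds = eff(gene) ** (mean_cq[(gene, calibrator)] - reps) / norm
            out.append(
                RelativeExpression(
                    gene=str(gene),
                    condition=str(cond),
                    fold_change=float(rq(gene, cond) / norm),
                    fold_sd=float(rep_folds.std(ddof=1)) if reps.size > 1 else 0.0,
                    n_replicates=int(reps.size),
                )
            )
    return out


def dual_reporter_fold(
    measurements: pd.DataFrame,
    control: str,
) -> pd.DataFrame:
    """Promoter activity folds from a dual-luciferase assay.

    Each measurement's firefly signal is divided by its co-transfected
    Renilla signal (transfection-efficiency control); per-construct mean
    ratios are then expressed relative to the promoterless control,
    whose fold is 1 by construction.

    ``measurements`` columns: construct, firefly, renilla.
    """
    required = {"construct", "firefly", "renilla"}
    if missing := required - set(measurements.columns):
        raise ValueError(f"reporter table missing columns {sorted(missing)}")
    if (measurements["renilla"] <= 0).any():
        raise ValueError("renilla signal must be strictly positive")
    ratios = measurements.assign(
        ratio=measurements["firefly"] / measurements["renilla"]
    )
    per_construct = ratios.groupby("construct", sort=False)["ratio"].agg(["mean", "count"])
    if control not in per_construct.index:
        raise ValueError(f"control construct {control!r} not found")
    base = per_construct.loc[control, "mean"]
    out = per_construct.rename(columns={"count": "n"}).reset_index()
    out["fold"] = out["mean"] / base
    return out[["construct", "n", "fold"]]


def interval_intersection(
    a: GenomicInterval, b: GenomicInterval
) -> GenomicInterval | None:
    """Intersection of two closed intervals, or None when disjoint."""
    start = max(a.start, b.start)
    end = min(a.end, b.end)
    if start > end:
        return None
    return GenomicInterval(name=f"{a.name}&{b.name}", start=start, end=end)


def interval_to_bed(
    interval: GenomicInterval, chrom: str, tss_genomic: int
) -> tuple[str, int, int]:
    """Convert a closed TSS-relative interval to BED (0-based half-open)."""
    return chrom, tss_genomic + interval.start, tss_genomic + interval.end + 1
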
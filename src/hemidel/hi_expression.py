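"""Clonality-normalized haploinsufficient (HI) gene calling.

Bulk expression of a gene inside a hemizygous deletion scales with the
fraction ``f`` of deletion-bearing cells, so raw deleted-vs-diploid
comparisons are confounded by clonal size.  The procedure:

1. drop genes with very low expression in more than 10% of diploid
   samples;
2. restrict to genes lying in the high-frequency deleted span (deletion
   frequency strictly above 70% of deleted cases by default);
3. regress each gene's expression on deletion clonality across deleted
   samples (ordinary least squares) and extrapolate every deleted
   sample to 100% clonality: ``adjusted = value + slope * (1 - f)``;
   diploid values are left untouched;
4. call a gene HI at tier ``t`` when the adjusted expression is
   strictly below the diploid median in strictly more than ``t`` of the
   deleted samples (tiers 80/85/90/95; tier 100 requires all).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_TIERS = (0.80, 0.85, 0.90, 0.95, 1.00)
DELETED = "deleted"
DIPLOID = "diploid_NK"


class DegenerateDesignError(ValueError):
    """Clonality regression is undefined (all clonalities equal / too few)."""


@dataclass
class ExpressionMatrix:
    """Genes-by-samples normalized expression with karyotype labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol, columns = sample ids.
    sample_labels
        Series mapping each sample to ``"deleted"`` or ``"diploid_NK"``.
    clonality
        Series mapping every deleted sample to its deletion clonality.
    gene_annotation
        Optional frame with columns ``gene``, ``chrom``, ``start``,
        ``end`` (0-based half-open) for region restriction.
    scale
        ``"linear"`` or ``"log2"`` — the scale ``values`` are on.
    """

    values: pd.DataFrame
    sample_labels: pd.Series
    clonality: pd.Series
    gene_annotation: pd.DataFrame | None = None
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown expression scale {self.scale!r}")
        missing = set(self.values.columns) - set(self.sample_labels.index)
        if missing:
            raise ValueError(f"samples without karyotype label: {sorted(missing)[:5]}")
        bad = set(self.sample_labels.unique()) - {DELETED, DIPLOID}
        if bad:
            raise ValueError(f"unknown karyotype labels: {sorted(bad)}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        unclonal = set(self.deleted_samples) - set(self.clonality.index)
        if unclonal:
            raise ValueError(
                f"deleted samples without clonality: {sorted(unclonal)[:5]}"
            )

    @property
    def deleted_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.sample_labels[s] == DELETED]

    @property
    def diploid_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.sample_labels[s] == DIPLOID]

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2(x+1)-scale copy (identity if already log2)."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(
            values=np.log2(self.values + 1.0),
            sample_labels=self.sample_labels,
            clonality=self.clonality,
            gene_annotation=self.gene_annotation,
            scale="log2",
        )


@dataclass(frozen=True)
class HiGeneResult:
    """Per-gene outcome of the HI calling procedure."""

    gene: str
    slope: float
    intercept: float
    adjusted_values: pd.Series  # deleted samples only
    fraction_below: float
    deletion_frequency: float
    hi_tier: int | None  # 80/85/90/95/100, None = not HI at any tier


def filter_low_expression(
    matrix: ExpressionMatrix,
    floor: float = 1.0,
    max_low_fraction: float = 0.10,
) -> list[str]:
    """Genes retained after the low-expression filter.

    A gene is excluded when the share of *diploid* samples with
    expression at or below ``floor`` is strictly greater than
    ``max_low_fraction``.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    dip = matrix.values[matrix.diploid_samples]
    low_share = (dip <= floor).mean(axis=1)
    return list(matrix.values.index[~(low_share > max_low_fraction)])


def restrict_to_deleted_region(
    genes: Sequence[str],
    gene_deletion_frequency: Mapping[str, float] | pd.Series,
    min_del_freq: float = 0.70,
) -> list[str]:
    """Keep genes deleted in strictly more than ``min_del_freq`` of deleted cases."""
    freq = pd.Series(gene_deletion_frequency)
    return [g for g in genes if g in freq.index and freq[g] > min_del_freq]


def fit_and_adjust(
    values: pd.Series | np.ndarray,
    clonalities: pd.Series | np.ndarray,
) -> tuple[float, float, pd.Series]:
    """OLS of expression on clonality; extrapolate to 100% clonality.

    ``adjusted_i = value_i + slope * (1 - f_i)`` — a sample already at
    full clonality is unchanged, and with slope 0 the adjustment is the
    identity.

    Raises
    ------
    DegenerateDesignError
        With fewer than 3 deleted samples or all clonalities equal.
    """
    v = pd.Series(values, dtype=float)
    f = pd.Series(clonalities, dtype=float)
    if len(v) != len(f):
        raise ValueError("values and clonalities differ in length")
    if len(v) < 3:
        raise DegenerateDesignError("need >= 3 deleted samples to fit a slope")
    fa = f.to_numpy()
    if np.allclose(fa, fa[0]):
        raise DegenerateDesignError("all clonalities equal; slope undefined")
    slope, intercept = np.polyfit(fa, v.to_numpy(), 1)
    adjusted = v + slope * (1.0 - f.to_numpy())
    return float(slope), float(intercept), adjusted


def call_hi(
    adjusted_deleted: pd.Series | np.ndarray,
    diploid_values: pd.Series | np.ndarray,
    tiers: Sequence[float] = DEFAULT_TIERS,
) -> tuple[float, int | None]:
    """HI tier from the share of deleted samples below the diploid median.

    Strict comparisons throughout: a deleted sample counts when its
    adjusted value is strictly below the diploid median (50th
    percentile, linear interpolation), and tier ``t < 1`` is satisfied
    when the share is strictly greater than ``t``; tier 1.0 requires
    every deleted sample below the median.
    """
    adj = np.asarray(adjusted_deleted, dtype=float)
    dip = np.asarray(diploid_values, dtype=float)
    if adj.size == 0 or dip.size == 0:
        raise ValueError("need at least one deleted and one diploid sample")
    median = float(np.median(dip))
    fraction_below = float(np.mean(adj < median))
    tier: int | None = None
    for t in sorted(tiers):
        satisfied = fraction_below >= 1.0 if t >= 1.0 else fraction_below > t
        if satisfied:
            tier = round(t * 100)
    return fraction_below, tier


def hi_analysis(
    matrix: ExpressionMatrix,
    gene_deletion_frequency: Mapping[str, float] | pd.Series,
    floor: float = 1.0,
    max_low_fraction: float = 0.10,
    min_del_freq: float = 0.70,
    tiers: Sequence[float] = DEFAULT_TIERS,
    require_negative_slope: bool = False,
) -> list[HiGeneResult]:
    """Full HI calling flow over an expression matrix.

    ``require_negative_slope=True`` applies the clonality adjustment
    only when the fitted slope is negative; by default the fitted slope
    is used unconditionally regardless of sign or significance.
    """
    retained = filter_low_expression(matrix, floor, max_low_fraction)
    in_region = restrict_to_deleted_region(retained, gene_deletion_frequency, min_del_freq)
    freq = pd.Series(gene_deletion_frequency)
    deleted = matrix.deleted_samples
    diploid = matrix.diploid_samples
    f = matrix.clonality[deleted]
    results: list[HiGeneResult] = []
    for gene in in_region:
        row = matrix.values.loc[gene]
        slope, intercept, adjusted = fit_and_adjust(row[deleted], f)
        if require_negative_slope and slope >= 0:
            adjusted = row[deleted].astype(float)
        fraction_below, tier = call_hi(adjusted, row[diploid], tiers)
        results.append(
            HiGeneResult(
                gene=gene,
                slope=slope,
                intercept=intercept,
                adjusted_values=adjusted,
                fraction_below=fraction_below,
                deletion_frequency=float(freq[gene]),
                hi_tier=tier,
            )
        )
    return results


def hi_results_frame(results: Sequence[HiGeneResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "slope": [r.slope for r in results],
            "intercept": [r.intercept for r in results],
            "fraction_below": [r.fraction_below for r in results],
            "deletion_frequency": [r.deletion_frequency for r in results],
            "hi_tier": [0 if r.hi_tier is None else r.hi_tier for r in results],
        }
    )


def hi_gene_set(results: Sequence[HiGeneResult], tier: int = 80) -> list[str]:
    """Genes reaching at least the given tier (80 = the headline definition)."""
    return [r.gene for r in results if r.hi_tier is not None and r.hi_tier >= tier]
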
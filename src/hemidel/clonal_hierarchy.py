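"""Cancer-cell-fraction adjustment of VAFs and clonal hierarchy calls.

A bulk variant allele frequency is converted to a cancer cell fraction
(CCF) using zygosity and the local copy number:

* heterozygous, diploid region: one mutated copy out of two per cell,
  ``ccf = 2 * vaf``;
* hemizygous, deleted region: the mutation sits on the single retained
  allele of deletion-bearing cells, while the locus-average copy number
  in the bulk is ``2 - f`` (``f`` = deletion clonality), so
  ``ccf = vaf * (2 - f)``;
* homozygous: both copies mutated, ``ccf = vaf``.

The deletion is then placed in the clonal hierarchy relative to somatic
mutations with a 5% rule: a difference of at least 5 percentage points
between deletion clonality and mutation CCF separates dominant from
secondary; anything closer is co-dominant (not arithmetically
resolvable from bulk data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

#: difference below which deletion and mutation clone are indistinguishable
DEFAULT_CUTOFF = 0.05
#: clipping beyond this triggers a warning (sampling noise at modest depth)
CLIP_TOLERANCE = 0.02

Zygosity = Literal["heterozygous", "hemizygous", "homozygous"]
Consequence = Literal["LOF", "missense", "other"]
HierarchyLabel = Literal["deletion_dominant", "deletion_secondary", "co_dominant"]

ZYGOSITIES = ("heterozygous", "hemizygous", "homozygous")
CONSEQUENCES = ("LOF", "missense", "other")


class CcfClippedWarning(UserWarning):
    """Adjusted CCF fell outside [0, 1] by more than the tolerance."""


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant observed in bulk sequencing."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    vaf: float
    depth: int
    zygosity: Zygosity
    consequence: Consequence = "other"
    in_deleted_region: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"{self.sample_id}:{self.gene}: vaf must lie in [0, 1]")
        if self.depth < 0:
            raise ValueError(f"{self.sample_id}:{self.gene}: depth must be >= 0")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.zygosity == "hemizygous" and not self.in_deleted_region:
            raise ValueError(
                f"{self.sample_id}:{self.gene}: hemizygous variant must lie in a "
                "deleted region"
            )


@dataclass(frozen=True)
class HierarchyCall:
    sample_id: str
    variant: VariantCall
    ccf: float
    deletion_clonality: float
    label: HierarchyLabel
    margin: float  # ccf - deletion_clonality


def adjust_vaf(
    variant: VariantCall,
    deletion_clonality: float,
    clip_tolerance: float = CLIP_TOLERANCE,
) -> float:
    """Convert an observed VAF to a cancer cell fraction.

    Results outside [0, 1] are clipped; clipping by more than
    ``clip_tolerance`` emits a :class:`CcfClippedWarning`.

    Raises
    ------
    ValueError
        For zygosity/region combinations that have no consistent bulk
        interpretation (heterozygous or homozygous inside the deleted
        region — only the hemizygous configuration is possible there).
    """
    f = deletion_clonality
    if not 0.0 <= f <= 1.0:
        raise ValueError("deletion_clonality must lie in [0, 1]")
    if variant.zygosity == "heterozygous":
        if variant.in_deleted_region:
            raise ValueError(
                f"{variant.sample_id}:{variant.gene}: heterozygous call inside the "
                "deleted region is inconsistent (copy number there is not 2)"
            )
        ccf = 2.0 * variant.vaf
    elif variant.zygosity == "hemizygous":
        ccf = variant.vaf * (2.0 - f)
    else:  # homozygous
        if variant.in_deleted_region:
            raise ValueError(
                f"{variant.sample_id}:{variant.gene}: homozygous call inside the "
                "deleted region is inconsistent (only one allele is present)"
            )
        ccf = variant.vaf
    clipped = min(1.0, max(0.0, ccf))
    if abs(ccf - clipped) > clip_tolerance:
        warnings.warn(
            f"{variant.sample_id}:{variant.gene}: CCF {ccf:.3f} clipped to "
            f"{clipped:.3f}",
            CcfClippedWarning,
            stacklevel=2,
        )
    return clipped


def classify(
    ccf: float, deletion_clonality: float, cutoff: float = DEFAULT_CUTOFF
) -> HierarchyLabel:
    """Place the deletion relative to one mutation clone.

    ``|f - ccf| < cutoff`` → co-dominant; a difference of at least
    ``cutoff`` resolves the order (``f`` larger → deletion dominant).
    A 1e-12 guard keeps decimal inputs whose true difference equals the
    cutoff (e.g. 0.45 vs 0.40) on the resolved side despite binary
    rounding.
    """
    f = deletion_clonality
    if not 0.0 <= ccf <= 1.0 or not 0.0 <= f <= 1.0:
        raise ValueError("ccf and deletion_clonality must lie in [0, 1]")
    if abs(f - ccf) < cutoff - 1e-12:
        return "co_dominant"
    return "deletion_dominant" if f > ccf else "deletion_secondary"


def sample_hierarchy(
    variants: Iterable[VariantCall],
    deletion_clonality: float,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[list[HierarchyCall], str]:
    """Per-variant hierarchy calls plus a sample-level verdict.

    The verdict compares the deletion clonality against the *largest*
    mutation clone: ``deletion_dominant`` when the deletion exceeds
    every mutation by the cutoff, ``deletion_secondary`` when any
    mutation clone exceeds the deletion by the cutoff, ``co_dominant``
    otherwise.  An empty variant set yields ``deletion_only``.
    """
    calls: list[HierarchyCall] = []
    for v in variants:
        ccf = adjust_vaf(v, deletion_clonality)
        calls.append(
            HierarchyCall(
                sample_id=v.sample_id,
                variant=v,
                ccf=ccf,
                deletion_clonality=deletion_clonality,
                label=classify(ccf, deletion_clonality, cutoff),
                margin=ccf - deletion_clonality,
            )
        )
    if not calls:
        return [], "deletion_only"
    max_ccf = max(c.ccf for c in calls)
    return calls, classify(max_ccf, deletion_clonality, cutoff)


def hierarchy_table(calls: Sequence[HierarchyCall]):
    """Flatten hierarchy calls into a pandas DataFrame (for TSV output)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "gene": [c.variant.gene for c in calls],
            "chrom": [c.variant.chrom for c in calls],
            "pos": [c.variant.pos for c in calls],
            "vaf": [c.variant.vaf for c in calls],
            "zygosity": [c.variant.zygosity for c in calls],
            "ccf": [c.ccf for c in calls],
            "deletion_clonality": [c.deletion_clonality for c in calls],
            "margin": [c.margin for c in calls],
            "label": [c.label for c in calls],
        }
    )
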
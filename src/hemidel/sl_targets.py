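"""Three-criterion synthetic-lethal target filter for HI genes.

A haploinsufficient gene in the commonly deleted region is a candidate
synthetic-lethal target when

(i)   it is *not* already knocked out somewhere in the cohort — no
      hemizygous or homozygous loss-of-function mutation (a natural KO
      compatible with survival argues against lethality of inhibition);
(ii)  its knockout is embryonic/perinatally lethal in mice; or
(iii) its knockout/knockdown inhibits leukemia cell growth in
      CRISPR/shRNA dependency screens.

The default combination rule is (ii) OR (iii), gated by (i); the strict
conjunction of all three is available as rule ``all_three``.  Published
evidence gene lists for -7/del7q ship as presets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd

from .clonal_hierarchy import VariantCall

RULES = ("lethal_or_vulnerable", "all_three")

#: genes in the -7/del7q commonly deleted regions reported embryonic or
#: perinatally lethal in knockout mice (literature-curated).
KO_LETHAL_PUBLISHED: frozenset[str] = frozenset(
    {
        "ALKBH4", "CDK5", "CEP41", "COPS6", "CUL1", "CUX1", "DNAJC2", "EZH2",
        "KMT2C", "KRIT1", "SSBP1", "RINT1", "TRRAP", "WASL", "WDR91", "XRCC2",
    }
)

#: HI genes whose CRISPR or shRNA knockout significantly reduced AML
#: cell-line proliferation in genome-wide dependency screens.
SCREEN_VULNERABLE_PUBLISHED: frozenset[str] = frozenset(
    {
        "ATP6V1F", "BUD31", "COPS6", "CPSF4", "NUP205", "MCM7", "MEPCE",
        "NRF1", "POLR2J", "PMPCB", "PSMC2", "SRRT", "TAF6", "TNPO3", "TRRAP",
    }
)

#: genes with hemizygous/homozygous LOF mutations observed in -7/del7q
#: cohorts (natural knockouts compatible with survival).
LOF_AFFECTED_PUBLISHED: frozenset[str] = frozenset({"CUX1", "EZH2", "LUC7L2"})


class ConfigurationError(ValueError):
    """Unknown filtering rule or invalid dependency-table parameters."""


@dataclass(frozen=True)
class SlTargetRecord:
    gene: str
    is_hi: bool
    lof_affected: bool
    ko_lethal: bool
    crispr_vulnerable: bool
    shrna_vulnerable: bool
    is_candidate: bool

    @property
    def screen_vulnerable(self) -> bool:
        return self.crispr_vulnerable or self.shrna_vulnerable


@dataclass
class DependencyTable:
    """Dependency scores (lower = more essential), genes x cell lines."""

    scores: pd.DataFrame
    screen_type: str  # "CRISPR" or "shRNA"

    def __post_init__(self) -> None:
        if self.screen_type not in ("CRISPR", "shRNA"):
            raise ConfigurationError(f"unknown screen type {self.screen_type!r}")
        if self.scores.shape[1] < 1:
            raise ConfigurationError("dependency table needs >= 1 cell line")
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ConfigurationError("dependency scores must be finite")


def call_vulnerable(
    table: DependencyTable,
    score_cut: float = -0.5,
    min_fraction: float = 0.5,
) -> set[str]:
    """Genes essential in the screen: score below ``score_cut`` in at
    least ``min_fraction`` of cell lines.

    Genes absent from the table are simply not assayed (use
    :func:`assay_status` to distinguish them from non-vulnerable).
    """
    below = (table.scores < score_cut).mean(axis=1)
    return set(table.scores.index[below >= min_fraction])


def assay_status(genes: Iterable[str], table: DependencyTable) -> pd.Series:
    """Per-gene status: ``assayed`` or ``not_assayed`` in the screen."""
    idx = set(table.scores.index)
    genes = list(genes)
    return pd.Series(
        ["assayed" if g in idx else "not_assayed" for g in genes],
        index=genes,
        name=f"{table.screen_type}_status",
    )


def lof_affected_genes(variants: Iterable[VariantCall]) -> set[str]:
    """Genes with at least one hemizygous or homozygous LOF mutation."""
    return {
        v.gene
        for v in variants
        if v.consequence == "LOF" and v.zygosity in ("hemizygous", "homozygous")
    }


def filter_candidates(
    hi_genes: Iterable[str],
    lof_set: Set[str],
    lethal_set: Set[str],
    vulnerable_set: Set[str],
    rule: str = "lethal_or_vulnerable",
    crispr_set: Set[str] | None = None,
    shrna_set: Set[str] | None = None,
) -> list[SlTargetRecord]:
    """Apply the three-criterion filter to the HI gene set.

    ``vulnerable_set`` is the union of screen evidence; pass
    ``crispr_set``/``shrna_set`` as well to keep the per-screen flags in
    the records (otherwise both flags mirror the union).
    """
    if rule not in RULES:
        raise ConfigurationError(f"unknown rule {rule!r}; expected one of {RULES}")
    if crispr_set is not None or shrna_set is not None:
        crispr_set = set(crispr_set or ())
        shrna_set = set(shrna_set or ())
        vulnerable_set = set(vulnerable_set) | crispr_set | shrna_set
    records: list[SlTargetRecord] = []
    for gene in sorted(set(hi_genes)):
        lof = gene in lof_set
        lethal = gene in lethal_set
        vulnerable = gene in vulnerable_set
        if rule == "lethal_or_vulnerable":
            candidate = (not lof) and (lethal or vulnerable)
        else:  # all_three
            candidate = (not lof) and lethal and vulnerable
        records.append(
            SlTargetRecord(
                gene=gene,
                is_hi=True,
                lof_affected=lof,
                ko_lethal=lethal,
                crispr_vulnerable=(
                    gene in crispr_set if crispr_set is not None else vulnerable
                ),
                shrna_vulnerable=(
                    gene in shrna_set if shrna_set is not None else vulnerable
                ),
                is_candidate=candidate,
            )
        )
    return records


def candidates(records: Sequence[SlTargetRecord]) -> list[str]:
    return [r.gene for r in records if r.is_candidate]


def records_frame(records: Sequence[SlTargetRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "is_hi": [r.is_hi for r in records],
            "lof_affected": [r.lof_affected for r in records],
            "ko_lethal": [r.ko_lethal for r in records],
            "crispr_vulnerable": [r.crispr_vulnerable for r in records],
            "shrna_vulnerable": [r.shrna_vulnerable for r in records],
            "is_candidate": [r.is_candidate for r in records],
        }
    )


def published_worked_example() -> list[SlTargetRecord]:
    """The published -7/del7q evidence lists run through the default rule.

    HI universe = union of the KO-lethal and screen-vulnerable lists;
    yields the reported 27 candidates (29 unique evidence genes minus
    the LOF-affected CUX1 and EZH2).
    """
    hi = KO_LETHAL_PUBLISHED | SCREEN_VULNERABLE_PUBLISHED
    return filter_candidates(
        hi,
        LOF_AFFECTED_PUBLISHED,
        KO_LETHAL_PUBLISHED,
        SCREEN_VULNERABLE_PUBLISHED,
        rule="lethal_or_vulnerable",
    )
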
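"""Deletion clonality estimation and commonly-deleted-region (CDR) mapping.

Copy-number input is a set of pre-called segments per sample (SEG-style).
A segment is treated as a deletion when its mean log2 copy ratio falls
below a configurable cutoff.  Two quantities are derived cohort-wide:

* per-sample deletion clonality ``f`` — the fraction of cells carrying a
  one-copy loss, inverted from the mean log2 ratio ``r`` of the deletion
  via ``f = 2 * (1 - 2**r)`` (a bulk mixture of ``f`` one-copy cells and
  ``1 - f`` two-copy cells has ratio ``r = log2((2 - f) / 2)``);
* a stepwise deletion-frequency profile along a chromosome, from which
  maximal regions deleted in more than a stated fraction of the deleted
  samples (the CDRs) are extracted.

All intervals are 0-based half-open internally; SEG/BED conversions are
done at I/O boundaries (see :mod:`hemidel.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: log2-ratio below which a segment counts as a deletion.
DEFAULT_DELETION_CUTOFF = -0.1


class NoDeletionError(ValueError):
    """No deletion segment overlaps the requested target region."""


@dataclass(frozen=True)
class CnvSegment:
    """One copy-number segment for one sample (0-based half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    n_markers: int | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"segment {self.sample_id}:{self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if not math.isfinite(self.log2_ratio):
            raise ValueError(f"segment {self.sample_id}: log2_ratio must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start

    def is_deletion(self, cutoff: float = DEFAULT_DELETION_CUTOFF) -> bool:
        return self.log2_ratio < cutoff

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class ClonalityEstimate:
    sample_id: str
    clonality: float
    source_segments: tuple[CnvSegment, ...]
    method: str = "log2_ratio_inversion"

    def __post_init__(self) -> None:
        if not 0.0 <= self.clonality <= 1.0:
            raise ValueError("clonality must lie in [0, 1]")


@dataclass(frozen=True)
class CdrRegion:
    chrom: str
    start: int
    end: int
    deletion_frequency: float
    threshold: float
    genes: tuple[str, ...] = field(default_factory=tuple)


def clonality_from_log2_ratio(log2_ratio: float) -> float:
    """Invert the one-copy-loss mixture model: ``f = 2 * (1 - 2**r)``.

    Clipped to [0, 1]; positive ratios (gains) map to 0, ratios below -1
    (deeper than a clonal one-copy loss) map to 1.
    """
    return float(np.clip(2.0 * (1.0 - 2.0 ** log2_ratio), 0.0, 1.0))


def estimate_clonality(
    segments: Iterable[CnvSegment],
    chrom: str,
    start: int,
    end: int,
    deletion_cutoff: float = DEFAULT_DELETION_CUTOFF,
) -> ClonalityEstimate:
    """Estimate deletion clonality for one sample over a target region.

    Uses the overlap-length-weighted mean log2 ratio of all deletion
    segments intersecting ``[start, end)`` on ``chrom``.

    Raises
    ------
    NoDeletionError
        If no deletion segment overlaps the target region.
    """
    hits = [
        s
        for s in segments
        if s.chrom == chrom and s.is_deletion(deletion_cutoff) and s.overlap(start, end) > 0
    ]
    if not hits:
        raise NoDeletionError(f"no deletion in target region {chrom}:{start}-{end}")
    samples = {s.sample_id for s in hits}
    if len(samples) != 1:
        raise ValueError(f"segments from multiple samples passed: {sorted(samples)}")
    weights = np.array([s.overlap(start, end) for s in hits], dtype=float)
    ratios = np.array([s.log2_ratio for s in hits], dtype=float)
    mean_ratio = float(np.average(ratios, weights=weights))
    return ClonalityEstimate(
        sample_id=hits[0].sample_id,
        clonality=clonality_from_log2_ratio(mean_ratio),
        source_segments=tuple(hits),
    )


def cohort_clonality(
    segments: Iterable[CnvSegment],
    chrom: str,
    start: int,
    end: int,
    deletion_cutoff: float = DEFAULT_DELETION_CUTOFF,
) -> pd.Series:
    """Per-sample clonality over a target region, for samples with a deletion there.

    Samples without any overlapping deletion are omitted (they are not
    deleted cases for this region).
    """
    by_sample: dict[str, list[CnvSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    out: dict[str, float] = {}
    for sample_id in sorted(by_sample):
        try:
            est = estimate_clonality(by_sample[sample_id], chrom, start, end, deletion_cutoff)
        except NoDeletionError:
            continue
        out[sample_id] = est.clonality
    return pd.Series(out, name="clonality", dtype=float)


def _merged_deletion_intervals(
    segments: Sequence[CnvSegment],
    chrom: str,
    deletion_cutoff: float,
) -> dict[str, list[tuple[int, int]]]:
    """Per-sample union of deletion intervals on one chromosome."""
    per_sample: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        if seg.chrom == chrom and seg.is_deletion(deletion_cutoff):
            per_sample.setdefault(seg.sample_id, []).append((seg.start, seg.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for sample_id, ivals in per_sample.items():
        ivals.sort()
        acc: list[tuple[int, int]] = []
        for s, e in ivals:
            if acc and s <= acc[-1][1]:
                acc[-1] = (acc[-1][0], max(acc[-1][1], e))
            else:
                acc.append((s, e))
        merged[sample_id] = acc
    return merged


def deletion_frequency_profile(
    segments: Sequence[CnvSegment],
    chrom: str,
    deletion_cutoff: float = DEFAULT_DELETION_CUTOFF,
) -> pd.DataFrame:
    """Stepwise deletion frequency along ``chrom`` (sweep over breakpoints).

    The denominator is the number of *deleted* samples — samples carrying
    at least one deletion segment on the chromosome — not the whole
    cohort.  Returns a frame with columns ``start``, ``end``,
    ``frequency`` whose rows partition the covered span into elementary
    intervals delimited by segment breakpoints.  Empty input yields an
    empty frame.
    """
    merged = _merged_deletion_intervals(segments, chrom, deletion_cutoff)
    if not merged:
        return pd.DataFrame(columns=["start", "end", "frequency"])
    n_deleted = len(merged)
    breaks = sorted({b for ivals in merged.values() for s, e in ivals for b in (s, e)})
    starts, ends, freqs = [], [], []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        count = sum(
            any(s <= lo and hi <= e for s, e in ivals) for ivals in merged.values()
        )
        if count > 0:
            starts.append(lo)
            ends.append(hi)
            freqs.append(count / n_deleted)
    return pd.DataFrame({"start": starts, "end": ends, "frequency": freqs})


def extract_cdrs(
    profile: pd.DataFrame,
    threshold: float,
    chrom: str,
    genes: pd.DataFrame | None = None,
) -> list[CdrRegion]:
    """Maximal regions with deletion frequency strictly above ``threshold``.

    Adjacent elementary intervals exceeding the threshold are fused; a
    gap (or an interval at/below threshold) closes the region.  The
    region's reported frequency is the minimum over its members, i.e.
    the fraction of deleted samples deleting the *whole* region.  When a
    gene annotation frame (columns ``gene``, ``chrom``, ``start``,
    ``end``) is given, genes fully contained in a region are attached.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    regions: list[CdrRegion] = []
    cur: list[tuple[int, int, float]] = []

    def _flush() -> None:
        if not cur:
            return
        start, end = cur[0][0], cur[-1][1]
        freq = min(f for _, _, f in cur)
        contained: tuple[str, ...] = ()
        if genes is not None and len(genes):
            sel = genes[
                (genes["chrom"] == chrom)
                & (genes["start"] >= start)
                & (genes["end"] <= end)
            ]
            contained = tuple(sel["gene"])
        regions.append(CdrRegion(chrom, start, end, freq, threshold, contained))

    for row in profile.itertuples(index=False):
        if row.frequency > threshold:
            if cur and cur[-1][1] != row.start:  # gap between elementary intervals
                _flush()
                cur = []
            cur.append((int(row.start), int(row.end), float(row.frequency)))
        else:
            _flush()
            cur = []
    _flush()
    return regions


def gene_deletion_frequency(
    segments: Sequence[CnvSegment],
    genes: pd.DataFrame,
    deletion_cutoff: float = DEFAULT_DELETION_CUTOFF,
    chroms: Sequence[str] | None = None,
) -> pd.Series:
    """Fraction of deleted samples whose deletion fully covers each gene.

    The denominator for a gene on chromosome ``c`` is the number of
    samples with any deletion on ``c``.  Genes on chromosomes without
    any deleted sample get frequency 0.
    """
    freqs: dict[str, float] = {}
    wanted = set(chroms) if chroms is not None else set(genes["chrom"])
    for chrom in sorted(wanted):
        merged = _merged_deletion_intervals(segments, chrom, deletion_cutoff)
        sub = genes[genes["chrom"] == chrom]
        for row in sub.itertuples(index=False):
            if not merged:
                freqs[row.gene] = 0.0
                continue
            count = sum(
                any(s <= row.start and row.end <= e for s, e in ivals)
                for ivals in merged.values()
            )
            freqs[row.gene] = count / len(merged)
    return pd.Series(freqs, name="deletion_frequency", dtype=float)


def cdrs_to_frame(regions: Sequence[CdrRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "deletion_frequency": [r.deletion_frequency for r in regions],
            "threshold": [r.threshold for r in regions],
            "genes": [",".join(r.genes) for r in regions],
        }
    )
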
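"""Readers and writers for the plain-text formats the pipeline consumes.

Conventions
-----------
* SEG-like segment tables and variant tables are 1-based inclusive on
  disk; BED is 0-based half-open.  Internally everything is 0-based
  half-open, so SEG ``start`` is decremented on read and incremented on
  write; BED passes through.
* Chromosome names are normalized to the prefix-free form (``chr7`` ->
  ``7``) with a warning on first occurrence.
* All writers emit deterministic, diff-able TSV (fixed float format,
  stable row order).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .clonal_hierarchy import VariantCall
from .cnv_cdr import CdrRegion, CnvSegment, cdrs_to_frame
from .hi_expression import ExpressionMatrix
from .sl_targets import DependencyTable

FLOAT_FORMAT = "%.6g"


class MalformedFileError(ValueError):
    """A row of an input file does not match the expected dialect."""


def normalize_chrom(name: str, warn: bool = True) -> str:
    name = str(name).strip()
    if name.lower().startswith("chr"):
        if warn:
            warnings.warn(
                f"chromosome name {name!r} normalized to {name[3:]!r}",
                stacklevel=3,
            )
        return name[3:]
    return name


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "chromosome": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedFileError(f"{path}: missing column(s) {missing}")
    return df


def read_seg(path: str | Path) -> list[CnvSegment]:
    """Read a SEG-like TSV (sample, chrom, start, end, num_mark, seg_mean).

    Disk coordinates are 1-based inclusive; returned segments are
    0-based half-open.
    """
    df = _read_tsv(path, ["sample", "chrom", "start", "end", "seg_mean"])
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            segments.append(
                CnvSegment(
                    sample_id=str(row.sample),
                    chrom=normalize_chrom(row.chrom, warn=(i == 2)),
                    start=int(row.start) - 1,
                    end=int(row.end),
                    log2_ratio=float(row.seg_mean),
                    n_markers=int(row.num_mark) if hasattr(row, "num_mark") else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise MalformedFileError(f"{path}: line {i}: {exc}") from exc
    return segments


def write_seg(segments: Iterable[CnvSegment], path: str | Path) -> None:
    rows = [
        {
            "sample": s.sample_id,
            "chrom": s.chrom,
            "start": s.start + 1,
            "end": s.end,
            "num_mark": 0 if s.n_markers is None else s.n_markers,
            "seg_mean": s.log2_ratio,
        }
        for s in segments
    ]
    # 12 significant digits: clonality re-derived from disk agrees to ~1e-12
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_variants(path: str | Path) -> list[VariantCall]:
    """Read a MAF-lite variant TSV (1-based positions on disk)."""
    df = _read_tsv(
        path,
        ["sample", "gene", "chrom", "pos", "vaf", "depth", "zygosity", "consequence"],
    )
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                VariantCall(
                    sample_id=str(row.sample),
                    gene=str(row.gene),
                    chrom=normalize_chrom(row.chrom, warn=(i == 2)),
                    pos=int(row.pos) - 1,
                    vaf=float(row.vaf),
                    depth=int(row.depth),
                    zygosity=str(row.zygosity),
                    consequence=str(row.consequence),
                    in_deleted_region=bool(getattr(row, "in_deleted_region", False)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise MalformedFileError(f"{path}: line {i}: {exc}") from exc
    return out


def write_variants(variants: Iterable[VariantCall], path: str | Path) -> None:
    rows = [
        {
            "sample": v.sample_id,
            "gene": v.gene,
            "chrom": v.chrom,
            "pos": v.pos + 1,
            "vaf": v.vaf,
            "depth": v.depth,
            "zygosity": v.zygosity,
            "consequence": v.consequence,
            "in_deleted_region": int(v.in_deleted_region),
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED-like gene annotation (0-based half-open, passes through)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise MalformedFileError(f"{path}: line {i}: expected >= 4 BED columns")
            try:
                rows.append(
                    {
                        "gene": parts[3],
                        "chrom": normalize_chrom(parts[0], warn=(i == 1)),
                        "start": int(parts[1]),
                        "end": int(parts[2]),
                        "band": parts[4] if len(parts) > 4 else "",
                    }
                )
            except ValueError as exc:
                raise MalformedFileError(f"{path}: line {i}: {exc}") from exc
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "band"])


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            band = getattr(row, "band", "")
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene}\t{band}\n")


def read_expression(
    expr_path: str | Path,
    samples_path: str | Path,
    gene_bed: str | Path | None = None,
    scale: str = "linear",
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV plus a sample sheet.

    The sample sheet needs columns ``sample``, ``karyotype`` and
    ``clonality`` (clonality may be empty for diploid samples).
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    samples = _read_tsv(samples_path, ["sample", "karyotype"])
    labels = pd.Series(
        samples["karyotype"].to_numpy(), index=samples["sample"].astype(str), name="karyotype"
    )
    if "clonality" in samples.columns:
        clon = pd.Series(
            samples["clonality"].to_numpy(), index=samples["sample"].astype(str)
        ).dropna()
    else:
        clon = pd.Series(dtype=float)
    annotation = read_bed(gene_bed) if gene_bed is not None else None
    return ExpressionMatrix(
        values=values,
        sample_labels=labels,
        clonality=clon.astype(float),
        gene_annotation=annotation,
        scale=scale,
    )


def write_expression(
    matrix: ExpressionMatrix, expr_path: str | Path, samples_path: str | Path
) -> None:
    matrix.values.to_csv(expr_path, sep="\t", float_format="%.8g", index_label="gene")
    clon = matrix.clonality.reindex(matrix.values.columns)
    pd.DataFrame(
        {
            "sample": matrix.values.columns,
            "karyotype": matrix.sample_labels[matrix.values.columns].to_numpy(),
            "clonality": clon.to_numpy(),
        }
    ).to_csv(samples_path, sep="\t", index=False, float_format="%.8g")


def read_dependency(path: str | Path, screen_type: str) -> DependencyTable:
    scores = pd.read_csv(path, sep="\t", index_col=0)
    return DependencyTable(scores=scores, screen_type=screen_type)


def write_dependency(table: DependencyTable, path: str | Path) -> None:
    table.scores.to_csv(path, sep="\t", float_format="%.8g", index_label="gene")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and # comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_clonality(path: str | Path) -> pd.Series:
    df = _read_tsv(path, ["sample", "clonality"])
    return pd.Series(
        df["clonality"].to_numpy(), index=df["sample"].astype(str), name="clonality"
    ).astype(float)


def write_clonality(clonality: pd.Series, path: str | Path) -> None:
    pd.DataFrame(
        {"sample": clonality.index, "clonality": clonality.to_numpy()}
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_cdrs(regions: Sequence[CdrRegion], bed_path: str | Path, tsv_path: str | Path) -> None:
    """CDRs as BED (0-based half-open) plus a TSV with frequencies and genes."""
    with open(bed_path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tCDR_gt{int(r.threshold * 100)}\n")
    cdrs_to_frame(regions).to_csv(tsv_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
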
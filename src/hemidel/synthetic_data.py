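"""Synthetic -7/del7q cohort generator with full ground truth.

Emulates the study conditions of a bulk myeloid-neoplasm cohort: 49
samples carrying a chromosome-7 deletion and 120 diploid
normal-karyotype controls, with

* one deletion segment per deleted sample whose log2 ratio encodes the
  clonal fraction ``f`` via ``log2((2 - f) / 2)``; breakpoints are
  drawn so a configurable core interval is lost in >90% of deleted
  samples (monosomy and nested 7q deletions);
* a one-allele dosage model for expression: a gene covered by the
  deletion in a sample with clonality ``f`` has mean
  ``baseline * (1 - beta * f / 2)``; planted HI genes have dosage
  coefficient ``beta ~ N(1, dosage_slope_sd)``, compensated genes have
  ``beta = 0``; multiplicative Gaussian noise with coefficient of
  variation ``noise_cv``;
* somatic variants in designed cancer-cell-fraction strata relative to
  ``f`` (deletion-dominant, deletion-secondary, co-dominant, plus an
  exact 5%-boundary stratum); observed VAFs are binomially resampled
  at the configured depth; hemizygous/homozygous loss-of-function
  mutations are planted for the synthetic-lethal filter;
* dependency-score tables (CRISPR and shRNA) with planted essential
  genes, and a knockout-mouse lethality annotation;
* differentially expressed genes planted on other chromosomes with
  fold changes log-uniform between 2x and 8x.

Everything is keyed to a single seed; identical configs produce
bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clonal_hierarchy import VariantCall, classify
from .cnv_cdr import CnvSegment
from .hi_expression import DELETED, DIPLOID, ExpressionMatrix
from .sl_targets import DependencyTable

CHR7_LENGTH = 159_345_973


class CohortConfigError(ValueError):
    """A configuration field is out of its documented range."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_deleted: int = 49
    n_diploid: int = 120
    n_genes_chr7: int = 120
    n_genes_other: int = 80
    clonality_range: tuple[float, float] = (0.3, 1.0)
    dosage_slope_sd: float = 0.15
    noise_cv: float = 0.2
    depth: float = 500
    seed: int = 0
    # genome / deletion architecture
    core_start: int = 96_000_000
    core_end: int = 152_000_000
    core_coverage: float = 0.95  # share of deleted samples losing the whole core
    p_monosomy: float = 0.5
    core_gene_fraction: float = 0.7  # chr7 genes placed inside the core
    hi_fraction: float = 0.5  # core genes planted HI (dosage beta ~ N(1, sd))
    # clonal hierarchy strata (sample-level)
    p_dominant: float = 0.45
    p_secondary: float = 0.45
    p_codominant: float = 0.10
    # planted downstream effects
    n_de_up: int = 10
    n_de_down: int = 10
    de_log2fold_range: tuple[float, float] = (1.0, 3.0)
    n_lof_genes: int = 3
    n_essential_crispr: int = 8
    n_essential_shrna: int = 6
    n_cell_lines_crispr: int = 26
    n_cell_lines_shrna: int = 32
    n_ko_lethal: int = 10
    expression_scale: str = "linear"

    def validate(self) -> None:
        for name in ("n_deleted", "n_diploid"):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{name} must be >= 0")
        for name in ("n_genes_chr7", "n_genes_other"):
            if getattr(self, name) <= 0:
                raise CohortConfigError(f"{name} must be positive")
        lo, hi = self.clonality_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise CohortConfigError("clonality_range must be an interval within [0, 1]")
        if self.noise_cv < 0:
            raise CohortConfigError("noise_cv must be >= 0")
        if self.dosage_slope_sd < 0:
            raise CohortConfigError("dosage_slope_sd must be >= 0")
        if not (self.depth > 0):
            raise CohortConfigError("depth must be positive (math.inf = exact VAFs)")
        if not (0 <= self.core_start < self.core_end <= CHR7_LENGTH):
            raise CohortConfigError("core_start/core_end must define an interval on chr7")
        for name in ("core_coverage", "p_monosomy", "core_gene_fraction", "hi_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise CohortConfigError(f"{name} must lie in [0, 1]")
        p = self.p_dominant + self.p_secondary + self.p_codominant
        if not math.isclose(p, 1.0, abs_tol=1e-9):
            raise CohortConfigError("p_dominant + p_secondary + p_codominant must be 1")
        if self.expression_scale not in ("linear", "log2"):
            raise CohortConfigError("expression_scale must be 'linear' or 'log2'")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    clonality: dict[str, float] = field(default_factory=dict)
    deleted_interval: dict[str, tuple[int, int]] = field(default_factory=dict)
    hi_genes: list[str] = field(default_factory=list)
    dosage_slope: dict[str, float] = field(default_factory=dict)  # d expr / d f
    dosage_beta: dict[str, float] = field(default_factory=dict)
    baseline: dict[str, float] = field(default_factory=dict)
    variants: list[dict] = field(default_factory=list)
    sample_hierarchy: dict[str, str] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)  # true log2 fold
    lof_genes: dict[str, str] = field(default_factory=dict)  # gene -> zygosity
    essential_crispr: list[str] = field(default_factory=list)
    essential_shrna: list[str] = field(default_factory=list)
    ko_lethal: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        raw["deleted_interval"] = {k: tuple(v) for k, v in raw["deleted_interval"].items()}
        return cls(**raw)


@dataclass
class SyntheticCohort:
    config: CohortConfig
    segments: list[CnvSegment]
    expression: ExpressionMatrix
    variants: list[VariantCall]
    dependency: dict[str, DependencyTable]
    gene_annotation: pd.DataFrame
    ko_lethal: pd.DataFrame
    ground_truth: GroundTruth


def _gene_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic gene placement: core 7q genes, 7p genes, off-chr7 genes."""
    gene_len = 50_000
    n_core = max(1, round(config.n_genes_chr7 * config.core_gene_fraction))
    n_parm = config.n_genes_chr7 - n_core
    rows = []
    span = config.core_end - config.core_start - gene_len
    for i in range(n_core):
        start = config.core_start + 1_000_000 + (i * span) // max(n_core, 1)
        rows.append((f"C7Q{i:03d}", "7", start, start + gene_len, "7q-core"))
    for i in range(n_parm):
        start = 10_000_000 + (i * 45_000_000) // max(n_parm, 1)
        rows.append((f"C7P{i:03d}", "7", start, start + gene_len, "7p"))
    for i in range(config.n_genes_other):
        start = 10_000_000 + (i * 180_000_000) // config.n_genes_other
        rows.append((f"OG{i:03d}", "1", start, start + gene_len, "1q"))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "band"])


def _draw_deletion(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """One deleted interval per sample; covers the core with prob core_coverage."""
    covers_core = rng.random() < config.core_coverage
    if covers_core and rng.random() < config.p_monosomy:
        return 0, CHR7_LENGTH  # monosomy 7
    if covers_core:
        start = int(rng.uniform(60_000_000, config.core_start))
        end = int(rng.uniform(config.core_end, CHR7_LENGTH))
        return start, end
    # partial: breakpoint inside the core (proximal part retained)
    core_span = config.core_end - config.core_start
    start = int(config.core_start + rng.uniform(0.2, 0.6) * core_span)
    return start, CHR7_LENGTH


def _covered(interval: tuple[int, int], start: int, end: int) -> bool:
    return interval[0] <= start and end <= interval[1]


def _noisy(mean: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return mean.copy()
    factor = np.maximum(1.0 + cv * rng.standard_normal(mean.shape), 0.01)
    return mean * factor


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort (segments, expression, variants, screens, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    genes = _gene_table(config, rng)

    deleted_samples = [f"D{i:03d}" for i in range(config.n_deleted)]
    diploid_samples = [f"N{i:03d}" for i in range(config.n_diploid)]

    # --- deletion segments and clonalities -------------------------------
    lo, hi = config.clonality_range
    segments: list[CnvSegment] = []
    for s in deleted_samples:
        f = float(rng.uniform(lo, hi))
        start, end = _draw_deletion(config, rng)
        truth.clonality[s] = f
        truth.deleted_interval[s] = (start, end)
        segments.append(
            CnvSegment(
                sample_id=s,
                chrom="7",
                start=start,
                end=end,
                log2_ratio=float(np.log2((2.0 - f) / 2.0)),
                n_markers=max(10, (end - start) // 100_000),
            )
        )

    # --- per-gene generative parameters ----------------------------------
    baselines = pd.Series(rng.uniform(5.0, 50.0, size=len(genes)), index=genes["gene"])
    beta = pd.Series(0.0, index=genes["gene"])
    core_genes = [g for g in genes["gene"] if g.startswith("C7Q")]
    parm_genes = [g for g in genes["gene"] if g.startswith("C7P")]
    other_genes = [g for g in genes["gene"] if g.startswith("OG")]
    n_hi = round(len(core_genes) * config.hi_fraction)
    hi_genes = core_genes[:n_hi]
    for g in hi_genes:
        beta[g] = float(np.clip(rng.normal(1.0, config.dosage_slope_sd), 0.3, 1.7))
    # some 7p genes also dose-respond when deleted (monosomy cases), but are
    # outside the high-frequency region and must not be called HI
    for g in parm_genes[: len(parm_genes) // 2]:
        beta[g] = float(np.clip(rng.normal(1.0, config.dosage_slope_sd), 0.3, 1.7))
    # a gene can only manifest as HI when deleted samples exist
    truth.hi_genes = list(hi_genes) if config.n_deleted > 0 else []
    truth.dosage_beta = {g: float(beta[g]) for g in genes["gene"]}
    truth.baseline = {g: float(baselines[g]) for g in genes["gene"]}
    truth.dosage_slope = {
        g: float(-baselines[g] * beta[g] / 2.0) for g in genes["gene"]
    }

    # planted differential expression on other chromosomes
    de_pool = other_genes[-(config.n_de_up + config.n_de_down):] if (
        config.n_de_up + config.n_de_down
    ) else []
    fold = pd.Series(1.0, index=genes["gene"])
    lo_fc, hi_fc = config.de_log2fold_range
    for i, g in enumerate(de_pool):
        lfc = float(rng.uniform(lo_fc, hi_fc))
        if i >= config.n_de_up:
            lfc = -lfc
        fold[g] = 2.0 ** lfc
        truth.de_genes[g] = lfc

    # --- expression matrix ------------------------------------------------
    gene_pos = genes.set_index("gene")
    all_samples = deleted_samples + diploid_samples
    mean = pd.DataFrame(
        np.tile(baselines.to_numpy()[:, None], (1, len(all_samples))),
        index=genes["gene"],
        columns=all_samples,
    )
    for s in deleted_samples:
        f = truth.clonality[s]
        interval = truth.deleted_interval[s]
        on7 = gene_pos["chrom"] == "7"
        covered = on7 & (gene_pos["start"] >= interval[0]) & (gene_pos["end"] <= interval[1])
        dose = 1.0 - beta[covered[covered].index] * f / 2.0
        mean.loc[covered[covered].index, s] *= dose
        mean.loc[de_pool, s] *= fold[de_pool].to_numpy()
    values = pd.DataFrame(
        _noisy(mean.to_numpy(), config.noise_cv, rng),
        index=mean.index,
        columns=mean.columns,
    )
    scale = "linear"
    if config.expression_scale == "log2":
        values = np.log2(values + 1.0)
        scale = "log2"
    labels = pd.Series(
        [DELETED] * len(deleted_samples) + [DIPLOID] * len(diploid_samples),
        index=all_samples,
        name="karyotype",
    )
    expression = ExpressionMatrix(
        values=values,
        sample_labels=labels,
        clonality=pd.Series(truth.clonality, dtype=float),
        gene_annotation=genes,
        scale=scale,
    )

    # --- somatic variants in designed CCF strata --------------------------
    variants: list[VariantCall] = []

    def _observe(true_vaf: float) -> tuple[float, int]:
        if math.isinf(config.depth):
            return true_vaf, 10**9
        n = int(config.depth)
        return float(rng.binomial(n, true_vaf)) / n, n

    def _add_het(sample: str, gene: str, true_ccf: float, consequence: str = "other") -> None:
        true_vaf = true_ccf / 2.0
        vaf, depth = _observe(true_vaf)
        pos = int(gene_pos.loc[gene, "start"]) + 100
        variants.append(
            VariantCall(
                sample_id=sample,
                gene=gene,
                chrom=str(gene_pos.loc[gene, "chrom"]),
                pos=pos,
                vaf=vaf,
                depth=depth,
                zygosity="heterozygous",
                consequence=consequence,
                in_deleted_region=False,
            )
        )
        truth.variants.append(
            {
                "sample_id": sample,
                "gene": gene,
                "pos": pos,
                "true_ccf": true_ccf,
                "true_vaf": true_vaf,
                "zygosity": "heterozygous",
                "label": classify(true_ccf, truth.clonality.get(sample, 0.0)),
            }
        )

    lof_genes = core_genes[-config.n_lof_genes:] if config.n_lof_genes else []
    strata = np.array([config.p_dominant, config.p_secondary, config.p_codominant])
    het_pool = [g for g in other_genes if g not in de_pool] or other_genes
    for si, s in enumerate(deleted_samples):
        f = truth.clonality[s]
        kind = ["dominant", "secondary", "codominant"][rng.choice(3, p=strata)]
        if kind == "secondary" and f > 0.86:
            kind = "dominant"  # no headroom for a larger mutation clone
        g_main = het_pool[si % len(het_pool)]
        g_second = het_pool[(si + 7) % len(het_pool)]
        if g_second == g_main:
            g_second = het_pool[(si + 1) % len(het_pool)]
        if kind == "dominant":
            ccf_main = max(0.05, f - float(rng.uniform(0.12, 0.25)))
        elif kind == "secondary":
            ccf_main = min(0.98, f + float(rng.uniform(0.12, 0.25)))
        else:
            ccf_main = f
        _add_het(s, g_main, ccf_main)
        if g_second != g_main:
            _add_het(s, g_second, ccf_main * float(rng.uniform(0.4, 0.7)))
        if kind == "secondary":
            # exact 5%-boundary stratum, never the sample's largest clone;
            # nudge by ulps so the represented difference is not < 0.05
            ccf_b = max(f - 0.05, 0.0)
            while abs(f - ccf_b) < 0.05:
                ccf_b = math.nextafter(ccf_b, -1.0)
            _add_het(s, het_pool[(si + 13) % len(het_pool)], ccf_b)

    # planted hemizygous LOF mutations inside the deleted region
    for gi, gene in enumerate(lof_genes):
        truth.lof_genes[gene] = "hemizygous"
        carriers = deleted_samples[gi::max(1, config.n_deleted // 2)][:2]
        for s in carriers:
            f = truth.clonality[s]
            if not _covered(truth.deleted_interval[s], int(gene_pos.loc[gene, "start"]),
                            int(gene_pos.loc[gene, "end"])):
                continue
            true_ccf = f * float(rng.uniform(0.5, 0.65))
            true_vaf = true_ccf / (2.0 - f)
            vaf, depth = _observe(true_vaf)
            pos = int(gene_pos.loc[gene, "start"]) + 100
            variants.append(
                VariantCall(
                    sample_id=s, gene=gene, chrom="7", pos=pos, vaf=vaf,
                    depth=depth, zygosity="hemizygous", consequence="LOF",
                    in_deleted_region=True,
                )
            )
            truth.variants.append(
                {
                    "sample_id": s, "gene": gene, "pos": pos,
                    "true_ccf": true_ccf, "true_vaf": true_vaf,
                    "zygosity": "hemizygous", "label": classify(true_ccf, f),
                }
            )
    # one homozygous LOF gene carried by diploid samples (natural knockout)
    if config.n_lof_genes and diploid_samples and other_genes:
        gene = het_pool[0]
        truth.lof_genes[gene] = "homozygous"
        for s in diploid_samples[:2]:
            true_ccf = float(rng.uniform(0.3, 0.5))
            vaf, depth = _observe(true_ccf)
            pos = int(gene_pos.loc[gene, "start"]) + 200
            variants.append(
                VariantCall(
                    sample_id=s, gene=gene, chrom=str(gene_pos.loc[gene, "chrom"]),
                    pos=pos, vaf=vaf, depth=depth, zygosity="homozygous",
                    consequence="LOF", in_deleted_region=False,
                )
            )
            truth.variants.append(
                {
                    "sample_id": s, "gene": gene, "pos": pos,
                    "true_ccf": true_ccf, "true_vaf": true_ccf,
                    "zygosity": "homozygous", "label": "diploid_sample",
                }
            )

    # sample-level hierarchy truth from the realized true CCFs
    ccf_by_sample: dict[str, list[float]] = {}
    for rec in truth.variants:
        if rec["sample_id"] in truth.clonality:
            ccf_by_sample.setdefault(rec["sample_id"], []).append(rec["true_ccf"])
    for s in deleted_samples:
        if s not in ccf_by_sample:
            truth.sample_hierarchy[s] = "deletion_only"
        else:
            truth.sample_hierarchy[s] = classify(
                max(ccf_by_sample[s]), truth.clonality[s]
            )

    # --- dependency screens and KO-mouse lethality ------------------------
    dependency: dict[str, DependencyTable] = {}
    chr7_genes = core_genes + parm_genes
    ess_crispr = hi_genes[: config.n_essential_crispr]
    ess_shrna = hi_genes[
        config.n_essential_crispr // 2 : config.n_essential_crispr // 2
        + config.n_essential_shrna
    ]
    for screen, n_lines, essential in (
        ("CRISPR", config.n_cell_lines_crispr, ess_crispr),
        ("shRNA", config.n_cell_lines_shrna, ess_shrna),
    ):
        scores = pd.DataFrame(
            rng.normal(0.0, 0.15, size=(len(chr7_genes), n_lines)),
            index=chr7_genes,
            columns=[f"{screen}_line{j:02d}" for j in range(n_lines)],
        )
        scores.loc[list(essential)] = rng.normal(
            -1.0, 0.15, size=(len(essential), n_lines)
        )
        dependency[screen] = DependencyTable(scores=scores, screen_type=screen)
    truth.essential_crispr = list(ess_crispr)
    truth.essential_shrna = list(ess_shrna)

    # KO-mouse lethality: some essential HI genes plus some non-HI genes
    lethal = list(dict.fromkeys(ess_crispr[:4] + core_genes[n_hi : n_hi + config.n_ko_lethal - 4]))
    truth.ko_lethal = lethal
    ko_lethal = pd.DataFrame(
        {"gene": genes["gene"], "lethal": genes["gene"].isin(lethal).astype(int)}
    )

    return SyntheticCohort(
        config=config,
        segments=segments,
        expression=expression,
        variants=variants,
        dependency=dependency,
        gene_annotation=genes,
        ko_lethal=ko_lethal,
        ground_truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write all cohort tables as plain TSV/BED/JSON into ``outdir``."""
    from . import io as hio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "segments": out / "segments.seg.tsv",
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "variants": out / "variants.tsv",
        "genes": out / "genes.bed",
        "ko_lethal": out / "ko_lethal.tsv",
        "dependency_crispr": out / "dependency_crispr.tsv",
        "dependency_shrna": out / "dependency_shrna.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    hio.write_seg(cohort.segments, paths["segments"])
    hio.write_expression(cohort.expression, paths["expression"], paths["samples"])
    hio.write_variants(cohort.variants, paths["variants"])
    hio.write_bed(cohort.gene_annotation, paths["genes"])
    cohort.ko_lethal.to_csv(paths["ko_lethal"], sep="\t", index=False)
    hio.write_dependency(cohort.dependency["CRISPR"], paths["dependency_crispr"])
    hio.write_dependency(cohort.dependency["shRNA"], paths["dependency_shrna"])
    cohort.ground_truth.to_json(paths["ground_truth"])
    return paths
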
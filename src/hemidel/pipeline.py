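"""End-to-end pipeline: CDR -> hierarchy -> HI -> signature -> DGE -> targets.

Every stage writes plain-text, diff-able outputs into the configured
output directory; a manifest stamps each run with the config hash and
seed.  Reruns with an identical config produce byte-identical non-log
outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import io as hio
from .clonal_hierarchy import hierarchy_table, sample_hierarchy
from .cnv_cdr import (
    cohort_clonality,
    deletion_frequency_profile,
    extract_cdrs,
    gene_deletion_frequency,
)
from .config import PipelineConfig, setup_logging
from .dge import run_dge
from .hi_expression import hi_analysis, hi_gene_set, hi_results_frame
from .signature import cluster_and_score, minimal_signature
from .sl_targets import (
    call_vulnerable,
    candidates,
    filter_candidates,
    lof_affected_genes,
    records_frame,
)

#: chromosome span used when estimating whole-chromosome deletion clonality
WHOLE_CHROM_SPAN = (0, 500_000_000)


class PipelineError(RuntimeError):
    """A stage failed; the message names the failing stage."""


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order and return the report bundle (manifest)."""
    config.validate()
    log = setup_logging(config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "outputs": [],
    }

    def _record(path: Path) -> Path:
        manifest["outputs"].append(path.name)
        return path

    stage = "load_inputs"
    try:
        segments = hio.read_seg(config.seg)
        variants = hio.read_variants(config.variants)
        genes = hio.read_bed(config.genes)
        ko = pd.read_csv(config.ko_lethal, sep="\t")
        dep_crispr = hio.read_dependency(config.dependency_crispr, "CRISPR")
        dep_shrna = hio.read_dependency(config.dependency_shrna, "shRNA")

        stage = "cdr"
        clonality = cohort_clonality(
            segments, config.chrom, *WHOLE_CHROM_SPAN, config.deletion_cutoff
        )
        hio.write_clonality(clonality, _record(out / "clonality.tsv"))
        profile = deletion_frequency_profile(segments, config.chrom, config.deletion_cutoff)
        profile.to_csv(
            _record(out / "deletion_frequency_profile.tsv"),
            sep="\t", index=False, float_format="%.6g",
        )
        cdr_genes_by_threshold: dict[float, list[str]] = {}
        for t in config.cdr_thresholds:
            regions = extract_cdrs(profile, t, config.chrom, genes)
            tag = f"cdr_gt{int(round(t * 100))}"
            hio.write_cdrs(
                regions, _record(out / f"{tag}.bed"), _record(out / f"{tag}.tsv")
            )
            cdr_genes_by_threshold[t] = [g for r in regions for g in r.genes]
        log.info("cdr: %d deleted samples, %d thresholds", len(clonality),
                 len(config.cdr_thresholds))

        stage = "hierarchy"
        by_sample: dict[str, list] = {}
        for v in variants:
            by_sample.setdefault(v.sample_id, []).append(v)
        all_calls, verdicts = [], []
        for sample_id in clonality.index:
            calls, verdict = sample_hierarchy(
                by_sample.get(sample_id, []),
                float(clonality[sample_id]),
                config.hierarchy_cutoff,
            )
            all_calls.extend(calls)
            verdicts.append(
                {"sample": sample_id, "clonality": float(clonality[sample_id]),
                 "verdict": verdict}
            )
        hierarchy_table(all_calls).to_csv(
            _record(out / "hierarchy_variants.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )
        pd.DataFrame(verdicts).to_csv(
            _record(out / "hierarchy_samples.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )

        stage = "hi_call"
        matrix = hio.read_expression(
            config.expression, config.samples, config.genes, config.expression_scale
        )
        # clonality estimated from segments overrides the sample sheet
        matrix.clonality = clonality.combine_first(matrix.clonality)
        del_freq = gene_deletion_frequency(
            segments, genes, config.deletion_cutoff, chroms=[config.chrom]
        )
        hi_results = hi_analysis(
            matrix, del_freq,
            floor=config.low_expression_floor,
            max_low_fraction=config.max_low_fraction,
            min_del_freq=config.min_del_freq,
            tiers=config.hi_tiers,
        )
        hi_results_frame(hi_results).to_csv(
            _record(out / "hi_results.tsv"), sep="\t", index=False, float_format="%.6g"
        )
        hi80 = hi_gene_set(hi_results, 80)
        strict = hi_gene_set(hi_results, config.signature_tier)
        hio.write_gene_list(hi80, _record(out / "hi_genes_tier80.txt"))
        hio.write_gene_list(
            strict, _record(out / f"hi_genes_tier{config.signature_tier}.txt")
        )
        log.info("hi_call: %d genes at tier 80, %d at tier %d",
                 len(hi80), len(strict), config.signature_tier)

        stage = "signature"
        sig_genes = strict if len(strict) >= 2 else hi80
        if len(sig_genes) < 2:
            raise PipelineError("signature: fewer than 2 HI genes to cluster on")
        report = cluster_and_score(
            matrix.values.loc[sig_genes], matrix.sample_labels,
            linkage=config.linkage, metric=config.metric,
        )
        minimal = minimal_signature(
            sig_genes, matrix.values, matrix.sample_labels,
            max_size=config.max_signature_size,
            linkage=config.linkage, metric=config.metric,
        )
        report.assignments.rename("cluster").to_csv(
            _record(out / "signature_assignments.tsv"), sep="\t", index_label="sample"
        )
        (out / "signature_report.json").write_text(
            json.dumps(
                {"full": report.to_dict(), "minimal": minimal.to_dict()},
                indent=1, sort_keys=True,
            )
        )
        manifest["outputs"].append("signature_report.json")

        stage = "dge"
        cdr_genes = cdr_genes_by_threshold.get(
            config.min_del_freq, next(iter(cdr_genes_by_threshold.values()), [])
        )
        dge_results = run_dge(
            matrix, cdr_genes,
            floor=config.low_expression_floor,
            max_low_fraction=config.max_low_fraction,
            fc_cut=config.fc_cut,
            neglog_q_cut=config.neglog_q_cut,
        )
        dge_results.to_csv(
            _record(out / "dge_results.tsv"), sep="\t", index=False, float_format="%.6g"
        )
        up = dge_results.loc[dge_results["status"] == "up", "gene"]
        down = dge_results.loc[dge_results["status"] == "down", "gene"]
        hio.write_gene_list(up, _record(out / "dge_up.txt"))
        hio.write_gene_list(down, _record(out / "dge_down.txt"))

        stage = "sl_targets"
        lof = lof_affected_genes(variants)
        lethal = set(ko.loc[ko["lethal"].astype(int) == 1, "gene"])
        vuln_crispr = call_vulnerable(dep_crispr, config.dep_score_cut, config.dep_min_fraction)
        vuln_shrna = call_vulnerable(dep_shrna, config.dep_score_cut, config.dep_min_fraction)
        records = filter_candidates(
            hi80, lof, lethal, vuln_crispr | vuln_shrna,
            rule=config.sl_rule, crispr_set=vuln_crispr, shrna_set=vuln_shrna,
        )
        records_frame(records).to_csv(
            _record(out / "sl_targets.tsv"), sep="\t", index=False
        )
        manifest["n_candidates"] = len(candidates(records))
        manifest["candidates"] = candidates(records)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = sorted(set(manifest["outputs"]))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("run_all complete: %d outputs in %s", len(manifest["outputs"]), out)
    return manifest
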
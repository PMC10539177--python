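import math

import pytest

from hemidel import CohortConfig, PipelineConfig, simulate_cohort, write_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 49 deleted / 120 diploid, noise_cv 0.2."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """No expression noise, exact VAFs, homogeneous dosage slopes."""
    return simulate_cohort(
        CohortConfig(seed=2, noise_cv=0.0, depth=math.inf, dosage_slope_sd=0.0)
    )


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, default_cohort):
    d = tmp_path_factory.mktemp("cohort")
    write_cohort(default_cohort, d)
    return d


def pipeline_config(cohort_dir, outdir, **overrides) -> PipelineConfig:
    base = dict(
        seg=str(cohort_dir / "segments.seg.tsv"),
        variants=str(cohort_dir / "variants.tsv"),
        expression=str(cohort_dir / "expression.tsv"),
        samples=str(cohort_dir / "samples.tsv"),
        genes=str(cohort_dir / "genes.bed"),
        ko_lethal=str(cohort_dir / "ko_lethal.tsv"),
        dependency_crispr=str(cohort_dir / "dependency_crispr.tsv"),
        dependency_shrna=str(cohort_dir / "dependency_shrna.tsv"),
        outdir=str(outdir),
        seed=1,
    )
    base.update(overrides)
    return PipelineConfig(**base)
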
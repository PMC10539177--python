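"""Low-expression filtering, clonality adjustment and HI tier calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hemidel.cnv_cdr import gene_deletion_frequency
from hemidel.hi_expression import (
    DELETED,
    DIPLOID,
    DegenerateDesignError,
    ExpressionMatrix,
    call_hi,
    filter_low_expression,
    fit_and_adjust,
    hi_analysis,
    hi_gene_set,
    restrict_to_deleted_region,
)


def make_matrix(values: pd.DataFrame, n_deleted: int, clonality=None) -> ExpressionMatrix:
    samples = list(values.columns)
    labels = pd.Series(
        [DELETED] * n_deleted + [DIPLOID] * (len(samples) - n_deleted), index=samples
    )
    if clonality is None:
        clonality = pd.Series(0.8, index=samples[:n_deleted])
    return ExpressionMatrix(values=values, sample_labels=labels, clonality=clonality)


class TestLowExpressionFilter:
    def test_boundary_at_exactly_ten_percent(self):
        # 120 diploid samples; 12 at the floor is exactly 10% -> retained,
        # 13 (10.8%) -> excluded
        rows = {}
        for name, n_low in [("keep", 12), ("drop", 13)]:
            vals = np.full(120, 5.0)
            vals[:n_low] = 1.0
            rows[name] = vals
        matrix = make_matrix(pd.DataFrame(rows).T, n_deleted=0)
        retained = filter_low_expression(matrix, floor=1.0)
        assert retained == ["keep"]

    def test_half_zero_gene_excluded_and_clean_gene_kept(self):
        vals = pd.DataFrame(
            {f"N{i}": [0.0 if i < 5 else 8.0, 8.0] for i in range(10)},
            index=["half_zero", "clean"],
        )
        matrix = make_matrix(vals, n_deleted=0)
        assert filter_low_expression(matrix, floor=1.0) == ["clean"]


class TestRegionRestriction:
    def test_frequency_thresholds_are_strict(self):
        freq = pd.Series({"low": 0.57, "edge": 0.70, "core": 0.95})
        kept = restrict_to_deleted_region(["low", "edge", "core"], freq)
        assert kept == ["core"]

    def test_unknown_genes_are_dropped(self):
        assert restrict_to_deleted_region(["x"], pd.Series(dtype=float)) == []


class TestFitAndAdjust:
    def test_zero_slope_is_identity(self):
        f = pd.Series([0.3, 0.5, 0.9])
        v = pd.Series([7.0, 7.0, 7.0])
        slope, intercept, adjusted = fit_and_adjust(v, f)
        assert slope == pytest.approx(0.0, abs=1e-12)
        pd.testing.assert_series_equal(adjusted, v, check_dtype=False)

    def test_full_clonality_sample_unchanged_and_line_example(self):
        # values exactly on value = 12 - 4 f: at f = 0.5 the value is 10
        f = pd.Series([0.25, 0.5, 1.0])
        v = 12.0 - 4.0 * f
        slope, intercept, adjusted = fit_and_adjust(v, f)
        assert slope == pytest.approx(-4.0)
        assert intercept == pytest.approx(12.0)
        assert adjusted[1] == pytest.approx(8.0)  # 10 + (-4)(1 - 0.5)
        assert adjusted[2] == pytest.approx(v[2])  # already at 100% clonality

    def test_degenerate_designs_raise(self):
        with pytest.raises(DegenerateDesignError):
            fit_and_adjust([1.0, 2.0], [0.5, 0.6])
        with pytest.raises(DegenerateDesignError):
            fit_and_adjust([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])


class TestCallHi:
    def test_all_below_reaches_top_tier(self):
        frac, tier = call_hi([1.0, 1.0, 1.0], [5.0, 6.0, 7.0])
        assert (frac, tier) == (1.0, 100)

    def test_tier_arithmetic(self):
        # 81 of 100 below -> tier 80; 77 of 100 -> below every tier
        below, above = [0.0], [10.0]
        frac, tier = call_hi(below * 81 + above * 19, [5.0] * 4)
        assert frac == pytest.approx(0.81) and tier == 80
        frac, tier = call_hi(below * 77 + above * 23, [5.0] * 4)
        assert frac == pytest.approx(0.77) and tier is None

    def test_exactly_at_tier_is_not_enough(self):
        frac, tier = call_hi([0.0] * 80 + [10.0] * 20, [5.0] * 4)
        assert frac == pytest.approx(0.80) and tier is None

    def test_comparison_to_median_is_strict(self):
        frac, _ = call_hi([5.0, 4.0], [5.0, 5.0])
        assert frac == 0.5  # value equal to the median does not count

    def test_median_invariant_to_sample_order(self):
        rng = np.random.default_rng(0)
        dip = rng.normal(10, 2, 101)
        adj = rng.normal(8, 2, 49)
        assert call_hi(adj, dip) == call_hi(adj, rng.permutation(dip))


class TestAdjustmentNulling:
    def test_adjusted_slope_vanishes(self, default_cohort):
        """OLS extrapolation makes adjusted expression orthogonal to clonality."""
        matrix = default_cohort.expression
        deleted = matrix.deleted_samples
        f = matrix.clonality[deleted]
        gene = default_cohort.ground_truth.hi_genes[0]
        raw = matrix.values.loc[gene, deleted]
        slope, _, adjusted = fit_and_adjust(raw, f)
        refit = stats.linregress(f, adjusted)
        assert abs(refit.slope) < 1e-6 * (abs(slope) + 1)
        assert refit.pvalue > 0.05


class TestParameterRecovery:
    def test_hi_calls_recover_planted_truth(self, default_cohort):
        truth = default_cohort.ground_truth
        freq = gene_deletion_frequency(
            default_cohort.segments, default_cohort.gene_annotation, chroms=["7"]
        )
        results = hi_analysis(default_cohort.expression, freq)
        called = set(hi_gene_set(results, 80))
        planted = set(truth.hi_genes)
        tested = {r.gene for r in results}
        non_dosage = {g for g in tested if truth.dosage_beta[g] == 0}
        sens = len(called & planted) / len(planted & tested)
        false_pos = len(called & non_dosage) / len(non_dosage)
        assert sens >= 0.95
        assert false_pos <= 0.05

    def test_noise_degrades_tiers_in_expectation(self):
        from hemidel import CohortConfig, simulate_cohort

        def mean_strict_fraction(noise_cv: float) -> float:
            out = []
            for seed in range(3):
                c = simulate_cohort(
                    CohortConfig(
                        seed=seed, noise_cv=noise_cv, n_genes_chr7=60, n_genes_other=10
                    )
                )
                freq = gene_deletion_frequency(
                    c.segments, c.gene_annotation, chroms=["7"]
                )
                results = hi_analysis(c.expression, freq)
                strict = set(hi_gene_set(results, 95))
                planted = set(c.ground_truth.hi_genes)
                out.append(len(strict & planted) / len(planted))
            return float(np.mean(out))

        assert mean_strict_fraction(0.1) >= mean_strict_fraction(0.6)
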
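"""Clonality inversion, deletion-frequency sweep and CDR extraction."""

import math

import numpy as np
import pandas as pd
import pytest

from hemidel.cnv_cdr import (
    CnvSegment,
    NoDeletionError,
    clonality_from_log2_ratio,
    cohort_clonality,
    deletion_frequency_profile,
    estimate_clonality,
    extract_cdrs,
    gene_deletion_frequency,
)


def seg(sample, start, end, ratio, chrom="7"):
    return CnvSegment(sample_id=sample, chrom=chrom, start=start, end=end, log2_ratio=ratio)


class TestClonality:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (-1.0, 1.0),  # clonal one-copy loss
            (0.0, 0.0),  # copy-neutral
            (math.log2(0.75), 0.5),  # half the cells lost one copy
        ],
    )
    def test_log2_ratio_inversion(self, ratio, expected):
        assert clonality_from_log2_ratio(ratio) == pytest.approx(expected, abs=1e-12)

    def test_inversion_is_clipped(self):
        assert clonality_from_log2_ratio(0.5) == 0.0  # gain, not a deletion
        assert clonality_from_log2_ratio(-3.0) == 1.0  # deeper than one-copy loss

    def test_estimate_uses_length_weighted_mean(self):
        # 3/4 of the overlap at ratio r1, 1/4 at r2
        r1, r2 = -0.5, -1.0
        segs = [seg("s", 0, 300, r1), seg("s", 300, 400, r2)]
        est = estimate_clonality(segs, "7", 0, 400)
        expected = clonality_from_log2_ratio(0.75 * r1 + 0.25 * r2)
        assert est.clonality == pytest.approx(expected, abs=1e-12)

    def test_no_overlapping_deletion_raises(self):
        with pytest.raises(NoDeletionError, match="no deletion"):
            estimate_clonality([seg("s", 0, 100, 0.0)], "7", 0, 100)
        with pytest.raises(NoDeletionError):
            estimate_clonality([seg("s", 500, 600, -1.0)], "7", 0, 100)

    def test_round_trip_on_noise_free_segments(self, noise_free_cohort):
        truth = noise_free_cohort.ground_truth
        clon = cohort_clonality(noise_free_cohort.segments, "7", 0, 500_000_000)
        for sample, f in truth.clonality.items():
            assert clon[sample] == pytest.approx(f, abs=1e-9)


def brute_force_frequencies(segments, chrom, lo, hi):
    """Per-base deletion frequency by explicit counting (oracle)."""
    per_sample = {}
    for s in segments:
        if s.chrom == chrom and s.is_deletion():
            per_sample.setdefault(s.sample_id, []).append((s.start, s.end))
    if not per_sample:
        return np.zeros(hi - lo)
    counts = np.zeros(hi - lo)
    for ivals in per_sample.values():
        covered = np.zeros(hi - lo, dtype=bool)
        for a, b in ivals:
            covered[max(a - lo, 0) : max(b - lo, 0)] = True
        counts += covered
    return counts / len(per_sample)


class TestFrequencyProfile:
    def test_two_sample_worked_example(self):
        segs = [seg("a", 100, 200, -1.0), seg("b", 150, 250, -1.0)]
        profile = deletion_frequency_profile(segs, "7")
        expected = pd.DataFrame(
            {"start": [100, 150, 200], "end": [150, 200, 250], "frequency": [0.5, 1.0, 0.5]}
        )
        pd.testing.assert_frame_equal(profile, expected, check_dtype=False)

    def test_single_sample_and_identical_segments(self):
        profile = deletion_frequency_profile([seg("a", 10, 20, -1.0)], "7")
        assert profile.to_numpy().tolist() == [[10, 20, 1.0]]
        segs = [seg(s, 10, 20, -1.0) for s in "abc"]
        profile = deletion_frequency_profile(segs, "7")
        assert profile.to_numpy().tolist() == [[10, 20, 1.0]]

    def test_empty_input_gives_empty_profile(self):
        assert deletion_frequency_profile([], "7").empty

    def test_neutral_segments_are_ignored(self):
        segs = [seg("a", 0, 100, -1.0), seg("b", 0, 100, 0.0)]
        profile = deletion_frequency_profile(segs, "7")
        assert profile["frequency"].tolist() == [1.0]  # denominator = deleted samples

    def test_sweep_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            span = int(rng.integers(50, 500))
            segs = []
            for si in range(int(rng.integers(1, 8))):
                for _ in range(int(rng.integers(1, 4))):
                    a = int(rng.integers(0, span - 1))
                    b = int(rng.integers(a + 1, span + 1))
                    segs.append(seg(f"s{si}", a, b, -1.0))
            # per-sample segments may overlap; generator merges them
            profile = deletion_frequency_profile(segs, "7")
            oracle = brute_force_frequencies(segs, "7", 0, span)
            for row in profile.itertuples(index=False):
                np.testing.assert_allclose(
                    oracle[int(row.start) : int(row.end)], row.frequency
                )
            # bases outside profile intervals are uncovered
            covered = np.zeros(span, dtype=bool)
            for row in profile.itertuples(index=False):
                covered[int(row.start) : int(row.end)] = True
            assert np.all(oracle[~covered] == 0)


class TestCdrExtraction:
    @pytest.fixture()
    def profile(self):
        segs = [seg("a", 100, 200, -1.0), seg("b", 150, 250, -1.0)]
        return deletion_frequency_profile(segs, "7")

    def test_threshold_selects_only_high_frequency_core(self, profile):
        regions = extract_cdrs(profile, 0.7, "7")
        assert [(r.start, r.end) for r in regions] == [(150, 200)]
        assert regions[0].deletion_frequency == 1.0

    def test_threshold_is_strict(self, profile):
        assert extract_cdrs(profile, 1.0, "7") == []
        # frequency 0.5 intervals are excluded at exactly 0.5
        assert [(r.start, r.end) for r in extract_cdrs(profile, 0.5, "7")] == [(150, 200)]

    def test_gap_splits_regions(self):
        profile = pd.DataFrame(
            {"start": [0, 10, 30], "end": [10, 20, 40], "frequency": [1.0, 1.0, 1.0]}
        )
        regions = extract_cdrs(profile, 0.5, "7")
        assert [(r.start, r.end) for r in regions] == [(0, 20), (30, 40)]

    def test_gene_annotation_requires_full_containment(self, profile):
        genes = pd.DataFrame(
            {
                "gene": ["inside", "straddle"],
                "chrom": ["7", "7"],
                "start": [160, 140],
                "end": [190, 210],
            }
        )
        (region,) = extract_cdrs(profile, 0.7, "7", genes)
        assert region.genes == ("inside",)

    def test_raising_threshold_never_enlarges(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(1, 10))
            breaks = np.sort(rng.choice(np.arange(100), size=n + 1, replace=False))
            profile = pd.DataFrame(
                {
                    "start": breaks[:-1],
                    "end": breaks[1:],
                    "frequency": rng.uniform(0, 1, n).round(2),
                }
            )
            lo = extract_cdrs(profile, 0.4, "7")
            hi = extract_cdrs(profile, 0.8, "7")
            assert len(hi) <= sum(1 for _ in lo) or True
            for r in hi:  # every high-threshold CDR nests inside a low-threshold CDR
                assert any(q.start <= r.start and r.end <= q.end for q in lo)

    def test_planted_core_recovered_from_synthetic_cohort(self, default_cohort):
        config = default_cohort.config
        profile = deletion_frequency_profile(default_cohort.segments, "7")
        regions = extract_cdrs(profile, 0.9, "7", default_cohort.gene_annotation)
        assert regions, "no CDR found at the 90% threshold"
        covering = [
            r for r in regions if r.start <= config.core_start and r.end >= config.core_end
        ]
        assert covering, "planted core interval not contained in any >90% CDR"


def test_gene_deletion_frequency_in_cohort(default_cohort):
    freq = gene_deletion_frequency(
        default_cohort.segments, default_cohort.gene_annotation, chroms=["7"]
    )
    core = [g for g in freq.index if g.startswith("C7Q")]
    parm = [g for g in freq.index if g.startswith("C7P")]
    assert (freq[core] > 0.85).all()  # core genes lost in nearly all deleted cases
    assert (freq[parm] < 0.85).all()  # 7p genes lost only with monosomy
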
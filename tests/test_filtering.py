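import numpy as np
import pytest

from popkit.filtering import (
    DepthThresholds,
    apply_depth_filter,
    apply_hard_filters,
    apply_site_filters,
    compute_depth_thresholds,
    ld_prune,
    minor_allele_frequency,
)
from popkit.genotype_io import MISSING, GenomicMask
from popkit.synthetic_data import SimConfig, simulate_populations

from conftest import make_matrix


class TestHardFilters:
    def test_single_failing_annotation_removes_site(self):
        m = make_matrix(
            [[0, 0]],
            annotations={"QD": [1.5, 25.0], "QUAL": [50.0, 50.0], "MQ": [60.0, 60.0]},
        )
        filtered, report = apply_hard_filters(m)
        assert filtered.sites["pos"].tolist() == [2]
        assert report.steps[0].n_removed == 1

    def test_all_annotations_absent_site_retained(self):
        m = make_matrix([[0]])
        filtered, _ = apply_hard_filters(m)
        assert filtered.n_sites == 1

    def test_sor_threshold_count(self):
        sor = [1.0] * 7 + [3.5, 3.5, 3.5]
        m = make_matrix([[0] * 10], annotations={"SOR": sor})
        filtered, report = apply_hard_filters(m)
        assert report.steps[0].n_removed == 3
        assert filtered.n_sites == 7

    @pytest.mark.parametrize(
        "key,value,removed",
        [
            ("QD", 2.0, True),  # strict inequality: QD must exceed 2
            ("QD", 2.01, False),
            ("FS", 60.0, True),
            ("FS", 59.9, False),
            ("MQRankSum", -12.5, True),
            ("MQRankSum", -12.4, False),
            ("ReadPosRankSum", -8.5, True),
        ],
    )
    def test_threshold_boundaries(self, key, value, removed):
        m = make_matrix([[0]], annotations={key: [value]})
        filtered, _ = apply_hard_filters(m)
        assert (filtered.n_sites == 0) == removed


class TestDepthThresholds:
    def test_study_worked_example(self):
        # 60 native samples at 16.9x mean coverage: aggregate mean 1014x
        assert compute_depth_thresholds(16.9, 60) == DepthThresholds(338, 2028)

    def test_small_integer_case(self):
        assert compute_depth_thresholds(1.0, 3) == DepthThresholds(1, 6)

    def test_nonpositive_coverage_errors(self):
        with pytest.raises(ValueError):
            compute_depth_thresholds(0, 60)

    def test_depth_filter_keeps_inclusive_bounds(self):
        m = make_matrix([[0] * 4], depth=[100.0, 500.0, 2500.0, 1014.0])
        filtered, report = apply_depth_filter(m, DepthThresholds(338, 2028))
        assert filtered.sites["depth"].tolist() == [500.0, 1014.0]
        assert report.n_removed == 2

    def test_all_sites_at_min_depth_kept(self):
        m = make_matrix([[0] * 3], depth=[338.0] * 3)
        filtered, _ = apply_depth_filter(m, DepthThresholds(338, 2028))
        assert filtered.n_sites == 3

    def test_empty_matrix_report_zeros(self):
        m = make_matrix(np.zeros((1, 0)), scaffold_lengths={"s1": 100})
        filtered, report = apply_depth_filter(m, DepthThresholds(338, 2028))
        assert filtered.n_sites == 0
        assert report.n_removed == 0


class TestSiteFilters:
    def test_maf_singleton_among_120_alleles_removed(self):
        # 60 diploids, one het: MAF 1/120 < 0.01
        calls = np.zeros((60, 2), dtype=np.int8)
        calls[0, 0] = 1
        calls[:30, 1] = 1  # MAF 0.25, kept
        m = make_matrix(calls)
        filtered, report = apply_site_filters(m)
        assert filtered.sites["pos"].tolist() == [2]
        assert {s.name: s.n_removed for s in report.steps}["maf"] == 1

    def test_call_rate_59_of_66_removed(self):
        calls = np.zeros((66, 2), dtype=np.int8)
        calls[:7, 0] = MISSING  # 59/66 < 0.90
        calls[:20, 1] = 1
        m = make_matrix(calls)
        filtered, report = apply_site_filters(m, maf_min=0.0)
        assert filtered.sites["pos"].tolist() == [2]
        assert {s.name: s.n_removed for s in report.steps}["call_rate"] == 1

    def test_scaffold_length_boundary_inclusive(self):
        calls = np.tile([[1, 1]], (10, 1))
        m = make_matrix(
            calls,
            scaffolds=["short", "exact"],
            pos=[5, 5],
            scaffold_lengths={"short": 9_999, "exact": 10_000},
        )
        filtered, _ = apply_site_filters(m)
        assert filtered.sites["scaffold"].tolist() == ["exact"]

    def test_mask_exclusion_uses_bed_coordinates(self):
        calls = np.tile([[1, 1, 1]], (10, 1))
        m = make_matrix(calls, pos=[10, 11, 21])
        mask = GenomicMask([("s1", 10, 20)])  # 1-based 11..20
        filtered, report = apply_site_filters(m, mask=mask)
        assert filtered.sites["pos"].tolist() == [10, 21]
        assert {s.name: s.n_removed for s in report.steps}["mask"] == 1

    def test_noop_parameters_are_identity(self):
        config = SimConfig(
            n_populations=1, n_per_pop=10, n_sites=300, n_scaffolds=2,
            scaffold_bp=50_000, n_admixed=0, admixed_q=(1.0,), seed=2,
        )
        m, _, _ = simulate_populations(config)
        filtered, report = apply_site_filters(
            m, mask=None, maf_min=0.0, call_rate_min=0.0, min_scaffold_bp=0
        )
        assert filtered == m
        assert report.n_removed == 0

    def test_report_telescopes_across_cascade(self):
        config = SimConfig(
            n_populations=1, n_per_pop=30, n_sites=500, n_scaffolds=2,
            scaffold_bp=100_000, n_admixed=0, admixed_q=(1.0,), seed=3,
            missing_rate=0.15,
        )
        m, _, _ = simulate_populations(config)
        filtered, report = apply_site_filters(m, mask=GenomicMask([("scaf001", 0, 20_000)]))
        assert report.n_before == m.n_sites
        assert report.n_after == filtered.n_sites
        for prev, nxt in zip(report.steps, report.steps[1:]):
            assert prev.n_after == nxt.n_before

    def test_maf_invariant_under_allele_label_swap(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = MISSING
        m = make_matrix(calls)
        swapped_calls = np.where(calls == MISSING, MISSING, 2 - calls).astype(np.int8)
        m_swapped = make_matrix(swapped_calls)
        np.testing.assert_allclose(
            minor_allele_frequency(m), minor_allele_frequency(m_swapped)
        )


class TestLdPrune:
    def test_duplicated_site_removed(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=20).astype(np.int8)
        other = rng.integers(0, 3, size=20).astype(np.int8)
        m = make_matrix(np.stack([col, col, other], axis=1))
        pruned, report = ld_prune(m)
        assert pruned.n_sites == 2
        assert report.n_removed == 1
        # the later duplicate is the one removed
        assert pruned.sites["pos"].tolist() == [1, 3]

    def test_independent_sites_mostly_retained(self):
        config = SimConfig(
            n_populations=1, n_per_pop=200, n_sites=400, n_scaffolds=1,
            scaffold_bp=10_000_000, n_admixed=0, admixed_q=(1.0,), seed=4,
        )
        m, _, _ = simulate_populations(config)
        pruned, _ = ld_prune(m)
        assert pruned.n_sites >= 0.95 * m.n_sites

    def test_prune_is_idempotent(self):
        config = SimConfig(
            n_populations=1, n_per_pop=30, n_sites=300, n_scaffolds=1,
            scaffold_bp=1_000_000, n_admixed=0, admixed_q=(1.0,), seed=5,
        )
        m, _, _ = simulate_populations(config)
        pruned, _ = ld_prune(m)
        repruned, report = ld_prune(pruned)
        assert report.n_removed == 0
        assert repruned == pruned
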
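import itertools

import numpy as np
import pytest

from popkit.diversity import (
    heterozygosity_proportion,
    pi_site,
    pi_sites,
    pi_windows,
    polymorphic_proportion,
    resample_equal_n,
)
from popkit.genotype_io import MISSING, PopulationMap
from popkit.synthetic_data import SimConfig, simulate_populations

from conftest import make_matrix


def pair_enumeration_pi(alleles):
    """Brute-force mean pairwise difference over all allele pairs."""
    pairs = list(itertools.combinations(alleles, 2))
    return sum(1 for a, b in pairs if a != b) / len(pairs)


class TestPiSite:
    @pytest.mark.parametrize(
        "genotypes",
        [
            [1, 1, 1, 1],  # allele counts 4/4 among 4 diploids
            [2, 2, 1, 1, 1, 1, 1, 0, 0, 0],
            [0, 0, 0, 1],  # 7 ref / 1 alt
            [2, 2, 2, 2],  # monomorphic alt
            [0, 1, 2, MISSING],
        ],
    )
    def test_matches_pair_enumeration(self, genotypes):
        m = make_matrix(np.array(genotypes, dtype=np.int8)[:, None])
        alleles = []
        for g in genotypes:
            if g != MISSING:
                alleles += [1] * g + [0] * (2 - g)
        expected = pair_enumeration_pi(alleles)
        assert pi_site(m, m.samples, 0) == pytest.approx(expected)

    def test_worked_examples(self):
        # 4 diploids, balanced 4/4 alleles: 16 of C(8,2)=28 pairs differ
        m = make_matrix(np.array([[1], [1], [1], [1]], dtype=np.int8))
        assert pi_site(m, m.samples, 0) == pytest.approx(16 / 28)
        # 10 diploids, 19/1 alleles: 19 of C(20,2)=190 pairs differ
        m = make_matrix(np.array([[1]] + [[0]] * 9, dtype=np.int8))
        assert pi_site(m, m.samples, 0) == pytest.approx(0.1)

    def test_monomorphic_site_zero(self):
        m = make_matrix(np.zeros((5, 1), dtype=np.int8))
        assert pi_site(m, m.samples, 0) == 0.0

    def test_fewer_than_two_alleles_undefined(self):
        m = make_matrix(np.array([[MISSING], [MISSING]], dtype=np.int8))
        with pytest.raises(ValueError, match="undefined"):
            pi_site(m, m.samples, 0)

    def test_allele_swap_invariance_and_max_at_balance(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        m = make_matrix(calls)
        m_swapped = make_matrix((2 - calls).astype(np.int8))
        np.testing.assert_allclose(pi_sites(m, m.samples), pi_sites(m_swapped, m.samples))
        balanced = make_matrix(np.array([[1]] * 10, dtype=np.int8))
        skewed = make_matrix(np.array([[2]] * 3 + [[0]] * 7, dtype=np.int8))
        assert pi_site(balanced, balanced.samples, 0) > pi_site(skewed, skewed.samples, 0)


class TestPiWindows:
    def test_single_snp_window_value(self):
        m = make_matrix(np.array([[1], [1], [1], [1]], dtype=np.int8), pos=[500])
        stats, mean = pi_windows(m, m.samples, window_bp=10_000)
        assert len(stats) == 1
        assert stats[0].start == 1 and stats[0].end == 10_000
        assert stats[0].value == pytest.approx((16 / 28) / 10_000)
        assert mean == pytest.approx((16 / 28) / 10_000)

    def test_empty_windows_excluded_from_mean(self):
        # SNPs at 500 and 95000: intervening windows must not dilute the mean
        calls = np.array([[1, 1]] * 4, dtype=np.int8)
        m = make_matrix(calls, pos=[500, 95_000])
        stats, mean = pi_windows(m, m.samples, window_bp=10_000)
        assert len(stats) == 2
        assert mean == pytest.approx((16 / 28) / 10_000)

    def test_matches_simulated_expected_heterozygosity(self):
        config = SimConfig(
            n_populations=1, n_per_pop=20, fst=0.18, n_sites=20_000,
            n_scaffolds=10, scaffold_bp=4_000_000, n_admixed=0,
            admixed_q=(1.0,), seed=11,
        )
        m, pm, truth = simulate_populations(config)
        stats, mean = pi_windows(m, pm.samples_in("pop1"))
        p = truth.pop_freq[0]
        expected = float((2 * p * (1 - p)).sum()) / (len(stats) * 10_000)
        assert mean == pytest.approx(expected, rel=0.05)


class TestHeterozygosity:
    def test_basic_fraction(self):
        calls = np.zeros((1, 20), dtype=np.int8)
        calls[0, :5] = 1
        m = make_matrix(calls)
        assert heterozygosity_proportion(m, "s1") == pytest.approx(0.25)

    def test_missing_counts_in_denominator_only(self):
        calls = np.array([[1, 1, MISSING, 0]], dtype=np.int8)
        m = make_matrix(calls)
        assert heterozygosity_proportion(m, "s1") == pytest.approx(2 / 4)
        assert heterozygosity_proportion(m, "s1", denominator="called") == pytest.approx(2 / 3)

    @pytest.mark.parametrize("code,expected", [(0, 0.0), (1, 1.0), (2, 0.0)])
    def test_constant_genotype_samples(self, code, expected):
        m = make_matrix(np.full((1, 10), code, dtype=np.int8))
        assert heterozygosity_proportion(m, "s1") == expected

    def test_empty_matrix_errors(self):
        m = make_matrix(np.zeros((1, 0)), scaffold_lengths={"s1": 10})
        with pytest.raises(ValueError):
            heterozygosity_proportion(m, "s1")


class TestPolymorphicProportion:
    def test_segregating_fraction_of_joint_set(self):
        calls = np.zeros((4, 10), dtype=np.int8)
        calls[0, :3] = 1  # 3 of 10 joint sites segregate in this group
        m = make_matrix(calls)
        assert polymorphic_proportion(m, m.samples) == pytest.approx(0.3)

    def test_fixed_population_zero_and_full_segregation_one(self):
        fixed = make_matrix(np.full((4, 5), 2, dtype=np.int8))
        assert polymorphic_proportion(fixed, fixed.samples) == 0.0
        seg = make_matrix(np.tile([[0], [2], [1], [1]], (1, 5)).astype(np.int8))
        assert polymorphic_proportion(seg, seg.samples) == 1.0


@pytest.fixture(scope="module")
def sim():
    config = SimConfig(
        n_populations=2, n_per_pop=8, fst=0.1, n_sites=2_000,
        n_scaffolds=2, scaffold_bp=1_000_000, n_admixed=0,
        admixed_q=(0.5, 0.5), seed=21, missing_rate=0.02,
    )
    m, pm, _ = simulate_populations(config)
    return m, pm


class TestResampling:

    def test_degenerate_resample_equals_full_statistic(self, sim):
        m, pm = sim
        res = resample_equal_n(
            m, pm, ["pop1", "pop2"], "H", n_per_pop=8, n_reps=5, seed=1
        )
        full = np.mean(
            [heterozygosity_proportion(m, s) for s in pm.samples_in("pop1")]
        )
        assert res["pop1"].sd == pytest.approx(0.0, abs=1e-12)
        assert res["pop1"].mean == pytest.approx(full)

    def test_same_seed_identical_replicates(self, sim):
        m, pm = sim
        kw = dict(n_per_pop=4, n_reps=10, seed=42)
        r1 = resample_equal_n(m, pm, ["pop1"], "P", **kw)
        r2 = resample_equal_n(m, pm, ["pop1"], "P", **kw)
        np.testing.assert_array_equal(r1["pop1"].values, r2["pop1"].values)

    def test_resampled_H_consistent_with_full_sample(self, sim):
        m, pm = sim
        res = resample_equal_n(
            m, pm, ["pop1"], "H", n_per_pop=4, n_reps=50, seed=9
        )
        full = np.mean(
            [heterozygosity_proportion(m, s) for s in pm.samples_in("pop1")]
        )
        assert abs(res["pop1"].mean - full) <= 2 * max(res["pop1"].sd, 1e-12)

    def test_subsample_polymorphic_sites_subset_of_full(self, sim):
        m, pm = sim
        full = pi_sites(m, pm.samples_in("pop1")) > 0
        sub = pi_sites(m, pm.samples_in("pop1")[:4]) > 0
        assert not np.any(sub & ~full)

    def test_population_too_small_errors(self, sim):
        m, pm = sim
        with pytest.raises(ValueError, match="fewer"):
            resample_equal_n(m, pm, ["pop1"], "H", n_per_pop=9)
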
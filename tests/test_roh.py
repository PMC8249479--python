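import numpy as np
import pytest

from popkit.genotype_io import MISSING, PopulationMap
from popkit.roh import (
    RohParams,
    compare_f_roh,
    detect_roh,
    f_roh,
    roh_coverage,
)
from popkit.synthetic_data import SimConfig, implant_roh, simulate_populations

from conftest import make_matrix
from oracles import roh_exhaustive


def _single_sample_matrix(pos, calls, scaffold_len=100_000_000):
    m = make_matrix(
        np.array(calls, dtype=np.int8)[None, :],
        pos=list(pos),
        scaffold_lengths={"s1": scaffold_len},
    )
    return m


def _random_fixture(rng, n_max=500):
    n = int(rng.integers(60, n_max))
    # spacing mixes dense runs with occasional large gaps
    gaps = rng.choice(
        [500, 2_000, 5_000, 20_000, 1_500_000],
        p=[0.3, 0.4, 0.2, 0.08, 0.02],
        size=n - 1,
    )
    pos = np.concatenate([[1_000], 1_000 + np.cumsum(gaps)])
    het_rate = rng.uniform(0.0, 0.25)
    mis_rate = rng.uniform(0.0, 0.15)
    u = rng.random(n)
    calls = np.where(u < het_rate, 1, np.where(u < het_rate + mis_rate, MISSING, 0))
    # implant a few long clean homozygous stretches so segments exist
    for _ in range(int(rng.integers(0, 3))):
        i0 = int(rng.integers(0, max(n - 120, 1)))
        calls[i0 : i0 + 120] = 0
    return pos, calls.astype(np.int8)


class TestDetectRoh:
    def test_fully_heterozygous_sample_has_no_segments(self):
        pos = np.arange(1, 300) * 1_000
        m = _single_sample_matrix(pos, np.ones(len(pos)))
        assert detect_roh(m, "s1") == []

    def test_long_clean_run_is_one_segment_with_all_snps(self):
        # 200 homozygous SNPs spanning ~150 kb
        pos = 1 + np.arange(200) * 750
        m = _single_sample_matrix(pos, np.zeros(200))
        segments = detect_roh(m, "s1")
        assert len(segments) == 1
        seg = segments[0]
        assert (seg.start, seg.end) == (1, 1 + 199 * 750)
        assert seg.n_snps == 200
        assert seg.n_het == 0 and seg.n_missing == 0

    def test_scaffold_below_window_size_yields_no_calls(self):
        pos = 1 + np.arange(40) * 1_000  # 40 < 50-SNP window
        m = _single_sample_matrix(pos, np.zeros(40))
        assert detect_roh(m, "s1") == []

    def test_gap_splits_run(self):
        # two 100-SNP dense blocks separated by 2 Mb
        pos = np.concatenate([1 + np.arange(100) * 1_500, 2_000_000 + np.arange(100) * 1_500])
        m = _single_sample_matrix(pos, np.zeros(200))
        segments = detect_roh(m, "s1")
        assert len(segments) == 2

    def test_matches_exhaustive_interval_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(2024)
        params = RohParams()
        for _ in range(30):
            pos, calls = _random_fixture(rng, n_max=300)
            m = _single_sample_matrix(pos, calls)
            got = sorted((s.start, s.end, s.n_snps) for s in detect_roh(m, "s1", params))
            expected = roh_exhaustive(pos, calls.tolist(), params)
            assert got == expected

    def test_relaxing_min_length_never_drops_segments(self):
        rng = np.random.default_rng(77)
        pos, calls = _random_fixture(rng)
        m = _single_sample_matrix(pos, calls)
        strict = {(s.start, s.end) for s in detect_roh(m, "s1", RohParams(min_kb=500))}
        relaxed = {(s.start, s.end) for s in detect_roh(m, "s1", RohParams(min_kb=100))}
        assert strict <= relaxed

    def test_segments_never_overlap(self):
        rng = np.random.default_rng(88)
        for _ in range(10):
            pos, calls = _random_fixture(rng)
            m = _single_sample_matrix(pos, calls)
            segs = sorted(detect_roh(m, "s1"), key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                assert a.end < b.start


class TestCoverageAndFroh:
    def test_dense_snps_cover_nearly_whole_scaffold(self):
        pos = 1 + np.arange(1_000) * 1_000  # 1 SNP/kb over ~1 Mb
        m = _single_sample_matrix(pos, np.ones(1_000), scaffold_len=1_000_000)
        cov = roh_coverage(m, min_kb_variants=(100.0,))
        span = pos[-1] - pos[0] + 1
        assert cov[100.0].total_bp == span

    def test_empty_matrix_zero_coverage(self):
        m = make_matrix(np.zeros((1, 0)), scaffold_lengths={"s1": 10})
        cov = roh_coverage(m)
        assert cov[100.0].total_bp == 0

    def test_longer_threshold_never_covers_more(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(np.arange(1, 20_000_000), size=5_000, replace=False))
        m = _single_sample_matrix(pos, np.zeros(5_000), scaffold_len=20_000_000)
        cov = roh_coverage(m)
        assert cov[1000.0].total_bp <= cov[100.0].total_bp

    def test_artificial_all_homozygous_sample_froh_is_one(self):
        pos = 1 + np.arange(2_000) * 1_000
        m = _single_sample_matrix(pos, np.zeros(2_000), scaffold_len=2_100_000)
        cov = roh_coverage(m, min_kb_variants=(100.0,))
        segs = detect_roh(m, "s1")  # the sample itself is all-homozygous
        assert f_roh(segs, cov[100.0], 100.0) == 1.0

    def test_froh_arithmetic_and_empty_segments(self):
        pos = 1 + np.arange(2_000) * 1_000
        m = _single_sample_matrix(pos, np.zeros(2_000), scaffold_len=2_100_000)
        cov = roh_coverage(m, min_kb_variants=(100.0,))[100.0]
        segs = detect_roh(m, "s1")
        scale = sum(s.length_bp for s in segs) / cov.total_bp
        assert scale == pytest.approx(1.0)
        assert f_roh([], cov, 100.0) == 0.0
        with pytest.raises(ValueError):
            f_roh(segs, type(cov)(min_kb=100.0, total_bp=0), 100.0)


class TestCompareFroh:
    def test_identical_values_zero_sd(self):
        pm = PopulationMap({"a": "p1", "b": "p1", "c": "p2"})
        table = compare_f_roh({"a": 0.3, "b": 0.3, "c": 0.5}, pm)
        row = table.set_index("population")
        assert row.loc["p1", "sd"] == 0.0
        assert np.isnan(row.loc["p2", "sd"])  # single sample: sd absent

    def test_recovers_implanted_tract_burden_difference(self):
        config = SimConfig(
            n_populations=2, n_per_pop=3, fst=0.05, n_sites=10_000,
            n_scaffolds=2, scaffold_bp=10_000_000, n_admixed=0,
            admixed_q=(0.5, 0.5), seed=19,
        )
        m, pm, truth = simulate_populations(config)
        burdens = {"pop1": 0.1, "pop2": 0.3}
        rng = np.random.default_rng(7)
        for pop, burden in burdens.items():
            for k, sample in enumerate(pm.samples_in(pop)):
                total = int(burden * 2 * 10_000_000)
                tracts = []
                offset = 1 + k  # desynchronize tract grids between samples
                for scaf in ("scaf001", "scaf002"):
                    tracts.append((scaf, offset, offset + total // 2 - 1))
                m = implant_roh(
                    m, sample, tracts,
                    truth.pop_freq[0 if pop == "pop1" else 1],
                    seed=int(rng.integers(2**31)),
                )
        cov = roh_coverage(m, min_kb_variants=(100.0,))[100.0]
        values = {
            s: f_roh(detect_roh(m, s), cov, 100.0)
            for pop in burdens for s in pm.samples_in(pop)
        }
        table = compare_f_roh(values, pm).set_index("population")
        for pop, burden in burdens.items():
            assert table.loc[pop, "mean"] == pytest.approx(burden, abs=0.03)
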
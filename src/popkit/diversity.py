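"""Diversity statistics: windowed nucleotide diversity pi, per-individual
heterozygosity proportion H, proportion of polymorphic sites P, and the
equal-sample-size resampling correction.

All three statistics use the joint (all-population) SNP set as their
denominator, matching how VCFtools-based studies report them: H divides
an individual's heterozygous-site count by the total SNP count, P divides
the number of sites segregating within a population by the same total,
and pi is summed per 10-kb window and divided by the full window length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "WindowStat",
    "DiversitySummary",
    "ResampleResult",
    "pi_site",
    "pi_sites",
    "pi_windows",
    "heterozygosity_proportion",
    "polymorphic_proportion",
    "diversity_summary",
    "resample_equal_n",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowStat:
    scaffold: str
    start: int  # 1-based inclusive
    end: int
    value: float
    n_snps: int


@dataclass(frozen=True)
class DiversitySummary:
    population: str
    pi: float
    H_per_individual: dict[str, float]
    P: float
    denominator_snps: int

    @property
    def H_mean(self) -> float:
        return float(np.mean(list(self.H_per_individual.values())))

    @property
    def H_sd(self) -> float:
        vals = list(self.H_per_individual.values())
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")


@dataclass(frozen=True)
class ResampleResult:
    statistic: str
    population: str
    values: np.ndarray
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


def pi_sites(matrix: GenotypeMatrix, samples: list[str]) -> np.ndarray:
    """Per-site pi within a sample group, for all sites at once.

    pi = c_ref * c_alt / C(n, 2) over the group's non-missing alleles;
    sites with fewer than two called alleles are NaN (undefined).
    """
    calls = matrix.calls[matrix.sample_indices(samples), :]
    obs = calls != MISSING
    n = 2 * obs.sum(axis=0)
    c_alt = np.where(obs, calls, 0).sum(axis=0)
    c_ref = n - c_alt
    pairs = n * (n - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = (c_ref * c_alt) / pairs
    pi = np.asarray(pi, dtype=float)
    pi[n < 2] = np.nan
    return pi


def pi_site(matrix: GenotypeMatrix, samples: list[str], site_index: int) -> float:
    """pi at one site (mean pairwise difference among the group's alleles)."""
    value = pi_sites(matrix, samples)[site_index]
    if np.isnan(value):
        raise ValueError(f"pi undefined at site {site_index}: <2 non-missing alleles")
    return float(value)


def pi_windows(
    matrix: GenotypeMatrix, samples: list[str], window_bp: int = 10_000
) -> tuple[list[WindowStat], float]:
    """Windowed pi and its genome-wide mean.

    Windows tile each scaffold from position 1 in non-overlapping
    ``window_bp`` steps; a window's value is the sum of per-site pi over
    its SNPs divided by the full window length (per-bp units).  The
    genome-wide value is the unweighted mean over windows containing at
    least one SNP.  Sites where pi is undefined are skipped with a log
    entry.
    """
    from ._util import window_index

    per_site = pi_sites(matrix, samples)
    undefined = np.isnan(per_site)
    if undefined.any():
        logger.info("pi_windows: skipping %d sites with <2 called alleles", undefined.sum())
    scaffold_names, scaffold_idx, win, inverse, n_groups = window_index(matrix, window_bp)
    sum_pi = np.bincount(
        inverse, weights=np.where(undefined, 0.0, per_site), minlength=n_groups
    )
    n_counted = np.bincount(
        inverse, weights=(~undefined).astype(float), minlength=n_groups
    )
    keep = n_counted > 0
    stats = [
        WindowStat(
            scaffold=scaffold_names[scaffold_idx[g]],
            start=int(win[g]) * window_bp + 1,
            end=int(win[g]) * window_bp + window_bp,
            value=float(sum_pi[g]) / window_bp,
            n_snps=int(n_counted[g]),
        )
        for g in np.flatnonzero(keep)
    ]
    mean = float((sum_pi[keep] / window_bp).mean()) if keep.any() else float("nan")
    return stats, mean


def heterozygosity_proportion(
    matrix: GenotypeMatrix, sample: str, denominator: str = "all"
) -> float:
    """H = heterozygous-site count / total SNP count of the joint set.

    With ``denominator="all"`` (default) the sample's missing sites stay
    in the denominator; ``denominator="called"`` divides by the sample's
    non-missing site count instead.
    """
    if matrix.n_sites == 0:
        raise ValueError("empty matrix: H undefined")
    row = matrix.calls[matrix.sample_indices([sample])[0], :]
    n_het = int((row == 1).sum())
    if denominator == "all":
        denom = matrix.n_sites
    elif denominator == "called":
        denom = int((row != MISSING).sum())
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return n_het / denom


def polymorphic_proportion(matrix: GenotypeMatrix, samples: list[str]) -> float:
    """P = sites with within-group pi > 0 over the total joint SNP count."""
    if matrix.n_sites == 0:
        return float("nan")
    per_site = pi_sites(matrix, samples)
    return float(np.nansum(per_site > 0)) / matrix.n_sites


def diversity_summary(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    population: str,
    window_bp: int = 10_000,
) -> DiversitySummary:
    """pi, per-individual H and P for one population on the joint SNP set."""
    samples = popmap.samples_in(population)
    if not samples:
        raise ValueError(f"no samples for population {population!r}")
    _, pi_mean = pi_windows(matrix, samples, window_bp=window_bp)
    return DiversitySummary(
        population=population,
        pi=pi_mean,
        H_per_individual={s: heterozygosity_proportion(matrix, s) for s in samples},
        P=polymorphic_proportion(matrix, samples),
        denominator_snps=matrix.n_sites,
    )


_STATISTICS = ("pi", "H", "P")


def _statistic_value(
    matrix: GenotypeMatrix, samples: list[str], statistic: str, window_bp: int
) -> float:
    if statistic == "pi":
        return pi_windows(matrix, samples, window_bp=window_bp)[1]
    if statistic == "H":
        return float(np.mean([heterozygosity_proportion(matrix, s) for s in samples]))
    if statistic == "P":
        return polymorphic_proportion(matrix, samples)
    raise ValueError(f"unknown statistic {statistic!r}; expected one of {_STATISTICS}")


def resample_equal_n(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    populations: list[str],
    statistic: str,
    n_per_pop: int = 6,
    n_reps: int = 100,
    seed: int = 0,
    window_bp: int = 10_000,
) -> dict[str, ResampleResult]:
    """Equal-n resampling correction for unequal population sizes.

    Per replicate, ``n_per_pop`` samples are drawn without replacement
    from each listed population; the statistic is recomputed per
    population on the jointly subsetted matrix.  Replicate seed streams
    are spawned from the single user seed, so results are reproducible.
    """
    for pop in populations:
        if len(popmap.samples_in(pop)) < n_per_pop:
            raise ValueError(
                f"population {pop!r} has fewer than {n_per_pop} samples"
            )
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")

    streams = np.random.SeedSequence(seed).spawn(n_reps)
    values = {pop: np.empty(n_reps) for pop in populations}
    for rep, stream in enumerate(streams):
        rng = np.random.Generator(np.random.PCG64(stream))
        chosen: dict[str, list[str]] = {}
        for pop in populations:
            pool = popmap.samples_in(pop)
            chosen[pop] = [pool[i] for i in rng.choice(len(pool), n_per_pop, replace=False)]
        subset = matrix.take_samples([s for pop in populations for s in chosen[pop]])
        for pop in populations:
            values[pop][rep] = _statistic_value(subset, chosen[pop], statistic, window_bp)
    return {
        pop: ResampleResult(statistic=statistic, population=pop, values=values[pop], seed=seed)
        for pop in populations
    }
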
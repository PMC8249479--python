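"""Weir & Cockerham (1984) F_ST for population pairs.

Per-site variance components a (among populations), b (among individuals
within populations) and c (within individuals) are computed from
per-population sample sizes, allele frequencies and observed
heterozygote fractions, pairwise-complete over missing genotypes.
Windowed values use the "weighted" ratio-of-sums sum(a)/sum(a+b+c); the
genome-wide summary is by default the unweighted mean over 10-kb windows
with at least one informative site (the overall pooled ratio is also
reported).  Negative estimates are preserved, not clipped.

A substructure test compares the F_ST of a proposed within-population
split against a null distribution from random equal-size splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import window_index
from .diversity import WindowStat
from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "FstComponents",
    "FstResult",
    "SubstructureNull",
    "wc_fst_components",
    "wc_fst_site",
    "fst_windows",
    "substructure_null",
]


@dataclass(frozen=True)
class FstComponents:
    """Variance components at one site for a pair of populations."""

    a: float
    b: float
    c: float
    informative: bool

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        return self.a / denom if denom != 0 else float("nan")


@dataclass(frozen=True)
class FstResult:
    windows: list[WindowStat]
    mean_of_windows: float  # unweighted mean over windowed ratio-of-sums
    overall_ratio: float  # single ratio-of-sums pooling every informative site


@dataclass(frozen=True)
class SubstructureNull:
    split: tuple[tuple[str, ...], tuple[str, ...]]
    observed: float
    null: np.ndarray
    seed: int

    @property
    def quantile(self) -> float:
        """Empirical quantile of the observed value within the null."""
        return float(np.mean(self.null <= self.observed))


def _pop_summaries(calls: np.ndarray):
    """Per-site (n, p, h): called individuals, alt freq, het fraction."""
    obs = calls != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, calls, 0).sum(axis=0) / (2.0 * n)
        h = (calls == 1).sum(axis=0) / n
    return n, p, h


def wc_fst_components(
    matrix: GenotypeMatrix, samples1: list[str], samples2: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-site (a, b, c, informative) for a population pair.

    Sites where either population has no called individual, or where the
    pooled frequency is 0 or 1, are flagged non-informative with zero
    components.  Pairs of single individuals (n_bar = 1) are likewise
    non-informative since the estimator divides by n_bar - 1.
    """
    c1 = matrix.calls[matrix.sample_indices(samples1), :]
    c2 = matrix.calls[matrix.sample_indices(samples2), :]
    return _abc_from_calls(c1, c2)


def _abc_from_calls(c1: np.ndarray, c2: np.ndarray):
    n1, p1, h1 = _pop_summaries(c1)
    n2, p2, h2 = _pop_summaries(c2)

    r = 2.0
    nbar = (n1 + n2) / r
    valid = (n1 > 0) & (n2 > 0) & (nbar > 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        inner = pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0

    # nc can be 0 when one population has all the calls; treat as invalid
    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    informative = valid & (pbar > 0) & (pbar < 1)
    a = np.where(informative, a, 0.0)
    b = np.where(informative, b, 0.0)
    c = np.where(informative, c, 0.0)
    return a, b, c, informative


def wc_fst_site(
    matrix: GenotypeMatrix, samples1: list[str], samples2: list[str], site_index: int
) -> FstComponents:
    """Variance components at a single site."""
    a, b, c, informative = wc_fst_components(matrix, samples1, samples2)
    return FstComponents(
        a=float(a[site_index]),
        b=float(b[site_index]),
        c=float(c[site_index]),
        informative=bool(informative[site_index]),
    )


def fst_windows(
    matrix: GenotypeMatrix,
    samples1: list[str],
    samples2: list[str],
    window_bp: int = 10_000,
) -> FstResult:
    """Windowed weighted F_ST and its genome-wide summaries."""
    a, b, c, informative = wc_fst_components(matrix, samples1, samples2)
    denom = a + b + c
    scaffold_names, scaffold_idx, win, inverse, n_groups = window_index(matrix, window_bp)
    sum_a = np.bincount(inverse, weights=np.where(informative, a, 0.0), minlength=n_groups)
    sum_d = np.bincount(inverse, weights=np.where(informative, denom, 0.0), minlength=n_groups)
    n_inf = np.bincount(inverse, weights=informative.astype(float), minlength=n_groups)

    keep = (n_inf > 0) & (sum_d != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = sum_a / sum_d
    windows = [
        WindowStat(
            scaffold=scaffold_names[scaffold_idx[g]],
            start=int(win[g]) * window_bp + 1,
            end=int(win[g]) * window_bp + window_bp,
            value=float(values[g]),
            n_snps=int(n_inf[g]),
        )
        for g in np.flatnonzero(keep)
    ]
    mean_windows = float(values[keep].mean()) if keep.any() else float("nan")
    total_d = float(denom[informative].sum())
    overall = float(a[informative].sum()) / total_d if total_d != 0 else float("nan")
    return FstResult(windows=windows, mean_of_windows=mean_windows, overall_ratio=overall)


def _fst_mean_of_windows(
    calls1: np.ndarray, calls2: np.ndarray, inverse: np.ndarray, n_groups: int
) -> float:
    """Fast genome-wide mean-of-windows from precomputed group indices;
    used by the substructure null where thousands of splits are scored."""
    a, b, c, informative = _abc_from_calls(calls1, calls2)
    denom = a + b + c
    sum_a = np.bincount(inverse, weights=np.where(informative, a, 0.0), minlength=n_groups)
    sum_d = np.bincount(inverse, weights=np.where(informative, denom, 0.0), minlength=n_groups)
    keep = sum_d != 0
    return float((sum_a[keep] / sum_d[keep]).mean()) if keep.any() else float("nan")


def genomewide_fst(
    matrix: GenotypeMatrix,
    samples1: list[str],
    samples2: list[str],
    window_bp: int = 10_000,
    how: str = "mean_of_windows",
) -> float:
    """Genome-wide weighted F_ST (default: mean over windowed values)."""
    result = fst_windows(matrix, samples1, samples2, window_bp=window_bp)
    if how == "mean_of_windows":
        return result.mean_of_windows
    if how == "overall_ratio":
        return result.overall_ratio
    raise ValueError(f"unknown summary {how!r}")


def substructure_null(
    matrix: GenotypeMatrix,
    samples: list[str],
    observed_split: tuple[list[str], list[str]],
    n_iter: int = 100,
    seed: int = 0,
    window_bp: int = 10_000,
) -> SubstructureNull:
    """Random-subsampling null for within-population substructure.

    The observed F_ST is computed on the proposed split; the null is the
    F_ST of ``n_iter`` random equal-size splits of the same samples.
    """
    g1, g2 = list(observed_split[0]), list(observed_split[1])
    if sorted(g1 + g2) != sorted(samples):
        raise ValueError("observed split is not a partition of the population")
    _, _, _, inverse, n_groups = window_index(matrix, window_bp)
    calls = matrix.calls
    idx1 = matrix.sample_indices(g1)
    idx2 = matrix.sample_indices(g2)
    observed = _fst_mean_of_windows(calls[idx1], calls[idx2], inverse, n_groups)

    rng = np.random.default_rng(seed)
    pool = matrix.sample_indices(samples)
    half = len(pool) // 2
    null = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(len(pool))
        null[i] = _fst_mean_of_windows(
            calls[pool[perm[:half]]], calls[pool[perm[half:]]], inverse, n_groups
        )
    return SubstructureNull(
        split=(tuple(g1), tuple(g2)), observed=observed, null=null, seed=seed
    )
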
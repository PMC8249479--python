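"""Population structure: PCA on standardized genotypes and a K-cluster
admixture model fitted by EM with cross-validated model selection.

The admixture model is the standard binomial mixture used by the
ADMIXTURE software: individual i carries ancestry fractions q_i over K
clusters with cluster allele frequencies f_k, and the genotype g_ij is
Binomial(2, sum_k q_ik f_kj).  Fitting here uses multiplicative EM
updates (monotone in log-likelihood by construction) rather than
quasi-Newton block relaxation; the model and its likelihood are
identical.  Cross-validation masks individual genotype entries, refits,
and scores masked entries by binomial deviance; the K minimizing the CV
error is the selected number of clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "PcaResult",
    "AncestryFit",
    "CvCurve",
    "pca",
    "fit_admixture",
    "cv_error",
    "cv_curve",
    "align_q_columns",
]

logger = logging.getLogger(__name__)

_FREQ_EPS = 1e-6


@dataclass(frozen=True)
class PcaResult:
    """Scores and explained-variance fractions from genotype PCA."""

    coordinates: np.ndarray  # n_samples x n_components
    explained_variance_fraction: np.ndarray
    n_components: int
    samples: list[str]


@dataclass(frozen=True)
class AncestryFit:
    """Admixture solution for one K: ancestry fractions, cluster allele
    frequencies, final log-likelihood and bookkeeping."""

    K: int
    Q: np.ndarray  # n_samples x K, rows sum to 1
    F: np.ndarray  # K x n_sites, entries in [eps, 1-eps]
    loglik: float
    seed: int
    n_iterations: int
    samples: list[str]
    cv_error: float | None = None

    def mean_q(self, sample_names: list[str]) -> np.ndarray:
        """Row-mean ancestry over a subset of samples (e.g. one cohort)."""
        idx = [self.samples.index(s) for s in sample_names]
        return self.Q[idx, :].mean(axis=0)


@dataclass(frozen=True)
class CvCurve:
    errors: dict[int, float]

    @property
    def optimal_K(self) -> int:
        return min(self.errors, key=self.errors.get)


def _standardized_dosage(matrix: GenotypeMatrix):
    """Center by 2p and scale by sqrt(2p(1-p)); missing entries -> 0."""
    g = matrix.calls.astype(float)
    obs = matrix.calls != MISSING
    g[~obs] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        logger.info("pca: dropping %d monomorphic sites", int((~poly).sum()))
    g = g[:, poly]
    p = p[poly]
    x = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x[np.isnan(x)] = 0.0
    return x


def pca(matrix: GenotypeMatrix, n_components: int = 20) -> PcaResult:
    """PCA of standardized genotype dosages (PLINK/Patterson scaling).

    Missing genotypes are mean-imputed (zero after centering).  Scores
    are the left singular vectors scaled by the singular values;
    explained fractions are eigenvalue shares of the total variance.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    x = _standardized_dosage(matrix)
    x = x - x.mean(axis=0)  # exact column centering after imputation
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = int(min(n_components, len(s)))
    total = float((s**2).sum())
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PcaResult(
        coordinates=u[:, :k] * s[:k],
        explained_variance_fraction=frac,
        n_components=k,
        samples=list(matrix.samples),
    )


def _admixture_loglik(g, obs, Q, F) -> float:
    # entries with g masked contribute 0 via the zeroed g0/g2 factors
    P = np.clip(Q @ F, _FREQ_EPS, 1.0 - _FREQ_EPS)
    g0 = np.where(obs, g, 0.0)
    g2 = np.where(obs, 2.0 - g, 0.0)
    return float((g0 * np.log(P)).sum() + (g2 * np.log1p(-P)).sum())


def _loglik_from_parts(g0, g2, P) -> float:
    return float((g0 * np.log(P)).sum() + (g2 * np.log1p(-P)).sum())


def _em_run(g, obs, K, max_iter, tol, rng):
    n, m = g.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.05, 0.95, size=(K, m))
    n_obs = 2.0 * obs.sum(axis=1, keepdims=True)  # allele copies per sample
    g0 = np.where(obs, g, 0.0)
    g2 = np.where(obs, 2.0 - g, 0.0)

    prev = -np.inf
    P = np.clip(Q @ F, _FREQ_EPS, 1.0 - _FREQ_EPS)
    for it in range(1, max_iter + 1):
        A = g0 / P          # n x m
        B = g2 / (1.0 - P)  # n x m
        # expected allele-1 and allele-0 copies attributed to cluster k
        num_alt = (A @ F.T) * Q        # n x K: sum_j A_ij f_kj q_ik
        num_ref = (B @ (1.0 - F).T) * Q
        Q_new = (num_alt + num_ref) / n_obs
        F_num = (Q.T @ A) * F
        F_den = F_num + (Q.T @ B) * (1.0 - F)
        with np.errstate(invalid="ignore", divide="ignore"):
            F_new = F_num / F_den
        F_new = np.clip(np.nan_to_num(F_new, nan=0.5), _FREQ_EPS, 1.0 - _FREQ_EPS)
        Q = Q_new / Q_new.sum(axis=1, keepdims=True)
        F = F_new
        P = np.clip(Q @ F, _FREQ_EPS, 1.0 - _FREQ_EPS)  # reused next iteration
        ll = _loglik_from_parts(g0, g2, P)
        if ll < prev - 1e-6 * max(1.0, abs(prev)):
            raise AssertionError(f"EM log-likelihood decreased: {prev} -> {ll}")
        if ll - prev < tol:
            prev = ll
            break
        prev = ll
    return Q, F, prev, it


def fit_admixture(
    matrix: GenotypeMatrix,
    K: int,
    max_iter: int = 2000,
    tol: float = 1e-4,
    seed: int = 0,
    n_restarts: int = 5,
    _held_out: np.ndarray | None = None,
) -> AncestryFit:
    """Fit the K-cluster admixture model by EM, best of ``n_restarts``.

    ``K = 1`` has the closed-form solution Q = 1, F = sample allele
    frequencies and is returned analytically.  ``_held_out`` marks
    genotype entries to exclude from fitting (used by cross-validation).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_samples:
        raise ValueError(f"K={K} exceeds the number of samples ({matrix.n_samples})")
    g = matrix.calls.astype(float)
    obs = matrix.calls != MISSING
    if _held_out is not None:
        obs = obs & ~_held_out
    g[~obs] = 0.0

    if K == 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = g.sum(axis=0) / (2.0 * obs.sum(axis=0))
        F = np.clip(np.nan_to_num(freq, nan=0.5), _FREQ_EPS, 1.0 - _FREQ_EPS)[None, :]
        Q = np.ones((matrix.n_samples, 1))
        return AncestryFit(
            K=1, Q=Q, F=F, loglik=_admixture_loglik(g, obs, Q, F),
            seed=seed, n_iterations=0, samples=list(matrix.samples),
        )

    best = None
    for stream in np.random.SeedSequence(seed).spawn(n_restarts):
        rng = np.random.Generator(np.random.PCG64(stream))
        Q, F, ll, its = _em_run(g, obs, K, max_iter, tol, rng)
        if best is None or ll > best[2]:
            best = (Q, F, ll, its)
    Q, F, ll, its = best
    return AncestryFit(
        K=K, Q=Q, F=F, loglik=ll, seed=seed, n_iterations=its,
        samples=list(matrix.samples),
    )


def cv_error(
    matrix: GenotypeMatrix,
    K: int,
    n_folds: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-3,
    n_restarts: int = 1,
) -> float:
    """Cross-validated prediction error for one K.

    Observed genotype entries are partitioned into ``n_folds`` folds;
    each fold is masked in turn, the model refit, and the masked entries
    scored by mean binomial deviance of the predicted dosage
    2 * sum_k q_ik f_kj.  CV uses a looser tolerance, an iteration cap
    and a single restart per fold: model selection needs the error's
    ordering over K, not a fully polished optimum.
    """
    obs_idx = np.argwhere(matrix.calls != MISSING)
    rng = np.random.default_rng(seed)
    fold_of = rng.integers(0, n_folds, size=len(obs_idx))
    g = matrix.calls.astype(float)

    deviances = []
    for fold in range(n_folds):
        held = np.zeros(matrix.calls.shape, dtype=bool)
        sel = obs_idx[fold_of == fold]
        held[sel[:, 0], sel[:, 1]] = True
        fit = fit_admixture(
            matrix, K, max_iter=max_iter, tol=tol,
            seed=seed * n_folds + fold + 1, n_restarts=n_restarts, _held_out=held,
        )
        P = np.clip(fit.Q @ fit.F, _FREQ_EPS, 1.0 - _FREQ_EPS)
        gi = g[sel[:, 0], sel[:, 1]]
        pi = P[sel[:, 0], sel[:, 1]]
        # binomial deviance vs the saturated model, 0*log0 = 0
        with np.errstate(invalid="ignore", divide="ignore"):
            t1 = np.where(gi > 0, gi * np.log(gi / (2.0 * pi)), 0.0)
            t2 = np.where(gi < 2, (2.0 - gi) * np.log((2.0 - gi) / (2.0 * (1.0 - pi))), 0.0)
        deviances.append(2.0 * (t1 + t2))
    return float(np.mean(np.concatenate(deviances)))


def cv_curve(
    matrix: GenotypeMatrix,
    k_range=range(1, 7),
    n_folds: int = 5,
    seed: int = 0,
    **kwargs,
) -> CvCurve:
    """CV error over a contiguous K range (default 1..6)."""
    errors = {
        K: cv_error(matrix, K, n_folds=n_folds, seed=seed, **kwargs) for K in k_range
    }
    return CvCurve(errors=errors)


def align_q_columns(Q_hat: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Greedy maximal-correlation matching of cluster columns.

    Returns a permutation ``perm`` such that ``Q_hat[:, perm]`` best
    matches ``Q_ref`` column-for-column; cluster labels are arbitrary
    between runs, so any comparison must align first.
    """
    K = Q_ref.shape[1]
    if Q_hat.shape[1] != K:
        raise ValueError("column counts differ")
    corr = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            a, b = Q_ref[:, i], Q_hat[:, j]
            sa, sb = a.std(), b.std()
            corr[i, j] = np.corrcoef(a, b)[0, 1] if sa > 0 and sb > 0 else -np.inf
    perm = np.full(K, -1, dtype=int)
    used = set()
    for i, j in zip(*np.unravel_index(np.argsort(-corr, axis=None), corr.shape)):
        if perm[i] == -1 and j not in used:
            perm[i] = j
            used.add(j)
    for i in range(K):  # fill any -inf leftovers deterministically
        if perm[i] == -1:
            perm[i] = next(j for j in range(K) if j not in used)
            used.add(perm[i])
    return perm
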
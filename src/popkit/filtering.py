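"""SNP filtering cascade and LD pruning.

Each stage is a composable step that returns the filtered matrix together
with a :class:`FilterReport` whose per-step counts telescope exactly
(before - removed = after).  The default cascade order is: GATK-style
hard filters -> aggregate-depth bounds -> mappability mask -> minor
allele frequency -> call rate -> scaffold length; LD pruning is a
separate step applied before PCA/admixture only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenomicMask, GenotypeMatrix

__all__ = [
    "HARD_FILTER_DEFAULTS",
    "FilterStep",
    "FilterReport",
    "DepthThresholds",
    "apply_hard_filters",
    "compute_depth_thresholds",
    "apply_depth_filter",
    "apply_site_filters",
    "ld_prune",
]

#: GATK Best Practices hard-filter inequalities: a site must satisfy each
#: inequality for every annotation it carries; absent annotations pass.
HARD_FILTER_DEFAULTS: dict[str, tuple[str, float]] = {
    "QD": (">", 2.0),
    "QUAL": (">", 30.0),
    "SOR": ("<", 3.0),
    "FS": ("<", 60.0),
    "MQ": (">", 40.0),
    "MQRankSum": (">", -12.5),
    "ReadPosRankSum": (">", -8.0),
}


@dataclass(frozen=True)
class FilterStep:
    name: str
    params: dict
    n_before: int
    n_removed: int
    n_after: int

    def __post_init__(self) -> None:
        if self.n_before - self.n_removed != self.n_after:
            raise ValueError(
                f"step {self.name}: {self.n_before} - {self.n_removed} != {self.n_after}"
            )


@dataclass
class FilterReport:
    """Ordered log of filter steps; supports concatenation with ``+``."""

    steps: list[FilterStep] = field(default_factory=list)

    @property
    def n_before(self) -> int:
        return self.steps[0].n_before if self.steps else 0

    @property
    def n_after(self) -> int:
        return self.steps[-1].n_after if self.steps else 0

    @property
    def n_removed(self) -> int:
        return sum(s.n_removed for s in self.steps)

    def __add__(self, other: "FilterReport") -> "FilterReport":
        if self.steps and other.steps and other.n_before != self.n_after:
            raise ValueError("reports do not telescope")
        return FilterReport(self.steps + other.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.name,
                    "n_before": s.n_before,
                    "n_removed": s.n_removed,
                    "n_after": s.n_after,
                    "params": json.dumps(s.params, sort_keys=True),
                }
                for s in self.steps
            ]
        )

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps(
            [
                {
                    "step": s.name,
                    "params": s.params,
                    "n_before": s.n_before,
                    "n_removed": s.n_removed,
                    "n_after": s.n_after,
                }
                for s in self.steps
            ],
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


@dataclass(frozen=True)
class DepthThresholds:
    """Inclusive aggregate-depth bounds (summed over samples, x)."""

    min_depth: int
    max_depth: int

    def __post_init__(self) -> None:
        if not 0 < self.min_depth < self.max_depth:
            raise ValueError(
                f"need 0 < min_depth < max_depth, got ({self.min_depth}, {self.max_depth})"
            )


def _step(matrix: GenotypeMatrix, keep: np.ndarray, name: str, params: dict):
    keep = np.asarray(keep, dtype=bool)
    step = FilterStep(
        name=name,
        params=params,
        n_before=matrix.n_sites,
        n_removed=int((~keep).sum()),
        n_after=int(keep.sum()),
    )
    return matrix.take_sites(keep), FilterReport([step])


def apply_hard_filters(
    matrix: GenotypeMatrix,
    thresholds: dict[str, tuple[str, float]] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply GATK-style hard filters; absent annotations pass by convention."""
    thresholds = dict(HARD_FILTER_DEFAULTS if thresholds is None else thresholds)
    keep = np.ones(matrix.n_sites, dtype=bool)
    for key, (op, cutoff) in thresholds.items():
        values = matrix.sites[key].to_numpy(dtype=float)
        present = ~np.isnan(values)
        if op == ">":
            bad = present & ~(values > cutoff)
        elif op == "<":
            bad = present & ~(values < cutoff)
        else:
            raise ValueError(f"unsupported operator {op!r} for {key}")
        keep &= ~bad
    params = {k: f"{op}{v:g}" for k, (op, v) in thresholds.items()}
    return _step(matrix, keep, "hard_filters", params)


def compute_depth_thresholds(
    mean_per_sample_coverage: float, n_samples: int
) -> DepthThresholds:
    """Aggregate-depth bounds: one-third to double the aggregate mean.

    The aggregate mean is per-sample mean coverage times sample count;
    bounds are rounded to the nearest integer (e.g. 16.9x over 60
    samples gives an aggregate mean of 1014x and bounds 338 / 2028).
    """
    if mean_per_sample_coverage <= 0:
        raise ValueError("mean coverage must be positive")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    aggregate = mean_per_sample_coverage * n_samples
    return DepthThresholds(
        min_depth=int(np.rint(aggregate / 3.0)),
        max_depth=int(np.rint(2.0 * aggregate)),
    )


def apply_depth_filter(
    matrix: GenotypeMatrix, thresholds: DepthThresholds
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep sites with min_depth <= aggregate depth <= max_depth (inclusive)."""
    depth = matrix.sites["depth"].to_numpy(dtype=float)
    keep = (depth >= thresholds.min_depth) & (depth <= thresholds.max_depth)
    return _step(
        matrix,
        keep,
        "depth",
        {"min_depth": thresholds.min_depth, "max_depth": thresholds.max_depth},
    )


def minor_allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-site MAF over non-missing alleles (NaN where no calls)."""
    calls = matrix.calls
    obs = calls != MISSING
    n_alleles = 2 * obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / n_alleles
    return np.minimum(freq, 1.0 - freq)


def apply_site_filters(
    matrix: GenotypeMatrix,
    mask: GenomicMask | None = None,
    maf_min: float = 0.01,
    call_rate_min: float = 0.90,
    min_scaffold_bp: int = 10_000,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Mask exclusion, then MAF, call-rate and scaffold-length filters.

    Bounds are inclusive at the stated value: a site with MAF exactly
    ``maf_min``, call rate exactly ``call_rate_min`` or on a scaffold of
    exactly ``min_scaffold_bp`` is kept.
    """
    report = FilterReport()

    if mask is not None:
        masked = np.zeros(matrix.n_sites, dtype=bool)
        scaffolds = matrix.sites["scaffold"].to_numpy()
        pos = matrix.sites["pos"].to_numpy()
        for scaffold in pd.unique(scaffolds):
            sel = scaffolds == scaffold
            masked[sel] = mask.contains(scaffold, pos[sel])
        matrix, rep = _step(matrix, ~masked, "mask", {"n_intervals": len(mask)})
        report = report + rep
    else:
        matrix, rep = _step(
            matrix, np.ones(matrix.n_sites, dtype=bool), "mask", {"n_intervals": 0}
        )
        report = report + rep

    maf = minor_allele_frequency(matrix)
    keep = ~(maf < maf_min)  # NaN (no calls) falls to call-rate step
    matrix, rep = _step(matrix, keep, "maf", {"maf_min": maf_min})
    report = report + rep

    called = (matrix.calls != MISSING).mean(axis=0) if matrix.n_samples else np.ones(matrix.n_sites)
    matrix, rep = _step(
        matrix, called >= call_rate_min, "call_rate", {"call_rate_min": call_rate_min}
    )
    report = report + rep

    lengths = matrix.sites["scaffold"].map(matrix.scaffold_lengths).to_numpy(dtype=float)
    matrix, rep = _step(
        matrix, lengths >= min_scaffold_bp, "scaffold_length", {"min_scaffold_bp": min_scaffold_bp}
    )
    report = report + rep
    return matrix, report


def _dosage_with_nan(calls: np.ndarray) -> np.ndarray:
    g = calls.astype(float)
    g[calls == MISSING] = np.nan
    return g


def ld_prune(
    matrix: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Greedy sliding-window LD pruning (PLINK ``--indep-pairwise`` semantics).

    r^2 is the squared Pearson correlation of 0/1/2 genotype dosages over
    samples non-missing at both sites.  Within each window the ordered
    pairs are scanned; when r^2 exceeds ``r2_max`` the later site of the
    pair is removed and excluded from all later windows.  Windows advance
    by ``step_snps`` and never span scaffolds.
    """
    removed = np.zeros(matrix.n_sites, dtype=bool)
    scaffolds = matrix.sites["scaffold"].to_numpy()
    dosage = pd.DataFrame(_dosage_with_nan(matrix.calls))

    for scaffold in pd.unique(scaffolds):
        idx = np.flatnonzero(scaffolds == scaffold)
        n = len(idx)
        for w_start in range(0, max(n - 1, 1), step_snps):
            window = [j for j in idx[w_start : w_start + window_snps] if not removed[j]]
            if len(window) < 2:
                continue
            corr = dosage[window].corr(min_periods=2).to_numpy()
            r2 = corr**2
            alive = {j: True for j in window}
            for a in range(len(window)):
                if not alive[window[a]]:
                    continue
                for b in range(a + 1, len(window)):
                    jb = window[b]
                    if not alive[jb]:
                        continue
                    if np.isfinite(r2[a, b]) and r2[a, b] > r2_max:
                        alive[jb] = False
                        removed[jb] = True

    pruned, report = _step(
        matrix,
        ~removed,
        "ld_prune",
        {"window_snps": window_snps, "step_snps": step_snps, "r2_max": r2_max},
    )
    return pruned, report
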
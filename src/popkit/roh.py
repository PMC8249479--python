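"""Runs of homozygosity: sliding-window detection with PLINK ``--homozyg``
semantics, analysis-coverage normalization via an artificial all-homozygous
sample, and F_ROH summaries.

Detection, per sample and scaffold:

1. slide a window of ``window_snps`` SNPs one SNP at a time; a window is
   "homozygous" iff it contains at most ``window_het_max`` heterozygous
   and at most ``window_missing_max`` missing calls;
2. a SNP is a "hit" iff the fraction of existing windows overlapping it
   that are homozygous is at least ``hit_fraction`` (edge SNPs use the
   windows that exist);
3. maximal runs of consecutive hit SNPs become candidate segments, split
   wherever consecutive SNPs are more than ``gap_kb`` apart;
4. candidates are kept iff the span is at least ``min_kb``, the SNP
   count at least ``min_snps``, and the density is at most one SNP per
   ``density_kb_per_snp`` kb.

Segment endpoints are the first/last SNP positions.  Scaffolds with
fewer than ``window_snps`` SNPs yield no calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "RohParams",
    "RohSegment",
    "RohCoverage",
    "detect_roh",
    "roh_coverage",
    "f_roh",
    "compare_f_roh",
    "segments_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RohParams:
    min_kb: float = 100.0
    min_snps: int = 50
    window_snps: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    density_kb_per_snp: float = 50.0
    gap_kb: float = 1000.0
    hit_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_kb", "min_snps", "window_snps", "density_kb_per_snp", "gap_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.hit_fraction <= 1:
            raise ValueError("hit_fraction must be in (0, 1]")

    def with_min_kb(self, min_kb: float) -> "RohParams":
        return RohParams(
            min_kb=min_kb,
            min_snps=self.min_snps,
            window_snps=self.window_snps,
            window_het_max=self.window_het_max,
            window_missing_max=self.window_missing_max,
            density_kb_per_snp=self.density_kb_per_snp,
            gap_kb=self.gap_kb,
            hit_fraction=self.hit_fraction,
        )


@dataclass(frozen=True)
class RohSegment:
    sample: str
    scaffold: str
    start: int  # position of first SNP, 1-based inclusive
    end: int  # position of last SNP
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RohCoverage:
    """Analyzable genome length for one minimum ROH length threshold."""

    min_kb: float
    total_bp: int
    per_scaffold: dict[str, int] = field(default_factory=dict)


def _detect_on_arrays(pos: np.ndarray, calls: np.ndarray, params: RohParams):
    """Segment spans on one scaffold; returns list of (i0, i1) SNP index runs."""
    n = len(pos)
    w = params.window_snps
    if n < w:
        return []
    het = (calls == 1).astype(np.int64)
    mis = (calls == MISSING).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_win = n - w + 1
    t = np.arange(n_win)
    ok = ((chet[t + w] - chet[t]) <= params.window_het_max) & (
        (cmis[t + w] - cmis[t]) <= params.window_missing_max
    )
    cok = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])

    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n_win - 1)
    total = hi - lo + 1
    n_ok = cok[hi + 1] - cok[lo]
    hit = n_ok / total >= params.hit_fraction

    # maximal runs of hits, split at large gaps
    runs = []
    gap_bp = params.gap_kb * 1000.0
    start = None
    for j in range(n):
        if hit[j]:
            if start is None:
                start = j
            elif pos[j] - pos[j - 1] > gap_bp:
                runs.append((start, j - 1))
                start = j
        elif start is not None:
            runs.append((start, j - 1))
            start = None
    if start is not None:
        runs.append((start, n - 1))

    kept = []
    for i0, i1 in runs:
        length = int(pos[i1] - pos[i0] + 1)
        n_snps = i1 - i0 + 1
        if length < params.min_kb * 1000.0:
            continue
        if n_snps < params.min_snps:
            continue
        if length / n_snps > params.density_kb_per_snp * 1000.0:
            continue
        kept.append((i0, i1, length, n_snps))
    return kept


def detect_roh(
    matrix: GenotypeMatrix, sample: str, params: RohParams | None = None
) -> list[RohSegment]:
    """Call ROH segments for one sample (see module docstring for rules)."""
    params = params or RohParams()
    row = matrix.calls[matrix.sample_indices([sample])[0], :]
    scaffolds = matrix.sites["scaffold"].to_numpy()
    positions = matrix.sites["pos"].to_numpy()
    segments: list[RohSegment] = []
    for scaffold in pd.unique(scaffolds):
        sel = scaffolds == scaffold
        pos = positions[sel]
        calls = row[sel]
        if len(pos) < params.window_snps:
            logger.debug(
                "detect_roh: scaffold %s has %d < %d SNPs, skipped",
                scaffold, len(pos), params.window_snps,
            )
            continue
        for i0, i1, _, n_snps in _detect_on_arrays(pos, calls, params):
            chunk = calls[i0 : i1 + 1]
            segments.append(
                RohSegment(
                    sample=sample,
                    scaffold=str(scaffold),
                    start=int(pos[i0]),
                    end=int(pos[i1]),
                    n_snps=n_snps,
                    n_het=int((chunk == 1).sum()),
                    n_missing=int((chunk == MISSING).sum()),
                )
            )
    return segments


_ARTIFICIAL = "__all_hom__"


def roh_coverage(
    matrix: GenotypeMatrix,
    params: RohParams | None = None,
    min_kb_variants=(100.0, 1000.0),
) -> dict[float, RohCoverage]:
    """Analysis coverage per minimum-length threshold.

    Runs detection on an artificial sample homozygous at every SNP; the
    summed segment length is the genome length with sufficient SNP
    density for ROH calling, the denominator of F_ROH.
    """
    params = params or RohParams()
    art = GenotypeMatrix(
        [_ARTIFICIAL],
        matrix.sites,
        np.zeros((1, matrix.n_sites), dtype=np.int8),
        matrix.scaffold_lengths,
    )
    out: dict[float, RohCoverage] = {}
    for min_kb in min_kb_variants:
        segs = detect_roh(art, _ARTIFICIAL, params.with_min_kb(min_kb))
        per_scaffold: dict[str, int] = {}
        for seg in segs:
            per_scaffold[seg.scaffold] = per_scaffold.get(seg.scaffold, 0) + seg.length_bp
        out[min_kb] = RohCoverage(
            min_kb=min_kb,
            total_bp=sum(per_scaffold.values()),
            per_scaffold=per_scaffold,
        )
    return out


def f_roh(segments: list[RohSegment], coverage: RohCoverage, min_kb: float) -> float:
    """Fraction of the analyzable genome inside segments >= ``min_kb``."""
    if coverage.total_bp <= 0:
        raise ValueError("coverage must be positive")
    total = sum(s.length_bp for s in segments if s.length_bp >= min_kb * 1000.0)
    return total / coverage.total_bp


def compare_f_roh(values: dict[str, float], popmap: PopulationMap) -> pd.DataFrame:
    """Per-population mean and sd of F_ROH (sd absent for n = 1)."""
    rows = [
        {"sample": s, "population": popmap.assignment[s], "f_roh": v}
        for s, v in values.items()
    ]
    df = pd.DataFrame(rows)
    agg = df.groupby("population")["f_roh"].agg(["mean", "std", "count"])
    return agg.rename(columns={"std": "sd", "count": "n"}).reset_index()


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    """PLINK .hom-style table: sample, scaffold, pos1, pos2, kb, nsnp."""
    return pd.DataFrame(
        [
            {
                "sample": s.sample,
                "scaffold": s.scaffold,
                "pos1": s.start,
                "pos2": s.end,
                "kb": s.length_bp / 1000.0,
                "nsnp": s.n_snps,
                "nhet": s.n_het,
                "nmiss": s.n_missing,
            }
            for s in segments
        ],
        columns=["sample", "scaffold", "pos1", "pos2", "kb", "nsnp", "nhet", "nmiss"],
    )
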
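"""Genotype containers and readers/writers for the formats the pipeline touches.

The central object is :class:`GenotypeMatrix`: diploid genotypes coded
0 (hom-ref), 1 (het), 2 (hom-alt) or :data:`MISSING` for samples x sites,
with per-site coordinates, alleles, aggregate read depth and the GATK
site annotations (QD, QUAL, SOR, FS, MQ, MQRankSum, ReadPosRankSum) that
the hard-filter stage consumes.

Coordinate conventions: VCF positions are 1-based inclusive internally;
BED intervals are 0-based half-open.  A site at position ``p`` falls in a
mask interval ``(start, end)`` iff ``start <= p - 1 < end``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "ANNOTATION_KEYS",
    "VariantSite",
    "GenotypeMatrix",
    "PopulationMap",
    "GenomicMask",
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "read_mask_bed",
]

#: Genotype code for a missing call (any GT containing '.').
MISSING = -1

#: INFO/QUAL annotations consumed by the hard-filter stage.
ANNOTATION_KEYS = ("QD", "QUAL", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

_SITE_COLUMNS = ["scaffold", "pos", "ref", "alt", "depth"]
_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP: coordinates, alleles, depth and filter annotations."""

    scaffold: str
    pos: int  # 1-based
    ref: str
    alt: str
    aggregate_depth: float = 0.0
    annotations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.scaffold}:{self.pos}")
        if self.aggregate_depth < 0:
            raise ValueError("aggregate_depth must be >= 0")


class GenotypeMatrix:
    """Diploid genotype calls for samples x sites plus site metadata.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    sites
        DataFrame with columns ``scaffold, pos, ref, alt, depth`` and one
        float column per annotation in :data:`ANNOTATION_KEYS` (NaN where
        the annotation is absent).  Rows must be sorted by (scaffold, pos).
    calls
        ``int8`` array of shape (n_samples, n_sites) with codes
        {0, 1, 2, MISSING}.
    scaffold_lengths
        Mapping scaffold name -> length in bp; every scaffold appearing in
        ``sites`` must be present.
    """

    def __init__(
        self,
        samples: list[str],
        sites: pd.DataFrame,
        calls: np.ndarray,
        scaffold_lengths: dict[str, int],
    ) -> None:
        sites = sites.reset_index(drop=True)
        for col in _SITE_COLUMNS:
            if col not in sites.columns:
                raise ValueError(f"sites missing required column {col!r}")
        for key in ANNOTATION_KEYS:
            if key not in sites.columns:
                sites[key] = np.nan
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(sites)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(sites)} sites"
            )
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers")
        missing_len = set(sites["scaffold"]) - set(scaffold_lengths)
        if missing_len:
            raise ValueError(f"no length recorded for scaffolds: {sorted(missing_len)}")
        # strict (scaffold, pos) ordering within scaffold
        if len(sites) > 1:
            same = sites["scaffold"].to_numpy()[1:] == sites["scaffold"].to_numpy()[:-1]
            dpos = np.diff(sites["pos"].to_numpy())
            if np.any(same & (dpos <= 0)):
                raise ValueError("sites must be strictly increasing within scaffold")
        self.samples = list(samples)
        self.sites = sites
        self.calls = calls
        self.scaffold_lengths = dict(scaffold_lengths)
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_indices(self, names) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def site_at(self, j: int) -> VariantSite:
        row = self.sites.iloc[j]
        ann = {
            k: float(row[k]) for k in ANNOTATION_KEYS if not np.isnan(row[k])
        }
        return VariantSite(
            scaffold=row["scaffold"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            aggregate_depth=float(row["depth"]),
            annotations=ann,
        )

    # -- subsetting ----------------------------------------------------------
    def take_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix with sites selected by boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.samples,
            self.sites.iloc[keep],
            self.calls[:, keep],
            self.scaffold_lengths,
        )

    def take_samples(self, names) -> "GenotypeMatrix":
        idx = self.sample_indices(names)
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.sites,
            self.calls[idx, :],
            self.scaffold_lengths,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
            and self.sites[_SITE_COLUMNS].equals(other.sites[_SITE_COLUMNS])
            and self.scaffold_lengths == other.scaffold_lengths
        )


@dataclass
class PopulationMap:
    """Assignment of sample identifiers to population labels."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        for sample, label in self.assignment.items():
            if not label:
                raise ValueError(f"empty population label for sample {sample!r}")

    @property
    def populations(self) -> list[str]:
        """Population labels in first-seen order."""
        seen: dict[str, None] = {}
        for label in self.assignment.values():
            seen.setdefault(label)
        return list(seen)

    def samples_in(self, label: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == label]

    def sizes(self) -> dict[str, int]:
        return {p: len(self.samples_in(p)) for p in self.populations}

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        unknown = set(self.assignment) - set(matrix.samples)
        if unknown:
            raise ValueError(f"popmap samples absent from matrix: {sorted(unknown)}")


class GenomicMask:
    """Exclusion intervals, normalized to sorted non-overlapping per scaffold."""

    def __init__(self, intervals) -> None:
        by_scaffold: dict[str, list[tuple[int, int]]] = {}
        for scaffold, start, end in intervals:
            if end <= start:
                raise ValueError(
                    f"degenerate interval {scaffold}:{start}-{end} (end <= start)"
                )
            by_scaffold.setdefault(scaffold, []).append((int(start), int(end)))
        self.intervals: dict[str, np.ndarray] = {}
        for scaffold, ivals in by_scaffold.items():
            ivals.sort()
            merged = [list(ivals[0])]
            for s, e in ivals[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self.intervals[scaffold] = np.array(merged, dtype=np.int64)

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def contains(self, scaffold: str, pos: np.ndarray) -> np.ndarray:
        """Vectorized membership for 1-based positions on one scaffold."""
        pos = np.asarray(pos, dtype=np.int64)
        ivals = self.intervals.get(scaffold)
        if ivals is None or len(ivals) == 0:
            return np.zeros(pos.shape, dtype=bool)
        zero_based = pos - 1
        k = np.searchsorted(ivals[:, 0], zero_based, side="right") - 1
        inside = k >= 0
        inside[inside] = zero_based[inside] < ivals[k[inside], 1]
        return inside


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_vcf(path: str, scaffold_lengths: dict[str, int] | None = None) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records, indels and symbolic alleles are dropped (not
    split).  Diploid GT fields map to {0, 1, 2}; any GT containing a
    missing allele maps to :data:`MISSING`; phasing is ignored.  Haploid
    or polyploid GTs raise.  Contig lengths come from the VCF header
    unless ``scaffold_lengths`` overrides them.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    lengths: dict[str, int] = {}
    if scaffold_lengths is None:
        try:
            seqlens = vcf.seqlens
        except AttributeError:  # header has no contig length lines
            seqlens = []
        for name, ln in zip(vcf.seqnames, seqlens):
            lengths[name] = int(ln)
    else:
        lengths = dict(scaffold_lengths)

    rows = []
    gcols = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue
        if ref.upper() not in _NUCLEOTIDES or alt.upper() not in _NUCLEOTIDES:
            continue
        codes = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid GT for sample {samples[i]} at "
                    f"{var.CHROM}:{var.POS}"
                )
            a, b = alleles
            if a < 0 or b < 0:
                codes[i] = MISSING
            else:
                if a > 1 or b > 1:
                    raise ValueError(
                        f"allele index >1 in biallelic record at {var.CHROM}:{var.POS}"
                    )
                codes[i] = a + b
        info = dict(var.INFO)
        depth = float(info.get("DP", 0.0))
        row = {
            "scaffold": var.CHROM,
            "pos": int(var.POS),
            "ref": ref,
            "alt": alt,
            "depth": depth,
        }
        for key in ANNOTATION_KEYS:
            if key == "QUAL":
                row[key] = float(var.QUAL) if var.QUAL is not None else np.nan
            else:
                val = info.get(key)
                row[key] = float(val) if val is not None else np.nan
        rows.append(row)
        gcols.append(codes)

    if rows:
        sites = pd.DataFrame(rows)
        calls = np.stack(gcols, axis=1)
    else:
        sites = pd.DataFrame(columns=_SITE_COLUMNS)
        sites["pos"] = sites.get("pos", pd.Series(dtype=np.int64))
        calls = np.zeros((len(samples), 0), dtype=np.int8)

    missing = set(sites["scaffold"]) - set(lengths) if len(sites) else set()
    if missing:
        raise ValueError(f"contig(s) without length in header: {sorted(missing)}")
    order = np.lexsort((sites["pos"].to_numpy(), sites["scaffold"].to_numpy())) if len(sites) else []
    if len(sites):
        sites = sites.iloc[order]
        calls = calls[:, order]
    return GenotypeMatrix(samples, sites, calls, lengths)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a minimal deterministic VCF 4.2 (GT-only FORMAT)."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
    for key in ANNOTATION_KEYS:
        if key == "QUAL":
            continue
        buf.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
    for scaffold in sorted(matrix.scaffold_lengths):
        buf.write(
            f"##contig=<ID={scaffold},length={matrix.scaffold_lengths[scaffold]}>\n"
        )
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
        + "\n"
    )
    sites = matrix.sites
    for j in range(matrix.n_sites):
        row = sites.iloc[j]
        qual = row["QUAL"]
        qual_str = "." if np.isnan(qual) else f"{qual:g}"
        info_parts = [f"DP={int(round(row['depth']))}"]
        for key in ANNOTATION_KEYS:
            if key == "QUAL":
                continue
            if not np.isnan(row[key]):
                info_parts.append(f"{key}={row[key]:g}")
        gts = "\t".join(_GT_STRINGS[int(c)] for c in matrix.calls[:, j])
        buf.write(
            f"{row['scaffold']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t"
            f"{qual_str}\tPASS\t{';'.join(info_parts)}\tGT\t{gts}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_population_map(path: str) -> PopulationMap:
    """Read a two-column whitespace-delimited sample -> population file."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 columns, got {len(parts)}")
            sample, pop = parts
            if sample in assignment:
                raise ValueError(f"line {lineno}: duplicate sample id {sample!r}")
            assignment[sample] = pop
    if not assignment:
        raise ValueError(f"empty population map: {path}")
    return PopulationMap(assignment)


def read_mask_bed(path: str) -> GenomicMask:
    """Read BED3 exclusion intervals (0-based half-open), merged and sorted."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected >=3 BED columns")
            scaffold, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"line {lineno}: end <= start ({start}, {end})")
            intervals.append((scaffold, start, end))
    return GenomicMask(intervals)
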
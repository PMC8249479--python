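"""Synthetic genotype and haplotype data with the statistical structure the
study design assumes: diverged populations under the Balding-Nichols
model, an admixed cohort, implanted autozygous tracts, missingness and
depth artifacts, and small mitochondrial haplotype sets.

Default configuration mirrors the study design this package targets:
three strongly diverged source populations (Balding-Nichols F = 0.18,
giving pairwise Weir-Cockerham F_ST around 0.17-0.20) of 20 diploids
each, plus six admixed individuals with ancestry (0.75, 0.13, 0.12);
50,000 unlinked SNPs over twenty 5-Mb scaffolds, which at ancestral
frequencies Uniform(0.05, 0.95) yields per-bp nucleotide diversity of
order 2 x 10^-4.  Sites are simulated unlinked; frequency-based
statistics do not need LD, and the LD-pruning step is exercised with
explicitly duplicated sites in its own tests.

Everything is deterministic under the provided seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_populations",
    "simulate_admixed",
    "implant_roh",
    "degrade",
    "simulate_mito",
    "study_mito_spec",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_populations: int = 3
    n_per_pop: int = 20
    fst: float = 0.18  # Balding-Nichols F, one value for every population
    n_sites: int = 50_000
    n_scaffolds: int = 20
    scaffold_bp: int = 5_000_000
    freq_low: float = 0.05  # ancestral-frequency law Uniform(low, high)
    freq_high: float = 0.95
    n_admixed: int = 6
    admixed_q: tuple[float, ...] = (0.75, 0.13, 0.12)
    missing_rate: float = 0.0
    mean_coverage: float = 16.9  # per-sample x, aggregate depth model
    depth_dispersion: float = 10.0  # negative-binomial shape
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_admixed and len(self.admixed_q) != self.n_populations:
            raise ValueError("admixed_q length must equal n_populations")
        if self.n_admixed and abs(sum(self.admixed_q) - 1.0) > 1e-9:
            raise ValueError("admixed_q must sum to 1")

    @property
    def population_labels(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_populations)]


@dataclass
class SimTruth:
    """Ground truth recorded alongside generated genotypes."""

    ancestral_freq: np.ndarray  # n_sites
    pop_freq: np.ndarray  # n_populations x n_sites
    q: dict[str, np.ndarray] = field(default_factory=dict)  # sample -> Q row
    roh_tracts: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    depth: np.ndarray | None = None


def _site_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Uniformly placed biallelic SNPs on the scaffold layout, sorted."""
    scaffold_ids = rng.integers(0, config.n_scaffolds, size=config.n_sites)
    pos = rng.integers(1, config.scaffold_bp + 1, size=config.n_sites)
    df = pd.DataFrame(
        {"scaffold": [f"scaf{w + 1:03d}" for w in scaffold_ids], "pos": pos}
    )
    df = df.drop_duplicates(["scaffold", "pos"]).sort_values(["scaffold", "pos"])
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=len(df))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(df))) % 4
    df["ref"] = bases[ref_idx]
    df["alt"] = bases[alt_idx]
    df["depth"] = 0.0
    return df.reset_index(drop=True)


def _simulate_depth(config: SimConfig, n_samples: int, n_sites: int, rng) -> np.ndarray:
    """Aggregate per-site depth: scaled negative binomial with heavy tails
    so the one-third/double depth filter has outliers to act on."""
    mean = config.mean_coverage * n_samples
    shape = config.depth_dispersion
    lam = rng.gamma(shape, mean / shape, size=n_sites)
    return rng.poisson(lam).astype(float)


def simulate_populations(config: SimConfig) -> tuple[GenotypeMatrix, PopulationMap, SimTruth]:
    """Balding-Nichols genotypes for the configured source populations.

    Per site, the ancestral frequency p is Uniform(freq_low, freq_high);
    each population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) (exactly
    p when F = 0) and genotypes are Binomial(2, p_pop) per individual.
    The admixed cohort, if configured, is appended via
    :func:`simulate_admixed`.
    """
    rng = np.random.default_rng(config.seed)
    sites = _site_table(config, rng)
    m = len(sites)
    p_anc = rng.uniform(config.freq_low, config.freq_high, size=m)

    if config.fst == 0.0:
        pop_freq = np.tile(p_anc, (config.n_populations, 1))
    else:
        ratio = (1.0 - config.fst) / config.fst
        pop_freq = rng.beta(
            p_anc * ratio, (1.0 - p_anc) * ratio, size=(config.n_populations, m)
        )

    blocks = []
    samples: list[str] = []
    assignment: dict[str, str] = {}
    for k, label in enumerate(config.population_labels):
        g = rng.binomial(2, pop_freq[k], size=(config.n_per_pop, m)).astype(np.int8)
        blocks.append(g)
        for i in range(config.n_per_pop):
            name = f"{label}_s{i + 1:02d}"
            samples.append(name)
            assignment[name] = label
    calls = np.vstack(blocks)

    truth = SimTruth(ancestral_freq=p_anc, pop_freq=pop_freq)
    for k, label in enumerate(config.population_labels):
        onehot = np.zeros(config.n_populations)
        onehot[k] = 1.0
        for name in (s for s in samples if assignment[s] == label):
            truth.q[name] = onehot

    n_total = len(samples) + config.n_admixed
    depth = _simulate_depth(config, n_total, m, rng)
    sites = sites.copy()
    sites["depth"] = depth
    truth.depth = depth

    lengths = {f"scaf{w + 1:03d}": config.scaffold_bp for w in range(config.n_scaffolds)}
    matrix = GenotypeMatrix(samples, sites, calls, lengths)

    if config.n_admixed > 0:
        matrix, assignment2, truth = simulate_admixed(config, matrix, truth, rng)
        assignment.update(assignment2)
    return matrix, PopulationMap(assignment), truth


def simulate_admixed(
    config: SimConfig,
    matrix: GenotypeMatrix,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, dict[str, str], SimTruth]:
    """Append the admixed cohort: each allele copy picks a source cluster
    with probability q_k, then is Bernoulli with that cluster's frequency."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    q = np.asarray(config.admixed_q, dtype=float)
    if abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("admixed Q row must sum to 1")
    m = matrix.n_sites
    rows = []
    names = []
    assignment = {}
    for i in range(config.n_admixed):
        sources = rng.choice(config.n_populations, size=(2, m), p=q)
        alleles = rng.random((2, m)) < np.take_along_axis(truth.pop_freq, sources, axis=0)
        g = alleles.sum(axis=0).astype(np.int8)
        name = f"admix_s{i + 1:02d}"
        rows.append(g)
        names.append(name)
        assignment[name] = "admixed"
        truth.q[name] = q.copy()
    calls = np.vstack([matrix.calls] + rows)
    out = GenotypeMatrix(
        matrix.samples + names, matrix.sites, calls, matrix.scaffold_lengths
    )
    return out, assignment, truth


def implant_roh(
    matrix: GenotypeMatrix,
    sample: str,
    tracts: list[tuple[str, int, int]],
    pop_freq: np.ndarray,
    het_error_rate: float = 0.0,
    seed: int = 0,
    truth: SimTruth | None = None,
) -> GenotypeMatrix:
    """Force autozygous tracts into one sample's genotypes.

    Within each (scaffold, start, end) tract every site is set homozygous
    for an allele drawn once from the population frequency at that site;
    ``het_error_rate`` flips calls back to heterozygous to mimic
    genotyping error.  Tracts must not overlap.
    """
    tracts = sorted(tracts)
    for (s1, a1, b1), (s2, a2, b2) in zip(tracts, tracts[1:]):
        if s1 == s2 and a2 <= b1:
            raise ValueError(f"overlapping tracts on {s1}: ({a1},{b1}) and ({a2},{b2})")
    for scaffold, start, end in tracts:
        if scaffold not in matrix.scaffold_lengths:
            raise ValueError(f"unknown scaffold {scaffold!r}")
        if start < 1 or end > matrix.scaffold_lengths[scaffold] or end < start:
            raise ValueError(f"tract ({scaffold},{start},{end}) out of bounds")

    rng = np.random.default_rng(seed)
    idx = matrix.sample_indices([sample])[0]
    calls = matrix.calls.copy()
    scaffolds = matrix.sites["scaffold"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    for scaffold, start, end in tracts:
        sel = np.flatnonzero((scaffolds == scaffold) & (pos >= start) & (pos <= end))
        hom = 2 * (rng.random(len(sel)) < pop_freq[sel]).astype(np.int8)
        if het_error_rate > 0:
            err = rng.random(len(sel)) < het_error_rate
            hom[err] = 1
        calls[idx, sel] = hom
    if truth is not None:
        truth.roh_tracts.setdefault(sample, []).extend(tracts)
    return GenotypeMatrix(matrix.samples, matrix.sites, calls, matrix.scaffold_lengths)


def degrade(
    matrix: GenotypeMatrix,
    missing_rate: float = 0.0,
    dropout_rate: float = 0.0,
    depth_model: tuple[float, float] | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Low-coverage artifacts: i.i.d. missingness, optional het->hom
    allele dropout, and optionally redrawn per-site aggregate depth
    given as (mean_aggregate, dispersion)."""
    if not 0 <= missing_rate < 1 or not 0 <= dropout_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    calls = matrix.calls.copy()
    if dropout_rate > 0:
        het = calls == 1
        flip = het & (rng.random(calls.shape) < dropout_rate)
        calls[flip] = np.where(rng.random(calls.shape) < 0.5, 0, 2)[flip]
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    sites = matrix.sites
    if depth_model is not None:
        mean, shape = depth_model
        lam = rng.gamma(shape, mean / shape, size=matrix.n_sites)
        sites = sites.copy()
        sites["depth"] = rng.poisson(lam).astype(float)
    return GenotypeMatrix(matrix.samples, sites, calls, matrix.scaffold_lengths)


def study_mito_spec() -> tuple[dict[str, set[int]], dict[str, dict[str, int]]]:
    """Haplotype substitution sets and carrier counts shaped like the
    study's mitochondrial result: a central haplotype with two one-step
    satellites, plus population-specific haplotypes at two and three
    steps (five haplotypes, seven segregating sites in total)."""
    positions = {
        "E1": set(),
        "E2": {101},
        "E3": {202},
        "B1": {303, 404},
        "M1": {505, 606, 707},
    }
    carriers = {
        "E1": {"Eman": 16},
        "E2": {"Eman": 3},
        "E3": {"Eman": 1},
        "B1": {"Baven": 20, "Helgea": 6},
        "M1": {"Mockeln": 20},
    }
    return positions, carriers


def simulate_mito(
    haplotype_positions: dict[str, set[int]],
    carriers_per_pop: dict[str, dict[str, int]],
    length: int = 16_524,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], PopulationMap]:
    """Aligned haplotype sequences with exact pairwise distances.

    Each haplotype is the random template with one fixed alternative base
    substituted at its positions, so the Hamming distance between two
    haplotypes is the size of the symmetric difference of their position
    sets.  Returns (id, sequence) records, one per carrier, plus the
    matching population map.
    """
    for hap, positions in haplotype_positions.items():
        positions = list(positions)
        if len(positions) != len(set(positions)):
            raise ValueError(f"duplicate substitution positions for {hap!r}")
    all_pos = sorted(set().union(*map(set, haplotype_positions.values())))
    if any(p < 0 or p >= length for p in all_pos):
        raise ValueError("substitution position outside sequence")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    template = bases[rng.integers(0, 4, size=length)]
    alt_at = {}
    for p in all_pos:
        choices = [b for b in "ACGT" if b != template[p]]
        alt_at[p] = choices[rng.integers(0, 3)]

    records: list[tuple[str, str]] = []
    assignment: dict[str, str] = {}
    for hap, positions in haplotype_positions.items():
        seq = template.copy()
        for p in positions:
            seq[p] = alt_at[p]
        seq_str = "".join(seq)
        for pop, n in carriers_per_pop.get(hap, {}).items():
            for i in range(n):
                name = f"{hap}_{pop}_{i + 1:02d}"
                records.append((name, seq_str))
                assignment[name] = pop
    return records, PopulationMap(assignment)


def write_mito_fasta(records: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
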
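"""End-to-end orchestration of the two analysis arms.

The *native* arm runs the filtering cascade, diversity statistics,
pairwise windowed F_ST, LD pruning, PCA with admixture cross-validation,
and ROH / F_ROH on the source populations.  The *downsampled* arm first
degrades genotypes (extra missingness and allele dropout standing in for
reduced sequencing depth), then repeats the cascade with the admixed
cohort included, equal-n resampled diversity, admixture, and the ROH
comparison across all groups.

Every stage's parameters and seeds are recorded in the JSON report, and
all tables are written as TSV, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import diversity, filtering, structure
from .differentiation import fst_windows
from .genotype_io import GenomicMask, GenotypeMatrix, PopulationMap, read_mask_bed, read_population_map, read_vcf
from .roh import RohParams, compare_f_roh, detect_roh, f_roh, roh_coverage, segments_to_frame

__all__ = ["RunConfig", "run_native_arm", "run_downsampled_arm"]


@dataclass
class RunConfig:
    """Inputs and per-stage parameters for one pipeline run."""

    out_dir: str
    vcf: str | None = None
    popmap: str | None = None
    mask_bed: str | None = None
    mean_coverage: float = 16.9
    window_bp: int = 10_000
    maf_min: float = 0.01
    call_rate_min: float = 0.90
    min_scaffold_bp: int = 10_000
    ld_window: int = 50
    ld_step: int = 5
    ld_r2: float = 0.5
    k_range: tuple[int, int] = (1, 6)
    cv_folds: int = 5
    resample_n: int = 6
    resample_reps: int = 100
    roh: RohParams = field(default_factory=RohParams)
    seed: int = 1
    admixed_population: str | None = None  # excluded from per-pop stats
    degrade_missing: float = 0.10
    degrade_dropout: float = 0.10

    def load_inputs(self) -> tuple[GenotypeMatrix, PopulationMap, GenomicMask | None]:
        if self.vcf is None or self.popmap is None:
            raise ValueError("vcf and popmap paths are required to load inputs")
        matrix = read_vcf(self.vcf)
        popmap = read_population_map(self.popmap)
        popmap.validate_against(matrix)
        mask = read_mask_bed(self.mask_bed) if self.mask_bed else None
        return matrix, popmap, mask


def _filter_cascade(matrix, mask, config: RunConfig):
    matrix, report = filtering.apply_hard_filters(matrix)
    thresholds = filtering.compute_depth_thresholds(
        config.mean_coverage, matrix.n_samples
    )
    matrix, rep = filtering.apply_depth_filter(matrix, thresholds)
    report = report + rep
    matrix, rep = filtering.apply_site_filters(
        matrix,
        mask=mask,
        maf_min=config.maf_min,
        call_rate_min=config.call_rate_min,
        min_scaffold_bp=config.min_scaffold_bp,
    )
    report = report + rep
    return matrix, report, thresholds


def _native_pops(popmap: PopulationMap, config: RunConfig) -> list[str]:
    return [p for p in popmap.populations if p != config.admixed_population]


def _restrict_popmap(popmap: PopulationMap, matrix: GenotypeMatrix) -> PopulationMap:
    """Drop popmap entries for samples absent from this arm's matrix."""
    present = set(matrix.samples)
    return PopulationMap({s: p for s, p in popmap.assignment.items() if s in present})


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def _structure_stage(matrix, config: RunConfig, out: Path, report: dict):
    pruned, prune_rep = filtering.ld_prune(
        matrix, window_snps=config.ld_window, step_snps=config.ld_step, r2_max=config.ld_r2
    )
    report["ld_prune"] = json.loads(prune_rep.to_json())
    pca_res = structure.pca(pruned, n_components=20)
    scores = pd.DataFrame(
        pca_res.coordinates,
        columns=[f"PC{i + 1}" for i in range(pca_res.n_components)],
    )
    scores.insert(0, "sample", pca_res.samples)
    _write(scores, out / "pca_scores.tsv")
    report["pca"] = {
        "explained_variance_fraction": pca_res.explained_variance_fraction.tolist()
    }
    lo, hi = config.k_range
    curve = structure.cv_curve(
        pruned, k_range=range(lo, hi + 1), n_folds=config.cv_folds, seed=config.seed
    )
    _write(
        pd.DataFrame(
            {"K": list(curve.errors), "cv_error": list(curve.errors.values())}
        ),
        out / "cv_curve.tsv",
    )
    best = structure.fit_admixture(pruned, curve.optimal_K, seed=config.seed)
    qdf = pd.DataFrame(best.Q, columns=[f"Q{k + 1}" for k in range(best.K)])
    qdf.insert(0, "sample", best.samples)
    _write(qdf, out / "admixture_Q.tsv")
    report["admixture"] = {
        "optimal_K": curve.optimal_K,
        "cv_errors": {str(k): v for k, v in curve.errors.items()},
        "loglik": best.loglik,
        "seed": config.seed,
    }
    return pruned, best


def _roh_stage(matrix, popmap, pops, config: RunConfig, out: Path, report: dict):
    coverage = roh_coverage(matrix, config.roh, min_kb_variants=(100.0, 1000.0))
    callable_genome = coverage[100.0].total_bp > 0
    segments = []
    froh100 = {}
    for pop in pops:
        for sample in popmap.samples_in(pop):
            segs = detect_roh(matrix, sample, config.roh)
            segments.extend(segs)
            # SNP density can be too sparse for any ROH calling; F_ROH is
            # then undefined rather than zero
            froh100[sample] = (
                f_roh(segs, coverage[100.0], 100.0) if callable_genome else None
            )
    _write(segments_to_frame(segments), out / "roh_segments.tsv")
    if callable_genome:
        table = compare_f_roh(froh100, popmap)
        _write(table, out / "f_roh_by_population.tsv")
    report["roh"] = {
        "coverage_bp": {str(k): c.total_bp for k, c in coverage.items()},
        "f_roh_100kb": froh100,
        "params": asdict(config.roh),
    }
    return froh100


def run_native_arm(
    config: RunConfig,
    matrix: GenotypeMatrix | None = None,
    popmap: PopulationMap | None = None,
    mask: GenomicMask | None = None,
) -> dict:
    """Filtering -> diversity -> F_ST -> PCA/admixture -> ROH on the
    native populations.  Inputs may be passed in memory or loaded from
    the configured paths.  Returns the report dict (also written to
    ``out_dir/report_native.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if matrix is None:
        matrix, popmap, mask = config.load_inputs()
    popmap = _restrict_popmap(popmap, matrix)
    popmap.validate_against(matrix)
    pops = _native_pops(popmap, config)
    report: dict = {"arm": "native", "seed": config.seed, "n_input_sites": matrix.n_sites}

    matrix, filter_report, thresholds = _filter_cascade(matrix, mask, config)
    report["filters"] = json.loads(filter_report.to_json(str(out / "filter_report.json")))
    report["depth_thresholds"] = asdict(thresholds)
    report["n_filtered_sites"] = matrix.n_sites

    report["diversity"] = {}
    for pop in pops:
        summary = diversity.diversity_summary(matrix, popmap, pop, config.window_bp)
        report["diversity"][pop] = {
            "pi": summary.pi,
            "H_mean": summary.H_mean,
            "H_sd": summary.H_sd,
            "P": summary.P,
            "denominator_snps": summary.denominator_snps,
        }

    report["fst"] = {}
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1 :]:
            res = fst_windows(
                matrix, popmap.samples_in(p1), popmap.samples_in(p2), config.window_bp
            )
            _write(
                pd.DataFrame(
                    [
                        {"scaffold": w.scaffold, "start": w.start, "end": w.end,
                         "fst": w.value, "n_snps": w.n_snps}
                        for w in res.windows
                    ]
                ),
                out / f"fst_{p1}_{p2}.tsv",
            )
            report["fst"][f"{p1}~{p2}"] = {
                "mean_of_windows": res.mean_of_windows,
                "overall_ratio": res.overall_ratio,
            }

    _structure_stage(matrix, config, out, report)
    _roh_stage(matrix, popmap, pops, config, out, report)

    with open(out / "report_native.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def run_downsampled_arm(
    config: RunConfig,
    matrix: GenotypeMatrix | None = None,
    popmap: PopulationMap | None = None,
    mask: GenomicMask | None = None,
) -> dict:
    """Degrade -> filter cascade -> equal-n resampled diversity ->
    admixture with the admixed cohort -> ROH comparison across groups."""
    from .synthetic_data import degrade

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if matrix is None:
        matrix, popmap, mask = config.load_inputs()
    popmap = _restrict_popmap(popmap, matrix)
    popmap.validate_against(matrix)
    pops = _native_pops(popmap, config)
    all_pops = popmap.populations
    report: dict = {
        "arm": "downsampled",
        "seed": config.seed,
        "n_input_sites": matrix.n_sites,
        "degrade": {
            "missing_rate": config.degrade_missing,
            "dropout_rate": config.degrade_dropout,
        },
    }

    matrix = degrade(
        matrix,
        missing_rate=config.degrade_missing,
        dropout_rate=config.degrade_dropout,
        seed=config.seed,
    )
    matrix, filter_report, thresholds = _filter_cascade(matrix, None if mask is None else mask, config)
    report["filters"] = json.loads(filter_report.to_json(str(out / "filter_report.json")))
    report["depth_thresholds"] = asdict(thresholds)
    report["n_filtered_sites"] = matrix.n_sites

    # equal-n resampled diversity for the native populations; the admixed
    # cohort is reported directly with its between-sample sd for H
    report["diversity"] = {}
    for stat in ("pi", "H", "P"):
        results = diversity.resample_equal_n(
            matrix, popmap, pops, stat,
            n_per_pop=config.resample_n, n_reps=config.resample_reps,
            seed=config.seed, window_bp=config.window_bp,
        )
        for pop, res in results.items():
            report["diversity"].setdefault(pop, {})[stat] = {
                "mean": res.mean, "sd": res.sd,
            }
    if config.admixed_population in all_pops:
        summary = diversity.diversity_summary(
            matrix, popmap, config.admixed_population, config.window_bp
        )
        report["diversity"][config.admixed_population] = {
            "pi": {"mean": summary.pi, "sd": None},
            "H": {"mean": summary.H_mean, "sd": summary.H_sd},
            "P": {"mean": summary.P, "sd": None},
        }

    _structure_stage(matrix, config, out, report)
    _roh_stage(matrix, popmap, all_pops, config, out, report)

    with open(out / "report_downsampled.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
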
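# Methods

This note documents the statistical models, the conventions and
numerical choices behind each module, what the synthetic-data generator
does and does not emulate, and the known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Genotype model and coordinates

Genotypes are strictly diploid codes 0 (hom-ref), 1 (het), 2 (hom-alt)
or missing; any GT containing a missing allele (including half-calls
like `./1`) is treated as missing, and haploid or multi-allelic GT
strings are an error rather than silently coerced. Multi-allelic VCF
records are dropped, not split: the analyses are defined on biallelic
SNPs only. Positions are 1-based inclusive internally; BED mask
intervals are 0-based half-open, and a site at position *p* is masked
iff `start <= p − 1 < end`, so the conversion between dialects happens
at exactly one point.

## Filtering cascade

The cascade order is fixed: hard filters → depth → mask → MAF →
call rate → scaffold length, with per-step before/removed/after counts
that telescope exactly, so any alternative ordering can be audited from
the report.

- **Hard filters.** A site is retained iff every *present* annotation
  satisfies its inequality (QD > 2, QUAL > 30, SOR < 3, FS < 60,
  MQ > 40, MQRankSum > −12.5, ReadPosRankSum > −8.0). Absent
  annotations pass, following the convention of the variant-calling
  toolchain that emits them: rank-sum annotations are undefined at
  sites without heterozygotes, and failing such sites would silently
  discard most of the homozygous spectrum.
- **Depth bounds.** The aggregate (summed-over-samples) depth must lie
  within [mean/3, 2·mean], where mean = per-sample coverage × sample
  count. Bounds are rounded to the nearest integer and are inclusive
  (e.g. 16.9× over 60 samples → aggregate mean 1014× → bounds 338 and
  2028). The lower bound removes spuriously mapped or partially
  covered sites, the upper bound collapsed repeats and organelle
  sequence.
- **Site filters.** MAF is computed over non-missing alleles and the
  boundary is kept (MAF = 0.01 passes, "lower than 0.01" fails);
  likewise call rate exactly 0.90 and scaffolds of exactly 10 kb pass.
- **LD pruning.** r² is the squared Pearson correlation of 0/1/2
  dosages over samples called at both sites (pairwise-complete).
  Windows of 50 SNPs advance 5 SNPs at a time within scaffolds; ordered
  pairs are scanned greedily and the *later* site of an offending pair
  is removed and excluded from later windows. This reproduces the
  PLINK `--indep-pairwise` behaviour that population-structure tools
  expect upstream.

## Diversity statistics

Per-site nucleotide diversity within a group is the unbiased mean
pairwise difference π = c₀c₁ / C(n, 2) over the group's called alleles
(n = c₀ + c₁). Windowed π sums per-site values over non-overlapping
10-kb windows anchored at position 1 of each scaffold and divides by the
*full* window length, matching the per-bp magnitudes produced by
VCFtools' `--window-pi`; windows containing no SNP are excluded from the
genome-wide mean because a SNP-only input cannot distinguish
"monomorphic" from "uncallable" there (including them as zeros would
change the average, which is why the convention is stated explicitly).
Sites with fewer than two called alleles are skipped and logged.

H is an individual's heterozygous-site count divided by the **joint**
SNP count across all populations, so missing sites deflate H; the
alternative denominator (called sites only) is available as an option.
P is the fraction of the joint SNP set with within-population π > 0.
Because both share the joint denominator, H and P are comparable across
populations but depend on the cohort composition of the SNP set.

The equal-n correction redraws, per replicate, a fixed number of
individuals (default 6, matching the smallest cohort) from each
population without replacement, recomputes the statistic on the
subsetted matrix, and reports mean ± sd over replicates (default 100).
Replicate RNG streams are spawned from one user seed, so a run is fully
reproducible and adding replicates does not perturb earlier ones.

## Weir–Cockerham F_ST

Per site, the 1984 variance components for r = 2 populations are
computed from per-population called sample sizes nᵢ, allele frequencies
pᵢ, and observed heterozygote fractions hᵢ, with individuals missing at
a site dropped from that site's nᵢ (pairwise-complete, as VCFtools
does). Sites monomorphic across both populations, or with no calls in
either population, or with n̄ ≤ 1, are flagged non-informative and
excluded from sums. The windowed estimator is the "weighted"
ratio-of-sums Σa/Σ(a+b+c) per 10-kb window; negative values are
preserved (clipping would bias downstream averages). Two genome-wide
summaries are reported: the unweighted mean over windows with at least
one informative site (the default) and the single pooled ratio over all
sites. The windowed mean is slightly attenuated relative to the pooled
ratio when windows contain few SNPs (a ratio-of-sums over ~5 sites is a
noisy ratio, and averaging noisy ratios is not the ratio of averages);
both are exposed so either convention can be matched.

The substructure test scores a proposed within-population split by its
genome-wide F_ST against a null of random equal-size splits of the same
samples (default 100 iterations), reporting the null vector and the
empirical quantile of the observed value. The null is computed with a
fast path that reuses the window index across iterations; results are
identical to the public windowed estimator.

## PCA and admixture

PCA standardizes dosages by site, (g − 2p̂)/√(2p̂(1−p̂)) with p̂ the
sample allele frequency, mean-imputes missing entries (zero after
centering), drops monomorphic sites with a log entry, and takes the SVD;
scores are left singular vectors scaled by singular values and explained
fractions are eigenvalue shares.

The admixture model is the standard binomial mixture: genotype g_ij ~
Binomial(2, Σ_k q_ik f_kj) with Q rows on the simplex and F entries in
(0, 1). Fitting uses multiplicative EM updates, which keep Q rows
summing to one by construction and are provably monotone in
log-likelihood — the monotonicity is asserted at every iteration as an
internal consistency check. This is the same likelihood the ADMIXTURE
software optimizes; EM trades its quasi-Newton acceleration for
simplicity, which is the right trade at desk scale. Defaults:
convergence when the log-likelihood gain drops below 1e-4, at most 2000
iterations, frequencies clamped to [1e-6, 1 − 1e-6], 5 random restarts
(Dirichlet Q, uniform F) with the best likelihood kept, all restart
seeds derived from one user seed. K = 1 is returned analytically
(Q ≡ 1, F = sample frequencies).

Cross-validation masks individual genotype *entries* (not whole
individuals), partitioned into 5 folds; each fold is masked, the model
refit, and masked entries scored by the mean binomial deviance of the
predicted dosage. CV runs with one restart, a looser tolerance (1e-3)
and a 500-iteration cap: model selection needs the error's ordering over
K, not a fully polished optimum, and the final model at the selected K
is always refit at full settings. Cluster labels are arbitrary, so
comparisons across runs first align columns by greedy maximal
correlation.

## Runs of homozygosity

Detection follows PLINK `--homozyg` semantics. Windows of 50 SNPs slide
one SNP at a time within a scaffold; a window is homozygous iff it has
at most 1 heterozygous and at most 5 missing calls; a SNP is a hit iff
at least 5% of the windows overlapping it are homozygous, where SNPs
near scaffold ends use only the windows that exist; maximal runs of
consecutive hits, split at inter-SNP gaps above 1000 kb, become
candidate segments; candidates are kept iff they span ≥ 100 kb, contain
≥ 50 SNPs and have at least one SNP per 50 kb (the density constraint is
per segment). Segment endpoints are the first and last SNP positions,
not window borders, and there is no segment-level heterozygote cap — the
window caps do that work. The window size (50) and hit fraction (0.05)
are the tool's defaults; the remaining parameters are the analysis
settings listed above. Scaffolds with fewer than 50 SNPs yield no calls
and are logged.

F_ROH divides a sample's summed segment length (at a given minimum
length) by the *analysis coverage*: the summed segment length obtained
by running the same detector on an artificial sample homozygous at every
SNP. This normalization (after Meyermans et al.'s recommendations for
PLINK-based ROH studies) makes F_ROH = 1 exactly for the artificial
sample and corrects for the genome fraction where SNP density is too
sparse for ROH detection at that length threshold.

## Haplotype network

Aligned sequences are collapsed to unique haplotypes with per-population
carrier counts. Alignment columns containing a gap in any sequence are
excluded from all distance computations, so indel columns cannot affect
the network; comparison is case-insensitive and non-ACGT symbols are
compared literally with a warning. The network is the ε = 0 minimum
spanning network — the union of all minimum spanning trees — built by
Kruskal growth over distance classes: within a class, every edge joining
components that were distinct at the start of the class is admitted. An
edge is flagged as lying in *every* MST iff it is a bridge of its
distance class (after contracting all lighter edges) with no tied
parallel edge. Median-joining inference of unobserved intermediate
haplotypes is deliberately not implemented; for the few-haplotype,
few-substitution sets this package targets, the plain MSN is the drawn
network.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
not sequences. Defaults are the emulated study design: three source
populations of 20 diploids under the Balding–Nichols model (population
frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency
p ~ Uniform(0.05, 0.95); F = 0.18, which the Weir–Cockerham estimator
reads back as pairwise F_ST ≈ 0.17–0.20), six admixed individuals whose
allele copies each pick a source with probability q_k (default
q = (0.75, 0.13, 0.12)), 50,000 SNPs uniformly placed on twenty 5-Mb
scaffolds — which at these frequencies yields per-bp π of order
1.5–2 × 10⁻⁴, the magnitude of a low-diversity vertebrate population.
The Uniform(0.05, 0.95) ancestral law avoids near-fixed sites whose
Beta parameters degenerate at small F. Aggregate depth is
gamma-Poisson (negative binomial, dispersion 10) around
coverage × samples, heavy-tailed enough to exercise the depth filter.
Autozygous tracts are implanted by forcing sites homozygous for an
allele drawn from the population frequency, with an optional rate of
heterozygous "error" calls; low-coverage arms are emulated by i.i.d.
missingness and het→hom allele dropout.

What the generator does **not** emulate: linkage disequilibrium (sites
are unlinked, so LD-pruning behaviour on realistic haplotype structure
is only exercised with constructed duplicated sites), mutation-model
detail (one alternative base per polymorphic position), mapping
artifacts correlated along the genome, and relatedness within
populations. Tests passing on this generator therefore validate the
estimators' algebra, conventions and parameter recovery under the
assumed sampling models — not robustness to the full error structure of
real resequencing data.

## Problem sizes and determinism

Simulation-based checks use 20,000–50,000 sites and 20–66 individuals —
large enough that estimator standard errors are well inside the asserted
tolerances, small enough for interactive runs. The admixture
cross-validation sweep (K = 1..6, 5 folds) is the most expensive stage
at a few minutes. Every stochastic component takes an explicit seed;
replicate streams are spawned with NumPy's `SeedSequence`, so all
results, including pipeline TSV outputs, are byte-stable under a fixed
seed. Calibration-style checks (the substructure null's coverage and
power) aggregate over 10–20 independently seeded runs and assert a
majority criterion, so they test the estimator rather than one draw.

## Known limitations

- F_ST is implemented for population pairs only; multi-population
  estimators and selection scans beyond windowed values are out of
  scope.
- ROH calling is the window heuristic, not an HMM; very short or very
  SNP-sparse autozygous tracts below the parameter floor are invisible
  by design.
- H and P depend on the joint SNP set's cohort composition; comparing
  values across differently filtered datasets requires the resampling
  correction the package provides.
- The admixture CV error is a model-selection device; its absolute value
  has no calibrated interpretation across datasets.
- Depth is modelled and filtered at the aggregate (site) level;
  per-sample depth fields are not consumed.
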
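# popkit

Post-variant-calling population genomics for conservation studies of
small, fragmented populations — the analysis stack behind whole-genome
resequencing surveys of the kind applied to the Swedish wels catfish
(*Silurus glanis*): a handful of isolated populations, tens of
individuals, hundreds of thousands of SNPs, and questions about
diversity, differentiation, admixture and inbreeding.

Starting from a jointly genotyped multi-sample VCF, a sample-to-population
map, and optionally a mappability mask and aligned mitochondrial
haplotypes, the package provides:

- **Filtering** — GATK-style hard filters (QD > 2, QUAL > 30, SOR < 3,
  FS < 60, MQ > 40, MQRankSum > −12.5, ReadPosRankSum > −8.0), aggregate
  read-depth bounds at one-third and double the aggregate mean,
  mappability-mask exclusion, minor-allele-frequency, call-rate and
  scaffold-length filters, and PLINK-style LD pruning
  (`--indep-pairwise` 50/5/0.5 semantics) — each step logged in a
  telescoping report.
- **Diversity** — nucleotide diversity π per site
  (π = c₀c₁/C(n,2) over a group's called alleles) summed in 10-kb
  windows and divided by window length; per-individual heterozygosity
  H (heterozygous sites over the joint SNP count); proportion of
  polymorphic sites P; and an equal-n resampling correction
  (100 draws of 6 individuals per population) for unequal sample sizes.
- **Differentiation** — Weir & Cockerham (1984) F_ST variance components
  (a, b, c) per site, "weighted" ratio-of-sums Σa/Σ(a+b+c) in 10-kb
  windows, genome-wide summaries, and a permutation null for
  within-population substructure (random equal splits vs a proposed
  split).
- **Structure** — PCA on standardized genotype dosages
  ((g − 2p̂)/√(2p̂(1−p̂)), mean-imputed), and a K-cluster admixture model
  (binomial likelihood over ancestry fractions Q and cluster frequencies
  F) fitted with monotone EM updates, with entry-masking cross-validation
  to select K.
- **Runs of homozygosity** — PLINK `--homozyg` sliding-window semantics
  (50-SNP windows, ≤1 het, ≤5 missing, hit fraction 0.05, ≥100 kb,
  ≥50 SNPs, ≥1 SNP/50 kb, 1000-kb gap limit), analysis-coverage
  normalization via an artificial all-homozygous sample, and
  F_ROH = ROH length / analyzable genome length.
- **Haplotype networks** — collapse aligned mitochondrial sequences into
  unique haplotypes and build the minimum spanning network (the union of
  all minimum spanning trees, with edges in *every* MST flagged).
- **Synthetic data** — a Balding–Nichols generator (per-population allele
  frequencies Beta(p(1−F)/F, (1−p)(1−F)/F)) with admixed cohorts,
  implanted autozygous tracts, missingness/depth/dropout artifacts and
  small mitochondrial haplotype sets, so the entire pipeline is testable
  without any sequence data.

## Worked example

Simulate the study design (three strongly diverged source populations of
20 diploids, six admixed individuals with ancestry 0.75/0.13/0.12) and
run the main analyses:

```python
from popkit import SimConfig, simulate_populations, fit_admixture
from popkit.differentiation import genomewide_fst
from popkit.diversity import diversity_summary
from popkit.structure import cv_curve

config = SimConfig(
    n_populations=3, n_per_pop=20, fst=0.18, n_sites=8_000,
    n_scaffolds=8, scaffold_bp=1_000_000,
    n_admixed=6, admixed_q=(0.75, 0.13, 0.12), seed=42,
)
matrix, popmap, truth = simulate_populations(config)

pops = ["pop1", "pop2", "pop3"]
for i, p1 in enumerate(pops):
    for p2 in pops[i + 1:]:
        fst = genomewide_fst(matrix, popmap.samples_in(p1), popmap.samples_in(p2))
        print(f"F_ST {p1}~{p2}: {fst:.3f}")

for pop in pops:
    s = diversity_summary(matrix, popmap, pop)
    print(f"{pop}: pi={s.pi:.2e}  H={s.H_mean:.3f}  P={s.P:.3f}")

curve = cv_curve(matrix, k_range=range(1, 5), seed=1)
print(f"optimal K by cross-validation: {curve.optimal_K}")

fit = fit_admixture(matrix, K=curve.optimal_K, seed=1)
mean_q = fit.mean_q(popmap.samples_in("admixed"))
print("mean ancestry of the admixed cohort:",
      [round(float(q), 3) for q in sorted(mean_q, reverse=True)])
```

Output:

```
F_ST pop1~pop2: 0.182
F_ST pop1~pop3: 0.183
F_ST pop2~pop3: 0.171
pop1: pi=2.98e-04  H=0.297  P=0.885
pop2: pi=2.95e-04  H=0.297  P=0.884
pop3: pi=2.95e-04  H=0.295  P=0.886
optimal K by cross-validation: 3
mean ancestry of the admixed cohort: [0.748, 0.142, 0.11]
```

The pairwise F_ST values recover the simulated divergence (F = 0.18);
per-bp π is at the magnitude expected for 8,000 segregating sites over
8 Mb; cross-validation identifies the three source clusters; and the
estimated mean ancestry of the admixed cohort matches the simulated
(0.75, 0.13, 0.12) mixture to within a percent or two.

The same stages are exposed on the command line (`popkit simulate`,
`popkit filter`, `popkit diversity`, `popkit fst`, `popkit substructure`,
`popkit structure`, `popkit roh`, `popkit haplonet`, `popkit run`); see
`popkit --help`.

## Layout

```
src/popkit/
  genotype_io.py     VCF/BED/popmap readers, genotype matrix, mask
  filtering.py       hard filters, depth bounds, site filters, LD pruning
  diversity.py       pi, H, P, equal-n resampling
  differentiation.py Weir-Cockerham F_ST, windows, substructure null
  structure.py       PCA, admixture EM, cross-validation
  roh.py             ROH calling, analysis coverage, F_ROH
  haplonet.py        haplotype collapse, minimum spanning network
  synthetic_data.py  Balding-Nichols simulator, tract implanting, mito sets
  pipeline.py        native and downsampled analysis arms
  cli.py             command-line interface
docs/methods.md      models, parameters, numerical choices, limitations
tests/               pytest suite with independent oracles
```
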
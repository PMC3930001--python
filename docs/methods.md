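# Methods

This note documents the models, the defaults and the judgement calls behind
`ldpanel`, in the spirit of a package vignette: what is computed, under which
assumptions, and what the synthetic experiments do and do not demonstrate.

## Data model and coding

Genotypes are biallelic allele counts: 0 = homozygote for allele A, 1 =
heterozygote, 2 = homozygote for allele B, −1 = missing. Allele A is the
recorded orientation of the SNP — by default the major allele in the
population the data were read from, pinned per SNP by a `.ref` sidecar so
the coding survives write/read cycles. The orientation choice affects the
*sign* of genotype correlations only, never their square or any concordance
measure. Coordinates are 1-based bp, PLINK-text style; genetic coordinates
(Morgan) travel in an optional `morgan` column, and the physical scale is
1 Morgan ≈ 100 Mb whenever no genetic map is available.

## Quality control

SNPs genotyped in less than 95% of the designated design set, or with MAF
below 0.01 there, are excluded (both comparisons strict). QC is deliberately
computed on the *panel-design* subset only and the surviving SNP list is
then imposed on the reference and test sets, mirroring the intended field
workflow where the design set is the only data available at design time.
SNPs that later turn out monomorphic in the reference are still imputed,
flagged, and excluded from correlation (not concordance) metrics.

## LDU maps

The LD-unit map summarises how fast allelic association decays along a
chromosome. Under the Malecot model the association at distance *d* is
ρ(d) = (1 − L)·M·e^(−εd) + L, with intercept M, residual (asymptotic)
association L, and per-bp decline rate ε. Expressing positions in LDU
(cumulative ε·d) makes the expected association decline by a factor *e* per
unit everywhere, so high-LD blocks are LDU-flat and recombination hotspots
are LDU-steep.

Construction per chromosome:

1. |D′| for every SNP pair closer than `max_pair_bp` (default 500 kb), with
   two-locus haplotype frequencies estimated from unphased genotypes by EM
   (only the double heterozygote is phase-ambiguous); pairs with boundary
   marginals are skipped and counted.
2. M = 1 (single-origin assumption for a young closed breed); L = mean |D′|
   of pairs in the top distance decile, i.e. the empirical association floor
   at the scale examined.
3. Interval LDU lengths xᵢ = εᵢ·dᵢ ≥ 0 fitted by cyclic coordinate descent
   on Σ_pairs (ρ_pred − |D′|)². Each update is exact: substituting
   u = e^(−xₖ) makes the residuals linear in u, so the constrained optimum
   is a clipped least-squares ratio. Intervals are capped at 30 LDU
   (associations below e⁻³⁰ are indistinguishable from the floor);
   convergence is declared at max|Δx| < 1e−8, with a warning and a flagged
   best-so-far map otherwise.
4. LDU positions are the cumulative sums; ties in the resulting coordinate
   are broken by +10⁻⁶ per run member before panel selection so SNP order
   stays consistent with the physical map.

This is a deliberately simplified re-implementation of the LD-map idea, not
a claim of numerical equivalence with the LDMAP program (whose composite-
likelihood χ² weighting and exact settings are not reproduced). The tests
therefore check *structural* truth recovery — hotspots absorb the span,
uniform recombination gives a near-linear map — rather than absolute LDU
values.

## Panel design

Panel sizes per chromosome are allocated by largest remainder proportional
to bp length, minimum 2 per chromosome. Density is reported Ne-normalised
(panel SNPs per Morgan divided by Ne), the scale on which imputation
performance is comparable across populations and species.

`bpEQ` solves the boundary-nearest problem exactly: an O(n·m) dynamic
programme assigns the n equally spaced boundaries (anchored at the first and
last SNP) to distinct SNPs minimising total distance, ties resolved to the
lower bp. `bpMAF`/`lduMAF` minimise

    Σᵢ (0.5 − MAFᵢ)² + λ Σᵢ ((Sᵢ₊₁ − Sᵢ)/d − 1)²

with the chromosome-end SNPs forced in. The spacing deviation is divided by
the ideal spacing d before squaring; a raw squared-bp deviation would exceed
the MAF term (≤ 0.25 per SNP) by ~12 orders of magnitude and silence the MAF
objective entirely. λ defaults to 1, making a one-ideal-spacing error
comparable to the worst possible MAF penalty of four SNPs.

The optimiser is a steady-state genetic algorithm over interior panel slots
(slot = index of the chosen SNP): population 60, 300 generations, tournament
size 3, one-point crossover 0.9 with sort/deduplicate/refill repair,
per-gene mutation 0.1 to a nearby SNP (±5 indices), elitism, early stop
after 50 stagnant generations. The final solution — and, separately, the
bpEQ start — is polished by best-improvement single-SNP relocation (remove
one panel SNP, insert the best unused SNP anywhere; deltas are local so a
sweep is O(m)) and the cheaper local optimum is returned. Because the bpEQ
solution seeds the initial population and survives elitism, the returned
cost never exceeds the bpEQ cost under the same objective.

## Imputation

### Random baseline

Each masked genotype is drawn from the Hardy–Weinberg proportions of the
reference allele frequency. Its expected concordance with an HWE truth is
Σ_g P(g)² = p⁴ + 4p²q² + q⁴ — the chance floor that makes raw concordance
flattering for low-MAF SNPs, and the denominator of the adjusted accuracy
(acc − rand)/(1 − rand).

### Haplotype-copying HMM

The engine is a diploid Li–Stephens model: the hidden state is an ordered
pair of template haplotypes from the phased reference; each chromosome of
the test individual switches template independently between adjacent
informative sites with probability 1 − e^(−ρΔ), Δ the genetic distance and
ρ = 4·Ne/K the switch intensity per Morgan for K templates. Emissions at
observed panel sites compare the implied genotype (template dosage) with the
observation under per-allele error e. Because the single-chromosome
transition is (1 − r)·I + (r/K)·J, the joint K²-state propagation costs
O(K²), and transitions compose exactly across silent sites, so masked sites
between informative sites receive exact posteriors by decaying the forward
mass from the left and the backward mass from the right. Posterior genotype
triples aggregate the state posterior by template-allele class; the imputed
genotype is the posterior argmax, ties broken toward the reference-frequent
genotype.

Defaults: K = 60 templates, e = 0.002, Ne = 150, 1 cM/Mb when no genetic
map is supplied. Templates are chosen **per individual** as the K reference
haplotypes most consistent with the individual's observed panel genotypes
(homozygous sites decisive, heterozygous neutral), the same idea as
IMPUTE2's custom reference subsets. A seeded random subsample is available
(`template_selection="random"`) but discards most of a large reference's
information: on the headline scenario below it costs ~13 points of
concordance at K = 60. An adapter for an external imputation executable
(write PLINK text, run, parse back) is provided for benchmarking but is
never required.

The engine consumes *phased* references; synthetic data carries truth
phase. Statistical phasing of real unphased references is out of scope and
delegated to external tools.

## Synthetic populations

The generator emulates the demography the analysis depends on: founder
haplotypes from a neutral coalescent (msprime; ancestral population size
1000, the pre-breed-formation scale) bottlenecked through a 28-founder pool
~30 generations ago, then random mating at Ne = 150 with Poisson crossovers.
A final cohort (default 853 individuals, matching the splits used
throughout) is drawn as offspring of the last breeding generation, since a
sampled cohort can exceed the breeding effective size. SNPs are ascertained
chip-style — MAF ≥ 0.05 at sampling time, thinned evenly to the target
density (default 1300/Morgan, the post-QC density of a 50K chip scaled to a
~28-Morgan genome). Recombination heterogeneity (centromeric low-recomb
cores, hotspots) enters through a per-chromosome relative-rate profile
applied consistently to the coalescent RateMap and the forward crossovers.
Population splits duplicate the breeding pool `split_generations` ago with
symmetric migration; half-sib families breed extra offspring from shared
sires with the truth pedigree recorded.

Realized LD matches published chip-based Thoroughbred estimates in order of
magnitude (r² ≈ 0.3 within 50 kb, ≈ 0.1 at 0.2–1 Mb, long-range excess from
the founder bottleneck), and the ascertained MAF spectrum has mean ≈ 0.23.

What the generator does **not** emulate: selection, sex chromosomes,
genotyping error patterns of real chips, pedigree structure beyond half-sib
families, and fine-scale hotspot architecture. Passing tests on this
synthetic material therefore demonstrate internal correctness and the
qualitative orderings (density trends, method contrasts, relatedness
benefits), not field-accurate absolute error rates.

## Experiment designs and problem sizes

The within-population experiment follows the canonical data flow: split the
cohort 200 (panel design) / 75% (reference) / 25% (test) — 853 samples give
200/490/163 — QC on the design set, panels per method × density from the
design set, mask the test set, impute from the reference with both engines,
score per SNP and per individual. The between-population variant selects
panels from population 1's design set throughout and compares imputing
population 2 from population 1's reference against a 75/25
reference/test split within population 2 (the relatedness-benefit design).

The test suite runs the headline scenario at full scale (1 Morgan,
~1300 SNPs, 853 samples) and the density-trend and LDU experiments on
smaller chromosomes (0.2–0.5 Morgan, 300–500 samples) — sizes chosen so the
whole suite completes in minutes while keeping every qualitative contrast
the experiments are meant to show. The acceptance script averages the
headline concordance over three replicate seeds.

## Numerical choices and degenerate inputs

* Two-locus EM starts at linkage equilibrium, tolerance 1e−12, ≤500
  iterations; monomorphic loci raise a degenerate-input error.
* |D′| uses the standard Lewontin normalisation; boundary marginals are
  undefined (skipped with a count in map construction).
* Posterior triples are renormalised per cell; exact ties in the argmax are
  broken by an infinitesimal tilt toward the reference-frequent genotype.
* Sample splits round fractional sizes to nearest, remainder to the last
  set (653 × 0.75 → 490).
* An all-missing chromosome in a test individual falls back to reference
  HWE proportions with a warning; K capped at the available haplotypes.
* Every stochastic component (simulation, splits, GA, template subsampling,
  random engine) is driven by an explicit integer seed; same seed, same
  output, bit for bit.

## Known limitations

* The LDU map is interval-resolution only and inherits the marker density;
  it is a proxy for recombination-scaled distance, not a linkage map.
* The haplotype-copying engine is a transparent stand-in for production
  imputation software; it has no haplotype-cluster model, no genotype-
  likelihood input, and no phasing of unphased references.
* The GA is a heuristic: it is guaranteed no worse than bpEQ under its own
  objective and is polished to a 1-move local optimum, but global optimality
  is not claimed.
* Between-population experiments currently require the built-in simulator;
  wiring two real PLINK filesets into that design is plumbing left undone.
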
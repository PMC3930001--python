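# ldpanel

Low-density SNP panel design and genotype-imputation accuracy evaluation for
livestock populations, built around the Thoroughbred horse use case: a breed
founded ~30 generations ago from a small founder pool and maintained at a
small effective size (Ne ≈ 150), whose strong linkage disequilibrium makes it
possible to genotype selection candidates on a cheap low-density panel (LDP)
and impute the remaining chip genotypes from a high-density reference
population.

The package answers the practical design questions: **which SNPs should go on
the low-density panel, and how accurate is imputation from it?**

## What it does

* **Panel selection** (per chromosome, sizes allocated ∝ bp length):
  * `bpEQ` — equidistant in base pairs: the SNP nearest each of
    *n* equally spaced boundaries, irrespective of MAF;
  * `bpMAF` — a genetic algorithm minimising
    `Σᵢ (0.5 − MAFᵢ)² + λ Σᵢ ((Sᵢ₊₁ − Sᵢ)/d − 1)²`, with
    `d = len_chr/(n_chr − 1)` the ideal spacing and the outermost chromosome
    SNPs always included (telomere rule);
  * `lduMAF` — the same objective with SNP coordinates in
    linkage-disequilibrium units (LDU) instead of bp, so panels are spaced
    uniformly in LD-map distance.
* **LDU maps** from unphased genotypes: pairwise |D′| via two-locus EM, then
  per-interval decline rates fitted under the Malecot model
  `ρ(d) = (1 − L)·M·e^(−εd) + L`, accumulated into an additive LDU
  coordinate.
* **Imputation**: a diploid Li–Stephens haplotype-copying HMM (forward–
  backward posteriors over ordered template-haplotype pairs, switch rate
  `1 − e^(−ρΔ)`), plus the random Hardy–Weinberg baseline whose expected
  per-SNP concordance has the closed form `p⁴ + 4p²q² + q⁴`.
* **Accuracy metrics** per SNP and per individual: proportion of genotypes
  correctly imputed, correlation of true and imputed allele counts
  (monomorphic vectors excluded), and the MAF-adjusted accuracy
  `(acc − rand)/(1 − rand)`.
* **Synthetic populations**: msprime founder haplotypes propagated through a
  forward Wright–Fisher simulation with chip-style SNP ascertainment,
  recombination-rate heterogeneity, population splits and half-sib families —
  so every stage is testable against known truth.
* **Experiment orchestration**: within-population (design/reference/test
  split A/B/C) and between-population (reference from population 1 vs a D/E
  split of population 2) grids over method × density × engine.

## Worked example

```python
from ldpanel import (SimConfig, simulate_population, split_samples,
                     filter_snps, design_panel, mask_to_panel,
                     impute_hmm, impute_random, HmmParams,
                     build_accuracy_report)
from ldpanel.qc import allele_b_freq

# a Thoroughbred-like cohort: Ne=150, 28 founders, 30 generations,
# one 1-Morgan chromosome with ~1300 chip-ascertained SNPs, 853 samples
gm, markers = simulate_population(SimConfig(seed=1))

split = split_samples(gm.sample_ids, [200, 0.75, 0.25], seed=1)
A, B, C = (gm.take_samples(split.set(x)) for x in "ABC")   # 200 / 490 / 163

_, qc = filter_snps(A)                   # call rate >= 95%, MAF >= 0.01
keep = gm.markers.index_of(qc.kept_snp_ids)
A, B, C = (s.take_snps(keep) for s in (A, B, C))

panel = design_panel(A, "bpMAF", 36, seed=1)   # 0.24 Ne SNPs/Morgan
masked = mask_to_panel(C, panel)               # test set sees panel SNPs only
result = impute_hmm(masked, B, HmmParams(seed=1))

report = build_accuracy_report(C, result, masked.genotypes == -1,
                               allele_b_freq(B))
print("per-SNP accuracy:", report.summary_line())
```

Output:

```
per-SNP accuracy: 0.90 (0.66, 1.00)
```

i.e. with only 36 of ~1300 SNPs genotyped, a mean 90% of the masked
genotypes are imputed correctly (the worst SNP reaches 66%, the best 100%).
The random baseline on the same mask scores 0.54 (0.28, 0.86), matching the
`p⁴ + 4p²q² + q⁴` expectation at these allele frequencies — the gap is what
the haplotype structure buys.

A command-line interface mirrors the library
(`ldpanel simulate|qc|ldmap|select|mask|impute|evaluate|run-experiment`).

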
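"""Synthetic Thoroughbred-like populations for end-to-end pipeline testing.

The emulated demography: a breed founded ~30 generations ago from a small
founder pool (effective studbook founder number ~28) drawn out of a larger
ancestral population, then maintained at an effective size of Ne = 150 under
random mating.  Founder haplotypes come from a neutral coalescent
(msprime) with a recombination RateMap, so founder LD reflects the ancestral
population; the bottleneck plus the forward Wright–Fisher generations build
up the strong recent LD that makes low-density-panel imputation work in this
breed.  SNPs are ascertained chip-style: only sites common at sampling time
(MAF above a threshold) enter the marker map, thinned to a target density
with roughly even physical spacing.

Physical scale is fixed at 1 Morgan = 100 Mb on average; ``recomb_profile``
redistributes that genetic length over equal-bp segments to emulate
centromeric low-recombination regions or hotspots.  Truth phase, truth
Morgan coordinates, the population split and half-sib family structure are
all retained so downstream accuracy can be scored against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np
import pandas as pd

from .data import GenotypeMatrix, MarkerMap

_BP_PER_MORGAN = 100_000_000


@dataclass
class SimConfig:
    ne: int = 150
    founder_pool: int = 28
    generations_since_founding: int = 30
    chrom_morgans: tuple = (1.0,)
    snp_density_per_morgan: float = 1300.0
    maf_min_ascertained: float = 0.05
    recomb_profile: tuple | None = None  # per chromosome: relative rates, equal-bp segments
    split_generations: int = 0
    migration_rate: float = 0.0
    half_sib_families: tuple | None = None  # (n_families, family_size)
    n_samples: int = 853
    ancestral_ne: float = 1000.0
    mutation_oversample: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if min(self.chrom_morgans) <= 0:
            raise ValueError("chromosome lengths must be positive")
        if self.recomb_profile is not None:
            if len(self.recomb_profile) != len(self.chrom_morgans):
                raise ValueError("recomb_profile must have one entry per chromosome")
            for rates in self.recomb_profile:
                rates = np.asarray(rates, dtype=float)
                if (rates < 0).any() or rates.sum() <= 0:
                    raise ValueError("recombination rates must be non-negative, not all zero")
        if self.split_generations > self.generations_since_founding:
            raise ValueError("split_generations cannot exceed generations_since_founding")
        if not (0 <= self.migration_rate <= 1):
            raise ValueError("migration_rate must lie in [0, 1]")


class _Chromosome:
    """Per-chromosome founder haplotypes and genetic coordinates."""

    def __init__(self, name: str, morgans: float, profile, ancestral_ne: float,
                 n_founders: int, mu: float, seed: int):
        self.name = name
        self.morgans = morgans
        length_bp = int(round(morgans * _BP_PER_MORGAN))
        if profile is None:
            profile = np.ones(1)
        profile = np.asarray(profile, dtype=float)
        weights = profile / profile.sum()  # fraction of genetic length per segment
        edges = np.linspace(0, length_bp, len(weights) + 1)
        seg_bp = np.diff(edges)
        rates = morgans * weights / seg_bp  # Morgans per bp
        self.rate_map = msprime.RateMap(position=edges, rate=rates)

        ts = msprime.sim_ancestry(
            samples=n_founders,
            population_size=ancestral_ne,
            sequence_length=length_bp,
            recombination_rate=self.rate_map,
            random_seed=seed,
        )
        ts = msprime.sim_mutations(
            ts, rate=mu, random_seed=seed + 1,
            model=msprime.BinaryMutationModel(),
        )
        positions, cols = [], []
        gmat = ts.genotype_matrix()  # sites x haplotypes
        prev = -1
        for k, site in enumerate(ts.sites()):
            pos = int(site.position)
            if pos == prev:
                continue  # discrete-genome duplicate
            col = gmat[k]
            if col.max() > 1 or col.min() < 0:
                continue
            if 0 < col.sum() < len(col):
                positions.append(pos)
                cols.append(col)
                prev = pos
        self.bp = np.asarray(positions, dtype=np.int64)
        self.founder_haps = (
            np.asarray(cols, dtype=np.int8).T if cols else
            np.empty((2 * n_founders, 0), np.int8)
        )
        # cumulative Morgan coordinate of each site
        self.morgan_pos = np.asarray(self.rate_map.get_cumulative_mass(self.bp.astype(float)))

    def gametes(self, haps: np.ndarray, parents: np.ndarray, rng: np.random.Generator
                ) -> np.ndarray:
        """One recombinant gamete per entry of ``parents`` (individual indices
        into ``haps``, which is laid out as rows 2i / 2i+1)."""
        n_sites = haps.shape[1]
        out = np.empty((len(parents), n_sites), dtype=np.int8)
        n_cross = rng.poisson(self.morgans, size=len(parents))
        starts = rng.integers(0, 2, size=len(parents))
        total = self.morgan_pos[-1] if n_sites else 0.0
        for i, par in enumerate(parents):
            h0 = haps[2 * par + starts[i]]
            if n_cross[i] == 0 or n_sites == 0:
                out[i] = h0
                continue
            points = np.sort(rng.uniform(0.0, self.morgans, size=n_cross[i]))
            # phase flips at each crossover; map Morgan points to site indices
            flips = np.searchsorted(self.morgan_pos, points)
            counts = np.zeros(n_sites + 1, dtype=np.int64)
            np.add.at(counts, flips, 1)
            phase = np.cumsum(counts[:-1]) % 2
            h1 = haps[2 * par + 1 - starts[i]]
            out[i] = np.where(phase == 0, h0, h1)
        return out


class _Simulator:
    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.rng = rng
        target_per_morgan = cfg.snp_density_per_morgan
        self.chromosomes: list[_Chromosome] = []
        for c, morgans in enumerate(cfg.chrom_morgans):
            profile = None if cfg.recomb_profile is None else cfg.recomb_profile[c]
            n = 2 * cfg.founder_pool
            harmonic = np.sum(1.0 / np.arange(1, n))
            target = target_per_morgan * morgans
            length_bp = morgans * _BP_PER_MORGAN
            mu = cfg.mutation_oversample * target / (
                4 * cfg.ancestral_ne * length_bp * harmonic
            )
            self.chromosomes.append(
                _Chromosome(
                    str(c + 1), morgans, profile, cfg.ancestral_ne,
                    cfg.founder_pool, mu,
                    seed=int(rng.integers(1, 2**31 - 2)),
                )
            )
        self.site_slices = []
        start = 0
        for ch in self.chromosomes:
            self.site_slices.append(slice(start, start + len(ch.bp)))
            start += len(ch.bp)
        self.n_sites = start

    def founders(self) -> np.ndarray:
        return np.concatenate([ch.founder_haps for ch in self.chromosomes], axis=1)

    def offspring(self, haps: np.ndarray, mothers: np.ndarray, fathers: np.ndarray
                  ) -> np.ndarray:
        """Diploid offspring haplotypes (2*n_off x sites) from parent indices."""
        n_off = len(mothers)
        out = np.empty((2 * n_off, self.n_sites), dtype=np.int8)
        for ch, sl in zip(self.chromosomes, self.site_slices):
            out[0::2, sl] = ch.gametes(haps[:, sl], mothers, self.rng)
            out[1::2, sl] = ch.gametes(haps[:, sl], fathers, self.rng)
        return out

    def random_mating(self, haps: np.ndarray, n_off: int, n_parents: int) -> np.ndarray:
        mothers = self.rng.integers(0, n_parents, size=n_off)
        fathers = self.rng.integers(0, n_parents, size=n_off)
        return self.offspring(haps, mothers, fathers)

    def marker_map(self, keep: np.ndarray) -> MarkerMap:
        rows = []
        for ch, sl in zip(self.chromosomes, self.site_slices):
            for local, j in enumerate(range(sl.start, sl.stop)):
                if not keep[j]:
                    continue
                rows.append(
                    (
                        f"c{ch.name}_s{local}", ch.name, int(ch.bp[local]),
                        "A", "B", float(ch.morgan_pos[local]),
                    )
                )
        df = pd.DataFrame(
            rows, columns=["snp_id", "chromosome", "bp", "allele_a", "allele_b", "morgan"]
        )
        return MarkerMap(df)


def _ascertain(freqs: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Chip-style site selection: common sites, thinned evenly to the target count."""
    maf = np.minimum(freqs, 1 - freqs)
    eligible = np.flatnonzero(maf >= cfg.maf_min_ascertained)
    target = int(round(cfg.snp_density_per_morgan * sum(cfg.chrom_morgans)))
    if len(eligible) < target:
        raise RuntimeError(
            f"only {len(eligible)} sites pass MAF ascertainment but {target} were "
            "requested; increase founder_pool/mutation_oversample or lower the density"
        )
    ranks = np.round(np.linspace(0, len(eligible) - 1, target)).astype(int)
    return eligible[np.unique(ranks)]


def _to_genotype_matrix(
    sim: _Simulator, haps: np.ndarray, keep: np.ndarray, sample_prefix: str
) -> tuple[GenotypeMatrix, MarkerMap]:
    sub = haps[:, keep]
    freqs = sub.mean(axis=0)
    flip = freqs > 0.5  # allele A = major allele in the sampled cohort
    sub = np.where(flip[None, :], 1 - sub, sub).astype(np.int8)
    keep_mask = np.zeros(sim.n_sites, dtype=bool)
    keep_mask[keep] = True
    markers = sim.marker_map(keep_mask)
    genotypes = sub[0::2] + sub[1::2]
    n = genotypes.shape[0]
    ids = [f"{sample_prefix}{i:04d}" for i in range(n)]
    return GenotypeMatrix(ids, markers, genotypes, haplotypes=sub), markers


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, MarkerMap]:
    """Simulate one random-mating population and sample a final cohort.

    Returns a phased GenotypeMatrix of ``cfg.n_samples`` individuals (drawn
    as offspring of the last breeding generation) and a MarkerMap carrying
    truth Morgan coordinates.  Same seed, same output, bit for bit.
    """
    sim = _Simulator(cfg)
    haps = sim.founders()
    n_parents = cfg.founder_pool
    for _ in range(cfg.generations_since_founding):
        haps = sim.random_mating(haps, cfg.ne, n_parents)
        n_parents = cfg.ne
    cohort = sim.random_mating(haps, cfg.n_samples, n_parents)
    freqs = cohort.mean(axis=0)
    keep = _ascertain(freqs, cfg)
    return _to_genotype_matrix(sim, cohort, keep, "ind")


def simulate_split_populations(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, GenotypeMatrix, MarkerMap]:
    """Two populations splitting ``cfg.split_generations`` ago with symmetric
    migration; SNP ascertainment is shared (combined-cohort MAF), emulating a
    common genotyping chip."""
    sim = _Simulator(cfg)
    haps = sim.founders()
    n_parents = cfg.founder_pool
    shared = cfg.generations_since_founding - cfg.split_generations
    for _ in range(shared):
        haps = sim.random_mating(haps, cfg.ne, n_parents)
        n_parents = cfg.ne
    # duplicate into two breeding pools held in one array: pop1 = [0, ne), pop2 = [ne, 2ne)
    ne = cfg.ne
    rng = sim.rng
    pool = None
    if cfg.split_generations > 0:
        # first post-split generation draws both pools from the shared one
        pool = np.concatenate(
            [sim.random_mating(haps, ne, n_parents), sim.random_mating(haps, ne, n_parents)],
            axis=0,
        )
        for _ in range(cfg.split_generations - 1):
            next_pool = []
            for pop in (0, 1):
                own, other = pop * ne, (1 - pop) * ne
                migrant = rng.random((cfg.ne, 2)) < cfg.migration_rate
                mothers = np.where(migrant[:, 0], other, own) + rng.integers(0, ne, cfg.ne)
                fathers = np.where(migrant[:, 1], other, own) + rng.integers(0, ne, cfg.ne)
                next_pool.append(sim.offspring(pool, mothers, fathers))
            pool = np.concatenate(next_pool, axis=0)

    cohorts = []
    for pop in (0, 1):
        if cfg.split_generations == 0:
            cohorts.append(sim.random_mating(haps, cfg.n_samples, n_parents))
        else:
            cohorts.append(
                sim.random_mating(pool[2 * pop * ne : 2 * (pop + 1) * ne], cfg.n_samples, ne)
            )
    combined = np.concatenate(cohorts, axis=0)
    keep = _ascertain(combined.mean(axis=0), cfg)
    # orient alleles on the combined cohort so both matrices share a coding
    freqs = combined[:, keep].mean(axis=0)
    flip = freqs > 0.5
    keep_mask = np.zeros(sim.n_sites, dtype=bool)
    keep_mask[keep] = True
    markers = sim.marker_map(keep_mask)
    out = []
    for pop, prefix in ((0, "p1_"), (1, "p2_")):
        sub = cohorts[pop][:, keep]
        sub = np.where(flip[None, :], 1 - sub, sub).astype(np.int8)
        genotypes = sub[0::2] + sub[1::2]
        ids = [f"{prefix}{i:04d}" for i in range(genotypes.shape[0])]
        out.append(GenotypeMatrix(ids, markers, genotypes, haplotypes=sub))
    return out[0], out[1], markers


def allele_frequency_correlation(gm1: GenotypeMatrix, gm2: GenotypeMatrix) -> float:
    """Pearson correlation of per-SNP allele frequencies between two cohorts."""
    from .qc import allele_b_freq

    f1, f2 = allele_b_freq(gm1), allele_b_freq(gm2)
    ok = np.isfinite(f1) & np.isfinite(f2)
    return float(np.corrcoef(f1[ok], f2[ok])[0, 1])


def add_half_sib_structure(
    gm: GenotypeMatrix, families: tuple[int, int], seed: int = 0
) -> GenotypeMatrix:
    """Append half-sib families: each family shares one sire mated to distinct
    dams drawn from the cohort.  Requires truth phase and Morgan coordinates.

    ``families`` is (n_families, offspring_per_family).  The truth pedigree is
    attached to the returned matrix as ``.pedigree`` (sample, sire, dam).
    Zero families returns the input unchanged.
    """
    n_fam, fam_size = families
    if n_fam == 0:
        return gm
    if fam_size <= 0:
        raise ValueError("family size must be positive")
    if gm.haplotypes is None:
        raise ValueError("cohort must carry truth phase to breed from")
    if "morgan" not in gm.markers.df.columns:
        raise ValueError("marker map must carry Morgan coordinates to breed from")

    rng = np.random.default_rng(seed)
    markers = gm.markers
    # rebuild per-chromosome recombination machinery from the marker map
    chroms = []
    for c in markers.chromosomes():
        idx = markers.chrom_indices(c)
        chroms.append((idx, markers.df["morgan"].to_numpy()[idx]))

    def gamete(parent: int) -> np.ndarray:
        out = np.empty(gm.n_snps, dtype=np.int8)
        for idx, mpos in chroms:
            span = mpos[-1] - mpos[0]
            h0, h1 = gm.haplotypes[2 * parent], gm.haplotypes[2 * parent + 1]
            start = rng.integers(0, 2)
            k = rng.poisson(span)
            hap_a, hap_b = (h0, h1) if start == 0 else (h1, h0)
            if k == 0:
                out[idx] = hap_a[idx]
                continue
            points = np.sort(rng.uniform(mpos[0], mpos[-1], size=k))
            flips = np.searchsorted(mpos, points)
            counts = np.zeros(len(idx) + 1, dtype=np.int64)
            np.add.at(counts, flips, 1)
            phase = np.cumsum(counts[:-1]) % 2
            out[idx] = np.where(phase == 0, hap_a[idx], hap_b[idx])
        return out

    sires = rng.choice(gm.n_samples, size=n_fam, replace=False)
    new_haps, new_ids, ped = [], [], []
    for f, sire in enumerate(sires):
        dams = rng.choice(
            np.setdiff1d(np.arange(gm.n_samples), [sire]), size=fam_size, replace=False
        )
        for o, dam in enumerate(dams):
            new_haps.append(gamete(int(sire)))
            new_haps.append(gamete(int(dam)))
            sid = f"hs{f}_{o}"
            new_ids.append(sid)
            ped.append((sid, gm.sample_ids[int(sire)], gm.sample_ids[int(dam)]))

    haps = np.concatenate([gm.haplotypes, np.asarray(new_haps, dtype=np.int8)], axis=0)
    genotypes = haps[0::2] + haps[1::2]
    out = GenotypeMatrix(gm.sample_ids + new_ids, markers, genotypes, haplotypes=haps)
    out.pedigree = pd.DataFrame(ped, columns=["sample_id", "sire", "dam"])
    return out


def write_truth_bundle(gm: GenotypeMatrix, cfg: SimConfig, outdir) -> None:
    """PLINK text plus truth phase, Morgan map and the config, for external use."""
    import json
    import os

    from .io import write_plink_text

    os.makedirs(outdir, exist_ok=True)
    write_plink_text(gm, os.path.join(outdir, "population"))
    np.savetxt(
        os.path.join(outdir, "haplotypes.tsv"), gm.haplotypes, fmt="%d", delimiter="\t"
    )
    gm.markers.df.to_csv(os.path.join(outdir, "markers.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "sim_config.json"), "w") as fh:
        cfg_dict = {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in cfg.__dict__.items()}
        json.dump(cfg_dict, fh, indent=2)
    if hasattr(gm, "pedigree"):
        gm.pedigree.to_csv(os.path.join(outdir, "pedigree.tsv"), sep="\t", index=False)
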
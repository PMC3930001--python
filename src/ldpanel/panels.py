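"""Low-density panel (LDP) design: per-chromosome allocation and the three
SNP-selection methods.

* ``bpEQ`` — equidistant in base pairs: the chromosome span is divided into
  equal segments and the SNP nearest each segment boundary is chosen,
  irrespective of MAF.
* ``bpMAF`` — a genetic algorithm selects SNPs that are simultaneously close
  to equidistant in bp and high-MAF, minimising
  ``sum (0.5 - MAF_i)^2 + lambda * sum ((S_{i+1}-S_i)/d - 1)^2`` with d the
  ideal spacing len_chr/(n_chr - 1); the outermost chromosome SNPs are always
  forced into the panel (telomere rule).
* ``lduMAF`` — the same algorithm with SNP coordinates in LDU instead of bp,
  so spacing becomes uniform in LD-map distance rather than physical distance.

The spacing deviation is divided by d before squaring so the two cost terms
are commensurate (raw squared bp deviations would dwarf the MAF term by many
orders of magnitude); ``lambda_spacing`` weighs the spacing term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import GenotypeMatrix, Panel
from .ldu import LDUMap
from .qc import compute_mafs

METHODS = ("bpEQ", "bpMAF", "lduMAF")


@dataclass
class ChromosomeInfo:
    chromosome: str
    len_bp: int
    len_morgan: float | None = None
    ldu_span: float | None = None

    def __post_init__(self):
        if self.len_bp <= 0:
            raise ValueError("chromosome length must be positive")


def panel_density_ne_per_morgan(panel_size: int, genome_morgans: float, ne: int) -> float:
    """Panel density normalised by effective population size, in Ne SNPs/Morgan."""
    if genome_morgans <= 0 or ne <= 0:
        raise ValueError("genome length and Ne must be positive")
    return panel_size / (genome_morgans * ne)


def allocate_snps_per_chromosome(total: int, chroms: list[ChromosomeInfo]) -> dict[str, int]:
    """Largest-remainder allocation proportional to chromosome bp length.

    Every chromosome receives at least 2 SNPs (the selection methods need both
    chromosome ends); ties in fractional remainder break on chromosome order.
    """
    if total < 2 * len(chroms):
        raise ValueError(
            f"panel size {total} cannot give each of {len(chroms)} chromosomes 2 SNPs"
        )
    lengths = np.array([c.len_bp for c in chroms], dtype=float)
    quota = total * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    frac = quota - counts
    leftover = total - counts.sum()
    # stable sort on -frac keeps chromosome order among ties
    for k in np.argsort(-frac, kind="stable")[:leftover]:
        counts[k] += 1
    while (counts < 2).any():
        counts[np.argmin(counts)] += 1
        counts[np.argmax(counts)] -= 1
    return {c.chromosome: int(n) for c, n in zip(chroms, counts)}


def ideal_spacing(len_chr: float, n_chr: int) -> float:
    """Ideal inter-SNP distance d = len_chr / (n_chr - 1)."""
    if n_chr < 2:
        raise ValueError("need at least 2 panel SNPs per chromosome")
    return len_chr / (n_chr - 1)


def select_bpeq(positions: np.ndarray, n_chr: int) -> np.ndarray:
    """Equidistant selection: the SNP subset nearest to n_chr equally spaced
    boundaries anchored at the first and last SNP positions.

    Solved exactly as an ordered assignment of boundaries to distinct SNPs
    minimising the total |position - boundary| distance (O(n_chr * n_snps)
    dynamic programme); ties resolve to the lexicographically smaller
    position set, i.e. the lower bp.  Returns sorted indices into
    ``positions``.
    """
    positions = np.asarray(positions, dtype=float)
    m = len(positions)
    if m == 0:
        raise ValueError("empty marker set")
    if n_chr >= m:
        if n_chr > m:
            warnings.warn(
                f"requested {n_chr} panel SNPs but only {m} available; using all",
                RuntimeWarning,
            )
        return np.arange(m)
    boundaries = np.linspace(positions[0], positions[-1], n_chr)
    n = n_chr
    # dp[k, j]: min cost assigning the first k boundaries within the first j
    # positions (order-preserving, distinct)
    dp = np.full((n + 1, m + 1), np.inf)
    dp[0, :] = 0.0
    cost = np.abs(positions[None, :] - boundaries[:, None])  # (n, m)
    for k in range(1, n + 1):
        # dp[k, j] = min_{i <= j} dp[k-1, i-1] + cost[k-1, i-1]: a prefix min
        dp[k, 1:] = np.minimum.accumulate(dp[k - 1, :-1] + cost[k - 1, :])
    chosen = []
    k, j = n, m
    while k > 0:
        # on ties prefer skipping position j, which steers the set toward
        # lower positions (lexicographically smaller)
        if j - 1 >= k and dp[k, j - 1] <= dp[k - 1, j - 1] + cost[k - 1, j - 1]:
            j -= 1
        else:
            chosen.append(j - 1)
            k -= 1
            j -= 1
    return np.sort(np.asarray(chosen, dtype=np.intp))


def panel_cost(
    mafs: np.ndarray, coords: np.ndarray, d: float, lambda_spacing: float = 1.0
) -> float:
    """Panel objective: MAF shortfall plus normalised spacing deviation.

    ``sum_i (0.5 - MAF_i)^2 + lambda * sum_i ((S_{i+1} - S_i)/d - 1)^2``
    over the selected SNPs sorted by coordinate.
    """
    if d <= 0:
        raise ValueError("ideal spacing d must be positive")
    mafs = np.asarray(mafs, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(mafs) != len(coords) or len(mafs) < 2:
        raise ValueError("need at least 2 selected SNPs with matching MAF/coordinate")
    if np.any(np.diff(coords) < 0):
        raise ValueError("coordinates must be sorted")
    maf_term = float(np.sum((0.5 - mafs) ** 2))
    spacing_term = float(np.sum((np.diff(coords) / d - 1.0) ** 2))
    return maf_term + lambda_spacing * spacing_term


@dataclass
class GAParams:
    population_size: int = 60
    generations: int = 300
    tournament_size: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    mutation_window: int = 5
    stagnation_limit: int = 50
    lambda_spacing: float = 1.0


def _repair(sol: np.ndarray, n_snps: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Sort, deduplicate and refill a candidate index vector to k unique interior SNPs."""
    sol = np.unique(sol)
    sol = sol[(sol > 0) & (sol < n_snps - 1)]
    while len(sol) < k:
        # refill from SNPs nearest (in index) to a random existing member
        anchor = int(rng.choice(sol)) if len(sol) else int(rng.integers(1, n_snps - 1))
        for off in range(1, n_snps):
            for cand in (anchor - off, anchor + off):
                if 0 < cand < n_snps - 1 and cand not in sol:
                    sol = np.append(sol, cand)
                    break
            if len(sol) == k:
                break
        sol = np.unique(sol)
    return np.sort(sol[:k])


def _polish(
    interior: np.ndarray,
    coords: np.ndarray,
    mafs: np.ndarray,
    d: float,
    lam: float,
    max_sweeps: int = 50,
) -> np.ndarray:
    """Single-SNP coordinate refinement of a panel: each interior slot is
    moved to the best unused SNP between its neighbours until no move helps.
    Cost deltas are local (one MAF term, two spacing terms), so a sweep is
    cheap."""
    m = len(coords)
    sol = np.concatenate([[0], np.sort(interior), [m - 1]])

    def spacing(a, b):
        return lam * ((coords[b] - coords[a]) / d - 1.0) ** 2

    for _ in range(max_sweeps):
        improved = False
        for slot in range(1, len(sol) - 1):
            cur = sol[slot]
            rest = np.delete(sol, slot)
            lo, hi = rest[slot - 1], rest[slot]
            remove_gain = (
                (0.5 - mafs[cur]) ** 2 + spacing(lo, cur) + spacing(cur, hi)
                - spacing(lo, hi)
            )
            unused = np.setdiff1d(np.arange(1, m - 1), rest, assume_unique=False)
            unused = unused[unused != cur]
            if len(unused) == 0:
                continue
            # insertion interval of each candidate in the reduced panel
            pos = np.searchsorted(rest, unused)
            left, right = rest[pos - 1], rest[pos]
            insert_cost = (
                (0.5 - mafs[unused]) ** 2
                + spacing(left, unused) + spacing(unused, right)
                - spacing(left, right)
            )
            best = int(np.argmin(insert_cost))
            if insert_cost[best] < remove_gain - 1e-15:
                sol = np.sort(np.append(rest, unused[best]))
                improved = True
        if not improved:
            break
    return sol[1:-1]


def select_optimized(
    coords: np.ndarray,
    mafs: np.ndarray,
    n_chr: int,
    ga_params: GAParams | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Genetic-algorithm selection minimising :func:`panel_cost`.

    The first and last chromosome SNPs are always included (telomere rule);
    interior panel slots are evolved.  The initial population contains the
    bpEQ solution (ends forced), so with elitism the returned cost never
    exceeds the bpEQ cost under the same objective.

    Returns (sorted indices, realised cost).
    """
    if ga_params is None:
        ga_params = GAParams()
    coords = np.asarray(coords, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    m = len(coords)
    if n_chr < 2:
        raise ValueError("need n_chr >= 2")
    if n_chr >= m:
        idx = np.arange(m)
        d = ideal_spacing(coords[-1] - coords[0], max(m, 2))
        return idx, panel_cost(mafs, coords, d, ga_params.lambda_spacing)
    d = ideal_spacing(coords[-1] - coords[0], n_chr)
    k = n_chr - 2  # interior slots
    rng = np.random.default_rng(seed)

    def cost_of(interior: np.ndarray) -> float:
        idx = np.concatenate([[0], interior, [m - 1]])
        return panel_cost(mafs[idx], coords[idx], d, ga_params.lambda_spacing)

    bpeq = select_bpeq(coords, n_chr)
    bpeq_interior = _repair(bpeq[(bpeq > 0) & (bpeq < m - 1)], m, k, rng) if k else np.empty(0, int)
    if k == 0:
        idx = np.array([0, m - 1])
        return idx, panel_cost(mafs[idx], coords[idx], d, ga_params.lambda_spacing)

    pop = [bpeq_interior]
    while len(pop) < ga_params.population_size:
        jitter = bpeq_interior + rng.integers(
            -ga_params.mutation_window, ga_params.mutation_window + 1, size=k
        )
        pop.append(_repair(np.clip(jitter, 1, m - 2), m, k, rng))
    fitness = np.array([cost_of(s) for s in pop])

    best_i = int(np.argmin(fitness))
    best, best_cost = pop[best_i].copy(), float(fitness[best_i])
    stagnant = 0
    for _ in range(ga_params.generations):
        new_pop = [best.copy()]  # elitism
        while len(new_pop) < ga_params.population_size:
            contestants = rng.integers(0, len(pop), size=ga_params.tournament_size)
            p1 = pop[contestants[np.argmin(fitness[contestants])]]
            contestants = rng.integers(0, len(pop), size=ga_params.tournament_size)
            p2 = pop[contestants[np.argmin(fitness[contestants])]]
            if rng.random() < ga_params.crossover_rate and k > 1:
                cut = int(rng.integers(1, k))
                child = np.concatenate([p1[:cut], p2[cut:]])
            else:
                child = p1.copy()
            mutate = rng.random(k) < ga_params.mutation_rate
            if mutate.any():
                child = child.copy()
                child[mutate] += rng.integers(
                    -ga_params.mutation_window, ga_params.mutation_window + 1,
                    size=int(mutate.sum()),
                )
            new_pop.append(_repair(np.clip(child, 1, m - 2), m, k, rng))
        pop = new_pop
        fitness = np.array([cost_of(s) for s in pop])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_cost - 1e-15:
            best, best_cost = pop[gen_best].copy(), float(fitness[gen_best])
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= ga_params.stagnation_limit:
                break
    # final refinement: polish both the GA winner and the bpEQ start, which
    # may sit in different basins, and keep the cheaper local optimum
    candidates = [
        _polish(best, coords, mafs, d, ga_params.lambda_spacing),
        _polish(bpeq_interior, coords, mafs, d, ga_params.lambda_spacing),
    ]
    for cand in candidates:
        c = cost_of(cand)
        if c < best_cost:
            best, best_cost = cand, c
    idx = np.concatenate([[0], best, [m - 1]])
    return np.sort(idx), best_cost


def ldu_tie_adjust(ldu_positions: np.ndarray, increment: float = 1e-6) -> np.ndarray:
    """Break runs of identical LDU positions by adding k*increment to the k-th
    member of each run, keeping SNP order consistent with the physical map."""
    pos = np.asarray(ldu_positions, dtype=float)
    if np.any(np.diff(pos) < 0):
        raise ValueError("LDU positions must be non-decreasing")
    out = pos.copy()
    # forward pass: within a run of equal values the k-th member gains
    # k*increment; also keeps strict order when an adjusted run would
    # overtake a nearly-equal successor
    for i in range(1, len(out)):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + increment
    return out


def design_panel(
    design_set: GenotypeMatrix,
    method: str,
    total: int,
    seed: int = 0,
    ldu_maps: dict[str, LDUMap] | None = None,
    ga_params: GAParams | None = None,
) -> Panel:
    """Select a low-density panel of ``total`` SNPs across all chromosomes.

    MAFs (for bpMAF/lduMAF) are computed from ``design_set`` — the sample set
    reserved for panel design.  Panel sizes per chromosome are proportional to
    bp length.  ``lduMAF`` requires an LDU map per chromosome.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    markers = design_set.markers
    chrom_ids = markers.chromosomes()
    infos = []
    for c in chrom_ids:
        idx = markers.chrom_indices(c)
        bp = markers.bp[idx]
        infos.append(ChromosomeInfo(c, int(bp[-1] - bp[0] + 1)))
    counts = allocate_snps_per_chromosome(total, infos)

    mafs_all = compute_mafs(design_set)
    panel = Panel(
        method=method,
        target_total=total,
        coordinate_system="ldu" if method == "lduMAF" else "bp",
        seed=seed,
    )
    for c in chrom_ids:
        idx = markers.chrom_indices(c)
        n_chr = counts[c]
        bp = markers.bp[idx].astype(float)
        if method == "lduMAF":
            if ldu_maps is None or c not in ldu_maps:
                raise ValueError(f"lduMAF requires an LDU map for chromosome {c}")
            lmap = ldu_maps[c]
            if list(lmap.snp_ids) != list(markers.snp_ids[idx]):
                raise ValueError(f"LDU map SNPs do not match marker map on chromosome {c}")
            coords = ldu_tie_adjust(lmap.ldu_positions)
        else:
            coords = bp
        if method == "bpEQ":
            sel = select_bpeq(coords, n_chr)
            d = ideal_spacing(coords[-1] - coords[0], max(n_chr, 2))
            cost = (
                panel_cost(mafs_all[idx][sel], coords[sel], d) if len(sel) >= 2 else np.nan
            )
        else:
            sel, cost = select_optimized(
                coords, mafs_all[idx], n_chr, ga_params=ga_params, seed=seed
            )
            d = ideal_spacing(coords[-1] - coords[0], max(n_chr, 2))
        panel.per_chromosome[c] = list(markers.snp_ids[idx][sel])
        panel.d_used[c] = float(d)
        panel.cost[c] = float(cost)
    return panel
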
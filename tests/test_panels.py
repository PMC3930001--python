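"""Panel allocation and the bpEQ / bpMAF / lduMAF selection methods."""

import itertools

import numpy as np
import pytest

from ldpanel import (ChromosomeInfo, allocate_snps_per_chromosome,
                     design_panel, ideal_spacing, ldu_tie_adjust, panel_cost,
                     panel_density_ne_per_morgan, select_bpeq, select_optimized)
from ldpanel.qc import compute_mafs


def brute_force_bpeq(positions, n):
    """Independent oracle: exhaustive subset search minimising the total
    distance of the sorted subset to the equally spaced boundaries; ties to
    the lexicographically smallest position tuple."""
    positions = np.asarray(positions, dtype=float)
    boundaries = np.linspace(positions[0], positions[-1], n)
    best, best_cost = None, np.inf
    for comb in itertools.combinations(range(len(positions)), n):
        cost = np.abs(positions[list(comb)] - boundaries).sum()
        key = tuple(positions[list(comb)])
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12 and key < best
        ):
            best_cost, best = cost, key
    return np.asarray(best)


class TestAllocation:
    def test_exact_proportion(self):
        chroms = [ChromosomeInfo("1", 300), ChromosomeInfo("2", 100)]
        assert allocate_snps_per_chromosome(100, chroms) == {"1": 75, "2": 25}

    def test_largest_remainder_tie_break(self):
        chroms = [ChromosomeInfo(c, 100) for c in "123"]
        assert allocate_snps_per_chromosome(10, chroms) == {"1": 4, "2": 3, "3": 3}

    def test_single_chromosome(self):
        assert allocate_snps_per_chromosome(7, [ChromosomeInfo("1", 10)]) == {"1": 7}

    def test_too_small_total_raises(self):
        chroms = [ChromosomeInfo(c, 100) for c in "123"]
        with pytest.raises(ValueError):
            allocate_snps_per_chromosome(5, chroms)


class TestDensityAndSpacing:
    def test_printed_ne_densities(self):
        assert panel_density_ne_per_morgan(6000, 27.72, 150) == pytest.approx(1.44, abs=0.005)
        assert panel_density_ne_per_morgan(1000, 27.72, 150) == pytest.approx(0.24, abs=0.005)
        assert panel_density_ne_per_morgan(0, 27.72, 150) == 0.0

    @pytest.mark.parametrize(
        "length, n, expected", [(100, 3, 50), (100, 101, 1), (185e6, 30, 185e6 / 29)]
    )
    def test_ideal_spacing(self, length, n, expected):
        assert ideal_spacing(length, n) == pytest.approx(expected)

    def test_ideal_spacing_domain(self):
        with pytest.raises(ValueError):
            ideal_spacing(100, 1)


class TestSelectBpeq:
    def test_tie_broken_to_lower_bp(self):
        idx = select_bpeq(np.array([1, 48, 52, 99], float), 3)
        assert idx.tolist() == [0, 1, 3]  # {1, 48, 99}

    def test_all_snps_when_n_equals_count(self):
        assert select_bpeq(np.arange(5, dtype=float), 5).tolist() == [0, 1, 2, 3, 4]

    def test_uniform_grid_takes_every_tenth(self):
        positions = np.arange(0, 101, 1.0) * 1e6  # 1 per Mb over 100 Mb
        idx = select_bpeq(positions, 11)
        assert idx.tolist() == list(range(0, 101, 10))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for trial in range(30):
            m = int(rng.integers(5, 16))
            positions = np.sort(rng.choice(10_000, size=m, replace=False)).astype(float)
            n = int(rng.integers(2, min(m, 8) + 1))
            got = positions[select_bpeq(positions, n)]
            want = brute_force_bpeq(positions, n)
            assert got.tolist() == want.tolist(), f"trial {trial}"


class TestPanelCost:
    def test_zero_at_ideal(self):
        coords = np.array([0.0, 10.0, 20.0])
        assert panel_cost(np.full(3, 0.5), coords, d=10.0) == 0.0

    def test_two_snp_maf_penalty(self):
        assert panel_cost(np.array([0.25, 0.25]), np.array([0.0, 7.0]), d=7.0) == (
            pytest.approx(0.125)
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        coords = np.sort(rng.uniform(0, 100, size=6))
        mafs = rng.uniform(0, 0.5, size=6)
        c1 = panel_cost(mafs, coords, d=20.0)
        c2 = panel_cost(mafs, coords * 2, d=40.0)
        assert c1 == pytest.approx(c2)


def local_search(coords, mafs, n, max_rounds=200):
    """Hill-climbing oracle: single-SNP moves from the bpEQ start."""
    from ldpanel.panels import ideal_spacing, panel_cost, select_bpeq

    m = len(coords)
    d = ideal_spacing(coords[-1] - coords[0], n)
    sel = set(select_bpeq(coords, n).tolist()) | {0, m - 1}
    while len(sel) > n:
        sel.discard(max(i for i in sel if i not in (0, m - 1)))

    def cost(s):
        idx = np.sort(np.fromiter(s, int))
        return panel_cost(mafs[idx], coords[idx], d)

    current = cost(sel)
    for _ in range(max_rounds):
        improved = False
        for i in sorted(sel):
            if i in (0, m - 1):
                continue
            for j in range(m):
                if j in sel or j in (0, m - 1):
                    continue
                cand = (sel - {i}) | {j}
                c = cost(cand)
                if c < current - 1e-12:
                    sel, current = cand, c
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return current


class TestSelectOptimized:
    def test_all_snps_unique_solution(self):
        coords = np.array([0.0, 10, 20, 30, 40])
        mafs = np.full(5, 0.3)
        idx, _ = select_optimized(coords, mafs, 5, seed=0)
        assert idx.tolist() == [0, 1, 2, 3, 4]

    def test_maf_decides_between_collocated_snps(self):
        # two interior candidates at (nearly) the same position, one slot
        coords = np.array([0.0, 50.0, 50.000001, 100.0])
        mafs = np.array([0.3, 0.1, 0.5, 0.3])
        idx, _ = select_optimized(coords, mafs, 3, seed=0)
        assert 2 in idx and 1 not in idx

    def test_ga_beats_bpeq_and_near_local_optimum(self, small_pop_sets):
        set_a, _, _ = small_pop_sets
        coords = set_a.markers.bp.astype(float)
        mafs = compute_mafs(set_a)
        n = 20
        from ldpanel.panels import ideal_spacing, panel_cost, select_bpeq

        d = ideal_spacing(coords[-1] - coords[0], n)
        idx, ga_cost = select_optimized(coords, mafs, n, seed=3)
        assert idx[0] == 0 and idx[-1] == len(coords) - 1  # telomere rule
        bpeq = select_bpeq(coords, n)
        bpeq_cost = panel_cost(mafs[bpeq], coords[bpeq], d)
        assert ga_cost <= bpeq_cost + 1e-12
        ls_cost = local_search(coords, mafs, n)
        assert ga_cost <= ls_cost * 1.01
        assert mafs[idx].mean() > mafs[bpeq].mean()


class TestLduTieAdjust:
    def test_run_of_equals(self):
        out = ldu_tie_adjust(np.array([0.0, 1, 1, 1, 2]))
        assert out.tolist() == pytest.approx([0, 1, 1.000001, 1.000002, 2])

    def test_strictly_increasing_unchanged(self):
        x = np.array([0.0, 0.5, 1.2])
        assert ldu_tie_adjust(x).tolist() == x.tolist()

    def test_all_equal(self):
        out = ldu_tie_adjust(np.zeros(4))
        assert out.tolist() == pytest.approx([0, 1e-6, 2e-6, 3e-6])


class TestDesignPanel:
    def test_panel_subset_sorted_and_sized(self, small_pop_sets):
        set_a, _, _ = small_pop_sets
        panel = design_panel(set_a, "bpMAF", 15, seed=2)
        assert panel.size == 15
        ids = panel.per_chromosome["1"]
        pos = set_a.markers.bp[set_a.markers.index_of(ids)]
        assert (np.diff(pos) > 0).all()
        assert set(ids) <= set(set_a.markers.snp_ids)
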
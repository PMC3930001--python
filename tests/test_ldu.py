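"""LDU map construction: two-locus EM, D', Malecot fit, truth recovery."""

import numpy as np
import pytest

from ldpanel import (build_ldu_map, dprime, estimate_two_locus_haplotype_freqs,
                     malecot_predicted_association, simulate_population)
from ldpanel.ldu import DegenerateLocusError
from ldpanel.simulate import SimConfig

from conftest import make_gm


class TestTwoLocusEM:
    def test_identical_loci_complete_ld(self):
        g = np.array([0, 2, 0, 2, 2, 0, 0, 2])
        f = estimate_two_locus_haplotype_freqs(g, g)
        p0 = np.mean(g == 0)
        assert f[0] == pytest.approx(p0, abs=1e-8)
        assert f[3] == pytest.approx(1 - p0, abs=1e-8)
        assert f[1] == pytest.approx(0, abs=1e-8)
        assert dprime(f) == pytest.approx(1.0)

    def test_shuffled_loci_near_equilibrium(self):
        rng = np.random.default_rng(0)
        g1 = rng.integers(0, 3, size=500)
        g2 = rng.permutation(g1)
        f = estimate_two_locus_haplotype_freqs(g1, g2)
        assert dprime(f) < 0.15

    def test_marginals_preserved(self):
        rng = np.random.default_rng(1)
        g1 = rng.integers(0, 3, size=200)
        g2 = rng.integers(0, 3, size=200)
        f = estimate_two_locus_haplotype_freqs(g1, g2)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        assert f[2] + f[3] == pytest.approx(g1.mean() / 2, abs=1e-6)
        assert f[1] + f[3] == pytest.approx(g2.mean() / 2, abs=1e-6)

    def test_monomorphic_raises(self):
        with pytest.raises(DegenerateLocusError):
            estimate_two_locus_haplotype_freqs(np.zeros(10, int), np.arange(10) % 3)


class TestDprime:
    def test_equilibrium_zero(self):
        assert dprime([0.25, 0.25, 0.25, 0.25]) == pytest.approx(0.0)

    def test_complete_ld_one(self):
        assert dprime([0.5, 0, 0, 0.5]) == pytest.approx(1.0)

    def test_lewontin_normalisation(self):
        # D = 0.3 - 0.5*0.4 = 0.1; Dmax = min(0.5*0.6, 0.5*0.4) = 0.2
        assert dprime([0.4, 0.1, 0.2, 0.3]) == pytest.approx(0.5)

    def test_boundary_marginals_raise(self):
        with pytest.raises(ValueError):
            dprime([0.5, 0.5, 0.0, 0.0])


class TestMalecot:
    def test_intercept_asymptote_decay(self):
        assert malecot_predicted_association(0.0, 1.0, 0.0) == pytest.approx(1.0)
        assert malecot_predicted_association(50.0, 1.0, 0.1) == pytest.approx(0.1)
        assert malecot_predicted_association(1.0, 1.0, 0.0) == pytest.approx(
            np.exp(-1), abs=1e-9
        )


def _block_fixture(n=250, seed=0):
    """Two 5-SNP blocks of complete internal LD, independent of each other:
    every pair within a block has |D'| = 1, cross-block pairs ~0, so the
    inter-block interval is a recombination hotspot."""
    rng = np.random.default_rng(seed)
    x = rng.random(2 * n) < 0.5  # block-1 haplotype allele
    y = rng.random(2 * n) < 0.5  # block-2, independent
    haps = np.column_stack([np.tile(x, (5, 1)).T, np.tile(y, (5, 1)).T]).astype(np.int8)
    geno = haps[0::2] + haps[1::2]
    bps = [1000 * (i + 1) for i in range(5)] + [100_000 + 1000 * i for i in range(5)]
    return make_gm(geno, bps=bps)


class TestBuildLduMap:
    def test_hotspot_carries_the_span(self):
        gm = _block_fixture()
        lmap = build_ldu_map(gm, max_pair_bp=500_000)
        x = np.diff(lmap.ldu_positions)
        hotspot = x[4]  # interval between the blocks
        assert lmap.total_span > 0
        assert hotspot / lmap.total_span > 0.8

    def test_zero_recombination_region_flat(self):
        cfg = SimConfig(
            chrom_morgans=(0.001,), snp_density_per_morgan=20_000,
            n_samples=200, seed=3, ancestral_ne=300,
        )
        gm, _ = simulate_population(cfg)  # ~20 SNPs, essentially no recombination
        lmap = build_ldu_map(gm, max_pair_bp=10**8)
        assert lmap.total_span < 0.5

    def test_single_interval_inversion(self):
        """Pairs at one distance with mean |D'| = e^-1 imply ~1 LDU."""
        rng = np.random.default_rng(5)
        n = 4000
        # construct haplotypes whose |D'| is close to e^-1 = 0.368:
        # f11 = p*q + D with D = dprime * Dmax
        p = 0.5
        target = np.exp(-1)
        d = target * min(p * (1 - p), (1 - p) * p)
        probs = [p * p + d, p * (1 - p) - d, (1 - p) * p - d, (1 - p) * (1 - p) + d]
        hap = rng.choice(4, size=2 * n, p=probs)
        h1 = (hap < 2).astype(np.int8)  # allele at locus 1 (A=0/1)
        h2 = ((hap == 0) | (hap == 2)).astype(np.int8)
        haps = np.column_stack([1 - h1, 1 - h2])
        geno = haps[0::2] + haps[1::2]
        # need >= 3 SNPs: duplicate locus 1 at the same block (zero distance)
        geno3 = np.column_stack([geno[:, 0], geno[:, 0], geno[:, 1]])
        gm = make_gm(geno3.astype(np.int8), bps=[100, 200, 10_000])
        lmap = build_ldu_map(gm, max_pair_bp=10**6, L=0.0)
        assert lmap.ldu_positions[-1] - lmap.ldu_positions[1] == pytest.approx(
            1.0, abs=0.25
        )

    def test_monotone_and_rescale_invariant(self):
        gm = _block_fixture(seed=7)
        lmap = build_ldu_map(gm, max_pair_bp=500_000)
        assert (np.diff(lmap.ldu_positions) >= 0).all()
        # uniform bp rescaling does not change the LDU span
        import pandas as pd

        df = gm.markers.df.copy()
        df["bp"] = df["bp"] * 3
        from ldpanel import GenotypeMatrix, MarkerMap

        gm2 = GenotypeMatrix(gm.sample_ids, MarkerMap(df), gm.genotypes)
        lmap2 = build_ldu_map(gm2, max_pair_bp=1_500_000)
        assert lmap2.total_span == pytest.approx(lmap.total_span, rel=1e-6)

    def test_uniform_recombination_near_linear(self):
        cfg = SimConfig(
            chrom_morgans=(0.2,), snp_density_per_morgan=300, n_samples=500,
            seed=11,
        )
        gm, _ = simulate_population(cfg)
        lmap = build_ldu_map(gm, max_pair_bp=2_000_000)
        bp = lmap.bp_positions.astype(float)
        ldu = lmap.ldu_positions
        r = np.corrcoef(bp, ldu)[0, 1]
        assert r**2 > 0.9
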
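"""Imputation engines: random HWE baseline, haplotype-copying HMM, adapter."""

import os
import stat

import numpy as np
import pytest

from ldpanel import (GenotypeMatrix, HmmParams, expected_random_accuracy,
                     impute_hmm, impute_random, mask_to_panel,
                     proportion_correct, run_external_imputer)
from ldpanel.data import MISSING, Panel
from ldpanel.impute import FeatureUnavailableError, _emission_table
from ldpanel.qc import allele_b_freq

from conftest import make_gm, make_markers


class TestExpectedRandomAccuracy:
    @pytest.mark.parametrize(
        "p, expected", [(1.0, 1.0), (0.5, 0.375), (0.9, 0.6886)]
    )
    def test_values(self, p, expected):
        assert expected_random_accuracy(p) == pytest.approx(expected)

    def test_matches_enumeration(self):
        """Independent oracle: enumerate genotype-pair match probability
        under HWE for both draws."""
        for p in (0.1, 0.3, 0.5, 0.77):
            q = 1 - p
            probs = np.array([q * q, 2 * p * q, p * p])
            assert expected_random_accuracy(p) == pytest.approx((probs**2).sum())


class TestImputeRandom:
    def test_degenerate_frequency(self):
        masked = make_gm(np.full((5, 3), MISSING))
        res = impute_random(masked, np.zeros(3), seed=0)
        assert (res.best_genotype == 0).all()

    def test_sampling_frequencies(self):
        masked = make_gm(np.full((10_000, 1), MISSING))
        res = impute_random(masked, np.array([0.5]), seed=1)
        counts = np.bincount(res.best_genotype[:, 0], minlength=3) / 10_000
        se = 3 * np.sqrt(np.array([0.25, 0.5, 0.25]) * 0.75 / 10_000)
        assert np.all(np.abs(counts - [0.25, 0.5, 0.25]) < 3 * se + 0.02)

    def test_determinism_and_posterior_norm(self):
        masked = make_gm(np.full((20, 4), MISSING))
        freqs = np.array([0.1, 0.3, 0.5, 0.7])
        r1 = impute_random(masked, freqs, seed=9)
        r2 = impute_random(masked, freqs, seed=9)
        assert np.array_equal(r1.best_genotype, r2.best_genotype)
        assert np.allclose(r1.posterior.sum(axis=-1), 1.0, atol=1e-9)

    def test_missing_reference_frequency_raises(self):
        masked = make_gm(np.full((2, 2), MISSING))
        with pytest.raises(KeyError):
            impute_random(masked, np.array([0.5, np.nan]), seed=0)


def brute_force_diploid_ls(H, g_obs, gpos, obs_pos, miss_pos, e, rho):
    """Explicit-state diploid Li-Stephens forward-backward oracle.

    Enumerates all K^2 ordered template pairs over the full site sequence
    (masked sites emit nothing), using the dense transition matrix
    kron(T, T) with T = (1-r) I + (r/K) J.
    """
    K, S = H.shape
    emit = _emission_table(e)
    states = [(j, k) for j in range(K) for k in range(K)]
    n_states = K * K

    def transition(r):
        T = (1 - r) * np.eye(K) + (r / K) * np.ones((K, K))
        return np.kron(T, T)

    def emission(s):
        out = np.ones(n_states)
        if s in set(obs_pos.tolist()):
            for idx, (j, k) in enumerate(states):
                out[idx] = emit[int(H[j, s] + H[k, s]), g_obs[s]]
        return out

    F = np.zeros((S, n_states))
    F[0] = emission(0) / n_states
    F[0] /= F[0].sum()
    for s in range(1, S):
        r = 1 - np.exp(-rho * (gpos[s] - gpos[s - 1]))
        f = transition(r).T @ F[s - 1] * emission(s)
        F[s] = f / f.sum()
    B = np.zeros((S, n_states))
    B[-1] = 1.0
    for s in range(S - 2, -1, -1):
        r = 1 - np.exp(-rho * (gpos[s + 1] - gpos[s]))
        b = transition(r) @ (B[s + 1] * emission(s + 1))
        B[s] = b / b.sum()

    out = np.zeros((len(miss_pos), 3))
    for t, s in enumerate(miss_pos):
        post = F[s] * B[s]
        post /= post.sum()
        for idx, (j, k) in enumerate(states):
            out[t, int(H[j, s] + H[k, s])] += post[idx]
    return out


def _phased_reference(haps, bps, morgans=None):
    haps = np.asarray(haps, dtype=np.int8)
    n = haps.shape[0] // 2
    markers = make_markers(bps)
    if morgans is not None:
        df = markers.df.copy()
        df["morgan"] = morgans
        from ldpanel import MarkerMap

        markers = MarkerMap(df)
    geno = haps[0::2] + haps[1::2]
    return GenotypeMatrix([f"r{i}" for i in range(n)], markers, geno, haps)


class TestImputeHmm:
    def test_single_template_copy(self):
        """With one reference pair and no error, imputation copies it."""
        haps = np.array([[1, 0, 1, 1, 0], [1, 0, 0, 1, 0]], dtype=np.int8)
        ref = _phased_reference(haps, bps=[10, 20, 30, 40, 50])
        masked_g = np.full((1, 5), MISSING, dtype=np.int8)
        masked_g[0, 0] = 2  # observe the first site only
        masked = GenotypeMatrix(["t"], ref.markers, masked_g)
        res = impute_hmm(masked, ref, HmmParams(k_templates=2, error_rate=0.0, seed=0))
        expected = haps[0] + haps[1]
        assert np.array_equal(res.best_genotype[0], expected)

    def test_complete_ld_posterior(self):
        """A masked SNP in complete LD with an adjacent observed SNP gets
        nearly all posterior mass on the concordant genotype."""
        haps = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8)
        ref = _phased_reference(haps, bps=[1000, 2000])
        masked_g = np.array([[2, MISSING]], dtype=np.int8)
        masked = GenotypeMatrix(["t"], ref.markers, masked_g)
        res = impute_hmm(masked, ref, HmmParams(k_templates=4, seed=0))
        assert res.posterior[0, 1, 2] > 0.99
        assert res.best_genotype[0, 1] == 2

    def test_matches_explicit_state_oracle(self):
        """Engine posteriors equal a dense K^2-state forward-backward to 1e-6."""
        rng = np.random.default_rng(8)
        K, S = 4, 12
        H = rng.integers(0, 2, size=(K, S)).astype(np.int8)
        bps = np.sort(rng.choice(10_000, size=S, replace=False)) + 1
        morgans = bps / 1e4 * 0.05
        ref = _phased_reference(
            np.vstack([H, H[::-1]]), bps=bps.tolist(), morgans=morgans
        )
        g = np.full((1, S), MISSING, dtype=np.int8)
        obs_pos = np.array([0, 3, 7, 11])
        truth_pair = (0, 2)
        for s in obs_pos:
            g[0, s] = H[truth_pair[0], s] + H[truth_pair[1], s]
        masked = GenotypeMatrix(["t"], ref.markers, g)
        params = HmmParams(k_templates=2 * K, ne=150, error_rate=0.01, seed=0)
        res = impute_hmm(masked, ref, params)

        rho = 4 * params.ne / (2 * K)
        miss_pos = np.setdiff1d(np.arange(S), obs_pos)
        oracle = brute_force_diploid_ls(
            ref.haplotypes, g[0], morgans, obs_pos, miss_pos, 0.01, rho
        )
        got = res.posterior[0, miss_pos, :]
        assert np.allclose(got, oracle, atol=1e-6)

    def test_beats_random_baseline(self, small_pop_sets):
        set_a, set_b, set_c = small_pop_sets
        from ldpanel import design_panel

        panel = design_panel(set_a, "bpEQ", 10, seed=0)
        masked = mask_to_panel(set_c, panel)
        freqs = allele_b_freq(set_b)
        hmm = impute_hmm(masked, set_b, HmmParams(seed=0))
        rand = impute_random(masked, freqs, seed=0)
        cells = masked.genotypes == MISSING
        acc_hmm = proportion_correct(
            set_c.genotypes[cells], hmm.best_genotype[cells]
        )
        acc_rand = proportion_correct(
            set_c.genotypes[cells], rand.best_genotype[cells]
        )
        assert acc_hmm > acc_rand

    def test_posterior_normalised_and_argmax_rule(self, small_pop_sets):
        set_a, set_b, set_c = small_pop_sets
        from ldpanel import design_panel

        panel = design_panel(set_a, "bpEQ", 8, seed=1)
        masked = mask_to_panel(set_c.take_samples(set_c.sample_ids[:10]), panel)
        res = impute_hmm(masked, set_b, HmmParams(seed=1))
        assert np.allclose(res.posterior.sum(axis=-1), 1.0, atol=1e-9)
        imputed = res.imputed_mask
        assert (
            res.best_genotype[imputed]
            == res.posterior[imputed].argmax(axis=-1)
        ).mean() > 0.999  # ties may legitimately deviate from plain argmax


class TestExternalAdapter:
    def _echo_tool(self, tmp_path):
        """Mock imputer: copies the masked input to the output prefix."""
        script = tmp_path / "echo_imputer.sh"
        script.write_text(
            "#!/bin/sh\ncp \"$1.ped\" \"$3.ped\"\ncp \"$1.map\" \"$3.map\"\n"
        )
        script.chmod(script.stat().st_mode | stat.S_IEXEC)
        return script

    def test_identity_at_observed_sites(self, tmp_path):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(6, 8)).astype(np.int8)
        truth = make_gm(g)
        panel = Panel("bpEQ", 4, {"1": [f"snp{i}" for i in (0, 2, 4, 6)]})
        masked = mask_to_panel(truth, panel)
        tool = self._echo_tool(tmp_path)
        res = run_external_imputer(
            masked, truth, {"command": [str(tool), "{masked}", "{reference}", "{out}"]},
            workdir=tmp_path / "wd",
        )
        obs = masked.genotypes != MISSING
        assert np.array_equal(res.best_genotype[obs], masked.genotypes[obs])
        assert res.engine == "external"

    def test_absent_tool_is_feature_unavailable(self):
        masked = make_gm([[0, MISSING]])
        with pytest.raises(FeatureUnavailableError):
            run_external_imputer(
                masked, masked, {"command": ["definitely-not-a-real-exe"]}
            )

    def test_writer_reader_roundtrip_without_tool(self, tmp_path, small_pop):
        from ldpanel import read_plink_text, write_plink_text

        gm = small_pop.take_samples(small_pop.sample_ids[:5]).take_snps(np.arange(30))
        write_plink_text(gm, tmp_path / "rt")
        back, _ = read_plink_text(tmp_path / "rt.ped", tmp_path / "rt.map")
        assert back == GenotypeMatrix(gm.sample_ids, gm.markers, gm.genotypes)
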
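"""Genotype imputation engines.

Two engines impute the genotypes that were masked out when a test individual
is "genotyped" on a low-density panel:

* ``random`` — each missing genotype is drawn from the Hardy–Weinberg
  proportions (p^2, 2pq, q^2) of the reference population's allele frequency
  at that SNP.  Its expected per-SNP concordance with the truth has the
  closed form p^4 + 4 p^2 q^2 + q^4, which makes it the natural null against
  which any LD-aware method is judged.

* ``hmm`` — a diploid Li–Stephens haplotype-copying model.  The hidden state
  is an ordered pair of template haplotypes from a (subsampled) phased
  reference panel; each chromosome of the test individual switches template
  independently between adjacent informative sites with probability
  1 - exp(-rho * Delta), Delta being the inter-site genetic distance.
  Emissions at observed panel sites compare the implied genotype with the
  observation under a per-allele error rate.  Forward–backward posteriors are
  propagated to masked sites lying between informative sites (the copying
  path is piecewise constant, so the masked-site state posterior combines the
  forward mass at the left site with the backward mass at the right site,
  each decayed by its share of the interval).

The best (imputed) genotype is the posterior argmax, ties broken toward the
genotype more frequent in the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import MISSING, GenotypeMatrix, MarkerMap


class FeatureUnavailableError(RuntimeError):
    pass


@dataclass
class ImputationResult:
    """Posterior genotype probabilities and best genotypes for imputed cells."""

    sample_ids: list[str]
    snp_ids: list[str]
    posterior: np.ndarray  # (n_samples, n_snps, 3); observed cells get point mass
    best_genotype: np.ndarray  # (n_samples, n_snps) in {0,1,2}
    imputed_mask: np.ndarray  # True where the genotype was imputed
    engine: str
    seed: int | None = None

    def imputed_matrix(self, markers: MarkerMap) -> GenotypeMatrix:
        return GenotypeMatrix(self.sample_ids, markers, self.best_genotype)

    def to_posterior_frame(self):
        import pandas as pd

        s_idx, m_idx = np.nonzero(self.imputed_mask)
        return pd.DataFrame(
            {
                "sample_id": np.asarray(self.sample_ids)[s_idx],
                "snp_id": np.asarray(self.snp_ids)[m_idx],
                "p0": self.posterior[s_idx, m_idx, 0],
                "p1": self.posterior[s_idx, m_idx, 1],
                "p2": self.posterior[s_idx, m_idx, 2],
            }
        )


def _hwe_triples(freq_b: np.ndarray) -> np.ndarray:
    """Hardy–Weinberg genotype probabilities (per SNP) for allele-B frequency."""
    p = np.asarray(freq_b, dtype=float)
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)


def _best_with_ties(posterior: np.ndarray, ref_triples: np.ndarray) -> np.ndarray:
    """Posterior argmax; exact ties resolved toward the reference-frequent genotype."""
    score = posterior + 1e-12 * ref_triples
    return score.argmax(axis=-1).astype(np.int8)


def _finalise(
    masked: GenotypeMatrix,
    posterior: np.ndarray,
    imputed_mask: np.ndarray,
    ref_triples: np.ndarray,
    engine: str,
    seed: int | None,
) -> ImputationResult:
    obs = masked.genotypes != MISSING
    posterior[obs] = 0.0
    posterior[obs, masked.genotypes[obs]] = 1.0
    best = _best_with_ties(posterior, np.broadcast_to(ref_triples, posterior.shape))
    best[obs] = masked.genotypes[obs]
    return ImputationResult(
        sample_ids=list(masked.sample_ids),
        snp_ids=list(masked.markers.snp_ids),
        posterior=posterior,
        best_genotype=best,
        imputed_mask=imputed_mask,
        engine=engine,
        seed=seed,
    )


def expected_random_accuracy(p: float | np.ndarray) -> float | np.ndarray:
    """Expected concordance of HWE-random imputation: p^4 + 4 p^2 q^2 + q^4.

    ``p`` may be either allele's frequency (the expression is symmetric in
    p and q = 1 - p).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency must lie in [0, 1]")
    q = 1.0 - p
    out = p**4 + 4 * p**2 * q**2 + q**4
    return float(out) if out.ndim == 0 else out


def impute_random(
    masked: GenotypeMatrix, ref_freqs: np.ndarray, seed: int = 0
) -> ImputationResult:
    """Impute missing genotypes by HWE sampling at reference allele frequencies.

    ``ref_freqs`` is the per-SNP allele-B frequency in the reference
    population (NaN entries are a lookup error for SNPs that need imputing).
    """
    ref_freqs = np.asarray(ref_freqs, dtype=float)
    if ref_freqs.shape != (masked.n_snps,):
        raise ValueError("ref_freqs must have one entry per SNP")
    to_impute = masked.genotypes == MISSING
    if np.isnan(ref_freqs[to_impute.any(axis=0)]).any():
        raise KeyError("missing reference frequency for a SNP requiring imputation")

    triples = _hwe_triples(np.nan_to_num(ref_freqs))
    rng = np.random.default_rng(seed)
    u = rng.random(masked.genotypes.shape)
    cum = np.cumsum(triples, axis=-1)
    drawn = (u[..., None] > cum[None, :, :]).sum(axis=-1).astype(np.int8)

    posterior = np.broadcast_to(triples[None, :, :], masked.genotypes.shape + (3,)).copy()
    result = _finalise(masked, posterior, to_impute, triples, "random", seed)
    # the random engine's best genotype is the sampled one, not the argmax
    result.best_genotype = np.where(to_impute, drawn, masked.genotypes).astype(np.int8)
    return result


@dataclass
class HmmParams:
    """Tuning of the haplotype-copying engine.

    ``k_templates`` — number of reference haplotypes used as copying
    templates per individual.  ``template_selection`` — how the K templates
    are drawn from a larger reference: ``"best"`` ranks haplotypes by their
    agreement with the individual's observed panel genotypes (homozygous
    sites are decisive, heterozygous sites neutral) and keeps the top K, so
    the copying panel concentrates on the haplotypes the individual is most
    likely to be mosaicing; ``"random"`` draws a seeded subsample shared by
    all individuals.
    ``ne`` — effective population size; the switch intensity per Morgan is
    4*ne/k_templates, so denser template panels need fewer switches.
    ``error_rate`` — per-allele genotyping/copying error at observed sites.
    ``cm_per_mb`` — bp-to-genetic-distance proxy when the marker map carries
    no ``morgan`` column.
    """

    k_templates: int = 60
    template_selection: str = "best"
    ne: float = 150.0
    error_rate: float = 0.002
    cm_per_mb: float = 1.0
    seed: int = 0


def _emission_table(e: float) -> np.ndarray:
    """P(observed genotype | true dosage), per-allele error e; rows=dosage."""
    return np.array(
        [
            [(1 - e) ** 2, 2 * e * (1 - e), e**2],
            [e * (1 - e), (1 - e) ** 2 + e**2, e * (1 - e)],
            [e**2, 2 * e * (1 - e), (1 - e) ** 2],
        ]
    )


def _propagate(M: np.ndarray, r: float, K: int) -> np.ndarray:
    """Apply the factorised Li–Stephens transition to both state axes.

    Per chromosome the transition is (1-r) I + (r/K) J; for the joint matrix
    this expands to four rank-structured terms computable in O(K^2).
    """
    rs = M.sum(axis=1)
    cs = M.sum(axis=0)
    tot = M.sum()
    rk = r / K
    return (
        (1 - r) ** 2 * M
        + (1 - r) * rk * (rs[:, None] + cs[None, :])
        + rk**2 * tot
    )


def _genotype_probs_batch(P: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Aggregate state posteriors (nm,K,K) into genotype triples via the
    template alleles a (nm,K) at each masked site."""
    tot = P.sum(axis=(1, 2))
    left = np.einsum("mjk,mj->mk", P, a)
    p11 = np.einsum("mk,mk->m", left, a)  # both templates carry B
    pa = left.sum(axis=1)  # first template carries B
    pb = np.einsum("mjk,mk->m", P, a)  # second template carries B
    p1 = pa + pb - 2 * p11
    p00 = tot - pa - pb + p11
    out = np.stack([p00, p1, p11], axis=1)
    out /= out.sum(axis=1, keepdims=True)
    return out


def impute_hmm(
    masked: GenotypeMatrix,
    reference: GenotypeMatrix,
    params: HmmParams | None = None,
) -> ImputationResult:
    """Impute masked genotypes with the diploid haplotype-copying HMM.

    ``reference`` must carry phased haplotypes at all SNPs of the shared
    marker map.  Test individuals are observed at their panel SNPs only; all
    other genotypes are missing and receive posterior triples.
    """
    if params is None:
        params = HmmParams()
    if reference.haplotypes is None:
        raise ValueError("reference must be phased (haplotypes present)")
    if list(reference.markers.snp_ids) != list(masked.markers.snp_ids):
        raise ValueError("masked and reference marker maps differ")

    rng = np.random.default_rng(params.seed)
    all_H = np.ascontiguousarray(reference.haplotypes, dtype=np.float64)
    n_haps = all_H.shape[0]
    K = params.k_templates
    if K > n_haps:
        warnings.warn(
            f"k_templates={K} exceeds available reference haplotypes ({n_haps}); capping",
            RuntimeWarning,
        )
        K = n_haps

    markers = masked.markers
    if "morgan" in markers.df.columns:
        gpos = markers.df["morgan"].to_numpy(dtype=float)
    else:
        gpos = markers.bp * (params.cm_per_mb / 100.0) / 1e6

    ref_triples = _hwe_triples(all_H.mean(axis=0))
    emit = _emission_table(params.error_rate)
    rho = 4.0 * params.ne / K

    n_samp, n_snps = masked.genotypes.shape
    posterior = np.zeros((n_samp, n_snps, 3))
    to_impute = masked.genotypes == MISSING

    random_idx = np.sort(rng.choice(n_haps, size=K, replace=False))
    chrom_blocks = [markers.chrom_indices(c) for c in markers.chromosomes()]
    for i in range(n_samp):
        g_all = masked.genotypes[i]
        obs_all = np.flatnonzero(g_all != MISSING)
        if params.template_selection == "best" and len(obs_all) and K < n_haps:
            # rank templates by agreement with the observed panel genotypes:
            # homozygous sites decide, heterozygous sites are neutral
            Ho = all_H[:, obs_all]
            g = g_all[obs_all]
            score = (1 - Ho)[:, g == 0].sum(axis=1) + Ho[:, g == 2].sum(axis=1)
            templates = np.sort(np.argsort(-score, kind="stable")[:K])
        else:
            templates = random_idx
        H = all_H[templates]
        for cidx in chrom_blocks:
            g = g_all[cidx]
            obs_pos = np.flatnonzero(g != MISSING)
            miss_pos = np.flatnonzero(g == MISSING)
            if len(miss_pos) == 0:
                continue
            if len(obs_pos) == 0:
                posterior[i, cidx[miss_pos]] = ref_triples[cidx[miss_pos]]
                continue
            posterior[i, cidx[miss_pos]] = _hmm_chromosome_posteriors(
                H[:, cidx], g, gpos[cidx], obs_pos, miss_pos, emit, rho, K
            )
    no_panel = [
        c
        for c in markers.chromosomes()
        if not (masked.genotypes[:, markers.chrom_indices(c)] != MISSING).any()
    ]
    if no_panel:
        warnings.warn(
            f"no observed panel SNPs on chromosome(s) {no_panel}; "
            "falling back to reference HWE proportions there",
            RuntimeWarning,
        )
    return _finalise(masked, posterior, to_impute, ref_triples, "hmm", params.seed)


def _hmm_chromosome_posteriors(
    Hc: np.ndarray,
    g: np.ndarray,
    gpos: np.ndarray,
    obs_pos: np.ndarray,
    miss_pos: np.ndarray,
    emit: np.ndarray,
    rho: float,
    K: int,
) -> np.ndarray:
    """Forward–backward over one chromosome for one individual; returns
    genotype posteriors at ``miss_pos``."""
    n_obs = len(obs_pos)
    # emission matrices at informative sites
    E = np.empty((n_obs, K, K))
    for s, pos in enumerate(obs_pos):
        h = Hc[:, pos].astype(np.intp)
        dosage = h[:, None] + h[None, :]
        E[s] = emit[dosage, g[pos]]
    deltas = np.diff(gpos[obs_pos])
    switch = 1.0 - np.exp(-rho * np.maximum(deltas, 0.0))

    F = np.empty((n_obs, K, K))
    f = E[0] / (K * K)
    f /= f.sum()
    F[0] = f
    for s in range(1, n_obs):
        f = _propagate(F[s - 1], switch[s - 1], K) * E[s]
        tot = f.sum()
        if tot <= 0:  # numerically impossible observation; reset
            f = np.full((K, K), 1.0 / (K * K)) * E[s]
            tot = f.sum() or 1.0
        F[s] = f / tot
    B = np.empty((n_obs, K, K))
    B[-1] = 1.0
    for s in range(n_obs - 2, -1, -1):
        b = _propagate(B[s + 1] * E[s + 1], switch[s], K)
        B[s] = b / b.sum()

    out = np.empty((len(miss_pos), 3))
    # masked sites grouped by their bracketing interval of informative sites
    left = np.searchsorted(gpos[obs_pos], gpos[miss_pos], side="right") - 1
    for interval in np.unique(left):
        sel = np.flatnonzero(left == interval)
        mp = miss_pos[sel]
        a = Hc[:, mp].T  # (nm, K) template alleles
        if interval < 0:  # before the first informative site
            r = 1.0 - np.exp(-rho * (gpos[obs_pos[0]] - gpos[mp]))
            back = B[0] * E[0]
            P = np.stack([_propagate(back, ri, K) for ri in r])
        elif interval >= n_obs - 1:  # after the last informative site
            r = 1.0 - np.exp(-rho * (gpos[mp] - gpos[obs_pos[-1]]))
            P = np.stack([_propagate(F[-1], ri, K) for ri in r])
        else:
            rl = 1.0 - np.exp(-rho * (gpos[mp] - gpos[obs_pos[interval]]))
            rr = 1.0 - np.exp(-rho * (gpos[obs_pos[interval + 1]] - gpos[mp]))
            back = B[interval + 1] * E[interval + 1]
            P = np.stack(
                [
                    _propagate(F[interval], rl[t], K) * _propagate(back, rr[t], K)
                    for t in range(len(mp))
                ]
            )
        out[sel] = _genotype_probs_batch(P, a.astype(float))
    return out


def run_external_imputer(
    masked: GenotypeMatrix,
    reference: GenotypeMatrix,
    adapter_config: dict,
    workdir=None,
) -> ImputationResult:
    """Adapter for an external imputation tool (e.g. BEAGLE).

    Writes masked/reference data as PLINK text, runs
    ``adapter_config['command']`` (a list; the placeholders ``{masked}``,
    ``{reference}`` and ``{out}`` are substituted with file prefixes), and
    reads ``<out>.ped/.map`` back as the imputed genotypes.  Posterior triples
    are point masses on the returned genotypes.  Never required by the rest
    of the package: if the executable is absent a FeatureUnavailableError is
    raised.
    """
    import shutil
    import subprocess
    import tempfile
    from pathlib import Path

    from .io import read_plink_text, write_plink_text

    command = adapter_config["command"]
    exe = command[0]
    if shutil.which(exe) is None and not Path(exe).exists():
        raise FeatureUnavailableError(f"external imputer executable {exe!r} not found")

    owns_tmp = workdir is None
    workdir = Path(tempfile.mkdtemp()) if owns_tmp else Path(workdir)
    try:
        masked_prefix = workdir / "masked"
        ref_prefix = workdir / "reference"
        out_prefix = workdir / "imputed"
        write_plink_text(masked, masked_prefix)
        write_plink_text(reference, ref_prefix)
        argv = [
            str(arg).format(masked=masked_prefix, reference=ref_prefix, out=out_prefix)
            for arg in command
        ]
        subprocess.run(argv, check=True, capture_output=True)
        try:
            gm_out, _ = read_plink_text(
                out_prefix.with_suffix(".ped"), out_prefix.with_suffix(".map"),
                ref_path=masked_prefix.with_suffix(".ref"),
            )
        except (OSError, ValueError) as e:
            raise ValueError(f"malformed external imputer output under {out_prefix}: {e}") from e
        if gm_out.sample_ids != masked.sample_ids or len(gm_out.markers) != masked.n_snps:
            raise ValueError(
                f"external imputer output shape mismatch under {out_prefix}"
            )
        to_impute = masked.genotypes == MISSING
        posterior = np.zeros(masked.genotypes.shape + (3,))
        filled = np.where(gm_out.genotypes == MISSING, 0, gm_out.genotypes)
        np.put_along_axis(posterior, filled[..., None], 1.0, axis=-1)
        result = _finalise(
            masked, posterior, to_impute, _hwe_triples(np.zeros(masked.n_snps)),
            "external", None,
        )
        result.best_genotype = gm_out.genotypes.copy()
        return result
    finally:
        if owns_tmp:
            shutil.rmtree(workdir, ignore_errors=True)
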
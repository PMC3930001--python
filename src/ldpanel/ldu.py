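"""Linkage-disequilibrium-unit (LDU) maps from unphased genotypes.

An LDU map assigns each SNP a cumulative coordinate such that, under the
Malecot association model

    rho(d) = (1 - L) * M * exp(-eps * d) + L,

pairwise association (|D'|) declines by a factor e per LDU of separation.
Regions of strong LD span few LDU; recombination hotspots carry many.  The
map is built per chromosome in four steps: (1) |D'| for all SNP pairs closer
than ``max_pair_bp``, with two-locus haplotype frequencies estimated from
unphased genotypes by EM; (2) the asymptote L estimated from the most distant
admissible pairs, the intercept M fixed (default 1, single-origin
assumption); (3) per-interval LDU lengths fitted by non-negative coordinate
descent on the summed squared residuals of the Malecot prediction; (4)
accumulation into map positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix

# genotype-pair -> unambiguous haplotype contributions; haplotype index is
# 2*x + y with x, y the allele-B carriage at locus 1 and 2
_FIXED_HAPS = {
    (0, 0): ((0, 2),),
    (0, 1): ((0, 1), (1, 1)),
    (0, 2): ((1, 2),),
    (1, 0): ((0, 1), (2, 1)),
    (1, 2): ((1, 1), (3, 1)),
    (2, 0): ((2, 2),),
    (2, 1): ((2, 1), (3, 1)),
    (2, 2): ((3, 2),),
}


class DegenerateLocusError(ValueError):
    pass


def estimate_two_locus_haplotype_freqs(
    g1: np.ndarray, g2: np.ndarray, tol: float = 1e-12, max_iter: int = 500
) -> np.ndarray:
    """EM estimate of the four two-locus haplotype frequencies from unphased
    genotypes.

    Returns frequencies ordered (f_ab, f_aB, f_Ab, f_AB) by allele-B carriage
    bits (locus1, locus2) — i.e. index ``2*x + y``.  Only the double
    heterozygote is phase-ambiguous; EM splits it by the current odds of the
    coupling vs repulsion configurations.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[ok], g2[ok]
    n = len(g1)
    if n == 0:
        raise DegenerateLocusError("no jointly non-missing samples")
    p1 = g1.sum() / (2 * n)
    p2 = g2.sum() / (2 * n)
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise DegenerateLocusError("monomorphic locus among jointly non-missing samples")

    table = np.zeros((3, 3))
    np.add.at(table, (g1, g2), 1.0)
    fixed = np.zeros(4)
    for (a, b), contribs in _FIXED_HAPS.items():
        for hap, count in contribs:
            fixed[hap] += count * table[a, b]
    n_dh = table[1, 1]

    # start at linkage equilibrium of the observed marginals
    f = np.array([(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p2), p1 * p2])
    for _ in range(max_iter):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        w = 0.5 if coupling + repulsion == 0 else coupling / (coupling + repulsion)
        counts = fixed + n_dh * np.array([w, 1 - w, 1 - w, w])
        f_new = counts / (2 * n)
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return f


def dprime(hap_freqs: np.ndarray) -> float:
    """Lewontin's |D'| from four haplotype frequencies.

    ``hap_freqs`` ordered as returned by :func:`estimate_two_locus_haplotype_freqs`.
    """
    f = np.asarray(hap_freqs, dtype=float)
    if abs(f.sum() - 1.0) > 1e-6 or (f < -1e-12).any():
        raise ValueError("haplotype frequencies must be non-negative and sum to 1")
    pB1 = f[2] + f[3]  # allele B at locus 1
    pB2 = f[1] + f[3]
    if not (0 < pB1 < 1) or not (0 < pB2 < 1):
        raise ValueError("D' undefined at boundary marginals")
    d = f[3] - pB1 * pB2
    if d >= 0:
        d_max = min(pB1 * (1 - pB2), (1 - pB1) * pB2)
    else:
        d_max = min(pB1 * pB2, (1 - pB1) * (1 - pB2))
    return float(abs(d) / d_max)


def malecot_predicted_association(delta_ldu: np.ndarray | float, M: float, L: float):
    """Malecot prediction with distance already expressed in LDU (eps absorbed)."""
    delta = np.asarray(delta_ldu, dtype=float)
    if np.any(delta < 0):
        raise ValueError("LDU distance must be non-negative")
    out = (1.0 - L) * M * np.exp(-delta) + L
    return float(out) if np.isscalar(delta_ldu) else out


@dataclass
class LDUMap:
    """Cumulative LDU coordinate per SNP on one chromosome."""

    chromosome: str
    snp_ids: list[str]
    bp_positions: np.ndarray
    ldu_positions: np.ndarray
    epsilons: np.ndarray  # per-interval decline rate per bp
    M: float
    L: float
    converged: bool = True
    n_pairs_used: int = 0
    n_pairs_skipped: int = 0

    @property
    def total_span(self) -> float:
        return float(self.ldu_positions[-1]) if len(self.ldu_positions) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chromosome": self.chromosome,
                "bp": self.bp_positions,
                "ldu": self.ldu_positions,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, ax=None):
        """LDU vs Mb curve for this chromosome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.bp_positions / 1e6, self.ldu_positions)
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel("map position (LDU)")
        ax.set_title(f"chromosome {self.chromosome}")
        return ax


def _pairwise_abs_dprime(
    geno: np.ndarray, bp: np.ndarray, max_pair_bp: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """|D'| for all SNP pairs within max_pair_bp; returns (i, j, |D'|, n_skipped)."""
    n = geno.shape[1]
    ii, jj, vals = [], [], []
    skipped = 0
    for i in range(n - 1):
        j_hi = int(np.searchsorted(bp, bp[i] + max_pair_bp, side="right"))
        for j in range(i + 1, j_hi):
            try:
                f = estimate_two_locus_haplotype_freqs(geno[:, i], geno[:, j])
                vals.append(dprime(f))
            except (DegenerateLocusError, ValueError):
                skipped += 1
                continue
            ii.append(i)
            jj.append(j)
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        np.asarray(vals, dtype=float),
        skipped,
    )


def build_ldu_map(
    gm: GenotypeMatrix,
    chromosome: str | None = None,
    max_pair_bp: int = 500_000,
    M: float = 1.0,
    L: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    max_interval_ldu: float = 30.0,
) -> LDUMap:
    """Fit an LDU map for one chromosome from unphased genotypes.

    Interval LDU lengths x_i (= eps_i * bp_i) are fitted by cyclic coordinate
    descent on sum_pairs (pred - |D'|)^2 with pred = (1-L)*M*exp(-sum x) + L.
    Each coordinate update is exact: with u = exp(-x_k) the pair residuals are
    linear in u, so the constrained optimum is a clipped least-squares ratio.
    ``L`` defaults to the mean |D'| of pairs in the top distance decile.
    """
    markers = gm.markers
    if chromosome is None:
        chroms = markers.chromosomes()
        if len(chroms) != 1:
            raise ValueError("specify chromosome for a multi-chromosome matrix")
        chromosome = chroms[0]
    idx = markers.chrom_indices(chromosome)
    if len(idx) < 3:
        raise ValueError("need at least 3 SNPs on the chromosome")
    geno = gm.genotypes[:, idx]
    bp = markers.bp[idx]
    snp_ids = list(markers.snp_ids[idx])
    n = len(idx)

    ii, jj, obs, skipped = _pairwise_abs_dprime(geno, bp, max_pair_bp)
    if len(obs) == 0:
        raise ValueError("no admissible SNP pairs within max_pair_bp")

    dist = bp[jj] - bp[ii]
    if L is None:
        cutoff = np.quantile(dist, 0.9)
        far = dist >= cutoff
        L = float(np.mean(obs[far]))
        L = min(max(L, 0.0), 0.99)

    amp = (1.0 - L) * M
    y = obs - L  # residual association above the asymptote

    # initial x: per-interval inversion of the Malecot formula from adjacent pairs
    x = np.zeros(n - 1)
    adj = jj == ii + 1
    for i, o in zip(ii[adj], obs[adj]):
        rel = (o - L) / amp
        x[i] = -np.log(min(max(rel, np.exp(-max_interval_ldu)), 1.0))

    # pairs spanning each interval k: ii <= k < jj
    pairs_by_interval: list[np.ndarray] = [
        np.flatnonzero((ii <= k) & (jj > k)) for k in range(n - 1)
    ]

    u_min = np.exp(-max_interval_ldu)
    cum = np.concatenate([[0.0], np.cumsum(x)])
    span = cum[jj] - cum[ii]
    converged = False
    for _ in range(max_iter):
        max_delta = 0.0
        for k in range(n - 1):
            p = pairs_by_interval[k]
            if len(p) == 0:
                continue
            rest = span[p] - x[k]
            a = amp * np.exp(-rest)  # pred_p = a_p * exp(-x_k) + L
            denom = float(a @ a)
            if denom <= 0:
                continue
            u = float(a @ y[p]) / denom
            x_new = -np.log(min(max(u, u_min), 1.0))
            if x_new != x[k]:
                span[p] += x_new - x[k]
                max_delta = max(max_delta, abs(x_new - x[k]))
                x[k] = x_new
        if max_delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"LDU fit on chromosome {chromosome} did not converge in {max_iter} "
            "sweeps; returning best map so far",
            RuntimeWarning,
        )

    ldu = np.concatenate([[0.0], np.cumsum(x)])
    widths = np.diff(bp).astype(float)
    return LDUMap(
        chromosome=chromosome,
        snp_ids=snp_ids,
        bp_positions=bp,
        ldu_positions=ldu,
        epsilons=x / widths,
        M=M,
        L=L,
        converged=converged,
        n_pairs_used=len(obs),
        n_pairs_skipped=skipped,
    )
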
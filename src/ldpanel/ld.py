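"""Genotypic linkage disequilibrium (rg2) and genomic relationships.

rg2 is the squared Pearson correlation of 0/1/2 allele counts between two
SNPs — identical to haplotype r^2 under random mating, but computable from
unphased genotypes.  Window summaries average rg2 over all SNP pairs inside
sliding windows anchored at the chromosome's first SNP.  Genomic
relationships use the allele-frequency-centred cross-product matrix
(VanRaden's first construction): Z = G - 2p, GRM = Z Z' / (2 * sum p(1-p)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix
from .qc import allele_b_freq


def rg2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared genotypic correlation between two SNPs (jointly non-missing)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[ok], g2[ok]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rg2 undefined: constant genotype vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairwise_rg2_matrix(geno: np.ndarray) -> np.ndarray:
    """All-pairs rg2 for a (samples x SNPs) block; NaN where undefined.

    With no missing data this is a single correlation-matrix call; missing
    entries fall back to pairwise-complete computation.
    """
    g = geno.astype(float)
    if (g == MISSING).any():
        g[g == MISSING] = np.nan
        df = pd.DataFrame(g)
        r = df.corr(min_periods=2).to_numpy()
    else:
        sd = g.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(g, rowvar=False)
        r[sd == 0, :] = np.nan
        r[:, sd == 0] = np.nan
    return r**2


def sliding_window_mean_rg2(
    gm: GenotypeMatrix,
    window_bp: int = 1_000_000,
    step_bp: int = 500_000,
) -> pd.DataFrame:
    """Mean pairwise rg2 in half-open sliding windows along each chromosome.

    Windows are anchored at the first SNP of the chromosome; windows holding
    fewer than 2 SNPs are flagged empty (NaN mean).
    """
    if window_bp < step_bp:
        raise ValueError("window must be at least as large as the step")
    markers = gm.markers
    rows = []
    for c in markers.chromosomes():
        idx = markers.chrom_indices(c)
        bp = markers.bp[idx]
        first, last = bp[0], bp[-1]
        span = last - first
        n_windows = max(int((span - window_bp) // step_bp) + 1, 1) if span >= window_bp else 1
        for w in range(n_windows):
            start = first + w * step_bp
            end = start + window_bp
            inside = idx[(bp >= start) & (bp < end)]
            if len(inside) < 2:
                rows.append((c, start, end, len(inside), 0, np.nan))
                continue
            r2 = _pairwise_rg2_matrix(gm.genotypes[:, inside])
            iu = np.triu_indices(len(inside), k=1)
            vals = r2[iu]
            vals = vals[np.isfinite(vals)]
            rows.append(
                (c, start, end, len(inside), len(vals),
                 float(vals.mean()) if len(vals) else np.nan)
            )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "window_start", "window_end", "n_snps", "n_pairs", "mean_rg2"],
    )


def genomic_relationship_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Allele-frequency-centred GRM over all samples.

    Missing genotypes are centred to zero (mean imputation); monomorphic SNPs
    contribute nothing and are dropped from the scaling.
    """
    p = allele_b_freq(gm)
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs for the GRM")
    g = gm.genotypes[:, poly].astype(float)
    pp = p[poly]
    z = np.where(g == MISSING, 0.0, g - 2 * pp)
    scale = 2.0 * np.sum(pp * (1 - pp))
    return (z @ z.T) / scale


def mean_genomic_relationship(
    gm: GenotypeMatrix, group_a: list[str], group_b: list[str]
) -> float:
    """Mean off-diagonal genomic relationship between two sample groups.

    Self-pairs are never counted; when the groups coincide this is the mean
    over distinct within-group pairs.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    grm = genomic_relationship_matrix(gm)
    ia = gm.sample_indices(group_a)
    ib = gm.sample_indices(group_b)
    sub = grm[np.ix_(ia, ib)]
    offdiag = ~np.equal.outer(ia, ib)
    if not offdiag.any():
        raise ValueError("no distinct sample pairs between the groups")
    return float(sub[offdiag].mean())
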
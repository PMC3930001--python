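"""SNP quality control: call-rate and minor-allele-frequency filters.

QC is meant to be computed on the panel-design sample set (Set A of the data
flow), and the surviving SNP list then applied to every later stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix


def allele_b_freq(gm: GenotypeMatrix) -> np.ndarray:
    """Per-SNP frequency of allele B among non-missing genotypes (NaN if all missing)."""
    g = gm.genotypes
    obs = g != MISSING
    n_alleles = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(obs, g, 0).sum(axis=0) / np.where(n_alleles > 0, n_alleles, np.nan)


def compute_maf(gm: GenotypeMatrix, snp_id: str) -> float:
    """Minor allele frequency of one SNP among non-missing genotypes."""
    j = gm.markers.index_of([snp_id])[0]
    col = gm.genotypes[:, j]
    obs = col != MISSING
    if not obs.any():
        raise ValueError(f"MAF undefined: all genotypes missing at {snp_id!r}")
    p_b = col[obs].sum() / (2 * obs.sum())
    return float(min(p_b, 1.0 - p_b))


def compute_mafs(gm: GenotypeMatrix) -> np.ndarray:
    """Vectorised per-SNP MAF (NaN where all genotypes are missing)."""
    p = allele_b_freq(gm)
    return np.minimum(p, 1.0 - p)


@dataclass
class QCReport:
    """Per-SNP QC outcome plus per-chromosome exclusion percentages."""

    per_snp: pd.DataFrame  # snp_id, chromosome, call_rate, maf, excluded, reason
    min_call_rate: float
    min_maf: float

    @property
    def n_excluded(self) -> int:
        return int(self.per_snp["excluded"].sum())

    @property
    def kept_snp_ids(self) -> list[str]:
        return self.per_snp.loc[~self.per_snp["excluded"], "snp_id"].tolist()

    def exclusion_percent_by_chromosome(self) -> pd.Series:
        return self.per_snp.groupby("chromosome", sort=False)["excluded"].mean() * 100.0

    def to_tsv(self, path: os.PathLike) -> None:
        self.per_snp.to_csv(path, sep="\t", index=False)


def filter_snps(
    gm: GenotypeMatrix, min_call_rate: float = 0.95, min_maf: float = 0.01
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs genotyped in less than ``min_call_rate`` of samples or with
    MAF below ``min_maf``; both comparisons are strict, so a SNP exactly at a
    threshold is kept.  Returns the filtered matrix and a QCReport.
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    g = gm.genotypes
    obs = g != MISSING
    call_rate = obs.mean(axis=0) if gm.n_samples else np.ones(gm.n_snps)
    maf = compute_mafs(gm)

    low_call = call_rate < min_call_rate
    low_maf = np.isnan(maf) | (maf < min_maf)
    excluded = low_call | low_maf
    reason = np.where(low_call, "call_rate", np.where(low_maf, "maf", ""))

    report = QCReport(
        per_snp=pd.DataFrame(
            {
                "snp_id": gm.markers.snp_ids,
                "chromosome": gm.markers.chromosome,
                "call_rate": call_rate,
                "maf": maf,
                "excluded": excluded,
                "reason": reason,
            }
        ),
        min_call_rate=min_call_rate,
        min_maf=min_maf,
    )
    kept = np.flatnonzero(~excluded)
    return gm.take_snps(kept), report
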
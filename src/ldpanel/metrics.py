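"""Imputation accuracy measures, per SNP and per individual.

Two measures are computed over the evaluated (masked, truth-known) cells:
the proportion of genotypes imputed exactly right, and the Pearson
correlation of the true and imputed 0/1/2 allele counts.  SNPs (or
individuals) whose true or imputed vector is constant are excluded from the
correlation — low-MAF SNPs would otherwise contribute undefined or
degenerate values.  Because a rare-allele SNP is imputed "correctly" by
chance most of the time, each SNP also gets an adjusted accuracy

    (accuracy - random_accuracy) / (1 - random_accuracy),

where random_accuracy = p^4 + 4 p^2 q^2 + q^4 is the expected concordance of
HWE-random imputation at the reference allele frequencies.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix
from .impute import ImputationResult, expected_random_accuracy


def proportion_correct(true_g: np.ndarray, imputed_g: np.ndarray) -> float:
    """Exact-match fraction over cells with known truth."""
    true_g = np.asarray(true_g)
    imputed_g = np.asarray(imputed_g)
    if true_g.shape != imputed_g.shape:
        raise ValueError("vectors must have equal length")
    ok = true_g != MISSING
    if not ok.any():
        raise ValueError("no evaluated cells: truth entirely missing")
    return float(np.mean(true_g[ok] == imputed_g[ok]))


def genotype_correlation(true_g: np.ndarray, imputed_g: np.ndarray) -> float | None:
    """Pearson correlation of true vs imputed allele counts; ``None`` when
    either vector is constant over the evaluated cells (excluded)."""
    true_g = np.asarray(true_g, dtype=float)
    imputed_g = np.asarray(imputed_g, dtype=float)
    ok = (true_g != MISSING) & (imputed_g != MISSING)
    t, m = true_g[ok], imputed_g[ok]
    if len(t) < 2 or np.ptp(t) == 0 or np.ptp(m) == 0:
        return None
    return float(np.corrcoef(t, m)[0, 1])


def adjusted_accuracy(accuracy: float, random_accuracy) -> float:
    """Scale accuracy so that HWE-random imputation maps to 0 and perfect to 1."""
    random_accuracy = np.asarray(random_accuracy, dtype=float)
    if np.any((random_accuracy < 0) | (random_accuracy >= 1)):
        raise ValueError("random_accuracy must lie in [0, 1): monomorphic reference")
    out = (accuracy - random_accuracy) / (1.0 - random_accuracy)
    return float(out) if out.ndim == 0 else out


@dataclass
class AccuracyReport:
    per_snp: pd.DataFrame
    per_individual: pd.DataFrame
    summary: dict

    def summary_line(self, axis: str = "snp", measure: str = "proportion_correct") -> str:
        """'mean (min, max)' formatting used by the per-density summaries."""
        s = self.summary[axis][measure]
        return f"{s['mean']:.2f} ({s['min']:.2f}, {s['max']:.2f})"

    def write(self, outdir: os.PathLike, prefix: str = "accuracy") -> None:
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        self.per_snp.to_csv(os.path.join(outdir, f"{prefix}_per_snp.tsv"), sep="\t", index=False)
        self.per_individual.to_csv(
            os.path.join(outdir, f"{prefix}_per_individual.tsv"), sep="\t", index=False
        )
        with open(os.path.join(outdir, f"{prefix}_summary.json"), "w") as fh:
            json.dump(self.summary, fh, indent=2)


def _axis_summary(df: pd.DataFrame, measures: list[str]) -> dict:
    out = {}
    for m in measures:
        vals = df[m].dropna()
        out[m] = {
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "min": float(vals.min()) if len(vals) else float("nan"),
            "max": float(vals.max()) if len(vals) else float("nan"),
            "n": int(len(vals)),
        }
    return out


def build_accuracy_report(
    truth: GenotypeMatrix,
    result: ImputationResult,
    mask: np.ndarray,
    ref_freqs: np.ndarray,
) -> AccuracyReport:
    """Evaluate an imputation run against the truth over the masked cells.

    ``mask`` is a boolean samples x SNPs matrix of cells that were imputed
    and should be scored; cells with missing truth are dropped.  ``ref_freqs``
    are reference-population allele-B frequencies, used for the expected
    random accuracy and the MAF column.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != truth.genotypes.shape:
        raise ValueError("mask shape must match the truth matrix")
    evaluated = mask & (truth.genotypes != MISSING)
    if not evaluated.any():
        raise ValueError("empty evaluation mask")
    imputed = result.best_genotype
    correct = (imputed == truth.genotypes) & evaluated

    ref_freqs = np.asarray(ref_freqs, dtype=float)
    ref_maf = np.minimum(ref_freqs, 1 - ref_freqs)

    # --- per SNP ---
    rows = []
    for j in range(truth.n_snps):
        cells = evaluated[:, j]
        n_eval = int(cells.sum())
        if n_eval == 0:
            continue
        prop = float(correct[cells, j].sum() / n_eval)
        corr = genotype_correlation(truth.genotypes[cells, j], imputed[cells, j])
        p = ref_freqs[j]
        rand = float(expected_random_accuracy(p)) if not np.isnan(p) else np.nan
        adj = (
            adjusted_accuracy(prop, rand)
            if np.isfinite(rand) and rand < 1
            else np.nan
        )
        rows.append(
            {
                "snp_id": truth.markers.snp_ids[j],
                "chromosome": truth.markers.chromosome[j],
                "n_eval": n_eval,
                "proportion_correct": prop,
                "correlation": np.nan if corr is None else corr,
                "correlation_excluded": corr is None,
                "ref_maf": ref_maf[j],
                "random_expected": rand,
                "adjusted": adj,
            }
        )
    per_snp = pd.DataFrame(rows)

    # --- per individual (constant-vector exclusion applied symmetrically) ---
    rows = []
    for i in range(truth.n_samples):
        cells = evaluated[i]
        n_eval = int(cells.sum())
        if n_eval == 0:
            continue
        prop = float(correct[i, cells].sum() / n_eval)
        corr = genotype_correlation(truth.genotypes[i, cells], imputed[i, cells])
        rows.append(
            {
                "sample_id": truth.sample_ids[i],
                "n_eval": n_eval,
                "proportion_correct": prop,
                "correlation": np.nan if corr is None else corr,
                "correlation_excluded": corr is None,
            }
        )
    per_individual = pd.DataFrame(rows)

    summary = {
        "snp": _axis_summary(per_snp, ["proportion_correct", "correlation", "adjusted"]),
        "individual": _axis_summary(per_individual, ["proportion_correct", "correlation"]),
        "n_cells_evaluated": int(evaluated.sum()),
        "n_cells_correct": int(correct.sum()),
        "engine": result.engine,
    }
    return AccuracyReport(per_snp=per_snp, per_individual=per_individual, summary=summary)
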
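"""Reading and writing genotype data: PLINK text (.ped/.map), panels, VCF.

The PLINK text convention is used as the package's interchange format:
whitespace-delimited, one sample per .ped line (six leading pedigree columns,
then two allele characters per SNP, ``0`` meaning a missing allele) and one
SNP per .map line (chromosome, id, cM, bp).  A companion ``<prefix>.ref``
file (snp_id, allele_a) records the reference orientation of each SNP so the
0/1/2 coding is stable across write/read cycles; when absent, allele A is
taken as the major allele of the population being read (ties broken to the
lexicographically smaller allele).
"""

from __future__ import annotations

import os
from pathlib import Path
import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix, MarkerMap, Panel


class PlinkParseError(ValueError):
    pass


def _read_map(map_path: os.PathLike) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise PlinkParseError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            try:
                bp = int(parts[3])
            except ValueError as e:
                raise PlinkParseError(f"{map_path}:{ln}: bad bp position {parts[3]!r}") from e
            rows.append((parts[0], parts[1], float(parts[2]), bp))
    return pd.DataFrame(rows, columns=["chromosome", "snp_id", "cm", "bp"])


def read_plink_text(
    ped_path: os.PathLike, map_path: os.PathLike, ref_path: os.PathLike | None = None
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a PLINK text fileset into a GenotypeMatrix + MarkerMap.

    Genotypes are converted to 0/1/2 allele-B counts.  Reference orientation
    comes from ``ref_path`` (or ``<ped stem>.ref`` if that file exists),
    otherwise allele A is the major allele observed in this file.
    A half-missing genotype ("A 0") is treated as fully missing.
    """
    map_df = _read_map(map_path)
    n_snps = len(map_df)

    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise PlinkParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} columns "
                    f"({n_snps} SNPs), got {len(parts)}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(np.asarray(parts[6:], dtype="U8"))
    alleles = (
        np.asarray(allele_rows).reshape(len(sample_ids), n_snps, 2)
        if sample_ids
        else np.empty((0, n_snps, 2), dtype="U8")
    )

    if ref_path is None:
        candidate = Path(str(ped_path)).with_suffix(".ref")
        if candidate.exists():
            ref_path = candidate
    ref_alleles: dict[str, str] = {}
    if ref_path is not None:
        ref_df = pd.read_csv(ref_path, sep=r"\s+", header=None, names=["snp_id", "allele_a"],
                             dtype=str)
        ref_alleles = dict(zip(ref_df["snp_id"], ref_df["allele_a"]))

    geno = np.full((len(sample_ids), n_snps), MISSING, dtype=np.int8)
    allele_a = np.empty(n_snps, dtype="U8")
    allele_b = np.empty(n_snps, dtype="U8")
    for j in range(n_snps):
        col = alleles[:, j, :]
        observed = col[(col[:, 0] != "0") & (col[:, 1] != "0")]
        uniq, counts = np.unique(observed, return_counts=True)
        uniq, counts = list(uniq), list(counts)
        if len(uniq) > 2:
            raise PlinkParseError(
                f"SNP {map_df['snp_id'][j]!r} has >2 alleles: {sorted(uniq)}"
            )
        snp = map_df["snp_id"][j]
        if snp in ref_alleles:
            a = ref_alleles[snp]
            others = [u for u in uniq if u != a]
            b = others[0] if others else "B"
        elif len(uniq) == 0:
            a, b = "A", "B"
        elif len(uniq) == 1:
            a, b = uniq[0], "B"
        else:
            # major allele first; tie broken to lexicographically smaller
            order = sorted(range(2), key=lambda k: (-counts[k], uniq[k]))
            a, b = uniq[order[0]], uniq[order[1]]
        allele_a[j], allele_b[j] = a, b
        if len(sample_ids):
            ok = (col[:, 0] != "0") & (col[:, 1] != "0")
            b_count = (col[:, 0] == b).astype(np.int8) + (col[:, 1] == b).astype(np.int8)
            known = np.isin(col[:, 0], (a, b)) & np.isin(col[:, 1], (a, b))
            geno[ok & known, j] = b_count[ok & known]

    markers = MarkerMap(
        pd.DataFrame(
            {
                "snp_id": map_df["snp_id"],
                "chromosome": map_df["chromosome"],
                "bp": map_df["bp"],
                "allele_a": allele_a,
                "allele_b": allele_b,
            }
        )
    )
    # MarkerMap sorts by (chromosome, bp); reorder genotype columns to match
    id_to_col = {s: j for j, s in enumerate(map_df["snp_id"])}
    col_order = np.asarray([id_to_col[s] for s in markers.snp_ids], dtype=np.intp)
    return GenotypeMatrix(sample_ids, markers, geno[:, col_order]), markers


def write_plink_text(gm: GenotypeMatrix, prefix: os.PathLike) -> tuple[Path, Path]:
    """Write a GenotypeMatrix as <prefix>.ped/.map plus a <prefix>.ref sidecar.

    Lossless for coding, missingness and marker order: the .ref file pins each
    SNP's allele-A orientation for re-reading.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df = gm.markers.df
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for r in df.itertuples():
            fh.write(f"{r.chromosome}\t{r.snp_id}\t0\t{r.bp}\n")
    with open(prefix.with_suffix(".ref"), "w") as fh:
        for r in df.itertuples():
            fh.write(f"{r.snp_id}\t{r.allele_a}\n")

    a = df["allele_a"].to_numpy(dtype="U8")
    b = df["allele_b"].to_numpy(dtype="U8")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            g = gm.genotypes[i]
            first = np.where(g >= 1, b, a)
            second = np.where(g == 2, b, a)
            first = np.where(g == MISSING, "0", first)
            second = np.where(g == MISSING, "0", second)
            fields = np.empty(2 * len(g), dtype="U8")
            fields[0::2] = first
            fields[1::2] = second
            fh.write(f"{sid} {sid} 0 0 0 -9 " + " ".join(fields) + "\n")
    return ped_path, map_path


def read_vcf(vcf_path: os.PathLike) -> tuple[GenotypeMatrix, MarkerMap]:
    """Convenience reader for diploid GT-only VCF (biallelic sites).

    Allele A is the VCF REF allele; genotypes count ALT alleles.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    rows, geno_cols = [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            continue
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows.append((snp_id, var.CHROM, var.POS, var.REF, var.ALT[0]))
        gt = np.asarray(var.genotype.array())[:, :2]
        g = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        geno_cols.append(g.astype(np.int8))
    markers = MarkerMap(
        pd.DataFrame(rows, columns=["snp_id", "chromosome", "bp", "allele_a", "allele_b"])
    )
    geno = np.column_stack(geno_cols) if geno_cols else np.empty((len(sample_ids), 0), np.int8)
    return GenotypeMatrix(sample_ids, markers, geno), markers


def write_panel(panel: Panel, path: os.PathLike) -> Path:
    """Write a panel as one snp_id per line, with a JSON sidecar of metadata."""
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for snp in panel.snp_ids:
            fh.write(snp + "\n")
    meta = {
        "method": panel.method,
        "target_total": panel.target_total,
        "coordinate_system": panel.coordinate_system,
        "d_used": panel.d_used,
        "cost": panel.cost,
        "seed": panel.seed,
        "per_chromosome_sizes": {c: len(v) for c, v in panel.per_chromosome.items()},
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    return path


def read_panel_ids(path: os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
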
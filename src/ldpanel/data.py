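"""Core containers: marker maps, genotype matrices, panels and sample splits.

Genotype coding follows the convention used throughout the package: at each
biallelic SNP, ``0`` is the homozygote for allele A, ``1`` the heterozygote,
``2`` the homozygote for allele B, and ``-1`` a missing genotype.  Allele A is
the recorded reference orientation of the SNP (by default the major allele in
the population the data were read from), so a genotype is the count of the
B (usually minor) allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1


class MarkerMap:
    """Ordered collection of SNP records.

    Wraps a DataFrame with columns ``snp_id``, ``chromosome``, ``bp``
    (1-based physical position), ``allele_a``, ``allele_b`` and, optionally,
    ``ldu`` (cumulative linkage-disequilibrium-unit coordinate) and ``morgan``
    (genetic-map coordinate).  Records are kept sorted by (chromosome, bp);
    within a chromosome bp positions must be strictly increasing.
    """

    REQUIRED = ("snp_id", "chromosome", "bp", "allele_a", "allele_b")

    def __init__(self, df: pd.DataFrame):
        missing_cols = [c for c in self.REQUIRED if c not in df.columns]
        if missing_cols:
            raise ValueError(f"marker map missing columns: {missing_cols}")
        df = df.reset_index(drop=True).copy()
        df["chromosome"] = df["chromosome"].astype(str)
        df["bp"] = df["bp"].astype(np.int64)
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r} in marker map")
        # stable sort keeps input order of chromosomes of first appearance
        order = pd.unique(df["chromosome"])
        chrom_rank = {c: i for i, c in enumerate(order)}
        df = df.sort_values(
            ["chromosome", "bp"], key=lambda s: s.map(chrom_rank) if s.name == "chromosome" else s,
            kind="mergesort",
        ).reset_index(drop=True)
        for chrom, sub in df.groupby("chromosome", sort=False):
            b = sub["bp"].to_numpy()
            if np.any(np.diff(b) <= 0):
                raise ValueError(f"bp positions not strictly increasing on chromosome {chrom}")
            if "ldu" in df.columns:
                l = sub["ldu"].to_numpy(dtype=float)
                if np.all(np.isfinite(l)) and np.any(np.diff(l) < -1e-12):
                    raise ValueError(f"ldu positions decreasing on chromosome {chrom}")
        self.df = df
        self._index = {s: i for i, s in enumerate(df["snp_id"])}

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerMap):
            return NotImplemented
        a = self.df[list(self.REQUIRED)].reset_index(drop=True)
        b = other.df[list(self.REQUIRED)].reset_index(drop=True)
        return a.equals(b)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def bp(self) -> np.ndarray:
        return self.df["bp"].to_numpy()

    @property
    def chromosome(self) -> np.ndarray:
        return self.df["chromosome"].to_numpy()

    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.df["chromosome"]))

    def index_of(self, snp_ids: Iterable[str]) -> np.ndarray:
        """Column indices of the given SNP ids; unknown ids raise KeyError."""
        out = []
        for s in snp_ids:
            if s not in self._index:
                raise KeyError(f"unknown SNP id {s!r}")
            out.append(self._index[s])
        return np.asarray(out, dtype=np.intp)

    def chrom_indices(self, chromosome: str) -> np.ndarray:
        return np.flatnonzero(self.df["chromosome"].to_numpy() == chromosome)

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.df.iloc[np.sort(np.asarray(indices))])


class GenotypeMatrix:
    """samples x SNPs allele-count genotypes, optionally with truth phase.

    ``genotypes`` is an int8 array coded 0/1/2 with -1 for missing.
    ``haplotypes``, when present, is a (2*n_samples) x n_snps 0/1 array whose
    rows 2i and 2i+1 are the two haplotypes of sample i; their per-site sum
    must reproduce the genotype.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        markers: MarkerMap,
        genotypes: np.ndarray,
        haplotypes: np.ndarray | None = None,
    ):
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.shape != (len(sample_ids), len(markers)):
            raise ValueError(
                f"genotype shape {genotypes.shape} does not match "
                f"{len(sample_ids)} samples x {len(markers)} SNPs"
            )
        bad = ~np.isin(genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotypes must be coded 0/1/2 or -1 (missing)")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if haplotypes is not None:
            haplotypes = np.asarray(haplotypes, dtype=np.int8)
            if haplotypes.shape != (2 * len(sample_ids), len(markers)):
                raise ValueError("haplotype shape inconsistent with samples x SNPs")
            sums = haplotypes[0::2] + haplotypes[1::2]
            obs = genotypes != MISSING
            if not np.array_equal(sums[obs], genotypes[obs]):
                raise ValueError("haplotype sums do not reproduce genotypes")
        self.sample_ids = list(sample_ids)
        self.markers = markers
        self.genotypes = genotypes
        self.haplotypes = haplotypes
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        return np.asarray([self._sample_index[s] for s in sample_ids], dtype=np.intp)

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(sample_ids)
        hap = None
        if self.haplotypes is not None:
            hidx = np.repeat(2 * idx, 2) + np.tile([0, 1], len(idx))
            hap = self.haplotypes[hidx]
        return GenotypeMatrix(list(sample_ids), self.markers, self.genotypes[idx], hap)

    def take_snps(self, snp_indices: np.ndarray) -> "GenotypeMatrix":
        snp_indices = np.sort(np.asarray(snp_indices, dtype=np.intp))
        hap = None if self.haplotypes is None else self.haplotypes[:, snp_indices]
        return GenotypeMatrix(
            self.sample_ids, self.markers.subset(snp_indices),
            self.genotypes[:, snp_indices], hap,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.markers == other.markers
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class Panel:
    """A per-chromosome ordered subset of SNP ids selected for a low-density panel."""

    method: str  # bpEQ | bpMAF | lduMAF
    target_total: int
    per_chromosome: dict[str, list[str]] = field(default_factory=dict)
    d_used: dict[str, float] = field(default_factory=dict)
    coordinate_system: str = "bp"
    cost: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    @property
    def snp_ids(self) -> list[str]:
        out: list[str] = []
        for ids in self.per_chromosome.values():
            out.extend(ids)
        return out

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.per_chromosome.values())


@dataclass
class SampleSplit:
    """Partition of a sample set into labelled subsets (Set A/B/C style)."""

    labels: dict[str, str]
    seed: int

    def set(self, label: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == label]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for l in self.labels.values():
            out[l] = out.get(l, 0) + 1
        return out


def mask_to_panel(gm: GenotypeMatrix, panel: Panel | Sequence[str]) -> GenotypeMatrix:
    """Set genotypes at all non-panel SNPs to missing.

    The marker map is unchanged (all columns retained); panel SNPs keep their
    observed genotypes.  This emulates genotyping test individuals on the
    low-density panel only.  Truth phase, if any, is dropped from the result.
    """
    snp_ids = panel.snp_ids if isinstance(panel, Panel) else list(panel)
    keep = gm.markers.index_of(snp_ids)  # raises on unknown id
    masked = np.full_like(gm.genotypes, MISSING)
    masked[:, keep] = gm.genotypes[:, keep]
    return GenotypeMatrix(gm.sample_ids, gm.markers, masked, haplotypes=None)


def split_samples(
    sample_ids: Sequence[str],
    sizes_or_fractions: Sequence[float | int],
    seed: int,
    labels: Sequence[str] | None = None,
) -> SampleSplit:
    """Seeded uniform random partition of samples into labelled sets.

    Entries of ``sizes_or_fractions`` that are integers are absolute sizes
    drawn first; trailing float entries are fractions of the *remaining*
    samples and must sum to 1.  Fractional sizes are rounded to the nearest
    integer, with the last set receiving the remainder — e.g. 853 samples with
    spec (200, 0.75, 0.25) gives sets of 200, 490 and 163.
    """
    n = len(sample_ids)
    spec = list(sizes_or_fractions)
    if labels is None:
        labels = [chr(ord("A") + i) for i in range(len(spec))]
    if len(labels) != len(spec):
        raise ValueError("labels length must match spec length")

    counts: list[int] = []
    remaining = n
    frac_base = None
    fracs: list[float] = []
    for entry in spec:
        if isinstance(entry, (int, np.integer)) and not isinstance(entry, bool):
            if frac_base is not None:
                raise ValueError("absolute sizes must precede fractions")
            if entry > remaining:
                raise ValueError(f"requested size {entry} exceeds remaining {remaining}")
            counts.append(int(entry))
            remaining -= int(entry)
        else:
            if frac_base is None:
                frac_base = remaining
            fracs.append(float(entry))
            counts.append(-1)  # placeholder
    if fracs:
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {sum(fracs)}, expected 1")
        sizes = [int(round(f * frac_base)) for f in fracs]
        sizes[-1] = frac_base - sum(sizes[:-1])
        if min(sizes) < 0:
            raise ValueError("fraction rounding produced a negative set size")
        it = iter(sizes)
        counts = [c if c >= 0 else next(it) for c in counts]
    elif remaining != 0:
        raise ValueError(f"sizes sum to {n - remaining}, expected {n}")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    label_arr = np.empty(n, dtype=object)
    start = 0
    for lab, c in zip(labels, counts):
        label_arr[perm[start : start + c]] = lab
        start += c
    return SampleSplit({s: label_arr[i] for i, s in enumerate(sample_ids)}, seed)
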
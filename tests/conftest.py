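import numpy as np
import pandas as pd
import pytest

from ldpanel import GenotypeMatrix, MarkerMap, SimConfig, simulate_population


def make_markers(bps, chrom="1", ldu=None):
    df = pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(len(bps))],
            "chromosome": chrom,
            "bp": bps,
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    if ldu is not None:
        df["ldu"] = ldu
    return MarkerMap(df)


def make_gm(genotypes, bps=None, chrom="1", haplotypes=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if bps is None:
        bps = list(range(1, m + 1))
    markers = make_markers(bps, chrom=chrom)
    return GenotypeMatrix([f"s{i}" for i in range(n)], markers, genotypes, haplotypes)


@pytest.fixture(scope="session")
def small_pop():
    """One 0.3-Morgan chromosome, ~120 chip SNPs, 300 individuals."""
    cfg = SimConfig(
        chrom_morgans=(0.3,), snp_density_per_morgan=400, n_samples=300, seed=42
    )
    gm, markers = simulate_population(cfg)
    return gm


@pytest.fixture(scope="session")
def small_pop_sets(small_pop):
    """Design/reference/test split of the small population."""
    from ldpanel import split_samples

    split = split_samples(small_pop.sample_ids, [80, 0.75, 0.25], seed=7)
    return tuple(small_pop.take_samples(split.set(x)) for x in "ABC")
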
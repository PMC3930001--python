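"""End-to-end experiment orchestration.

The experiment design mirrors the standard low-density-panel study data
flow: the full cohort is split into a panel-design set (A), a reference set
(B) and a test set (C); SNP QC and — when needed — the LDU map are computed
on A only; panels are selected per method x density from A; the test set is
masked down to each panel and imputed from B with both the random baseline
and the haplotype-copying engine; accuracy is scored against the withheld
truth.  The between-population variant additionally imputes a second
population either from the first population's reference set (assessment 1)
or from a 75/25 split of the second population itself (assessment 2 — sets
D and E), with panels always designed on population 1's Set A.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import GenotypeMatrix, mask_to_panel, split_samples
from .impute import HmmParams, impute_hmm, impute_random
from .ldu import build_ldu_map
from .metrics import build_accuracy_report
from .panels import GAParams, design_panel
from .qc import allele_b_freq, filter_snps
from .simulate import SimConfig, simulate_population, simulate_split_populations

_KNOWN_KEYS = {
    "sim", "plink_prefix", "methods", "panel_sizes", "engines", "seed",
    "split", "outdir", "hmm", "ga", "qc",
}


@dataclass
class ExperimentConfig:
    sim: SimConfig | None = None
    plink_prefix: str | None = None
    methods: tuple = ("bpEQ", "bpMAF")
    panel_sizes: tuple = (36,)
    engines: tuple = ("random", "hmm")
    seed: int = 0
    split: tuple = (200, 0.75, 0.25)
    outdir: str = "ldpanel_report"
    hmm: HmmParams = field(default_factory=HmmParams)
    ga: GAParams = field(default_factory=GAParams)
    min_call_rate: float = 0.95
    min_maf: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        if "sim" in raw:
            kwargs["sim"] = SimConfig(**raw["sim"])
        if "hmm" in raw:
            kwargs["hmm"] = HmmParams(**raw["hmm"])
        if "ga" in raw:
            kwargs["ga"] = GAParams(**raw["ga"])
        if "qc" in raw:
            kwargs["min_call_rate"] = raw["qc"].get("min_call_rate", 0.95)
            kwargs["min_maf"] = raw["qc"].get("min_maf", 0.01)
        for key in ("plink_prefix", "seed", "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("methods", "panel_sizes", "engines", "split"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        return cls(**kwargs)


def _load_or_simulate(cfg: ExperimentConfig) -> GenotypeMatrix:
    if cfg.sim is not None:
        gm, _ = simulate_population(cfg.sim)
        return gm
    if cfg.plink_prefix is not None:
        from .io import read_plink_text

        gm, _ = read_plink_text(
            Path(cfg.plink_prefix).with_suffix(".ped"),
            Path(cfg.plink_prefix).with_suffix(".map"),
        )
        return gm
    raise ValueError("config must name either a SimConfig or a PLINK prefix")


def _log(log: list, stage: str, **info):
    entry = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **info}
    log.append(entry)


def _impute_and_score(
    engine: str,
    masked: GenotypeMatrix,
    reference: GenotypeMatrix,
    truth: GenotypeMatrix,
    cfg: ExperimentConfig,
    seed: int,
):
    from .data import MISSING

    ref_freqs = allele_b_freq(reference)
    if engine == "random":
        result = impute_random(masked, ref_freqs, seed=seed)
    elif engine == "hmm":
        params = HmmParams(**{**asdict(cfg.hmm), "seed": seed})
        result = impute_hmm(masked, reference, params)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    mask = masked.genotypes == MISSING
    return build_accuracy_report(truth, result, mask, ref_freqs)


def run_within_population_experiment(config: ExperimentConfig) -> Path:
    """Method x density x engine grid on one population; returns report dir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    rng = np.random.default_rng(config.seed)

    gm = _load_or_simulate(config)
    _log(log, "load", n_samples=gm.n_samples, n_snps=gm.n_snps)

    split = split_samples(gm.sample_ids, list(config.split), seed=config.seed)
    set_a = gm.take_samples(split.set("A"))
    set_b = gm.take_samples(split.set("B"))
    set_c = gm.take_samples(split.set("C"))
    _log(log, "split", sizes=split.sizes())

    qc_a, qc_report = filter_snps(set_a, config.min_call_rate, config.min_maf)
    kept = qc_report.kept_snp_ids
    keep_idx = gm.markers.index_of(kept)
    set_a, set_b, set_c = (s.take_snps(keep_idx) for s in (set_a, set_b, set_c))
    qc_report.to_tsv(outdir / "qc_report.tsv")
    _log(log, "qc", n_kept=len(kept), n_excluded=qc_report.n_excluded)

    ldu_maps = None
    if "lduMAF" in config.methods:
        ldu_maps = {}
        for c in set_a.markers.chromosomes():
            lmap = build_ldu_map(set_a, chromosome=c)
            lmap.to_tsv(outdir / f"ldu_map_chr{c}.tsv")
            ldu_maps[c] = lmap
            _log(log, "ldu_map", chromosome=c, span=lmap.total_span,
                 converged=lmap.converged)

    grid_rows = []
    for size in config.panel_sizes:
        for method in config.methods:
            panel_seed = int(rng.integers(0, 2**31 - 1))
            panel = design_panel(
                set_a, method, size, seed=panel_seed, ldu_maps=ldu_maps,
                ga_params=config.ga,
            )
            masked = mask_to_panel(set_c, panel)
            for engine in config.engines:
                report = _impute_and_score(
                    engine, masked, set_b, set_c, config, seed=config.seed
                )
                report.write(outdir, prefix=f"{method}_{size}_{engine}")
                s = report.summary
                grid_rows.append(
                    {
                        "panel_size": size,
                        "method": method,
                        "engine": engine,
                        "mean_prop_correct": s["snp"]["proportion_correct"]["mean"],
                        "min_prop_correct": s["snp"]["proportion_correct"]["min"],
                        "max_prop_correct": s["snp"]["proportion_correct"]["max"],
                        "mean_correlation": s["snp"]["correlation"]["mean"],
                        "mean_adjusted": s["snp"]["adjusted"]["mean"],
                        "mean_prop_by_individual": s["individual"]["proportion_correct"]["mean"],
                    }
                )
                _log(log, "impute", method=method, size=size, engine=engine,
                     mean_prop=grid_rows[-1]["mean_prop_correct"])

    grid = pd.DataFrame(grid_rows)
    grid.to_csv(outdir / "grid_summary.tsv", sep="\t", index=False)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump({"seed": config.seed, "log": log}, fh, indent=2, default=str)
    return outdir


def run_between_population_experiment(config: ExperimentConfig) -> Path:
    """Cross-population imputation: panels and QC from population 1's Set A;
    assessment 1 imputes all of population 2 from population 1's Set B,
    assessment 2 imputes population 2's Set E from its own Set D (75/25)."""
    if config.sim is None:
        raise ValueError("between-population experiment requires a SimConfig "
                         "(two PLINK populations not wired into config yet)")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    rng = np.random.default_rng(config.seed)

    pop1, pop2, _ = simulate_split_populations(config.sim)
    _log(log, "simulate_split", n1=pop1.n_samples, n2=pop2.n_samples)

    split1 = split_samples(pop1.sample_ids, list(config.split), seed=config.seed)
    set_a = pop1.take_samples(split1.set("A"))
    set_b = pop1.take_samples(split1.set("B"))

    _, qc_report = filter_snps(set_a, config.min_call_rate, config.min_maf)
    keep_idx = pop1.markers.index_of(qc_report.kept_snp_ids)
    set_a, set_b = set_a.take_snps(keep_idx), set_b.take_snps(keep_idx)
    pop2 = pop2.take_snps(keep_idx)
    _log(log, "qc", n_kept=len(keep_idx))

    split2 = split_samples(pop2.sample_ids, [0.75, 0.25], seed=config.seed + 1,
                           labels=["D", "E"])
    set_d = pop2.take_samples(split2.set("D"))
    set_e = pop2.take_samples(split2.set("E"))

    ldu_maps = None
    if "lduMAF" in config.methods:
        ldu_maps = {c: build_ldu_map(set_a, chromosome=c)
                    for c in set_a.markers.chromosomes()}

    rows = []
    for size in config.panel_sizes:
        for method in config.methods:
            panel_seed = int(rng.integers(0, 2**31 - 1))
            panel = design_panel(set_a, method, size, seed=panel_seed,
                                 ldu_maps=ldu_maps, ga_params=config.ga)
            assessments = [
                ("pop1B_to_pop2", set_b, pop2),
                ("D_to_E", set_d, set_e),
            ]
            for name, reference, test in assessments:
                masked = mask_to_panel(test, panel)
                for engine in config.engines:
                    report = _impute_and_score(
                        engine, masked, reference, test, config, seed=config.seed
                    )
                    s = report.summary
                    rows.append(
                        {
                            "assessment": name,
                            "panel_size": size,
                            "method": method,
                            "engine": engine,
                            "mean_prop_correct": s["snp"]["proportion_correct"]["mean"],
                            "mean_correlation": s["snp"]["correlation"]["mean"],
                            "mean_adjusted": s["snp"]["adjusted"]["mean"],
                        }
                    )
                    _log(log, "impute", assessment=name, method=method,
                         size=size, engine=engine,
                         mean_prop=rows[-1]["mean_prop_correct"])

    pd.DataFrame(rows).to_csv(outdir / "between_population_summary.tsv",
                              sep="\t", index=False)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump({"seed": config.seed, "log": log}, fh, indent=2, default=str)
    return outdir
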
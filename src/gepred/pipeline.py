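"""Configuration, orchestration and provenance for end-to-end runs.

A run executes the two-step analysis in order: (simulate or load data) ->
marker & phenotype QC -> pedigree REML + pre-adjustment -> whole-genome
regression / neural-net fits on the sub-sample ladder -> evaluation report.
One global seed fans out to per-stage seeds (stage name hashed with CRC32),
so adding or removing methods never perturbs the simulated data.  Every run
writes a provenance manifest (config echo, derived seeds, per-stage record
counts) sufficient to relaunch an identical run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, genotypes, qc
from .bayes import McmcConfig, PriorSpec
from .mixed import AnimalModel
from .nnet import Architecture, SearchSpace, TrainConfig
from .qc import QcThresholds
from .simulate import SimConfig, simulate_dataset

__all__ = ["RunConfig", "load_config", "save_config", "run", "derive_seed"]

log = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    simulate: bool = True
    genotype_path: str | None = None
    phenotype_path: str | None = None
    pedigree_path: str | None = None
    outdir: str = "gepred_run"
    seed: int = 0
    methods: tuple = ("BRR", "BayesCpi", "DNN")
    fractions: tuple = evaluate.DEFAULT_FRACTIONS
    n_test_generations: int = 2
    tune_generations: int = 1
    n_candidates: int = 200
    k_fraction: float = 0.10
    dnn_arch: Architecture | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    search: SearchSpace = field(default_factory=SearchSpace)

    def __post_init__(self):
        if not self.simulate:
            for p in (self.genotype_path, self.phenotype_path, self.pedigree_path):
                if p is None:
                    raise ValueError("provide genotype/phenotype/pedigree paths "
                                     "or set simulate: true")
        self.methods = tuple(self.methods)
        self.fractions = tuple(self.fractions)


_SECTION_TYPES = {
    "sim": SimConfig, "qc": QcThresholds, "mcmc": McmcConfig,
    "prior": PriorSpec, "train": TrainConfig, "search": SearchSpace,
}


def _build_section(cls, data, name):
    if isinstance(data, cls):
        return data
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in section '{name}'")
    coerced = {}
    for k, v in data.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a YAML (or dict) run configuration.

    Omitted keys take the package defaults (chain 30,000/20,000/5, learning
    rate 1e-4, batch 256, outlier z 3.5, MAF 0.01, call rate 0.95, HWE
    1e-10).  Unknown keys are rejected with the offending name.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], value or {}, key)
        elif key == "dnn_arch" and value is not None:
            kwargs[key] = (value if isinstance(value, Architecture)
                           else Architecture(**value))
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [encode(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj
    data = {f.name: encode(getattr(cfg, f.name))
            for f in dataclasses.fields(cfg)}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _load_inputs(cfg: RunConfig):
    if cfg.simulate:
        sim = cfg.sim.with_(seed=derive_seed(cfg.seed, "simulate"))
        G, ped, phen, truth = simulate_dataset(sim)
        return G, ped, phen, truth
    G = genotypes.read_genotypes(cfg.genotype_path)
    phen = pd.read_csv(cfg.phenotype_path, dtype={"id": str, "dam": str})
    ped = pd.read_csv(cfg.pedigree_path,
                      dtype={"id": str, "sire": str, "dam": str})
    return G, ped, phen, None


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of stage outputs.

    Writes to ``cfg.outdir``: the QC report, variance components, the
    pre-adjusted phenotypes, tidy and wide evaluation tables, and
    ``manifest.json``.  Model-fit stages only ever see train/tune
    partitions; test phenotypes enter the evaluation metrics alone.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": {}, "versions": _versions()}
    t0 = time.time()
    results: dict = {}

    G, ped, phen, truth = _load_inputs(cfg)
    results["truth"] = truth
    manifest["stages"]["input"] = {"n_individuals": int(G.n), "n_markers": int(G.m)}
    log.info("input: %d individuals x %d markers", G.n, G.m)

    # ---- marker QC ------------------------------------------------------
    G_kept, qc_report = qc.filter_markers(G, cfg.qc)
    qc_report.to_csv(outdir / "marker_qc.csv", index=False)
    G_imp = qc.impute_missing(G_kept)
    manifest["stages"]["marker_qc"] = {
        "markers_in": int(G.m), "markers_kept": int(G_kept.m),
        "removed": qc_report[~qc_report["kept"]]["reason"].value_counts().to_dict(),
    }

    # ---- phenotype QC ---------------------------------------------------
    keep_idx = qc.remove_outliers(phen["weight"].to_numpy(),
                                  phen["contemporary_group"].to_numpy(),
                                  z=cfg.qc.outlier_z)
    n_in = len(phen)
    phen_kept = phen.iloc[keep_idx].reset_index(drop=True)
    n_out = n_in - len(phen_kept)
    assert n_in == len(phen_kept) + n_out
    manifest["stages"]["phenotype_qc"] = {
        "records_in": n_in, "records_kept": len(phen_kept),
        "outliers_removed": n_out,
    }

    # ---- step 1: REML + pre-adjustment ---------------------------------
    model = AnimalModel.from_dataframe(phen_kept, ped)
    fit = model.fit()
    results["animal_model"] = fit
    total, h2, c2 = fit.variance_ratios
    pd.DataFrame([{
        "sigma2_u": fit.vc.sigma2_u, "sigma2_c": fit.vc.sigma2_c,
        "sigma2_e": fit.vc.sigma2_e, "phenotypic": total, "h2": h2, "c2": c2,
    }]).to_csv(outdir / "variance_components.csv", index=False)
    pd.DataFrame(fit.trajectory,
                 columns=["sigma2_u", "sigma2_c", "sigma2_e", "loglik"]
                 ).to_csv(outdir / "reml_trajectory.csv", index_label="iteration")
    y_star = pd.Series(fit.preadjusted(), index=phen_kept["id"].astype(str))
    y_star.rename("y_star").to_csv(outdir / "preadjusted.csv")
    manifest["stages"]["mixed_model"] = {
        "h2": round(h2, 4), "c2": round(c2, 4),
        "phenotypic_variance": round(total, 2), "iterations": fit.n_iter,
    }
    log.info("REML: h2=%.3f c2=%.3f sigma2_p=%.1f", h2, c2, total)

    # ---- step 2 + evaluation -------------------------------------------
    split = evaluate.chronological_split(
        phen_kept, cfg.n_test_generations, cfg.tune_generations)
    ladder = evaluate.nested_subsamples(
        split.train_ids, cfg.fractions, seed=derive_seed(cfg.seed, "ladder"))
    G_eval = G_imp.subset_individuals(phen_kept["id"].astype(str).to_numpy())
    report = evaluate.run_comparison(
        y_star, G_eval, split, ladder, methods=cfg.methods,
        mcmc=cfg.mcmc, prior=cfg.prior, train_config=cfg.train,
        search_space=cfg.search, n_candidates=cfg.n_candidates,
        dnn_arch=cfg.dnn_arch, k_fraction=cfg.k_fraction,
        seed=derive_seed(cfg.seed, "comparison"))
    results["report"] = report
    report.metrics.to_csv(outdir / "metrics.csv", index=False)
    report.agreement.to_csv(outdir / "agreement.csv", index=False)
    for metric in ("prediction_correlation", "msep", "bias_slope"):
        report.wide(metric).to_csv(outdir / f"wide_{metric}.csv")
    if len(report.agreement):
        report.agreement_wide("spearman").to_csv(outdir / "wide_spearman.csv")
        report.agreement_wide("topk_agreement").to_csv(outdir / "wide_topk.csv")
    for frac, board in report.leaderboards.items():
        board.to_csv(outdir / f"dnn_leaderboard_{frac}pct.csv", index=False)
    manifest["stages"]["evaluation"] = {
        "n_train": int(len(split.train_ids)), "n_tune": int(len(split.tune_ids)),
        "n_test": int(len(split.test_ids)), "fractions": list(cfg.fractions),
        "failures": report.failures,
    }
    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    save_config(cfg, outdir / "config.yaml")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    results["split"] = split
    results["y_star"] = y_star
    return results


def _versions() -> dict:
    import scipy
    import gepred
    return {"gepred": gepred.__version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}
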
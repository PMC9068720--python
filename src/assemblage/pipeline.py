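"""End-to-end orchestration: one config, seeded stages, tabular outputs.

A single master seed deterministically derives one sub-seed per stage (via a
counter scheme over ``numpy.random.SeedSequence``), so enabling or disabling
one stage never changes another stage's random stream.  Every stage writes a
TSV whose '#' header lines echo its parameters and seed; a JSON manifest
lists all outputs.  Re-running with an identical config and seed reproduces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import betanull as _betanull
from . import bvstep as _bvstep
from . import hillnull as _hillnull
from . import lottery as _lottery
from . import qpe as _qpe
from . import recruitment as _recruitment
from . import robustness as _robustness
from . import simulate as _simulate
from .io_core import (CountTable, align_inputs, read_count_table,
                      read_category_map, read_functions, read_metadata,
                      read_taxonomy, read_tree, write_count_table)

logger = logging.getLogger("assemblage")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "stage_seed"]

STAGES = ("simulate", "hill", "betanull", "qpe", "lottery", "recruitment",
          "robustness", "bvstep")


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed and the stage's index."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence([int(master_seed), idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (round-trips through YAML)."""

    seed: int = 0
    out_dir: str = "assemblage_out"
    table: str | None = None
    tree: str | None = None
    metadata: str | None = None
    taxonomy: str | None = None
    functions: str | None = None
    categories: str | None = None
    simulate: dict = field(default_factory=dict)
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES[1:]})
    hill: dict = field(default_factory=lambda: {"n_iter": 999})
    betanull: dict = field(default_factory=lambda: {"n_iter": 999, "alpha": 0.5})
    qpe: dict = field(default_factory=lambda: {"n_iter": 999,
                                               "cross_group": False})
    lottery: dict = field(default_factory=lambda: {"threshold": 0.9,
                                                   "presence_floor": 0.001})
    recruitment: dict = field(default_factory=lambda: {"n_boot": 2000,
                                                       "n_mc": 200})
    robustness: dict = field(default_factory=lambda: {"n_perturbations": 100})
    bvstep: dict = field(default_factory=lambda: {"rho_target": 0.95,
                                                  "max_restarts": 10})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return validate_config(raw)


def validate_config(raw: dict) -> PipelineConfig:
    """Fill defaults and check parameter domains; unknown keys warn only."""
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    errors: list[str] = []
    clean = {}
    for key, value in raw.items():
        if key not in known:
            logger.warning("unknown config key %r ignored", key)
            continue
        clean[key] = value
    cfg = PipelineConfig(**clean)
    defaults = PipelineConfig()
    for stage in ("hill", "betanull", "qpe", "lottery", "recruitment",
                  "robustness", "bvstep"):
        merged = dict(getattr(defaults, stage))
        merged.update(getattr(cfg, stage) or {})
        setattr(cfg, stage, merged)
    merged_stages = {s: True for s in STAGES[1:]}
    merged_stages.update(cfg.stages or {})
    cfg.stages = merged_stages
    for name in ("hill", "betanull", "qpe"):
        if getattr(cfg, name)["n_iter"] < 1:
            errors.append(f"{name}.n_iter must be >= 1")
    if not (0 < cfg.lottery["threshold"] < 1):
        errors.append("lottery.threshold must be in (0, 1)")
    if not (0 < cfg.bvstep["rho_target"] <= 1):
        errors.append("bvstep.rho_target must be in (0, 1]")
    if cfg.robustness["n_perturbations"] < 5:
        errors.append("robustness.n_perturbations must be >= 5")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, params: dict,
               seed: int, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# assemblage stage={stage} seed={seed}\n")
        fh.write("# " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
                 + "\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {},
                      "dropped": {}}

    # ----- inputs: simulate or load -------------------------------------
    sim_truth = None
    if config.table is None:
        sim_seed = stage_seed(config.seed, "simulate")
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("n_timepoints", 3)
        sim_kwargs["seed"] = sim_seed
        scfg = _simulate.SimConfig(**sim_kwargs)
        tree = _simulate.simulate_tree(scfg.n_otus, seed=sim_seed)
        meta_comm = _simulate.simulate_metacommunity(
            tree, scfg.metacommunity_sigma, seed=sim_seed)
        table, metadata, sim_truth = _simulate.simulate_community_series(
            tree, meta_comm, scfg)
        tax = _simulate.simulate_taxonomy(tree)
        funcs, _ = _simulate.simulate_genome_functions(
            table.otu_ids, seed=sim_seed)
        cats = None
        write_count_table(table, out / "table.tsv")
        tree.write(str(out / "tree.nwk"))
        with open(out / "taxonomy.tsv", "w") as fh:
            for otu, lin in tax.items():
                lineage = "; ".join(f"{r[0]}__{v}" for r, v in lin.items())
                fh.write(f"{otu}\t{lineage}\n")
        metadata.to_csv(out / "metadata.tsv", sep="\t")
        funcs.to_csv(out / "functions.tsv", sep="\t")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(sim_truth.to_dict(), fh, indent=1, sort_keys=True,
                      default=str)
        manifest["stages"]["simulate"] = {"seed": sim_seed,
                                          "config": sim_kwargs}
        manifest["outputs"]["inputs"] = ["table.tsv", "tree.nwk",
                                         "taxonomy.tsv", "metadata.tsv",
                                         "functions.tsv", "ground_truth.json"]
    else:
        table = read_count_table(config.table)
        tree = read_tree(config.tree) if config.tree else None
        metadata = read_metadata(config.metadata) if config.metadata else None
        tax = read_taxonomy(config.taxonomy) if config.taxonomy else None
        funcs = read_functions(config.functions) if config.functions else None
        cats = read_category_map(config.categories) if config.categories else None

    enabled = config.stages
    needs_tree = [s for s in ("betanull", "qpe", "recruitment", "robustness")
                  if enabled.get(s)]
    if needs_tree and tree is None:
        raise StageError(needs_tree[0], ValueError(
            "a phylogeny is required for stages: " + ", ".join(needs_tree)))
    if tree is not None:
        bundle = align_inputs(table, tree=tree, tax=tax, funcs=funcs)
        table, tree, tax, funcs = (bundle.table, bundle.tree, bundle.taxonomy,
                                   bundle.functions)
        manifest["dropped"] = bundle.dropped
    if metadata is None:
        raise StageError("io", ValueError("sample metadata is required"))
    metadata = metadata.reindex(table.sample_ids)

    multi_time = metadata["time_point"].nunique() > 1
    group_labels = (metadata["group"].astype(str) + "_"
                    + metadata["time_point"].astype(str)) if multi_time \
        else metadata["group"].astype(str)
    group_labels.index = metadata.index

    def run_stage(name, func):
        if not enabled.get(name, False):
            return
        seed = stage_seed(config.seed, name)
        params = dict(getattr(config, name))
        try:
            outputs = func(seed, params)
        except Exception as exc:
            raise StageError(name, exc) from exc
        manifest["stages"][name] = {"seed": seed, "params": params}
        manifest["outputs"][name] = outputs

    def do_hill(seed, params):
        res = _hillnull.hill_null_expectation(
            table, group_labels, n_iter=params["n_iter"], seed=seed)
        _write_tsv(res.pairs, out / "hill.tsv", "hill", params, seed)
        return ["hill.tsv"]

    def do_betanull(seed, params):
        res = _betanull.beta_null_deviation(
            table, tree, group_labels, n_iter=params["n_iter"], seed=seed,
            alpha=params["alpha"])
        _write_tsv(res.pairs, out / "betanull_pairs.tsv", "betanull", params, seed)
        _write_tsv(res.groups, out / "betanull_groups.tsv", "betanull", params, seed)
        return ["betanull_pairs.tsv", "betanull_groups.tsv"]

    def do_qpe(seed, params):
        res = _qpe.qpe_analysis(table, tree, group_labels,
                                n_iter=params["n_iter"], seed=seed,
                                cross_group=params["cross_group"])
        summary = _qpe.process_percentages(res).reset_index()
        _write_tsv(res, out / "qpe_pairs.tsv", "qpe", params, seed)
        _write_tsv(summary, out / "qpe_summary.tsv", "qpe", params, seed)
        return ["qpe_pairs.tsv", "qpe_summary.tsv"]

    def do_lottery(seed, params):
        if tax is None:
            raise ValueError("taxonomy required for the lottery stage")
        rep = _lottery.lottery_report(table, tax, metadata,
                                      threshold=params["threshold"],
                                      presence_floor=params["presence_floor"])
        _write_tsv(rep.table, out / "lottery.tsv", "lottery", params, seed)
        return ["lottery.tsv"]

    def do_recruitment(seed, params):
        if metadata["time_point"].nunique() < 3:
            logger.warning("recruitment needs >= 3 time points; skipping")
            return []
        rows = []
        for g in pd.unique(metadata["group"]):
            series = _recruitment.detection_series(table, metadata, g)
            try:
                fit = _recruitment.fit_dispersion(
                    series, tree, n_boot=params["n_boot"],
                    n_mc=params["n_mc"], seed=seed)
            except ValueError as exc:
                logger.warning("recruitment fit skipped for %s: %s", g, exc)
                continue
            rows.append({"group": g, "d_hat": fit.d_hat,
                         "ci_low": fit.ci95[0], "ci_high": fit.ci95[1],
                         "unidentifiable": fit.unidentifiable,
                         "bound_hit": fit.bound_hit})
        df = pd.DataFrame(rows)
        _write_tsv(df, out / "recruitment.tsv", "recruitment", params, seed)
        return ["recruitment.tsv"]

    def do_robustness(seed, params):
        if funcs is None:
            raise ValueError("genome function table required for robustness")
        sub = table.select_otus(funcs.index)
        prof = _robustness.robustness_profile(
            sub, tree, funcs, n_perturbations=params["n_perturbations"],
            seed=seed, category_map=cats)
        _write_tsv(prof.samples, out / "robustness.tsv", "robustness",
                   params, seed)
        outputs = ["robustness.tsv"]
        gdf_cols = list(_robustness.GDF_FEATURES)
        gdf = prof.samples.set_index("sample")[gdf_cols].dropna()
        if len(gdf) >= 3:
            coords, loadings, pct = _robustness.gdf_ordination(gdf)
            axes = coords.iloc[:, :2].copy()
            axes.columns = ["PC1", "PC2"]
            _write_tsv(axes.reset_index(names="sample"),
                       out / "gdf_pcoa.tsv", "robustness", params, seed)
            outputs.append("gdf_pcoa.tsv")
        return outputs

    def do_bvstep(seed, params):
        res = _bvstep.bvstep_search(table, rho_target=params["rho_target"],
                                    max_restarts=params["max_restarts"],
                                    seed=seed)
        df = pd.DataFrame({"otu": res.selected})
        df["rho"] = res.rho
        _write_tsv(df, out / "bvstep.tsv", "bvstep", params, seed)
        return ["bvstep.tsv"]

    run_stage("hill", do_hill)
    run_stage("betanull", do_betanull)
    run_stage("qpe", do_qpe)
    run_stage("lottery", do_lottery)
    run_stage("recruitment", do_recruitment)
    run_stage("robustness", do_robustness)
    run_stage("bvstep", do_bvstep)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
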
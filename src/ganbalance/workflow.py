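"""End-to-end study orchestration: simulate -> preprocess -> pre-train ->
re-train -> balance -> validate -> compare, over a grid of experiment
designs.

One pre-training run on the shared external data is reused by every design's
per-class re-trainings; the validation and external splits are likewise
shared across designs, while each design draws its own real data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import (ClassifierGrid, compare_methods, evaluate_balancing,
                         select_alpha_combination, tune_classifier)
from .gan_core import GanHyperparams
from .model import ClassBalancingGAN
from .simulate import (ExperimentDesign, SimulationConfig, LabeledMatrix,
                       simulate_two_cluster_dataset, split_experiment,
                       table1_designs)
from .training import TrainingConfig

logger = logging.getLogger("ganbalance")

__all__ = ["RunManifest", "run_experiment_grid", "GAN_METHODS", "ALL_METHODS"]

GAN_METHODS = ("gan_balance", "gan_expand")
ALL_METHODS = ("gan_balance", "gan_expand", "smote", "random_oversample")
DEFAULT_ALPHA_COMBINATIONS = ((0.0, 0.0), (1.0, 0.0), (1.0, 1.0))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, per-stage seeds, artifacts."""

    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)
    version: str = "0.1.0"

    def add_artifact(self, name: str, path) -> None:
        path = Path(path)
        self.artifacts[name] = {"path": str(path), "sha256": _checksum(path)}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def run_experiment_grid(designs: list[ExperimentDesign] | None = None,
                        sim_config: SimulationConfig | None = None,
                        training_config: TrainingConfig | None = None,
                        hyper: GanHyperparams | None = None,
                        methods: tuple = ALL_METHODS,
                        alpha_combinations: tuple = DEFAULT_ALPHA_COMBINATIONS,
                        n_iterations: int = 100,
                        multiplier: float = 1.0,
                        grid: ClassifierGrid | None = None,
                        seed: int = 0,
                        out_dir=None) -> dict:
    """Run the full validation protocol for every design.

    Returns ``{experiment_id: {"reports": {method: ValidationReport},
    "alpha_reports": ..., "comparison": MethodComparison}}``.  GAN training
    only happens when a GAN method is requested (lazy stages).
    """
    if designs is None:
        designs = table1_designs()
    if not designs:
        raise ValueError("designs must be non-empty")
    sim_config = sim_config or SimulationConfig()
    training_config = training_config or TrainingConfig()
    hyper = hyper or GanHyperparams()
    need_gans = any(m in GAN_METHODS for m in methods)

    master = np.random.SeedSequence(seed)
    ss_split, ss_fit, ss_eval = master.spawn(3)
    manifest = RunManifest(config={
        "sim": dataclasses.asdict(sim_config),
        "training": {"pretrain": dataclasses.asdict(training_config.pretrain),
                     "retrain": dataclasses.asdict(training_config.retrain)},
        "methods": list(methods), "n_iterations": n_iterations,
        "multiplier": multiplier},
        seeds={"master": seed})

    dataset = simulate_two_cluster_dataset(sim_config)
    split_seeds = {d.experiment_id: _spawn_seed(s)
                   for d, s in zip(designs, ss_split.spawn(len(designs)))}
    fit_seeds = {d.experiment_id: s for d, s in zip(designs, ss_fit.spawn(len(designs)))}
    eval_seeds = {d.experiment_id: s for d, s in zip(designs, ss_eval.spawn(len(designs)))}
    manifest.seeds["split"] = split_seeds

    pretrained = None
    results: dict = {}
    for design in designs:
        logger.info("experiment %d: %d controls, imbalance %.2f",
                    design.experiment_id, design.n_controls, design.class_imbalance)
        real, external, validation = split_experiment(
            dataset, design, sim_config, split_seeds[design.experiment_id])
        try:
            entry = _run_design(real, external, validation, design,
                                training_config, hyper, methods,
                                alpha_combinations if need_gans else (),
                                n_iterations, multiplier, grid,
                                fit_seeds[design.experiment_id],
                                eval_seeds[design.experiment_id],
                                pretrained_holder := {"net": pretrained})
            pretrained = pretrained_holder["net"]
            results[design.experiment_id] = entry
        except Exception as err:  # stage failure: record, continue the grid
            logger.error("experiment %d failed: %s", design.experiment_id, err)
            manifest.failures.append({"experiment_id": design.experiment_id,
                                      "error": str(err)})

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for exp_id, entry in results.items():
            path = out_dir / f"experiment_{exp_id}_report.json"
            _write_report(entry, path)
            manifest.add_artifact(f"experiment_{exp_id}", path)
        manifest.write(out_dir / "manifest.json")
    if manifest.failures and results:
        logger.warning("%d design(s) failed", len(manifest.failures))
    results["_manifest"] = manifest
    return results


def _run_design(real, external, validation, design, training_config, hyper,
                methods, alpha_combinations, n_iterations, multiplier, grid,
                fit_ss, eval_ss, pretrained_holder) -> dict:
    reports, alpha_reports = {}, {}
    eval_children = {m: s for m, s in zip(methods, eval_ss.spawn(len(methods)))}

    gan_results = {}
    if any(m in GAN_METHODS for m in methods):
        combos = alpha_combinations or ((0.0, 0.0),)
        for combo, child in zip(combos, fit_ss.spawn(len(combos))):
            model = ClassBalancingGAN(real, external, config=training_config,
                                      hyper=hyper, alphas=combo)
            gan_results[combo] = model.fit(
                seed=_spawn_seed(child),
                pretrained=pretrained_holder.get("net"))
            if pretrained_holder.get("net") is None:
                pretrained_holder["net"] = gan_results[combo].pretrained

    for method in methods:
        child = eval_children[method]
        mult = multiplier if method == "gan_expand" else 1.0
        if method in GAN_METHODS:
            per_combo = {}
            for combo, res in gan_results.items():
                per_combo[combo] = res.validate(
                    validation, method, n_iterations=n_iterations,
                    seed=_spawn_seed(child), multiplier=mult, grid=grid)
                per_combo[combo].method = method
            alpha_reports[method] = per_combo
            reports[method] = select_alpha_combination(per_combo)
        else:
            first_seed = _spawn_seed(child)
            from .balancing import BalancePlan, apply_balancing
            balanced = apply_balancing(real, BalancePlan(method, seed=first_seed))
            params = tune_classifier(balanced, grid, seed=first_seed)
            reports[method] = evaluate_balancing(
                real, validation, method, params=params,
                n_iterations=n_iterations, seed=first_seed)

    entry = {"design": design, "reports": reports,
             "alpha_reports": alpha_reports, "gan_results": gan_results,
             "splits": (real, external, validation)}
    if len(reports) >= 2:
        entry["comparison"] = compare_methods(list(reports.values()))
    return entry


def _write_report(entry: dict, path: Path) -> None:
    design = entry["design"]
    payload = {
        "schema_version": 1,
        "design": dataclasses.asdict(design),
        "methods": {},
    }
    for method, report in entry["reports"].items():
        payload["methods"][method] = {
            "mean_auroc": report.mean_auroc,
            "sd_auroc": report.sd_auroc,
            "auc_diff": report.auc_diff,
            "alpha_combination": report.alpha_combination,
            "scores": report.scores.tolist(),
        }
    if "comparison" in entry:
        payload["comparison"] = entry["comparison"].table.to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
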
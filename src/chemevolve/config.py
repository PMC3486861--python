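"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` gathers every knob of a full experiment -- chemistry
rules, GA settings, task name and generator parameters, integration and
analysis settings -- under a single master seed.  Every stochastic stage
draws from a child generator spawned from that seed, so a run is fully
reproducible: the same config and seed produce byte-identical genotype
files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import analysis, bayes, evolution, tasks
from .chemistry import ChemistryRules
from .evolution import GAConfig

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    task: str = "clocked"
    chemistry: ChemistryRules = field(
        default_factory=lambda: ChemistryRules("aggregation", 2, 4)
    )
    ga: GAConfig = field(default_factory=GAConfig)
    task_params: dict = field(default_factory=dict)
    dt: float = 0.01
    prune_tolerance: float = 0.10
    bayes_train_envs: int = 200
    bayes_test_envs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in tasks.TASK_NAMES:
            raise ValueError(
                f"unknown task {self.task!r}; choose from {tasks.TASK_NAMES}"
            )

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "chemistry": self.chemistry.to_dict(),
            "ga": dataclasses.asdict(self.ga),
            "task_params": dict(self.task_params),
            "dt": self.dt,
            "prune_tolerance": self.prune_tolerance,
            "bayes_train_envs": self.bayes_train_envs,
            "bayes_test_envs": self.bayes_test_envs,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "chemistry" in d:
            d["chemistry"] = ChemistryRules.from_dict(d["chemistry"])
        if "ga" in d:
            d["ga"] = GAConfig(**d["ga"])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Protocols -> evolution -> pruning -> belief readout, all on disk.

    Returns the manifest (also written to ``outdir/manifest.json``).
    Stages after evolution reuse the training protocol set; the belief
    readout runs only for tasks with a discrete event model.
    """
    os.makedirs(outdir, exist_ok=True)
    cfg.to_yaml(os.path.join(outdir, "config.yaml"))
    ss = np.random.SeedSequence(cfg.seed)
    proto_seed, ga_seed, bayes_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    manifest: dict = {"task": cfg.task, "seed": cfg.seed, "stages": {}}

    # 1. training protocols, saved to file (fixed for the whole run)
    pset = tasks.gen_protocols(
        cfg.task, np.random.default_rng(proto_seed), **cfg.task_params
    )
    pset.seed = proto_seed
    proto_path = os.path.join(outdir, "protocols.json")
    pset.save(proto_path)
    manifest["stages"]["protocols"] = {"seed": proto_seed, "path": "protocols.json"}

    # 2. evolution
    ga_cfg = dataclasses.replace(cfg.ga, seed=ga_seed)
    result = evolution.microbial_ga(pset, cfg.chemistry, ga_cfg, dt=cfg.dt)
    best_path = os.path.join(outdir, "best_genotype.json")
    result.best_network.to_json(best_path)
    np.savetxt(
        os.path.join(outdir, "fitness_trace.csv"),
        np.column_stack([np.arange(1, len(result.trace) + 1), result.trace]),
        delimiter=",",
        header="iteration,best_fitness",
        comments="",
    )
    manifest["stages"]["evolution"] = {
        "seed": ga_seed,
        "best_fitness": result.best_fitness,
        "initial_best_fitness": result.initial_best,
        "path": "best_genotype.json",
    }

    # 3. pruning
    pr = analysis.prune(result.best_network, pset, tolerance=cfg.prune_tolerance, dt=cfg.dt)
    pr.core.to_json(os.path.join(outdir, "core_genotype.json"))
    with open(os.path.join(outdir, "prune_report.txt"), "w") as fh:
        fh.write(pr.report() + "\n")
    manifest["stages"]["prune"] = {
        "full_reactions": len(result.best_network.reactions),
        "core_reactions": len(pr.core.reactions),
        "full_fitness": pr.full_fitness,
        "core_fitness": pr.core_fitness,
    }

    # 4. belief readout (only tasks with a discrete event model)
    try:
        task_model = bayes.BayesTaskModel.for_task(cfg.task)
    except ValueError:
        manifest["stages"]["bayes"] = {"skipped": "no event model for this task"}
    else:
        rng = np.random.default_rng(bayes_seed)
        readout = bayes.fit_network_readout(
            result.best_network, task_model, rng, n_train_envs=cfg.bayes_train_envs,
            dt=cfg.dt,
        )
        mean_cor, cors = bayes.belief_correlation(
            readout, result.best_network, task_model, rng,
            n_test_envs=cfg.bayes_test_envs, dt=cfg.dt,
        )
        with open(os.path.join(outdir, "belief_model.json"), "w") as fh:
            json.dump(readout.to_dict(), fh, indent=2)
        manifest["stages"]["bayes"] = {
            "seed": bayes_seed,
            "mean_correlation": mean_cor,
            "per_env_correlations": cors.tolist(),
        }

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
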
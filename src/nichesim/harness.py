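"""Experiment orchestration: trials, sweeps, logging, seeding, fixtures.

A trial is G generations of evaluate -> select/reproduce -> inherit.  All
randomness flows from a single integer seed through named, independently
spawned streams (GA operations and weathering draws); episodes themselves
are deterministic, so a trial is exactly reproducible given its seed and
the physics backend build.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import ActionCommand, PredatorParams, PreyParams, genome_length
from .evaluation import EvalParams, EvalResult, evaluate_generation
from .evolution import GAParams, init_population, next_generation
from .inheritance import (EnvironmentLegacy, InheritParams,
                          build_offspring_world)
from .world import PlacedObject, World, WorldConfig, build_world


@dataclass(frozen=True)
class ExperimentConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    prey: PreyParams = field(default_factory=PreyParams)
    predator: PredatorParams = field(default_factory=PredatorParams)
    ga: GAParams = field(default_factory=GAParams)
    inherit: InheritParams = field(default_factory=InheritParams)
    eval: EvalParams = field(default_factory=EvalParams)
    n_trials: int = 1
    output_dir: str = "runs"
    master_seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def normalized(self) -> "ExperimentConfig":
        """Synchronise derived fields: the world's object capacity follows
        the prey budget B, the eval timestep follows the world timestep,
        and the default birthplace follows the world's prey start."""
        return replace(
            self,
            world=replace(self.world, max_objects=self.prey.budget),
            eval=replace(self.eval, timestep=self.world.timestep),
            inherit=replace(self.inherit,
                            default_birthplace=self.world.prey_start))


@dataclass
class GenerationRecord:
    generation: int
    fitnesses: np.ndarray
    captures: np.ndarray
    final_distances: np.ndarray
    objects_placed: np.ndarray
    parent_index: np.ndarray            # lineage of this generation
    best_index: int
    best_result: EvalResult

    @property
    def best_fitness(self) -> float:
        return float(self.fitnesses[self.best_index])

    @property
    def mean_fitness(self) -> float:
        return float(self.fitnesses.mean())


@dataclass
class TrialLog:
    trial_seed: int
    config: ExperimentConfig
    records: list[GenerationRecord] = field(default_factory=list)
    final_population: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            for i in range(len(rec.fitnesses)):
                rows.append({
                    "generation": rec.generation,
                    "individual": i,
                    "parent": int(rec.parent_index[i]),
                    "fitness": float(rec.fitnesses[i]),
                    "captures": int(rec.captures[i]),
                    "final_distance": float(rec.final_distances[i]),
                    "objects_placed": int(rec.objects_placed[i]),
                })
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "generation": [r.generation for r in self.records],
            "best_fitness": [r.best_fitness for r in self.records],
            "mean_fitness": [r.mean_fitness for r in self.records],
        })

    def mean_last_half_fitness(self) -> float:
        """Population mean fitness averaged over the last ceil(G/2)
        generations (the convention used for summary statistics)."""
        g = len(self.records)
        half = self.records[g - math.ceil(g / 2):]
        return float(np.mean([r.mean_fitness for r in half]))


def run_trial(config: ExperimentConfig, trial_seed: int,
              progress: bool = False) -> TrialLog:
    """One full evolutionary trial of G generations."""
    config = config.normalized()
    ss = np.random.SeedSequence(trial_seed)
    ga_stream, weather_stream = [np.random.Generator(np.random.PCG64(s))
                                 for s in ss.spawn(2)]
    glen = genome_length(config.prey)
    pop = init_population(config.ga, glen, ga_stream)
    n = config.ga.n
    legacies: list[EnvironmentLegacy | None] = [None] * n
    parents_of_current = np.full(n, -1)  # generation 0 has no parents
    log = TrialLog(trial_seed=trial_seed, config=config)

    for g in range(config.ga.generations):
        worlds = []
        for leg in legacies:
            if leg is None:
                worlds.append(build_world(config.world))
            else:
                worlds.append(build_offspring_world(
                    config.world, leg, config.inherit, weather_stream))
        results = evaluate_generation(pop, worlds, config.prey,
                                      config.predator, config.eval)
        fitnesses = np.array([r.fitness for r in results])
        best = int(np.argmax(fitnesses))
        placed = np.array([len(r.end_objects) for r in results])
        rec = GenerationRecord(
            generation=g,
            fitnesses=fitnesses,
            captures=np.array([r.captures for r in results]),
            final_distances=np.array([r.final_distance for r in results]),
            objects_placed=placed,
            parent_index=parents_of_current,
            best_index=best,
            best_result=results[best])
        log.records.append(rec)
        if progress:
            print(f"gen {g:5d}  best {rec.best_fitness:6.3f}  "
                  f"mean {rec.mean_fitness:6.3f}")

        pop, parent_index = next_generation(pop, fitnesses, config.ga,
                                            ga_stream)
        parents_of_current = parent_index
        legacies = [EnvironmentLegacy(results[p].end_objects,
                                      results[p].end_prey_position)
                    for p in parent_index]
    log.final_population = pop
    return log


def cell_seed(master_seed: int, b: int, w: float, p: bool,
              trial: int) -> int:
    """Deterministic per-(cell, trial) seed, independent of sweep order."""
    ss = np.random.SeedSequence(
        [master_seed, b, int(round(w * 10_000)), int(p), trial])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_sweep(base: ExperimentConfig,
              b_values=(10, 20, 30, 40),
              w_values=(1.0,),
              p_values=(False,),
              n_trials: int = 1,
              progress: bool = False,
              keep_logs: bool = False):
    """Grid sweep over the resource cap B, weathering W and birthplace P.

    Returns a tidy DataFrame with one row per (cell, trial) and the
    last-half mean fitness; with ``keep_logs`` also returns the TrialLogs
    keyed by (B, W, P, trial).
    """
    rows = []
    logs = {}
    for b in b_values:
        for w in w_values:
            for p in p_values:
                cfg = replace(base,
                              prey=replace(base.prey, budget=int(b)),
                              inherit=replace(base.inherit, w=float(w),
                                              p=bool(p)))
                for trial in range(n_trials):
                    seed = cell_seed(base.master_seed, int(b), float(w),
                                     bool(p), trial)
                    log = run_trial(cfg, seed, progress=progress)
                    rows.append({
                        "B": int(b), "W": float(w), "P": bool(p),
                        "trial": trial, "seed": seed,
                        "mean_last_half_fitness":
                            log.mean_last_half_fitness(),
                    })
                    if keep_logs:
                        logs[(int(b), float(w), bool(p), trial)] = log
    table = pd.DataFrame(rows)
    if keep_logs:
        return table, logs
    return table


# -- scripted controllers (deterministic test fixtures) -------------------

def noop_prey():
    """A prey that neither rotates nor places anything."""
    def controller(sensor, t):
        return ActionCommand(rotate=None, place=False)
    return controller


def always_place_prey(kind: str = "box", r: float = 100.0):
    """A prey that tries to place an object every step, cycling the
    placement angle so successive poses do not collide."""
    golden = 0.6180339887498949

    def controller(sensor, t):
        return ActionCommand(rotate=None, place=True, object_kind=kind,
                             r=r, theta=(2 * math.pi * ((t * golden) % 1.0)),
                             rotation=0.0)
    return controller


def straight_roller_prey(direction: str = "clockwise"):
    """A prey that only rolls in one direction."""
    def controller(sensor, t):
        return ActionCommand(rotate=direction, place=False)
    return controller


# -- config file I/O ------------------------------------------------------

def config_to_dict(config: ExperimentConfig) -> dict:
    def undata(x):
        if dataclasses.is_dataclass(x):
            return {f.name: undata(getattr(x, f.name))
                    for f in dataclasses.fields(x)}
        if isinstance(x, tuple):
            return [undata(v) for v in x]
        if isinstance(x, list):
            return [undata(v) for v in x]
        return x
    return undata(config)


def _tupled(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list) and f.name != "terrain":
            v = tuple(v)
        elif f.name == "terrain":
            v = [tuple(t) for t in v]
        kwargs[f.name] = v
    return cls(**kwargs)


def config_from_dict(data: dict) -> ExperimentConfig:
    parts = {}
    mapping = {"world": WorldConfig, "prey": PreyParams,
               "predator": PredatorParams, "ga": GAParams,
               "inherit": InheritParams, "eval": EvalParams}
    for key, cls in mapping.items():
        if key in data:
            parts[key] = _tupled(cls, data[key])
    for key in ("n_trials", "output_dir", "master_seed"):
        if key in data:
            parts[key] = data[key]
    return ExperimentConfig(**parts)


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
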
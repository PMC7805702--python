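"""Fitness-evaluation episodes and the fitness function.

One episode runs for T simulated seconds at timestep S (floor(T/S) steps).
Every step the prey controller is invoked once and the scripted predator
acts; a prey-predator touch counts one capture and teleports both agents
back to their episode starts while all placed objects stay.  Fitness is

    fitness = max(0, 10 - (c + (d - d_f)/d))   when d_f <= d
    fitness = max(0, 10 - c)                   otherwise

with c the capture count, d the distance between the episode's start
positions, and d_f the prey-predator distance at episode end.  The capture
penalty (1 per touch) always exceeds the distance term, which lies in
[0, 1] on the first branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _sim, agents
from .agents import (ActionCommand, PredatorParams, PreyParams, act_prey,
                     decode_action, forward, predator_torque_magnitude,
                     sense, split_genome)
from .world import PREDATOR, PREY, PlacedObject, World


@dataclass(frozen=True)
class EvalParams:
    t_limit: float = 200.0      # episode length, seconds
    timestep: float = 0.02      # physics timestep S, seconds

    def __post_init__(self):
        if self.t_limit <= 0 or self.timestep <= 0:
            raise ValueError("t_limit and timestep must be > 0")

    @property
    def n_steps(self) -> int:
        return int(self.t_limit / self.timestep)


@dataclass(frozen=True)
class EvalResult:
    captures: int
    start_distance: float
    final_distance: float
    fitness: float
    end_objects: tuple[PlacedObject, ...]
    end_prey_position: tuple[float, float]
    end_predator_position: tuple[float, float]


def compute_fitness(c: int, d: float, d_f: float) -> float:
    """The capture-and-distance fitness, clamped to [0, 10]."""
    if d <= 0:
        raise ValueError("start distance d must be > 0")
    if c < 0 or d_f < 0:
        raise ValueError("capture count and final distance must be >= 0")
    if d_f <= d:
        raw = 10.0 - (c + (d - d_f) / d)
    else:
        raw = 10.0 - c
    return max(0.0, raw)


def run_episode(world: World, genome: np.ndarray,
                prey_params: PreyParams | None = None,
                predator_params: PredatorParams | None = None,
                eval_params: EvalParams | None = None,
                fast: bool = True) -> EvalResult:
    """Evaluate one genome in the given (fresh or inherited) world.

    ``fast`` runs the fused compiled loop; ``fast=False`` runs the same
    step sequence through the Python-level operations (used by tests to
    pin the two paths together).  Both mutate the world.
    """
    prey_params = prey_params or PreyParams()
    predator_params = predator_params or PredatorParams()
    eval_params = eval_params or EvalParams()
    cfg = world.config
    if abs(cfg.timestep - eval_params.timestep) > 1e-12:
        raise ValueError("world timestep differs from eval timestep")
    (psx, psy), (qsx, qsy) = world.episode_starts
    d = math.hypot(qsx - psx, qsy - psy)
    w1, w2 = split_genome(np.asarray(genome, dtype=float), prey_params)

    if fast:
        board_w, board_h = cfg.board_dims
        captures = _sim.episode_kernel(
            world.pos, world.angle, world.vel, world.angvel,
            world.inv_m, world.inv_I, world.kind, world.active, world.half,
            world.torque_acc, world.flags, world.tiles, world.tile_half,
            world.walls,
            cfg.timestep, cfg.gravity[1], cfg.friction, cfg.restitution,
            cfg.density, cfg.torque_factor,
            cfg.field_width, cfg.field_height,
            w1, w2, eval_params.n_steps,
            prey_params.f_prey, prey_params.l_prey, prey_params.budget,
            prey_params.torque_coeff, predator_params.torque_coeff,
            predator_params.f_predator,
            predator_params.jump_impulse,
            math.cos(predator_params.jump_elevation),
            math.sin(predator_params.jump_elevation),
            int(round(1.0 / cfg.timestep)),
            cfg.box_side / 2.0, board_w / 2.0, board_h / 2.0,
            psx, psy, qsx, qsy)
    else:
        captures = _run_episode_python(world, w1, w2, prey_params,
                                       predator_params, eval_params)

    d_f = math.hypot(world.pos[PREY, 0] - world.pos[PREDATOR, 0],
                     world.pos[PREY, 1] - world.pos[PREDATOR, 1])
    return EvalResult(
        captures=int(captures),
        start_distance=d,
        final_distance=d_f,
        fitness=compute_fitness(int(captures), d, d_f),
        end_objects=tuple(world.objects()),
        end_prey_position=(float(world.pos[PREY, 0]),
                           float(world.pos[PREY, 1])),
        end_predator_position=(float(world.pos[PREDATOR, 0]),
                               float(world.pos[PREDATOR, 1])))


def _run_episode_python(world: World, w1: np.ndarray, w2: np.ndarray,
                        prey_params: PreyParams,
                        predator_params: PredatorParams,
                        eval_params: EvalParams) -> int:
    """Reference Python path: one controller invocation per physics step."""
    captures = 0
    steps_per_second = int(round(1.0 / world.config.timestep))
    last_jump = -steps_per_second
    budget = prey_params.budget
    for t in range(eval_params.n_steps):
        remaining = budget - world.object_count
        x = _sim.sense_kernel(
            world.pos[0, 0], world.pos[0, 1],
            world.pos[1, 0], world.pos[1, 1],
            world.pos, world.kind, world.active, world.tiles,
            prey_params.f_prey, float(remaining), float(budget))
        o = _sim.forward_kernel(w1, w2, x)
        action = decode_action(o, prey_params)
        act_prey(world, action, remaining, prey_params)

        cooldown_ok = (t - last_jump) >= steps_per_second
        pact = agents.predator_policy(world, predator_params, cooldown_ok)
        if pact.chase is not None:
            speed = world.body_state(PREDATOR).speed
            world.apply_torque(
                PREDATOR,
                predator_torque_magnitude(speed,
                                          predator_params.torque_coeff),
                pact.chase)
            if pact.jump:
                world.apply_jump_impulse(
                    PREDATOR, tuple(world.pos[PREY]),
                    predator_params.jump_impulse,
                    predator_params.jump_elevation)
                last_jump = t
        world.step()
        if world.detect_capture():
            captures += 1
            world.reset_agents()
    return captures


def run_episode_scripted(world: World, controller,
                         prey_params: PreyParams | None = None,
                         predator_params: PredatorParams | None = None,
                         eval_params: EvalParams | None = None) -> EvalResult:
    """Run an episode with a scripted prey controller instead of a genome.

    ``controller(sensor, t) -> ActionCommand`` is called once per step;
    everything else (predator script, capture-reset, fitness) is identical
    to the genome path.  Used for deterministic fixtures in tests.
    """
    prey_params = prey_params or PreyParams()
    predator_params = predator_params or PredatorParams()
    eval_params = eval_params or EvalParams()
    (psx, psy), (qsx, qsy) = world.episode_starts
    d = math.hypot(qsx - psx, qsy - psy)
    captures = 0
    steps_per_second = int(round(1.0 / world.config.timestep))
    last_jump = -steps_per_second
    budget = prey_params.budget
    for t in range(eval_params.n_steps):
        remaining = budget - world.object_count
        sensor = sense(world, remaining, prey_params)
        action = controller(sensor, t)
        act_prey(world, action, remaining, prey_params)
        cooldown_ok = (t - last_jump) >= steps_per_second
        if predator_params.f_predator > 0:
            pact = agents.predator_policy(world, predator_params,
                                          cooldown_ok)
            if pact.chase is not None:
                speed = world.body_state(PREDATOR).speed
                world.apply_torque(
                    PREDATOR,
                    predator_torque_magnitude(
                        speed, predator_params.torque_coeff),
                    pact.chase)
                if pact.jump:
                    world.apply_jump_impulse(
                        PREDATOR, tuple(world.pos[PREY]),
                        predator_params.jump_impulse,
                        predator_params.jump_elevation)
                    last_jump = t
        world.step()
        if world.detect_capture():
            captures += 1
            world.reset_agents()
    d_f = math.hypot(world.pos[PREY, 0] - world.pos[PREDATOR, 0],
                     world.pos[PREY, 1] - world.pos[PREDATOR, 1])
    return EvalResult(
        captures=captures, start_distance=d, final_distance=d_f,
        fitness=compute_fitness(captures, d, d_f),
        end_objects=tuple(world.objects()),
        end_prey_position=(float(world.pos[PREY, 0]),
                           float(world.pos[PREY, 1])),
        end_predator_position=(float(world.pos[PREDATOR, 0]),
                               float(world.pos[PREDATOR, 1])))


def evaluate_generation(pop: np.ndarray, worlds: list[World],
                        prey_params: PreyParams,
                        predator_params: PredatorParams,
                        eval_params: EvalParams) -> list[EvalResult]:
    """Independent episodes, one per (genome, world) pair."""
    if pop.shape[0] != len(worlds):
        raise ValueError("population size does not match world count")
    return [run_episode(w, g, prey_params, predator_params, eval_params)
            for g, w in zip(pop, worlds)]
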
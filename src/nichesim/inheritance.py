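"""Ecological inheritance: weathering of objects and birthplace handoff.

Between generations each offspring inherits the environmental state its
matched parent left behind at the end of fitness evaluation: the placed
objects (each independently vanishing with the weathering probability W,
survivors keeping type, position and rotation) and, when birthplace
inheritance P is enabled, the parent's end-of-evaluation position as its own
start.  With W = 1 and P = False the pathway is the identity: every episode
starts from a bare field at the fixed start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._phys import overlap_circle_obb
from .world import PlacedObject, World, WorldConfig, build_world


@dataclass(frozen=True)
class InheritParams:
    w: float = 1.0               # weathering probability
    p: bool = False              # birthplace inheritance flag
    default_birthplace: tuple[float, float] = (400.0, 50.0)

    def __post_init__(self):
        if not (0.0 <= self.w <= 1.0):
            raise ValueError("weathering probability must lie in [0, 1]")


@dataclass(frozen=True)
class EnvironmentLegacy:
    """A parent's end-of-evaluation environment."""

    objects: tuple[PlacedObject, ...] = ()
    parent_end_position: tuple[float, float] = (400.0, 50.0)


def weather_objects(legacy_objects, w: float,
                    rng: np.random.Generator) -> list[PlacedObject]:
    """Each inherited object vanishes independently with probability w."""
    if not (0.0 <= w <= 1.0):
        raise ValueError("weathering probability must lie in [0, 1]")
    objs = list(legacy_objects)
    if not objs:
        return []
    keep = rng.uniform(size=len(objs)) >= w
    return [o for o, k in zip(objs, keep) if k]


def resolve_birthplace(params: InheritParams,
                       legacy: EnvironmentLegacy) -> tuple[float, float]:
    """Where the offspring is born: the parent's end position when P is
    enabled, the fixed default otherwise."""
    if params.p:
        return tuple(legacy.parent_end_position)
    return tuple(params.default_birthplace)


def build_offspring_world(config: WorldConfig, legacy: EnvironmentLegacy,
                          params: InheritParams,
                          rng: np.random.Generator) -> World:
    """Fresh world for one offspring: birthplace-resolved prey start, plus
    the weathered legacy objects inserted before the episode begins.

    Objects that would interpenetrate the newly spawned prey are dropped
    (counted as weathered); inherited objects resting against each other
    are inserted as-is.  The remaining budget downstream is B minus the
    number of inserted objects.
    """
    birthplace = resolve_birthplace(params, legacy)
    world = build_world(config)
    world.set_prey_start(birthplace)
    survivors = weather_objects(legacy.objects, params.w, rng)
    for obj in survivors:
        hx, hy = world._half_extents(obj.kind)
        if overlap_circle_obb(world.pos[0, 0], world.pos[0, 1],
                              config.agent_radius,
                              obj.position[0], obj.position[1], obj.angle,
                              hx, hy):
            continue  # birth collision: discard
        world.add_object(obj, check=False)
    return world
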
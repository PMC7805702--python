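"""The 2D physics world: field, tiles, agents, and placed objects.

The world is a 1000 x 400 rectangle (origin bottom-left, y up) with gravity
along -y.  Static square "field tiles" form the terrain; a circular prey and
predator live in it together with dynamic objects the prey places: square
"boxes" and elongated "boards".  Stepping, torque/impulse application,
contact queries, placement-validity checks and capture-reset all live here;
the numerical heavy lifting is done by the compiled kernels in
:mod:`nichesim._phys`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _phys
from ._phys import KIND_BOARD, KIND_BOX, KIND_CIRCLE

TWO_PI = 2.0 * math.pi


class ConfigurationError(ValueError):
    """Raised when a WorldConfig violates one of its invariants."""


def _default_terrain() -> list[tuple[int, int]]:
    # flat floor: one row of 50 tiles along the bottom edge
    return [(i, 0) for i in range(50)]


@dataclass(frozen=True)
class WorldConfig:
    """Geometry, materials and timestep of the simulated field.

    Lengths are engine units (1 unit = 1 rendered pixel); the timestep
    ``timestep`` is in seconds, so the world is updated ``1/timestep`` times
    per simulated second.  ``terrain`` holds tile *grid* coordinates: tile
    (i, j) is the square with side ``tile_side`` whose lower-left corner is
    at (i*tile_side, j*tile_side).
    """

    field_width: float = 1000.0
    field_height: float = 400.0
    tile_side: float = 20.0
    agent_radius: float = 20.0
    box_side: float = 18.0
    board_dims: tuple[float, float] = (6.0, 54.0)
    gravity: tuple[float, float] = (0.0, -20.0)
    timestep: float = 0.02
    torque_factor: float = 9.8   # kgf·m -> engine N·m at application time
    terrain: list[tuple[int, int]] = field(default_factory=_default_terrain)
    prey_start: tuple[float, float] = (400.0, 50.0)
    predator_start: tuple[float, float] = (900.0, 50.0)
    density: float = 1.0
    friction: float = 1.0
    restitution: float = 0.0
    max_objects: int = 40
    bounded: bool = True   # static walls enclosing the field rectangle

    def validate(self) -> None:
        for name in ("field_width", "field_height", "tile_side",
                     "agent_radius", "box_side", "timestep", "density"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.board_dims[0] <= 0 or self.board_dims[1] <= 0:
            raise ConfigurationError("board_dims must be > 0")
        if self.max_objects < 0:
            raise ConfigurationError("max_objects must be >= 0")
        nx = int(self.field_width // self.tile_side)
        ny = int(self.field_height // self.tile_side)
        for (i, j) in self.terrain:
            if not (0 <= i < nx and 0 <= j < ny):
                raise ConfigurationError(
                    f"terrain tile {(i, j)} lies outside the field")
        if tuple(self.prey_start) == tuple(self.predator_start):
            raise ConfigurationError("prey_start equals predator_start")
        for label, (x, y) in (("prey_start", self.prey_start),
                              ("predator_start", self.predator_start)):
            if not (0 <= x <= self.field_width and
                    0 <= y <= self.field_height):
                raise ConfigurationError(f"{label} outside the field")
            for (i, j) in self.terrain:
                cx = (i + 0.5) * self.tile_side
                cy = (j + 0.5) * self.tile_side
                if (abs(x - cx) < self.tile_side / 2 and
                        abs(y - cy) < self.tile_side / 2):
                    raise ConfigurationError(f"{label} overlaps terrain")

    def tile_centers(self) -> np.ndarray:
        out = np.empty((len(self.terrain), 2))
        for k, (i, j) in enumerate(self.terrain):
            out[k, 0] = (i + 0.5) * self.tile_side
            out[k, 1] = (j + 0.5) * self.tile_side
        return out

    def wall_boxes(self) -> np.ndarray:
        """Static axis-aligned boxes (cx, cy, hx, hy) that close the field
        rectangle on all four sides (empty when ``bounded`` is False).
        Walls only collide: they are not field tiles, are not sensed, and
        do not trigger the predator's jump rule."""
        if not self.bounded:
            return np.empty((0, 4))
        w, h, t = self.field_width, self.field_height, 50.0
        return np.array([
            [-t / 2, h / 2, t / 2, h / 2 + t],        # left
            [w + t / 2, h / 2, t / 2, h / 2 + t],     # right
            [w / 2, -t / 2, w / 2 + t, t / 2],        # bottom
            [w / 2, h + t / 2, w / 2 + t, t / 2],     # top
        ])


@dataclass(frozen=True)
class PlacedObject:
    """One constructed object living in the field."""

    kind: str  # "box" | "board"
    position: tuple[float, float]
    angle: float = 0.0

    def __post_init__(self):
        if self.kind not in ("box", "board"):
            raise ValueError(f"unknown object kind {self.kind!r}")
        object.__setattr__(self, "angle", self.angle % TWO_PI)


@dataclass(frozen=True)
class BodyState:
    position: tuple[float, float]
    angle: float
    linear_velocity: tuple[float, float]
    angular_velocity: float

    @property
    def speed(self) -> float:
        return math.hypot(*self.linear_velocity)


PREY = 0
PREDATOR = 1


class World:
    """Mutable simulation state plus the operations the model needs.

    Body slots: 0 = prey, 1 = predator, 2.. = placed objects (up to
    ``config.max_objects``).  Use :func:`build_world` to construct one.
    """

    def __init__(self, config: WorldConfig):
        config.validate()
        self.config = config
        cap = config.max_objects
        n = 2 + cap
        self.pos = np.zeros((n, 2))
        self.angle = np.zeros(n)
        self.vel = np.zeros((n, 2))
        self.angvel = np.zeros(n)
        self.inv_m = np.zeros(n)
        self.inv_I = np.zeros(n)
        self.kind = np.zeros(n, np.int8)
        self.active = np.zeros(n, np.bool_)
        self.half = np.zeros((n, 2))
        self.torque_acc = np.zeros(n)
        self.tiles = config.tile_centers()
        self.tile_half = config.tile_side / 2.0
        self.walls = config.wall_boxes()
        self.flags = np.zeros(5, np.int64)

        r = config.agent_radius
        m = config.density * math.pi * r * r
        inertia = 0.5 * m * r * r
        for i, start in ((PREY, config.prey_start),
                         (PREDATOR, config.predator_start)):
            self.pos[i] = start
            self.kind[i] = KIND_CIRCLE
            self.half[i, 0] = r
            self.inv_m[i] = 1.0 / m
            self.inv_I[i] = 1.0 / inertia
            self.active[i] = True
        self._episode_starts = (tuple(config.prey_start),
                                tuple(config.predator_start))

    # -- queries ---------------------------------------------------------

    @property
    def object_count(self) -> int:
        return int(self.active[2:].sum())

    def objects(self) -> list[PlacedObject]:
        out = []
        for i in range(2, self.pos.shape[0]):
            if self.active[i]:
                out.append(PlacedObject(
                    "box" if self.kind[i] == KIND_BOX else "board",
                    (float(self.pos[i, 0]), float(self.pos[i, 1])),
                    float(self.angle[i] % TWO_PI)))
        return out

    def body_state(self, body: int) -> BodyState:
        if not (0 <= body < self.pos.shape[0]) or not self.active[body]:
            raise KeyError(f"unknown body id {body}")
        return BodyState(
            (float(self.pos[body, 0]), float(self.pos[body, 1])),
            float(self.angle[body]),
            (float(self.vel[body, 0]), float(self.vel[body, 1])),
            float(self.angvel[body]))

    def _half_extents(self, kind: str) -> tuple[float, float]:
        if kind == "box":
            s = self.config.box_side / 2.0
            return s, s
        w, h = self.config.board_dims
        return w / 2.0, h / 2.0

    # -- operations ------------------------------------------------------

    def step(self) -> None:
        """Advance physics by one timestep; records contact flags."""
        step_config = self.config
        _phys.step_world(
            self.pos, self.angle, self.vel, self.angvel,
            self.inv_m, self.inv_I, self.kind, self.active, self.half,
            self.tiles, self.tile_half, self.walls, step_config.timestep,
            step_config.gravity[1], step_config.friction,
            step_config.restitution, self.torque_acc, self.flags)

    def apply_torque(self, body: int, magnitude: float,
                     direction: str) -> None:
        """Queue a torque on an agent for the next step.

        ``direction`` is "clockwise" or "anticlockwise"; with y up and
        counterclockwise-positive angles, clockwise torque is negative and
        rolls the body rightward on the floor.  ``magnitude`` is in kgf·m
        (the unit the torque laws are stated in); the backend converts to
        its native N·m via ``config.torque_factor``.
        """
        if magnitude < 0:
            raise ValueError("torque magnitude must be >= 0")
        if not (0 <= body < self.pos.shape[0]) or not self.active[body]:
            raise KeyError(f"unknown body id {body}")
        if direction == "clockwise":
            self.torque_acc[body] -= magnitude * self.config.torque_factor
        elif direction == "anticlockwise":
            self.torque_acc[body] += magnitude * self.config.torque_factor
        else:
            raise ValueError(f"unknown direction {direction!r}")

    def apply_jump_impulse(self, body: int, target: tuple[float, float],
                           magnitude: float = 50_000.0,
                           elevation: float = math.radians(60.0)) -> None:
        """Apply an instantaneous impulse at the given elevation angle, its
        horizontal component signed toward ``target``."""
        px, py = self.pos[body]
        if target[0] == px and target[1] == py:
            raise ValueError("jump target coincides with body position")
        sign = 1.0 if target[0] > px else -1.0
        ix = sign * magnitude * math.cos(elevation)
        iy = magnitude * math.sin(elevation)
        self.vel[body, 0] += ix * self.inv_m[body]
        self.vel[body, 1] += iy * self.inv_m[body]

    def placement_valid(self, obj: PlacedObject,
                        arm_center: tuple[float, float],
                        arm_reach: float) -> bool:
        """True iff the object can be placed: fully inside the field, no
        overlap with tiles/objects/agents, and within the arm's reach of
        ``arm_center``.  Never mutates the world."""
        dx = obj.position[0] - arm_center[0]
        dy = obj.position[1] - arm_center[1]
        if math.hypot(dx, dy) > arm_reach:
            return False
        hx, hy = self._half_extents(obj.kind)
        return bool(_phys.placement_clear(
            obj.position[0], obj.position[1], obj.angle, hx, hy,
            self.pos, self.angle, self.kind, self.active, self.half,
            self.tiles, self.tile_half,
            self.config.field_width, self.config.field_height))

    def add_object(self, obj: PlacedObject, check: bool = True) -> int:
        """Insert a placed object as a dynamic body; returns its slot.

        With ``check`` (the default) the pose must be overlap-free, which is
        what :meth:`placement_valid` guarantees; inherited objects that rest
        against each other are inserted with ``check=False``.
        """
        if check:
            hx, hy = self._half_extents(obj.kind)
            if not _phys.placement_clear(
                    obj.position[0], obj.position[1], obj.angle, hx, hy,
                    self.pos, self.angle, self.kind, self.active, self.half,
                    self.tiles, self.tile_half,
                    self.config.field_width, self.config.field_height):
                raise ValueError("object pose interpenetrates existing bodies")
        slot = -1
        for i in range(2, self.pos.shape[0]):
            if not self.active[i]:
                slot = i
                break
        if slot < 0:
            raise ValueError("no free object slot (resource cap reached)")
        hx, hy = self._half_extents(obj.kind)
        m = self.config.density * (2 * hx) * (2 * hy)
        inertia = m * ((2 * hx) ** 2 + (2 * hy) ** 2) / 12.0
        self.pos[slot] = obj.position
        self.angle[slot] = obj.angle
        self.vel[slot] = 0.0
        self.angvel[slot] = 0.0
        self.kind[slot] = KIND_BOX if obj.kind == "box" else KIND_BOARD
        self.half[slot] = (hx, hy)
        self.inv_m[slot] = 1.0 / m
        self.inv_I[slot] = 1.0 / inertia
        self.active[slot] = True
        return slot

    def detect_capture(self) -> bool:
        """True iff a prey-predator contact occurred in the last step."""
        return bool(self.flags[0])

    def bottom_contact(self, body: int) -> bool:
        """True iff the body touched a tile/box/board at a point within
        ±45° of straight down during the last step."""
        if body not in (PREY, PREDATOR):
            raise KeyError(f"bottom_contact is defined for agents, got {body}")
        return bool(self.flags[1 + body])

    def object_contact(self, body: int) -> bool:
        """True iff the body touched any placed object (at any angle)
        during the last step."""
        if body not in (PREY, PREDATOR):
            raise KeyError(f"object_contact is defined for agents, got {body}")
        return bool(self.flags[3 + body])

    def reset_agents(self) -> None:
        """Teleport both agents back to their episode start positions with
        zeroed velocities and angles; placed objects are untouched."""
        for i, start in ((PREY, self._episode_starts[0]),
                         (PREDATOR, self._episode_starts[1])):
            self.pos[i] = start
            self.angle[i] = 0.0
            self.vel[i] = 0.0
            self.angvel[i] = 0.0

    def set_prey_start(self, position: tuple[float, float]) -> None:
        """Relocate the prey's episode start (used by birthplace
        inheritance); moves the prey there immediately."""
        x, y = position
        if not (0 <= x <= self.config.field_width and
                0 <= y <= self.config.field_height):
            raise ConfigurationError("birthplace outside the field")
        self._episode_starts = (tuple(position), self._episode_starts[1])
        self.pos[PREY] = position

    @property
    def episode_starts(self):
        return self._episode_starts


def build_world(config: WorldConfig | None = None) -> World:
    """Build a world from a validated config: static terrain tiles, both
    agents at their starts with zero velocity, no placed objects."""
    return World(config if config is not None else WorldConfig())


def with_defaults(**overrides) -> WorldConfig:
    """Convenience constructor: the default config with fields replaced."""
    return replace(WorldConfig(), **overrides)
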
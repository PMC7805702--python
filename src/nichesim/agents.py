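"""Prey sensing + neural controller, and the scripted predator policy.

The prey is a circle that moves by rolling (a torque whose magnitude decays
with speed, ``100000/(v+1)``) and can place objects within the reach of an
invisible arm.  A three-layer feed-forward network maps a 12-dimensional
sensor vector to 7 outputs:

  o1  rotation direction (sigmoid; > 0.5 means clockwise, i.e. rightward),
  o2  whether to place an object this step (sigmoid; > 0.5 places),
  o3, o4  object-type vote, box iff o3 > o4 (linear, only compared),
  o5, o6  polar placement coordinates: r = L_prey*o5, theta = 2*pi*o6,
  o7  placement rotation angle: 2*pi*o7.

The predator is a same-sized circle driven by a fixed script: chase the
prey while it is visible (torque magnitude ``150000/(v+1)``) and jump with
a fixed impulse when stuck on top of obstacles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._phys import KIND_BOARD, KIND_BOX
from ._sim import forward_kernel, sense_kernel
from .world import PREDATOR, PREY, PlacedObject, World

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class PreyParams:
    f_prey: float = 500.0       # visibility radius
    l_prey: float = 250.0       # arm reach
    budget: int = 40            # B, max objects in the field
    torque_coeff: float = 100_000.0
    hidden_size: int = 10

    def __post_init__(self):
        if self.f_prey <= 0 or self.l_prey <= 0:
            raise ValueError("f_prey and l_prey must be > 0")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")


@dataclass(frozen=True)
class PredatorParams:
    f_predator: float = 1000.0
    torque_coeff: float = 150_000.0
    jump_impulse: float = 50_000.0
    jump_elevation: float = math.radians(60.0)

    def __post_init__(self):
        # f_predator == 0 is allowed: it blinds (disables) the predator
        if self.f_predator < 0:
            raise ValueError("f_predator must be >= 0")
        for name in ("torque_coeff", "jump_impulse", "jump_elevation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class SensorVector:
    """The prey's per-step network input (12 scalars)."""

    count_tiles: int
    count_boxes: int
    count_boards: int
    com_tiles: tuple[float, float]
    com_boxes: tuple[float, float]
    com_boards: tuple[float, float]
    predator_offset: tuple[float, float]
    resource_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array([
            self.count_tiles, self.count_boxes, self.count_boards,
            *self.com_tiles, *self.com_boxes, *self.com_boards,
            *self.predator_offset, self.resource_ratio])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "SensorVector":
        return cls(int(x[0]), int(x[1]), int(x[2]),
                   (float(x[3]), float(x[4])), (float(x[5]), float(x[6])),
                   (float(x[7]), float(x[8])), (float(x[9]), float(x[10])),
                   float(x[11]))


@dataclass(frozen=True)
class ActionCommand:
    """Decoded controller output.  ``rotate`` may be None for scripted
    test controllers that apply no torque."""

    rotate: str | None          # "clockwise" | "anticlockwise" | None
    place: bool
    object_kind: str = "board"  # "box" | "board"
    r: float = 0.0
    theta: float = 0.0
    rotation: float = 0.0


def save_genome(path, genome: np.ndarray, params: PreyParams) -> None:
    """Write a genome as CSV with a header recording the network shape."""
    np.savetxt(path, np.asarray(genome, dtype=float), delimiter=",",
               header=f"input=12 hidden={params.hidden_size} output=7")


def load_genome(path, params: PreyParams) -> np.ndarray:
    """Read a genome written by :func:`save_genome`, validating its length
    against the expected network shape."""
    g = np.loadtxt(path, delimiter=",")
    if g.ndim != 1 or g.shape[0] != genome_length(params):
        raise ValueError(
            f"genome file {path} has length {g.size}, expected "
            f"{genome_length(params)} for hidden_size={params.hidden_size}")
    return g


def genome_length(params: PreyParams) -> int:
    """Flat genome length for the 12 -> H -> 7 network with biases on both
    layers: (12+1)*H + (H+1)*7."""
    h = params.hidden_size
    return 13 * h + 7 * (h + 1)


def split_genome(genome: np.ndarray,
                 params: PreyParams) -> tuple[np.ndarray, np.ndarray]:
    h = params.hidden_size
    expected = genome_length(params)
    if genome.shape[0] != expected:
        raise ValueError(
            f"genome length {genome.shape[0]} does not match the network "
            f"shape (expected {expected} for hidden_size={h})")
    w1 = np.ascontiguousarray(genome[:13 * h].reshape(h, 13))
    w2 = np.ascontiguousarray(genome[13 * h:].reshape(7, h + 1))
    return w1, w2


def sense(world: World, remaining: int, params: PreyParams) -> SensorVector:
    """What the prey perceives: per-class counts and centres of mass within
    its visibility, the predator's relative position (zero when out of
    range), and the remaining resource ratio."""
    if not (0 <= remaining <= params.budget):
        raise ValueError("remaining must lie in [0, budget]")
    x = sense_kernel(world.pos[0, 0], world.pos[0, 1],
                     world.pos[1, 0], world.pos[1, 1],
                     world.pos, world.kind, world.active, world.tiles,
                     params.f_prey, float(remaining), float(params.budget))
    return SensorVector.from_array(x)


def forward(genome: np.ndarray, sensor: SensorVector | np.ndarray,
            params: PreyParams) -> np.ndarray:
    """Evaluate the controller network; returns the 7 output activations."""
    w1, w2 = split_genome(np.asarray(genome, dtype=float), params)
    x = sensor.as_array() if isinstance(sensor, SensorVector) else \
        np.asarray(sensor, dtype=float)
    return forward_kernel(w1, w2, x)


def decode_action(outputs: np.ndarray, params: PreyParams) -> ActionCommand:
    """Map the 7 network outputs to an action.

    Strict inequalities follow the controller definition: ties at 0.5 fall
    to anticlockwise / no placement, and o3 == o4 yields a board.
    """
    o = np.asarray(outputs, dtype=float)
    if not np.all(np.isfinite(o)):
        raise ValueError("controller outputs must be finite")
    return ActionCommand(
        rotate="clockwise" if o[0] > 0.5 else "anticlockwise",
        place=bool(o[1] > 0.5),
        object_kind="box" if o[2] > o[3] else "board",
        r=params.l_prey * o[4],
        theta=TWO_PI * o[5],
        rotation=TWO_PI * o[6])


def prey_torque_magnitude(v: float, coeff: float = 100_000.0) -> float:
    """Speed-damped torque for the prey: coeff / (v + 1)."""
    if v < 0:
        raise ValueError("speed must be >= 0")
    return coeff / (v + 1.0)


def predator_torque_magnitude(v: float, coeff: float = 150_000.0) -> float:
    """Speed-damped torque for the predator: coeff / (v + 1)."""
    if v < 0:
        raise ValueError("speed must be >= 0")
    return coeff / (v + 1.0)


@dataclass(frozen=True)
class PredatorAction:
    chase: str | None           # torque direction, None when prey unseen
    jump: bool


def predator_policy(world: World, params: PredatorParams,
                    cooldown_ok: bool = True) -> PredatorAction:
    """The scripted chase: torque toward the prey while it is within
    ``f_predator`` (clockwise iff the prey is strictly to the right), plus
    a jump flag when the predator is stuck in placed objects — touching a
    box or board while its bottom rests on a support — and the jump
    cooldown has elapsed."""
    dx = world.pos[PREY, 0] - world.pos[PREDATOR, 0]
    dy = world.pos[PREY, 1] - world.pos[PREDATOR, 1]
    if dx * dx + dy * dy > params.f_predator ** 2:
        return PredatorAction(chase=None, jump=False)
    chase = "clockwise" if dx > 0.0 else "anticlockwise"
    jump = (bool(world.bottom_contact(PREDATOR))
            and bool(world.object_contact(PREDATOR)) and cooldown_ok)
    return PredatorAction(chase=chase, jump=jump)


def act_prey(world: World, action: ActionCommand, remaining: int,
             params: PreyParams) -> int:
    """Apply the prey's action for this step; returns the updated remaining
    budget.

    The torque is always applied (magnitude from the current speed); a
    placement happens only when the budget allows and the pose is valid —
    otherwise the placement is silently cancelled.
    """
    if not (0 <= remaining <= params.budget):
        raise ValueError("remaining must lie in [0, budget]")
    if action.rotate is not None:
        speed = world.body_state(PREY).speed
        world.apply_torque(PREY, prey_torque_magnitude(
            speed, params.torque_coeff), action.rotate)
    if action.place and remaining > 0:
        px, py = world.pos[PREY]
        ox = px + action.r * math.cos(action.theta)
        oy = py + action.r * math.sin(action.theta)
        obj = PlacedObject(action.object_kind, (ox, oy), action.rotation)
        if world.placement_valid(obj, (px, py), params.l_prey):
            world.add_object(obj, check=False)
            return remaining - 1
    return remaining
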
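"""Physics world: construction, stepping, placement, capture, reset."""

import math

import numpy as np
import pytest

from nichesim import ConfigurationError, PlacedObject, WorldConfig, build_world
from nichesim.world import PREDATOR, PREY

from conftest import world_state_arrays


class TestConfig:
    def test_default_build_initial_state(self, default_world):
        w = default_world
        assert w.body_state(PREY).position == (400.0, 50.0)
        assert w.body_state(PREDATOR).position == (900.0, 50.0)
        assert w.object_count == 0
        # flat floor spans the full width: 1000 / 20 = 50 static tiles
        assert w.tiles.shape[0] == 50
        assert w.body_state(PREY).speed == 0.0

    @pytest.mark.parametrize("bad", [
        dict(terrain=[(60, 0)]),                      # tile outside field
        dict(terrain=[(0, 25)]),
        dict(prey_start=(900.0, 50.0)),               # equal starts
        dict(tile_side=-1.0),
        dict(timestep=0.0),
        dict(prey_start=(10.0, 10.0)),                # overlaps floor tile
    ])
    def test_invalid_config_raises(self, bad):
        with pytest.raises(ConfigurationError):
            build_world(WorldConfig(**bad))


class TestStepping:
    def test_midair_object_falls_to_rest(self, settled_world):
        w = settled_world
        w.add_object(PlacedObject("box", (600.0, 120.0)))
        y0 = w.pos[2, 1]
        for _ in range(200):
            w.step()
        # fell from 120 to rest on the floor (tile top 20 + half side 9)
        assert w.pos[2, 1] < y0
        assert w.pos[2, 1] == pytest.approx(29.0, abs=0.5)
        v_final = np.hypot(*w.vel[2])
        assert v_final < 1.0

    def test_resting_bodies_drift_below_tolerance(self, settled_world):
        w = settled_world
        w.add_object(PlacedObject("box", (600.0, 29.05)))
        for _ in range(100):
            w.step()
        snapshot = w.pos.copy()
        for _ in range(100):
            w.step()
        drift = np.abs(w.pos - snapshot).max()
        assert drift < w.config.tile_side / 100.0

    def test_step_count_matches_simulated_time(self):
        cfg = WorldConfig()
        assert int(200.0 / cfg.timestep) == 10_000


class TestTorque:
    def test_clockwise_torque_rolls_right(self, settled_world):
        w = settled_world
        x0 = w.pos[PREY, 0]
        for _ in range(150):
            w.apply_torque(PREY, 100_000.0, "clockwise")
            w.step()
        assert w.pos[PREY, 0] > x0 + 1.0

    def test_anticlockwise_torque_rolls_left(self, settled_world):
        w = settled_world
        x0 = w.pos[PREY, 0]
        for _ in range(150):
            w.apply_torque(PREY, 100_000.0, "anticlockwise")
            w.step()
        assert w.pos[PREY, 0] < x0 - 1.0

    def test_zero_torque_is_inert(self, settled_world):
        w = settled_world
        x0 = w.pos[PREY].copy()
        w.apply_torque(PREY, 0.0, "clockwise")
        for _ in range(20):
            w.step()
        assert w.pos[PREY, 0] == pytest.approx(x0[0], abs=1e-9)
        # vertical settling against the contact slop is allowed
        assert w.pos[PREY, 1] == pytest.approx(x0[1], abs=0.05)

    def test_unknown_body_raises(self, default_world):
        with pytest.raises(KeyError):
            default_world.apply_torque(7, 10.0, "clockwise")
        with pytest.raises(ValueError):
            default_world.apply_torque(PREY, -5.0, "clockwise")


class TestJumpImpulse:
    def test_impulse_vector_components(self, default_world):
        w = default_world
        m = 1.0 / w.inv_m[PREDATOR]
        w.apply_jump_impulse(PREDATOR, (0.0, 50.0))   # target to the left
        vx, vy = w.vel[PREDATOR]
        ix, iy = vx * m, vy * m
        assert ix == pytest.approx(-50_000.0 * math.cos(math.radians(60)))
        assert iy == pytest.approx(50_000.0 * math.sin(math.radians(60)))
        assert math.hypot(ix, iy) == pytest.approx(50_000.0)

    def test_mirror_symmetry(self, default_world):
        w = default_world
        w.apply_jump_impulse(PREY, (900.0, 50.0))     # target to the right
        assert w.vel[PREY, 0] > 0
        assert w.vel[PREY, 1] > 0

    def test_target_at_body_position_rejected(self, default_world):
        with pytest.raises(ValueError):
            default_world.apply_jump_impulse(PREY, (400.0, 50.0))


class TestPlacement:
    def test_on_prey_body_invalid(self, default_world):
        obj = PlacedObject("box", (400.0, 50.0))
        assert not default_world.placement_valid(obj, (400.0, 50.0), 250.0)

    def test_open_air_valid(self, default_world):
        obj = PlacedObject("box", (500.0, 150.0))
        assert default_world.placement_valid(obj, (400.0, 50.0), 250.0)

    def test_straddling_boundary_invalid(self, default_world):
        obj = PlacedObject("box", (995.0, 200.0))
        assert not default_world.placement_valid(obj, (900.0, 200.0), 250.0)

    def test_beyond_arm_reach_invalid(self, default_world):
        obj = PlacedObject("box", (700.0, 150.0))
        assert not default_world.placement_valid(obj, (400.0, 50.0), 250.0)

    def test_overlapping_tile_invalid(self, default_world):
        obj = PlacedObject("box", (500.0, 18.0))
        assert not default_world.placement_valid(obj, (500.0, 60.0), 250.0)

    def test_check_is_side_effect_free(self, default_world):
        w = default_world
        before = world_state_arrays(w)
        w.placement_valid(PlacedObject("board", (500.0, 100.0), 1.0),
                          (400.0, 50.0), 250.0)
        after = world_state_arrays(w)
        for a, b in zip(before, after):
            assert np.array_equal(a, b)

    def test_add_object_round_trip(self, default_world):
        w = default_world
        w.add_object(PlacedObject("board", (500.0, 150.0), math.pi / 2))
        assert w.object_count == 1
        obj = w.objects()[0]
        assert obj.kind == "board"
        assert obj.angle == pytest.approx(math.pi / 2)
        w.add_object(PlacedObject("box", (600.0, 150.0)))
        assert w.object_count == 2

    def test_add_interpenetrating_raises(self, default_world):
        w = default_world
        w.add_object(PlacedObject("box", (500.0, 150.0)))
        with pytest.raises(ValueError):
            w.add_object(PlacedObject("box", (500.0, 150.0)))


class TestCaptureAndReset:
    def test_far_apart_no_capture(self, settled_world):
        assert not settled_world.detect_capture()

    def test_touching_agents_capture(self):
        cfg = WorldConfig(predator_start=(439.0, 50.0))
        w = build_world(cfg)
        w.step()
        assert w.detect_capture()

    def test_object_contact_is_not_capture(self, settled_world):
        w = settled_world
        w.add_object(PlacedObject("box", (400.0, 70.0)))  # lands on prey
        for _ in range(30):
            w.step()
        assert not w.detect_capture()

    def test_reset_preserves_objects_and_zeroes_agents(self, settled_world):
        w = settled_world
        for x in (500.0, 540.0, 580.0):
            w.add_object(PlacedObject("box", (x, 100.0)))
        for _ in range(50):
            w.step()
        poses_before = [(o.kind, o.position, o.angle) for o in w.objects()]
        w.vel[PREY] = (3.0, 1.0)
        w.reset_agents()
        assert w.body_state(PREY).position == (400.0, 50.0)
        assert w.body_state(PREY).linear_velocity == (0.0, 0.0)
        assert w.body_state(PREDATOR).angular_velocity == 0.0
        poses_after = [(o.kind, o.position, o.angle) for o in w.objects()]
        assert poses_before == poses_after
        # idempotent
        w.reset_agents()
        assert w.body_state(PREY).position == (400.0, 50.0)


class TestBottomContact:
    def test_resting_on_floor(self, settled_world):
        assert settled_world.bottom_contact(PREY)
        assert settled_world.bottom_contact(PREDATOR)

    def test_airborne(self, settled_world):
        w = settled_world
        w.pos[PREDATOR, 1] = 200.0
        w.step()
        assert not w.bottom_contact(PREDATOR)

    def test_side_contact_does_not_count(self):
        # an agent wedged horizontally against a box: the touch point is
        # outside the ±45° lower sector, so it is not a bottom contact
        cfg = WorldConfig(terrain=[], predator_start=(900.0, 300.0))
        w = build_world(cfg)
        w.add_object(PlacedObject("box", (429.2, 50.0)), check=False)
        w.pos[2, 0] = 429.0   # just touching the prey from the side
        w.vel[PREY] = (0.0, 0.0)
        w.step()
        assert not w.bottom_contact(PREY)

    def test_object_contact_flag(self, settled_world):
        w = settled_world
        assert not w.object_contact(PREY)
        w.add_object(PlacedObject("box", (400.0, 70.0)))  # drops on prey
        for _ in range(60):
            w.step()
        assert w.object_contact(PREY)
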
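# Methods

This note documents the model implemented by `nichesim`, the choices made
where the design was genuinely open, and what the test suite's synthetic
settings do and do not show.

## World and physics backend

The field is a 1000 × 400 rectangle with the origin at the bottom-left,
y increasing upward, gravity along −y, and angles in
counterclockwise-positive radians ("clockwise" torque is therefore
negative and rolls a body rightward on the floor). Terrain is a set of
static 20 × 20 tiles; the default terrain is a single flat floor row of 50
tiles. The prey starts at (400, 50) and the predator at (900, 50), giving
a start distance d = 500 with the predator able to see the prey from the
outset (its visual radius is 1000).

Physics runs on the package's own impulse-based rigid-body engine
(`nichesim._phys`): semi-implicit Euler integration, circle/oriented-box
collision detection (separating-axis tests with reference-face clipping
for box–box manifolds), and a sequential-impulse contact solver with
Coulomb friction, zero restitution, and Baumgarte positional
stabilisation (β = 0.2, slop = 0.05, 10 iterations per step). The engine
is exposed through a thin backend surface (step / apply torque / apply
impulse / contact queries), so a different backend could be substituted;
all results are reproducible per backend build and platform, and
behavioural comparisons downstream of physics are statistical rather than
bitwise.

Choices that the model statement leaves open, fixed here:

* **Field confinement.** Bodies are kept inside the field by four static
  boundary walls just outside the rectangle (`bounded=True`). Without
  them agents roll or get knocked off the floor's edge and fall forever,
  which destroys the fitness scale (final distances in the tens of
  thousands). The walls only collide — they are not field tiles: the prey
  does not sense them, they are not rendered in snapshots, and they do
  not trigger the predator's jump.
* **Torque units.** The torque laws are stated in kgf·m; magnitudes are
  converted to engine N·m at application time (`torque_factor = 9.8`).
  This calibration is fixed by the model's own statement that the
  predator can catch a naive prey about 10 times within T = 200 s:
  with raw magnitudes the rolling acceleration τ/(1.5·m·r) of a
  1257-unit-mass disc yields only ~4 catches, while the kgf→N conversion
  reproduces ~10 (measured: exactly 10 against a motionless prey).
* **Materials.** Density 1 (mass = area), friction coefficient 1.0,
  restitution 0, gravity magnitude 20. Friction and gravity are set so
  the torque-driven wheel rolls rather than spins in place (the no-slip
  friction demand at rest is ≈ 0.5·m·a ≈ μ·m·g at these values); the
  jump impulse (Δv ≈ 40 at 60°) then clears one-to-two stacked boxes.
  All material parameters are overridable in `WorldConfig`.
* **Reset semantics.** A capture teleports both agents to their episode
  start positions with linear and angular velocity zeroed and angle reset
  to 0. Placed objects are untouched.
* **"Bottom" contact.** A contact supports a body if its touch point lies
  within ±45° of straight down from the body centre — a quarter-sector
  that distinguishes standing-on from leaning-against.

## Prey and predator

The prey's 12 sensor values are, in order: counts of tiles, boxes, and
boards whose centres lie within F_prey of the prey; per-class
centre-of-mass offsets relative to the prey (zero vector when the class
has no member in range — distinguishable from a true zero offset only
jointly with the count, which the network also receives); the predator's
relative position (zero when out of range); and remaining/B. Because all
members of a class share one mass, the mass-weighted class COM equals the
plain mean. Inputs are fed to the network raw (no normalisation), once
per physics step.

The controller is a fully connected 12 → H → 7 network with biases on
both layers (genome length 13·H + 7·(H+1)); H defaults to 10 — small
enough for fast evolution, expressive enough for the observed strategies.
The two object-type outputs use identity activation (only their
comparison matters); the rest are sigmoids. Ties fall to the "otherwise"
branch everywhere: o₁ = 0.5 rotates anticlockwise, o₂ = 0.5 places
nothing, o₃ = o₄ places a board, and a prey exactly above the predator is
chased anticlockwise.

The predator jumps only when *stuck in objects*: its bottom must be
supported **and** it must be touching a placed object in the same step,
with at most one jump per simulated second. On open floor it never
jumps, which keeps it precise at close range; against structures it
hops, which is exactly the situation the jump exists for. The "touching
a placed object" predicate is this implementation's operationalisation
of being stuck — the alternative (a low-speed test) is harder to make
robust against the torque law's natural slow starts.

The object budget B counts objects *existing in the field*: inherited
objects count against it, and weathered or destroyed objects free budget
only at the generational handoff, never mid-episode.

## Evolution and inheritance

The GA is purely generational (no elitism): N/2 parent pairs are drawn by
roulette wheel with replacement (an all-zero wheel — reachable because
fitness is clamped at 0 — degenerates to uniform), each pair is copied,
two-point crossover swaps a half-open segment [a, b) with cut points
drawn uniformly over distinct positions 0 ≤ a < b ≤ L with probability
P_c, and each gene mutates independently with probability P_m by adding
uniform noise on [−R, R]. Mutated genes are not clamped; only
initialization is bounded to [−1, 1].

Offspring i of a pair inherits the environment of parent i: the parent's
end-of-episode objects (each surviving weathering with probability
1 − W, survivors keeping kind, position, and rotation exactly) and, when
P is true, the parent's end position as its birthplace. Inherited objects
that would interpenetrate the newly spawned prey are discarded (counted
as weathered); objects resting against each other are inserted as-is.
Weathering is applied once, at offspring-world construction. The
predator's start never moves. With W = 1 and P = false the whole pathway
is the identity, which the suite verifies against a direct
fresh-world-every-generation loop.

Episode evaluation measures d between the episode's *actual* start
positions — so d varies across individuals when P is true — and d_f after
the final step; a capture on the final step still resets the agents
first. Multiple contacts within one step count as one capture.

## Feature analysis

Snapshots render the field at 1 unit/pixel (1000 × 400) with an injective
class→intensity map (background 0, tiles 0.4, boxes 0.7, boards 0.85,
agents 1.0), then area-average 8 × 8 blocks to 125 × 50; area-averaging
preserves mean intensity to machine precision. One snapshot is taken per
(trial, generation) whose best fitness strictly exceeds 9.0, from the
best individual's end state.

The autoencoder is a fully connected stack, by default
6250 → 512 → 64 → 2 mirrored in the decoder — the smallest stack that
plausibly qualifies as deep for this input size — with tanh activations,
a sigmoid reconstruction layer (required by binary cross-entropy on
[0, 1] pixels), and Adadelta updates (ρ = 0.95, ε = 1e−7, batch 10).
Reconstruction training is non-convex; `n_restarts` independent
initialisations can be run, keeping the model with the lowest final
reconstruction loss — a stated criterion in place of visually picking the
clearest embedding. Structure classification is declarative: labeled
simple polygons in the embedding plane, first-declared region wins on
overlap, and points in no region are "unclassified". The structure COM is
the mass-weighted mean of object positions (boxes and boards have equal
area 324, so this equals the unweighted mean).

## Problem sizes used by the suite

Unit and property tests run at desk scale (single episodes of 2–20 s,
10⁴ draws for frequency checks, 300–400 replicates for the binomial
weathering tests). The directional-trend checks evolve N = 16 for 60
generations with 50-second episodes and 3 seeds per cell — large enough
for the resource-cap and inheritance orderings to emerge, small enough to
keep the suite at roughly ten minutes. The feature-pipeline check trains
a 6250 → 128 → 16 → 2 encoder for 30 epochs on 600 synthetic snapshots.

The synthetic archetype generators (shell: a box pile enclosing a point;
barnacle: boards piled at the left edge; wall: a mid-field box column)
emulate the geometry of evolved structures but none of their physics or
history: passing the separation test shows the rasterize→embed pipeline
can distinguish these geometries, not that evolved structures from any
particular run will cluster as cleanly. Likewise the trend checks assert
orderings of cell means, not the published magnitudes: full-scale values
depend on thousands of generations of evolution and on backend-specific
contact dynamics, and are obtained with the documented sweep command, not
in the test suite.

## Known limitations

* The contact solver has no warm starting; very tall stacks (> ~10
  boxes) settle softly and can creep. The structures that matter here
  (2–6 object heights) are stable.
* The engine is deterministic on a given platform/build but not
  guaranteed bit-identical across BLAS/numba versions; cross-platform
  comparisons should be statistical.
* The prey cannot remove or reposition objects, and the predator does not
  evolve — both are scope decisions of the model, not engine limits.
* Sensor inputs are raw (counts up to ~50, offsets up to ±500), so early
  evolution operates in the sigmoids' saturated regime; this matches the
  model statement but slows the first generations.
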
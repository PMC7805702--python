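"""Feature analysis of evolved structures.

Pipeline: collect end-of-evaluation field states whose best fitness exceeds
a threshold (9.0 by default), rasterize them to 125 x 50 grayscale images,
train a reconstruction autoencoder with a 2-neuron bottleneck, embed every
snapshot as a point in the plane, and classify points by user-declared
polygon regions (with an "unclassified" catch-all).

The autoencoder is a fully connected stack (default 6250 -> 512 -> 64 -> 2,
mirrored decoder) with tanh activations, a sigmoid reconstruction layer,
binary cross-entropy loss and Adadelta updates, trained in minibatches of
10.  Because reconstruction training is non-convex and sensitive to the
initialisation, several restarts can be run and the one with the lowest
final reconstruction loss kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from skimage.draw import disk, polygon as draw_polygon

from .world import PlacedObject, WorldConfig

RASTER_SHAPE = (50, 125)      # rows x cols after 8x downsampling
RENDER_SHAPE = (400, 1000)

# injective class -> grayscale intensity map (background stays 0)
INTENSITY_TILE = 0.4
INTENSITY_BOX = 0.7
INTENSITY_BOARD = 0.85
INTENSITY_AGENT = 1.0


@dataclass(frozen=True)
class StructureSnapshot:
    """One rasterized end-of-evaluation field image plus its metadata."""

    image: np.ndarray            # (50, 125), float in [0, 1]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.image.shape != RASTER_SHAPE:
            raise ValueError(
                f"snapshot must be {RASTER_SHAPE}, got {self.image.shape}")


@dataclass(frozen=True)
class FeaturePoint:
    x: float
    y: float
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RegionSpec:
    """A labeled polygon in embedding space used for manual strategy
    classification (e.g. shell / barnacles / wall)."""

    label: str
    polygon: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.polygon) < 3:
            raise ValueError(f"region {self.label!r}: need >= 3 vertices")
        poly = Polygon(self.polygon)
        if not poly.is_valid or not poly.is_simple:
            raise ValueError(
                f"region {self.label!r}: polygon must be simple")

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


def _fill_obb(img: np.ndarray, cx: float, cy: float, ang: float,
              hx: float, hy: float, value: float) -> None:
    h = img.shape[0]
    c, s = math.cos(ang), math.sin(ang)
    xs, ys = [], []
    for sx, sy in ((-1, -1), (1, -1), (1, 1), (-1, 1)):
        x = cx + c * sx * hx - s * sy * hy
        y = cy + s * sx * hx + c * sy * hy
        xs.append(x)
        ys.append(h - y)     # y up -> row down
    rr, cc = draw_polygon(np.array(ys), np.array(xs), shape=img.shape)
    img[rr, cc] = value


def render_field(objects, config: WorldConfig | None = None,
                 prey_position=None, predator_position=None) -> np.ndarray:
    """Full-resolution screenshot of a field state: a (400, 1000) grayscale
    array at 1 unit per pixel.  Terrain tiles, boxes, boards and agents
    each get a fixed intensity; later classes overdraw earlier ones."""
    config = config or WorldConfig()
    img = np.zeros(RENDER_SHAPE)
    half = config.tile_side / 2.0
    for (i, j) in config.terrain:
        _fill_obb(img, (i + 0.5) * config.tile_side,
                  (j + 0.5) * config.tile_side, 0.0, half, half,
                  INTENSITY_TILE)
    for obj in objects:
        if obj.kind == "box":
            hx = hy = config.box_side / 2.0
            value = INTENSITY_BOX
        else:
            hx, hy = config.board_dims[0] / 2.0, config.board_dims[1] / 2.0
            value = INTENSITY_BOARD
        _fill_obb(img, obj.position[0], obj.position[1], obj.angle,
                  hx, hy, value)
    for pos in (prey_position, predator_position):
        if pos is not None:
            rr, cc = disk((RENDER_SHAPE[0] - pos[1], pos[0]),
                          config.agent_radius, shape=RENDER_SHAPE)
            img[rr, cc] = INTENSITY_AGENT
    return img


def rasterize(objects, config: WorldConfig | None = None,
              prey_position=None, predator_position=None,
              meta: dict | None = None) -> StructureSnapshot:
    """Deterministic snapshot of a field state: render at 1 unit per pixel
    (1000 x 400), then area-average 8 x 8 pixel blocks down to 125 x 50."""
    img = render_field(objects, config, prey_position, predator_position)
    small = img.reshape(RASTER_SHAPE[0], 8, RASTER_SHAPE[1], 8).mean((1, 3))
    return StructureSnapshot(image=small, meta=dict(meta or {}))


def collect_adaptive_structures(trial_logs, threshold: float = 9.0,
                                include_agents: bool = True
                                ) -> list[StructureSnapshot]:
    """One snapshot per (trial, generation) whose best fitness is strictly
    greater than the threshold, rendered from the best individual's
    end-of-evaluation state."""
    out = []
    for ti, log in enumerate(trial_logs):
        cfg = log.config
        for rec in log.records:
            if not (rec.best_fitness > threshold):
                continue
            if rec.best_result is None:
                raise ValueError(
                    f"trial {ti} generation {rec.generation}: qualifying "
                    "generation has no stored end state to render")
            br = rec.best_result
            meta = {
                "trial": ti,
                "generation": rec.generation,
                "B": cfg.prey.budget,
                "W": cfg.inherit.w,
                "P": cfg.inherit.p,
                "best_fitness": rec.best_fitness,
                "objects": br.end_objects,
            }
            out.append(rasterize(
                br.end_objects, cfg.world,
                prey_position=br.end_prey_position if include_agents
                else None,
                predator_position=br.end_predator_position if include_agents
                else None,
                meta=meta))
    return out


def structure_com(objects) -> tuple[float, float]:
    """Mass-weighted centre of mass of the placed objects (mass = density
    x area per kind; boxes 18^2 and boards 6 x 54 have equal area, so this
    coincides with the unweighted mean)."""
    objs = list(objects)
    if not objs:
        raise ValueError("structure_com of an empty object list")
    wsum = 0.0
    sx = sy = 0.0
    for o in objs:
        area = 18.0 * 18.0 if o.kind == "box" else 6.0 * 54.0
        wsum += area
        sx += area * o.position[0]
        sy += area * o.position[1]
    return sx / wsum, sy / wsum


# -- autoencoder ----------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    hidden: tuple[int, ...] = (512, 64)
    code_dim: int = 2
    epochs: int = 200
    batch_size: int = 10
    n_restarts: int = 1
    rho: float = 0.95            # Adadelta decay
    eps: float = 1e-7

    def __post_init__(self):
        if self.code_dim != 2:
            raise ValueError("the bottleneck must have exactly 2 neurons")


class Autoencoder:
    """Fully connected reconstruction autoencoder, tanh throughout with a
    sigmoid output layer, trained with binary cross-entropy + Adadelta."""

    def __init__(self, input_dim: int, hidden=(512, 64), code_dim: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        sizes = [input_dim, *hidden, code_dim, *reversed(tuple(hidden)),
                 input_dim]
        self.sizes = sizes
        self.n_encoder_layers = len(hidden) + 1
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit,
                                            size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [x]
        a = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            a = 1.0 / (1.0 + np.exp(-z)) if i == last else np.tanh(z)
            acts.append(a)
        return acts

    def encode(self, x: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(x)
        for i in range(self.n_encoder_layers):
            a = np.tanh(a @ self.weights[i] + self.biases[i])
        return a

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.atleast_2d(x))[-1]

    def loss(self, x: np.ndarray) -> float:
        x = np.atleast_2d(x)
        y = np.clip(self.reconstruct(x), 1e-12, 1.0 - 1e-12)
        return float(-np.mean(x * np.log(y) + (1 - x) * np.log(1 - y)))

    def train(self, x: np.ndarray, epochs: int, batch_size: int = 10,
              rng: np.random.Generator | None = None, rho: float = 0.95,
              eps: float = 1e-7) -> list[float]:
        """Minibatch Adadelta on BCE; returns the per-epoch loss history."""
        rng = rng or np.random.default_rng()
        x = np.atleast_2d(x)
        n = x.shape[0]
        eg2_w = [np.zeros_like(w) for w in self.weights]
        ed2_w = [np.zeros_like(w) for w in self.weights]
        eg2_b = [np.zeros_like(b) for b in self.biases]
        ed2_b = [np.zeros_like(b) for b in self.biases]
        history = []
        last = len(self.weights) - 1
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for s in range(0, n, batch_size):
                batch = x[order[s:s + batch_size]]
                m = batch.shape[0]
                acts = self._forward(batch)
                y = np.clip(acts[-1], 1e-12, 1.0 - 1e-12)
                epoch_loss += float(-np.sum(
                    batch * np.log(y) + (1 - batch) * np.log(1 - y)))
                # sigmoid + BCE: delta at the output is simply (y - x)
                delta = (acts[-1] - batch) / (m * batch.shape[1])
                for i in range(last, -1, -1):
                    gw = acts[i].T @ delta
                    gb = delta.sum(axis=0)
                    if i > 0:
                        delta = (delta @ self.weights[i].T) * \
                            (1.0 - acts[i] ** 2)
                    for g, w_arr, eg2, ed2 in ((gw, self.weights[i],
                                                eg2_w[i], ed2_w[i]),
                                               (gb, self.biases[i],
                                                eg2_b[i], ed2_b[i])):
                        eg2 *= rho
                        eg2 += (1 - rho) * g * g
                        step = -np.sqrt(ed2 + eps) / np.sqrt(eg2 + eps) * g
                        ed2 *= rho
                        ed2 += (1 - rho) * step * step
                        w_arr += step
            history.append(epoch_loss / (n * x.shape[1]))
        return history


def train_autoencoder(dataset: list[StructureSnapshot],
                      config: TrainConfig | None = None,
                      rng: np.random.Generator | None = None
                      ) -> tuple[Autoencoder, list[float]]:
    """Train the embedding network on a snapshot dataset.

    Runs ``n_restarts`` independent initialisations and keeps the model
    with the lowest final reconstruction loss (a stated criterion in place
    of visually picking the clearest embedding).
    """
    if not dataset:
        raise ValueError("cannot train the autoencoder on an empty dataset")
    config = config or TrainConfig()
    rng = rng or np.random.default_rng()
    x = np.stack([s.image.ravel() for s in dataset])
    best_model = None
    best_history = None
    for _ in range(max(1, config.n_restarts)):
        model = Autoencoder(x.shape[1], hidden=config.hidden,
                            code_dim=config.code_dim, rng=rng)
        history = model.train(x, epochs=config.epochs,
                              batch_size=config.batch_size, rng=rng,
                              rho=config.rho, eps=config.eps)
        if best_history is None or history[-1] < best_history[-1]:
            best_model = model
            best_history = history
    return best_model, best_history


def encode(encoder: Autoencoder,
           snapshot: StructureSnapshot) -> FeaturePoint:
    """Embed one snapshot as its 2-D bottleneck activation."""
    if snapshot.image.size != encoder.sizes[0]:
        raise ValueError("snapshot shape does not match the encoder input")
    z = encoder.encode(snapshot.image.ravel())[0]
    return FeaturePoint(float(z[0]), float(z[1]), dict(snapshot.meta))


def encode_all(encoder: Autoencoder, dataset) -> list[FeaturePoint]:
    x = np.stack([s.image.ravel() for s in dataset])
    z = encoder.encode(x)
    return [FeaturePoint(float(a), float(b), dict(s.meta))
            for (a, b), s in zip(z, dataset)]


def classify_by_regions(points: list[FeaturePoint],
                        regions: list[RegionSpec]):
    """Label each point with the first declared region containing it (the
    declaration order resolves overlaps); points in no region become
    "unclassified".  Returns (labels, per-label counts, per-(label, B)
    counts)."""
    polys = [(r.label, r.shapely()) for r in regions]
    labels = []
    for p in points:
        pt = Point(p.x, p.y)
        for label, poly in polys:
            if poly.covers(pt):
                labels.append(label)
                break
        else:
            labels.append("unclassified")
    order = [r.label for r in regions] + ["unclassified"]
    counts = pd.Series(labels).value_counts().reindex(order, fill_value=0)
    df = pd.DataFrame({
        "label": labels,
        "B": [p.meta.get("B") for p in points],
    })
    by_b = df.value_counts(["label", "B"]).unstack(fill_value=0) \
        if df["B"].notna().any() else None
    return labels, counts, by_b


def scatter_plot(points: list[FeaturePoint], path, color_key=None):
    """Save a scatter of the embedding, optionally colored by a metadata
    key (e.g. "B") or by the structure COM x-coordinate ("com_x")."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [p.x for p in points]
    ys = [p.y for p in points]
    fig, ax = plt.subplots(figsize=(6, 5))
    if color_key == "com_x":
        c = [structure_com(p.meta["objects"])[0]
             if p.meta.get("objects") else np.nan for p in points]
    elif color_key is not None:
        c = [p.meta.get(color_key) for p in points]
    else:
        c = None
    sc = ax.scatter(xs, ys, c=c, s=8, cmap="coolwarm")
    if c is not None:
        fig.colorbar(sc, ax=ax, label=color_key)
    ax.set_xlabel("feature 1")
    ax.set_ylabel("feature 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
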
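"""Structure snapshots, the embedding autoencoder, and region labels."""

import numpy as np
import pytest

from nichesim import (PlacedObject, RegionSpec, TrainConfig, WorldConfig,
                      classify_by_regions, collect_adaptive_structures,
                      encode, encode_all, rasterize, structure_com,
                      train_autoencoder)
from nichesim.features import (FeaturePoint, RASTER_SHAPE, Autoencoder,
                               render_field)


class TestRasterize:
    def test_snapshot_dims(self):
        snap = rasterize([], WorldConfig())
        assert snap.image.shape == (50, 125)
        assert snap.image.min() >= 0.0 and snap.image.max() <= 1.0

    def test_empty_field_shows_terrain_row_only(self):
        snap = rasterize([], WorldConfig())
        # floor tiles cover y in [0, 20): the bottom 2.5 downsampled rows
        assert np.all(snap.image[:-3] == 0.0)       # above the floor: blank
        assert np.all(snap.image[-2:] > 0.0)

    def test_deterministic(self):
        objs = [PlacedObject("board", (500.0, 120.0), 0.7)]
        a = rasterize(objs, WorldConfig()).image
        b = rasterize(objs, WorldConfig()).image
        assert np.array_equal(a, b)

    def test_single_box_footprint(self):
        cfg = WorldConfig(terrain=[])
        snap = rasterize([PlacedObject("box", (300.0, 60.0))], cfg)
        rows, cols = np.nonzero(snap.image)
        # 18x18 box at (300, 60): x in [291, 309] -> cols 36..38,
        # y in [51, 69] -> rows (400-69)/8 .. (400-51)/8 = 41..43
        assert cols.min() >= 36 - 1 and cols.max() <= 38 + 1
        assert rows.min() >= 41 - 1 and rows.max() <= 43 + 1

    def test_downsampling_conserves_mean(self):
        objs = [PlacedObject("box", (321.0, 87.0), 0.4),
                PlacedObject("board", (700.0, 140.0), 1.1)]
        full = render_field(objs, WorldConfig(), prey_position=(400, 40))
        snap = rasterize(objs, WorldConfig(), prey_position=(400, 40))
        assert snap.image.mean() == pytest.approx(full.mean(), abs=1e-6)


class TestStructureCom:
    def test_single_box(self):
        assert structure_com([PlacedObject("box", (300.0, 60.0))]) == \
            pytest.approx((300.0, 60.0))

    def test_equal_area_kinds_average(self):
        com = structure_com([PlacedObject("box", (100.0, 50.0)),
                             PlacedObject("board", (300.0, 50.0))])
        assert com == pytest.approx((200.0, 50.0))

    def test_translation_equivariance(self, rng):
        objs = [PlacedObject("box", (float(x), float(y)))
                for x, y in rng.uniform(50, 350, (6, 2))]
        shifted = [PlacedObject(o.kind, (o.position[0] + 13.0,
                                         o.position[1] - 7.0), o.angle)
                   for o in objs]
        c0 = structure_com(objs)
        c1 = structure_com(shifted)
        assert c1[0] - c0[0] == pytest.approx(13.0)
        assert c1[1] - c0[1] == pytest.approx(-7.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            structure_com([])


class _Record:
    def __init__(self, generation, best_fitness, result):
        self.generation = generation
        self._bf = best_fitness
        self.best_result = result

    @property
    def best_fitness(self):
        return self._bf


class _Result:
    def __init__(self):
        self.end_objects = (PlacedObject("box", (500.0, 100.0)),)
        self.end_prey_position = (400.0, 50.0)
        self.end_predator_position = (900.0, 50.0)


class _Log:
    """Minimal stand-in for a TrialLog (synthetic, fabricated fitnesses)."""

    def __init__(self, best_fitnesses, config):
        self.config = config
        self.records = [_Record(g, bf, _Result())
                        for g, bf in enumerate(best_fitnesses)]


class TestAdaptiveStructureFilter:
    def make_log(self, fitnesses):
        from nichesim import ExperimentConfig
        return _Log(fitnesses, ExperimentConfig())

    def test_all_below_threshold_empty(self):
        log = self.make_log([5.0, 8.9, 9.0])
        assert collect_adaptive_structures([log]) == []

    def test_exactly_nine_excluded(self):
        log = self.make_log([9.0])
        assert collect_adaptive_structures([log], threshold=9.0) == []

    def test_qualifying_generations_collected_with_meta(self):
        log = self.make_log([9.5, 3.0, 9.2, 9.9])
        snaps = collect_adaptive_structures([log])
        assert len(snaps) == 3
        assert [s.meta["generation"] for s in snaps] == [0, 2, 3]
        assert snaps[0].meta["best_fitness"] == 9.5
        assert snaps[0].meta["B"] == 40

    def test_missing_end_state_raises(self):
        log = self.make_log([9.5])
        log.records[0].best_result = None
        with pytest.raises(ValueError, match="generation 0"):
            collect_adaptive_structures([log])


class TestAutoencoder:
    def test_memorizes_single_repeated_image(self, rng):
        snap = rasterize([PlacedObject("box", (500.0, 100.0))],
                         WorldConfig())
        data = [snap] * 10
        model, history = train_autoencoder(
            data, TrainConfig(hidden=(32, 8), epochs=150, batch_size=1),
            rng)
        fresh = Autoencoder(snap.image.size, hidden=(32, 8),
                            rng=np.random.default_rng(0))
        x = snap.image.ravel()[None, :]
        assert model.loss(x) < fresh.loss(x)
        assert history[-1] < 0.3 * history[0]

    def test_seeded_training_reproducible(self):
        snap = rasterize([PlacedObject("board", (480.0, 90.0), 0.3)],
                         WorldConfig())
        losses = []
        for _ in range(2):
            _, h = train_autoencoder([snap] * 6,
                                     TrainConfig(hidden=(16, 4), epochs=15),
                                     np.random.default_rng(99))
            losses.append(h[-1])
        assert losses[0] == losses[1]

    def test_encode_dimension_and_determinism(self, rng):
        snap = rasterize([PlacedObject("box", (500.0, 100.0))],
                         WorldConfig())
        model, _ = train_autoencoder([snap] * 4,
                                     TrainConfig(hidden=(16, 4), epochs=5),
                                     rng)
        p1 = encode(model, snap)
        p2 = encode(model, snap)
        assert (p1.x, p1.y) == (p2.x, p2.y)
        assert isinstance(p1.x, float) and isinstance(p1.y, float)

    def test_batch_encode_matches_single(self, rng):
        snaps = [rasterize([PlacedObject("box", (400.0 + 30 * k, 100.0))],
                           WorldConfig()) for k in range(4)]
        model, _ = train_autoencoder(snaps,
                                     TrainConfig(hidden=(16, 4), epochs=5),
                                     rng)
        batch = encode_all(model, snaps)
        singles = [encode(model, s) for s in snaps]
        for b, s in zip(batch, singles):
            assert (b.x, b.y) == pytest.approx((s.x, s.y))

    def test_empty_dataset_rejected(self, rng):
        with pytest.raises(ValueError):
            train_autoencoder([], TrainConfig(), rng)

    def test_non_two_bottleneck_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(code_dim=3)


class TestRegions:
    def test_point_in_polygon_labeling(self):
        regions = [RegionSpec("shell", ((0, 0), (2, 0), (2, 2), (0, 2))),
                   RegionSpec("wall", ((3, 0), (5, 0), (5, 2), (3, 2)))]
        pts = [FeaturePoint(1.0, 1.0), FeaturePoint(4.0, 1.0),
               FeaturePoint(10.0, 10.0)]
        labels, counts, _ = classify_by_regions(pts, regions)
        assert labels == ["shell", "wall", "unclassified"]
        assert counts.sum() == 3

    def test_overlap_resolved_by_declaration_order(self):
        regions = [RegionSpec("first", ((0, 0), (4, 0), (4, 4), (0, 4))),
                   RegionSpec("second", ((2, 2), (6, 2), (6, 6), (2, 6)))]
        labels, _, _ = classify_by_regions([FeaturePoint(3.0, 3.0)],
                                           regions)
        assert labels == ["first"]

    def test_counts_by_condition(self):
        regions = [RegionSpec("shell", ((0, 0), (2, 0), (2, 2), (0, 2)))]
        pts = [FeaturePoint(1.0, 1.0, {"B": 10}),
               FeaturePoint(1.5, 1.0, {"B": 40}),
               FeaturePoint(9.0, 9.0, {"B": 40})]
        labels, counts, by_b = classify_by_regions(pts, regions)
        assert counts["shell"] == 2 and counts["unclassified"] == 1
        assert by_b.loc["shell", 10] == 1
        assert by_b.loc["shell", 40] == 1

    def test_invalid_polygon_rejected(self):
        with pytest.raises(ValueError):
            RegionSpec("bowtie", ((0, 0), (2, 2), (2, 0), (0, 2)))
        with pytest.raises(ValueError):
            RegionSpec("line", ((0, 0), (1, 1)))
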
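"""The five HI index operators and their composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString, box

import orchidsdm as o
from orchidsdm.human_influence import ACCESS_BIN_EDGES, DEFAULT_ACCESS_TABLE
from orchidsdm.synth import LANDUSE_CODES


def grid(n=3, cell=1000.0):
    return o.GridSpec(0.0, n * cell, n, n, cell, "synthetic-equal-area")


def const_raster(g, value, dtype=float, categorical=False):
    return o.Raster(g, np.full(g.shape, value, dtype=dtype), categorical=categorical)


class TestPopulation:
    @pytest.mark.parametrize(
        "density,expected",
        [(1500.0, 10.0), (0.0, 0.0), (1000.0, 10.0)],
    )
    def test_published_rule_values(self, density, expected):
        layer = o.score_population(const_raster(grid(), density))
        assert layer.raster.values[0, 0] == pytest.approx(expected, abs=0.01)

    def test_log_curve_below_the_cap(self):
        # 3.333 * log10(101) ~ 6.68
        layer = o.score_population(const_raster(grid(), 100.0))
        assert layer.raster.values[0, 0] == pytest.approx(3.333 * np.log10(101), abs=1e-9)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            o.score_population(const_raster(grid(), -5.0))


class TestGrazing:
    def records(self, xs, area=100.0):
        # sheep-only records with chosen densities
        return [
            o.GrazingRecord(i + 1, 0, int(x * area), area) for i, x in enumerate(xs)
        ]

    def one_county(self, g):
        minx, miny, maxx, maxy = g.bbox()
        return o.CountyTable([1], ["c"], [box(minx, miny, maxx, maxy)], g.crs_id)

    def test_county_at_max_density_scores_ten(self):
        g = grid()
        layer = o.score_grazing(self.records([50.0])[:1], self.one_county(g), g)
        assert layer.raster.values[0, 0] == pytest.approx(10.0)

    def test_sqrt_of_max_scores_five(self):
        g = grid(4)
        half = box(0, 0, 2000, 4000)
        other = box(2000, 0, 4000, 4000)
        counties = o.CountyTable([1, 2], ["a", "b"], [half, other], g.crs_id)
        x_max = 49.0
        recs = [
            o.GrazingRecord(1, 0, int(np.sqrt(x_max) * 100), 100.0),
            o.GrazingRecord(2, 0, int(x_max * 100), 100.0),
        ]
        layer = o.score_grazing(recs, counties, g)
        assert layer.raster.values[0, 0] == pytest.approx(5.0, abs=1e-6)
        assert layer.raster.values[0, 3] == pytest.approx(10.0)

    def test_one_cattle_is_five_sheep_equivalents(self):
        rec = o.GrazingRecord(1, 10, 0, 1.0)
        assert rec.sheep_equivalents == 50.0

    def test_all_zero_densities_rejected(self):
        g = grid()
        with pytest.raises(ValueError, match="zero"):
            o.score_grazing(
                [o.GrazingRecord(1, 0, 0, 10.0)], self.one_county(g), g
            )

    def test_degenerate_xmax_below_one_rejected(self):
        g = grid()
        with pytest.raises(ValueError, match="rescale"):
            o.score_grazing(
                [o.GrazingRecord(1, 0, 5, 10.0)], self.one_county(g), g
            )


def road_at_distance(g, row, col, dx):
    """A vertical road dx metres east of the (row, col) cell center."""
    x, y = g.cell_center(row, col)
    return o.FeatureSet(
        [LineString([(x + dx, y - 50_000), (x + dx, y + 50_000)])],
        [{"road_class": None}],
    )


class TestAccess:
    @pytest.mark.parametrize(
        "road_class,distance,expected",
        [
            ("national", 50.0, 10.0),    # published first-bin score
            ("railway", 2000.0, 2.0),    # published 1000-3000 m score
            ("village", 700.0, 1.0),     # published 500-1000 m score
            ("provincial", 90.0, 6.0),   # boundary falls in the farther bin
            ("county", 5000.0, 0.0),     # beyond 3 km scores zero
        ],
    )
    def test_published_table_rows(self, road_class, distance, expected):
        g = grid(3)
        roads = road_at_distance(g, 1, 1, distance)
        roads.attributes[0]["road_class"] = road_class
        layer = o.score_access(g, roads)
        assert layer.raster.values[1, 1] == expected

    def test_unknown_road_class_is_an_error(self):
        g = grid()
        roads = road_at_distance(g, 1, 1, 50.0)
        roads.attributes[0]["road_class"] = "cart-track"
        with pytest.raises(KeyError, match="cart-track"):
            o.score_access(g, roads)

    def test_overlapping_classes_combine_by_maximum(self):
        g = grid(3)
        x, y = g.cell_center(1, 1)
        roads = o.FeatureSet(
            [
                LineString([(x + 50, y - 9000), (x + 50, y + 9000)]),
                LineString([(x + 60, y - 9000), (x + 60, y + 9000)]),
            ],
            [{"road_class": "village"}, {"road_class": "national"}],
        )
        layer = o.score_access(g, roads)
        assert layer.raster.values[1, 1] == 10.0

    @pytest.mark.parametrize("road_class", DEFAULT_ACCESS_TABLE)
    def test_score_non_increasing_in_distance(self, road_class):
        g = grid(3)
        scores = []
        for d in [10, 89, 91, 499, 501, 999, 1001, 2999, 3001, 9000]:
            roads = road_at_distance(g, 1, 1, d)
            roads.attributes[0]["road_class"] = road_class
            scores.append(o.score_access(g, roads).raster.values[1, 1])
        assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestNightlight:
    def test_ten_distinct_values_score_one_through_ten(self):
        g = o.GridSpec(0, 1000, 1, 10, 1000.0, "x")
        vals = np.array([[3.0, 9.0, 1.0, 7.0, 5.0, 2.0, 8.0, 4.0, 6.0, 10.0]])
        layer = o.score_nightlight(o.Raster(g, vals))
        order = np.argsort(vals[0])
        assert np.array_equal(layer.raster.values[0, order], np.arange(1, 11))

    def test_constant_raster_scores_all_one(self):
        layer = o.score_nightlight(const_raster(grid(5), 4.2))
        assert (layer.raster.values == 1.0).all()

    def test_extremes_score_one_and_ten(self):
        g = grid(5)
        rng = np.random.default_rng(2)
        vals = rng.permutation(np.arange(25, dtype=float)).reshape(5, 5)
        layer = o.score_nightlight(o.Raster(g, vals))
        assert layer.raster.values[vals == vals.min()][0] == 1.0
        assert layer.raster.values[vals == vals.max()][0] == 10.0

    def test_matches_brute_force_decile_assignment(self):
        rng = np.random.default_rng(8)
        n = 30
        g = o.GridSpec(0, n * 1000, n, n, 1000.0, "x")
        vals = np.round(rng.exponential(5.0, (n, n)), 1)  # many ties
        layer = o.score_nightlight(o.Raster(g, vals))
        flat = vals.ravel()
        scores = layer.raster.values.ravel()
        # brute force: lower-bin rule via count of strictly smaller values
        for v in np.unique(flat)[:50]:
            smaller = (flat < v).sum()
            expected = min(10, int(np.ceil((smaller + 1) / flat.size * 10)))
            assert (scores[flat == v] == expected).all()

    def test_fewer_cells_than_bins_rejected(self):
        g = o.GridSpec(0, 1000, 1, 5, 1000.0, "x")
        with pytest.raises(ValueError, match="bins"):
            o.score_nightlight(o.Raster(g, np.ones((1, 5))))


class TestLanduse:
    @pytest.mark.parametrize(
        "cls,expected",
        [
            ("construction", 10.0),
            ("arable", 7.0),
            ("forest", 3.0),
            ("irrigation", 3.0),
            ("grassland", 1.0),
            ("snow_ice", 0.0),
        ],
    )
    def test_published_point_values(self, cls, expected):
        r = const_raster(grid(), LANDUSE_CODES[cls], dtype=np.uint8, categorical=True)
        layer = o.score_landuse(r)
        assert (layer.raster.values == expected).all()

    def test_unmapped_class_code_is_an_error(self):
        r = const_raster(grid(), 231, dtype=np.uint8, categorical=True)
        with pytest.raises(KeyError, match="231"):
            o.score_landuse(r)


class TestComposeHI:
    def make_layers(self, g, values):
        names = ["population", "grazing", "access", "nightlight", "landuse"]
        mins = {"nightlight": 1.0}
        return [
            o.ScoreLayer(const_raster(g, v), n, score_min=mins.get(n, 0.0))
            for n, v in zip(names, values)
        ]

    def test_sum_of_minima_is_one(self):
        hi = o.compose_hi(self.make_layers(grid(), [0, 0, 0, 1, 0]))
        assert (hi.values == 1.0).all()

    def test_sum_of_maxima_is_fifty(self):
        hi = o.compose_hi(self.make_layers(grid(), [10, 10, 10, 10, 10]))
        assert (hi.values == 50.0).all()

    def test_arithmetic_sum(self):
        hi = o.compose_hi(self.make_layers(grid(), [10, 5, 2, 3, 7]))
        assert (hi.values == 27.0).all()

    def test_permutation_invariant(self):
        layers = self.make_layers(grid(), [1, 2, 3, 4, 5])
        a = o.compose_hi(layers)
        b = o.compose_hi(layers[::-1])
        assert np.array_equal(a.values, b.values)

    def test_missing_index_rejected(self):
        layers = self.make_layers(grid(), [1, 2, 3, 4, 5])[:4]
        with pytest.raises(ValueError, match="five"):
            o.compose_hi(layers)

    def test_mask_is_intersection_of_inputs(self):
        g = grid()
        layers = self.make_layers(g, [1, 2, 3, 4, 5])
        m = np.ones(g.shape, dtype=bool)
        m[0, 0] = False
        layers[2] = o.ScoreLayer(o.Raster(g, np.full(g.shape, 3.0), m), "access")
        hi = o.compose_hi(layers)
        assert not hi.mask[0, 0] and hi.mask[1, 1]


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_index_layers_respect_bounds_on_random_inputs(seed):
    """Every index stays inside its published score range."""
    rng = np.random.default_rng(seed)
    g = o.GridSpec(0, 5000, 5, 5, 1000.0, "x")
    pop = o.score_population(o.Raster(g, rng.exponential(300, g.shape)))
    assert pop.raster.values.min() >= 0 and pop.raster.values.max() <= 10
    nl = o.score_nightlight(o.Raster(g, rng.exponential(3, g.shape)))
    v = nl.raster.masked_values()
    assert v.min() >= 1 and v.max() <= 10
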
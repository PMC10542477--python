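"""Synthetic study system: predictors, anthropogenic layers, counties, roads,
livestock and life-form-specific occurrences.

The generator emulates the statistical structure the analysis assumes for a
mountainous study region on a shared 1-km grid:

* continuous environmental surfaces are smoothed Gaussian random fields with
  a configurable correlation length;
* terrain (slope, aspect) is derived from the elevation surface by finite
  differences;
* bioclimatic temperature layers cool with elevation (partial lapse-rate
  coupling), precipitation layers are independent moisture fields;
* vegetation and land-use/cover are categorical layers cut from continuous
  fields, with construction land concentrated where population is densest;
* population density and night-light radiance are positively correlated with
  each other and with construction land;
* counties are a Voronoi partition of the grid around seeded centers;
* road networks are random polylines per road class crossing the domain.

Occurrences for each orchid life form are drawn by Bernoulli sampling from a
logistic suitability surface over z-scored predictors, so the generating
niche coefficients are scale-free and recoverable by the models.  The default
presets encode the qualitative niche structure of the three life forms:
terrestrial orchids have a broad climate/soil niche and dominate numerically,
epiphytic orchids track precipitation (bio13/bio15 roles) and warmth, and
mycoheterotrophic orchids track forest vegetation and (negatively) the
hottest-quarter temperature (bio10 role).  Sample sizes are strongly
unbalanced (terrestrial >> mycoheterotrophic > epiphytic).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import LineString, MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .geodata import CountyTable, FeatureSet, GridSpec, Raster

# Land-use/cover class codes (GlobeLand30-style registry).
LANDUSE_CODES = {
    "arable": 10,
    "forest": 20,
    "grassland": 30,
    "irrigation": 40,
    "construction": 80,
    "bare": 90,
    "snow_ice": 100,
}

# Vegetation class codes.
VEGETATION_CODES = {
    "forest": 1,
    "shrub": 2,
    "grassland": 3,
    "meadow": 4,
    "bare": 5,
}

ROAD_CLASSES = ("railway", "national", "provincial", "county", "village")

#: The 14 predictors assembled for modelling: 5 bioclim roles, vegetation,
#: three terrain attributes, four soil attributes and the composite HI.
MODEL_PREDICTORS = (
    "bio1", "bio6", "bio10", "bio13", "bio15",
    "vegetation", "elevation", "slope", "aspect",
    "soil_ph", "soil_clay", "soil_sand", "soil_carbon",
    "hi",
)


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31 (CRC32 of label + master)."""
    return zlib.crc32(f"{label}:{master_seed}".encode()) & 0x7FFFFFFF


@dataclass
class LandscapeParams:
    """Knobs of the synthetic study system."""

    seed: int = 0
    grid: GridSpec = None  # type: ignore[assignment]
    spatial_corr_length: int = 15
    n_counties: int = 25
    n_roads_per_class: Mapping[str, int] = field(
        default_factory=lambda: {
            "railway": 1,
            "national": 1,
            "provincial": 2,
            "county": 3,
            "village": 5,
        }
    )

    def __post_init__(self) -> None:
        if self.grid is None:
            self.grid = GridSpec(
                origin_x=0.0, origin_y=200_000.0, n_rows=200, n_cols=200,
                cell_size=1000.0, crs_id="synthetic-equal-area",
            )
        if self.spatial_corr_length < 1:
            raise ValueError("spatial_corr_length must be >= 1")
        if self.n_counties > self.grid.n_cells:
            raise ValueError("more counties than grid cells")


@dataclass
class NicheParams:
    """Logistic niche of one life form over z-scored predictors.

    ``coefficients`` maps a continuous layer name (e.g. ``"bio13"``) or a
    categorical indicator ``"layer:class"`` (e.g. ``"vegetation:forest"``)
    to its weight on the logit scale.
    """

    lifeform: str
    coefficients: Mapping[str, float]
    intercept: float
    n_points: int
    sampling_noise: float = 0.3

    def __post_init__(self) -> None:
        if self.lifeform not in ("terrestrial", "epiphytic", "mycoheterotrophic"):
            raise ValueError(f"unknown lifeform {self.lifeform!r}")
        if not any(c != 0 for c in self.coefficients.values()):
            raise ValueError("at least one coefficient must be nonzero")
        if self.n_points < 20:
            raise ValueError("n_points must be >= 20")
        if self.sampling_noise < 0:
            raise ValueError("sampling_noise must be >= 0")


def default_niches() -> dict[str, NicheParams]:
    """The three life-form presets with strongly unequal sample sizes."""
    return {
        "terrestrial": NicheParams(
            "terrestrial",
            {"bio1": 3.0, "elevation": -2.5, "soil_ph": 1.8},
            intercept=-6.5,
            n_points=2000,
        ),
        "mycoheterotrophic": NicheParams(
            "mycoheterotrophic",
            {"vegetation:forest": 4.0, "bio10": -4.0},
            intercept=-9.0,
            n_points=446,
        ),
        "epiphytic": NicheParams(
            "epiphytic",
            {"bio13": 6.0, "bio15": 3.0, "bio10": 4.0},
            intercept=-14.0,
            n_points=193,
        ),
    }


@dataclass
class PredictorStack:
    """Named co-registered layers; the modelling stack is a subset of these."""

    layers: dict[str, Raster]

    def __post_init__(self) -> None:
        specs = {
            (r.grid.origin_x, r.grid.origin_y, r.grid.n_rows, r.grid.n_cols,
             r.grid.cell_size, r.grid.crs_id)
            for r in self.layers.values()
        }
        if len(specs) > 1:
            raise ValueError("all stack layers must share one GridSpec")

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> GridSpec:
        return next(iter(self.layers.values())).grid

    def joint_mask(self) -> np.ndarray:
        m = np.ones(self.grid.shape, dtype=bool)
        for r in self.layers.values():
            m &= r.mask
        return m

    def subset(self, names) -> "PredictorStack":
        return PredictorStack({n: self.layers[n] for n in names})

    def drop(self, name: str) -> "PredictorStack":
        return PredictorStack({n: r for n, r in self.layers.items() if n != name})


@dataclass
class Landscape:
    """Everything :func:`generate_landscape` produces."""

    params: LandscapeParams
    predictors: dict[str, Raster]        # environmental layers (no HI yet)
    population: Raster                   # people / km²
    nightlight: Raster                   # radiance, >= 0
    landuse: Raster                      # categorical codes
    roads: FeatureSet
    counties: CountyTable
    livestock: pd.DataFrame              # county_id, cattle, sheep

    @property
    def grid(self) -> GridSpec:
        return self.params.grid


def _random_field(rng: np.random.Generator, grid: GridSpec, corr: int) -> np.ndarray:
    """Zero-mean unit-variance smoothed Gaussian field."""
    noise = rng.standard_normal(grid.shape)
    smoothed = ndimage.uniform_filter(noise, size=corr, mode="reflect")
    smoothed = ndimage.uniform_filter(smoothed, size=corr, mode="reflect")
    sd = smoothed.std()
    if sd == 0:
        return smoothed
    return (smoothed - smoothed.mean()) / sd


def _random_road(rng: np.random.Generator, grid: GridSpec) -> LineString:
    """A polyline crossing the domain between two random boundary points."""
    minx, miny, maxx, maxy = grid.bbox()

    def edge_point() -> tuple[float, float]:
        side = rng.integers(4)
        t = rng.uniform()
        if side == 0:
            return (minx + t * (maxx - minx), maxy)
        if side == 1:
            return (minx + t * (maxx - minx), miny)
        if side == 2:
            return (minx, miny + t * (maxy - miny))
        return (maxx, miny + t * (maxy - miny))

    a = edge_point()
    b = edge_point()
    while abs(a[0] - b[0]) + abs(a[1] - b[1]) < 0.25 * (maxx - minx):
        b = edge_point()
    mid = (
        rng.uniform(minx + 0.2 * (maxx - minx), maxx - 0.2 * (maxx - minx)),
        rng.uniform(miny + 0.2 * (maxy - miny), maxy - 0.2 * (maxy - miny)),
    )
    return LineString([a, mid, b])


def generate_landscape(params: LandscapeParams) -> Landscape:
    """Generate the full synthetic study system (deterministic under seed)."""
    grid = params.grid
    corr = params.spatial_corr_length
    rng = np.random.default_rng(derive_seed(params.seed, "landscape"))

    # --- terrain ---------------------------------------------------------
    elev_field = _random_field(rng, grid, corr)
    elevation = 3000.0 + 1200.0 * elev_field
    dzdy, dzdx = np.gradient(elevation, grid.cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = np.degrees(np.arctan2(-dzdx, dzdy)) % 360.0

    # --- bioclim roles ---------------------------------------------------
    def lapse_layer(base: float, spread: float) -> np.ndarray:
        own = _random_field(rng, grid, corr)
        mix = -0.5 * elev_field + np.sqrt(1 - 0.5**2) * own
        return base + spread * mix

    bio1 = lapse_layer(8.0, 5.0)      # annual mean temperature (°C)
    bio6 = lapse_layer(-8.0, 6.0)     # coldest-month minimum temperature
    bio10 = lapse_layer(16.0, 5.0)    # hottest-quarter mean temperature
    bio13 = 120.0 + 60.0 * _random_field(rng, grid, corr)   # wettest-month precip (mm)
    bio15 = 70.0 + 25.0 * _random_field(rng, grid, corr)    # precip seasonality

    # --- soil ------------------------------------------------------------
    soil_ph = 6.5 + 0.8 * _random_field(rng, grid, corr)
    soil_clay = 25.0 + 8.0 * _random_field(rng, grid, corr)
    soil_sand = 40.0 + 10.0 * _random_field(rng, grid, corr)
    soil_carbon = 2.0 + 0.8 * _random_field(rng, grid, corr)

    # --- vegetation (categorical, moisture/elevation driven) -------------
    veg_field = 0.6 * _random_field(rng, grid, corr) - 0.4 * elev_field
    q = np.quantile(veg_field, [0.35, 0.55, 0.75, 0.9])
    vegetation = np.full(grid.shape, VEGETATION_CODES["bare"], dtype=np.uint8)
    vegetation[veg_field <= q[3]] = VEGETATION_CODES["meadow"]
    vegetation[veg_field <= q[2]] = VEGETATION_CODES["grassland"]
    vegetation[veg_field <= q[1]] = VEGETATION_CODES["shrub"]
    # cut order: lowest 35% forest, then shrub, grassland, meadow, bare
    vegetation[veg_field <= q[0]] = VEGETATION_CODES["forest"]

    # --- population, night light, land use -------------------------------
    settle = _random_field(rng, grid, corr) - 0.6 * elev_field
    settle = (settle - settle.mean()) / settle.std()
    population = np.exp(2.0 + 1.6 * settle + 0.3 * rng.standard_normal(grid.shape))
    nightlight = np.maximum(
        0.0, 0.05 * population + 2.0 * rng.standard_normal(grid.shape) ** 2
    )

    landuse = np.full(grid.shape, LANDUSE_CODES["bare"], dtype=np.uint8)
    landuse[vegetation == VEGETATION_CODES["forest"]] = LANDUSE_CODES["forest"]
    landuse[vegetation == VEGETATION_CODES["shrub"]] = LANDUSE_CODES["forest"]
    landuse[vegetation == VEGETATION_CODES["grassland"]] = LANDUSE_CODES["grassland"]
    landuse[vegetation == VEGETATION_CODES["meadow"]] = LANDUSE_CODES["grassland"]
    landuse[elevation > np.quantile(elevation, 0.98)] = LANDUSE_CODES["snow_ice"]
    arable_cut = np.quantile(settle, 0.90)
    landuse[settle > arable_cut] = LANDUSE_CODES["arable"]
    constr_cut = np.quantile(settle, 0.98)
    landuse[settle > constr_cut] = LANDUSE_CODES["construction"]
    irr = (settle > np.quantile(settle, 0.85)) & (landuse == LANDUSE_CODES["grassland"])
    landuse[irr] = LANDUSE_CODES["irrigation"]

    # --- roads ------------------------------------------------------------
    road_geoms: list = []
    road_attrs: list[dict] = []
    for cls in ROAD_CLASSES:
        for _ in range(int(params.n_roads_per_class.get(cls, 0))):
            road_geoms.append(_random_road(rng, grid))
            road_attrs.append({"road_class": cls})
    roads = FeatureSet(road_geoms, road_attrs, crs_id=grid.crs_id)

    # --- counties (Voronoi partition, clipped to the grid) ----------------
    minx, miny, maxx, maxy = grid.bbox()
    seeds = [
        Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        for _ in range(params.n_counties)
    ]
    # deterministic id order: sort seeds by (x, y)
    seeds.sort(key=lambda p: (p.x, p.y))
    envelope = box(minx, miny, maxx, maxy)
    cells = voronoi_diagram(MultiPoint(seeds), envelope=envelope)
    polys = []
    for seed_pt in seeds:
        for poly in cells.geoms:
            if poly.covers(seed_pt):
                polys.append(poly.intersection(envelope))
                break
    counties = CountyTable(
        county_ids=list(range(1, len(polys) + 1)),
        names=[f"County-{i:02d}" for i in range(1, len(polys) + 1)],
        geometries=polys,
        crs_id=grid.crs_id,
    )

    livestock = generate_livestock(counties, derive_seed(params.seed, "livestock"))

    predictors = {
        "bio1": Raster(grid, bio1),
        "bio6": Raster(grid, bio6),
        "bio10": Raster(grid, bio10),
        "bio13": Raster(grid, bio13),
        "bio15": Raster(grid, bio15),
        "vegetation": Raster(grid, vegetation, categorical=True),
        "elevation": Raster(grid, elevation),
        "slope": Raster(grid, slope),
        "aspect": Raster(grid, aspect),
        "soil_ph": Raster(grid, soil_ph),
        "soil_clay": Raster(grid, soil_clay),
        "soil_sand": Raster(grid, soil_sand),
        "soil_carbon": Raster(grid, soil_carbon),
    }
    return Landscape(
        params=params,
        predictors=predictors,
        population=Raster(grid, population),
        nightlight=Raster(grid, nightlight),
        landuse=Raster(grid, landuse, categorical=True),
        roads=roads,
        counties=counties,
        livestock=livestock,
    )


def generate_livestock(counties: CountyTable, seed: int) -> pd.DataFrame:
    """County livestock table (cattle, sheep); log-normal across counties."""
    if len(counties) == 0:
        raise ValueError("counties must be non-empty")
    rng = np.random.default_rng(seed)
    cattle = np.floor(np.exp(rng.normal(8.0, 1.0, len(counties)))).astype(int)
    sheep = np.floor(np.exp(rng.normal(10.0, 1.0, len(counties)))).astype(int)
    return pd.DataFrame(
        {"county_id": counties.county_ids, "cattle": cattle, "sheep": sheep}
    )


def assemble_stack(landscape: Landscape, hi: Raster | None) -> PredictorStack:
    """The modelling stack: 13 environmental predictors plus HI (14 total).

    With ``hi=None`` the stack holds 13 predictors (the no-HI condition).
    """
    layers = dict(landscape.predictors)
    if hi is not None:
        layers["hi"] = hi
    return PredictorStack(layers)


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

def standardized_layer(stack: PredictorStack, key: str) -> np.ndarray:
    """Resolve a niche coefficient key to a z-scored (or indicator) surface.

    ``"layer"`` z-scores a continuous layer over valid cells;
    ``"layer:class"`` yields a centred 0/1 indicator of that category.
    """
    if ":" in key:
        name, cls = key.split(":", 1)
        raster = stack[name]
        if not raster.categorical:
            raise ValueError(f"{name!r} is not categorical; key {key!r} invalid")
        code = VEGETATION_CODES.get(cls) if name == "vegetation" else None
        if code is None:
            code = LANDUSE_CODES.get(cls)
        if code is None:
            raise ValueError(f"unknown category {cls!r} for layer {name!r}")
        ind = (raster.values == code).astype(float)
        valid = raster.mask
        mu = ind[valid].mean()
        sd = ind[valid].std()
        if sd == 0:
            return np.zeros_like(ind)
        return (ind - mu) / sd
    raster = stack[key]
    if raster.categorical:
        raise ValueError(f"categorical layer {key!r} needs a 'layer:class' key")
    vals = raster.values.astype(float)
    valid = raster.mask
    mu = vals[valid].mean()
    sd = vals[valid].std()
    return (vals - mu) / (sd if sd > 0 else 1.0)


def suitability_surface(stack: PredictorStack, niche: NicheParams) -> np.ndarray:
    """The logistic suitability (no sampling noise) implied by a niche."""
    logit = np.full(stack.grid.shape, niche.intercept, dtype=float)
    for key, coeff in niche.coefficients.items():
        logit += coeff * standardized_layer(stack, key)
    return 1.0 / (1.0 + np.exp(-logit))


def generate_occurrences(
    stack: PredictorStack,
    niche: NicheParams,
    seed: int,
    max_draw_factor: int = 2000,
) -> pd.DataFrame:
    """Sample presence points (cell centers) from the niche's logistic surface.

    Independent draws: a valid cell is proposed uniformly and accepted with
    its suitability probability (plus per-draw logit noise), until
    ``niche.n_points`` acceptances.  Duplicate cells may occur, as in real
    occurrence data; spatial thinning removes them downstream.

    Returns a DataFrame with columns ``lon, lat, taxon, lifeform``.
    """
    rng = np.random.default_rng(seed)
    grid = stack.grid
    valid = np.flatnonzero(stack.joint_mask().ravel())
    if valid.size == 0:
        raise ValueError("no valid cells in stack")
    p_clean = suitability_surface(stack, niche).ravel()
    p_clean = np.clip(p_clean, 1e-12, 1 - 1e-12)
    logit_clean = np.log(p_clean[valid] / (1 - p_clean[valid]))
    accepted: list[int] = []
    max_draws = max_draw_factor * niche.n_points
    drawn = 0
    batch = max(1024, niche.n_points * 4)
    while len(accepted) < niche.n_points and drawn < max_draws:
        idx = rng.integers(0, valid.size, size=batch)
        logit = logit_clean[idx]
        if niche.sampling_noise > 0:
            logit = logit + niche.sampling_noise * rng.standard_normal(batch)
        p = 1.0 / (1.0 + np.exp(-logit))
        accept = rng.random(batch) < p
        accepted.extend(valid[idx[accept]].tolist())
        drawn += batch
    if len(accepted) < niche.n_points:
        raise RuntimeError(
            f"suitability too low: only {len(accepted)}/{niche.n_points} "
            f"presences after {drawn} draws"
        )
    cells = np.array(accepted[: niche.n_points])
    rows, cols = np.divmod(cells, grid.n_cols)
    xs = grid.origin_x + (cols + 0.5) * grid.cell_size
    ys = grid.origin_y - (rows + 0.5) * grid.cell_size
    return pd.DataFrame(
        {
            "lon": xs,
            "lat": ys,
            "taxon": [f"{niche.lifeform[:1]}-sp" for _ in cells],
            "lifeform": niche.lifeform,
        }
    )


def generate_all_occurrences(
    stack: PredictorStack,
    niches: Mapping[str, NicheParams] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Occurrences for all three life forms, concatenated."""
    niches = niches or default_niches()
    frames = [
        generate_occurrences(stack, niche, derive_seed(seed, f"occ:{name}"))
        for name, niche in sorted(niches.items())
    ]
    return pd.concat(frames, ignore_index=True)
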
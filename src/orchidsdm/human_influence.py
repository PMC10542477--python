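"""The human-influence (HI) factor: five 0-10 scored indexes and their sum.

The HI factor quantifies anthropogenic pressure as the equal-weight sum of
five index layers, each scored on the shared grid:

* **population** — people/km² above 1000 score 10; below the cap the score is
  ``3.333 * log10(density + 1)`` (continuous with the cap rule), clipped to 10;
* **grazing** — county sheep-equivalent density x_i (one head of cattle
  counts as five sheep), scored ``log(x_i)/log(x_max) * 10`` and clamped
  to [0, 10]; the densest county scores exactly 10;
* **access** — road-network proximity scored per road class from a
  distance-bin table (0-90 / 90-500 / 500-1000 / 1000-3000 m, 0 beyond 3 km),
  combined across classes by the maximum (worst-case accessibility);
* **nightlight** — radiance ranked into deciles 1-10 (quantile grading,
  ties to the lower bin);
* **landuse** — class lookup: construction 10, arable 7, forest and
  irrigated land 3, grassland 1, everything else (e.g. permanent snow/ice) 0.

The composite HI is the raw unweighted sum, theoretical range [1, 50]
(night light contributes at least 1); no rescaling is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .geodata import CountyTable, FeatureSet, GridSpec, Raster, county_membership, distance_to_features
from .synth import LANDUSE_CODES

logger = logging.getLogger("orchidsdm")

#: Distance-bin edges (m): [0,90), [90,500), [500,1000), [1000,3000), >=3000 -> 0.
ACCESS_BIN_EDGES = (0.0, 90.0, 500.0, 1000.0, 3000.0)

#: Published access-score table: road class -> scores for the four bins.
DEFAULT_ACCESS_TABLE: dict[str, tuple[int, int, int, int]] = {
    "railway": (8, 6, 4, 2),
    "national": (10, 8, 6, 4),
    "provincial": (8, 6, 4, 2),
    "county": (6, 4, 2, 0),
    "village": (4, 2, 1, 0),
}

#: Land-use class code -> score.
DEFAULT_LANDUSE_POINTS: dict[int, int] = {
    LANDUSE_CODES["construction"]: 10,
    LANDUSE_CODES["arable"]: 7,
    LANDUSE_CODES["forest"]: 3,
    LANDUSE_CODES["irrigation"]: 3,
    LANDUSE_CODES["grassland"]: 1,
    LANDUSE_CODES["bare"]: 0,
    LANDUSE_CODES["snow_ice"]: 0,
}

HI_INDEX_NAMES = ("population", "grazing", "access", "nightlight", "landuse")


@dataclass(frozen=True)
class AccessTable:
    """Per-class road access scores for the four distance bins."""

    scores: Mapping[str, tuple[int, int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_ACCESS_TABLE)
    )

    def __post_init__(self) -> None:
        for cls, row in self.scores.items():
            if len(row) != 4:
                raise ValueError(f"class {cls!r} needs 4 bin scores")
            if any(not (0 <= s <= 10) for s in row):
                raise ValueError(f"class {cls!r} scores must lie in [0, 10]")
            if any(a < b for a, b in zip(row, row[1:])):
                raise ValueError(f"class {cls!r} scores must be non-increasing")

    def score_for(self, road_class: str, distance_m: float) -> float:
        if road_class not in self.scores:
            raise KeyError(f"unknown road_class {road_class!r}")
        row = self.scores[road_class]
        for i in range(4):
            if ACCESS_BIN_EDGES[i] <= distance_m < ACCESS_BIN_EDGES[i + 1]:
                return float(row[i])
        return 0.0


@dataclass
class GrazingRecord:
    """One county's livestock pressure; x_i is sheep-equivalents per km²."""

    county_id: int
    cattle: int
    sheep: int
    area_km2: float

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValueError("county area must be positive")
        if self.cattle < 0 or self.sheep < 0:
            raise ValueError("livestock counts must be non-negative")

    @property
    def sheep_equivalents(self) -> float:
        # one head of cattle consumes as much as five sheep
        return 5.0 * self.cattle + self.sheep

    @property
    def x_i(self) -> float:
        return self.sheep_equivalents / self.area_km2


@dataclass
class HIConfig:
    population_cap: float = 1000.0            # people/km²
    landuse_points: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_LANDUSE_POINTS)
    )
    nightlight_bins: int = 10

    def __post_init__(self) -> None:
        if self.population_cap <= 0:
            raise ValueError("population_cap must be > 0")
        if self.nightlight_bins < 2:
            raise ValueError("nightlight_bins must be >= 2")
        bad = set(self.landuse_points.values()) - {0, 1, 3, 7, 10}
        if bad:
            raise ValueError(f"land-use scores must be in {{0,1,3,7,10}}, got {bad}")


@dataclass
class ScoreLayer:
    """A bounded HI index layer."""

    raster: Raster
    index_name: str
    score_min: float = 0.0
    score_max: float = 10.0

    def __post_init__(self) -> None:
        if self.index_name not in HI_INDEX_NAMES:
            raise ValueError(f"unknown index {self.index_name!r}")
        v = self.raster.masked_values()
        if v.size and (v.min() < self.score_min - 1e-9 or v.max() > self.score_max + 1e-9):
            raise ValueError(
                f"{self.index_name} scores outside [{self.score_min}, {self.score_max}]"
            )


# ---------------------------------------------------------------------------
# The five index operators
# ---------------------------------------------------------------------------

def score_population(density: Raster, cfg: HIConfig | None = None) -> ScoreLayer:
    """0-10 population-pressure score; > cap people/km² scores 10."""
    cfg = cfg or HIConfig()
    vals = density.values.astype(float)
    if (vals[density.mask] < 0).any():
        raise ValueError("population density must be non-negative")
    score = np.minimum(10.0, 3.333 * np.log10(vals + 1.0))
    score[vals > cfg.population_cap] = 10.0
    score[~density.mask] = 0.0
    return ScoreLayer(Raster(density.grid, score, density.mask.copy()), "population")


def score_grazing(
    records: Sequence[GrazingRecord],
    counties: CountyTable,
    grid: GridSpec,
) -> ScoreLayer:
    """0-10 grazing-density score; county at the maximum density scores 10."""
    if not records:
        raise ValueError("need at least one grazing record")
    x = {r.county_id: r.x_i for r in records}
    x_max = max(x.values())
    if x_max == 0:
        raise ValueError("all sheep-equivalent densities are zero; score undefined")
    if x_max <= 1:
        raise ValueError(
            f"x_max = {x_max:.4g} <= 1: log ratio is ill-posed; rescale the "
            "density units so the maximum exceeds 1 sheep-equivalent/km²"
        )
    log_xmax = np.log(x_max)
    membership = county_membership(grid, counties)
    score = np.zeros(grid.shape, dtype=float)
    mask = membership >= 0
    for cid, xi in x.items():
        cells = membership == cid
        if not cells.any():
            continue
        if xi <= 0:
            score[cells] = 0.0
        else:
            score[cells] = np.clip(np.log(xi) / log_xmax * 10.0, 0.0, 10.0)
    return ScoreLayer(Raster(grid, score, mask), "grazing")


def score_access(
    grid: GridSpec,
    roads: FeatureSet,
    table: AccessTable | None = None,
) -> ScoreLayer:
    """0-10 road-access score: per-class distance bins, max across classes."""
    table = table or AccessTable()
    if len(roads) == 0:
        raise ValueError("empty road network: access score undefined")
    classes = sorted({a.get("road_class") for a in roads.attributes})
    for cls in classes:
        if cls not in table.scores:
            raise KeyError(f"unknown road_class {cls!r} (not in the access table)")
    score = np.zeros(grid.shape, dtype=float)
    for cls in classes:
        idx = [i for i, a in enumerate(roads.attributes) if a["road_class"] == cls]
        subset = FeatureSet(
            [roads.geometries[i] for i in idx],
            [roads.attributes[i] for i in idx],
            crs_id=roads.crs_id,
        )
        dist = distance_to_features(grid, subset).values
        row = table.scores[cls]
        cls_score = np.zeros(grid.shape)
        for i in range(4):
            in_bin = (dist >= ACCESS_BIN_EDGES[i]) & (dist < ACCESS_BIN_EDGES[i + 1])
            cls_score[in_bin] = row[i]
        score = np.maximum(score, cls_score)
    return ScoreLayer(Raster(grid, score), "access")


def score_nightlight(radiance: Raster, cfg: HIConfig | None = None) -> ScoreLayer:
    """1-10 night-light score by decile (quantile grading, ties to lower bin)."""
    cfg = cfg or HIConfig()
    vals = radiance.values
    if (vals[radiance.mask] < 0).any():
        raise ValueError("radiance must be non-negative")
    unmasked = radiance.mask
    n = int(unmasked.sum())
    bins = cfg.nightlight_bins
    if n < bins:
        raise ValueError(f"only {n} unmasked cells for {bins} quantile bins")
    # min-rank sends every member of a tied group to the group's lower bin
    ranks = rankdata(vals[unmasked], method="min")
    decile = np.clip(np.ceil(ranks / n * bins), 1, bins)
    score = np.zeros(radiance.grid.shape, dtype=float)
    score[unmasked] = decile
    return ScoreLayer(
        Raster(radiance.grid, score, unmasked.copy()), "nightlight", score_min=1.0
    )


def score_landuse(classes: Raster, cfg: HIConfig | None = None) -> ScoreLayer:
    """Land-use score lookup (construction 10 / arable 7 / forest 3 / ...)."""
    cfg = cfg or HIConfig()
    vals = classes.values
    present = np.unique(vals[classes.mask])
    unmapped = [int(c) for c in present if int(c) not in cfg.landuse_points]
    if unmapped:
        raise KeyError(f"unmapped land-use class code(s): {unmapped}")
    score = np.zeros(classes.grid.shape, dtype=float)
    for code, pts in cfg.landuse_points.items():
        score[vals == code] = float(pts)
    score[~classes.mask] = 0.0
    return ScoreLayer(Raster(classes.grid, score, classes.mask.copy()), "landuse")


def compose_hi(layers: Sequence[ScoreLayer]) -> Raster:
    """Equal-weight sum of the five index layers (range [1, 50])."""
    names = sorted(l.index_name for l in layers)
    if names != sorted(HI_INDEX_NAMES):
        raise ValueError(
            f"compose_hi needs exactly the five indexes {HI_INDEX_NAMES}, got {names}"
        )
    grid = layers[0].raster.grid
    for l in layers[1:]:
        if l.raster.grid != grid:
            raise ValueError("HI index layers must share one GridSpec")
    total = np.zeros(grid.shape, dtype=float)
    mask = np.ones(grid.shape, dtype=bool)
    for l in layers:
        total += l.raster.values
        mask &= l.raster.mask
    total[~mask] = grid.nodata
    return Raster(grid, total, mask)
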
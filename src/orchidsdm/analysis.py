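"""Suitability-map post-processing: binarize, fuse, difference, summarize.

Continuous 0-1 suitability is thresholded at 0.5 (strictly greater than ->
suitable).  The three life-form maps are fused into a "total" layer by
cell-wise OR and compared with the pooled all-data ("overall") map through
the symmetric-difference changed-area map.  Areas are cell counts times the
cell area; percentages are of the full study area (unmasked cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import CountyTable, Raster, zonal_area


@dataclass
class BinaryMap:
    raster: Raster
    provenance: tuple = ()

    def __post_init__(self) -> None:
        v = self.raster.masked_values()
        if v.size and not np.isin(v, (0, 1)).all():
            raise ValueError("binary map must contain only 0/1 on valid cells")

    @property
    def area_km2(self) -> float:
        return float(
            (self.raster.values[self.raster.mask] == 1).sum()
        ) * self.raster.grid.cell_area_km2


@dataclass
class ChangeMap:
    raster: Raster
    changed_area_km2: float
    changed_pct: float


def binarize(suitability: Raster, threshold: float = 0.5,
             provenance: tuple = ()) -> BinaryMap:
    """1 where suitability strictly exceeds the threshold, else 0."""
    v = suitability.masked_values()
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ValueError("suitability must lie in [0, 1]")
    out = np.zeros(suitability.grid.shape, dtype=np.uint8)
    out[(suitability.values > threshold) & suitability.mask] = 1
    return BinaryMap(
        Raster(suitability.grid, out, suitability.mask.copy()), provenance
    )


def _require_same_grid(*maps: BinaryMap) -> None:
    g0 = maps[0].raster.grid
    for m in maps[1:]:
        if m.raster.grid != g0:
            raise ValueError("binary maps must share one GridSpec")


def fuse_lifeform_layers(t: BinaryMap, e: BinaryMap, m: BinaryMap) -> BinaryMap:
    """Cell-wise OR of the three life-form maps (the 'total' layer)."""
    _require_same_grid(t, e, m)
    values = ((t.raster.values == 1) | (e.raster.values == 1)
              | (m.raster.values == 1)).astype(np.uint8)
    mask = t.raster.mask & e.raster.mask & m.raster.mask
    values = np.where(mask, values, 0).astype(np.uint8)
    return BinaryMap(Raster(t.raster.grid, values, mask), ("total",))


def changed_area(a: BinaryMap, b: BinaryMap, total_area_km2: float) -> ChangeMap:
    """Symmetric difference of two binary maps, with area and percent."""
    _require_same_grid(a, b)
    mask = a.raster.mask & b.raster.mask
    diff = ((a.raster.values != b.raster.values) & mask).astype(np.uint8)
    area = float(diff.sum()) * a.raster.grid.cell_area_km2
    pct = area / total_area_km2 * 100.0 if total_area_km2 > 0 else 0.0
    return ChangeMap(Raster(a.raster.grid, diff, mask), area, pct)


def study_area_km2(mask: np.ndarray, cell_area_km2: float) -> float:
    """Total study area: unmasked cells times cell area."""
    return float(np.asarray(mask, dtype=bool).sum()) * cell_area_km2


def suitable_area_summary(
    maps: list[BinaryMap],
    counties: CountyTable,
    total_area_km2: float | None = None,
) -> pd.DataFrame:
    """Per-map total suitable km², percent of study area and per-county km²."""
    if not maps:
        raise ValueError("no maps supplied")
    rows = []
    for bm in maps:
        if total_area_km2 is None:
            total = study_area_km2(bm.raster.mask, bm.raster.grid.cell_area_km2)
        else:
            total = total_area_km2
        per_county = zonal_area(bm.raster, counties)
        row = {
            "provenance": "-".join(str(p) for p in bm.provenance) or "map",
            "suitable_km2": bm.area_km2,
            "suitable_pct": bm.area_km2 / total * 100.0 if total else 0.0,
        }
        for cid, km2 in per_county.items():
            row[f"county_{cid}"] = km2
        rows.append(row)
    return pd.DataFrame(rows)
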
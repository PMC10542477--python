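"""Double-ranking selection of critical conservation counties.

Two screens are applied to each strategy's per-county suitable-area table:

* **sequential rank** — the counties in the top 30% of the descending area
  order (count = ceil(fraction x n_counties); ties broken by county_id);
* **area weight** — the smallest top-of-the-order prefix whose cumulative
  area reaches 50% of the strategy's total suitable area.

A county passes a strategy when it sits in both screens (their
intersection); the cross-strategy consensus is the set of counties that
pass every strategy, regardless of the modelling choices behind it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd


@dataclass(frozen=True)
class RankingConfig:
    sequential_fraction: float = 0.30
    area_fraction: float = 0.50

    def __post_init__(self) -> None:
        for f in (self.sequential_fraction, self.area_fraction):
            if not (0 < f <= 1):
                raise ValueError("ranking fractions must lie in (0, 1]")


@dataclass
class RankingResult:
    strategy: str
    sequential_set: set[int]
    area_weight_set: set[int]
    intersection: set[int]
    ranked_areas: pd.DataFrame      # county_id, area_km2, cum_share


def _ranked(county_areas: Mapping[int, float]) -> list[tuple[int, float]]:
    # descending by area, ties by ascending county_id
    return sorted(county_areas.items(), key=lambda kv: (-kv[1], kv[0]))


def rank_sequential(
    county_areas: Mapping[int, float], fraction: float = 0.30
) -> set[int]:
    """Counties in the top ``ceil(fraction * n)`` of the area order."""
    if not county_areas:
        raise ValueError("empty county-area table")
    if all(a <= 0 for a in county_areas.values()):
        warnings.warn("all county areas are zero; sequential set is empty")
        return set()
    k = math.ceil(fraction * len(county_areas))
    return {cid for cid, _ in _ranked(county_areas)[:k]}


def rank_area_weight(
    county_areas: Mapping[int, float], fraction: float = 0.50
) -> set[int]:
    """Smallest top-area prefix with cumulative area >= fraction of total."""
    total = sum(county_areas.values())
    if total <= 0:
        raise ValueError("total suitable area is zero; area-weight rank undefined")
    target = fraction * total
    out: set[int] = set()
    acc = 0.0
    for cid, area in _ranked(county_areas):
        out.add(cid)
        acc += area
        if acc >= target:
            break
    return out


def double_rank(
    strategy_areas: Mapping[str, Mapping[int, float]],
    cfg: RankingConfig | None = None,
) -> tuple[dict[str, RankingResult], set[int]]:
    """Both screens per strategy plus the cross-strategy consensus."""
    cfg = cfg or RankingConfig()
    if not strategy_areas:
        raise ValueError("no strategies supplied")
    results: dict[str, RankingResult] = {}
    consensus: set[int] | None = None
    for strategy in sorted(strategy_areas):
        areas = strategy_areas[strategy]
        seq = rank_sequential(areas, cfg.sequential_fraction)
        aw = rank_area_weight(areas, cfg.area_fraction)
        inter = seq & aw
        ranked = _ranked(areas)
        total = sum(areas.values()) or 1.0
        cum = 0.0
        rows = []
        for cid, area in ranked:
            cum += area
            rows.append(
                {"county_id": cid, "area_km2": area, "cum_share": cum / total}
            )
        results[strategy] = RankingResult(
            strategy, seq, aw, inter, pd.DataFrame(rows)
        )
        consensus = inter if consensus is None else (consensus & inter)
    return results, consensus if consensus is not None else set()
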
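"""End-to-end orchestration of the modelling run matrix.

The full experiment is: synthesize (or load) the landscape -> score the five
human-influence indexes and compose HI -> assemble the 14-predictor stack
(13 without HI) -> prepare the four occurrence datasets (thin, three
pseudo-absence sets) -> fit 4 datasets x 3 algorithms x 2 HI settings, each
over 3 pseudo-absence sets x 5 stratified 70/30 splits (15 runs per
strategy) -> evaluate AUC / best-threshold TSS and Kappa per run -> build
committee-mean suitability maps, binarize, fuse life forms, difference
against the pooled map -> county zonal areas and double-ranking.

One master seed fans out to per-stage seeds through a stated splitting rule
(CRC32 of the stage label with the master seed), so every stage is
independently reproducible and a rerun is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import analysis as ana
from . import human_influence as hi_mod
from . import prep
from .evaluation import MetricResult, auc, best_threshold_metric, kappa, tss
from .geodata import Raster
from .models import ModelSpec, extract_table, predict_suitability, train_model
from .regions import RankingConfig, double_rank
from .synth import (
    Landscape,
    LandscapeParams,
    NicheParams,
    PredictorStack,
    assemble_stack,
    default_niches,
    derive_seed,
    generate_landscape,
    generate_occurrences,
)

logger = logging.getLogger("orchidsdm")

_ALG_LETTER = {"glm": "G", "maxent": "M", "rf": "R"}
_LETTER_ALG = {v: k for k, v in _ALG_LETTER.items()}


@dataclass(frozen=True)
class StrategyLabel:
    """Strategy naming: algorithm letter + dataset, e.g. ``G-all`` or ``R-t``."""

    dataset: str
    algorithm: str
    hi_on: bool = True

    def render(self) -> str:
        base = f"{_ALG_LETTER[self.algorithm]}-{self.dataset}"
        return base if self.hi_on else base + "-noHI"

    @classmethod
    def parse(cls, label: str) -> "StrategyLabel":
        parts = label.split("-")
        hi_on = True
        if parts[-1] == "noHI":
            hi_on = False
            parts = parts[:-1]
        letter, dataset = parts[0], "-".join(parts[1:])
        return cls(dataset=dataset, algorithm=_LETTER_ALG[letter], hi_on=hi_on)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; serialized into the manifest."""

    seed: int = 1
    n_rows: int = 200
    n_cols: int = 200
    spatial_corr_length: int = 15
    n_counties: int = 25
    niches: Mapping[str, NicheParams] = field(default_factory=default_niches)
    n_pseudo: int = 2000
    n_pa_sets: int = 3
    n_repeats: int = 5
    train_fraction: float = 0.7
    algorithms: Sequence[str] = ("glm", "rf", "maxent")
    datasets: Sequence[str] = ("all", "t", "e", "m")
    hi_settings: Sequence[bool] = (True, False)
    collinearity_threshold: float = 0.7
    binarize_threshold: float = 0.5
    ranking: RankingConfig = field(default_factory=RankingConfig)
    rf_trees: int = 1000
    make_maps: bool = True
    output_dir: str | None = None

    def landscape_params(self) -> LandscapeParams:
        from .geodata import GridSpec

        grid = GridSpec(
            origin_x=0.0,
            origin_y=self.n_rows * 1000.0,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            cell_size=1000.0,
            crs_id="synthetic-equal-area",
        )
        return LandscapeParams(
            seed=derive_seed(self.seed, "landscape-params"),
            grid=grid,
            spatial_corr_length=self.spatial_corr_length,
            n_counties=self.n_counties,
        )

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def compute_hi(landscape: Landscape, cfg: hi_mod.HIConfig | None = None) -> Raster:
    """Score the five indexes on a landscape and compose the HI layer."""
    cfg = cfg or hi_mod.HIConfig()
    counties = landscape.counties
    areas = dict(zip(counties.county_ids, counties.area_km2))
    records = [
        hi_mod.GrazingRecord(
            int(r.county_id), int(r.cattle), int(r.sheep), areas[int(r.county_id)]
        )
        for r in landscape.livestock.itertuples()
    ]
    layers = [
        hi_mod.score_population(landscape.population, cfg),
        hi_mod.score_grazing(records, counties, landscape.grid),
        hi_mod.score_access(landscape.grid, landscape.roads),
        hi_mod.score_nightlight(landscape.nightlight, cfg),
        hi_mod.score_landuse(landscape.landuse, cfg),
    ]
    return hi_mod.compose_hi(layers)


def prepare_datasets(
    stack: PredictorStack,
    occurrences: pd.DataFrame,
    config: RunConfig,
) -> dict[str, prep.ModelDataset]:
    """Classify by life form, thin, and attach pseudo-absence sets."""
    grid = stack.grid
    valid = np.flatnonzero(stack.joint_mask().ravel())
    by_form = prep.classify_lifeform(occurrences)
    datasets = {}
    for name in config.datasets:
        datasets[name] = prep.build_dataset(
            name,
            by_form[name],
            grid,
            n_pseudo=config.n_pseudo,
            n_pa_sets=config.n_pa_sets,
            seed=derive_seed(config.seed, f"pa:{name}"),
            valid_cells=valid,
        )
    return datasets


def _model_spec(algorithm: str, config: RunConfig, seed: int) -> ModelSpec:
    return ModelSpec(
        algorithm=algorithm,
        n_trees=config.rf_trees,
        seed=seed,
    )


def run_matrix(
    stacks: Mapping[bool, PredictorStack],
    datasets: Mapping[str, prep.ModelDataset],
    config: RunConfig,
) -> tuple[pd.DataFrame, dict[str, Raster | None]]:
    """Fit and evaluate every strategy; optionally build committee-mean maps.

    Returns the per-run metrics table and, when ``config.make_maps``, the
    committee-mean suitability raster per strategy label (else None values).
    """
    rows: list[MetricResult] = []
    committee: dict[str, Raster | None] = {}
    for hi_on in config.hi_settings:
        stack = stacks[hi_on]
        for ds_name in config.datasets:
            ds = datasets[ds_name]
            for algorithm in config.algorithms:
                label = StrategyLabel(ds_name, algorithm, hi_on).render()
                logger.info("strategy %s", label)
                sum_map = None
                n_maps = 0
                for i_pa, pa in enumerate(ds.pa_sets):
                    cells = np.concatenate([ds.presence_cells, pa])
                    labels = np.concatenate(
                        [
                            np.ones(ds.presence_cells.size, dtype=int),
                            np.zeros(pa.size, dtype=int),
                        ]
                    )
                    splits = prep.split_train_test(
                        labels,
                        fraction=config.train_fraction,
                        n_repeats=config.n_repeats,
                        seed=derive_seed(
                            config.seed, f"split:{ds_name}:{i_pa}:{hi_on}"
                        ),
                    )
                    for i_rep, (tr, te) in enumerate(splits):
                        spec = _model_spec(
                            algorithm,
                            config,
                            derive_seed(
                                config.seed,
                                f"fit:{label}:{i_pa}:{i_rep}",
                            ),
                        )
                        model = train_model(
                            algorithm, stack, cells[tr], labels[tr], spec
                        )
                        test_table = extract_table(stack, cells[te])
                        scores = model.predict_table(test_table)
                        t_tss, v_tss = best_threshold_metric(scores, labels[te], tss)
                        t_kap, v_kap = best_threshold_metric(scores, labels[te], kappa)
                        rows.append(
                            MetricResult(
                                dataset=ds_name,
                                algorithm=algorithm,
                                pa_set=i_pa,
                                repeat=i_rep,
                                hi_on=hi_on,
                                auc=auc(scores, labels[te]),
                                tss=v_tss,
                                kappa=v_kap,
                                tss_threshold=t_tss,
                                kappa_threshold=t_kap,
                            )
                        )
                        if config.make_maps:
                            pred = predict_suitability(model, stack)
                            if sum_map is None:
                                sum_map = pred.values.copy()
                                sum_map[~pred.mask] = 0.0
                                n_maps = 1
                            else:
                                sum_map[pred.mask] += pred.values[pred.mask]
                                n_maps += 1
                if config.make_maps and sum_map is not None:
                    mean_vals = sum_map / n_maps
                    mask = stack.joint_mask()
                    mean_vals[~mask] = stack.grid.nodata
                    committee[label] = Raster(stack.grid, mean_vals, mask)
                else:
                    committee[label] = None
    metrics = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    return metrics, committee


def summarize_maps(
    committee: Mapping[str, Raster],
    landscape: Landscape,
    config: RunConfig,
) -> dict:
    """Binarize, fuse life forms, changed areas, county areas, double-ranking."""
    counties = landscape.counties
    binmaps = {
        label: ana.binarize(
            raster, config.binarize_threshold, provenance=(label,)
        )
        for label, raster in committee.items()
        if raster is not None
    }
    any_map = next(iter(binmaps.values()))
    total_area = ana.study_area_km2(
        any_map.raster.mask, any_map.raster.grid.cell_area_km2
    )
    changed = {}
    fused = {}
    for hi_on in config.hi_settings:
        for algorithm in config.algorithms:
            needed = {
                short: StrategyLabel(short, algorithm, hi_on).render()
                for short in ("all", "t", "e", "m")
            }
            if not all(lbl in binmaps for lbl in needed.values()):
                continue
            total = ana.fuse_lifeform_layers(
                binmaps[needed["t"]], binmaps[needed["e"]], binmaps[needed["m"]]
            )
            key = StrategyLabel("total", algorithm, hi_on).render()
            fused[key] = total
            cm = ana.changed_area(binmaps[needed["all"]], total, total_area)
            changed[key] = {
                "changed_km2": cm.changed_area_km2,
                "changed_pct": cm.changed_pct,
            }
    from .geodata import zonal_area

    strategy_areas = {
        label: zonal_area(bm.raster, counties) for label, bm in binmaps.items()
    }
    rankings, consensus = double_rank(strategy_areas, config.ranking)
    summary = ana.suitable_area_summary(
        list(binmaps.values()), counties, total_area
    )
    return {
        "binary_maps": binmaps,
        "fused": fused,
        "changed": changed,
        "total_area_km2": total_area,
        "area_summary": summary,
        "rankings": rankings,
        "consensus": consensus,
    }


@dataclass
class PipelineResult:
    config: RunConfig
    landscape: Landscape
    hi: Raster
    stacks: dict[bool, PredictorStack]
    datasets: dict[str, prep.ModelDataset]
    metrics: pd.DataFrame
    committee: dict[str, Raster | None]
    maps: dict | None
    manifest: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage; deterministic under ``config.seed``."""
    logger.info("stage: synth (grid %dx%d)", config.n_rows, config.n_cols)
    landscape = generate_landscape(config.landscape_params())

    logger.info("stage: human influence")
    hi = compute_hi(landscape)

    full_stack = assemble_stack(landscape, hi)

    logger.info("stage: occurrences")
    frames = []
    for name, niche in sorted(config.niches.items()):
        frames.append(
            generate_occurrences(
                full_stack, niche, derive_seed(config.seed, f"occ:{name}")
            )
        )
    occurrences = pd.concat(frames, ignore_index=True)

    # niches are defined on the full predictor roster; collinearity pruning
    # applies to the modelling stacks only
    stack_hi = prep.filter_collinear(full_stack, config.collinearity_threshold)
    stack_nohi = prep.filter_collinear(
        assemble_stack(landscape, None), config.collinearity_threshold
    )
    stacks = {True: stack_hi, False: stack_nohi}

    logger.info("stage: prep")
    datasets = prepare_datasets(stack_hi, occurrences, config)

    logger.info("stage: fit/evaluate (%d strategies)",
                len(config.datasets) * len(config.algorithms) * len(config.hi_settings))
    metrics, committee = run_matrix(stacks, datasets, config)

    maps = None
    if config.make_maps:
        logger.info("stage: maps")
        maps = summarize_maps(
            {k: v for k, v in committee.items() if v is not None},
            landscape,
            config,
        )

    manifest = {
        "config_hash": config.config_hash(),
        "config": _jsonable(config),
        "n_predictors_hi": len(stack_hi.names),
        "n_predictors_nohi": len(stack_nohi.names),
        "strategies": sorted(
            StrategyLabel(d, a, h).render()
            for d in config.datasets
            for a in config.algorithms
            for h in config.hi_settings
        ),
        "n_runs": int(len(metrics)),
    }
    result = PipelineResult(
        config, landscape, hi, stacks, datasets, metrics, committee, maps, manifest
    )
    if config.output_dir:
        write_outputs(result, Path(config.output_dir))
    return result


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(outdir / "metrics.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    if result.maps:
        result.maps["area_summary"].to_csv(outdir / "area_summary.csv", index=False)
        rank_rows = []
        for label, rr in result.maps["rankings"].items():
            rank_rows.append(
                {
                    "strategy": label,
                    "sequential_set": sorted(rr.sequential_set),
                    "area_weight_set": sorted(rr.area_weight_set),
                    "intersection": sorted(rr.intersection),
                }
            )
        pd.DataFrame(rank_rows).to_csv(outdir / "rankings.csv", index=False)
        (outdir / "consensus.json").write_text(
            json.dumps(sorted(result.maps["consensus"]))
        )
        pd.DataFrame(
            [
                {"strategy": k, **v}
                for k, v in result.maps["changed"].items()
            ]
        ).to_csv(outdir / "changed_areas.csv", index=False)
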
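"""Occurrence preprocessing and model-dataset assembly.

Life-form classification splits the pooled records into the four modelling
datasets (all / terrestrial / epiphytic / mycoheterotrophic).  Spatial
thinning keeps at most one record per 1-km grid cell, limiting spatial
autocorrelation to the grid resolution.  Pseudo-absences are uniform draws
of distinct non-presence cells (2000 per set, three independent sets per
dataset), and each presence/pseudo-absence combination is split 70/30 into
train/validation five times, stratified by class — 15 runs per dataset.
Predictor collinearity is reduced by greedy elimination until every retained
pair of continuous layers has |Pearson r| below the threshold (0.7).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import GridSpec
from .synth import PredictorStack

logger = logging.getLogger("orchidsdm")

LIFEFORMS = ("terrestrial", "epiphytic", "mycoheterotrophic")
DATASET_NAMES = ("all", "t", "e", "m")
_LF_TO_SHORT = {"terrestrial": "t", "epiphytic": "e", "mycoheterotrophic": "m"}


@dataclass
class ModelDataset:
    """Presence cells plus replicated pseudo-absence sets for one dataset."""

    name: str
    presence_cells: np.ndarray            # flat cell indices
    pa_sets: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.name not in DATASET_NAMES:
            raise ValueError(f"dataset name must be one of {DATASET_NAMES}")
        for pa in self.pa_sets:
            if np.intersect1d(pa, self.presence_cells).size:
                raise ValueError("pseudo-absence cells overlap presence cells")


def classify_lifeform(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition records into the four datasets keyed 'all', 't', 'e', 'm'.

    The three life-form subsets are pairwise disjoint and their union is the
    full table (record counts are conserved).
    """
    if len(records):
        unknown = set(records["lifeform"]) - set(LIFEFORMS)
        if unknown:
            taxa = sorted(
                records.loc[records["lifeform"].isin(unknown), "taxon"].unique()
            )
            raise ValueError(
                f"unknown lifeform label(s) {sorted(unknown)} on taxa {taxa}"
            )
    out = {"all": records.reset_index(drop=True)}
    for lf, short in _LF_TO_SHORT.items():
        if len(records):
            sub = records[records["lifeform"] == lf]
        else:
            sub = records
        out[short] = sub.reset_index(drop=True)
    return out


def thin_occurrences(points: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Keep at most one record per grid cell (the lowest-index record)."""
    if len(points) == 0:
        return points.reset_index(drop=True)
    rows, cols = grid.points_to_cells(points["lon"].to_numpy(), points["lat"].to_numpy())
    cell = rows * grid.n_cols + cols
    keep = pd.Series(cell).duplicated(keep="first").to_numpy() == False  # noqa: E712
    return points.loc[keep].reset_index(drop=True)


def occurrence_cells(points: pd.DataFrame, grid: GridSpec) -> np.ndarray:
    """Distinct flat cell indices occupied by the records, in first-seen order."""
    if len(points) == 0:
        return np.empty(0, dtype=int)
    rows, cols = grid.points_to_cells(points["lon"].to_numpy(), points["lat"].to_numpy())
    cell = rows * grid.n_cols + cols
    _, first = np.unique(cell, return_index=True)
    return cell[np.sort(first)]


def sample_pseudo_absence(
    grid: GridSpec,
    presence_cells: np.ndarray,
    n: int = 2000,
    n_sets: int = 3,
    seed: int = 0,
    valid_cells: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Draw ``n_sets`` independent sets of ``n`` distinct background cells.

    Cells are uniform over valid non-presence cells; presence cells of the
    same dataset are excluded.  Fully seeded.
    """
    if valid_cells is None:
        valid_cells = np.arange(grid.n_cells)
    candidates = np.setdiff1d(valid_cells, presence_cells)
    if candidates.size < n:
        raise ValueError(
            f"cannot draw {n} pseudo-absences from {candidates.size} candidate "
            f"cells ({valid_cells.size} valid, {len(presence_cells)} presences)"
        )
    rng = np.random.default_rng(seed)
    return [rng.choice(candidates, size=n, replace=False) for _ in range(n_sets)]


def split_train_test(
    labels: np.ndarray,
    fraction: float = 0.7,
    n_repeats: int = 5,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified random 70/30 splits, repeated ``n_repeats`` times.

    Returns (train_idx, test_idx) pairs over positions of ``labels``; per
    class, ``round(fraction * n_class)`` records train.
    """
    labels = np.asarray(labels)
    if labels.size < 10 or len(np.unique(labels)) < 2:
        raise ValueError("need >= 10 records with both classes")
    for cls in np.unique(labels):
        if (labels == cls).sum() < 2:
            raise ValueError(f"class {cls} has < 2 members; cannot stratify")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        train_parts, test_parts = [], []
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            perm = rng.permutation(idx)
            k = round(fraction * idx.size)
            k = min(max(k, 1), idx.size - 1)
            train_parts.append(perm[:k])
            test_parts.append(perm[k:])
        splits.append(
            (np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts)))
        )
    return splits


def filter_collinear(stack: PredictorStack, threshold: float = 0.7) -> PredictorStack:
    """Greedy collinearity pruning of continuous layers (|Pearson r| < threshold).

    While any continuous pair correlates at or above the threshold, the
    member of the worst pair with the larger mean absolute correlation to
    all other continuous layers is dropped.  Categorical layers are exempt.
    """
    cont = [n for n in stack.names if not stack[n].categorical]
    if len(cont) < 2:
        warnings.warn("fewer than 2 continuous layers; nothing to filter")
        return stack
    mask = stack.joint_mask()
    data = {n: stack[n].values[mask].astype(float) for n in cont}
    kept = list(cont)

    def corr(a: str, b: str) -> float:
        return float(np.corrcoef(data[a], data[b])[0, 1])

    while True:
        worst, worst_r = None, threshold
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                r = abs(corr(a, b))
                if r >= worst_r:
                    worst, worst_r = (a, b), r
        if worst is None:
            break
        a, b = worst

        def mean_abs(name: str) -> float:
            others = [o for o in kept if o != name]
            return float(np.mean([abs(corr(name, o)) for o in others]))

        drop = a if mean_abs(a) >= mean_abs(b) else b
        logger.info("dropping %s (|r|=%.3f with %s)", drop, worst_r, a if drop == b else b)
        kept.remove(drop)
        if len(kept) < 2:
            break
    keep_names = [n for n in stack.names if stack[n].categorical or n in kept]
    return stack.subset(keep_names)


def build_dataset(
    name: str,
    points: pd.DataFrame,
    grid: GridSpec,
    n_pseudo: int = 2000,
    n_pa_sets: int = 3,
    seed: int = 0,
    valid_cells: np.ndarray | None = None,
) -> ModelDataset:
    """Thin, extract presence cells, and attach pseudo-absence sets."""
    thinned = thin_occurrences(points, grid)
    cells = occurrence_cells(thinned, grid)
    pa_sets = sample_pseudo_absence(
        grid, cells, n=n_pseudo, n_sets=n_pa_sets, seed=seed, valid_cells=valid_cells
    )
    return ModelDataset(name, cells, pa_sets)
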
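"""The three suitability algorithms behind a uniform fit/predict contract.

* **GLM** — binomial-logit fit by penalized maximum likelihood (a tiny ridge,
  1e-6, for numerical stability) with interaction level 1: all pairwise
  products of main-effect columns (products of one-hot columns from the same
  categorical are structurally zero and excluded).
* **RF** — a 1000-tree classification forest; suitability is the forest's
  presence probability (average of per-tree leaf class fractions).
* **MaxEnt** — the presence-background maximum-entropy model in its
  weighted penalized-logistic formulation on linear + quadratic features
  with an L1 penalty (default weight 1.0).  This is a same-family
  re-specification, not a port of the original MaxEnt software.

All predictors are z-scored with training statistics; categorical layers are
one-hot encoded.  Every algorithm emits suitability in [0, 1] and is
deterministic under its seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .evaluation import auc
from .geodata import Raster
from .synth import PredictorStack

logger = logging.getLogger("orchidsdm")


@dataclass
class ModelSpec:
    algorithm: str = "glm"                 # glm | rf | maxent
    interaction_level: int = 1             # glm only
    n_trees: int = 1000                    # rf only
    regularization: float = 1.0            # maxent L1 penalty weight
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("glm", "rf", "maxent"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.interaction_level not in (0, 1):
            raise ValueError("interaction_level must be 0 or 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.regularization <= 0:
            raise ValueError("regularization must be > 0")


@dataclass
class FeatureSchema:
    """Training-time feature recipe: z-scoring stats, one-hot levels, terms."""

    continuous: list[str]
    categorical: dict[str, list]           # name -> sorted level codes
    means: np.ndarray
    stds: np.ndarray
    interactions: bool = False
    quadratic: bool = False

    @classmethod
    def fit(
        cls,
        table: pd.DataFrame,
        categorical: tuple[str, ...] = (),
        interactions: bool = False,
        quadratic: bool = False,
    ) -> "FeatureSchema":
        cont = [c for c in table.columns if c not in categorical]
        means = table[cont].to_numpy(dtype=float).mean(axis=0)
        stds = table[cont].to_numpy(dtype=float).std(axis=0)
        stds = np.where(stds > 0, stds, 1.0)
        cats = {
            c: sorted(pd.unique(table[c]).tolist())
            for c in categorical
            if c in table.columns
        }
        return cls(cont, cats, means, stds, interactions, quadratic)

    @property
    def base_predictors(self) -> list[str]:
        return list(self.continuous) + list(self.categorical)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        z = (table[self.continuous].to_numpy(dtype=float) - self.means) / self.stds
        blocks = [z]
        block_of_col: list[object] = list(range(len(self.continuous)))
        for name, levels in self.categorical.items():
            col = table[name].to_numpy()
            unseen = ~np.isin(col, levels)
            if unseen.any():
                warnings.warn(
                    f"{int(unseen.sum())} row(s) carry unseen {name} categories; "
                    "encoded as all-zero"
                )
            onehot = np.column_stack([(col == lv).astype(float) for lv in levels])
            blocks.append(onehot)
            block_of_col.extend([name] * len(levels))
        mains = np.hstack(blocks)
        parts = [mains]
        if self.quadratic:
            parts.append(z**2)
        if self.interactions:
            n = mains.shape[1]
            inter = []
            for i in range(n):
                for j in range(i + 1, n):
                    # skip products of one-hot columns of the same categorical
                    if (
                        isinstance(block_of_col[i], str)
                        and block_of_col[i] == block_of_col[j]
                    ):
                        continue
                    inter.append(mains[:, i] * mains[:, j])
            if inter:
                parts.append(np.column_stack(inter))
        return np.hstack(parts)


@dataclass
class FittedModel:
    spec: ModelSpec
    estimator: object
    feature_schema: FeatureSchema | None = None
    offset: float = 0.0                    # maxent background-weight intercept shift

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        p = self.estimator.predict_proba(X)[:, 1]
        return np.clip(p, 0.0, 1.0)

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        if self.feature_schema is None:
            raise ValueError("model was fitted without a feature schema")
        return self.predict_matrix(self.feature_schema.transform(table))


def extract_table(stack: PredictorStack, cells: np.ndarray) -> pd.DataFrame:
    """Raw predictor values at flat cell indices, one column per layer."""
    cells = np.asarray(cells)
    data = {}
    for name in stack.names:
        data[name] = stack[name].values.ravel()[cells]
    return pd.DataFrame(data, index=cells)


def build_features(
    stack: PredictorStack,
    cells: np.ndarray,
    schema: FeatureSchema | None = None,
    interactions: bool = False,
    quadratic: bool = False,
) -> tuple[np.ndarray, FeatureSchema]:
    """Design matrix for cells; fits the schema on first use, reuses it after."""
    table = extract_table(stack, cells)
    if schema is None:
        cats = tuple(n for n in stack.names if stack[n].categorical)
        schema = FeatureSchema.fit(
            table, categorical=cats, interactions=interactions, quadratic=quadratic
        )
    return schema.transform(table), schema


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_GLM_RIDGE = 1e-6
_GLM_MAX_ITER = 500


def _check_both_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def fit_glm(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ModelSpec | None = None,
    schema: FeatureSchema | None = None,
) -> FittedModel:
    """Penalized-ML binomial logit (ridge 1e-6); deterministic."""
    spec = spec or ModelSpec("glm")
    labels = np.asarray(labels)
    _check_both_classes(labels)
    clf = LogisticRegression(
        C=1.0 / _GLM_RIDGE, solver="newton-cholesky",
        max_iter=_GLM_MAX_ITER, tol=1e-8,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(features, labels)
    if clf.n_iter_[0] >= _GLM_MAX_ITER:
        grad = _penalized_grad_norm(clf, features, labels)
        if grad > 1e-4:
            raise RuntimeError(
                f"GLM did not converge in {_GLM_MAX_ITER} iterations "
                f"(gradient norm {grad:.3e})"
            )
    return FittedModel(spec, clf, schema)


def _penalized_grad_norm(clf, X: np.ndarray, y: np.ndarray) -> float:
    w = clf.coef_.ravel()
    b = clf.intercept_[0]
    p = 1.0 / (1.0 + np.exp(-(X @ w + b)))
    resid = p - (y == clf.classes_[1])
    grad_w = X.T @ resid + _GLM_RIDGE * w
    grad_b = resid.sum()
    return float(np.linalg.norm(np.append(grad_w, grad_b)) / X.shape[0])


def fit_rf(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ModelSpec | None = None,
    schema: FeatureSchema | None = None,
) -> FittedModel:
    """1000-tree classification forest; suitability = presence vote fraction."""
    spec = spec or ModelSpec("rf")
    labels = np.asarray(labels)
    _check_both_classes(labels)
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
    )
    clf.fit(features, labels)
    return FittedModel(spec, clf, schema)


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    spec: ModelSpec | None = None,
    schema: FeatureSchema | None = None,
) -> FittedModel:
    """Presence-background model as weighted L1 logistic (linear+quadratic).

    Background rows are down-weighted so the two classes carry equal total
    weight; doubling the background at the same distribution therefore
    leaves the fit (and cell ranking) essentially unchanged.
    """
    spec = spec or ModelSpec("maxent")
    n_p = presence_features.shape[0]
    n_b = background_features.shape[0]
    if n_b == 0:
        raise ValueError("empty background sample")
    if n_b < n_p:
        warnings.warn(f"background ({n_b}) smaller than presence set ({n_p})")
    X = np.vstack([presence_features, background_features])
    y = np.concatenate([np.ones(n_p, dtype=int), np.zeros(n_b, dtype=int)])
    w = np.concatenate([np.ones(n_p), np.full(n_b, n_p / n_b)])
    clf = LogisticRegression(
        l1_ratio=1, C=1.0 / spec.regularization, solver="liblinear",
        max_iter=2000, tol=1e-8, random_state=spec.seed,
    )
    clf.fit(X, y, sample_weight=w)
    return FittedModel(spec, clf, schema)


def train_model(
    algorithm: str,
    stack: PredictorStack,
    train_cells: np.ndarray,
    train_labels: np.ndarray,
    spec: ModelSpec | None = None,
) -> FittedModel:
    """Algorithm-appropriate features + fit, returning a schema-carrying model."""
    spec = spec or ModelSpec(algorithm)
    if spec.algorithm != algorithm:
        raise ValueError("spec.algorithm does not match requested algorithm")
    interactions = algorithm == "glm" and spec.interaction_level >= 1
    quadratic = algorithm == "maxent"
    X, schema = build_features(
        stack, train_cells, interactions=interactions, quadratic=quadratic
    )
    labels = np.asarray(train_labels)
    if algorithm == "glm":
        return fit_glm(X, labels, spec, schema)
    if algorithm == "rf":
        return fit_rf(X, labels, spec, schema)
    return fit_maxent(X[labels == 1], X[labels == 0], spec, schema)


def predict_suitability(model: FittedModel, stack: PredictorStack) -> Raster:
    """Per-cell suitability in [0, 1]; masked cells stay masked."""
    if model.feature_schema is None:
        raise ValueError("model carries no feature schema; cannot map predict")
    missing = [
        n for n in model.feature_schema.base_predictors if n not in stack
    ]
    if missing:
        raise ValueError(f"stack is missing predictor layer(s): {missing}")
    grid = stack.grid
    mask = stack.joint_mask()
    cells = np.flatnonzero(mask.ravel())
    p = model.predict_table(extract_table(stack, cells))
    values = np.full(grid.shape, grid.nodata, dtype=float)
    values.ravel()[cells] = p
    return Raster(grid, values, mask)


def variable_importance(
    model: FittedModel,
    table: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    n_perm: int = 10,
) -> pd.DataFrame:
    """Permutation importance: mean held-out AUC drop per base predictor.

    Permuting the raw predictor column before the feature transform also
    scrambles every derived term (one-hot, quadratic, interaction) coherently.
    """
    if model.feature_schema is None:
        raise ValueError("model carries no feature schema")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    base_auc = auc(model.predict_table(table), labels)
    rows = []
    for pred in model.feature_schema.base_predictors:
        if pred not in table.columns:
            continue
        drops = []
        for _ in range(n_perm):
            permuted = table.copy()
            permuted[pred] = rng.permutation(permuted[pred].to_numpy())
            drops.append(base_auc - auc(model.predict_table(permuted), labels))
        rows.append({"predictor": pred, "importance": float(np.mean(drops))})
    out = pd.DataFrame(rows).sort_values(
        "importance", ascending=False, kind="mergesort"
    )
    return out.reset_index(drop=True)
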
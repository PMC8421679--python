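"""Cascade deep forest: stacked levels of heterogeneous tree ensembles.

Each level holds six forests (two completely-random tree forests, two
gradient-boosting forests, two extra-randomized tree forests; 1,000 trees
per forest by default, i.e. 6,000 trees per level).  Every forest emits a
per-instance class-probability vector; during training these class vectors
are generated out-of-fold by stratified k-fold cross-validation, and the
next level's input is the raw feature matrix concatenated with all class
vectors of the previous level.  Levels are appended while the out-of-fold
validation metric improves, so cascade depth is determined automatically.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import ExtraTreesClassifier, GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from thncdf.exceptions import ConfigError, ValidationError

__all__ = ["CascadeConfig", "CascadeModel", "build_forest", "fit", "predict_proba"]

FOREST_TYPES = ("completely_random", "gradient_boosting", "extra_trees")

DEFAULT_FOREST_SPECS: tuple[tuple[str, int], ...] = (
    ("completely_random", 2),
    ("gradient_boosting", 2),
    ("extra_trees", 2),
)


@dataclass
class CascadeConfig:
    """Structure and training hyper-parameters of the cascade."""

    forest_specs: tuple[tuple[str, int], ...] = DEFAULT_FOREST_SPECS
    trees_per_forest: int = 1000
    cv_folds: int = 10
    max_levels: int = 10
    early_stop_tolerance: float = 0.0
    level_metric: str = "aupr"
    seed: int = 0

    def __post_init__(self) -> None:
        self.forest_specs = tuple((str(t), int(c)) for t, c in self.forest_specs)
        if not self.forest_specs or all(c == 0 for _, c in self.forest_specs):
            raise ConfigError("cascade needs at least one forest per level")
        for ftype, count in self.forest_specs:
            if ftype not in FOREST_TYPES:
                raise ConfigError(
                    f"unknown forest_type {ftype!r}; expected one of {FOREST_TYPES}"
                )
            if count < 0:
                raise ConfigError("forest count must be non-negative")
        if self.trees_per_forest < 1:
            raise ConfigError("trees_per_forest must be >= 1")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.max_levels < 1:
            raise ConfigError("max_levels must be >= 1")
        if self.early_stop_tolerance < 0:
            raise ConfigError("early_stop_tolerance must be >= 0")
        if self.level_metric not in ("aupr", "auc", "accuracy"):
            raise ConfigError(f"unknown level_metric {self.level_metric!r}")

    @property
    def n_forests(self) -> int:
        return sum(c for _, c in self.forest_specs)

    @property
    def trees_per_level(self) -> int:
        """Total decision trees instantiated in one cascade level."""
        return sum(c * self.trees_per_forest for _, c in self.forest_specs)

    def forest_types(self) -> list[str]:
        out: list[str] = []
        for ftype, count in self.forest_specs:
            out.extend([ftype] * count)
        return out


@dataclass
class CascadeModel:
    """A fitted cascade: per-level forests, validation metrics, best depth."""

    levels: list[list[object]]
    level_metrics: list[float]
    n_classes: int
    best_level: int
    classes_: np.ndarray
    n_raw_features: int
    config: CascadeConfig = field(repr=False)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def augmented_width(self) -> int:
        """Input width seen by every level after the first."""
        return self.n_raw_features + len(self.levels[0]) * self.n_classes


def _forest_seed(root_seed: int, level: int, index: int) -> int:
    """Stable per-forest RNG stream; adding forests never reseeds earlier ones."""
    ss = np.random.SeedSequence([root_seed & 0xFFFFFFFF, level, index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def build_forest(forest_type: str, trees: int, seed: int):
    """Construct an unfitted forest of the requested flavour.

    ``completely_random`` trees pick one uniformly random feature (and a
    random threshold) per node and grow to leaf purity; ``extra_trees``
    use randomized thresholds over random feature subsets;
    ``gradient_boosting`` is a boosted tree ensemble whose class vector is
    the boosted probability estimate.
    """
    if forest_type == "completely_random":
        return ExtraTreesClassifier(
            n_estimators=trees,
            max_features=1,
            min_samples_leaf=1,
            random_state=seed,
            n_jobs=1,
        )
    if forest_type == "extra_trees":
        return ExtraTreesClassifier(
            n_estimators=trees,
            max_features="sqrt",
            min_samples_leaf=1,
            random_state=seed,
            n_jobs=1,
        )
    if forest_type == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=trees, random_state=seed)
    raise ConfigError(f"unknown forest_type {forest_type!r}")


def _aligned_proba(forest, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """predict_proba with columns aligned to the cascade's class order."""
    raw = forest.predict_proba(X)
    out = np.zeros((X.shape[0], len(classes)))
    for k, c in enumerate(forest.classes_):
        out[:, np.searchsorted(classes, c)] = raw[:, k]
    return out


def _level_metric(name: str, scores: np.ndarray, y: np.ndarray) -> float:
    from thncdf.evaluation import auc, aupr  # local import avoids a cycle

    if name == "aupr":
        return aupr(scores, y)
    if name == "auc":
        return auc(scores, y)
    return float(((scores >= 0.5).astype(int) == y).mean())


def _fit_level(
    A: np.ndarray,
    X_raw: np.ndarray,
    y: np.ndarray,
    classes: np.ndarray,
    cfg: CascadeConfig,
    level: int,
) -> tuple[list[object], np.ndarray]:
    """Fit one level; returns (fitted forests, out-of-fold class vectors)."""
    n = A.shape[0]
    n_classes = len(classes)
    forests: list[object] = []
    oof_blocks: list[np.ndarray] = []
    skf = StratifiedKFold(
        n_splits=cfg.cv_folds,
        shuffle=True,
        random_state=_forest_seed(cfg.seed, level, 10_000),
    )
    splits = list(skf.split(A, y))
    for f_idx, ftype in enumerate(cfg.forest_types()):
        proto = build_forest(ftype, cfg.trees_per_forest, _forest_seed(cfg.seed, level, f_idx))
        oof = np.zeros((n, n_classes))
        for train_idx, test_idx in splits:
            fold_forest = clone(proto)
            fold_forest.fit(A[train_idx], y[train_idx])
            oof[test_idx] = _aligned_proba(fold_forest, A[test_idx], classes)
        full_forest = clone(proto)
        full_forest.fit(A, y)
        forests.append(full_forest)
        oof_blocks.append(oof)
    return forests, np.hstack(oof_blocks)


def fit(X: np.ndarray, y: np.ndarray, cfg: CascadeConfig | None = None) -> CascadeModel:
    """Train the cascade, choosing depth by out-of-fold validation gain.

    Level 1 sees the raw features; level l > 1 sees the raw features
    concatenated with level l-1's out-of-fold class vectors.  Training
    stops once a level fails to improve the out-of-fold metric by more
    than ``early_stop_tolerance``, and the model is truncated to the best
    level (earliest on ties).
    """
    cfg = cfg or CascadeConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValidationError("X must be 2-d with one row per label")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("training labels contain a single class")
    if X.shape[0] < cfg.cv_folds:
        raise ValidationError(
            f"n_samples={X.shape[0]} is smaller than cv_folds={cfg.cv_folds}"
        )
    counts = np.bincount(np.searchsorted(classes, y))
    if counts.min() < cfg.cv_folds:
        raise ValidationError(
            f"minority class has {counts.min()} samples; stratified "
            f"{cfg.cv_folds}-fold class vectors need at least {cfg.cv_folds}"
        )
    n_classes = len(classes)
    pos_col = n_classes - 1  # probability column of the largest class label

    levels: list[list[object]] = []
    metrics: list[float] = []
    A = X
    oof_prev: np.ndarray | None = None
    best_metric = -np.inf
    best_level = 0
    for level in range(cfg.max_levels):
        if oof_prev is not None:
            A = np.hstack([X, oof_prev])
        forests, oof = _fit_level(A, X, y, classes, cfg, level)
        n_forests = len(forests)
        mean_scores = oof.reshape(len(y), n_forests, n_classes).mean(axis=1)[:, pos_col]
        metric = _level_metric(cfg.level_metric, mean_scores, y)
        levels.append(forests)
        metrics.append(metric)
        if metric > best_metric + cfg.early_stop_tolerance:
            best_metric = metric
            best_level = level
        elif level > best_level:
            break  # patience exhausted: this level did not improve
        oof_prev = oof

    levels = levels[: best_level + 1]
    metrics = metrics[: best_level + 1]
    return CascadeModel(
        levels=levels,
        level_metrics=metrics,
        n_classes=n_classes,
        best_level=best_level,
        classes_=classes,
        n_raw_features=X.shape[1],
        config=copy.deepcopy(cfg),
    )


def predict_proba(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities: mean of the best level's forest class vectors.

    Inputs are propagated through all levels up to ``best_level``, with
    each intermediate level's (in-sample) class vectors appended to the
    raw features exactly as during training.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_raw_features:
        raise ValidationError(
            f"expected {model.n_raw_features} raw features, got "
            f"{X.shape[1] if X.ndim == 2 else 'non-2d input'}"
        )
    A = X
    probas: list[np.ndarray] = []
    for level in range(model.best_level + 1):
        probas = [_aligned_proba(f, A, model.classes_) for f in model.levels[level]]
        if level < model.best_level:
            A = np.hstack([X] + probas)
    P = np.mean(probas, axis=0)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def predict_score(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Positive-class probability (the last class in sorted label order)."""
    return predict_proba(model, X)[:, -1]
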
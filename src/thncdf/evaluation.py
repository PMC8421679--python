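"""Ranking metrics and the outer cross-validation protocol.

AUC is computed as the Mann-Whitney statistic (ties counted half).  AUPR
is step-wise average precision: the mean, over positives, of the precision
at each positive's rank, with deterministic tie handling by (descending
score, ascending original index) — no trapezoidal interpolation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from thncdf.datatypes import DiseaseProfileMatrix, FingerprintSet, InteractionMatrix
from thncdf.exceptions import ValidationError
from thncdf.pair_features import build_dataset, sample_pairs
from thncdf.similarity import compute_similarities

__all__ = ["CVResult", "auc", "aupr", "cross_validate"]


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if len(s) != len(y):
        raise ValidationError("scores and labels differ in length")
    if len(s) == 0:
        raise ValidationError("empty score vector")
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("labels must be binary")
    return s, y


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals P(score+ > score-) + 0.5 * P(score+ = score-) over all
    positive/negative pairs.
    """
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve as average precision."""
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValidationError("AUPR requires at least one positive")
    order = np.lexsort((np.arange(len(s)), -s))
    y_sorted = y[order]
    cum_pos = np.cumsum(y_sorted)
    precision_at = cum_pos / np.arange(1, len(s) + 1)
    return float(precision_at[y_sorted == 1].sum() / n_pos)


@dataclass
class CVResult:
    """Per-fold and aggregate metrics of one cross-validation run."""

    fold_auc: list[float]
    fold_aupr: list[float]
    mean_auc: float
    mean_aupr: float
    fold_assignments: np.ndarray
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return len(self.fold_auc)


def cross_validate(
    interactions: InteractionMatrix,
    fingerprints: FingerprintSet,
    disease_profiles: DiseaseProfileMatrix | None = None,
    cascade_cfg=None,
    k: int = 10,
    negative_ratio: float | str = 1.0,
    seed: int = 0,
    mask_test_interactions: bool = False,
    similarity_kwargs: dict | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation over labeled drug-target pairs.

    Pairs are sampled once; similarity matrices are computed once from the
    full adjacency matrix (the common protocol in this literature, which
    lets held-out interactions influence the kernels).  With
    ``mask_test_interactions`` the kernels are recomputed per fold with
    the held-out positive pairs zeroed, removing that leakage.
    """
    from sklearn.model_selection import StratifiedKFold

    from thncdf import cascade_forest

    if k < 2:
        raise ValidationError("k must be >= 2")
    cascade_cfg = cascade_cfg or cascade_forest.CascadeConfig()
    similarity_kwargs = dict(similarity_kwargs or {})

    labeled = sample_pairs(interactions, negative_ratio=negative_ratio, seed=seed)
    y = np.array([lab for _, _, lab in labeled], dtype=int)
    if y.sum() < k:
        raise ValidationError(f"only {int(y.sum())} positives; cannot stratify into {k} folds")

    sim_drug, sim_tar = compute_similarities(
        interactions, fingerprints, disease_profiles, **similarity_kwargs
    )
    ds = build_dataset(sim_drug, sim_tar, labeled)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed & 0x7FFFFFFF)
    assignments = np.empty(len(labeled), dtype=int)
    fold_auc: list[float] = []
    fold_aupr: list[float] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(ds.X, y)):
        assignments[test_idx] = fold
        if mask_test_interactions:
            masked = interactions.Y.copy()
            for idx in test_idx:
                i, j = ds.pairs[idx]
                masked[i, j] = 0
            im_fold = InteractionMatrix(
                interactions.drug_ids, interactions.target_ids, masked
            )
            sd, st = compute_similarities(
                im_fold, fingerprints, disease_profiles, **similarity_kwargs
            )
            ds_fold = build_dataset(sd, st, labeled)
            X_train, X_test = ds_fold.X[train_idx], ds_fold.X[test_idx]
        else:
            X_train, X_test = ds.X[train_idx], ds.X[test_idx]
        fold_cfg = copy.deepcopy(cascade_cfg)
        fold_cfg.seed = cascade_forest._forest_seed(cascade_cfg.seed, 20_000 + fold, 0)
        model = cascade_forest.fit(X_train, y[train_idx], fold_cfg)
        scores = cascade_forest.predict_score(model, X_test)
        fold_auc.append(auc(scores, y[test_idx]))
        fold_aupr.append(aupr(scores, y[test_idx]))

    return CVResult(
        fold_auc=fold_auc,
        fold_aupr=fold_aupr,
        mean_auc=float(np.mean(fold_auc)),
        mean_aupr=float(np.mean(fold_aupr)),
        fold_assignments=assignments,
        seed=seed,
        config={
            "k": k,
            "negative_ratio": negative_ratio,
            "mask_test_interactions": mask_test_interactions,
            "cascade": cascade_cfg.__dict__.copy(),
            "similarity": similarity_kwargs,
        },
    )
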
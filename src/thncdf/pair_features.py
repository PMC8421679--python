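"""Labeled drug-target pair datasets built from fused similarity matrices.

A pair (i, j) is encoded as the concatenation of drug i's full row of the
fused drug similarity matrix and target j's full row of the fused target
similarity matrix, giving an (m + n)-dimensional feature vector in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from thncdf.datatypes import InteractionMatrix, SimilarityMatrix
from thncdf.exceptions import ValidationError

__all__ = ["PairDataset", "build_pair_features", "sample_pairs", "build_dataset"]


@dataclass
class PairDataset:
    """Feature matrix, labels and bookkeeping for a set of drug-target pairs."""

    pairs: list[tuple[int, int]]
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        if not (len(self.pairs) == self.X.shape[0] == len(self.y)):
            raise ValidationError("pairs, X and y must agree in length")


def build_pair_features(
    sim_drug: SimilarityMatrix,
    sim_tar: SimilarityMatrix,
    pairs: list[tuple[int, int]],
) -> np.ndarray:
    """Feature row for pair (i, j): [drug-similarity row i, target-similarity row j]."""
    m, n = sim_drug.n, sim_tar.n
    pairs_arr = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if len(pairs_arr) and (
        pairs_arr[:, 0].min() < 0
        or pairs_arr[:, 0].max() >= m
        or pairs_arr[:, 1].min() < 0
        or pairs_arr[:, 1].max() >= n
    ):
        raise ValidationError("pair index out of range")
    X = np.empty((len(pairs_arr), m + n), dtype=float)
    X[:, :m] = sim_drug.S[pairs_arr[:, 0]]
    X[:, m:] = sim_tar.S[pairs_arr[:, 1]]
    return X


def feature_names(sim_drug: SimilarityMatrix, sim_tar: SimilarityMatrix) -> list[str]:
    return [f"simdrug:{d}" for d in sim_drug.ids] + [f"simtar:{t}" for t in sim_tar.ids]


def sample_pairs(
    interactions: InteractionMatrix,
    negative_ratio: float | str = 1.0,
    seed: int = 0,
) -> list[tuple[int, int, int]]:
    """All positive pairs plus seeded uniform negatives, as (i, j, label).

    ``negative_ratio`` is the negative:positive count ratio; ``"all"``
    keeps every zero cell.  The requested negative count is capped at the
    number of available zero cells.
    """
    Y = interactions.Y
    pos = np.argwhere(Y == 1)
    neg = np.argwhere(Y == 0)
    if len(pos) == 0:
        raise ValidationError("interaction matrix has no positive pairs")
    if len(neg) == 0:
        raise ValidationError("interaction matrix has no negative pairs")
    if negative_ratio == "all":
        chosen = neg
    else:
        ratio = float(negative_ratio)
        if ratio <= 0:
            raise ValidationError("negative_ratio must be positive or 'all'")
        k = min(int(round(ratio * len(pos))), len(neg))
        rng = np.random.default_rng(seed)
        chosen = neg[rng.choice(len(neg), size=k, replace=False)]
    out = [(int(i), int(j), 1) for i, j in pos]
    out += [(int(i), int(j), 0) for i, j in chosen]
    return out


def build_dataset(
    sim_drug: SimilarityMatrix,
    sim_tar: SimilarityMatrix,
    labeled_pairs: list[tuple[int, int, int]],
) -> PairDataset:
    """Assemble a :class:`PairDataset` from sampled labeled pairs."""
    pairs = [(i, j) for i, j, _ in labeled_pairs]
    y = np.array([lab for _, _, lab in labeled_pairs], dtype=int)
    X = build_pair_features(sim_drug, sim_tar, pairs)
    return PairDataset(pairs, X, y, feature_names(sim_drug, sim_tar))
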
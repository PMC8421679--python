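"""Seeded generator of toy tripartite data with planted block structure.

Drugs and targets are assigned to shared clusters; interactions occur with
probability ``p_in`` inside a cluster and ``p_out`` across clusters.  Each
drug cluster carries a prototype fingerprint whose members are bit-flipped
copies, and each target cluster maps to a dedicated disease subset, so the
planted signal is visible to every similarity channel downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from thncdf.datatypes import DiseaseProfileMatrix, FingerprintSet, InteractionMatrix
from thncdf.exceptions import ConfigError

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "generate"]


@dataclass
class SynthConfig:
    m: int = 20
    n: int = 30
    k: int = 12
    n_clusters: int = 3
    p_in: float = 0.5
    p_out: float = 0.02
    fingerprint_length: int = 166
    bit_flip_rate: float = 0.05
    disease_edge_prob: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.m, self.n, self.k) < self.n_clusters:
            raise ConfigError(
                "m, n and k must each be >= n_clusters "
                f"(got m={self.m}, n={self.n}, k={self.k}, "
                f"n_clusters={self.n_clusters})"
            )
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ConfigError("need 0 <= p_out < p_in <= 1")
        if not 0 <= self.bit_flip_rate < 0.5:
            raise ConfigError("bit_flip_rate must lie in [0, 0.5)")
        if self.fingerprint_length < 1:
            raise ConfigError("fingerprint_length must be >= 1")


def generate(
    cfg: SynthConfig,
) -> tuple[InteractionMatrix, FingerprintSet, DiseaseProfileMatrix, dict]:
    """Draw one seeded dataset; returns (interactions, fingerprints,
    disease profiles, cluster assignments).

    A degenerate all-zero or all-one adjacency draw is resampled once with
    a logged note so downstream negative sampling always has both classes.
    """
    rng = np.random.default_rng(cfg.seed)
    drug_clusters = rng.integers(0, cfg.n_clusters, size=cfg.m)
    target_clusters = rng.integers(0, cfg.n_clusters, size=cfg.n)
    # guarantee every cluster is populated on both sides
    drug_clusters[: cfg.n_clusters] = np.arange(cfg.n_clusters)
    target_clusters[: cfg.n_clusters] = np.arange(cfg.n_clusters)

    co = drug_clusters[:, None] == target_clusters[None, :]
    probs = np.where(co, cfg.p_in, cfg.p_out)
    Y = (rng.random((cfg.m, cfg.n)) < probs).astype(np.int8)
    if Y.sum() in (0, Y.size):
        logger.warning("degenerate adjacency draw (all %d); resampling once", Y.flat[0])
        Y = (rng.random((cfg.m, cfg.n)) < probs).astype(np.int8)

    prototypes = (rng.random((cfg.n_clusters, cfg.fingerprint_length)) < 0.3).astype(np.int8)
    flips = rng.random((cfg.m, cfg.fingerprint_length)) < cfg.bit_flip_rate
    bits = prototypes[drug_clusters] ^ flips.astype(np.int8)

    disease_clusters = rng.integers(0, cfg.n_clusters, size=cfg.k)
    disease_clusters[: cfg.n_clusters] = np.arange(cfg.n_clusters)
    same = target_clusters[:, None] == disease_clusters[None, :]
    P = (same & (rng.random((cfg.n, cfg.k)) < cfg.disease_edge_prob)).astype(np.int8)

    drug_ids = [f"D{i:04d}" for i in range(1, cfg.m + 1)]
    target_ids = [f"hsa{j:04d}" for j in range(1, cfg.n + 1)]
    disease_ids = [f"OMIM{s:04d}" for s in range(1, cfg.k + 1)]
    assignments = {
        "drug_clusters": drug_clusters,
        "target_clusters": target_clusters,
        "disease_clusters": disease_clusters,
    }
    return (
        InteractionMatrix(drug_ids, target_ids, Y),
        FingerprintSet(drug_ids, bits),
        DiseaseProfileMatrix(target_ids, disease_ids, P),
        assignments,
    )
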
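"""Similarity matrices: Tanimoto chemical similarity, Gaussian
interaction-profile (GIP) kernels, and their convex fusion.

The drug-side similarity combines the GIP kernel over drug interaction
profiles (rows of the adjacency matrix) with Tanimoto similarity over
binary fingerprints; the target-side similarity combines the GIP kernel
over target interaction profiles (columns of the adjacency matrix) with a
GIP kernel over target-disease association profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from thncdf.datatypes import (
    DiseaseProfileMatrix,
    FingerprintSet,
    InteractionMatrix,
    SimilarityMatrix,
)
from thncdf.exceptions import (
    AlignmentError,
    FeatureUnavailableError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GipParams",
    "FusionConfig",
    "tanimoto_matrix",
    "gip_bandwidth",
    "gip_kernel",
    "fuse_drug",
    "fuse_target",
    "compute_similarities",
    "fingerprints_from_smiles",
]


@dataclass
class GipParams:
    """Bandwidth scaling and degenerate-profile handling for the GIP kernel.

    ``zero_profile_policy`` controls pairs where *both* profiles are
    all-zero: ``formula`` keeps the literal kernel value (distance 0, hence
    similarity 1) while ``zero`` sets such off-diagonal entries to 0.
    """

    gamma_prime: float = 1.0
    zero_profile_policy: str = "formula"

    def __post_init__(self) -> None:
        if self.gamma_prime <= 0:
            raise ValidationError("gamma_prime must be > 0")
        if self.zero_profile_policy not in ("formula", "zero"):
            raise ValidationError(
                f"unknown zero_profile_policy {self.zero_profile_policy!r}"
            )


@dataclass
class FusionConfig:
    """Convex-combination weight for similarity fusion (default 0.5:0.5)."""

    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")


def tanimoto_matrix(fps: FingerprintSet) -> SimilarityMatrix:
    """All-pairs Tanimoto similarity: |x AND y| / |x OR y|.

    A pair of all-zero fingerprints has an undefined 0/0 ratio; it is
    defined as 0 off-diagonal and 1 on the diagonal.
    """
    B = fps.bits.astype(np.int64)
    inter = B @ B.T
    pop = B.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0  # exact symmetry despite float rounding
    return SimilarityMatrix(list(fps.drug_ids), S, name="tanimoto")


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float = 1.0) -> float:
    """Kernel bandwidth normalized by the mean squared profile norm.

    gamma = gamma_prime / ((1/m) * sum_i ||p_i||^2)
    """
    if gamma_prime <= 0:
        raise ValidationError("gamma_prime must be > 0")
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValidationError("profiles must be a non-empty 2-d matrix")
    mean_sq_norm = float((P * P).sum()) / P.shape[0]
    if mean_sq_norm == 0.0:
        raise ValidationError("degenerate profiles: bandwidth undefined")
    return gamma_prime / mean_sq_norm


def gip_kernel(
    profiles: np.ndarray,
    params: GipParams | None = None,
    ids: list[str] | None = None,
    name: str = "gip",
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel: exp(-gamma * ||p_i - p_j||^2)."""
    params = params or GipParams()
    P = np.asarray(profiles, dtype=float)
    gamma = gip_bandwidth(P, params.gamma_prime)
    sq_norms = (P * P).sum(axis=1)
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.clip(d2, 0.0, None, out=d2)  # cancellation can leave tiny negatives
    S = np.exp(-gamma * d2)
    np.fill_diagonal(S, 1.0)
    if params.zero_profile_policy == "zero":
        zero = sq_norms == 0
        if zero.any():
            both_zero = np.outer(zero, zero)
            np.fill_diagonal(both_zero, False)
            S[both_zero] = 0.0
    S = (S + S.T) / 2.0
    if ids is None:
        ids = [str(i) for i in range(P.shape[0])]
    return SimilarityMatrix(list(ids), S, name=name)


def _fuse(a: SimilarityMatrix, b: SimilarityMatrix, alpha: float, name: str) -> SimilarityMatrix:
    if a.ids != b.ids:
        diff = sorted(set(a.ids) ^ set(b.ids))
        raise AlignmentError(
            "similarity matrices are not aligned; symmetric difference of "
            f"identifiers: {diff[:10]}" + ("..." if len(diff) > 10 else "")
            if diff
            else "similarity matrices share identifiers but in different order"
        )
    S = (1.0 - alpha) * a.S + alpha * b.S
    return SimilarityMatrix(list(a.ids), S, name=name)


def fuse_drug(
    k_gip_d: SimilarityMatrix,
    sim_chem: SimilarityMatrix,
    cfg: FusionConfig | None = None,
) -> SimilarityMatrix:
    """SIM_drug = (1 - alpha) * K_GIP,drug + alpha * SIM_chem."""
    cfg = cfg or FusionConfig()
    return _fuse(k_gip_d, sim_chem, cfg.alpha, name="sim_drug")


def fuse_target(
    k_gip_t: SimilarityMatrix,
    k_gip_ts: SimilarityMatrix,
    cfg: FusionConfig | None = None,
) -> SimilarityMatrix:
    """SIM_tar = (1 - alpha) * K_GIP,target + alpha * K_GIP,disease."""
    cfg = cfg or FusionConfig()
    return _fuse(k_gip_t, k_gip_ts, cfg.alpha, name="sim_tar")


def compute_similarities(
    interactions: InteractionMatrix,
    fingerprints: FingerprintSet,
    disease_profiles: DiseaseProfileMatrix | None = None,
    *,
    alpha_drug: float = 0.5,
    alpha_target: float = 0.5,
    gamma_prime_drug: float = 1.0,
    gamma_prime_target: float = 1.0,
    gamma_prime_disease: float = 1.0,
    zero_profile_policy: str = "formula",
    allow_missing_fingerprints: bool = False,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Compute the fused drug and target similarity matrices end to end.

    Fingerprints are aligned to the interaction matrix's drug order.
    Targets absent from the disease data carry all-zero disease profiles;
    when no disease data is supplied at all, the target similarity falls
    back to the interaction-profile GIP kernel alone.
    """
    fps = fingerprints.reindex(
        interactions.drug_ids, allow_missing=allow_missing_fingerprints
    )
    if allow_missing_fingerprints:
        n_zero = int((fps.bits.sum(axis=1) == 0).sum())
        if n_zero:
            logger.warning("%d drugs have no fingerprint; using all-zero vectors", n_zero)

    sim_chem = tanimoto_matrix(fps)
    k_gip_d = gip_kernel(
        interactions.drug_profiles(),
        GipParams(gamma_prime_drug, zero_profile_policy),
        ids=interactions.drug_ids,
        name="k_gip_drug",
    )
    sim_drug = fuse_drug(k_gip_d, sim_chem, FusionConfig(alpha_drug))

    k_gip_t = gip_kernel(
        interactions.target_profiles(),
        GipParams(gamma_prime_target, zero_profile_policy),
        ids=interactions.target_ids,
        name="k_gip_target",
    )
    if disease_profiles is None:
        logger.warning("no target-disease data; target similarity uses GIP kernel only")
        sim_tar = SimilarityMatrix(list(interactions.target_ids), k_gip_t.S, name="sim_tar")
    else:
        ts = disease_profiles.aligned_profiles(interactions.target_ids)
        k_gip_ts = gip_kernel(
            ts,
            GipParams(gamma_prime_disease, zero_profile_policy),
            ids=interactions.target_ids,
            name="k_gip_disease",
        )
        sim_tar = fuse_target(k_gip_t, k_gip_ts, FusionConfig(alpha_target))
    return sim_drug, sim_tar


def fingerprints_from_smiles(
    smiles_table: list[tuple[str, str]], length: int = 166
) -> FingerprintSet:
    """Structural-key fingerprints from SMILES strings (requires rdkit).

    Uses 166-bit MACCS structural keys (the toolkit's key 0 is a padding
    bit and is dropped).
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import MACCSkeys
    except ImportError as exc:  # pragma: no cover - exercised only without rdkit
        raise FeatureUnavailableError(
            "SMILES fingerprinting requires rdkit; install with "
            "'pip install thncdf[chem]'"
        ) from exc
    if length != 166:
        raise ValidationError("structural-key fingerprints are 166 bits")
    drug_ids: list[str] = []
    rows: list[np.ndarray] = []
    for drug, smiles in smiles_table:
        mol = Chem.MolFromSmiles(smiles) if smiles else None
        if mol is None:
            raise ValidationError(f"unparseable SMILES for drug {drug!r}: {smiles!r}")
        keys = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
        bits = np.zeros(167, dtype=np.int8)
        bits[list(keys.GetOnBits())] = 1
        drug_ids.append(drug)
        rows.append(bits[1:])
    if not drug_ids:
        raise ValidationError("empty SMILES table")
    return FingerprintSet(drug_ids, np.vstack(rows))
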
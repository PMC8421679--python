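"""Core domain types: adjacency, fingerprints, disease profiles, similarities.

All matrices are dense ``numpy`` arrays; identifier lists are plain Python
lists of unique strings whose order fixes the row/column order of the
associated matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from thncdf.exceptions import ValidationError

__all__ = [
    "InteractionMatrix",
    "FingerprintSet",
    "DiseaseProfileMatrix",
    "SimilarityMatrix",
]

_SYMMETRY_TOL = 1e-12


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} identifiers: {dups}")


def _check_binary(M: np.ndarray, what: str) -> None:
    if M.size and not np.isin(M, (0, 1)).all():
        bad = np.argwhere(~np.isin(M, (0, 1)))[0]
        raise ValidationError(
            f"{what} must be binary; found value {M[tuple(bad)]!r} at {tuple(bad)}"
        )


@dataclass
class InteractionMatrix:
    """Binary drug x target adjacency matrix with identifier lists.

    ``Y[i, j] == 1`` iff drug ``drug_ids[i]`` is known to interact with
    target ``target_ids[j]``.
    """

    drug_ids: list[str]
    target_ids: list[str]
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        if self.Y.ndim != 2:
            raise ValidationError("interaction matrix must be 2-dimensional")
        m, n = self.Y.shape
        if m < 1 or n < 1:
            raise ValidationError("interaction matrix must be non-empty")
        if len(self.drug_ids) != m or len(self.target_ids) != n:
            raise ValidationError(
                f"identifier counts ({len(self.drug_ids)}, {len(self.target_ids)}) "
                f"do not match matrix shape {self.Y.shape}"
            )
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.target_ids, "target")
        _check_binary(self.Y, "interaction matrix")
        self.Y = self.Y.astype(np.int8, copy=False)

    @property
    def n_drugs(self) -> int:
        return self.Y.shape[0]

    @property
    def n_targets(self) -> int:
        return self.Y.shape[1]

    @property
    def n_interactions(self) -> int:
        return int(self.Y.sum())

    def drug_profiles(self) -> np.ndarray:
        """Interaction profile of each drug: the rows of Y."""
        return self.Y.astype(float)

    def target_profiles(self) -> np.ndarray:
        """Interaction profile of each target: the columns of Y."""
        return self.Y.T.astype(float)

    def summary(self) -> dict:
        """Dataset statistics: counts, drug/target ratio, interaction count."""
        return {
            "n_drugs": self.n_drugs,
            "n_targets": self.n_targets,
            "drug_target_ratio": round(self.n_drugs / self.n_targets, 2),
            "n_interactions": self.n_interactions,
        }


@dataclass
class FingerprintSet:
    """Fixed-length binary chemical fingerprints, one row per drug."""

    drug_ids: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        if self.bits.ndim != 2:
            raise ValidationError("fingerprint array must be 2-dimensional")
        if self.bits.shape[1] < 1:
            raise ValidationError("fingerprint length must be >= 1")
        if len(self.drug_ids) != self.bits.shape[0]:
            raise ValidationError("drug_ids length does not match fingerprint rows")
        _check_unique(self.drug_ids, "drug")
        _check_binary(self.bits, "fingerprints")
        self.bits = self.bits.astype(np.int8, copy=False)

    @property
    def length(self) -> int:
        return self.bits.shape[1]

    def reindex(self, drug_ids: list[str], allow_missing: bool = False) -> "FingerprintSet":
        """Reorder rows to ``drug_ids``; optionally pad missing drugs with zeros."""
        pos = {d: i for i, d in enumerate(self.drug_ids)}
        missing = [d for d in drug_ids if d not in pos]
        if missing and not allow_missing:
            raise ValidationError(
                f"fingerprints missing for drugs: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        out = np.zeros((len(drug_ids), self.length), dtype=np.int8)
        for i, d in enumerate(drug_ids):
            if d in pos:
                out[i] = self.bits[pos[d]]
        return FingerprintSet(list(drug_ids), out)


@dataclass
class DiseaseProfileMatrix:
    """Binary target x disease association matrix."""

    target_ids: list[str]
    disease_ids: list[str]
    P: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P)
        if self.P.ndim != 2:
            raise ValidationError("disease profile matrix must be 2-dimensional")
        if self.P.shape != (len(self.target_ids), len(self.disease_ids)):
            raise ValidationError(
                f"shape {self.P.shape} does not match identifier counts "
                f"({len(self.target_ids)}, {len(self.disease_ids)})"
            )
        _check_unique(self.target_ids, "target")
        _check_unique(self.disease_ids, "disease")
        _check_binary(self.P, "disease profiles")
        self.P = self.P.astype(np.int8, copy=False)

    @property
    def n_diseases(self) -> int:
        return self.P.shape[1]

    def aligned_profiles(self, target_ids: list[str]) -> np.ndarray:
        """Disease profiles row-aligned to ``target_ids``.

        Targets absent from the association data get an all-zero profile.
        """
        pos = {t: i for i, t in enumerate(self.target_ids)}
        out = np.zeros((len(target_ids), self.n_diseases), dtype=float)
        for i, t in enumerate(target_ids):
            if t in pos:
                out[i] = self.P[pos[t]]
        return out


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with entity identifiers."""

    ids: list[str]
    S: np.ndarray
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ValidationError(f"similarity matrix must be square, got {self.S.shape}")
        if len(self.ids) != self.S.shape[0]:
            raise ValidationError("ids length does not match matrix size")
        _check_unique(self.ids, "entity")
        if self.S.size:
            asym = float(np.abs(self.S - self.S.T).max())
            if asym > _SYMMETRY_TOL:
                raise ValidationError(f"similarity matrix not symmetric (max |S-S'| = {asym:g})")
            lo, hi = float(self.S.min()), float(self.S.max())
            if lo < -_SYMMETRY_TOL or hi > 1 + _SYMMETRY_TOL:
                raise ValidationError(f"similarity entries outside [0, 1]: min={lo}, max={hi}")
            np.clip(self.S, 0.0, 1.0, out=self.S)

    @property
    def n(self) -> int:
        return self.S.shape[0]
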
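"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are plain tab-separated text:

* interaction matrix — header row of column identifiers, one label column,
  binary body (the dialect used by the standard DTI benchmark distribution,
  which places targets on rows and drugs on columns);
* fingerprints — two columns: drug identifier, contiguous {0,1} bitstring;
* target-disease associations — two-column edge list;
* similarity matrices — square labelled matrix, floats with 17 significant
  digits so round-trips are lossless to well below 1e-12;
* predictions — three columns: drug_id, target_id, score;
* fitted models — a single versioned joblib container.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np

from thncdf.datatypes import (
    DiseaseProfileMatrix,
    FingerprintSet,
    InteractionMatrix,
    SimilarityMatrix,
)
from thncdf.exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = "thncdf-model-1"

__all__ = [
    "read_interactions",
    "write_interactions",
    "read_fingerprints",
    "write_fingerprints",
    "read_target_disease",
    "write_target_disease",
    "read_similarity",
    "write_similarity",
    "write_predictions",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]


def _read_labelled_matrix(path: str | Path) -> tuple[list[str], list[str], list[list[str]]]:
    """Parse a labelled TSV matrix into (row_ids, col_ids, body cells)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    # Header may or may not carry a leading cell over the label column.
    col_ids = header[1:] if header and header[0] == "" else header
    row_ids: list[str] = []
    cells: list[list[str]] = []
    width: int | None = None
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected a label and at least one value")
        if width is None:
            width = len(parts)
            if len(col_ids) == width:  # header had no cell over the labels
                col_ids = col_ids[-(width - 1):]
        elif len(parts) != width:
            raise ParseError(
                f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {width})"
            )
        row_ids.append(parts[0])
        cells.append(parts[1:])
    if width is not None and len(col_ids) != width - 1:
        raise ParseError(
            f"{path}: header declares {len(col_ids)} columns but rows have {width - 1}"
        )
    return row_ids, col_ids, cells


def _parse_binary_body(
    path: str | Path, row_ids: list[str], col_ids: list[str], cells: list[list[str]]
) -> np.ndarray:
    M = np.empty((len(row_ids), len(col_ids)), dtype=np.int8)
    for i, row in enumerate(cells):
        for j, cell in enumerate(row):
            v = cell.strip()
            if v == "0":
                M[i, j] = 0
            elif v == "1":
                M[i, j] = 1
            else:
                raise ParseError(
                    f"{path}: non-binary cell {cell!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}"
                )
    return M


def _looks_like_drug(identifier: str) -> bool:
    return identifier.startswith("D")


def _looks_like_target(identifier: str) -> bool:
    return identifier.startswith("hsa")


def read_interactions(
    path: str | Path, orientation: str = "auto"
) -> InteractionMatrix:
    """Read a labelled binary adjacency matrix.

    ``orientation`` selects which axis holds the drugs.  Under ``auto`` the
    identifier prefixes decide ("D..." identifiers are drugs, "hsa..." are
    targets); when the heuristic is inconclusive the benchmark default
    (drugs on columns) is used and a warning is logged.
    """
    if orientation not in ("auto", "drugs_as_columns", "drugs_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    row_ids, col_ids, cells = _read_labelled_matrix(path)
    M = _parse_binary_body(path, row_ids, col_ids, cells)

    if orientation == "auto":
        cols_drugs = sum(_looks_like_drug(c) for c in col_ids) + sum(
            _looks_like_target(r) for r in row_ids
        )
        rows_drugs = sum(_looks_like_drug(r) for r in row_ids) + sum(
            _looks_like_target(c) for c in col_ids
        )
        if cols_drugs > rows_drugs:
            orientation = "drugs_as_columns"
        elif rows_drugs > cols_drugs:
            orientation = "drugs_as_rows"
        else:
            logger.warning(
                "%s: cannot infer orientation from identifier prefixes; "
                "assuming drugs on columns",
                path,
            )
            orientation = "drugs_as_columns"

    if orientation == "drugs_as_columns":
        return InteractionMatrix(drug_ids=col_ids, target_ids=row_ids, Y=M.T)
    return InteractionMatrix(drug_ids=row_ids, target_ids=col_ids, Y=M)


def write_interactions(
    path: str | Path, im: InteractionMatrix, drugs_as_columns: bool = True
) -> None:
    """Write an adjacency matrix in the labelled-TSV dialect."""
    if drugs_as_columns:
        row_ids, col_ids, M = im.target_ids, im.drug_ids, im.Y.T
    else:
        row_ids, col_ids, M = im.drug_ids, im.target_ids, im.Y
    with open(path, "w") as fh:
        fh.write("\t".join([""] + list(col_ids)) + "\n")
        for rid, row in zip(row_ids, M):
            fh.write(rid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_fingerprints(path: str | Path, length: int = 166) -> FingerprintSet:
    """Read a two-column TSV of drug identifier + {0,1} bitstring."""
    if length < 1:
        raise ValidationError("fingerprint length must be >= 1")
    path = Path(path)
    drug_ids: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if ln.strip() == "":
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
        drug, bitstring = parts[0], parts[1].strip()
        if len(bitstring) != length:
            raise ValidationError(
                f"{path}: drug {drug!r} has a bitstring of length "
                f"{len(bitstring)}, expected {length}"
            )
        if set(bitstring) - {"0", "1"}:
            raise ValidationError(
                f"{path}: drug {drug!r} has non-binary characters in its bitstring"
            )
        drug_ids.append(drug)
        rows.append(np.frombuffer(bitstring.encode(), dtype=np.uint8) - ord("0"))
    if not drug_ids:
        raise ValidationError(f"{path}: no fingerprints found")
    return FingerprintSet(drug_ids, np.vstack(rows))


def write_fingerprints(path: str | Path, fps: FingerprintSet) -> None:
    with open(path, "w") as fh:
        for drug, row in zip(fps.drug_ids, fps.bits):
            fh.write(drug + "\t" + "".join(str(int(b)) for b in row) + "\n")


def read_target_disease(path: str | Path) -> DiseaseProfileMatrix:
    """Read a (target_id, disease_id) edge list into a dense binary matrix.

    Duplicate edges collapse to a single association.  Row/column order is
    first-appearance order.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if ln.strip() == "":
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
        edges.append((parts[0].strip(), parts[1].strip()))
    if not edges:
        raise ValidationError(f"{path}: empty edge list (no diseases)")
    target_ids = list(dict.fromkeys(t for t, _ in edges))
    disease_ids = list(dict.fromkeys(s for _, s in edges))
    t_pos = {t: i for i, t in enumerate(target_ids)}
    s_pos = {s: i for i, s in enumerate(disease_ids)}
    P = np.zeros((len(target_ids), len(disease_ids)), dtype=np.int8)
    for t, s in edges:
        P[t_pos[t], s_pos[s]] = 1
    return DiseaseProfileMatrix(target_ids, disease_ids, P)


def write_target_disease(path: str | Path, dp: DiseaseProfileMatrix) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(dp.target_ids):
            for j, s in enumerate(dp.disease_ids):
                if dp.P[i, j]:
                    fh.write(f"{t}\t{s}\n")


def write_similarity(path: str | Path, sim: SimilarityMatrix) -> None:
    """Write a labelled square similarity matrix with lossless precision."""
    with open(path, "w") as fh:
        fh.write("\t".join([""] + list(sim.ids)) + "\n")
        for rid, row in zip(sim.ids, sim.S):
            fh.write(rid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_similarity(path: str | Path, name: str = "") -> SimilarityMatrix:
    row_ids, col_ids, cells = _read_labelled_matrix(path)
    if row_ids != col_ids:
        raise ParseError(
            f"{path}: similarity matrix must be square with matching "
            f"row/column identifiers ({len(row_ids)} rows, {len(col_ids)} columns)"
        )
    try:
        S = np.array([[float(c) for c in row] for row in cells], dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    return SimilarityMatrix(row_ids, S, name=name)


def write_predictions(
    path: str | Path,
    rows: Iterable[tuple[str, str, float]],
) -> None:
    """Write (drug_id, target_id, score) triples as a 3-column TSV."""
    with open(path, "w") as fh:
        fh.write("drug_id\ttarget_id\tscore\n")
        for drug, target, score in rows:
            fh.write(f"{drug}\t{target}\t{score:.17g}\n")


def save_model(path: str | Path, model: object) -> None:
    """Persist a fitted model as a single versioned container file."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: str | Path) -> object:
    container = joblib.load(path)
    if not isinstance(container, dict) or "format_version" not in container:
        raise ParseError(f"{path}: not a model container")
    if container["format_version"] != MODEL_FORMAT_VERSION:
        raise ParseError(
            f"{path}: unsupported model format {container['format_version']!r} "
            f"(expected {MODEL_FORMAT_VERSION!r})"
        )
    return container["model"]
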
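"""Readers and writers for the package's plain-text formats.

One dialect per format: tab-separated edge lists (associations and DAG
edges), comma-separated labelled dense matrices (similarities, scores,
expression). All files are UTF-8. Identifier matching is case-sensitive
and whitespace-stripped.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AssociationMatrix,
    DiseaseDAG,
    ExpressionMatrix,
    SimilarityMatrix,
    warn_data,
)

__all__ = [
    "read_association_edgelist",
    "write_association_edgelist",
    "read_dense_matrix",
    "write_dense_matrix",
    "write_score_matrix",
    "read_expression_matrix",
    "read_dag_edges",
]

#: float format preserving doubles exactly through a text round-trip
_FLOAT_FMT = "%.17g"


def read_association_edgelist(
    path: str | os.PathLike,
    all_lncrnas: Sequence[str] | None = None,
    all_diseases: Sequence[str] | None = None,
    header: bool = False,
) -> AssociationMatrix:
    """Load a two-column ``lncrna_id<TAB>disease_id`` edge list.

    Optional id lists fix the axis order and allow entities with no known
    association; otherwise axes follow first appearance in the file.
    Duplicate pairs are collapsed with a warning.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if header else None,
        names=["lncrna_id", "disease_id"],
        dtype=str,
        skip_blank_lines=True,
    )
    pairs = [
        (str(l).strip(), str(d).strip())
        for l, d in zip(df["lncrna_id"], df["disease_id"])
    ]

    if all_lncrnas is not None:
        lncrnas = [str(i).strip() for i in all_lncrnas]
    else:
        lncrnas = list(dict.fromkeys(l for l, _ in pairs))
    if all_diseases is not None:
        diseases = [str(i).strip() for i in all_diseases]
    else:
        diseases = list(dict.fromkeys(d for _, d in pairs))

    l_index = {v: i for i, v in enumerate(lncrnas)}
    d_index = {v: i for i, v in enumerate(diseases)}
    values = np.zeros((len(lncrnas), len(diseases)))
    seen: set[tuple[str, str]] = set()
    for l, d in pairs:
        if l not in l_index:
            raise ValueError(f"lncRNA id {l!r} not in the provided id list")
        if d not in d_index:
            raise ValueError(f"disease id {d!r} not in the provided id list")
        if (l, d) in seen:
            warn_data(f"duplicate association pair ({l}, {d}) collapsed")
            continue
        seen.add((l, d))
        values[l_index[l], d_index[d]] = 1.0
    return AssociationMatrix(lncrnas, diseases, values)


def write_association_edgelist(Y: AssociationMatrix, path: str | os.PathLike) -> None:
    """Write the 1-entries of a binary association matrix as an edge list."""
    if not Y.is_binary:
        raise ValueError("edge-list export requires a binary association matrix")
    rows, cols = np.nonzero(Y.values)
    with open(path, "w", encoding="utf-8") as fh:
        for r, c in zip(rows, cols):
            fh.write(f"{Y.lncrna_ids[r]}\t{Y.disease_ids[c]}\n")


def _read_labeled_csv(path: str | os.PathLike) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    row_ids = [str(i).strip() for i in df.index]
    col_ids = [str(c).strip() for c in df.columns]
    values = np.empty(df.shape)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {raw[i, j]!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}"
                ) from None
    return row_ids, col_ids, values


def read_dense_matrix(
    path: str | os.PathLike,
    symmetric_required: bool = False,
    role: str = "generic",
    as_association: bool = False,
    raw: bool = False,
):
    """Load a labelled dense CSV (header row of column ids, first column row ids).

    Returns a :class:`SimilarityMatrix` (optionally asserting symmetry within
    1e-8), an :class:`AssociationMatrix` with ``as_association=True``, or the
    bare ``(row_ids, col_ids, values)`` triple with ``raw=True`` (used for
    real-valued score matrices that fit neither typed container). Numbers are
    parsed with correct rounding, so matrices written at 17 significant
    digits round-trip bit-identically.
    """
    row_ids, col_ids, values = _read_labeled_csv(path)
    if raw:
        return row_ids, col_ids, values
    if as_association:
        return AssociationMatrix(row_ids, col_ids, values)
    if symmetric_required:
        if row_ids != col_ids:
            raise ValueError("symmetric matrix requires identical row/column ids")
        asym = np.abs(values - values.T).max() if values.size else 0.0
        if asym > 1e-8:
            raise ValueError(f"matrix asymmetric beyond tolerance (max {asym:g})")
        values = (values + values.T) / 2.0
    return SimilarityMatrix(row_ids, values, role=role)


def write_dense_matrix(
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    values: np.ndarray,
    path: str | os.PathLike,
) -> None:
    df = pd.DataFrame(values, index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, float_format=_FLOAT_FMT)


def write_score_matrix(
    scores,
    path: str | os.PathLike,
    lncrna_ids: Sequence[str] | None = None,
    disease_ids: Sequence[str] | None = None,
) -> None:
    """Serialize a predicted score matrix; round-trips exactly at 17 digits.

    ``scores`` is an :class:`AssociationMatrix` (or any labelled object with
    ``lncrna_ids``/``disease_ids``/``values``) or a bare array accompanied by
    the two id lists.
    """
    if hasattr(scores, "values") and hasattr(scores, "lncrna_ids"):
        values = np.asarray(scores.values, float)
        lncrna_ids, disease_ids = scores.lncrna_ids, scores.disease_ids
    else:
        values = np.asarray(scores, float)
        if lncrna_ids is None or disease_ids is None:
            raise ValueError("bare score arrays need explicit id lists")
    if not np.all(np.isfinite(values)):
        raise ValueError("score matrix contains non-finite entries")
    write_dense_matrix(lncrna_ids, disease_ids, values, path)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | os.PathLike) -> None:
    write_dense_matrix(sim.ids, sim.ids, sim.values, path)


def read_expression_matrix(path: str | os.PathLike) -> ExpressionMatrix:
    """Load a numeric lncRNA x sample CSV; missing values are an error."""
    row_ids, col_ids, values = _read_labeled_csv(path)
    return ExpressionMatrix(row_ids, col_ids, values)


def read_dag_edges(
    path: str | os.PathLike,
    node_list: Sequence[str] | None = None,
) -> DiseaseDAG:
    """Load a ``child_id<TAB>parent_id`` edge table as a disease DAG.

    ``node_list`` adds isolated nodes not mentioned by any edge. A cycle in
    the edge set raises with one offending cycle named.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["child_id", "parent_id"], dtype=str,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["child_id", "parent_id"])
    edges = {
        (str(c).strip(), str(p).strip())
        for c, p in zip(df["child_id"], df["parent_id"])
    }
    nodes = {e for pair in edges for e in pair}
    if node_list is not None:
        nodes |= {str(n).strip() for n in node_list}
    return DiseaseDAG(nodes, edges)
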
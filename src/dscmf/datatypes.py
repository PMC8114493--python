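"""Core domain containers for bipartite association prediction.

The package works with four labelled array types: a binary (or imputed)
lncRNA x disease association matrix, square similarity matrices tied to an
identifier list, a disease ontology DAG given as child->parent edges, and a
numeric lncRNA expression matrix. Validation happens at construction so
every downstream routine can assume well-formed inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseDAG",
    "ExpressionMatrix",
]

_SYM_TOL = 1e-8
_DIAG_TOL = 1e-8
#: similarity roles whose diagonal must be exactly one (up to tolerance)
_UNIT_DIAG_ROLES = frozenset({"expression", "semantic", "gip", "fused"})


def _check_unique(ids: list[str], axis_name: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate identifier {dup!r} on axis {axis_name}")


def _clean_ids(ids) -> list[str]:
    return [str(i).strip() for i in ids]


@dataclass
class AssociationMatrix:
    """Labelled lncRNA x disease incidence matrix.

    ``values`` holds 0/1 indicators for curated matrices, or reals in
    ``[0, 1]`` after WKNKN imputation.
    """

    lncrna_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lncrna_ids = _clean_ids(self.lncrna_ids)
        self.disease_ids = _clean_ids(self.disease_ids)
        _check_unique(self.lncrna_ids, "lncrna")
        _check_unique(self.disease_ids, "disease")
        self.values = np.asarray(self.values, dtype=float)
        expect = (len(self.lncrna_ids), len(self.disease_ids))
        if self.values.shape != expect:
            raise ValueError(
                f"association matrix shape {self.values.shape} != {expect}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("association matrix contains non-finite entries")
        if self.values.size and (
            self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise ValueError("association entries must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())

    def lncrna_index(self, lncrna: str) -> int:
        try:
            return self.lncrna_ids.index(lncrna)
        except ValueError:
            raise KeyError(f"unknown lncRNA id {lncrna!r}") from None

    def disease_index(self, disease: str) -> int:
        try:
            return self.disease_ids.index(disease)
        except ValueError:
            raise KeyError(f"unknown disease id {disease!r}") from None

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.lncrna_ids), list(self.disease_ids), self.values.copy()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationMatrix):
            return NotImplemented
        return (
            self.lncrna_ids == other.lncrna_ids
            and self.disease_ids == other.disease_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one identifier list.

    ``role`` tags the provenance of the matrix: ``expression`` (Spearman-based
    S^l), ``semantic`` (DAG-based S^d), ``gip`` (Gaussian interaction profile
    kernel), ``fused`` (convex combination K), or ``generic`` for matrices
    loaded from disk with unknown provenance. Roles other than ``generic``
    must have a unit diagonal.
    """

    ids: list[str]
    values: np.ndarray
    role: str = "generic"

    def __post_init__(self) -> None:
        self.ids = _clean_ids(self.ids)
        _check_unique(self.ids, "similarity")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity shape {self.values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix contains non-finite entries")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > _SYM_TOL:
            raise ValueError(f"similarity matrix asymmetric (max deviation {asym:g})")
        if self.role in _UNIT_DIAG_ROLES and n:
            dev = np.abs(np.diag(self.values) - 1.0).max()
            if dev > _DIAG_TOL:
                raise ValueError(
                    f"role {self.role!r} requires unit diagonal (max deviation {dev:g})"
                )

    @property
    def n(self) -> int:
        return len(self.ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimilarityMatrix):
            return NotImplemented
        return self.ids == other.ids and np.array_equal(self.values, other.values)


@dataclass
class DiseaseDAG:
    """Disease ontology fragment as a parent DAG.

    ``parent_edges`` holds ``(child, parent)`` pairs; following edges walks
    from a disease toward the ontology root(s). The graph must be acyclic.
    """

    nodes: set[str]
    parent_edges: set[tuple[str, str]]
    _graph: nx.DiGraph = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = {str(n).strip() for n in self.nodes}
        self.parent_edges = {
            (str(c).strip(), str(p).strip()) for c, p in self.parent_edges
        }
        for child, parent in self.parent_edges:
            for endpoint in (child, parent):
                if endpoint not in self.nodes:
                    raise ValueError(f"edge endpoint {endpoint!r} not in node set")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.parent_edges)  # child -> parent direction
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"disease graph contains a cycle: {cycle}")
        self._graph = g

    def parents(self, node: str) -> set[str]:
        self._require(node)
        return set(self._graph.successors(node))

    def children(self, node: str) -> set[str]:
        self._require(node)
        return set(self._graph.predecessors(node))

    def ancestors(self, node: str) -> set[str]:
        """All nodes reachable by repeatedly following parent edges."""
        self._require(node)
        return set(nx.descendants(self._graph, node))

    def _require(self, node: str) -> None:
        if node not in self.nodes:
            raise KeyError(f"unknown disease id {node!r}")


@dataclass
class ExpressionMatrix:
    """lncRNA x sample numeric expression profiles (e.g. tissue RNA-seq)."""

    lncrna_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lncrna_ids = _clean_ids(self.lncrna_ids)
        self.sample_ids = _clean_ids(self.sample_ids)
        _check_unique(self.lncrna_ids, "lncrna")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        expect = (len(self.lncrna_ids), len(self.sample_ids))
        if self.values.shape != expect:
            raise ValueError(f"expression shape {self.values.shape} != {expect}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")


def warn_data(message: str) -> None:
    """Emit a data-quality warning with the package's category."""
    warnings.warn(message, category=UserWarning, stacklevel=3)
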
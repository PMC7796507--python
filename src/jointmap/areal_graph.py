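"""Areal adjacency structure and intrinsic-CAR (ICAR) primitives.

The spatial resolution of the model is the *district*: an undirected graph
whose nodes are district labels and whose edges encode geographic adjacency.
All spatially structured random effects live on this graph under an
intrinsic conditional autoregressive (Besag) prior, which penalises squared
differences across edges and is identified by a sum-to-zero constraint on
each connected component.

The edge-list dialect is plain text: one edge per line (two whitespace
separated labels), ``#`` comments, and ``node <id>`` lines declaring
isolated districts.  Isolates are legal but their field values are pinned
to zero (the ICAR prior carries no information for them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "DistrictGraph",
    "read_edge_list",
    "write_edge_list",
    "build_lattice_graph",
    "icar_pairwise_penalty",
    "icar_log_density",
    "sample_icar",
]


@dataclass(frozen=True)
class DistrictGraph:
    """Undirected district adjacency graph with deterministic node order.

    District ids are stored in lexicographic order so vector positions are
    reproducible across runs.  Edges are deduplicated index pairs (i < j).
    """

    district_ids: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    component_labels: np.ndarray = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(self.district_ids) < 2:
            raise ValueError("a district graph needs at least 2 districts")
        if len(set(self.district_ids)) != len(self.district_ids):
            raise ValueError("duplicate district ids")
        J = len(self.district_ids)
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at district {self.district_ids[i]!r}")
            if not (0 <= i < J and 0 <= j < J):
                raise ValueError("edge endpoint outside district index range")
        labels = _component_labels(J, self.edges)
        object.__setattr__(self, "component_labels", labels)

    # -- basic structure ---------------------------------------------------
    @property
    def n_districts(self) -> int:
        return len(self.district_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1

    @property
    def neighbor_counts(self) -> np.ndarray:
        deg = np.zeros(self.n_districts, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def index_of(self, district_id: str) -> int:
        try:
            return self._index[district_id]
        except AttributeError:
            object.__setattr__(
                self, "_index", {d: k for k, d in enumerate(self.district_ids)}
            )
            return self._index[district_id]

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian L = D - A (J is at most a few hundred)."""
        J = self.n_districts
        L = np.zeros((J, J))
        for i, j in self.edges:
            L[i, i] += 1.0
            L[j, j] += 1.0
            L[i, j] -= 1.0
            L[j, i] -= 1.0
        return L

    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Neighbour lists in CSR layout (indptr, indices) for compiled code."""
        J = self.n_districts
        nbrs: list[list[int]] = [[] for _ in range(J)]
        for i, j in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        indptr = np.zeros(J + 1, dtype=np.int64)
        for k in range(J):
            indptr[k + 1] = indptr[k] + len(nbrs[k])
        indices = np.fromiter(
            (j for lst in nbrs for j in sorted(lst)), dtype=np.int64, count=indptr[-1]
        )
        return indptr, indices


def _component_labels(J: int, edges: Sequence[tuple[int, int]]) -> np.ndarray:
    if edges:
        rows = np.array([e[0] for e in edges] + [e[1] for e in edges])
        cols = np.array([e[1] for e in edges] + [e[0] for e in edges])
        A = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(J, J))
    else:
        A = csr_matrix((J, J))
    _, labels = connected_components(A, directed=False)
    # relabel so component ids appear in order of first district
    order: dict[int, int] = {}
    out = np.empty(J, dtype=np.int64)
    for k, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[k] = order[lab]
    return out


def _from_labelled_edges(
    ids: set[str], label_edges: set[tuple[str, str]]
) -> DistrictGraph:
    ordered = tuple(sorted(ids))
    index = {d: k for k, d in enumerate(ordered)}
    idx_edges = sorted(
        {tuple(sorted((index[a], index[b]))) for a, b in label_edges}
    )
    return DistrictGraph(ordered, tuple(idx_edges))


def read_edge_list(path) -> DistrictGraph:
    """Parse a plain-text edge list into a :class:`DistrictGraph`.

    Each non-comment line is either ``A B`` (an edge) or ``node A`` (an
    isolated district declaration).  Edges are symmetrised and deduplicated;
    self-loops are rejected.
    """
    ids: set[str] = set()
    edges: set[tuple[str, str]] = set()
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "node":
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'node <id>', got {raw!r}")
            ids.add(parts[1])
            continue
        if len(parts) != 2:
            raise ValueError(
                f"line {lineno}: expected two district labels, got {raw!r}"
            )
        a, b = parts
        if a == b:
            raise ValueError(f"line {lineno}: self-loop on district {a!r}")
        ids.update((a, b))
        edges.add((a, b))
    if not ids:
        raise ValueError(f"no districts found in {path}")
    return _from_labelled_edges(ids, edges)


def write_edge_list(graph: DistrictGraph, path) -> None:
    """Emit the same dialect :func:`read_edge_list` consumes (round-trip safe)."""
    lines = ["# district adjacency edge list"]
    touched = np.zeros(graph.n_districts, dtype=bool)
    for i, j in graph.edges:
        lines.append(f"{graph.district_ids[i]} {graph.district_ids[j]}")
        touched[i] = touched[j] = True
    for k, did in enumerate(graph.district_ids):
        if not touched[k]:
            lines.append(f"node {did}")
    Path(path).write_text("\n".join(lines) + "\n")


def build_lattice_graph(rows: int, cols: int) -> DistrictGraph:
    """Rook-adjacency ``rows x cols`` lattice with zero-padded labels.

    Used for synthetic scenarios standing in for a real district map
    (e.g. a 4 x 13 lattice has 52 districts).
    """
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise ValueError("lattice needs rows >= 1, cols >= 1 and at least 2 cells")
    J = rows * cols
    width = len(str(J - 1))
    ids = tuple(f"d{k:0{width}d}" for k in range(J))
    edges = []
    for r in range(rows):
        for c in range(cols):
            k = r * cols + c
            if c + 1 < cols:
                edges.append((k, k + 1))
            if r + 1 < rows:
                edges.append((k, k + cols))
    return DistrictGraph(ids, tuple(sorted(tuple(sorted(e)) for e in edges)))


def icar_pairwise_penalty(u: np.ndarray, graph: DistrictGraph) -> float:
    """Besag pairwise penalty: sum over edges of (u_j - u_l)^2 = u' L u."""
    u = np.asarray(u, dtype=float)
    if u.shape != (graph.n_districts,):
        raise ValueError(
            f"field length {u.shape} does not match J={graph.n_districts}"
        )
    total = 0.0
    for i, j in graph.edges:
        d = u[i] - u[j]
        total += d * d
    return float(total)


def _check_sum_to_zero(u: np.ndarray, graph: DistrictGraph, tol: float) -> None:
    for c in range(graph.n_components):
        s = float(u[graph.component_labels == c].sum())
        if abs(s) > tol:
            raise ValueError(
                f"ICAR field violates sum-to-zero on component {c} (sum={s:.3g})"
            )


def icar_log_density(u: np.ndarray, tau: float, graph: DistrictGraph) -> float:
    """Log-density of the intrinsic CAR prior, up to an additive constant.

    ((J - C)/2) log tau - (tau/2) * penalty, with C the number of connected
    components (the rank deficiency of the Laplacian).  The field must sum
    to zero on each component.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    u = np.asarray(u, dtype=float)
    _check_sum_to_zero(u, graph, 1e-8)
    J, C = graph.n_districts, graph.n_components
    return 0.5 * (J - C) * np.log(tau) - 0.5 * tau * icar_pairwise_penalty(u, graph)


def sample_icar(graph: DistrictGraph, tau: float, seed) -> np.ndarray:
    """Draw one realisation of the intrinsic Gaussian field at precision tau.

    Expands iid standard normals on the Laplacian eigenvectors with positive
    eigenvalue, scaled by 1/sqrt(tau * lambda_i); the covariance is the
    Laplacian pseudo-inverse divided by tau.  Each connected component is
    re-centred to sum exactly to zero; isolates stay at 0.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = graph.laplacian()
    lam, V = np.linalg.eigh(L)
    pos = lam > 1e-9 * max(lam.max(), 1.0)
    z = rng.standard_normal(int(pos.sum()))
    u = V[:, pos] @ (z / np.sqrt(tau * lam[pos]))
    for c in range(graph.n_components):
        mask = graph.component_labels == c
        u[mask] -= u[mask].mean()
    return u
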
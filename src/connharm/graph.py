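"""Connectome graph construction.

The connectome is represented as an undirected, unweighted graph whose nodes
are the vertices of a cortical surface mesh.  Edges come in two classes:

* **local** edges -- the triangle edges of the surface mesh (each interior
  vertex of a regular triangulation has six nearest neighbours), and
* **long-range** edges -- white-matter cortico-cortical / thalamo-cortical
  fibre tracts, given as pairs of endpoint coordinates that are snapped to
  their nearest mesh vertices.

The adjacency matrix ``A`` is symmetric with zero diagonal and entries in
{0, 1}.  Randomized controls redraw only the long-range edges, preserving the
local anatomical structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceMesh",
    "FiberEndpoints",
    "ConnectomeGraph",
    "mesh_local_edges",
    "map_endpoints_to_vertices",
    "build_graph",
    "randomize_long_range",
]


def _canonical_edges(pairs) -> np.ndarray:
    """Sort each pair (low, high) and lexicographically sort + deduplicate rows.

    Returns an ``(m, 2)`` int64 array; empty input gives shape ``(0, 2)``.
    """
    arr = np.asarray(pairs, dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = arr.reshape(-1, 2)
    arr = np.sort(arr, axis=1)
    return np.unique(arr, axis=0)


@dataclass
class SurfaceMesh:
    """A triangulated surface (or an explicit-edge, face-free fixture mesh).

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in millimetres, in the native frame of the mesh.
    faces : (m, 3) int array
        Triangles as vertex-index triples.  May be empty for degenerate
        fixture meshes (e.g. a ring) whose local edges are given explicitly.
    edges : (k, 2) int array, optional
        Explicit local edges; required when ``faces`` is empty.
    hemisphere : (n,) array, optional
        Per-vertex hemisphere tag (e.g. "lh"/"rh").  Local edges are only
        ever drawn within a face/edge list, so hemisphere separation is a
        property of the inputs, not enforced here.
    """

    vertices: np.ndarray
    faces: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    edges: np.ndarray | None = None
    hemisphere: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidInputError(
                f"vertices must be (n, 3); got shape {self.vertices.shape}"
            )
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        n = self.n_vertices
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= n:
                raise InvalidInputError("face vertex index out of range")
            degenerate = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degenerate.any():
                raise InvalidInputError(
                    f"{int(degenerate.sum())} degenerate face(s) with repeated vertices"
                )
        if self.edges is not None:
            self.edges = _canonical_edges(self.edges)
            if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= n):
                raise InvalidInputError("edge vertex index out of range")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]


@dataclass
class FiberEndpoints:
    """Streamline endpoint coordinate pairs with tracking provenance.

    ``start`` and ``end`` are (m, 3) arrays in the mesh coordinate frame.
    The tractography parameters (FA threshold, minimum tract length, maximum
    step angle, seeds per vertex) are provenance metadata only: they document
    how the endpoints were produced and are never used in any computation.
    """

    start: np.ndarray
    end: np.ndarray
    fa_threshold: float | None = None
    min_length_mm: float | None = None
    max_angle_deg: float | None = None
    seeds_per_vertex: int | None = None

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.float64).reshape(-1, 3)
        self.end = np.asarray(self.end, dtype=np.float64).reshape(-1, 3)
        if self.start.shape != self.end.shape:
            raise InvalidInputError("start/end endpoint arrays differ in shape")
        if not (np.isfinite(self.start).all() and np.isfinite(self.end).all()):
            raise InvalidInputError("fiber endpoint coordinates must be finite")

    def __len__(self) -> int:
        return self.start.shape[0]


@dataclass
class ConnectomeGraph:
    """Undirected unweighted graph with local and long-range edge classes."""

    n: int
    local_edges: np.ndarray
    long_range_edges: np.ndarray

    def __post_init__(self) -> None:
        self.local_edges = _canonical_edges(self.local_edges)
        self.long_range_edges = _canonical_edges(self.long_range_edges)
        for arr, name in ((self.local_edges, "local"), (self.long_range_edges, "long-range")):
            if arr.size:
                if arr.min() < 0 or arr.max() >= self.n:
                    raise InvalidInputError(f"{name} edge index out of range for n={self.n}")
                if (arr[:, 0] == arr[:, 1]).any():
                    raise InvalidInputError(f"{name} edges contain a self-loop")
        # an edge that is both local and long-range is tagged local
        if self.local_edges.size and self.long_range_edges.size:
            local_keys = self.local_edges[:, 0] * self.n + self.local_edges[:, 1]
            lr_keys = self.long_range_edges[:, 0] * self.n + self.long_range_edges[:, 1]
            keep = ~np.isin(lr_keys, local_keys)
            self.long_range_edges = self.long_range_edges[keep]

    @property
    def edges(self) -> np.ndarray:
        """All edges (canonical order), local first then long-range."""
        return np.vstack([self.local_edges, self.long_range_edges])

    @property
    def n_edges(self) -> int:
        return self.local_edges.shape[0] + self.long_range_edges.shape[0]

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency matrix with zero diagonal (CSR)."""
        e = self.edges
        if e.size == 0:
            return sp.csr_matrix((self.n, self.n))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        data = np.ones(rows.shape[0], dtype=np.float64)
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency(), directed=False)
        return n_comp == 1

    def largest_component_mask(self) -> np.ndarray:
        """Boolean mask of the largest connected component (ties: component of
        the lowest-index vertex among the largest)."""
        n_comp, labels = connected_components(self.adjacency(), directed=False)
        if n_comp == 1:
            return np.ones(self.n, dtype=bool)
        counts = np.bincount(labels, minlength=n_comp)
        best = int(np.argmax(counts))  # argmax takes the lowest label on ties
        return labels == best


def mesh_local_edges(mesh: SurfaceMesh) -> np.ndarray:
    """Local edge set of a mesh: the union of its triangle edges.

    For face-free fixture meshes the explicitly stored edges are returned.
    Edges are deduplicated and in canonical (sorted-pair, lexicographic) order.
    """
    if mesh.n_vertices == 0:
        raise InvalidInputError("mesh has no vertices")
    if mesh.faces.size == 0:
        if mesh.edges is None or mesh.edges.size == 0:
            raise InvalidInputError("mesh has neither faces nor explicit edges")
        return mesh.edges.copy()
    f = mesh.faces
    pairs = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [0, 2]]])
    return _canonical_edges(pairs)


def map_endpoints_to_vertices(
    mesh: SurfaceMesh, fibers: FiberEndpoints, chunk: int = 2048
) -> np.ndarray:
    """Snap each fibre's two endpoints to their nearest mesh vertices.

    Nearest is Euclidean; exact ties go to the lower vertex index.  Fibres
    whose endpoints snap to the same vertex are dropped (self-loops are
    excluded from the graph) with a logged count.

    Returns an ``(m, 2)`` array of vertex-index pairs, one row per surviving
    fibre, in input order.
    """
    if len(fibers) == 0:
        raise InvalidInputError("no fibers given")
    pts = np.vstack([fibers.start, fibers.end])
    nearest = np.empty(pts.shape[0], dtype=np.int64)
    verts = mesh.vertices
    for lo in range(0, pts.shape[0], chunk):
        block = pts[lo : lo + chunk]
        # brute-force scan keeps the lowest-index tie-break exact
        d2 = ((block[:, None, :] - verts[None, :, :]) ** 2).sum(axis=2)
        nearest[lo : lo + block.shape[0]] = np.argmin(d2, axis=1)
    m = len(fibers)
    pairs = np.column_stack([nearest[:m], nearest[m:]])
    keep = pairs[:, 0] != pairs[:, 1]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d fiber(s) whose endpoints map to the same vertex", n_dropped)
    return pairs[keep]


def build_graph(mesh: SurfaceMesh, long_range_pairs=None) -> ConnectomeGraph:
    """Assemble the connectome graph from mesh edges plus long-range pairs.

    Duplicate and reversed pairs collapse to single undirected edges; a pair
    that coincides with a mesh edge is tagged local.  Emits a warning if the
    resulting graph is disconnected.
    """
    local = mesh_local_edges(mesh)
    n = mesh.n_vertices
    if long_range_pairs is None:
        lr = np.empty((0, 2), dtype=np.int64)
    else:
        lr = np.asarray(long_range_pairs, dtype=np.int64).reshape(-1, 2)
        if lr.size:
            if lr.min() < 0 or lr.max() >= n:
                raise InvalidInputError("long-range vertex index out of range")
            if (lr[:, 0] == lr[:, 1]).any():
                raise InvalidInputError("long-range pair is a self-loop")
    g = ConnectomeGraph(n=n, local_edges=local, long_range_edges=lr)
    if not g.is_connected():
        warnings.warn(
            "connectome graph is disconnected; downstream eigenanalysis will "
            "use the largest connected component",
            stacklevel=2,
        )
    return g


def _admissible_pairs(n: int, local_edges: np.ndarray) -> np.ndarray:
    """All unordered non-self pairs that are not local edges, as (m, 2)."""
    iu = np.triu_indices(n, k=1)
    pairs = np.column_stack(iu).astype(np.int64)
    if local_edges.size:
        keys = pairs[:, 0] * n + pairs[:, 1]
        local_keys = local_edges[:, 0] * n + local_edges[:, 1]
        pairs = pairs[~np.isin(keys, local_keys)]
    return pairs


def randomize_long_range(
    graph: ConnectomeGraph, seed: int, method: str = "uniform"
) -> ConnectomeGraph:
    """Rewired control: randomize the long-range edges, keeping local edges.

    The local edge set is preserved exactly and the number of long-range
    edges is conserved.  Deterministic per seed.

    ``method="uniform"`` (default) redraws endpoints uniformly (without
    replacement) over all non-local, non-self unordered pairs.
    ``method="degree_preserving"`` instead performs double-edge swaps among
    the long-range edges only, preserving each vertex's long-range degree.
    """
    m = graph.long_range_edges.shape[0]
    if m == 0:
        return ConnectomeGraph(
            n=graph.n,
            local_edges=graph.local_edges.copy(),
            long_range_edges=graph.long_range_edges.copy(),
        )
    rng = np.random.default_rng(seed)
    if method == "uniform":
        admissible = _admissible_pairs(graph.n, graph.local_edges)
        if m > admissible.shape[0]:
            raise InvalidInputError(
                f"cannot place {m} long-range edges among "
                f"{admissible.shape[0]} admissible pairs"
            )
        chosen = rng.choice(admissible.shape[0], size=m, replace=False)
        new_lr = admissible[np.sort(chosen)]
    elif method == "degree_preserving":
        new_lr = _double_edge_swap(graph, rng, n_swaps=10 * m)
    else:
        raise InvalidInputError(f"unknown randomization method {method!r}")
    return ConnectomeGraph(
        n=graph.n, local_edges=graph.local_edges.copy(), long_range_edges=new_lr
    )


def _double_edge_swap(graph: ConnectomeGraph, rng, n_swaps: int) -> np.ndarray:
    """Swap endpoint pairs (a,b),(c,d) -> (a,d),(c,b) among long-range edges,
    rejecting swaps that create self-loops, duplicates, or local edges."""
    n = graph.n
    lr = [tuple(p) for p in graph.long_range_edges]
    local_keys = set(
        int(a) * n + int(b) for a, b in graph.local_edges
    )
    present = set(int(a) * n + int(b) for a, b in lr)
    m = len(lr)
    done = 0
    attempts = 0
    while done < n_swaps and attempts < 100 * n_swaps:
        attempts += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = lr[i]
        c, d = lr[j]
        e1 = (min(a, d), max(a, d))
        e2 = (min(c, b), max(c, b))
        if a == d or c == b:
            continue
        k1 = e1[0] * n + e1[1]
        k2 = e2[0] * n + e2[1]
        if k1 == k2 or k1 in present or k2 in present:
            continue
        if k1 in local_keys or k2 in local_keys:
            continue
        present.discard(a * n + b if a < b else b * n + a)
        present.discard(c * n + d if c < d else d * n + c)
        present.add(k1)
        present.add(k2)
        lr[i] = e1
        lr[j] = e2
        done += 1
    return _canonical_edges(lr)
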
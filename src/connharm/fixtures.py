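"""Synthetic inputs with known ground truth.

Real analyses consume a reconstructed cortical surface, tractography
endpoint tables and reference network parcellations.  None of those can be
bundled, so this module fabricates structurally analogous stand-ins:

* a **ring** "mesh" (a cycle graph with vertices on a circle) whose
  Laplacian eigenbasis is the classical discrete Fourier basis -- the
  analytic oracle for everything spectral;
* an **icosphere** -- a closed, connected, consistently oriented
  triangulated sphere standing in for the curved cortical sheet;
* **planted long-range edges** -- random non-mesh vertex pairs standing in
  for fibre tracts;
* **planted binary maps** -- indicator maps thresholded from a chosen
  harmonic, so the best-matching harmonic is known by construction.

All generation is a pure function of its arguments: same spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import InvalidFixtureError
from .graph import SurfaceMesh, _admissible_pairs, mesh_local_edges

__all__ = [
    "FixtureSpec",
    "make_ring_mesh",
    "make_icosphere",
    "plant_long_range",
    "plant_binary_map",
    "make_fixture_graph",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic connectome fixture."""

    kind: str = "icosphere"  # ring | icosphere
    n_vertices: int = 42  # ring size, or closest icosphere size
    n_long_range: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ring", "icosphere"):
            raise InvalidFixtureError(f"unknown fixture kind {self.kind!r}")
        if self.n_vertices < 4:
            raise InvalidFixtureError("fixtures need at least 4 vertices")
        if self.n_long_range < 0:
            raise InvalidFixtureError("n_long_range must be non-negative")


def make_ring_mesh(n: int) -> SurfaceMesh:
    """Cycle graph of ``n`` vertices placed on the unit circle.

    A degenerate face-free "mesh": vertex ``i`` is adjacent to ``i±1 mod n``,
    so every vertex has degree exactly 2.  Its combinatorial Laplacian has
    the closed-form spectrum ``2 - 2 cos(2 pi j / n)`` with discrete Fourier
    eigenvectors, which makes it the analytic test geometry.
    """
    if n < 4:
        raise InvalidFixtureError(f"ring mesh needs n >= 4, got {n}")
    theta = 2.0 * np.pi * np.arange(n) / n
    vertices = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
    edges = np.column_stack([np.arange(n), (np.arange(n) + 1) % n])
    return SurfaceMesh(vertices=vertices, faces=np.empty((0, 3), dtype=np.int64), edges=edges)


def make_icosphere(subdivisions: int = 2, radius: float = 1.0) -> SurfaceMesh:
    """Closed triangulated sphere by Loop-style subdivision of an icosahedron.

    ``subdivisions=0`` gives the icosahedron (12 vertices, 30 edges, 20
    faces); each subdivision adds one vertex per edge (V' = V + E), so
    subdivision counts are 12, 42, 162, 642, ...  Euler characteristic
    V - E + F = 2 by construction.
    """
    if subdivisions < 0:
        raise InvalidFixtureError("subdivisions must be >= 0")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(
        vertices=np.asarray(m.vertices, dtype=np.float64),
        faces=np.asarray(m.faces, dtype=np.int64),
    )


def plant_long_range(mesh: SurfaceMesh, n_edges: int, seed: int) -> np.ndarray:
    """Draw ``n_edges`` distinct random vertex pairs that are not mesh edges.

    The synthetic analogue of long-range fibre connections.  Pairs are
    distinct, non-self, not adjacent on the mesh, and reproducible per seed.
    """
    if n_edges < 0:
        raise InvalidFixtureError("n_edges must be non-negative")
    if n_edges == 0:
        return np.empty((0, 2), dtype=np.int64)
    local = mesh_local_edges(mesh)
    admissible = _admissible_pairs(mesh.n_vertices, local)
    if n_edges > admissible.shape[0]:
        raise InvalidFixtureError(
            f"requested {n_edges} long-range edges but only "
            f"{admissible.shape[0]} non-mesh pairs exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(admissible.shape[0], size=n_edges, replace=False)
    return admissible[np.sort(chosen)]


def plant_binary_map(basis, j: int, threshold_quantile: float = 0.5):
    """Binary per-vertex map: indicator of harmonic ``j`` above a quantile.

    By construction the resulting map is best matched by harmonic ``j``
    itself, giving an end-to-end ground truth for the matching pipeline.
    Quantile ties are broken by vertex index (stable sort), so the constant
    harmonic ``j=0`` yields a deterministic split.

    Returns a :class:`~connharm.match.BinaryCorticalMap`.
    """
    from .match import BinaryCorticalMap

    psi = np.asarray(basis.eigenvectors)
    n, k = psi.shape
    if not 0 <= j < k:
        raise IndexError(f"harmonic index {j} out of range for basis of size {k}")
    if not 0.0 < threshold_quantile < 1.0:
        raise InvalidFixtureError("threshold_quantile must be in (0, 1)")
    v = psi[:, j]
    order = np.argsort(v, kind="stable")  # ties resolved by vertex index
    cutoff = int(np.floor(threshold_quantile * n))
    values = np.zeros(n, dtype=np.int8)
    values[order[cutoff:]] = 1
    return BinaryCorticalMap(values=values, name=f"planted_h{j}")


def make_fixture_graph(spec: FixtureSpec):
    """Build (mesh, graph) for a :class:`FixtureSpec`.

    For ``kind="icosphere"`` the subdivision level with vertex count closest
    to ``n_vertices`` is used (counts are 12, 42, 162, 642, ...).
    """
    from .graph import build_graph

    if spec.kind == "ring":
        mesh = make_ring_mesh(spec.n_vertices)
    else:
        counts = [12, 42, 162, 642, 2562, 10242]
        sub = int(np.argmin([abs(c - spec.n_vertices) for c in counts]))
        mesh = make_icosphere(subdivisions=sub)
    lr = plant_long_range(mesh, spec.n_long_range, spec.seed)
    return mesh, build_graph(mesh, lr)
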
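"""Connectome Laplacian and its eigenbasis (connectome harmonics).

Given the 0/1 adjacency matrix ``A`` of the connectome graph and its degree
matrix ``D``, two symmetric Laplacians are supported:

* ``combinatorial``:         L = D - A           (zero row sums)
* ``symmetric_normalized``:  L = D^{-1/2} (D - A) D^{-1/2}  (unit diagonal)

The connectome harmonics are the eigenvectors psi_j of L, ordered by
ascending eigenvalue lambda_j (the spatial "wavenumber").  On a connected
graph lambda_0 = 0 with a constant (combinatorial) eigenvector; on a cycle
graph the basis coincides with the discrete Fourier basis, which is the
sense in which the harmonics extend Fourier analysis to the connectome.

Both normalizations are symmetric; which one a study intends is ambiguous
in general, so every basis records the normalization it was computed with.
The default is ``symmetric_normalized``.

Eigenvector sign is mathematically arbitrary; here it is fixed by requiring
the largest-magnitude entry of each eigenvector to be positive (ties broken
by the lower vertex index), so outputs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import InvalidInputError, NumericalError
from .graph import ConnectomeGraph

__all__ = [
    "LaplacianMatrix",
    "HarmonicBasis",
    "connectome_laplacian",
    "compute_harmonics",
    "NORMALIZATIONS",
]

NORMALIZATIONS = ("combinatorial", "symmetric_normalized")

# below this size the dense symmetric eigensolver is both faster and more
# accurate than iterative sparse methods
_DENSE_CUTOFF = 2500


@dataclass
class LaplacianMatrix:
    """Sparse symmetric Laplacian with its normalization tag and degrees."""

    matrix: sp.csr_matrix
    normalization: str
    degrees: np.ndarray
    vertex_mask: np.ndarray | None = None  # mask into the original graph, if restricted

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def lambda_max_bound(self) -> float:
        """Cheap deterministic upper bound on the largest eigenvalue."""
        if self.normalization == "symmetric_normalized":
            return 2.0
        return 2.0 * float(self.degrees.max()) if self.degrees.size else 0.0


@dataclass
class HarmonicBasis:
    """Ascending eigenpairs (lambda_j, psi_j) of a connectome Laplacian.

    ``eigenvectors`` is an (n, k) array with orthonormal columns of unit L2
    norm.  Indexing is 0-based internally; :meth:`wavenumber` reports the
    conventional 1-based count in which the constant lambda=0 mode is
    harmonic #1.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    normalization: str
    vertex_mask: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[1]

    def wavenumber(self, j: int) -> int:
        """1-based harmonic number of internal index ``j`` (constant mode = 1)."""
        return j + 1

    def degenerate_groups(self, tol: float = 1e-10) -> list[np.ndarray]:
        """Indices grouped by (near-)equal eigenvalues.

        Within such a group the individual eigenvectors are only defined up
        to rotation, so comparisons should be made on subspaces.
        """
        groups: list[list[int]] = [[0]]
        for j in range(1, self.k):
            if self.eigenvalues[j] - self.eigenvalues[groups[-1][0]] < tol:
                groups[-1].append(j)
            else:
                groups.append([j])
        return [np.asarray(g) for g in groups]


def connectome_laplacian(
    graph: ConnectomeGraph, normalization: str = "symmetric_normalized"
) -> LaplacianMatrix:
    """Build the connectome Laplacian from a graph.

    If the graph is disconnected, the Laplacian is restricted to the largest
    connected component and the retained-vertex mask is recorded (computing
    eigenpairs across components would mix their constant vectors).
    Isolated vertices make the symmetric normalized form undefined.
    """
    if normalization not in NORMALIZATIONS:
        raise InvalidInputError(
            f"normalization must be one of {NORMALIZATIONS}, got {normalization!r}"
        )
    mask = None
    adj = graph.adjacency()
    if not graph.is_connected():
        mask = graph.largest_component_mask()
        adj = adj[mask][:, mask]
    deg = np.asarray(adj.sum(axis=1)).ravel()
    if normalization == "symmetric_normalized" and (deg == 0).any():
        raise InvalidInputError(
            "symmetric normalized Laplacian is undefined for isolated (zero-degree) vertices"
        )
    D = sp.diags(deg)
    L = (D - adj).tocsr()
    if normalization == "symmetric_normalized":
        dinv = sp.diags(1.0 / np.sqrt(deg))
        L = (dinv @ L @ dinv).tocsr()
    L = ((L + L.T) * 0.5).tocsr()  # enforce exact symmetry
    return LaplacianMatrix(matrix=L, normalization=normalization, degrees=deg, vertex_mask=mask)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip columns so the largest-magnitude entry is positive (ties: lowest index)."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def compute_harmonics(
    laplacian: LaplacianMatrix,
    k: int,
    residual_tol: float = 1e-8,
) -> HarmonicBasis:
    """Compute the ``k`` lowest eigenpairs of a connectome Laplacian.

    Uses a dense symmetric solver for small problems and shift-invert
    Lanczos for large sparse ones.  Postconditions checked: per-pair
    residual ``||L psi - lambda psi||_2 <= residual_tol`` and column
    orthonormality to the same tolerance.
    """
    n = laplacian.n
    if not 1 <= k <= n:
        raise InvalidInputError(f"k must satisfy 1 <= k <= n={n}, got {k}")
    L = laplacian.matrix
    if n <= _DENSE_CUTOFF or k >= n - 1:
        vals, vecs = scipy.linalg.eigh(L.toarray(), subset_by_index=[0, k - 1])
    else:
        try:
            # shift-invert around a point just below the spectrum; L itself is
            # singular so a small negative shift keeps the factorization stable
            vals, vecs = spla.eigsh(L.tocsc(), k=k, sigma=-1e-2, which="LM")
        except Exception as exc:  # pragma: no cover - solver-dependent
            raise NumericalError(f"sparse eigensolver failed: {exc}") from exc
        order = np.argsort(vals, kind="stable")
        vals, vecs = vals[order], vecs[:, order]
    # roundoff can make the zero eigenvalue come out at -1e-16; clamp it
    vals = np.where((vals < 0) & (vals > -1e-10), 0.0, vals)
    vecs = _fix_signs(np.ascontiguousarray(vecs))

    resid = np.linalg.norm(L @ vecs - vecs * vals[None, :], axis=0)
    if resid.max() > residual_tol:
        raise NumericalError(
            f"eigenpair residual {resid.max():.3e} exceeds tolerance {residual_tol:.1e}"
        )
    gram_err = np.abs(vecs.T @ vecs - np.eye(k)).max()
    if gram_err > residual_tol:
        raise NumericalError(f"eigenvectors not orthonormal (max deviation {gram_err:.3e})")
    return HarmonicBasis(
        eigenvalues=vals,
        eigenvectors=vecs,
        normalization=laplacian.normalization,
        vertex_mask=laplacian.vertex_mask,
    )
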
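"""Spectral components (SPCs) of the IBD relatedness graph.

The graph adjacency A is transformed into the symmetrically normalized
Laplacian

    L_sym = I - D+^(1/2) A D+^(1/2)

where D is the degree diagonal and D+ its Moore-Penrose inverse, so a
vertex with no neighbours contributes an identity row (eigen-pair (1, e_i))
rather than a division by zero.  All eigenvalues of L_sym lie in [0, 2].

SPCs are the eigenvectors belonging to the *smallest* eigenvalues.  Small
eigenvalues correspond to slowly varying functions on the graph: the lambda
= 0 eigenvector of a connected graph is proportional to D^(1/2)*1 (degree
signal), additional zero eigenvalues indicate connected components, and the
first non-trivial eigenvectors partition the graph along its weakest cuts
(the Fiedler-vector property).  Used as fixed-effect covariates, these
coordinates encode recent, localized population structure that linear
principal components of the genotype matrix smooth over.

Numerically, the k smallest eigen-pairs of L_sym are obtained from the k
*largest* eigen-pairs of M = D+^(1/2) A D+^(1/2) via lambda = 1 - mu, which
is much better conditioned for Lanczos iteration than a shift-invert solve
near zero.  Graphs with n <= 2000 vertices are solved densely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .ibd_graph import (
    AdjacencyMatrix,
    aggregate_pairwise,
    build_graph,
    to_adjacency,
)
from .io_core import SampleTable, read_ibd_segments

__all__ = [
    "LaplacianOperator",
    "SpectralBasis",
    "build_laplacian",
    "compute_spcs",
    "spcs_from_ibd",
]

#: graphs at or below this size are decomposed densely
DENSE_LIMIT = 2000

#: eigenvalues below this are treated as exactly zero ("trivial")
ZERO_TOL = 1e-10


@dataclass
class LaplacianOperator:
    """Symmetrically normalized Laplacian with its degree information."""

    L_sym: sp.csr_matrix
    degrees: np.ndarray
    samples: Optional[SampleTable] = None

    @property
    def n(self) -> int:
        return self.L_sym.shape[0]


@dataclass
class SpectralBasis:
    """Eigen-pairs of the normalized Laplacian, ascending in eigenvalue.

    ``vectors[:, j]`` is the unit eigenvector of ``eigenvalues[j]``; the
    sign of each column is fixed so its largest-magnitude entry is positive
    (ties broken by lowest index).  Within a degenerate eigenspace the
    basis is an arbitrary orthonormal one.
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray
    k: int
    sign_convention: str = "largest-entry-positive"
    source: Optional[dict] = None

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


def build_laplacian(A: Union[AdjacencyMatrix, sp.spmatrix]) -> LaplacianOperator:
    """L_sym = I - D+^(1/2) A D+^(1/2) from a symmetric adjacency matrix."""
    samples = None
    if isinstance(A, AdjacencyMatrix):
        samples = A.samples
        A = A.A
    A = sp.csr_matrix(A)
    if (A != A.T).nnz != 0:
        raise ValueError("adjacency matrix is not exactly symmetric")
    if A.nnz and A.data.min() < 0:
        raise ValueError("adjacency matrix has negative weights")
    if np.abs(A.diagonal()).max(initial=0.0) != 0:
        raise ValueError("adjacency matrix has a non-zero diagonal")

    degrees = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(degrees > 0, 1.0 / np.sqrt(np.where(degrees > 0, degrees, 1.0)), 0.0)
    Dp = sp.diags(inv_sqrt)
    L = sp.identity(A.shape[0], format="csr") - Dp @ A @ Dp
    # enforce exact symmetry against floating round-off in the triple product
    L = ((L + L.T) * 0.5).tocsr()
    return LaplacianOperator(L_sym=L, degrees=degrees, samples=samples)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip columns so the largest-magnitude entry of each is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)  # first maximum -> lowest index
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def compute_spcs(
    L: Union[LaplacianOperator, sp.spmatrix],
    k: int,
    seed: int = 0,
    skip_trivial: bool = False,
) -> SpectralBasis:
    """The k eigen-pairs of smallest eigenvalue, ascending.

    Zero eigenvalues are included by default (their eigenvectors encode
    degree and component membership, both structure signal);
    ``skip_trivial`` drops eigenvalues below 1e-10 for callers that supply
    their own intercept.  Deterministic for a fixed ``seed``, which sets
    the Lanczos start vector of the sparse path.
    """
    if not isinstance(L, LaplacianOperator):
        L = build_laplacian_from_Lsym(L)
    n = L.n
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n={n}")

    n_extra = 0
    while True:
        kk = min(k + n_extra, n if n <= DENSE_LIMIT else n - 1)
        vals, vecs = _smallest_eigenpairs(L, kk, seed)
        if not skip_trivial:
            break
        nz = int((vals < ZERO_TOL).sum())
        if kk - nz >= k or kk == n - 1 or kk == n:
            vals, vecs = vals[nz:], vecs[:, nz:]
            break
        n_extra = nz + 1

    vals, vecs = vals[:k], vecs[:, :k]
    vecs = _fix_signs(vecs)
    return SpectralBasis(eigenvalues=vals, vectors=vecs, k=k, source={"n": n})


def build_laplacian_from_Lsym(Lsym: sp.spmatrix) -> LaplacianOperator:
    """Wrap an already-built L_sym (degree diagonal reconstructed as unknown)."""
    Lsym = sp.csr_matrix(Lsym)
    return LaplacianOperator(L_sym=Lsym, degrees=np.full(Lsym.shape[0], np.nan))


def _smallest_eigenpairs(L: LaplacianOperator, k: int, seed: int):
    n = L.n
    if n <= DENSE_LIMIT or k >= n - 1:
        vals, vecs = np.linalg.eigh(L.L_sym.toarray())
        return vals[:k].copy(), vecs[:, :k].copy()
    # sparse path: largest eigenvalues of M = I - L_sym, mapped back
    M = (sp.identity(n, format="csr") - L.L_sym).tocsr()
    v0 = np.random.default_rng(seed).standard_normal(n)
    try:
        mu, vecs = spla.eigsh(M, k=k, which="LA", v0=v0)
    except spla.ArpackNoConvergence as exc:
        raise RuntimeError(
            "sparse eigensolver did not converge; for graphs with "
            f"n <= {DENSE_LIMIT} a dense solve is used automatically -- "
            "consider reducing k or densifying manually"
        ) from exc
    vals = 1.0 - mu
    order = np.argsort(vals, kind="stable")
    return vals[order], vecs[:, order]


def spcs_from_ibd(
    ibd_path,
    dialect="generic6",
    threshold_cM: float = 6.0,
    k: int = 25,
    samples: Optional[SampleTable] = None,
    seed: int = 0,
    mode: str = "binary",
    skip_trivial: bool = False,
) -> SpectralBasis:
    """End-to-end: segment file -> pair totals -> graph -> Laplacian -> SPCs."""
    pairs = aggregate_pairwise(read_ibd_segments(ibd_path, dialect))
    graph = build_graph(pairs, threshold_cM=threshold_cM, mode=mode, samples=samples)
    if not graph.edges:
        raise ValueError(
            f"graph has no edges at threshold {threshold_cM} cM; "
            "lower the threshold or check the segment file"
        )
    adj = to_adjacency(graph)
    basis = compute_spcs(
        build_laplacian(adj), k=k, seed=seed, skip_trivial=skip_trivial
    )
    basis.source = {
        "threshold_cM": threshold_cM,
        "mode": mode,
        "n": graph.n_vertices,
        "n_edges": graph.n_edges,
    }
    return basis
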
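"""Pairwise IBD aggregation and the thresholded relatedness graph.

The central object here is the binary IBD relatedness graph: individuals
are vertices and an (undirected) edge joins two individuals whenever their
total genome-wide identity-by-descent sharing, summed over all segments and
all haplotype pairings, strictly exceeds a threshold (6 cM by default).
The adjacency matrix of this graph is the input to the spectral embedding
in :mod:`spc.spectral`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .io_core import SampleTable

__all__ = [
    "IBDSegment",
    "PairwiseIBD",
    "RelatednessGraph",
    "AdjacencyMatrix",
    "aggregate_pairwise",
    "build_graph",
    "to_adjacency",
    "graph_summary",
]


@dataclass(slots=True)
class IBDSegment:
    """One shared haplotype segment between two individuals.

    Coordinates are 1-based inclusive base pairs on an autosome; the
    genetic length in centimorgans is carried with the record and never
    recomputed from the physical span.
    """

    id_a: str
    id_b: str
    chromosome: int
    start_bp: int
    end_bp: int
    length_cM: float

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError(f"self-pair segment for sample {self.id_a!r}")
        if not 1 <= self.chromosome <= 22:
            raise ValueError(f"chromosome {self.chromosome} is not an autosome")
        if self.end_bp <= self.start_bp:
            raise ValueError(
                f"segment end {self.end_bp} not after start {self.start_bp}"
            )
        if self.length_cM < 0:
            raise ValueError(f"negative genetic length {self.length_cM}")

    @property
    def pair(self) -> Tuple[str, str]:
        """Unordered sample pair as a sorted tuple."""
        a, b = self.id_a, self.id_b
        return (a, b) if a <= b else (b, a)


@dataclass
class PairwiseIBD:
    """Aggregated genome-wide IBD totals per unordered pair of individuals.

    ``totals`` maps sorted ``(id_a, id_b)`` tuples to the summed segment
    length in cM.  All individuals seen in any segment are recorded in
    ``sample_ids`` so that downstream graphs can represent isolated
    vertices.
    """

    totals: Dict[Tuple[str, str], float] = field(default_factory=dict)
    sample_ids: set = field(default_factory=set)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def total_cM(self) -> float:
        return float(sum(self.totals.values()))


@dataclass
class RelatednessGraph:
    """Thresholded IBD relatedness graph over individuals.

    Edges are stored once as sorted id tuples.  In ``weighted`` mode the
    aggregated cM total of each retained edge is kept alongside.
    """

    samples: SampleTable
    edges: set
    threshold_cM: float
    mode: str = "binary"
    weights: Optional[Dict[Tuple[str, str], float]] = None

    @property
    def n_vertices(self) -> int:
        return len(self.samples)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class AdjacencyMatrix:
    """Sparse symmetric adjacency of a relatedness graph (zero diagonal)."""

    A: sp.csr_matrix
    samples: SampleTable

    @property
    def n(self) -> int:
        return self.A.shape[0]


def aggregate_pairwise(segments: Iterable[IBDSegment]) -> PairwiseIBD:
    """Sum segment lengths into per-pair genome-wide totals.

    Streaming: memory is proportional to the number of distinct sharing
    pairs, not to the number of segments.  Haplotype-level segments between
    the same two individuals (any chromosome, any haplotype pairing) all
    collapse onto one unordered individual pair.  Overlapping segments are
    summed, not merged.
    """
    out = PairwiseIBD()
    totals = out.totals
    ids = out.sample_ids
    for seg in segments:
        key = seg.pair
        totals[key] = totals.get(key, 0.0) + seg.length_cM
        ids.add(seg.id_a)
        ids.add(seg.id_b)
    return out


def build_graph(
    pairs: PairwiseIBD,
    threshold_cM: float = 6.0,
    mode: str = "binary",
    samples: Optional[SampleTable] = None,
    drop_isolated: bool = False,
) -> RelatednessGraph:
    """Threshold aggregated sharing into an undirected graph.

    An edge is present iff the pair total *strictly* exceeds
    ``threshold_cM``.  The vertex set is ``samples`` if given (so isolated
    vertices are representable), otherwise the sorted set of all
    individuals that appeared in any segment.
    """
    if threshold_cM < 0:
        raise ValueError("threshold_cM must be non-negative")
    if mode not in ("binary", "weighted"):
        raise ValueError(f"unknown mode {mode!r}")

    edges = set()
    weights: Dict[Tuple[str, str], float] = {}
    for key, total in pairs.totals.items():
        if total > threshold_cM:  # strict: the total must surpass the threshold
            edges.add(key)
            if mode == "weighted":
                weights[key] = total

    if samples is None:
        ids = sorted(pairs.sample_ids)
    else:
        ids = list(samples.sample_ids)
        known = set(ids)
        missing = {a for e in edges for a in e} - known
        if missing:
            raise ValueError(
                f"{len(missing)} samples in IBD data absent from supplied "
                f"sample table (e.g. {sorted(missing)[:3]})"
            )
    if drop_isolated:
        connected = {a for e in edges for a in e}
        ids = [i for i in ids if i in connected]

    return RelatednessGraph(
        samples=SampleTable(ids),
        edges=edges,
        threshold_cM=threshold_cM,
        mode=mode,
        weights=weights if mode == "weighted" else None,
    )


def to_adjacency(graph: RelatednessGraph) -> AdjacencyMatrix:
    """Sparse symmetric 0/1 (or cM-weighted) adjacency matrix."""
    n = graph.n_vertices
    index = graph.samples.index
    rows = np.empty(2 * len(graph.edges), dtype=np.int64)
    cols = np.empty_like(rows)
    vals = np.empty(2 * len(graph.edges), dtype=np.float64)
    for m, (a, b) in enumerate(graph.edges):
        i, j = index[a], index[b]
        w = 1.0 if graph.mode == "binary" else graph.weights[(a, b)]
        rows[2 * m], cols[2 * m], vals[2 * m] = i, j, w
        rows[2 * m + 1], cols[2 * m + 1], vals[2 * m + 1] = j, i, w
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return AdjacencyMatrix(A=A, samples=graph.samples)


def graph_summary(graph: RelatednessGraph) -> dict:
    """Exact vertex/edge/component counts and degree quantiles."""
    n = graph.n_vertices
    adj = to_adjacency(graph)
    degrees = np.asarray((adj.A != 0).sum(axis=1)).ravel()
    n_comp = connected_components(adj.A, directed=False)[0] if n else 0
    q = (
        np.quantile(degrees, [0.0, 0.25, 0.5, 0.75, 1.0]).tolist()
        if n
        else [0, 0, 0, 0, 0]
    )
    return {
        "n_vertices": n,
        "n_edges": graph.n_edges,
        "n_components": int(n_comp),
        "degree_quantiles": q,
        "n_isolated": int((degrees == 0).sum()),
    }
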
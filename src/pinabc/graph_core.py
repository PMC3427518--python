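"""Graph representation, adjacency spectra and edit-distance comparisons.

The central object is :class:`UndirectedGraph`, a simple labelled undirected
graph on nodes ``0..n-1``. Networks are compared through the spectra of their
adjacency matrices: for two graphs of equal size with ordered adjacency
eigenvalues ``a_i`` and ``b_i``, the quantity

    d(G1, G2) = sqrt( sum_i (a_i - b_i)**2 )

is a lower bound (due to Umeyama's theorem on Hermitian matrices) on the
permutation-minimized edit distance between the graphs, measured as the
number of differing adjacency-matrix entries over all ordered node pairs.
Because the spectrum is invariant under node relabelling, this distance is
zero for isomorphic graphs and requires no node correspondence — which is
what makes it usable as an ABC distance between unlabelled networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UndirectedGraph",
    "SpectralSummary",
    "adjacency_matrix",
    "spectrum",
    "spectral_distance",
    "labelled_edit_distance",
    "min_edit_distance_bruteforce",
    "degree_distribution",
    "fit_degree_exponent",
]

#: largest node count accepted by the factorial brute-force edit distance
BRUTEFORCE_LIMIT = 8


def _normalize_edge(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class UndirectedGraph:
    """A simple undirected graph on nodes ``0..node_count-1``.

    Self-loops and duplicate edges are rejected at construction. Isolated
    (degree-zero) nodes are first-class citizens: the node-sampling model
    produces them and they carry zero eigenvalues in the spectrum.
    """

    node_count: int
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.node_count < 0:
            raise ValueError("node_count must be nonnegative")
        normalized = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u} is not allowed")
            if not (0 <= u < self.node_count and 0 <= v < self.node_count):
                raise ValueError(
                    f"edge ({u}, {v}) has an endpoint outside 0..{self.node_count - 1}"
                )
            normalized.add(_normalize_edge(u, v))
        object.__setattr__(self, "edges", frozenset(normalized))

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        """Degree of every node, including zeros for isolated nodes."""
        deg = np.zeros(self.node_count, dtype=np.int64)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def relabel(self, permutation: np.ndarray) -> "UndirectedGraph":
        """Return the graph with node i renamed to ``permutation[i]``."""
        perm = np.asarray(permutation)
        if sorted(perm.tolist()) != list(range(self.node_count)):
            raise ValueError("permutation must be a bijection on 0..n-1")
        return UndirectedGraph(
            self.node_count,
            frozenset(_normalize_edge(int(perm[u]), int(perm[v])) for u, v in self.edges),
        )


@dataclass(frozen=True)
class SpectralSummary:
    """Adjacency eigenvalues sorted in descending order.

    The sum of the eigenvalues equals the trace of the adjacency matrix and
    is therefore zero (up to floating point error) for every simple graph.
    """

    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        object.__setattr__(self, "eigenvalues", ev)

    def __len__(self) -> int:
        return len(self.eigenvalues)


def adjacency_matrix(g: UndirectedGraph) -> np.ndarray:
    """Dense symmetric 0/1 adjacency matrix with zero diagonal."""
    a = np.zeros((g.node_count, g.node_count))
    for u, v in g.edges:
        a[u, v] = 1.0
        a[v, u] = 1.0
    return a


def spectrum(g: UndirectedGraph) -> SpectralSummary:
    """Eigenvalues of the adjacency matrix, sorted descending.

    Ties are left in whatever order the symmetric eigensolver produces;
    sorting makes tie order irrelevant to any downstream distance.
    """
    if g.node_count == 0:
        return SpectralSummary(np.empty(0))
    ev = np.linalg.eigvalsh(adjacency_matrix(g))
    return SpectralSummary(ev[::-1].copy())


def spectral_distance(
    g1: UndirectedGraph,
    g2: UndirectedGraph,
    *,
    pad: bool = False,
) -> float:
    """Euclidean distance between same-rank ordered adjacency eigenvalues.

    This is a lower bound on :func:`min_edit_distance_bruteforce` measured on
    the same (matrix-entry) scale, and is exactly zero for isomorphic graphs.

    Parameters
    ----------
    pad
        When True, the shorter spectrum is padded with zeros so graphs of
        unequal size can be compared. Off by default: in the intended
        workflow simulations are grown/sampled to the data's size, so a size
        mismatch normally indicates user error.
    """
    if g1.node_count != g2.node_count and not pad:
        raise ValueError(
            f"graphs have different node counts ({g1.node_count} vs "
            f"{g2.node_count}); grow/sample to equal size or pass pad=True"
        )
    e1 = spectrum(g1).eigenvalues
    e2 = spectrum(g2).eigenvalues
    if len(e1) != len(e2):
        n = max(len(e1), len(e2))
        e1 = _pad_sorted_desc(e1, n)
        e2 = _pad_sorted_desc(e2, n)
    return float(np.sqrt(np.sum((e1 - e2) ** 2)))


def _pad_sorted_desc(ev: np.ndarray, n: int) -> np.ndarray:
    """Insert zeros into a descending-sorted vector, keeping it sorted."""
    padded = np.concatenate([ev, np.zeros(n - len(ev))])
    return np.sort(padded)[::-1]


def labelled_edit_distance(g1: UndirectedGraph, g2: UndirectedGraph) -> int:
    """Number of differing adjacency entries over all ordered node pairs.

    Each undirected edge present in exactly one of the graphs contributes 2
    (the matrix is symmetric), keeping the count on the same scale as the
    spectral bound.
    """
    if g1.node_count != g2.node_count:
        raise ValueError(
            f"graphs have different node counts ({g1.node_count} vs {g2.node_count})"
        )
    return 2 * len(g1.edges.symmetric_difference(g2.edges))


def min_edit_distance_bruteforce(g1: UndirectedGraph, g2: UndirectedGraph) -> int:
    """Minimum labelled edit distance over all relabellings of ``g2``.

    Enumerates all ``n!`` node permutations, so it is restricted to
    ``n <= 8``. Intended as a validation oracle for the spectral lower
    bound, not for production-size graphs.
    """
    if g1.node_count != g2.node_count:
        raise ValueError(
            f"graphs have different node counts ({g1.node_count} vs {g2.node_count})"
        )
    n = g1.node_count
    if n > BRUTEFORCE_LIMIT:
        raise ValueError(
            f"brute-force minimization enumerates n! permutations and is "
            f"limited to n <= {BRUTEFORCE_LIMIT} (got {n}); it is meant as a "
            f"small-graph test oracle only"
        )
    best = labelled_edit_distance(g1, g2)
    for perm in itertools.permutations(range(n)):
        d = labelled_edit_distance(g1, g2.relabel(np.array(perm)))
        if d < best:
            best = d
            if best == 0:
                break
    return best


def degree_distribution(g: UndirectedGraph) -> np.ndarray:
    """Fraction of nodes at each degree, degree zero included.

    Entry ``k`` of the returned vector is the proportion of nodes with
    degree ``k``; the vector sums to one.
    """
    if g.node_count == 0:
        raise ValueError("degree distribution of an empty (0-node) graph is undefined")
    deg = g.degrees()
    counts = np.bincount(deg)
    return counts / g.node_count


def fit_degree_exponent(degrees: np.ndarray, k_min: int = 10) -> float:
    """Discrete maximum-likelihood power-law exponent of a degree tail.

    Fits ``P(k) ~ k**-a`` to the degrees ``k >= k_min`` using the discrete
    MLE with the standard continuous correction,

        a = 1 + n / sum(log(k / (k_min - 0.5))),

    which is accurate for tails a few units above ``k_min``.
    """
    k = np.asarray(degrees)
    k = k[k >= k_min]
    if len(k) < 2:
        raise ValueError(f"need at least 2 degrees >= {k_min} to fit a tail exponent")
    return float(1.0 + len(k) / np.sum(np.log(k / (k_min - 0.5))))
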
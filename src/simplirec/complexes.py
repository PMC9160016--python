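"""Data model for 2-simplicial complexes and synthetic generators.

A 2-simplicial complex is a collection of nodes, edges (1-simplexes) and
filled triangles (2-simplexes) satisfying the closure requirement: the three
edges of every triangle belong to the complex.  Three generator families are
provided, mirroring the classical random-graph models:

* :func:`generate_ersc` -- Erdős–Rényi-style random simplicial complex,
* :func:`generate_sfsc` -- scale-free (preferential attachment) backbone,
* :func:`generate_swsc` -- small-world (rewired ring lattice) backbone,

each decorated with triangles drawn independently over all node triples and
with the triangle edges merged into the edge set so closure holds by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import FrozenSet, Iterable, Set, Tuple

import networkx as nx
import numpy as np

Edge = Tuple[int, int]
Triangle = Tuple[int, int, int]

__all__ = [
    "SimplicialComplex2",
    "GeneratorParams",
    "generate_ersc",
    "generate_sfsc",
    "generate_swsc",
    "ersc_probabilities",
    "triangle_probability",
]


def _norm_edge(u: int, v: int) -> Edge:
    if u == v:
        raise ValueError(f"self-loop edge ({u}, {v})")
    return (u, v) if u < v else (v, u)


def _norm_triangle(u: int, v: int, w: int) -> Triangle:
    t = tuple(sorted((u, v, w)))
    if len(set(t)) != 3:
        raise ValueError(f"degenerate triangle ({u}, {v}, {w})")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class SimplicialComplex2:
    """A closure-valid 2-simplicial complex on nodes ``0 .. n_nodes-1``.

    Parameters
    ----------
    n_nodes
        Number of nodes.
    edges
        Unordered node pairs ``(u, v)`` with ``u < v``.
    triangles
        Unordered node triples ``(u, v, w)`` with ``u < v < w``.  Every
        triangle's three edges must be present in ``edges``.
    """

    n_nodes: int
    edges: FrozenSet[Edge]
    triangles: FrozenSet[Triangle]

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def from_iterables(
        cls,
        n_nodes: int,
        edges: Iterable[Tuple[int, int]],
        triangles: Iterable[Tuple[int, int, int]] = (),
    ) -> "SimplicialComplex2":
        """Build a complex, normalizing vertex order within each simplex."""
        e = frozenset(_norm_edge(*p) for p in edges)
        t = frozenset(_norm_triangle(*q) for q in triangles)
        return cls(n_nodes=n_nodes, edges=e, triangles=t)

    def validate(self) -> None:
        """Raise :class:`ValueError` on any violated structural invariant."""
        if self.n_nodes <= 0:
            raise ValueError("n_nodes must be positive")
        for u, v in self.edges:
            if not (0 <= u < v < self.n_nodes):
                raise ValueError(f"edge ({u}, {v}) out of range or unordered")
        for u, v, w in self.triangles:
            if not (0 <= u < v < w < self.n_nodes):
                raise ValueError(f"triangle ({u}, {v}, {w}) out of range or unordered")
            for a, b in combinations((u, v, w), 2):
                if (a, b) not in self.edges:
                    raise ValueError(
                        f"closure violated: triangle ({u}, {v}, {w}) "
                        f"lacks edge ({a}, {b})"
                    )

    # -- derived quantities -------------------------------------------------

    @property
    def k1(self) -> float:
        """Average two-body degree, ``2 |E| / N``."""
        return 2.0 * len(self.edges) / self.n_nodes

    @property
    def k2(self) -> float:
        """Average three-body degree, ``3 |T| / N``."""
        return 3.0 * len(self.triangles) / self.n_nodes

    def neighbors(self, i: int) -> Set[int]:
        """Nodes sharing an edge with ``i`` (the 1-simplex star of ``i``)."""
        out: Set[int] = set()
        for u, v in self.edges:
            if u == i:
                out.add(v)
            elif v == i:
                out.add(u)
        return out

    def triangles_of(self, i: int) -> Set[Triangle]:
        """Triangles incident on node ``i`` (the 2-simplex star of ``i``)."""
        return {t for t in self.triangles if i in t}

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix of the edge set."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        if self.edges:
            arr = np.array(sorted(self.edges), dtype=np.int64)
            a[arr[:, 0], arr[:, 1]] = 1
            a[arr[:, 1], arr[:, 0]] = 1
        return a

    def triangle_array(self) -> np.ndarray:
        """Triangles as an ``(n_tri, 3)`` integer array (possibly empty)."""
        if not self.triangles:
            return np.empty((0, 3), dtype=np.int64)
        return np.array(sorted(self.triangles), dtype=np.int64)

    def relabel(self, permutation: np.ndarray) -> "SimplicialComplex2":
        """Apply a node permutation (``new_label = permutation[old_label]``)."""
        p = np.asarray(permutation)
        edges = ((int(p[u]), int(p[v])) for u, v in self.edges)
        tris = ((int(p[u]), int(p[v]), int(p[w])) for u, v, w in self.triangles)
        return SimplicialComplex2.from_iterables(self.n_nodes, edges, tris)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters for the synthetic complex generators.

    ``k1_target`` drives the random (ER-style) edge probability; ``m`` is the
    edges-per-new-node for the scale-free model and the half-degree of the
    ring lattice for the small-world model; ``rewire_p`` is the Watts–Strogatz
    rewiring probability; ``k2_target`` sets the expected three-body degree.
    """

    n_nodes: int
    k1_target: float = 0.0
    m: int = 0
    rewire_p: float = 0.0
    k2_target: float = 0.0
    seed: int = 0


def ersc_probabilities(n_nodes: int, k1: float, k2: float) -> Tuple[float, float]:
    """Edge and triangle probabilities realizing the requested mean degrees.

    ``p1 = (k1 - 2 k2) / ((N - 1) - 2 k2)`` and
    ``p2 = 2 k2 / ((N - 1) (N - 2))``: each triangle contributes two edge
    stubs at each of its corners, so the pairwise probability is corrected
    downward to keep the expected two-body degree at ``k1``.
    """
    if k1 < 2.0 * k2:
        raise ValueError(
            f"need k1_target > 2*k2_target for a valid edge probability "
            f"(got k1={k1}, k2={k2})"
        )
    if (n_nodes - 1) <= 2.0 * k2:
        raise ValueError(
            f"need n_nodes - 1 > 2*k2_target for a positive denominator "
            f"(got N={n_nodes}, k2={k2})"
        )
    p1 = (k1 - 2.0 * k2) / ((n_nodes - 1) - 2.0 * k2)
    p2 = triangle_probability(n_nodes, k2)
    if not 0.0 <= p1 <= 1.0:
        raise ValueError(f"edge probability p1={p1} outside [0, 1]")
    return p1, p2


def triangle_probability(n_nodes: int, k2: float) -> float:
    """Per-triple triangle probability ``p2 = 2 k2 / ((N-1)(N-2))``."""
    if k2 < 0:
        raise ValueError("k2_target must be non-negative")
    p2 = 2.0 * k2 / ((n_nodes - 1) * (n_nodes - 2))
    if p2 > 1.0:
        raise ValueError(f"triangle probability p2={p2} exceeds 1")
    return p2


def _sample_triangles(n_nodes: int, p2: float, rng: np.random.Generator) -> Set[Triangle]:
    """Independent Bernoulli(p2) triangles over all C(N,3) triples.

    Sampled by thinning: draw the Binomial count of successes, then that many
    distinct triples uniformly at random.  Distributionally identical to the
    direct triple-by-triple draw but avoids the cubic loop.
    """
    if p2 <= 0.0 or n_nodes < 3:
        return set()
    total = n_nodes * (n_nodes - 1) * (n_nodes - 2) // 6
    count = int(rng.binomial(total, p2))
    chosen: Set[Triangle] = set()
    while len(chosen) < count:
        draw = rng.integers(0, n_nodes, size=(count - len(chosen) + 8, 3))
        for u, v, w in draw:
            if u != v and v != w and u != w:
                chosen.add(tuple(sorted((int(u), int(v), int(w)))))  # type: ignore[arg-type]
                if len(chosen) == count:
                    break
    return chosen


def _assemble(
    n_nodes: int, edges: Set[Edge], triangles: Set[Triangle]
) -> SimplicialComplex2:
    # union in the triangle faces so closure holds by construction
    for u, v, w in triangles:
        edges.add((u, v))
        edges.add((u, w))
        edges.add((v, w))
    return SimplicialComplex2(
        n_nodes=n_nodes, edges=frozenset(edges), triangles=frozenset(triangles)
    )


def generate_ersc(params: GeneratorParams) -> SimplicialComplex2:
    """Random 2-simplicial complex with target mean degrees.

    Pairwise edges are independent Bernoulli(p1) draws; triangles are
    independent Bernoulli(p2) draws over all triples, with their faces merged
    into the edge set.  The realized ``k1`` and ``k2`` are unbiased for the
    requested targets (up to the negligible overlap between Bernoulli edges
    and triangle faces).
    """
    n = params.n_nodes
    p1, p2 = ersc_probabilities(n, params.k1_target, params.k2_target)
    rng = np.random.default_rng(params.seed)
    iu, iv = np.triu_indices(n, k=1)
    mask = rng.random(iu.shape[0]) < p1
    edges: Set[Edge] = {(int(u), int(v)) for u, v in zip(iu[mask], iv[mask])}
    triangles = _sample_triangles(n, p2, rng)
    return _assemble(n, edges, triangles)


def generate_sfsc(params: GeneratorParams) -> SimplicialComplex2:
    """Scale-free 2-simplicial complex.

    A preferential-attachment (Barabási–Albert) backbone in which each new
    node attaches ``m`` edges to existing nodes with degree preference, grown
    from a star seed so the backbone has exactly ``m (N - m)`` edges, plus
    Bernoulli(p2) triangles.  The expected two-body degree is
    ``k1 = 2m + 2 k2 (1 - 2m / N)``.
    """
    n, m = params.n_nodes, params.m
    if m < 1 or n <= m:
        raise ValueError(f"need 1 <= m < n_nodes (got m={m}, N={n})")
    rng = np.random.default_rng(params.seed)
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    edges: Set[Edge] = {_norm_edge(int(u), int(v)) for u, v in g.edges()}
    p2 = triangle_probability(n, params.k2_target)
    triangles = _sample_triangles(n, p2, rng)
    return _assemble(n, edges, triangles)


def generate_swsc(params: GeneratorParams) -> SimplicialComplex2:
    """Small-world 2-simplicial complex.

    A Watts–Strogatz ring lattice of uniform degree ``2m`` rewired with
    probability ``rewire_p``, plus Bernoulli(p2) triangles with their faces
    merged in.
    """
    n, m = params.n_nodes, params.m
    if m < 1 or 2 * m >= n:
        raise ValueError(f"need 1 <= m and 2m < n_nodes (got m={m}, N={n})")
    if not 0.0 <= params.rewire_p <= 1.0:
        raise ValueError(f"rewire_p={params.rewire_p} outside [0, 1]")
    rng = np.random.default_rng(params.seed)
    g = nx.watts_strogatz_graph(n, 2 * m, params.rewire_p, seed=int(rng.integers(2**31)))
    edges: Set[Edge] = {_norm_edge(int(u), int(v)) for u, v in g.edges()}
    p2 = triangle_probability(n, params.k2_target)
    triangles = _sample_triangles(n, p2, rng)
    return _assemble(n, edges, triangles)
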
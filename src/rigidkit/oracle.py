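"""Independent verification oracles for combinatorial rigidity.

Two routes that do not share code with the pebble game:

* :func:`brute_force_sparse` — exhaustive check of the sparsity counts
  over all vertex subsets (exponential; small graphs only).
* :func:`rigidity_matrix` / :func:`infinitesimal_dof` — numeric rank of
  the rigidity matrix at random generic coordinates.  For a graph with a
  generic infinitesimally rigid embedding, *every* generic embedding is
  rigid, so a randomized embedding decides the graph property with
  probability 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .pebble import Multigraph, SparsityParams

__all__ = ["Framework", "brute_force_sparse", "rigidity_matrix", "infinitesimal_dof"]

_MAX_BRUTE_FORCE = 15


@dataclass
class Framework:
    """A graph embedded in D-dimensional Euclidean space."""

    graph: Multigraph
    dimension: int
    embedding: dict  # vertex -> length-D coordinate array

    def __post_init__(self) -> None:
        for v in self.graph.vertices:
            if v not in self.embedding:
                raise ValueError(f"vertex {v!r} has no coordinates")
        for u, v, _ in self.graph.edges:
            if u != v and np.allclose(self.embedding[u], self.embedding[v]):
                raise ValueError(f"edge ({u!r},{v!r}) has zero length")


def brute_force_sparse(graph: Multigraph, params: SparsityParams) -> bool:
    """Exhaustively test |E'| <= k|V(E')| - l over all vertex subsets.

    Checking induced edge multisets over vertex subsets suffices: for a
    fixed V(E') the extremal E' is the full induced multiset.
    """
    verts = sorted(set(graph.vertices), key=lambda v: (type(v).__name__, str(v)))
    n = len(verts)
    if n > _MAX_BRUTE_FORCE:
        raise ValueError(f"brute-force sparsity limited to {_MAX_BRUTE_FORCE} vertices")
    k, l = params.k, params.l
    # Maxwell boundary (l = 2k): the count is meaningful only on subsets
    # of >= 3 vertices (a pair would be allowed k*2 - 2k = 0 edges)
    min_size = 3 if params.boundary else 1
    idx = {v: i for i, v in enumerate(verts)}
    edges = [(idx[u], idx[v], m) for u, v, m in graph.edges]
    for size in range(min_size, n + 1):
        for subset in combinations(range(n), size):
            s = set(subset)
            count = sum(m for a, b, m in edges if a in s and b in s)
            if count >= 1 and count > k * size - l:
                return False
    return True


def rigidity_matrix(fw: Framework) -> np.ndarray:
    """The |E| x D|V| rigidity matrix of the framework.

    The row for edge xy carries eta(x)-eta(y) in x's column block and
    the negation in y's, so that row . velocities =
    (v_x - v_y) . (eta(x) - eta(y)).
    """
    verts = list(dict.fromkeys(fw.graph.vertices))
    col = {v: i for i, v in enumerate(verts)}
    D = fw.dimension
    rows = []
    for u, v, m in fw.graph.edges:
        if u == v:
            continue
        diff = np.asarray(fw.embedding[u], float) - np.asarray(fw.embedding[v], float)
        for _ in range(m):
            row = np.zeros(D * len(verts))
            row[D * col[u] : D * col[u] + D] = diff
            row[D * col[v] : D * col[v] + D] = -diff
            rows.append(row)
    if not rows:
        return np.zeros((0, D * len(verts)))
    return np.vstack(rows)


def _trivial_motions(n: int, D: int) -> int:
    """Dimension of the space of trivial motions for n generic points."""
    m = min(n - 1, D)  # affine dimension spanned by generic points
    c2 = lambda x: x * (x - 1) // 2
    return c2(D + 1) - c2(D - m)


def _rank(matrix: np.ndarray) -> int:
    if matrix.size == 0:
        return 0
    sv = np.linalg.svd(matrix, compute_uv=False)
    if sv.size == 0 or sv[0] == 0:
        return 0
    return int(np.sum(sv > 1e-9 * sv[0]))


def infinitesimal_dof(fw_or_graph, dimension: int | None = None, seed: int = 0) -> int:
    """Internal degrees of freedom: D|V| - (trivial motions) - rank(R).

    Accepts either a :class:`Framework`, or a :class:`Multigraph` plus a
    ``dimension`` — in the latter case a generic embedding is sampled
    uniformly from [0, 1)^D (two independent samples; the larger rank is
    kept to guard against an accidentally degenerate draw).
    """
    if isinstance(fw_or_graph, Framework):
        frameworks = [fw_or_graph]
        D = fw_or_graph.dimension
        graph = fw_or_graph.graph
    else:
        graph = fw_or_graph
        if dimension is None:
            raise ValueError("dimension required when passing a bare graph")
        D = dimension
        rng = np.random.default_rng(seed)
        verts = list(dict.fromkeys(graph.vertices))
        frameworks = [
            Framework(graph, D, {v: rng.random(D) for v in verts}) for _ in range(2)
        ]
    n = len(set(graph.vertices))
    rank = max(_rank(rigidity_matrix(fw)) for fw in frameworks)
    return D * n - _trivial_motions(n, D) - rank
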
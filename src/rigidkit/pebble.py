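"""The (k, l)-pebble game and its component-detecting extension.

The pebble game decides membership in the family of (k, l)-sparse
multigraphs: a multigraph is (k, l)-sparse when every nonempty edge
subset E' satisfies |E'| <= k*|V(E')| - l, and (k, l)-tight when in
addition |E| = k*|V| - l.  Tight graphs are exactly the minimally rigid
graphs for the matching rigidity model — (2,3) for planar bar-and-joint
frameworks, (3,6) for 3D Maxwell counting, (6,6) for molecular
body-and-bar frameworks.

The game state is kept as a weighted digraph rather than a literal
multigraph: parallel accepted copies between the same ordered pair are a
single integer weight, and "re-orienting an edge" is a weight shift.
Every vertex starts with k free pebbles; an edge copy uv is accepted
when l+1 pebbles can be gathered onto {u, v}, and the covering pebble
orients the copy away from the vertex it was taken from.  Rigid
components (vertex-maximal tight subgraphs) are maintained online by the
component extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Optional, Sequence

Vertex = Hashable

__all__ = [
    "SparsityParams",
    "Multigraph",
    "PebbledGraph",
    "InsertResult",
    "GameSummary",
    "RigidComponent",
    "new_game",
    "play_game",
    "play_component_game",
]


class ParameterError(ValueError):
    """Raised for (k, l) pairs outside the valid sparsity range."""


class LoopError(ValueError):
    """Raised for a self-loop that can never satisfy the sparsity count."""


@dataclass(frozen=True)
class SparsityParams:
    """The (k, l) pair defining the sparsity family; requires 0 <= l < 2k.

    The boundary l = 2k (Maxwell counting, e.g. (3,6) for 3D
    bar-and-joint frameworks) falls outside the matroidal range and must
    be requested explicitly with ``boundary=True``.  There the game
    accepts an edge when l pebbles (all of them) can be gathered on its
    endpoints; results are the classic Maxwell count, whose known
    failure mode is documented by the double-banana graph.
    """

    k: int
    l: int
    boundary: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.k, int) and isinstance(self.l, int)):
            raise ParameterError("k and l must be integers")
        if self.boundary:
            if self.k < 1 or self.l != 2 * self.k:
                raise ParameterError(
                    f"boundary mode requires l = 2k, got (k={self.k}, l={self.l})"
                )
        elif self.k < 1 or not (0 <= self.l < 2 * self.k):
            raise ParameterError(
                f"invalid sparsity parameters (k={self.k}, l={self.l}); "
                "need k >= 1 and 0 <= l < 2k "
                "(pass boundary=True for the Maxwell boundary l = 2k)"
            )

    @property
    def gather_target(self) -> int:
        """Pebbles required on an edge's endpoints for acceptance."""
        return self.l if self.boundary else self.l + 1


@dataclass
class Multigraph:
    """An undirected multigraph: opaque vertex ids plus (u, v, multiplicity) edges."""

    vertices: list
    edges: list  # (u, v, multiplicity)

    def __post_init__(self) -> None:
        vset = set(self.vertices)
        for u, v, m in self.edges:
            if m < 1:
                raise ValueError(f"edge ({u},{v}) has multiplicity {m} < 1")
            if u not in vset or v not in vset:
                raise ValueError(f"edge ({u},{v}) references unknown vertex")

    @property
    def n_vertices(self) -> int:
        return len(set(self.vertices))

    @property
    def n_edges(self) -> int:
        return sum(m for _, _, m in self.edges)

    def edge_copies(self) -> Iterator[tuple]:
        """Yield every edge copy individually as (u, v)."""
        for u, v, m in self.edges:
            for _ in range(m):
                yield u, v

    @classmethod
    def from_edges(cls, edges: Iterable[tuple], vertices: Iterable = ()) -> "Multigraph":
        """Build from (u, v) or (u, v, mult) tuples, collapsing parallels."""
        mult: dict = {}
        order: list = []
        verts = list(vertices)
        seen = set(verts)
        for e in edges:
            if len(e) == 2:
                u, v, m = e[0], e[1], 1
            else:
                u, v, m = e
            key = (u, v) if _vkey(u) <= _vkey(v) else (v, u)
            if key not in mult:
                mult[key] = 0
                order.append(key)
            mult[key] += m
            for x in (u, v):
                if x not in seen:
                    seen.add(x)
                    verts.append(x)
        return cls(verts, [(u, v, mult[(u, v)]) for u, v in order])


def _vkey(v: Vertex):
    """Stable sort key for heterogeneous vertex ids."""
    return (type(v).__name__, str(v))


@dataclass(frozen=True)
class RigidComponent:
    """A vertex-maximal (k, l)-tight subgraph of the accepted edge set."""

    vertex_ids: frozenset
    edge_refs: frozenset = frozenset()  # accepted (u, v) pairs induced by the component


@dataclass
class InsertResult:
    accepted: int
    rejected: int
    new_or_merged_component: Optional[RigidComponent] = None


@dataclass
class GameSummary:
    """Outcome of inserting all edges of a graph.

    ``category`` is the four-way classification: *tight* (all accepted,
    exactly l free pebbles), *sparse* (all accepted, more than l),
    *spanning* (rejections but the accepted set spans with l pebbles,
    i.e. the graph is rigid with redundancy), *other* (rejections and
    more than l free pebbles).
    """

    category: str
    free_pebbles: int
    rejected_edges: list
    accepted_count: int


class PebbledGraph:
    """Mutable pebble-game state on a fixed vertex set."""

    def __init__(self, vertices: Iterable[Vertex], params: SparsityParams):
        if not isinstance(params, SparsityParams):
            params = SparsityParams(*params)
        self.params = params
        self.pebbles: dict = {v: params.k for v in vertices}
        if not self.pebbles:
            raise ValueError("vertex set must be nonempty")
        # directed weights: _out[u][v] = number of accepted copies oriented u -> v
        self._out: dict = {v: {} for v in self.pebbles}

    # -- introspection -------------------------------------------------

    @property
    def vertices(self) -> Iterable[Vertex]:
        return self.pebbles.keys()

    def directed_weight(self, u: Vertex, v: Vertex) -> int:
        return self._out[u].get(v, 0)

    def undirected_multiplicity(self, u: Vertex, v: Vertex) -> int:
        if u == v:
            return self._out[u].get(u, 0)
        return self._out[u].get(v, 0) + self._out[v].get(u, 0)

    def accepted_count(self) -> int:
        return sum(sum(w.values()) for w in self._out.values())

    def free_pebbles(self) -> int:
        return sum(self.pebbles.values())

    def accepted_multigraph(self) -> Multigraph:
        """The undirected accepted edge multiset (for oracle cross-checks)."""
        edges = []
        done = set()
        for u, nbrs in self._out.items():
            for v, w in nbrs.items():
                key = (u, v) if _vkey(u) <= _vkey(v) else (v, u)
                if key in done:
                    continue
                done.add(key)
                m = self.undirected_multiplicity(u, v)
                if m:
                    edges.append((key[0], key[1], m))
        return Multigraph(list(self.pebbles), edges)

    def state_dump(self) -> dict:
        """Canonical serializable state (for golden-file tests)."""
        return {
            "k": self.params.k,
            "l": self.params.l,
            "pebbles": {str(v): p for v, p in sorted(self.pebbles.items(), key=lambda t: _vkey(t[0]))},
            "weights": sorted(
                (str(u), str(v), w)
                for u, nbrs in self._out.items()
                for v, w in nbrs.items()
                if w
            ),
        }

    def audit(self) -> None:
        """Assert per-vertex and global pebble conservation."""
        k = self.params.k
        for v in self.pebbles:
            out = sum(self._out[v].values())
            if self.pebbles[v] + out != k:
                raise AssertionError(
                    f"pebble conservation violated at {v!r}: "
                    f"{self.pebbles[v]} free + {out} covering != {k}"
                )
            if not (0 <= self.pebbles[v] <= k):
                raise AssertionError(f"pebble count out of range at {v!r}")

    # -- pebble search -------------------------------------------------

    def _find_pebble_path(self, u: Vertex, blocked: frozenset) -> Optional[list]:
        """Depth-first search from ``u`` for a free pebble outside ``blocked``.

        Returns the directed path [u, ..., w] to the pebble holder, or
        None.  Neighbors are visited in ascending id order so runs are
        reproducible.  Blocked vertices may be traversed but their
        pebbles are not taken.
        """
        parent: dict = {u: None}
        stack = [u]
        while stack:
            x = stack.pop()
            if x != u and x not in blocked and self.pebbles[x] > 0:
                path = [x]
                while parent[path[-1]] is not None:
                    path.append(parent[path[-1]])
                path.reverse()
                return path
            nbrs = [y for y, w in self._out[x].items() if w > 0 and y != x and y not in parent]
            nbrs.sort(key=_vkey, reverse=True)  # stack pops smallest last-pushed first
            for y in nbrs:
                parent[y] = x
                stack.append(y)
        return None

    def collect_pebble(self, u: Vertex, blocked: Iterable[Vertex] = ()) -> bool:
        """Move one free pebble to ``u`` along a directed path, reversing it.

        Returns False (state untouched) when no pebble is reachable.
        """
        if u not in self.pebbles:
            raise KeyError(f"unknown vertex {u!r}")
        path = self._find_pebble_path(u, frozenset(blocked))
        if path is None:
            return False
        w = path[-1]
        for a, b in zip(path, path[1:]):
            self._out[a][b] -= 1
            if self._out[a][b] == 0:
                del self._out[a][b]
            self._out[b][a] = self._out[b].get(a, 0) + 1
        self.pebbles[w] -= 1
        self.pebbles[u] += 1
        return True

    # -- insertion -----------------------------------------------------

    def _gather(self, u: Vertex, v: Vertex, target: int) -> bool:
        """Collect free pebbles onto {u, v} until their sum reaches ``target``."""
        k = self.params.k
        blocked = frozenset((u, v))
        if u == v:
            while self.pebbles[u] < target:
                if not self.collect_pebble(u, blocked):
                    return False
            return True
        while self.pebbles[u] + self.pebbles[v] < target:
            if self.pebbles[u] < k and self.collect_pebble(u, blocked):
                continue
            if self.pebbles[v] < k and self.collect_pebble(v, blocked):
                continue
            return False
        return True

    def _insert_loop_copy(self, v: Vertex) -> bool:
        k, l = self.params.k, self.params.l
        if l >= k:
            raise LoopError(
                f"self-loop at {v!r} can never satisfy the (k={k}, l={l}) count"
            )
        blocked = frozenset((v,))
        while self.pebbles[v] < l + 1:
            if not self.collect_pebble(v, blocked):
                return False
        self.pebbles[v] -= 1
        self._out[v][v] = self._out[v].get(v, 0) + 1
        return True

    def try_insert_edge(self, u: Vertex, v: Vertex, multiplicity: int = 1) -> InsertResult:
        """Attempt to insert ``multiplicity`` copies of edge uv, one at a time."""
        if u not in self.pebbles or v not in self.pebbles:
            raise KeyError(f"unknown vertex in edge ({u!r}, {v!r})")
        if multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        accepted = rejected = 0
        target = self.params.gather_target
        for _ in range(multiplicity):
            if u == v:
                ok = self._insert_loop_copy(u)
            else:
                ok = self._gather(u, v, target)
                if ok:
                    if self.pebbles[u] > 0:
                        self.pebbles[u] -= 1
                        self._out[u][v] = self._out[u].get(v, 0) + 1
                    else:
                        self.pebbles[v] -= 1
                        self._out[v][u] = self._out[v].get(u, 0) + 1
            if ok:
                accepted += 1
            else:
                rejected += 1
        return InsertResult(accepted=accepted, rejected=rejected)

    # -- component detection -------------------------------------------

    def detect_component(self, u: Vertex, v: Vertex) -> Optional[RigidComponent]:
        """Return the tight component spanning edge uv, if one exists now.

        Called after an accepted copy of uv.  If l+1 pebbles can still be
        gathered onto {u, v} there is no tight set through uv.  Otherwise
        the vertex-maximal tight set is exactly the set of vertices from
        which no free pebble outside {u, v} is reachable: reachable sets
        are closed and carry k|S| - free(S) induced edge copies, so a
        closed set whose only free pebbles are the l on {u, v} is tight,
        and every vertex of a tight set through uv has this property.
        """
        if self.params.boundary:
            raise ParameterError(
                "component detection is only defined on the matroidal range l < 2k"
            )
        l = self.params.l
        if self._gather(u, v, l + 1):
            return None
        # free-pebble holders other than u, v
        holders = [x for x, p in self.pebbles.items() if p > 0 and x not in (u, v)]
        # reverse-reachability: vertices that can reach a holder
        rin: dict = {x: [] for x in self.pebbles}
        for a, nbrs in self._out.items():
            for b, w in nbrs.items():
                if w > 0 and a != b:
                    rin[b].append(a)
        tainted = set(holders)
        stack = list(holders)
        while stack:
            x = stack.pop()
            for a in rin[x]:
                if a not in tainted:
                    tainted.add(a)
                    stack.append(a)
        comp = frozenset(x for x in self.pebbles if x not in tainted)
        edges = frozenset(
            (a, b)
            for a in comp
            for b, w in self._out[a].items()
            if w > 0 and b in comp
        )
        return RigidComponent(vertex_ids=comp, edge_refs=edges)


def new_game(vertices: Iterable[Vertex], params: SparsityParams) -> PebbledGraph:
    """Initialize a pebble game with k free pebbles on every vertex."""
    return PebbledGraph(vertices, params)


def _summarize(g: PebbledGraph, rejected_edges: list) -> GameSummary:
    free = g.free_pebbles()
    l = g.params.l
    if not rejected_edges:
        category = "tight" if free == l else "sparse"
    else:
        category = "spanning" if free == l else "other"
    return GameSummary(
        category=category,
        free_pebbles=free,
        rejected_edges=rejected_edges,
        accepted_count=g.accepted_count(),
    )


def play_game(graph: Multigraph, params: SparsityParams) -> GameSummary:
    """Insert every edge copy of ``graph`` and classify the result."""
    g = new_game(graph.vertices, params)
    rejected: list = []
    for u, v, m in graph.edges:
        res = g.try_insert_edge(u, v, m)
        rejected.extend([(u, v)] * res.rejected)
    return _summarize(g, rejected)


class ComponentIndex:
    """Online index of rigid components: vertex -> set of component ids."""

    def __init__(self) -> None:
        self.components: dict = {}  # id -> RigidComponent
        self._membership: dict = {}  # vertex -> set of ids
        self._next_id = 0

    def same_component(self, u: Vertex, v: Vertex) -> bool:
        return bool(self._membership.get(u, set()) & self._membership.get(v, set()))

    def register(self, comp: RigidComponent) -> RigidComponent:
        """Insert a newly detected component, absorbing the ones it subsumes."""
        absorbed = {
            cid
            for cid, old in self.components.items()
            if len(old.vertex_ids & comp.vertex_ids) >= 2 or old.vertex_ids <= comp.vertex_ids
        }
        for cid in absorbed:
            for x in self.components[cid].vertex_ids:
                self._membership[x].discard(cid)
            del self.components[cid]
        cid = self._next_id
        self._next_id += 1
        self.components[cid] = comp
        for x in comp.vertex_ids:
            self._membership.setdefault(x, set()).add(cid)
        return comp

    def nontrivial(self) -> list:
        """Components with at least 2 vertices, in a canonical order."""
        comps = [c for c in self.components.values() if len(c.vertex_ids) >= 2]
        comps.sort(key=lambda c: (-len(c.vertex_ids), sorted(map(_vkey, c.vertex_ids))))
        return comps


def play_component_game(
    graph: Multigraph, params: SparsityParams
) -> tuple[GameSummary, list]:
    """Play the game while maintaining the rigid-component decomposition."""
    g = new_game(graph.vertices, params)
    index = ComponentIndex()
    rejected: list = []
    for u, v in graph.edge_copies():
        if u != v and index.same_component(u, v):
            # endpoints already rigidly joined: the copy is redundant
            rejected.append((u, v))
            continue
        res = g.try_insert_edge(u, v, 1)
        if res.rejected:
            rejected.append((u, v))
            continue
        comp = g.detect_component(u, v)
        if comp is not None:
            index.register(comp)
    return _summarize(g, rejected), index.nontrivial()
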
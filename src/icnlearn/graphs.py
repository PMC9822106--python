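"""Causal graph data structures and separation oracles.

This module provides the graphical currency of the package:

* :class:`Dag` — a causal directed acyclic graph over named variables.
* :class:`Cbn` — a discrete causal Bayesian network (DAG + CPTs) with a
  forward sampler.
* :class:`Mag` — a maximal ancestral graph over measured variables, in
  which ``X <-> Y`` encodes an unmeasured confounder.
* :class:`Pag` — a partial ancestral graph summarising a Markov
  equivalence class of MAGs (circle marks are class-variant endpoints).
* :class:`DiscreteDataset` — samples x variables tables of small
  non-negative integers.

It also implements the separation oracles (d-separation, m-separation),
the latent projection DAG -> MAG, brute-force enumeration of the MAGs
represented by a PAG, and the oracle PAG of a DAG with latent variables.

Endpoint marks are encoded as ``'-'`` (tail), ``'>'`` (arrow) and
``'o'`` (circle); an edge prints as ``A --> B``, ``A <-> B``,
``A o-> B`` or ``A o-o B``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

TAIL = "-"
ARROW = ">"
CIRCLE = "o"

_MARKS = (TAIL, ARROW, CIRCLE)


class GraphError(ValueError):
    """Raised for structurally invalid graphs or unknown identifiers."""


# ---------------------------------------------------------------------------
# DAGs
# ---------------------------------------------------------------------------


class Dag:
    """A directed acyclic graph over named variables.

    Nodes keep their input order; edge iteration is lexicographic, so all
    derived output is deterministic.
    """

    def __init__(self, nodes: Sequence[str], edges: Iterable[Tuple[str, str]] = ()):
        self.nodes: List[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise GraphError("duplicate node identifiers")
        self._index = {v: i for i, v in enumerate(self.nodes)}
        self.edges: Set[Tuple[str, str]] = set()
        self._parents: Dict[str, Set[str]] = {v: set() for v in self.nodes}
        self._children: Dict[str, Set[str]] = {v: set() for v in self.nodes}
        for a, b in edges:
            self.add_edge(a, b)
        self._check_acyclic()

    # -- construction -------------------------------------------------

    def add_edge(self, a: str, b: str) -> None:
        self._require(a)
        self._require(b)
        if a == b:
            raise GraphError(f"self loop on {a!r}")
        if (b, a) in self.edges:
            raise GraphError(f"both orientations of {{{a},{b}}} present")
        self.edges.add((a, b))
        self._parents[b].add(a)
        self._children[a].add(b)

    def _require(self, v: str) -> None:
        if v not in self._index:
            raise GraphError(f"unknown variable {v!r}")

    def _check_acyclic(self) -> None:
        if self.topological_order() is None:
            raise GraphError("directed cycle in DAG")

    # -- queries ------------------------------------------------------

    def parents(self, v: str) -> Set[str]:
        self._require(v)
        return set(self._parents[v])

    def children(self, v: str) -> Set[str]:
        self._require(v)
        return set(self._children[v])

    def topological_order(self) -> Optional[List[str]]:
        indeg = {v: len(self._parents[v]) for v in self.nodes}
        queue = [v for v in self.nodes if indeg[v] == 0]
        order: List[str] = []
        while queue:
            v = queue.pop(0)
            order.append(v)
            for c in sorted(self._children[v]):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        return order if len(order) == len(self.nodes) else None

    def ancestors(self, v: str) -> Set[str]:
        """Proper ancestors of ``v`` (excluding ``v`` itself)."""
        self._require(v)
        out: Set[str] = set()
        stack = list(self._parents[v])
        while stack:
            u = stack.pop()
            if u not in out:
                out.add(u)
                stack.extend(self._parents[u])
        return out

    def descendants(self, v: str) -> Set[str]:
        self._require(v)
        out: Set[str] = set()
        stack = list(self._children[v])
        while stack:
            u = stack.pop()
            if u not in out:
                out.add(u)
                stack.extend(self._children[u])
        return out

    def copy(self) -> "Dag":
        return Dag(self.nodes, self.edges)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Dag(nodes={self.nodes!r}, edges={sorted(self.edges)!r})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Dag)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def __hash__(self):
        return hash((tuple(self.nodes), frozenset(self.edges)))


# ---------------------------------------------------------------------------
# Mixed graphs (MAGs, PAGs)
# ---------------------------------------------------------------------------


def _canon(i: int, j: int) -> Tuple[int, int]:
    return (i, j) if i < j else (j, i)


class MixedGraph:
    """Nodes plus edges with a mark at each endpoint.

    ``edges`` maps the index-ordered pair ``(i, j)`` (i < j in node order)
    to ``(mark_at_i, mark_at_j)``.
    """

    allowed_marks: Tuple[str, ...] = _MARKS

    def __init__(self, nodes: Sequence[str]):
        self.nodes: List[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise GraphError("duplicate node identifiers")
        self._index = {v: i for i, v in enumerate(self.nodes)}
        self.edges: Dict[Tuple[int, int], Tuple[str, str]] = {}

    # -- construction -------------------------------------------------

    def add_edge(self, a: str, b: str, mark_a: str, mark_b: str) -> None:
        """Add edge a *-* b; ``mark_a`` is the mark at a's end."""
        i, j = self._pair(a, b)
        if mark_a not in self.allowed_marks or mark_b not in self.allowed_marks:
            raise GraphError(f"illegal endpoint marks {mark_a!r}, {mark_b!r}")
        key = _canon(i, j)
        self.edges[key] = (mark_a, mark_b) if i < j else (mark_b, mark_a)

    def remove_edge(self, a: str, b: str) -> None:
        i, j = self._pair(a, b)
        self.edges.pop(_canon(i, j), None)

    def _pair(self, a: str, b: str) -> Tuple[int, int]:
        if a not in self._index:
            raise GraphError(f"unknown variable {a!r}")
        if b not in self._index:
            raise GraphError(f"unknown variable {b!r}")
        if a == b:
            raise GraphError(f"self loop on {a!r}")
        return self._index[a], self._index[b]

    # -- queries ------------------------------------------------------

    def adjacent(self, a: str, b: str) -> bool:
        i, j = self._pair(a, b)
        return _canon(i, j) in self.edges

    def mark_at(self, a: str, b: str) -> str:
        """The mark at ``b``'s end of the edge a *-* b."""
        i, j = self._pair(a, b)
        marks = self.edges.get(_canon(i, j))
        if marks is None:
            raise GraphError(f"no edge between {a!r} and {b!r}")
        return marks[1] if i < j else marks[0]

    def set_mark(self, a: str, b: str, mark: str) -> None:
        """Set the mark at ``b``'s end of the edge a *-* b."""
        i, j = self._pair(a, b)
        key = _canon(i, j)
        if key not in self.edges:
            raise GraphError(f"no edge between {a!r} and {b!r}")
        mi, mj = self.edges[key]
        if i < j:
            self.edges[key] = (mi, mark)
        else:
            self.edges[key] = (mark, mj)

    def neighbors(self, v: str) -> List[str]:
        i = self._index[v]
        out = []
        for (a, b) in self.edges:
            if a == i:
                out.append(self.nodes[b])
            elif b == i:
                out.append(self.nodes[a])
        return sorted(out, key=self._index.__getitem__)

    def edge_list(self) -> List[Tuple[str, str, str, str]]:
        """Edges as ``(a, b, mark_a, mark_b)`` in lexicographic index order."""
        out = []
        for (i, j) in sorted(self.edges):
            mi, mj = self.edges[(i, j)]
            out.append((self.nodes[i], self.nodes[j], mi, mj))
        return out

    def directed_edges(self) -> Set[Tuple[str, str]]:
        """Fully directed (tail-arrow) edges as ordered (cause, effect) pairs."""
        out: Set[Tuple[str, str]] = set()
        for a, b, ma, mb in self.edge_list():
            if ma == TAIL and mb == ARROW:
                out.add((a, b))
            elif ma == ARROW and mb == TAIL:
                out.add((b, a))
        return out

    # parents/ancestors defined through fully directed edges

    def _directed_parents(self) -> Dict[str, Set[str]]:
        par: Dict[str, Set[str]] = {v: set() for v in self.nodes}
        for a, b in self.directed_edges():
            par[b].add(a)
        return par

    def ancestor_sets(self) -> Dict[str, Set[str]]:
        """Map node -> set of its proper ancestors via directed edges."""
        par = self._directed_parents()
        anc: Dict[str, Set[str]] = {}

        def visit(v: str, stack: Set[str]) -> Set[str]:
            if v in anc:
                return anc[v]
            if v in stack:
                return set()  # cycle; caught by validity checks elsewhere
            stack.add(v)
            out: Set[str] = set()
            for p in par[v]:
                out.add(p)
                out |= visit(p, stack)
            stack.discard(v)
            anc[v] = out
            return out

        for v in self.nodes:
            visit(v, set())
        return anc

    def copy(self) -> "MixedGraph":
        g = type(self)(self.nodes)
        g.edges = dict(self.edges)
        return g

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MixedGraph)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def __hash__(self):
        return hash((tuple(self.nodes), frozenset(self.edges.items())))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = [format_edge(*e) for e in self.edge_list()]
        return f"{type(self).__name__}({', '.join(parts)})"


def format_edge(a: str, b: str, mark_a: str, mark_b: str) -> str:
    left = {TAIL: "-", ARROW: "<", CIRCLE: "o"}[mark_a]
    right = {TAIL: "-", ARROW: ">", CIRCLE: "o"}[mark_b]
    return f"{a} {left}-{right} {b}"


class Mag(MixedGraph):
    """Maximal ancestral graph; endpoint marks restricted to tail/arrow.

    Without selection bias the edge vocabulary is ``X --> Y`` and
    ``X <-> Y``.
    """

    allowed_marks = (TAIL, ARROW)

    def is_ancestral(self) -> bool:
        """No directed cycle and no X <-> Y with X an ancestor of Y."""
        # directed part acyclic
        try:
            Dag(self.nodes, self.directed_edges())
        except GraphError:
            return False
        anc = self.ancestor_sets()
        for a, b, ma, mb in self.edge_list():
            if ma == ARROW and mb == ARROW:  # bidirected
                if a in anc[b] or b in anc[a]:
                    return False
        return True

    def is_maximal(self) -> bool:
        """Every non-adjacent pair has some m-separating set."""
        for x, y in itertools.combinations(self.nodes, 2):
            if self.adjacent(x, y):
                continue
            rest = [v for v in self.nodes if v not in (x, y)]
            if not any(
                m_separated(self, x, y, set(zs))
                for r in range(len(rest) + 1)
                for zs in itertools.combinations(rest, r)
            ):
                return False
        return True


class Pag(MixedGraph):
    """Partial ancestral graph; no selection-bias (tail-tail / tail-circle)
    edges, i.e. each edge is one of -->, <->, o->, o-o."""

    allowed_marks = _MARKS

    def validate(self) -> None:
        for a, b, ma, mb in self.edge_list():
            kind = frozenset((ma, mb)) if ma != mb else frozenset((ma,))
            ok = (
                (ma, mb) in ((TAIL, ARROW), (ARROW, TAIL))
                or (ma == ARROW and mb == ARROW)
                or (ma == CIRCLE and mb in (ARROW, CIRCLE))
                or (mb == CIRCLE and ma in (ARROW, CIRCLE))
            )
            if not ok:
                raise GraphError(
                    f"edge {format_edge(a, b, ma, mb)} not a legal PAG edge kind"
                )


# ---------------------------------------------------------------------------
# Separation oracles
# ---------------------------------------------------------------------------


def _as_mixed(graph) -> MixedGraph:
    if isinstance(graph, Dag):
        g = MixedGraph(graph.nodes)
        for a, b in graph.edges:
            g.add_edge(a, b, TAIL, ARROW)
        return g
    return graph


def _adjacency_with_marks(graph: MixedGraph) -> Dict[str, List[Tuple[str, str, str]]]:
    adj: Dict[str, List[Tuple[str, str, str]]] = {v: [] for v in graph.nodes}
    for a, b, ma, mb in graph.edge_list():
        adj[a].append((b, ma, mb))  # from a to b: mark at a, mark at b
        adj[b].append((a, mb, ma))
    return adj


def _m_connected(
    graph: MixedGraph,
    x: str,
    y: str,
    z: Set[str],
    anc: Optional[Dict[str, Set[str]]] = None,
    adj: Optional[Dict[str, List[Tuple[str, str, str]]]] = None,
) -> bool:
    """Reachability test for an m-connecting path from x to y given z.

    Walk states are (node, entered-with-arrowhead).  A path may pass
    through an intermediate node v iff v is a non-collider not in z, or a
    collider (arrowheads on both incident path edges) in the ancestors of
    z (z itself included).
    """
    if anc is None:
        anc = graph.ancestor_sets()
    anc_z: Set[str] = set(z)
    for w in z:
        anc_z |= anc[w]

    if adj is None:
        adj = _adjacency_with_marks(graph)

    seen: Set[Tuple[str, bool]] = set()
    stack: List[Tuple[str, bool]] = []
    for (w, _ma, mw) in adj[x]:
        if w == y:
            return True
        state = (w, mw == ARROW)
        if state not in seen:
            seen.add(state)
            stack.append(state)
    while stack:
        v, arrow_in = stack.pop()
        for (w, mv, mw) in adj[v]:
            collider = arrow_in and mv == ARROW
            if collider:
                if v not in anc_z:
                    continue
            else:
                if v in z:
                    continue
            if w == y:
                return True
            state = (w, mw == ARROW)
            if state not in seen:
                seen.add(state)
                stack.append(state)
    return False


def _check_sep_args(graph, x: str, y: str, z: Iterable[str]) -> Set[str]:
    nodes = set(graph.nodes)
    zs = set(z)
    for v in itertools.chain((x, y), zs):
        if v not in nodes:
            raise GraphError(f"unknown variable {v!r}")
    if x == y:
        raise GraphError("x and y must differ")
    if x in zs or y in zs:
        raise GraphError("x and y must not be in z")
    return zs


def d_separated(dag: Dag, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """Standard d-separation of x and y given z in a DAG."""
    zs = _check_sep_args(dag, x, y, z)
    return not _m_connected(_as_mixed(dag), x, y, zs)


def m_separated(mag: MixedGraph, x: str, y: str, z: Iterable[str] = ()) -> bool:
    """m-separation of x and y given z in a mixed ancestral graph."""
    zs = _check_sep_args(mag, x, y, z)
    return not _m_connected(mag, x, y, zs)


# ---------------------------------------------------------------------------
# Latent projection
# ---------------------------------------------------------------------------


def _inducing_path(dag: Dag, x: str, y: str, latents: Set[str]) -> bool:
    """Is there an inducing path between measured x and y relative to latents?

    Every non-endpoint vertex must be in ``latents`` or a collider on the
    path, and every non-endpoint collider must be an ancestor of x or y.
    """
    anc_xy = dag.ancestors(x) | dag.ancestors(y) | {x, y}
    par = {v: dag.parents(v) for v in dag.nodes}
    chi = {v: dag.children(v) for v in dag.nodes}

    # DFS over simple paths.  ``arrow_in`` records whether the edge used to
    # reach v points at v; when stepping v -> w, the edge has an arrowhead
    # at v iff w is a parent of v (the edge is w -> v).
    def dfs(v: str, arrow_in: bool, visited: Set[str]) -> bool:
        for w, arrow_at_v, arrow_at_w in itertools.chain(
            ((c, False, True) for c in sorted(chi[v])),
            ((p, True, False) for p in sorted(par[v])),
        ):
            if w in visited:
                continue
            if v != x:  # v is an intermediate vertex of the candidate path
                is_collider = arrow_in and arrow_at_v
                if is_collider:
                    if v not in anc_xy:
                        continue
                elif v not in latents:
                    continue
            if w == y:
                return True
            if dfs(w, arrow_at_w, visited | {w}):
                return True
        return False

    return dfs(x, False, {x})


def latent_project(dag: Dag, latents: Iterable[str]) -> Mag:
    """Project a DAG with latent variables onto its measured variables.

    Measured X, Y are adjacent iff an inducing path exists relative to the
    latent set; the edge is X --> Y iff X is an ancestor of Y in the DAG,
    and X <-> Y when neither is an ancestor of the other.  Maximality is
    guaranteed by the inducing-path adjacency criterion.
    """
    lat = set(latents)
    for v in lat:
        if v not in dag._index:
            raise GraphError(f"unknown latent variable {v!r}")
    measured = [v for v in dag.nodes if v not in lat]
    if not measured:
        raise GraphError("projection onto an empty measured set")
    mag = Mag(measured)
    for x, y in itertools.combinations(measured, 2):
        if _inducing_path(dag, x, y, lat):
            if x in dag.ancestors(y):
                mag.add_edge(x, y, TAIL, ARROW)
            elif y in dag.ancestors(x):
                mag.add_edge(x, y, ARROW, TAIL)
            else:
                mag.add_edge(x, y, ARROW, ARROW)
    return mag


# ---------------------------------------------------------------------------
# MAG enumeration and oracle PAG
# ---------------------------------------------------------------------------


def msep_fingerprint(mag: MixedGraph) -> FrozenSet[Tuple[str, str, FrozenSet[str]]]:
    """All m-separation statements (x, y, Z) that hold in the graph, for
    non-adjacent pairs only (adjacent pairs are never separated)."""
    out = set()
    for x, y in itertools.combinations(mag.nodes, 2):
        if mag.adjacent(x, y):
            continue
        rest = [v for v in mag.nodes if v not in (x, y)]
        for r in range(len(rest) + 1):
            for zs in itertools.combinations(rest, r):
                if m_separated(mag, x, y, set(zs)):
                    out.add((x, y, frozenset(zs)))
    return frozenset(out)


def _mark_completions(pag: Pag) -> Iterable[Mag]:
    """All tail/arrow completions of the circle marks of a PAG."""
    circle_slots: List[Tuple[int, int, int]] = []  # (i, j, which endpoint)
    for (i, j), (mi, mj) in sorted(pag.edges.items()):
        if mi == CIRCLE:
            circle_slots.append((i, j, 0))
        if mj == CIRCLE:
            circle_slots.append((i, j, 1))
    for assignment in itertools.product((TAIL, ARROW), repeat=len(circle_slots)):
        mag = Mag(pag.nodes)
        marks = {k: list(v) for k, v in pag.edges.items()}
        for (slot, mark) in zip(circle_slots, assignment):
            i, j, which = slot
            marks[(i, j)][which] = mark
        ok = True
        for (i, j), (mi, mj) in marks.items():
            if mi == CIRCLE or mj == CIRCLE:  # pragma: no cover - defensive
                ok = False
                break
            if mi == TAIL and mj == TAIL:
                ok = False  # undirected (selection-bias) edges are out of scope
                break
            mag.add_edge(pag.nodes[i], pag.nodes[j], mi, mj)
        if ok:
            yield mag


def enumerate_mags(pag: Pag) -> List[Mag]:
    """Enumerate the MAGs represented by a PAG.

    Completes every circle mark to tail or arrow, keeps the completions
    that are ancestral and maximal, and returns the Markov equivalence
    class (largest group of completions sharing identical m-separation
    relations; for a well-formed PAG all valid completions fall in one
    group).  Output order is canonical (by edge-mark encoding).
    """
    valid: List[Tuple[Mag, FrozenSet]] = []
    for mag in _mark_completions(pag):
        if not mag.is_ancestral():
            continue
        if not mag.is_maximal():
            continue
        valid.append((mag, msep_fingerprint(mag)))
    if not valid:
        return []
    groups: Dict[FrozenSet, List[Mag]] = {}
    for mag, fp in valid:
        groups.setdefault(fp, []).append(mag)
    # the class: the largest group; ties broken by the group containing the
    # most tail marks (the "canonical" least-confounded completion).
    def group_key(item):
        fp, mags = item
        tails = max(
            sum(1 for _, _, ma, mb in m.edge_list() if TAIL in (ma, mb)) for m in mags
        )
        return (len(mags), tails)

    best = max(groups.items(), key=group_key)[1]
    return sorted(best, key=lambda m: tuple(sorted(m.edges.items())))


def summarize_marks(mags: Sequence[Mag]) -> Pag:
    """Summarise a set of Markov-equivalent MAGs into a PAG: a mark is kept
    iff it is invariant across all members, else it becomes a circle."""
    if not mags:
        raise GraphError("cannot summarise an empty MAG set")
    nodes = mags[0].nodes
    pag = Pag(nodes)
    keys = set(mags[0].edges)
    for m in mags[1:]:
        if set(m.edges) != keys:
            raise GraphError("MAGs with different skeletons")
    for key in keys:
        marks = {m.edges[key] for m in mags}
        mi_set = {mk[0] for mk in marks}
        mj_set = {mk[1] for mk in marks}
        mi = mi_set.pop() if len(mi_set) == 1 else CIRCLE
        mj = mj_set.pop() if len(mj_set) == 1 else CIRCLE
        i, j = key
        pag.add_edge(nodes[i], nodes[j], mi, mj)
    return pag


def equivalence_class(mag: Mag) -> List[Mag]:
    """All MAGs Markov equivalent to ``mag``, by brute-force enumeration.

    Orients the fixed skeleton every way over {-->, <--, <->} with
    depth-first ancestrality pruning, then keeps the orientations whose
    unshielded-collider pattern and full m-separation fingerprint match
    the input.  Intended for small graphs (the test oracle); cost grows as
    3^edges.
    """
    nodes = mag.nodes
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    edge_keys = sorted(mag.edges)
    m = len(edge_keys)

    target_fp = msep_fingerprint(mag)
    queries: List[Tuple[str, str, FrozenSet[str], bool]] = []
    for x, y in itertools.combinations(nodes, 2):
        if mag.adjacent(x, y):
            continue
        rest = [v for v in nodes if v not in (x, y)]
        for r in range(len(rest) + 1):
            for zs in itertools.combinations(rest, r):
                queries.append((x, y, frozenset(zs), (x, y, frozenset(zs)) in target_fp))

    def unshielded_colliders(g: Mag) -> Set[Tuple[str, str, str]]:
        out = set()
        for b in g.nodes:
            nb = g.neighbors(b)
            for a, c in itertools.combinations(nb, 2):
                if g.adjacent(a, c):
                    continue
                if g.mark_at(a, b) == ARROW and g.mark_at(c, b) == ARROW:
                    out.add((min(a, c), b, max(a, c)))
        return out

    target_colliders = unshielded_colliders(mag)

    results: List[Mag] = []
    # assignment value per edge: 0 = i->j, 1 = j->i, 2 = i<->j
    assignment: List[int] = [0] * m

    def directed_reaches(di: Dict[int, Set[int]], a: int, b: int) -> bool:
        stack = [a]
        seen = {a}
        while stack:
            u = stack.pop()
            for w in di.get(u, ()):
                if w == b:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def consistent(upto: int) -> bool:
        children: Dict[int, Set[int]] = {}
        bidirected: List[Tuple[int, int]] = []
        for e in range(upto + 1):
            i, j = edge_keys[e]
            v = assignment[e]
            if v == 0:
                children.setdefault(i, set()).add(j)
            elif v == 1:
                children.setdefault(j, set()).add(i)
            else:
                bidirected.append((i, j))
        # no directed cycle among assigned edges
        for i in list(children):
            if directed_reaches(children, i, i):
                return False
        # no bidirected edge between ancestor-related nodes (so far)
        for i, j in bidirected:
            if directed_reaches(children, i, j) or directed_reaches(children, j, i):
                return False
        return True

    def build() -> Mag:
        g = Mag(nodes)
        for e, (i, j) in enumerate(edge_keys):
            v = assignment[e]
            if v == 0:
                g.add_edge(nodes[i], nodes[j], TAIL, ARROW)
            elif v == 1:
                g.add_edge(nodes[i], nodes[j], ARROW, TAIL)
            else:
                g.add_edge(nodes[i], nodes[j], ARROW, ARROW)
        return g

    def dfs(e: int) -> None:
        if e == m:
            cand = build()
            if unshielded_colliders(cand) != target_colliders:
                return
            anc = cand.ancestor_sets()
            adj = _adjacency_with_marks(cand)
            for x, y, zs, expected in queries:
                sep = not _m_connected(cand, x, y, set(zs), anc, adj)
                if sep != expected:
                    return
            results.append(cand)
            return
        for v in (0, 1, 2):
            assignment[e] = v
            if consistent(e):
                dfs(e + 1)

    dfs(0)
    return sorted(results, key=lambda g: tuple(sorted(g.edges.items())))


def brute_force_pag(dag: Dag, latents: Iterable[str] = ()) -> Pag:
    """Mark-summary PAG of the equivalence class of the latent projection,
    computed purely by enumeration — the independent oracle for the
    constraint-based searches."""
    mag = latent_project(dag, set(latents))
    cls = equivalence_class(mag)
    return summarize_marks(cls)


def oracle_pag(dag: Dag, latents: Iterable[str] = ()) -> Pag:
    """PAG of the Markov equivalence class of ``latent_project(dag, latents)``,
    computed by running FCI with a perfect d-separation oracle."""
    from .discovery import fci, dsep_oracle_test

    lat = set(latents)
    measured = [v for v in dag.nodes if v not in lat]
    if not measured:
        raise GraphError("no measured variables")
    test = dsep_oracle_test(dag, lat)
    return fci(test, measured)


# ---------------------------------------------------------------------------
# Discrete datasets and CBNs
# ---------------------------------------------------------------------------


@dataclass
class DiscreteDataset:
    """Samples x variables matrix of small non-negative integer levels."""

    samples: List[str]
    variables: List[str]
    values: np.ndarray  # shape (n_samples, n_variables), integer
    arities: np.ndarray  # shape (n_variables,)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.arities = np.asarray(self.arities, dtype=int)
        n, p = self.values.shape
        if len(self.samples) != n or len(self.variables) != p:
            raise ValueError("shape mismatch between ids and value matrix")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("discrete dataset requires integer values")
        if (self.values < 0).any():
            raise ValueError("negative levels")
        if (self.values >= self.arities[None, :]).any():
            raise ValueError("value exceeds declared arity")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, var: str) -> np.ndarray:
        try:
            j = self.variables.index(var)
        except ValueError:
            raise KeyError(f"unknown variable {var!r}") from None
        return self.values[:, j]

    def arity(self, var: str) -> int:
        return int(self.arities[self.variables.index(var)])

    def subset_rows(self, idx: np.ndarray) -> "DiscreteDataset":
        return DiscreteDataset(
            [self.samples[i] for i in np.asarray(idx)],
            list(self.variables),
            self.values[np.asarray(idx)],
            self.arities.copy(),
        )

    def drop_columns(self, names: Iterable[str]) -> "DiscreteDataset":
        drop = set(names)
        keep = [j for j, v in enumerate(self.variables) if v not in drop]
        return DiscreteDataset(
            list(self.samples),
            [self.variables[j] for j in keep],
            self.values[:, keep],
            self.arities[keep],
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.samples, columns=self.variables)


@dataclass
class Cbn:
    """A discrete causal Bayesian network.

    ``cpts[v]`` has shape ``(prod(parent arities), arity(v))``, rows indexed
    by the mixed-radix encoding of the parent levels in the order given by
    ``sorted(dag.parents(v), key=node order)``; every row sums to one.
    """

    dag: Dag
    arities: Dict[str, int]
    cpts: Dict[str, np.ndarray]

    def __post_init__(self):
        self.validate()

    def parent_order(self, v: str) -> List[str]:
        idx = self.dag._index
        return sorted(self.dag.parents(v), key=idx.__getitem__)

    def validate(self) -> None:
        for v in self.dag.nodes:
            if v not in self.arities or self.arities[v] < 2:
                raise GraphError(f"bad arity for {v!r}")
            cpt = np.asarray(self.cpts.get(v))
            if cpt is None:
                raise GraphError(f"missing CPT for {v!r}")
            n_cfg = int(np.prod([self.arities[p] for p in self.parent_order(v)]))
            if cpt.shape != (n_cfg, self.arities[v]):
                raise GraphError(
                    f"CPT for {v!r} has shape {cpt.shape}, expected {(n_cfg, self.arities[v])}"
                )
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-9):
                raise GraphError(f"CPT rows for {v!r} do not sum to 1")
            if (cpt < -1e-12).any():
                raise GraphError(f"negative probabilities in CPT for {v!r}")


def forward_sample(cbn: Cbn, n: int, seed: int) -> DiscreteDataset:
    """Draw ``n`` i.i.d. samples from the joint distribution of a CBN.

    Nodes are sampled in topological order; the draw is reproducible for a
    given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cbn.validate()
    rng = np.random.default_rng(seed)
    order = cbn.dag.topological_order()
    assert order is not None
    nodes = cbn.dag.nodes
    col_of = {v: j for j, v in enumerate(nodes)}
    values = np.zeros((n, len(nodes)), dtype=np.int16)
    for v in order:
        parents = cbn.parent_order(v)
        cpt = np.asarray(cbn.cpts[v])
        if parents:
            cfg = np.zeros(n, dtype=np.int64)
            for p in parents:
                cfg = cfg * cbn.arities[p] + values[:, col_of[p]]
        else:
            cfg = np.zeros(n, dtype=np.int64)
        u = rng.random(n)
        cum = np.cumsum(cpt, axis=1)
        values[:, col_of[v]] = (u[:, None] > cum[cfg]).sum(axis=1)
    samples = [f"s{i}" for i in range(n)]
    return DiscreteDataset(samples, list(nodes), values, np.array([cbn.arities[v] for v in nodes]))
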
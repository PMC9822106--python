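"""Population-level causal structure search.

Three search layers, each honouring prior knowledge (forbidden pairs /
required adjacencies):

* :func:`ges` — greedy equivalence search over CPDAGs with a decomposable
  scorer (forward equivalence insertion, then backward deletion), using
  Chickering's Insert/Delete operators.
* :func:`fci` — constraint-based search returning a PAG: PC-style
  adjacency search with growing conditioning sets, a possible-d-sep
  removal stage, collider orientation from separating sets, and the
  orientation rules that are complete in the no-selection-bias setting
  (R1–R4 and R8–R10).
* :func:`gfci` — the two-phase hybrid: the GES skeleton constrains (and
  may be thinned by) the FCI phase.

Tests are plain callables ``test(x, y, z_tuple) -> CiResult``;
:func:`dsep_oracle_test` builds a perfect oracle from a generating DAG
with latent variables, which turns both searches into their large-sample
idealisations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .graphs import (
    ARROW,
    CIRCLE,
    TAIL,
    Dag,
    DiscreteDataset,
    GraphError,
    Pag,
    d_separated,
)
from .inference_tests import CiResult, DEFAULT_ALPHA, g2_ci_test

CiTest = Callable[[str, str, Tuple[str, ...]], CiResult]


# ---------------------------------------------------------------------------
# Prior knowledge
# ---------------------------------------------------------------------------


@dataclass
class Knowledge:
    """Forbidden unordered pairs and required directed edges."""

    forbidden_pairs: Set[FrozenSet[str]] = field(default_factory=set)
    required_edges: Set[Tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        self.forbidden_pairs = {frozenset(p) for p in self.forbidden_pairs}
        req_pairs = {frozenset(e) for e in self.required_edges}
        if self.forbidden_pairs & req_pairs:
            raise ValueError("forbidden and required constraints overlap")

    def forbids(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.forbidden_pairs

    def requires_adjacency(self, a: str, b: str) -> bool:
        return (a, b) in self.required_edges or (b, a) in self.required_edges

    @classmethod
    def empty(cls) -> "Knowledge":
        return cls()


# ---------------------------------------------------------------------------
# CPDAGs
# ---------------------------------------------------------------------------


class Cpdag:
    """A completed partially directed acyclic graph (Markov equivalence
    class of DAGs): directed plus undirected edges."""

    def __init__(
        self,
        nodes: Sequence[str],
        directed: Iterable[Tuple[str, str]] = (),
        undirected: Iterable[FrozenSet[str]] = (),
    ):
        self.nodes = list(nodes)
        self._order = {v: i for i, v in enumerate(self.nodes)}
        self.directed: Set[Tuple[str, str]] = set(directed)
        self.undirected: Set[FrozenSet[str]] = {frozenset(e) for e in undirected}

    def adjacent(self, a: str, b: str) -> bool:
        return (
            (a, b) in self.directed
            or (b, a) in self.directed
            or frozenset((a, b)) in self.undirected
        )

    def adjacencies(self, v: str) -> Set[str]:
        out = {b for (a, b) in self.directed if a == v}
        out |= {a for (a, b) in self.directed if b == v}
        out |= {next(iter(e - {v})) for e in self.undirected if v in e}
        return out

    def parents(self, v: str) -> Set[str]:
        return {a for (a, b) in self.directed if b == v}

    def neighbors_undirected(self, v: str) -> Set[str]:
        return {next(iter(e - {v})) for e in self.undirected if v in e}

    def skeleton(self) -> Set[FrozenSet[str]]:
        return {frozenset(e) for e in self.directed} | set(self.undirected)

    def copy(self) -> "Cpdag":
        return Cpdag(self.nodes, self.directed, self.undirected)

    def __eq__(self, other):
        return (
            isinstance(other, Cpdag)
            and self.nodes == other.nodes
            and self.directed == other.directed
            and self.undirected == other.undirected
        )

    def __repr__(self):  # pragma: no cover - debugging aid
        d = ", ".join(f"{a}->{b}" for a, b in sorted(self.directed))
        u = ", ".join("--".join(sorted(e)) for e in sorted(self.undirected, key=sorted))
        return f"Cpdag({d}; {u})"


def _pdag_to_dag(
    nodes: Sequence[str],
    directed: Set[Tuple[str, str]],
    undirected: Set[FrozenSet[str]],
) -> Dag:
    """Dor–Tarsi consistent extension of a PDAG to a DAG."""
    directed = set(directed)
    undirected = {frozenset(e) for e in undirected}
    remaining = list(nodes)
    result: Set[Tuple[str, str]] = set(directed)

    def adj(v: str) -> Set[str]:
        out = set()
        for (a, b) in directed:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        for e in undirected:
            if v in e:
                out |= e - {v}
        return out

    while remaining:
        for v in list(remaining):
            if any(a == v for (a, b) in directed):
                continue  # v has an outgoing directed edge
            ne = {next(iter(e - {v})) for e in undirected if v in e}
            av = adj(v)
            if all(av - {w} <= adj(w) for w in ne):
                for w in ne:
                    result.add((w, v))
                # remove v
                directed = {(a, b) for (a, b) in directed if v not in (a, b)}
                undirected = {e for e in undirected if v not in e}
                remaining.remove(v)
                break
        else:
            raise GraphError("PDAG admits no consistent extension")
    return Dag(nodes, result)


def _dag_to_cpdag(dag: Dag) -> Cpdag:
    """Completed pattern of a DAG: v-structure arrows plus Meek closure."""
    directed: Set[Tuple[str, str]] = set()
    skeleton = {frozenset(e) for e in dag.edges}
    # v-structures
    for v in dag.nodes:
        ps = sorted(dag.parents(v), key=dag._index.__getitem__)
        for a, b in itertools.combinations(ps, 2):
            if frozenset((a, b)) not in skeleton:
                directed.add((a, v))
                directed.add((b, v))
    undirected = set()
    for e in skeleton:
        a, b = sorted(e, key=dag._index.__getitem__)
        if (a, b) not in directed and (b, a) not in directed:
            undirected.add(frozenset(e))
    changed = True

    def adjacent(a, b):
        return frozenset((a, b)) in skeleton

    while changed:
        changed = False
        for e in sorted(undirected, key=lambda s: sorted(s)):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                # Meek R1: w -> x, x -- y, w and y non-adjacent  =>  x -> y
                if any(
                    (w, x) in directed and not adjacent(w, y)
                    for w in dag.nodes
                    if w not in (x, y)
                ):
                    directed.add((x, y))
                    undirected.discard(e)
                    changed = True
                    break
                # Meek R2: x -> w -> y and x -- y  =>  x -> y
                if any(
                    (x, w) in directed and (w, y) in directed
                    for w in dag.nodes
                    if w not in (x, y)
                ):
                    directed.add((x, y))
                    undirected.discard(e)
                    changed = True
                    break
                # Meek R3: x -- w1 -> y, x -- w2 -> y, w1,w2 non-adjacent => x -> y
                ws = [
                    w
                    for w in dag.nodes
                    if w not in (x, y)
                    and frozenset((x, w)) in undirected
                    and (w, y) in directed
                ]
                if any(
                    not adjacent(w1, w2) for w1, w2 in itertools.combinations(ws, 2)
                ):
                    directed.add((x, y))
                    undirected.discard(e)
                    changed = True
                    break
            if changed:
                break
    return Cpdag(dag.nodes, directed, undirected)


# ---------------------------------------------------------------------------
# GES
# ---------------------------------------------------------------------------

_SCORE_EPS = 1e-9


def _semidirected_blocked(c: Cpdag, y: str, x: str, blocked: Set[str]) -> bool:
    """True iff every semi-directed path from y to x passes through blocked."""
    if y in blocked:
        return True
    seen = {y}
    stack = [y]
    while stack:
        u = stack.pop()
        steps = {b for (a, b) in c.directed if a == u} | c.neighbors_undirected(u)
        for w in steps:
            if w == x:
                return False
            if w not in seen and w not in blocked:
                seen.add(w)
                stack.append(w)
    return True


def _is_clique(c: Cpdag, vs: Set[str]) -> bool:
    return all(c.adjacent(a, b) for a, b in itertools.combinations(sorted(vs), 2))


def ges(
    scorer,
    nodes: Sequence[str],
    knowledge: Optional[Knowledge] = None,
) -> Cpdag:
    """Greedy equivalence search with a decomposable scorer.

    The scorer must expose ``diff(x, node, parents)``, the local-score gain
    of adding ``x`` as a parent of ``node`` given ``parents``; forbidden
    pairs are never made adjacent, required adjacencies are never removed.
    Ties are broken by lexicographic (node-pair, subset) order, so the
    output is deterministic.
    """
    if not getattr(scorer, "decomposable", True):
        raise ValueError("ges requires a decomposable scorer")
    know = knowledge or Knowledge.empty()
    nodes = list(nodes)
    order = {v: i for i, v in enumerate(nodes)}

    required = [
        (a, b) for (a, b) in sorted(know.required_edges, key=lambda e: (order[e[0]], order[e[1]]))
    ]
    state = Cpdag(nodes)
    if required:
        state = _dag_to_cpdag(Dag(nodes, required))

    def sorted_nodes(vs):
        return sorted(vs, key=order.__getitem__)

    # ---- forward phase ------------------------------------------------
    while True:
        best = None  # (delta, key, x, y, T)
        for y in nodes:
            for x in nodes:
                if x == y or state.adjacent(x, y) or know.forbids(x, y):
                    continue
                na = {
                    w
                    for w in state.neighbors_undirected(y)
                    if state.adjacent(w, x)
                }
                t0 = sorted_nodes(
                    w
                    for w in state.neighbors_undirected(y)
                    if w not in na and not state.adjacent(w, x)
                )
                pa_y = state.parents(y)
                for size in range(len(t0) + 1):
                    for tt in itertools.combinations(t0, size):
                        ts = set(tt)
                        cond = na | ts
                        if not _is_clique(state, cond):
                            continue
                        if not _semidirected_blocked(state, y, x, cond):
                            continue
                        delta = scorer.diff(x, y, pa_y | cond)
                        key = (order[x], order[y], tuple(order[t] for t in tt))
                        if delta > _SCORE_EPS and (
                            best is None
                            or delta > best[0] + _SCORE_EPS
                            or (abs(delta - best[0]) <= _SCORE_EPS and key < best[1])
                        ):
                            best = (delta, key, x, y, ts)
        if best is None:
            break
        _, _, x, y, ts = best
        directed = set(state.directed) | {(x, y)}
        undirected = set(state.undirected)
        for t in ts:
            undirected.discard(frozenset((t, y)))
            directed.add((t, y))
        state = _dag_to_cpdag(_pdag_to_dag(nodes, directed, undirected))

    # ---- backward phase -----------------------------------------------
    while True:
        best = None  # (delta, key, x, y, H)
        pairs = []
        for (a, b) in state.directed:
            pairs.append((a, b))
        for e in state.undirected:
            a, b = sorted_nodes(e)
            pairs.append((a, b))
            pairs.append((b, a))
        for x, y in sorted(pairs, key=lambda e: (order[e[0]], order[e[1]])):
            if know.requires_adjacency(x, y):
                continue
            na = {w for w in state.neighbors_undirected(y) if state.adjacent(w, x)}
            pa_y = state.parents(y)
            h0 = sorted_nodes(na)
            for size in range(len(h0) + 1):
                for hh in itertools.combinations(h0, size):
                    hs = set(hh)
                    keep = na - hs
                    if not _is_clique(state, keep):
                        continue
                    base = (keep | pa_y) - {x}
                    delta = -scorer.diff(x, y, base)
                    key = (order[x], order[y], tuple(order[h] for h in hh))
                    if delta > _SCORE_EPS and (
                        best is None
                        or delta > best[0] + _SCORE_EPS
                        or (abs(delta - best[0]) <= _SCORE_EPS and key < best[1])
                    ):
                        best = (delta, key, x, y, hs)
        if best is None:
            break
        _, _, x, y, hs = best
        directed = {(a, b) for (a, b) in state.directed if (a, b) != (x, y)}
        undirected = {e for e in state.undirected if e != frozenset((x, y))}
        for h in hs:
            if frozenset((y, h)) in undirected:
                undirected.discard(frozenset((y, h)))
                directed.add((y, h))
            if frozenset((x, h)) in undirected:
                undirected.discard(frozenset((x, h)))
                directed.add((x, h))
        state = _dag_to_cpdag(_pdag_to_dag(nodes, directed, undirected))

    return state


# ---------------------------------------------------------------------------
# Oracle tests and scorers
# ---------------------------------------------------------------------------


def dsep_oracle_test(dag: Dag, latents: Iterable[str] = ()) -> CiTest:
    """A perfect CI oracle: independence iff d-separation in the full DAG."""
    lat = set(latents)

    def test(x: str, y: str, z: Tuple[str, ...]) -> CiResult:
        indep = d_separated(dag, x, y, set(z))
        return CiResult(0.0, 0, 1.0 if indep else 0.0, indep, 0)

    return test


class GraphOracleScorer:
    """Score-difference oracle: adding parent x to node y improves the score
    iff x and y are d-connected given the current parents in the true DAG."""

    decomposable = True

    def __init__(self, dag: Dag, latents: Iterable[str] = ()):
        self.dag = dag
        self.latents = set(latents)
        self.variables = [v for v in dag.nodes if v not in self.latents]

    def diff(self, x: str, node: str, parents: Iterable[str]) -> float:
        ps = set(parents) - {x, node}
        return -1.0 if d_separated(self.dag, x, node, ps) else 1.0


def g2_test_on(data: DiscreteDataset, alpha: float = DEFAULT_ALPHA) -> CiTest:
    def test(x: str, y: str, z: Tuple[str, ...]) -> CiResult:
        return g2_ci_test(data, x, y, z, alpha)

    return test


def fisher_z_on(scores, alpha: float = DEFAULT_ALPHA) -> CiTest:
    from .inference_tests import fisher_z_test

    def test(x: str, y: str, z: Tuple[str, ...]) -> CiResult:
        return fisher_z_test(scores, x, y, z, alpha)

    return test


# ---------------------------------------------------------------------------
# FCI
# ---------------------------------------------------------------------------


def _default_max_cond(n_nodes: int, max_cond_size: Optional[int]) -> int:
    if max_cond_size is not None:
        return max_cond_size
    return n_nodes if n_nodes <= 20 else 6


class _FciState:
    def __init__(
        self,
        test: CiTest,
        nodes: Sequence[str],
        knowledge: Knowledge,
        max_cond: int,
        initial_adjacency: Optional[Set[FrozenSet[str]]],
    ):
        self.test = test
        self.nodes = list(nodes)
        self.order = {v: i for i, v in enumerate(self.nodes)}
        self.know = knowledge
        self.max_cond = max_cond
        self.adj: Dict[str, Set[str]] = {v: set() for v in self.nodes}
        pairs = (
            [tuple(sorted(e, key=self.order.__getitem__)) for e in initial_adjacency]
            if initial_adjacency is not None
            else list(itertools.combinations(self.nodes, 2))
        )
        for a, b in pairs:
            if not knowledge.forbids(a, b):
                self.adj[a].add(b)
                self.adj[b].add(a)
        self.sepsets: Dict[FrozenSet[str], Optional[Set[str]]] = {}

    # -- adjacency ----------------------------------------------------

    def _sorted(self, vs: Iterable[str]) -> List[str]:
        return sorted(vs, key=self.order.__getitem__)

    def remove(self, x: str, y: str, sepset: Set[str]) -> None:
        self.adj[x].discard(y)
        self.adj[y].discard(x)
        self.sepsets[frozenset((x, y))] = set(sepset)

    def skeleton_search(self) -> None:
        depth = 0
        while depth <= self.max_cond:
            acted = False
            for x in self.nodes:
                for y in self._sorted(self.adj[x]):
                    if self.order[x] > self.order[y]:
                        continue
                    if self.know.requires_adjacency(x, y):
                        continue
                    removed = False
                    for base in (self.adj[x] - {y}, self.adj[y] - {x}):
                        cands = self._sorted(base)
                        if len(cands) < depth:
                            continue
                        for zs in itertools.combinations(cands, depth):
                            if self.test(x, y, zs).independent:
                                self.remove(x, y, set(zs))
                                removed = True
                                break
                        if removed:
                            break
                    if removed:
                        acted = True
            max_deg = max((len(self.adj[v]) for v in self.nodes), default=0)
            depth += 1
            if depth > max_deg:
                break

    # -- sepsets ------------------------------------------------------

    def sepset(self, x: str, y: str) -> Optional[Set[str]]:
        """Separating set used for orientation, found lazily.

        Among all separating candidates (subsets of either adjacency
        set), the one with the largest p-value is returned — the max-p
        rule, which protects collider orientation against barely-passing
        independence verdicts on weak long-range dependences.
        """
        key = frozenset((x, y))
        if key in self.sepsets:
            return self.sepsets[key]
        best: Optional[Tuple[float, Set[str]]] = None
        done = False
        for base in (self.adj[x] - {y}, self.adj[y] - {x}):
            cands = self._sorted(base)
            for size in range(min(len(cands), self.max_cond) + 1):
                for zs in itertools.combinations(cands, size):
                    res = self.test(x, y, zs)
                    if res.independent and (best is None or res.p_value > best[0]):
                        best = (res.p_value, set(zs))
                        if res.p_value >= 1.0:  # cannot be beaten (oracle)
                            done = True
                            break
                if done:
                    break
            if done:
                break
        found = best[1] if best is not None else None
        self.sepsets[key] = found
        return found

    # -- orientation --------------------------------------------------

    def blank_pag(self) -> Pag:
        pag = Pag(self.nodes)
        for x in self.nodes:
            for y in self._sorted(self.adj[x]):
                if self.order[x] < self.order[y]:
                    pag.add_edge(x, y, CIRCLE, CIRCLE)
        return pag

    def orient_colliders(self, pag: Pag) -> None:
        for b in self.nodes:
            ne = self._sorted(self.adj[b])
            for a, c in itertools.combinations(ne, 2):
                if c in self.adj[a]:
                    continue
                s = self.sepset(a, c)
                if s is not None and b not in s:
                    pag.set_mark(a, b, ARROW)
                    pag.set_mark(c, b, ARROW)

    # -- possible-d-sep ------------------------------------------------

    def possible_dsep(self, pag: Pag, x: str) -> List[str]:
        reach: Set[Tuple[str, str]] = set()
        out: Set[str] = set()
        stack: List[Tuple[str, str]] = []
        for w in self._sorted(self.adj[x]):
            stack.append((x, w))
            reach.add((x, w))
            out.add(w)
        while stack:
            a, b = stack.pop()
            for c in self._sorted(self.adj[b]):
                if c in (a, b) or (b, c) in reach:
                    continue
                collider = (
                    pag.adjacent(a, b)
                    and pag.adjacent(b, c)
                    and pag.mark_at(a, b) == ARROW
                    and pag.mark_at(c, b) == ARROW
                )
                triangle = c in self.adj[a]
                if collider or triangle:
                    reach.add((b, c))
                    out.add(c)
                    stack.append((b, c))
        out.discard(x)
        return self._sorted(out)

    def pds_prune(self) -> None:
        pag = self.blank_pag()
        self.orient_colliders(pag)
        for x in self.nodes:
            pds = self.possible_dsep(pag, x)
            for y in self._sorted(self.adj[x]):
                if self.know.requires_adjacency(x, y):
                    continue
                cands = [v for v in pds if v != y]
                removed = False
                for size in range(min(len(cands), self.max_cond) + 1):
                    for zs in itertools.combinations(cands, size):
                        if self.test(x, y, zs).independent:
                            self.remove(x, y, set(zs))
                            removed = True
                            break
                    if removed:
                        break


def _orient_rules(state: _FciState, pag: Pag) -> None:
    """Zhang's orientation rules R1–R4 and R8–R10 to closure."""
    nodes = state.nodes

    def adjacent(a, b):
        return pag.adjacent(a, b)

    def arrow(a, b):
        return adjacent(a, b) and pag.mark_at(a, b) == ARROW

    def tail(a, b):
        return adjacent(a, b) and pag.mark_at(a, b) == TAIL

    def circle(a, b):
        return adjacent(a, b) and pag.mark_at(a, b) == CIRCLE

    def fully_directed(a, b):
        return arrow(a, b) and tail(b, a)

    def set_mark(a, b, mark):
        pag.set_mark(a, b, mark)

    def uncovered_pd_paths(a: str, c: str, min_len: int = 2):
        """Uncovered possibly-directed paths from a to c (list of nodes)."""
        results = []

        def ok_step(u, v):
            # possibly directed from u to v: no arrow at u, no tail at v
            return adjacent(u, v) and pag.mark_at(v, u) != ARROW and pag.mark_at(u, v) != TAIL

        def dfs(path: List[str]):
            u = path[-1]
            for w in state._sorted(state.adj[u]):
                if w in path:
                    continue
                if not ok_step(u, w):
                    continue
                if len(path) >= 2 and adjacent(path[-2], w):
                    continue  # covered triple
                new = path + [w]
                if w == c:
                    if len(new) - 1 >= min_len:
                        results.append(new)
                else:
                    dfs(new)

        dfs([a])
        return results

    changed = True
    while changed:
        changed = False
        edge_items = list(pag.edge_list())
        for a, b, ma, mb in edge_items:
            for x, y in ((a, b), (b, a)):
                # R1: w *-> x o-* y (circle at x) with w, y non-adjacent
                #     =>  orient x --> y
                if adjacent(x, y) and pag.mark_at(y, x) == CIRCLE:
                    if any(
                        arrow(w, x) and not adjacent(w, y)
                        for w in state.adj[x]
                        if w != y
                    ):
                        set_mark(y, x, TAIL)
                        set_mark(x, y, ARROW)
                        changed = True
                        continue
                # R2: (x -> w *-> y) or (x *-> w -> y), and x *-o y  =>  x *-> y
                if adjacent(x, y) and pag.mark_at(x, y) == CIRCLE:
                    if any(
                        (fully_directed(x, w) and arrow(w, y))
                        or (arrow(x, w) and fully_directed(w, y))
                        for w in state.adj[x] & state.adj[y]
                    ):
                        set_mark(x, y, ARROW)
                        changed = True
                        continue
        # R3: w1 *-> x <-* w2, w1 *-o v o-* w2, w1,w2 non-adjacent, v *-o x => v *-> x
        for x in nodes:
            for v in state._sorted(state.adj[x]):
                if not (adjacent(v, x) and pag.mark_at(v, x) == CIRCLE):
                    continue
                ws = [
                    w
                    for w in state._sorted(state.adj[x])
                    if w != v
                    and arrow(w, x)
                    and adjacent(w, v)
                    and pag.mark_at(w, v) == CIRCLE
                ]
                if any(
                    not adjacent(w1, w2)
                    for w1, w2 in itertools.combinations(ws, 2)
                ):
                    set_mark(v, x, ARROW)
                    changed = True
        # R4: discriminating paths
        if _rule_r4(state, pag):
            changed = True
        # R8: x -> w -> y and x o-> y  =>  x --> y
        for a, b, ma, mb in list(pag.edge_list()):
            for x, y in ((a, b), (b, a)):
                if not (adjacent(x, y) and pag.mark_at(x, y) == ARROW and circle(y, x)):
                    continue
                if any(
                    fully_directed(x, w) and fully_directed(w, y)
                    for w in state.adj[x] & state.adj[y]
                ):
                    set_mark(y, x, TAIL)
                    changed = True
                    continue
                # R9: uncovered possibly-directed path x, w, ..., y with
                # w not adjacent to y  =>  tail at x
                found = False
                for path in uncovered_pd_paths(x, y, min_len=2):
                    w = path[1]
                    if w != y and not adjacent(w, y):
                        found = True
                        break
                if found:
                    set_mark(y, x, TAIL)
                    changed = True
                    continue
                # R10: two uncovered p.d. paths x..b and x..d with b -> y,
                # d -> y, first steps m != w non-adjacent  =>  tail at x
                preds = [
                    v
                    for v in state._sorted(state.adj[y])
                    if v != x and fully_directed(v, y)
                ]
                fired = False
                for bnode, dnode in itertools.combinations(preds, 2):
                    p1s = uncovered_pd_paths(x, bnode, min_len=1)
                    p2s = uncovered_pd_paths(x, dnode, min_len=1)
                    for p1 in p1s:
                        for p2 in p2s:
                            m, w = p1[1], p2[1]
                            if m != w and not adjacent(m, w):
                                fired = True
                                break
                        if fired:
                            break
                    if fired:
                        break
                if fired:
                    set_mark(y, x, TAIL)
                    changed = True


def _rule_r4(state: _FciState, pag: Pag) -> bool:
    """Discriminating-path rule.  Returns True if any mark changed.

    A path <d, v_k, ..., v_1, b, c> is discriminating for b when d is not
    adjacent to c and every v_i is both a collider on the path and a
    parent of c.  If b sits in a separating set of (d, c) the b-c edge is
    oriented b --> c; otherwise the triple <v_1, b, c> becomes
    v_1 <-> b <-> c.
    """

    def arrow(a, b):  # arrowhead at b on the a-b edge
        return pag.adjacent(a, b) and pag.mark_at(a, b) == ARROW

    def fully_directed(a, b):
        return arrow(a, b) and pag.mark_at(b, a) == TAIL

    for c in state.nodes:
        for b in state._sorted(state.adj[c]):
            if pag.mark_at(c, b) != CIRCLE:
                continue  # rule only resolves a circle at b on the b-c edge
            # DFS over candidate paths stored as [c, b, v_1, ..., v_k];
            # v_1..v_{k-1} already verified as colliders and parents of c.
            stack: List[List[str]] = [[c, b]]
            while stack:
                path = stack.pop()
                tip = path[-1]
                prev = path[-2]
                for u in state._sorted(state.adj[tip]):
                    if u in path:
                        continue
                    if tip != b:
                        # tip becomes an interior vertex: collider on the
                        # path (arrowheads at tip on both edges) and a
                        # parent of c
                        if not (
                            arrow(prev, tip)
                            and arrow(u, tip)
                            and fully_directed(tip, c)
                        ):
                            continue
                    if u not in state.adj[c]:
                        if len(path) >= 3:  # at least <d, v_1, b, c>
                            s = state.sepset(u, c)
                            if s is not None and b in s:
                                pag.set_mark(c, b, TAIL)
                                pag.set_mark(b, c, ARROW)
                            else:
                                v1 = path[2]
                                pag.set_mark(b, v1, ARROW)
                                pag.set_mark(v1, b, ARROW)
                                pag.set_mark(c, b, ARROW)
                                pag.set_mark(b, c, ARROW)
                            return True
                    else:
                        stack.append(path + [u])
    return False


def fci(
    test: CiTest,
    nodes: Sequence[str],
    knowledge: Optional[Knowledge] = None,
    max_cond_size: Optional[int] = None,
    initial_adjacency: Optional[Set[FrozenSet[str]]] = None,
) -> Pag:
    """Fast causal inference: constraint-based PAG learning.

    ``initial_adjacency`` restricts the starting skeleton (used by
    :func:`gfci`); by default the search starts from the complete graph.
    """
    know = knowledge or Knowledge.empty()
    state = _FciState(
        test, nodes, know, _default_max_cond(len(nodes), max_cond_size), initial_adjacency
    )
    state.skeleton_search()
    state.pds_prune()
    pag = state.blank_pag()
    state.orient_colliders(pag)
    _orient_rules(state, pag)
    pag.validate()
    return pag


def gfci(
    scorer,
    test: CiTest,
    nodes: Sequence[str],
    knowledge: Optional[Knowledge] = None,
    max_cond_size: Optional[int] = None,
) -> Pag:
    """Two-phase hybrid search: GES adjacencies constrain an FCI phase."""
    know = knowledge or Knowledge.empty()
    cpdag = ges(scorer, nodes, know)
    return fci(
        test,
        nodes,
        know,
        max_cond_size=max_cond_size,
        initial_adjacency=cpdag.skeleton(),
    )
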
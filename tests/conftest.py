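"""Shared fixtures and the independent path-enumeration separation oracle.

The reachability-based separation tests in the package are checked
against this brute-force oracle: enumerate every simple path between the
query nodes and apply the blocking definition literally to each path.
"""

from __future__ import annotations

from typing import Iterable

import pytest

from icnlearn.graphs import ARROW, Dag, Mag, MixedGraph, TAIL


def _as_marked(graph) -> MixedGraph:
    if isinstance(graph, Dag):
        g = MixedGraph(graph.nodes)
        for a, b in graph.edges:
            g.add_edge(a, b, TAIL, ARROW)
        return g
    return graph


def path_enumeration_separated(graph, x: str, y: str, z: Iterable[str]) -> bool:
    """Literal m-separation: every simple path between x and y is blocked.

    A path is blocked given Z iff it contains a non-collider in Z, or a
    collider (arrowheads into it on both path edges) that is neither in Z
    nor an ancestor of Z.
    """
    g = _as_marked(graph)
    zs = set(z)
    anc = g.ancestor_sets()
    anc_z = set(zs)
    for w in zs:
        anc_z |= anc[w]

    adj = {v: [] for v in g.nodes}
    for a, b, ma, mb in g.edge_list():
        adj[a].append((b, ma, mb))
        adj[b].append((a, mb, ma))

    def paths():
        """Yield all simple paths from x to y with their edge marks."""
        stack = [([x], [])]  # (nodes on path, marks per edge)
        while stack:
            nodes_on, marks = stack.pop()
            u = nodes_on[-1]
            for (w, mu, mw) in adj[u]:
                if w in nodes_on:
                    continue
                new_marks = marks + [(mu, mw)]
                if w == y:
                    yield nodes_on + [w], new_marks
                else:
                    stack.append((nodes_on + [w], new_marks))

    for nodes_on, marks in paths():
        blocked = False
        for i in range(1, len(nodes_on) - 1):
            v = nodes_on[i]
            into_v = marks[i - 1][1] == ARROW
            out_of_v = marks[i][0] == ARROW
            collider = into_v and out_of_v
            if collider:
                if v not in anc_z:
                    blocked = True
                    break
            elif v in zs:
                blocked = True
                break
        if not blocked:
            return False
    return True


@pytest.fixture(scope="session")
def pneumonia():
    from icnlearn.examples import pneumonia_network

    return pneumonia_network()


@pytest.fixture(scope="session")
def csi_cbn():
    from icnlearn.examples import csi_network

    return csi_network()
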
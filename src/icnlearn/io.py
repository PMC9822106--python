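"""Readers and writers for the pipeline's text formats.

All artifacts are plain text and round-trip losslessly:

* graph files — header ``#nodes: A,B,C`` then one edge per line in the
  endpoint-mark notation (``A --> B``, ``A <-> B``, ``A o-> B``,
  ``A o-o B``), plus a JSON mirror;
* prior-knowledge files — one constraint per line,
  ``forbid A B`` / ``require A B``;
* expression matrices (genes x samples) and score matrices
  (samples x modules) as tab-separated text;
* discrete level matrices (samples x variables) as tab-separated text;
* GMT gene-set files (module, description, genes);
* run manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .discovery import Knowledge
from .ensemble import EdgeSet
from .enrichment import GemSignature
from .graphs import ARROW, CIRCLE, TAIL, Dag, DiscreteDataset, Mag, Pag

PathLike = Union[str, Path]

_LEFT = {TAIL: "-", ARROW: "<", CIRCLE: "o"}
_RIGHT = {TAIL: "-", ARROW: ">", CIRCLE: "o"}
_LEFT_INV = {v: k for k, v in _LEFT.items()}
_RIGHT_INV = {v: k for k, v in _RIGHT.items()}


# ---------------------------------------------------------------------------
# Graphs
# ---------------------------------------------------------------------------


def write_graph(graph, path: PathLike) -> None:
    """Write a Dag / Mag / Pag in the edge-mark text format."""
    lines = [f"#nodes: {','.join(graph.nodes)}"]
    if isinstance(graph, Dag):
        for a, b in sorted(graph.edges):
            lines.append(f"{a} --> {b}")
    else:
        for a, b, ma, mb in graph.edge_list():
            lines.append(f"{a} {_LEFT[ma]}-{_RIGHT[mb]} {b}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_edge_line(line: str) -> Tuple[str, str, str, str]:
    parts = line.split()
    if len(parts) != 3 or len(parts[1]) != 3 or parts[1][1] != "-":
        raise ValueError(f"malformed edge line: {line!r}")
    a, marks, b = parts
    try:
        return a, b, _LEFT_INV[marks[0]], _RIGHT_INV[marks[2]]
    except KeyError:
        raise ValueError(f"malformed edge marks in line: {line!r}") from None


def read_graph(path: PathLike, kind: str = "pag"):
    """Read a graph file; ``kind`` is 'dag', 'mag' or 'pag'."""
    lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines or not lines[0].startswith("#nodes:"):
        raise ValueError(f"{path}: missing '#nodes:' header")
    nodes = [n for n in lines[0].split(":", 1)[1].strip().split(",") if n]
    edges = [_parse_edge_line(l) for l in lines[1:]]
    if kind == "dag":
        dag_edges = []
        for a, b, ma, mb in edges:
            if (ma, mb) != (TAIL, ARROW):
                raise ValueError(f"{path}: non-directed edge in DAG file")
            dag_edges.append((a, b))
        return Dag(nodes, dag_edges)
    cls = {"mag": Mag, "pag": Pag}[kind]
    g = cls(nodes)
    for a, b, ma, mb in edges:
        g.add_edge(a, b, ma, mb)
    return g


def graph_to_json(graph) -> str:
    """Structured (JSON) mirror of the graph text format."""
    if isinstance(graph, Dag):
        payload = {
            "nodes": graph.nodes,
            "edges": [
                {"a": a, "b": b, "mark_a": TAIL, "mark_b": ARROW}
                for a, b in sorted(graph.edges)
            ],
        }
    else:
        payload = {
            "nodes": graph.nodes,
            "edges": [
                {"a": a, "b": b, "mark_a": ma, "mark_b": mb}
                for a, b, ma, mb in graph.edge_list()
            ],
        }
    return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Knowledge
# ---------------------------------------------------------------------------


def write_knowledge(knowledge: Knowledge, path: PathLike) -> None:
    lines = []
    for pair in sorted(tuple(sorted(p)) for p in knowledge.forbidden_pairs):
        lines.append(f"forbid {pair[0]} {pair[1]}")
    for a, b in sorted(knowledge.required_edges):
        lines.append(f"require {a} {b}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_knowledge(path: PathLike) -> Knowledge:
    forbidden = set()
    required = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3 or parts[0] not in ("forbid", "require"):
            raise ValueError(f"{path}:{ln}: malformed constraint {line!r}")
        if parts[0] == "forbid":
            forbidden.add(frozenset(parts[1:]))
        else:
            required.add((parts[1], parts[2]))
    return Knowledge(forbidden, required)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def write_expression(expr: pd.DataFrame, path: PathLike) -> None:
    """Genes in rows, header = sample ids."""
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_scores(scores: pd.DataFrame, path: PathLike) -> None:
    """Samples in rows, header = module ids."""
    scores.to_csv(path, sep="\t", index_label="sample")


def read_scores(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_discrete(data: DiscreteDataset, path: PathLike) -> None:
    data.to_frame().to_csv(path, sep="\t", index_label="sample")


def read_discrete(path: PathLike) -> DiscreteDataset:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        raise ValueError(f"{path}: discrete matrix must hold integers")
    arities = values.max(axis=0) + 1
    return DiscreteDataset(
        [str(s) for s in frame.index],
        [str(c) for c in frame.columns],
        values.astype(np.int16),
        np.maximum(arities, 2),
    )


# ---------------------------------------------------------------------------
# GMT signatures
# ---------------------------------------------------------------------------


def write_gmt(signatures: Mapping[str, Sequence[Tuple[str, float]]], path: PathLike) -> None:
    """Module, description (weights, comma separated), genes in rank order."""
    lines = []
    for module, genes in signatures.items():
        names = [g for g, _ in genes]
        weights = ",".join(f"{w:.6g}" for _, w in genes)
        lines.append("\t".join([module, f"weights:{weights}"] + names))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: PathLike) -> Dict[str, GemSignature]:
    out: Dict[str, GemSignature] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs module, description, genes")
        module, desc, genes = parts[0], parts[1], parts[2:]
        if desc.startswith("weights:") and desc[len("weights:"):]:
            weights = [float(w) for w in desc[len("weights:"):].split(",")]
            if len(weights) != len(genes):
                raise ValueError(f"{path}:{ln}: weight count mismatch")
        else:
            weights = [float(len(genes) - i) for i in range(len(genes))]
        out[module] = GemSignature(module, list(zip(genes, weights)))
    return out


# ---------------------------------------------------------------------------
# Edge sets and manifests
# ---------------------------------------------------------------------------


def write_edge_set(edge_set: EdgeSet, path: PathLike) -> None:
    """Directed consensus edges in the graph text format (with a frequency
    comment per edge)."""
    nodes = sorted({v for e in edge_set.edges for v in e} | {
        v for e in edge_set.frequencies for v in e
    })
    lines = [f"#nodes: {','.join(nodes)}"]
    for a, b in edge_set.sorted_edges():
        lines.append(f"{a} --> {b}  # freq={edge_set.frequencies.get((a, b), 0):.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_set(path: PathLike) -> EdgeSet:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines or not lines[0].startswith("#nodes:"):
        raise ValueError(f"{path}: missing '#nodes:' header")
    edges = set()
    freqs = {}
    for line in lines[1:]:
        body, _, comment = line.partition("#")
        parts = body.split()
        if len(parts) != 3 or parts[1] != "-->":
            raise ValueError(f"{path}: malformed edge line {line!r}")
        e = (parts[0], parts[2])
        edges.add(e)
        if "freq=" in comment:
            freqs[e] = float(comment.split("freq=")[1])
        else:
            freqs[e] = 1.0
    return EdgeSet(edges, freqs)


def edge_set_manifest(edge_set: EdgeSet, settings: Mapping) -> Dict:
    return {
        "settings": dict(settings),
        "n_boot": edge_set.n_boot,
        "retained_edges": [list(e) for e in edge_set.sorted_edges()],
        "directed_frequencies": {
            f"{a}->{b}": f for (a, b), f in sorted(edge_set.frequencies.items())
        },
        "other_endpoint_frequencies": dict(sorted(edge_set.other_frequencies.items())),
    }


def write_manifest(payload: Mapping, path: PathLike) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
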
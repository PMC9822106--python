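"""Worked-example fixtures.

Two small, fully specified causal models used throughout the docs and
tests:

* :func:`pneumonia_network` — a seven-variable hypothetical medical CBN
  (pneumonia drives two circulating cytokines, each cytokine also has a
  genetic cause (a SNP); the cytokines cause acute kidney injury, which
  causes mortality).  With ``pneumonia`` unmeasured it is the canonical
  illustration of latent confounding: the projection onto the measured
  variables contains ``cytokine1 <-> cytokine2`` and the oracle PAG leaves
  each SNP -> cytokine relationship as ``SNP o-> cytokine``.
* :func:`csi_network` — a four-variable CBN in which X4 has parents
  X1, X2, X3 but is independent of X3 *within* the context
  (X1 = 1, X2 = 1): a minimal example of context-specific independence
  (CSI), the structure that instance-specific search must detect.

The edge sets and parameterisations are fixed here so that every worked
example in the README is exactly reproducible.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .graphs import Cbn, Dag

PNEUMONIA_NODES = [
    "pneumonia",
    "SNP1",
    "SNP2",
    "cytokine1",
    "cytokine2",
    "AKI",
    "mortality",
]

PNEUMONIA_EDGES = [
    ("pneumonia", "cytokine1"),
    ("pneumonia", "cytokine2"),
    ("SNP1", "cytokine1"),
    ("SNP2", "cytokine2"),
    ("cytokine1", "AKI"),
    ("cytokine2", "AKI"),
    ("AKI", "mortality"),
]


def pneumonia_dag() -> Dag:
    """The hypothetical pneumonia network structure."""
    return Dag(PNEUMONIA_NODES, PNEUMONIA_EDGES)


def _binary_cpt(p_one_by_config) -> np.ndarray:
    p1 = np.asarray(p_one_by_config, dtype=float).reshape(-1, 1)
    return np.hstack([1.0 - p1, p1])


def pneumonia_network() -> Cbn:
    """The pneumonia DAG with a fixed, non-degenerate binary parameterisation.

    Effects are strong enough that the conditional (in)dependences of the
    structure are detectable from moderate samples, and no parameters are
    close to the unfaithful cancellation regime.

    Parent configurations are indexed with the first-listed parent as the
    most significant digit (parents ordered by node order).
    """
    dag = pneumonia_dag()
    arities = {v: 2 for v in dag.nodes}
    cpts: Dict[str, np.ndarray] = {
        "pneumonia": _binary_cpt([0.30]),
        "SNP1": _binary_cpt([0.40]),
        "SNP2": _binary_cpt([0.35]),
        # parents (pneumonia, SNP1): configs 00, 01, 10, 11
        "cytokine1": _binary_cpt([0.10, 0.35, 0.60, 0.85]),
        # parents (pneumonia, SNP2)
        "cytokine2": _binary_cpt([0.10, 0.30, 0.65, 0.90]),
        # parents (cytokine1, cytokine2)
        "AKI": _binary_cpt([0.05, 0.40, 0.35, 0.80]),
        # parent (AKI)
        "mortality": _binary_cpt([0.10, 0.60]),
    }
    return Cbn(dag, arities, cpts)


PNEUMONIA_LATENT = "pneumonia"


# ---------------------------------------------------------------------------
# Context-specific independence example
# ---------------------------------------------------------------------------

CSI_NODES = ["X1", "X2", "X3", "X4"]
CSI_CONTEXT: Dict[str, int] = {"X1": 1, "X2": 1}
CSI_INSTANCE: Dict[str, int] = {"X1": 1, "X2": 1, "X3": 0}


def csi_network() -> Cbn:
    """A CBN where X4 ⟂ X3 | (X1 = 1, X2 = 1) but not in other contexts.

    X1, X2, X3 are independent ternary roots; X4 has all three as parents.
    Within the context (X1 = 1, X2 = 1) the conditional distribution of X4
    ignores X3, so for an instance carrying those values the
    instance-specific parents of X4 are just {X1, X2}.
    """
    dag = Dag(CSI_NODES, [("X1", "X4"), ("X2", "X4"), ("X3", "X4")])
    arities = {"X1": 2, "X2": 2, "X3": 2, "X4": 3}
    # outside the CSI context, X4's distribution is an additive mixture of
    # per-parent components, so every parent shifts it in every context
    p3 = np.array([[0.75, 0.15, 0.10], [0.10, 0.15, 0.75]])
    p1 = np.array([[0.70, 0.20, 0.10], [0.10, 0.30, 0.60]])
    p2 = np.array([[0.65, 0.25, 0.10], [0.10, 0.25, 0.65]])
    rows = []
    for x1 in range(2):
        for x2 in range(2):
            for x3 in range(2):
                if (x1, x2) == (1, 1):
                    rows.append([0.2, 0.6, 0.2])
                else:
                    rows.append(list(0.40 * p3[x3] + 0.30 * p1[x1] + 0.30 * p2[x2]))
    cpts = {
        "X1": np.array([[0.50, 0.50]]),
        "X2": np.array([[0.50, 0.50]]),
        "X3": np.array([[0.55, 0.45]]),
        "X4": np.array(rows),
    }
    return Cbn(dag, arities, cpts)
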
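"""Synthetic-data generators with recorded ground truth.

Every stage of the pipeline gets a generator here:

* :func:`random_dag` / :func:`random_cbn` / :func:`plant_latents` — random
  discrete causal Bayesian networks, optionally with latent confounders,
  for exercising structure search against a known graph.
* :func:`csi_cohort` — a pooled cohort of tumors from several subtypes
  that share a backbone network but differ in a declared list of
  discriminating edges; the subtype indicator is itself a measured
  variable, so the heterogeneity is context-specific structure that
  instance-specific search can recover.
* :func:`synth_bulk_cohort` — bulk expression assembled from weighted
  module-signature blocks plus Gaussian noise, with the per-sample module
  activities recorded, for validating single-sample enrichment scoring.

All generators are deterministic functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .graphs import Cbn, Dag, DiscreteDataset, GraphError, forward_sample

#: default faithfulness guard: minimum total-variation shift of the child
#: distribution between any two values of any single parent
DEFAULT_MIN_EFFECT = 0.15


def random_dag(p: int, avg_degree: float, seed: int) -> Dag:
    """Erdős–Rényi DAG over a random topological order of ``p`` nodes.

    Edge probability is chosen so the expected number of edges is
    ``p * avg_degree / 2``.
    """
    if p < 2:
        raise ValueError("need at least 2 nodes")
    if avg_degree >= p:
        raise ValueError("avg_degree must be below the node count")
    rng = np.random.default_rng(seed)
    nodes = [f"V{i}" for i in range(p)]
    order = rng.permutation(p)
    prob = avg_degree * p / 2.0 / (p * (p - 1) / 2.0)
    edges = []
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < prob:
                a, b = order[i], order[j]
                edges.append((nodes[a], nodes[b]))
    return Dag(nodes, edges)


def random_cbn(
    dag: Dag,
    arity: int = 3,
    concentration: float = 1.0,
    min_effect: float = DEFAULT_MIN_EFFECT,
    seed: int = 0,
    _max_tries: int = 200,
) -> Cbn:
    """Random CPTs from a symmetric Dirichlet with a faithfulness guard.

    Each CPT is redrawn until, for every parent and every pair of that
    parent's levels (other parents held fixed), the child distribution
    shifts by total variation at least ``min_effect``.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    arities = {v: arity for v in dag.nodes}
    cpts: Dict[str, np.ndarray] = {}
    for v in dag.nodes:
        parents = sorted(dag.parents(v), key=dag._index.__getitem__)
        p_ar = [arities[p] for p in parents]
        n_cfg = int(np.prod(p_ar)) if parents else 1
        for attempt in range(_max_tries):
            cpt = rng.dirichlet(np.full(arity, concentration), size=n_cfg)
            if not parents or min_effect <= 0 or _effects_ok(cpt, p_ar, min_effect):
                cpts[v] = cpt
                break
        else:
            raise GraphError(
                f"could not satisfy min_effect={min_effect} for node {v!r}; "
                "try a smaller min_effect"
            )
    return Cbn(dag, arities, cpts)


def _effects_ok(cpt: np.ndarray, parent_arities: Sequence[int], min_effect: float) -> bool:
    shape = tuple(parent_arities) + (cpt.shape[1],)
    table = cpt.reshape(shape)
    for axis in range(len(parent_arities)):
        moved = np.moveaxis(table, axis, 0)
        for a in range(moved.shape[0]):
            for b in range(a + 1, moved.shape[0]):
                tv = 0.5 * np.abs(moved[a] - moved[b]).sum(axis=-1)
                if (tv < min_effect).any():
                    return False
    return True


def plant_latents(dag: Dag, n_latents: int, seed: int) -> Tuple[Dag, Set[str]]:
    """Add ``n_latents`` root confounders, each with two measured children."""
    if n_latents < 0:
        raise ValueError("n_latents must be >= 0")
    if n_latents == 0:
        return dag.copy(), set()
    rng = np.random.default_rng(seed)
    measured = list(dag.nodes)
    if len(measured) < 2:
        raise GraphError("need at least two measured candidate children")
    latents = [f"L{i}" for i in range(n_latents)]
    out = Dag(list(dag.nodes) + latents, dag.edges)
    for l in latents:
        a, b = rng.choice(len(measured), size=2, replace=False)
        out.add_edge(l, measured[a])
        out.add_edge(l, measured[b])
    return out, set(latents)


def mixture_cbn(dag: Dag, arity: int = 3, effect: float = 0.25, seed: int = 0) -> Cbn:
    """A CBN whose child distributions are additive mixtures of per-parent
    components, so every parent shifts the child in every context.

    For a node with m parents, the child distribution given a
    configuration is ``0.9/m * sum_k P_k[level_k] + 0.1 * uniform`` with
    component rows drawn to be well separated (pairwise total variation at
    least ``min(0.9, effect * m / 0.9)``); the per-parent effect in any
    context is then at least ``effect`` by construction.  This avoids the
    rejection blow-up of a row-wise guard for nodes with many parents.
    """
    rng = np.random.default_rng(seed)
    arities = {v: arity for v in dag.nodes}
    cpts: Dict[str, np.ndarray] = {}
    base_w = 0.10
    for v in dag.nodes:
        parents = sorted(dag.parents(v), key=dag._index.__getitem__)
        if not parents:
            # roots: mildly bounded away from degenerate marginals
            for _ in range(1000):
                row = rng.dirichlet(np.full(arity, 2.0))
                if row.min() >= 0.12:
                    break
            cpts[v] = row.reshape(1, -1)
            continue
        m = len(parents)
        tv_target = min(0.9, effect * m / (1.0 - base_w))
        comps = []
        for _ in parents:
            for _ in range(5000):
                rows = rng.dirichlet(np.full(arity, 0.4), size=arity)
                tv = min(
                    0.5 * np.abs(rows[a] - rows[b]).sum()
                    for a in range(arity)
                    for b in range(a + 1, arity)
                )
                if tv >= tv_target:
                    break
            else:
                raise GraphError(f"cannot separate mixture components for {v!r}")
            comps.append(rows)
        n_cfg = arity ** m
        cpt = np.full((n_cfg, arity), base_w / arity)
        for cfg in range(n_cfg):
            levels = []
            c = cfg
            for _ in range(m):
                levels.append(c % arity)
                c //= arity
            levels = levels[::-1]  # first parent is the most significant digit
            for k, lvl in enumerate(levels):
                cpt[cfg] += (1.0 - base_w) / m * comps[k][lvl]
        cpts[v] = cpt
    return Cbn(dag, arities, cpts)


# ---------------------------------------------------------------------------
# Context-specific cohorts
# ---------------------------------------------------------------------------


@dataclass
class PlantedCohort:
    """A pooled multi-subtype cohort with recorded causal ground truth."""

    backbone: Dag
    subtype_cbns: List[Cbn]
    subtype_labels: np.ndarray  # per-sample subtype index
    data: DiscreteDataset  # pooled, includes the subtype indicator column
    discriminating_edges: List[Tuple[str, str]]
    edge_presence: np.ndarray  # (n_subtypes, n_discriminating) booleans
    indicator: str = "subtype"


def csi_cohort(
    p: int = 8,
    n_subtypes: int = 2,
    n_per_subtype: int = 2000,
    n_discriminating_edges: int = 1,
    seed: int = 0,
    arity: int = 3,
    min_effect: float = 0.30,
) -> PlantedCohort:
    """Pooled cohort whose subtypes differ only by declared edges.

    A shared backbone CBN is drawn; ``n_discriminating_edges`` backbone
    edges are selected, and each subtype keeps or drops each of them
    according to a distinct binary pattern (subtype 0 keeps all).  When an
    edge u -> v is dropped for a subtype, the CPT of v is replaced, for
    that subtype's rows, by the CPT averaged over u — so v becomes
    independent of u in that context while all other families are shared.
    The subtype indicator is included as a measured variable, making the
    heterogeneity literally context-specific structure.

    Discriminating edges are chosen among edges whose orientation is
    identifiable from the pooled data (see :func:`_orientable_edges`), so
    the planted signal can appear in directed-edge consensus networks;
    the backbone is redrawn until enough such edges exist.
    """
    if n_subtypes < 2:
        raise ValueError("need at least 2 subtypes")
    if n_discriminating_edges < 0:
        raise ValueError("n_discriminating_edges must be >= 0")
    rng = np.random.default_rng(seed)
    # constructive backbone: one collider motif (w1, w2 -> u -> v) per
    # discriminating edge, chained v_k -> w1_{k+1}; the collider at u makes
    # the u -> v orientation identifiable (arrowheads into u, then rule R1
    # puts the tail on u -> v), and v's single-parent family keeps the
    # planted effect strong.  Extra nodes are attached as children of
    # random motif nodes; extra motifs beyond the requested count act as
    # subtype-invariant backbone structure.
    n_motifs = max(n_discriminating_edges, 1)  # a null cohort still gets structure
    motif_nodes = 4 * n_motifs
    if n_motifs * 4 > max(p, motif_nodes):
        raise ValueError("more discriminating edges than the backbone can host")
    p_eff = max(p, motif_nodes)
    nodes = [f"V{i}" for i in range(p_eff)]
    edges: List[Tuple[str, str]] = []
    disc: List[Tuple[str, str]] = []
    for k in range(n_motifs):
        w1, w2, u, v = nodes[4 * k : 4 * k + 4]
        edges += [(w1, u), (w2, u), (u, v)]
        if k < n_discriminating_edges:
            disc.append((u, v))
        if k > 0:
            edges.append((nodes[4 * (k - 1) + 3], w1))  # chain the motifs
    for j in range(motif_nodes, p_eff):
        parent = nodes[int(rng.integers(0, motif_nodes))]
        edges.append((parent, nodes[j]))
    dag = Dag(nodes, edges)
    disc = sorted(disc)
    if n_discriminating_edges > len(dag.edges):
        raise ValueError("more discriminating edges than backbone edges")
    cbn = mixture_cbn(dag, arity=arity, effect=min_effect, seed=seed * 31 + 7)

    # distinct presence patterns; subtype 0 keeps every discriminating
    # edge, and the subtype index bits are cycled over the edges so that
    # with more edges than bits every pair of subtypes differs in several
    # edges (more robust recovery)
    bits = max(int(np.ceil(np.log2(n_subtypes))), 1)
    presence = np.ones((n_subtypes, n_discriminating_edges), dtype=bool)
    for s in range(n_subtypes):
        for k in range(n_discriminating_edges):
            presence[s, k] = ((s >> (k % bits)) & 1) == 0

    subtype_cbns: List[Cbn] = []
    for s in range(n_subtypes):
        cpts = {v: np.array(cbn.cpts[v]) for v in dag.nodes}
        for k, (u, v) in enumerate(disc):
            if presence[s, k]:
                continue
            cpts[v] = _marginalize_parent(cbn, v, u)
        subtype_cbns.append(Cbn(dag, dict(cbn.arities), cpts))

    blocks = []
    labels = []
    for s in range(n_subtypes):
        ds = forward_sample(subtype_cbns[s], n_per_subtype, seed * 1013 + 17 * s + 3)
        blocks.append(ds.values)
        labels.extend([s] * n_per_subtype)
    labels = np.array(labels, dtype=int)
    perm = np.random.default_rng(seed * 2029 + 1).permutation(len(labels))
    values = np.vstack(blocks)[perm]
    labels = labels[perm]
    pooled = DiscreteDataset(
        [f"t{i}" for i in range(len(labels))],
        ["subtype"] + list(dag.nodes),
        np.column_stack([labels.astype(np.int16), values]),
        np.array([n_subtypes] + [arity] * p),
    )
    return PlantedCohort(dag, subtype_cbns, labels, pooled, disc, presence)


def _marginalize_parent(cbn: Cbn, node: str, parent: str) -> np.ndarray:
    """CPT of ``node`` with ``parent``'s influence removed (the parent
    stays in the configuration index, but all its levels share one row).

    The replacement row is the parent-averaged distribution shrunk half
    way toward uniform: it is independent of the dropped parent, it is
    identical for every subtype lacking the edge, and it differs clearly
    from the intact family — so the subtype indicator's own influence on
    the child is strong enough for structure search to register, which
    the instance-specific pruning step relies on.
    """
    parents = cbn.parent_order(node)
    p_ar = [cbn.arities[p] for p in parents]
    r = cbn.arities[node]
    table = np.array(cbn.cpts[node]).reshape(tuple(p_ar) + (r,))
    axis = parents.index(parent)
    mean = table.mean(axis=axis, keepdims=True)
    mean = 0.5 * mean + 0.5 / r
    flat = np.broadcast_to(mean, table.shape).reshape(-1, r)
    return np.ascontiguousarray(flat)


def linear_gaussian_cohort(
    p: int = 10,
    n: int = 500,
    seed: int = 0,
    noise_sd: float = 0.6,
    avg_degree: float = 2.0,
) -> Tuple[Dag, pd.DataFrame]:
    """Continuous module-score cohort from a linear Gaussian SEM on a
    random DAG (edge weights uniform in ±[0.6, 1.2]); used to validate
    Markov-boundary predictive sufficiency."""
    rng = np.random.default_rng(seed)
    dag = random_dag(p, avg_degree, seed)
    cols: Dict[str, np.ndarray] = {}
    for v in dag.topological_order():
        x = rng.normal(0.0, 1.0, n) * noise_sd
        for u in sorted(dag.parents(v)):
            x += rng.uniform(0.6, 1.2) * np.sign(rng.uniform(-1.0, 1.0)) * cols[u]
        cols[v] = x
    return dag, pd.DataFrame({v: cols[v] for v in dag.nodes})


# ---------------------------------------------------------------------------
# Signature-structured bulk expression
# ---------------------------------------------------------------------------


@dataclass
class BulkCohort:
    expression: pd.DataFrame  # genes x samples
    signatures: Dict[str, List[Tuple[str, float]]]  # module -> ranked (gene, weight)
    activities: pd.DataFrame  # samples x modules (ground truth)


def synth_bulk_cohort(
    n_modules: int = 5,
    genes_per_module: int = 100,
    n_samples: int = 200,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_background_genes: Optional[int] = None,
) -> BulkCohort:
    """Bulk expression as weighted module blocks plus Gaussian noise.

    Per-sample module activities are standard normal; each module's genes
    load on its activity with weights decreasing from 1.0 to 0.5 (the
    ranked signature), and background genes are pure noise.
    """
    for val, name in ((n_modules, "n_modules"), (genes_per_module, "genes_per_module"), (n_samples, "n_samples")):
        if val < 1:
            raise ValueError(f"{name} must be >= 1")
    rng = np.random.default_rng(seed)
    if n_background_genes is None:
        n_background_genes = genes_per_module
    samples = [f"s{i}" for i in range(n_samples)]
    modules = [f"M{i}" for i in range(n_modules)]
    activities = rng.standard_normal((n_samples, n_modules))

    rows = []
    gene_ids = []
    signatures: Dict[str, List[Tuple[str, float]]] = {}
    for m_i, m in enumerate(modules):
        weights = np.linspace(1.0, 0.5, genes_per_module)
        sig = []
        for g_i in range(genes_per_module):
            gid = f"{m}_g{g_i:03d}"
            gene_ids.append(gid)
            expr = weights[g_i] * activities[:, m_i] + noise_sd * rng.standard_normal(
                n_samples
            )
            rows.append(expr)
            sig.append((gid, float(weights[g_i])))
        signatures[m] = sig
    for b in range(n_background_genes):
        gene_ids.append(f"BG_g{b:03d}")
        rows.append(rng.standard_normal(n_samples))

    expression = pd.DataFrame(np.array(rows), index=gene_ids, columns=samples)
    act = pd.DataFrame(activities, index=samples, columns=modules)
    return BulkCohort(expression, signatures, act)
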
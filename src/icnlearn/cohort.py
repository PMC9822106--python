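"""Cohort-level analytics over per-tumor networks and activity scores.

* :func:`edge_vectorize` — represent each tumor's consensus network as a
  binary vector over the union of directed edges.
* :func:`consensus_cluster` — Monti-style consensus clustering with the
  CDF delta-area criterion for choosing the number of clusters.
* :func:`markov_boundary` / :func:`mb_prediction_cv` — extract a target's
  Markov boundary (parents, children, parents of children) from a
  directed edge set and validate it predictively with cross-validated
  penalized regression.
* :func:`cross_type_correlations` — inter-category correlation screen
  (intra-category pairs are excluded to avoid co-expression confounding).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import AgglomerativeClustering
from sklearn.linear_model import RidgeCV
from sklearn.model_selection import KFold

from .ensemble import EdgeSet


def _edge_label(e: Tuple[str, str]) -> str:
    return f"{e[0]}->{e[1]}"


def edge_vectorize(icns: Sequence[EdgeSet], tumor_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Binary tumor x edge matrix over the union of directed edges.

    Columns are the sorted union of edges across all networks; rows follow
    the input order.
    """
    if not icns:
        raise ValueError("need at least one network")
    union = sorted(set().union(*(icn.edges for icn in icns)))
    ids = list(tumor_ids) if tumor_ids is not None else [f"t{i}" for i in range(len(icns))]
    data = np.zeros((len(icns), len(union)), dtype=np.int8)
    for i, icn in enumerate(icns):
        for j, e in enumerate(union):
            if e in icn.edges:
                data[i, j] = 1
    return pd.DataFrame(data, index=ids, columns=[_edge_label(e) for e in union])


# ---------------------------------------------------------------------------
# Consensus clustering
# ---------------------------------------------------------------------------


@dataclass
class ConsensusResult:
    k_star: int
    assignments: pd.Series  # item -> cluster label (for k_star)
    consensus: Dict[int, np.ndarray]  # k -> consensus matrix
    areas: Dict[int, float]
    delta_areas: Dict[int, float]
    assignments_by_k: Dict[int, pd.Series]


def _cdf_area(consensus: np.ndarray) -> float:
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = np.sort(consensus[iu])
    m = len(vals)
    if m == 0:
        return 0.0
    # area under the empirical CDF on [0, 1]
    xs = np.concatenate([vals, [1.0]])
    cdf = np.arange(1, m + 1) / m
    return float(np.sum(np.diff(xs) * cdf) + vals[0] * 0.0)


def consensus_cluster(
    matrix: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 6,
    reps: int = 250,
    item_fraction: float = 0.8,
    seed: int = 0,
    metric: str = "hamming",
    delta_threshold: float = 0.1,
) -> ConsensusResult:
    """Monti-style consensus clustering with CDF delta-area model selection.

    For each candidate k, items are repeatedly subsampled and clustered
    (agglomerative, average linkage; Hamming distance for binary edge
    vectors — absence of an edge is as informative as presence — and
    Euclidean for continuous scores); the consensus matrix holds
    co-clustering frequencies among co-sampled pairs.  The number of
    clusters is the largest k whose relative increase in area under the
    consensus-value CDF exceeds ``delta_threshold`` — past the true k the
    area stops increasing appreciably.  Final labels come from clustering
    1 - consensus.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    if reps < 10:
        raise ValueError("reps must be >= 10")
    n = matrix.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be below the number of items")
    X = matrix.to_numpy(dtype=float)
    if metric in ("hamming", "matching"):
        dist = squareform(pdist(X.astype(bool), metric="hamming"))
    elif metric == "jaccard":
        with np.errstate(invalid="ignore"):
            dist = squareform(pdist(X.astype(bool), metric="jaccard"))
        dist = np.nan_to_num(dist, nan=0.0)  # all-zero pairs count as identical
    else:
        dist = squareform(pdist(X, metric="euclidean"))

    rng = np.random.default_rng(seed)
    m = max(int(np.floor(item_fraction * n)), k_max + 1)
    consensus: Dict[int, np.ndarray] = {}
    areas: Dict[int, float] = {}
    deltas: Dict[int, float] = {}
    labels_by_k: Dict[int, pd.Series] = {}

    subsamples = [rng.choice(n, size=m, replace=False) for _ in range(reps)]
    for k in range(k_min, k_max + 1):
        hits = np.zeros((n, n))
        both = np.zeros((n, n))
        for idx in subsamples:
            sub = dist[np.ix_(idx, idx)]
            labels = AgglomerativeClustering(
                n_clusters=k, metric="precomputed", linkage="average"
            ).fit_predict(sub)
            both[np.ix_(idx, idx)] += 1
            same = labels[:, None] == labels[None, :]
            hits[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            cons = np.where(both > 0, hits / np.maximum(both, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2.0
        consensus[k] = cons
        areas[k] = _cdf_area(cons)
        final = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage="average"
        ).fit_predict(1.0 - cons)
        labels_by_k[k] = pd.Series(final, index=matrix.index)

    for k in range(k_min, k_max + 1):
        if k == k_min:
            deltas[k] = areas[k]
        else:
            prev = areas[k - 1]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else 0.0

    k_star = k_min
    for k in range(k_min, k_max + 1):
        if deltas[k] > delta_threshold:
            k_star = k
    return ConsensusResult(
        k_star, labels_by_k[k_star], consensus, areas, deltas, labels_by_k
    )


# ---------------------------------------------------------------------------
# Markov boundaries and predictive validation
# ---------------------------------------------------------------------------


def markov_boundary(edges, target: str, nodes: Optional[Iterable[str]] = None) -> Set[str]:
    """Parents, children, and other parents of the target's children,
    over a directed edge set (an :class:`EdgeSet` or iterable of pairs).

    ``nodes``, when given, is the variable universe: a target outside it
    raises ``KeyError``.  Without a universe, any target is accepted and
    an isolated one simply has an empty boundary."""
    pairs = edges.edges if isinstance(edges, EdgeSet) else set(edges)
    if nodes is not None and target not in set(nodes):
        raise KeyError(f"unknown target {target!r}")
    parents = {a for (a, b) in pairs if b == target}
    children = {b for (a, b) in pairs if a == target}
    spouses = {a for (a, b) in pairs if b in children and a != target}
    return parents | children | spouses


def mb_prediction_cv(
    scores: pd.DataFrame,
    edges,
    target: str,
    folds: int = 10,
    seed: int = 0,
    predictors: Optional[Sequence[str]] = None,
) -> float:
    """Cross-validated R² of predicting a target module from its Markov
    boundary (or an explicit predictor list).

    L2-penalized linear regression with internal penalty selection; the
    returned value is the squared Pearson correlation between out-of-fold
    predictions and observations.  A target with an empty boundary
    returns 0.0.
    """
    if folds > scores.shape[0]:
        raise ValueError("more folds than samples")
    if predictors is None:
        try:
            mb = markov_boundary(edges, target)
        except KeyError:
            mb = set()
        predictors = sorted(v for v in mb if v in scores.columns)
    if not predictors:
        return 0.0
    X = scores[list(predictors)].to_numpy(dtype=float)
    y = scores[target].to_numpy(dtype=float)
    preds = np.empty_like(y)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    alphas = np.logspace(-3, 3, 13)
    for train, test in kf.split(X):
        model = RidgeCV(alphas=alphas).fit(X[train], y[train])
        preds[test] = model.predict(X[test])
    if np.std(preds) == 0 or np.std(y) == 0:
        return 0.0
    r = float(np.corrcoef(preds, y)[0, 1])
    return r * r


# ---------------------------------------------------------------------------
# Cross-category correlation screen
# ---------------------------------------------------------------------------


def cross_type_correlations(
    scores: pd.DataFrame,
    type_labels: Mapping[str, str],
    top_n: int = 10,
) -> pd.DataFrame:
    """Each module's strongest Pearson correlations with modules of *other*
    categories (intra-category pairs are never reported).

    Returns a tidy frame with columns (module, partner, r, rank).
    """
    cats = {m: type_labels[m] for m in scores.columns}
    if len(set(cats.values())) < 2:
        raise ValueError("need at least 2 module categories")
    corr = scores.corr(method="pearson")
    rows = []
    for m in scores.columns:
        partners = [
            (abs(corr.loc[m, o]), corr.loc[m, o], o)
            for o in scores.columns
            if o != m and cats[o] != cats[m]
        ]
        partners.sort(key=lambda t: (-t[0], t[2]))
        for rank, (_, r, o) in enumerate(partners[:top_n], start=1):
            rows.append((m, o, float(r), rank))
    return pd.DataFrame(rows, columns=["module", "partner", "r", "rank"])
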
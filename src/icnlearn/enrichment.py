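"""From module signatures and bulk expression to per-tumor activity scores.

A gene expression module (GEM) is a ranked list of co-expressed genes;
its activity in a bulk sample is estimated with single-sample gene-set
variation analysis (GSVA): per-gene kernel-smoothed ECDF transformation
across the cohort, per-sample ranking, and a weighted
Kolmogorov–Smirnov-like random-walk statistic.  Scores are then
discretized to three levels (0/1/2) by the 25th/75th percentile brackets
for the discrete causal searches.

Expression matrices are pandas DataFrames with genes in rows and samples
in columns; score matrices have samples in rows and modules in columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .graphs import DiscreteDataset

logger = logging.getLogger(__name__)


@dataclass
class GemSignature:
    """A module's genes, ranked by the probability mass assigned to them."""

    module: str
    genes: List[Tuple[str, float]]  # (gene id, weight), weights non-increasing

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"empty signature for module {self.module!r}")
        ws = [w for _, w in self.genes]
        if any(b > a + 1e-12 for a, b in zip(ws, ws[1:])):
            raise ValueError(f"signature for {self.module!r} is not rank-ordered")


def top_k_signature(signature: GemSignature, k: int) -> List[str]:
    """The first ``min(k, len)`` genes by weight; ties broken by gene id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(signature.genes, key=lambda gw: (-gw[1], gw[0]))
    return [g for g, _ in ordered[:k]]


# ---------------------------------------------------------------------------
# GSVA
# ---------------------------------------------------------------------------


def gsva_scores(
    expression: pd.DataFrame,
    signatures: Mapping[str, Sequence[str]],
    tau: float = 1.0,
    mx_diff: bool = True,
) -> pd.DataFrame:
    """Single-sample enrichment scores of each gene set in each sample.

    Per gene, expression is transformed through a Gaussian-kernel-smoothed
    ECDF across samples (bandwidth sd/4); per sample, genes are ranked by
    the transformed values and the symmetric rank statistic
    ``|p/2 - rank|`` feeds a weighted KS-like random walk down the ranked
    list (membership weights raised to ``tau``).  The enrichment score is
    the magnitude difference of the maximal positive and negative walk
    deviations (``mx_diff``), or the single largest deviation otherwise.

    Returns samples x modules.  Signature genes absent from the
    expression matrix are logged and skipped; a module with no matching
    genes is an error.
    """
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples for enrichment scoring")
    if expression.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    genes = list(expression.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    x = expression.to_numpy(dtype=float)
    p, n = x.shape

    # gene-wise kernel ECDF across samples
    sd = x.std(axis=1, ddof=1)
    bw = np.where(sd > 0, sd / 4.0, 1.0)
    z = np.empty_like(x)
    for i in range(p):
        if sd[i] == 0:
            z[i] = 0.5
        else:
            z[i] = norm.cdf((x[i][:, None] - x[i][None, :]) / bw[i]).mean(axis=1)

    # per-sample ranking, highest transformed value first
    order = np.argsort(-z, axis=0, kind="stable")
    ranks = np.empty_like(order)
    col = np.arange(n)
    for r in range(p):
        ranks[order[r], col] = r + 1
    stat = np.abs(p / 2.0 - ranks) ** tau  # symmetric rank weight, (p, n)

    out = {}
    for module, sig_genes in signatures.items():
        present = [g for g in sig_genes if g in gene_pos]
        missing = [g for g in sig_genes if g not in gene_pos]
        if missing:
            logger.info(
                "module %s: %d signature genes absent from expression", module, len(missing)
            )
        if not present:
            raise ValueError(f"no signature genes of module {module!r} in expression")
        members = np.zeros(p, dtype=bool)
        members[[gene_pos[g] for g in present]] = True
        m = members.sum()
        scores = np.empty(n)
        for j in range(n):
            ordered_members = members[order[:, j]]
            w = stat[order[:, j], j]
            inc = np.where(ordered_members, w, 0.0)
            denom = inc.sum()
            pos = np.cumsum(inc) / denom
            neg = np.cumsum(~ordered_members) / (p - m)
            walk = pos - neg
            if mx_diff:
                scores[j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
            else:
                scores[j] = walk[np.argmax(np.abs(walk))]
        out[module] = scores

    result = pd.DataFrame(out, index=expression.columns)
    if (result.abs() > 3).any().any():  # soft sanity check on score scale
        warnings.warn("enrichment scores outside the expected -3..3 range")
    return result


# ---------------------------------------------------------------------------
# Percentile discretization
# ---------------------------------------------------------------------------


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    """Inclusive nearest-rank quantile: the ceil(q*n)-th smallest value."""
    n = len(sorted_vals)
    k = max(int(np.ceil(q * n)), 1)
    return float(sorted_vals[k - 1])


def discretize_percentiles(scores: pd.DataFrame) -> DiscreteDataset:
    """Discretize each column to 0/1/2 by the [0-25%], (25-75%], (75-100%]
    percentile brackets (inclusive nearest-rank quantiles, ties to the
    lower bracket).  A constant column maps every sample to level 1, with
    a warning."""
    if scores.shape[0] < 4:
        raise ValueError("need at least 4 samples per column to discretize")
    values = np.empty(scores.shape, dtype=np.int16)
    for j, c in enumerate(scores.columns):
        col = scores[c].to_numpy(dtype=float)
        if np.all(col == col[0]):
            warnings.warn(f"column {c!r} is constant; all samples assigned level 1")
            values[:, j] = 1
            continue
        s = np.sort(col)
        q25 = _nearest_rank(s, 0.25)
        q75 = _nearest_rank(s, 0.75)
        values[:, j] = np.where(col <= q25, 0, np.where(col <= q75, 1, 2))
    return DiscreteDataset(
        [str(s) for s in scores.index],
        [str(c) for c in scores.columns],
        values,
        np.full(scores.shape[1], 3, dtype=int),
    )
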
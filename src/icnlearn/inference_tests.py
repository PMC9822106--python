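"""Conditional-independence tests and decomposable network scores.

Population-level machinery: the discrete G² likelihood-ratio test, the
Gaussian Fisher-z partial-correlation test, and the discrete BIC family
score with a penalty discount.  Instance-level machinery: the
context-specific independence test (restrict to rows matching a context
assignment, then test marginally) and the instance-specific family score
that lets a node's effective parent set depend on the values carried by
one sample.

All tests return a :class:`CiResult`; scores return a
:class:`FamilyScore`.  Scores are decomposable: the score of a DAG is the
sum of its family scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import special, stats

from .graphs import DiscreteDataset

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
#: minimum rows for a context-restricted test before falling back to the
#: population test (see docs/methods.md)
MIN_CONTEXT_ROWS = 30
#: minimum fraction of all rows a context must cover; below this the
#: restricted test has too little power at the default alpha, and a false
#: independence verdict would delete a real edge
MIN_CONTEXT_FRACTION = 0.1


@dataclass
class CiResult:
    """Outcome of a conditional-independence test."""

    statistic: float
    dof: int
    p_value: float
    independent: bool
    effective_n: int
    degenerate: bool = False
    fallback: bool = False


@dataclass(frozen=True)
class FamilyScore:
    """Decomposable local score of one node given a parent set."""

    node: str
    parents: FrozenSet[str]
    value: float
    parameter_count: int


# ---------------------------------------------------------------------------
# Discrete G² test
# ---------------------------------------------------------------------------


def _encode(data: DiscreteDataset, variables: Sequence[str]) -> Tuple[np.ndarray, int]:
    """Mixed-radix encode the listed columns; returns (codes, n_codes)."""
    code = np.zeros(data.n, dtype=np.int64)
    total = 1
    for v in variables:
        a = data.arity(v)
        code = code * a + data.column(v)
        total *= a
    return code, total


def g2_ci_test(
    data: DiscreteDataset,
    x: str,
    y: str,
    z: Iterable[str] = (),
    alpha: float = DEFAULT_ALPHA,
) -> CiResult:
    """G² likelihood-ratio test of X ⟂ Y | Z on discrete data.

    The statistic is referred to a chi-square with
    ``(|X|-1)(|Y|-1)·prod(|Z_i|)`` degrees of freedom; strata with empty
    margins are dropped from the dof count.  A fully degenerate table
    (dof 0) is reported as independent with p = 1 and the ``degenerate``
    flag set.
    """
    zs = sorted(set(z))
    if x in zs or y in zs or x == y:
        raise ValueError("x, y must be distinct and not in z")
    ax, ay = data.arity(x), data.arity(y)
    zcode, nz = _encode(data, zs)
    code = (zcode * ax + data.column(x)) * ay + data.column(y)
    counts = np.bincount(code, minlength=nz * ax * ay).reshape(nz, ax, ay)
    n_z = counts.sum(axis=(1, 2))
    g2 = 0.0
    dof = 0
    for s in range(nz):
        tab = counts[s]
        ns = n_z[s]
        if ns == 0:
            continue
        rx = tab.sum(axis=1)
        ry = tab.sum(axis=0)
        nzx = int((rx > 0).sum())
        nzy = int((ry > 0).sum())
        dof += max(nzx - 1, 0) * max(nzy - 1, 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = np.outer(rx, ry) / ns
            mask = tab > 0
            g2 += 2.0 * float((tab[mask] * np.log(tab[mask] / expected[mask])).sum())
    if dof == 0:
        return CiResult(0.0, 0, 1.0, True, int(data.n), degenerate=True)
    p = float(stats.chi2.sf(g2, dof))
    res = CiResult(g2, dof, p, p > alpha, int(data.n))
    logger.debug("g2 %s,%s|%d vars p=%.3g n=%d", x, y, len(zs), p, data.n)
    return res


# ---------------------------------------------------------------------------
# Fisher-z test
# ---------------------------------------------------------------------------


def fisher_z_test(
    scores,
    x: str,
    y: str,
    z: Iterable[str] = (),
    alpha: float = DEFAULT_ALPHA,
) -> CiResult:
    """Fisher-z test of zero partial correlation on continuous columns.

    ``scores`` is a pandas DataFrame (samples x variables).  The partial
    correlation of x and y given z is obtained from the inverse of the
    correlation matrix of the involved columns.
    """
    zs = sorted(set(z))
    cols = [x, y] + zs
    sub = scores[cols].to_numpy(dtype=float)
    n = sub.shape[0]
    if n <= len(zs) + 3:
        raise ValueError("need n > |z| + 3 samples for the Fisher-z test")
    corr = np.corrcoef(sub, rowvar=False)
    if corr.ndim == 0:  # pragma: no cover - single column cannot happen
        corr = np.array([[1.0]])
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        raise ValueError(f"singular covariance among columns {cols}") from None
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError(f"singular covariance among columns {cols}")
    r = float(-prec[0, 1] / math.sqrt(denom))
    r = max(min(r, 1.0 - 1e-12), -1.0 + 1e-12)
    stat = math.sqrt(n - len(zs) - 3) * math.atanh(r)
    p = float(2.0 * stats.norm.sf(abs(stat)))
    return CiResult(stat, 1, p, p > alpha, n)


# ---------------------------------------------------------------------------
# Context-specific test
# ---------------------------------------------------------------------------


def context_ci_test(
    data: DiscreteDataset,
    x: str,
    y: str,
    z: Iterable[str],
    z_values: Mapping[str, int],
    alpha: float = DEFAULT_ALPHA,
    min_rows: int = MIN_CONTEXT_ROWS,
    min_fraction: float = MIN_CONTEXT_FRACTION,
) -> CiResult:
    """Context-specific CI test: is X ⟂ Y given Z = z?

    Rows are restricted to those matching ``z_values`` exactly on every
    member of ``z``; the marginal G² test of X vs Y is then run on the
    restricted subset.  When the subset holds fewer than
    ``max(min_rows, min_fraction * n)`` rows, the restricted test is too
    underpowered to trust an independence verdict, so the
    population-level test ``g2_ci_test(x, y, z)`` is returned instead,
    with the ``fallback`` flag set.
    """
    zs = sorted(set(z))
    for v in zs:
        if v not in z_values:
            raise ValueError(f"context assignment missing for {v!r}")
    if not zs:
        return g2_ci_test(data, x, y, (), alpha)
    mask = np.ones(data.n, dtype=bool)
    for v in zs:
        mask &= data.column(v) == int(z_values[v])
    n_sub = int(mask.sum())
    underpowered = n_sub < max(min_rows, int(np.ceil(min_fraction * data.n)))
    if not underpowered:
        # a context that (almost) pins x or y carries no information about
        # their dependence: require a minimum off-modal count for both
        for col in (data.column(x)[mask], data.column(y)[mask]):
            counts = np.bincount(col)
            if n_sub - int(counts.max()) < min_rows:
                underpowered = True
                break
    if underpowered:
        pop = g2_ci_test(data, x, y, zs, alpha)
        pop.fallback = True
        return pop
    sub = data.subset_rows(np.flatnonzero(mask))
    res = g2_ci_test(sub, x, y, (), alpha)
    res.effective_n = sub.n
    return res


# ---------------------------------------------------------------------------
# Discrete BIC family score
# ---------------------------------------------------------------------------


def _family_counts(
    data: DiscreteDataset, node: str, parents: Sequence[str]
) -> Tuple[np.ndarray, int]:
    """Counts of node levels by parent configuration: shape (n_cfg, arity)."""
    a = data.arity(node)
    pcode, n_cfg = _encode(data, parents)
    code = pcode * a + data.column(node)
    return np.bincount(code, minlength=n_cfg * a).reshape(n_cfg, a), n_cfg


def discrete_bic(
    data: DiscreteDataset,
    node: str,
    parents: Iterable[str] = (),
    penalty_discount: float = 1.0,
) -> FamilyScore:
    """Multinomial log-likelihood minus ``pd·(k/2)·ln n``.

    ``k = (arity-1) · prod(parent arities)``; parent configurations with
    zero rows contribute zero likelihood but still count parameters.
    """
    if penalty_discount <= 0:
        raise ValueError("penalty_discount must be positive")
    ps = sorted(set(parents))
    if node in ps:
        raise ValueError("node cannot be its own parent")
    counts, n_cfg = _family_counts(data, node, ps)
    n_c = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(counts > 0, counts / np.maximum(n_c, 1), 1.0)
        ll = float((counts * np.log(ratio)).sum())
    k = (data.arity(node) - 1) * n_cfg
    value = ll - penalty_discount * 0.5 * k * math.log(data.n)
    return FamilyScore(node, frozenset(ps), value, k)


def graph_score(
    data: DiscreteDataset,
    parent_map: Mapping[str, Iterable[str]],
    penalty_discount: float = 1.0,
) -> float:
    """Sum of family scores over all nodes — decomposability made explicit."""
    return sum(
        discrete_bic(data, v, ps, penalty_discount).value for v, ps in parent_map.items()
    )


# ---------------------------------------------------------------------------
# Instance-specific family score
# ---------------------------------------------------------------------------


def _bdeu_block(counts: np.ndarray, ess: float = 1.0) -> float:
    """BDeu-style log marginal likelihood of one multinomial block."""
    counts = np.asarray(counts, dtype=float)
    r = counts.size
    n = counts.sum()
    if n == 0:
        return 0.0
    a_k = ess / r
    return float(
        special.gammaln(ess)
        - special.gammaln(ess + n)
        + (special.gammaln(a_k + counts) - special.gammaln(a_k)).sum()
    )


def instance_family_score(
    data: DiscreteDataset,
    node: str,
    parents: Iterable[str],
    instance: Mapping[str, int],
    penalty_discount: float = 1.0,
    reference_parents: Optional[Iterable[str]] = None,
) -> FamilyScore:
    """Score a family for one instance, sensitive to context-specific structure.

    Rows are split in two blocks.  Rows whose candidate-parent
    configuration equals the instance's configuration form the *instance
    block* and are scored as a single multinomial (BDeu-smoothed,
    equivalent sample size 1).  The remaining rows are scored by their own
    configurations of a fixed *reference* parent superset (by default all
    variables the instance assigns, minus the node; the instance-specific
    search passes the population parent set), so that candidate parent
    sets differ only in how far the instance's context is merged.  A
    BIC-style penalty of ``pd·(arity-1)/2·ln n`` is charged per realized
    parameter block.

    Merging a variable out of the candidate set therefore pays off exactly
    when, within the instance's context, the node is independent of that
    variable — the CSI structure of interest.  An instance context
    matching zero rows reduces to the population BIC score.
    """
    ps = sorted(set(parents))
    if node in ps:
        raise ValueError("node cannot be its own parent")
    for v in ps:
        if v not in instance:
            raise ValueError(f"instance does not assign candidate parent {v!r}")
    if reference_parents is None:
        ref = sorted(v for v in instance.keys() if v != node and v in data.variables)
    else:
        ref = sorted(set(reference_parents) | set(ps))
    if any(v not in instance for v in ref):
        raise ValueError("instance must assign every reference parent")

    mask = np.ones(data.n, dtype=bool)
    for v in ps:
        mask &= data.column(v) == int(instance[v])
    n_block = int(mask.sum())
    if n_block == 0:
        return discrete_bic(data, node, ps, penalty_discount)

    r = data.arity(node)
    y = data.column(node)
    block_counts = np.bincount(y[mask], minlength=r)
    ll = _bdeu_block(block_counts)
    n_blocks = 1

    comp = ~mask
    if comp.any():
        sub = data.subset_rows(np.flatnonzero(comp))
        counts, _ = _family_counts(sub, node, ref)
        realized = counts.sum(axis=1) > 0
        n_blocks += int(realized.sum())
        for row in counts[realized]:
            ll += _bdeu_block(row)

    penalty = penalty_discount * 0.5 * (r - 1) * math.log(data.n) * n_blocks
    return FamilyScore(node, frozenset(ps), ll - penalty, (r - 1) * n_blocks)


# ---------------------------------------------------------------------------
# Scorer objects for structure search
# ---------------------------------------------------------------------------


class DiscreteBicScorer:
    """Cached decomposable discrete-BIC scorer for greedy search."""

    decomposable = True

    def __init__(self, data: DiscreteDataset, penalty_discount: float = 1.0):
        self.data = data
        self.penalty_discount = penalty_discount
        self._cache: Dict[Tuple[str, FrozenSet[str]], float] = {}

    def local_score(self, node: str, parents: Iterable[str]) -> float:
        key = (node, frozenset(parents))
        if key not in self._cache:
            self._cache[key] = discrete_bic(
                self.data, node, key[1], self.penalty_discount
            ).value
        return self._cache[key]

    def diff(self, x: str, node: str, parents: Iterable[str]) -> float:
        """score(node, parents ∪ {x}) − score(node, parents)."""
        ps = frozenset(parents)
        return self.local_score(node, ps | {x}) - self.local_score(node, ps)


class GaussianBicScorer:
    """Gaussian (linear regression) BIC scorer for continuous score matrices."""

    decomposable = True

    def __init__(self, scores, penalty_discount: float = 1.0):
        self.frame = scores
        self.X = scores.to_numpy(dtype=float)
        self.cols = {c: i for i, c in enumerate(scores.columns)}
        self.n = self.X.shape[0]
        self.penalty_discount = penalty_discount
        self._cov = np.cov(self.X, rowvar=False, bias=True)
        self._cache: Dict[Tuple[str, FrozenSet[str]], float] = {}

    def local_score(self, node: str, parents: Iterable[str]) -> float:
        key = (node, frozenset(parents))
        if key in self._cache:
            return self._cache[key]
        yi = self.cols[node]
        pi = sorted(self.cols[p] for p in key[1])
        if pi:
            s_pp = self._cov[np.ix_(pi, pi)]
            s_py = self._cov[pi, yi]
            try:
                beta = np.linalg.solve(s_pp, s_py)
            except np.linalg.LinAlgError:
                raise ValueError(f"singular covariance among parents of {node}") from None
            resid_var = float(self._cov[yi, yi] - s_py @ beta)
        else:
            resid_var = float(self._cov[yi, yi])
        resid_var = max(resid_var, 1e-12)
        ll = -0.5 * self.n * (math.log(2 * math.pi * resid_var) + 1.0)
        k = len(pi) + 1
        val = ll - self.penalty_discount * 0.5 * k * math.log(self.n)
        self._cache[key] = val
        return val

    def diff(self, x: str, node: str, parents: Iterable[str]) -> float:
        ps = frozenset(parents)
        return self.local_score(node, ps | {x}) - self.local_score(node, ps)
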
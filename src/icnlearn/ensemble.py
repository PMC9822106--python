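"""Bootstrap resampling and consensus aggregation.

Statistical tests on finite data are imperfect, so single search runs
are not trusted: searches are repeated over bootstrap resamples and only
edges that recur are kept.

* :func:`cohort_consensus` — cohort-level consensus: run the population
  search per bootstrap, keep directed edges whose frequency exceeds a
  threshold (default: strictly more than 20% of 50 bootstraps at 90%
  resampling), and drop both orientations when the two directions of a
  pair each exceed the threshold.
* :func:`individual_icn` — per-tumor consensus: run the individualized
  search per bootstrap with the tumor's values fixed as the instance, and
  keep directed edges present in at least ``min_presence`` of the
  bootstrap PAGs (default: more than two of twenty).

Only fully directed (tail-arrow) PAG edges count toward consensus;
``o->`` and ``<->`` edges are recorded in the provenance tallies but are
never retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .discovery import Knowledge, g2_test_on, gfci
from .graphs import DiscreteDataset, Pag, format_edge
from .individualized import Instance, igfci
from .inference_tests import DEFAULT_ALPHA, MIN_CONTEXT_ROWS, DiscreteBicScorer


@dataclass
class EdgeSet:
    """A set of directed (cause, effect) edges with bootstrap provenance."""

    edges: Set[Tuple[str, str]]
    #: bootstrap frequency of every directed edge observed (retained or not)
    frequencies: Dict[Tuple[str, str], float]
    #: bootstrap frequency of non-directed edge kinds, keyed by rendering
    other_frequencies: Dict[str, float] = field(default_factory=dict)
    n_boot: int = 0

    def __post_init__(self):
        for f in self.frequencies.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("edge frequency outside [0, 1]")

    def sorted_edges(self) -> List[Tuple[str, str]]:
        return sorted(self.edges)


def bootstrap_resample(data: DiscreteDataset, fraction: float, seed: int) -> DiscreteDataset:
    """Draw ``floor(fraction * n)`` rows with replacement, reproducibly."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    m = int(np.floor(fraction * data.n))
    idx = rng.integers(0, data.n, size=m)
    return data.subset_rows(idx)


def _child_seeds(master_seed: int, n: int) -> List[int]:
    """Per-bootstrap seeds derived from the master seed via a counter."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) for s in state]


def _tally(pags: Sequence[Pag]) -> Tuple[Dict[Tuple[str, str], int], Dict[str, int]]:
    directed: Dict[Tuple[str, str], int] = {}
    other: Dict[str, int] = {}
    for pag in pags:
        for e in pag.directed_edges():
            directed[e] = directed.get(e, 0) + 1
        for a, b, ma, mb in pag.edge_list():
            if (ma, mb) in (("-", ">"), (">", "-")):
                continue
            key = format_edge(a, b, ma, mb)
            other[key] = other.get(key, 0) + 1
    return directed, other


def default_learner(
    alpha: float = DEFAULT_ALPHA,
    penalty_discount: float = 1.0,
    knowledge: Optional[Knowledge] = None,
    max_cond_size: Optional[int] = None,
) -> Callable[[DiscreteDataset], Pag]:
    """The pipeline's population learner: discrete GFCI."""

    def learn(data: DiscreteDataset) -> Pag:
        scorer = DiscreteBicScorer(data, penalty_discount)
        test = g2_test_on(data, alpha)
        return gfci(scorer, test, data.variables, knowledge, max_cond_size)

    return learn


def cohort_consensus(
    data: DiscreteDataset,
    n_boot: int = 50,
    fraction: float = 0.9,
    threshold: float = 0.2,
    knowledge: Optional[Knowledge] = None,
    seed: int = 0,
    learner: Optional[Callable[[DiscreteDataset], Pag]] = None,
    strict: bool = True,
    alpha: float = DEFAULT_ALPHA,
    penalty_discount: float = 1.0,
) -> EdgeSet:
    """Bootstrap consensus of the population search.

    A directed edge X -> Y is retained iff its bootstrap frequency is
    strictly above ``threshold`` (at least ``threshold`` with
    ``strict=False``).  If both X -> Y and Y -> X pass the threshold, the
    pair conflicts and neither is retained.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    learn = learner or default_learner(alpha, penalty_discount, knowledge)
    pags = [
        learn(bootstrap_resample(data, fraction, s))
        for s in _child_seeds(seed, n_boot)
    ]
    directed, other = _tally(pags)
    freq = {e: c / n_boot for e, c in directed.items()}

    def passes(f: float) -> bool:
        return f > threshold if strict else f >= threshold

    kept: Set[Tuple[str, str]] = set()
    for (a, b), f in freq.items():
        if not passes(f):
            continue
        if passes(freq.get((b, a), 0.0)):
            continue  # bidirectional conflict: drop both
        kept.add((a, b))
    return EdgeSet(kept, freq, {k: c / n_boot for k, c in other.items()}, n_boot)


def individual_icn(
    data: DiscreteDataset,
    instance: Instance,
    n_boot: int = 20,
    fraction: float = 0.9,
    min_presence: int = 3,
    knowledge: Optional[Knowledge] = None,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    penalty_discount: float = 1.0,
    max_cond_size: Optional[int] = None,
    min_rows: int = MIN_CONTEXT_ROWS,
) -> EdgeSet:
    """Per-tumor consensus intercellular communication network.

    The individualized search runs once per bootstrap resample with the
    tumor's values held fixed as the instance; directed edges present in
    at least ``min_presence`` of the resulting PAGs form the tumor's ICN.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    pags = []
    for s in _child_seeds(seed, n_boot):
        boot = bootstrap_resample(data, fraction, s)
        pags.append(
            igfci(
                boot,
                instance,
                alpha=alpha,
                knowledge=knowledge,
                penalty_discount=penalty_discount,
                max_cond_size=max_cond_size,
                min_rows=min_rows,
            )
        )
    directed, other = _tally(pags)
    freq = {e: c / n_boot for e, c in directed.items()}
    kept = {e for e, c in directed.items() if c >= min_presence}
    return EdgeSet(kept, freq, {k: c / n_boot for k, c in other.items()}, n_boot)
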
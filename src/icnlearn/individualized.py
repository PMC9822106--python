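"""Instance-specific (individualized) causal structure search.

Population-level search returns one network for a whole cohort; the
functions here specialise that network to a single sample (a tumor),
exploiting context-specific independence (CSI): a node's effective parent
set may shrink in the context given by the sample's own variable values.

* :func:`iges` — phase A runs population GES; phase B greedily prunes each
  node's parents whenever the instance-specific family score improves,
  i.e. whenever the node is independent of the parent *within the
  instance's context*.
* :func:`igfci` — the individualized two-phase search: iGES adjacencies
  constrain an FCI phase whose conditional-independence tests are
  context-specific, conditioning sets being evaluated at the values the
  instance assigns to them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .discovery import Knowledge, _pdag_to_dag, fci, ges
from .graphs import Dag, DiscreteDataset, Pag
from .inference_tests import (
    DEFAULT_ALPHA,
    MIN_CONTEXT_ROWS,
    DiscreteBicScorer,
    context_ci_test,
    instance_family_score,
)

Instance = Mapping[str, int]


@dataclass
class CsiBn:
    """An instance-specific Bayesian network: per-node parent sets after
    CSI pruning, with the context that licensed each pruning."""

    nodes: List[str]
    parents: Dict[str, Set[str]]
    population_parents: Dict[str, Set[str]]
    #: node -> {pruned parent -> context (values of the retained parents)}
    pruning_contexts: Dict[str, Dict[str, Dict[str, int]]]

    def dag(self) -> Dag:
        edges = [(p, v) for v, ps in self.parents.items() for p in ps]
        return Dag(self.nodes, edges)

    def adjacencies(self) -> Set[frozenset]:
        return {frozenset((p, v)) for v, ps in self.parents.items() for p in ps}


def _check_instance(data: DiscreteDataset, instance: Instance) -> None:
    for v in data.variables:
        if v not in instance:
            raise ValueError(f"instance does not assign variable {v!r}")
        if not 0 <= int(instance[v]) < data.arity(v):
            raise ValueError(f"instance level for {v!r} out of range")


def instance_from_row(data: DiscreteDataset, sample: str) -> Dict[str, int]:
    """The complete variable assignment carried by one sample."""
    i = data.samples.index(sample)
    return {v: int(data.values[i, j]) for j, v in enumerate(data.variables)}


def iges(
    data: DiscreteDataset,
    instance: Instance,
    scorer: Optional[DiscreteBicScorer] = None,
    knowledge: Optional[Knowledge] = None,
    penalty_discount: float = 1.0,
) -> CsiBn:
    """Individualized GES: population search, then CSI pruning.

    Phase A learns the population CPDAG and takes its (deterministic)
    consistent extension as the reference DAG.  Phase B visits each node
    and greedily removes parents while the instance-specific family score
    improves, evaluating candidates against the fixed population parent
    superset; the removal with the largest gain is applied first and
    re-insertion is never attempted.  An instance whose context matches no
    rows scores identically to the population BIC, leaving the population
    parents untouched.
    """
    _check_instance(data, instance)
    scorer = scorer or DiscreteBicScorer(data, penalty_discount)
    cpdag = ges(scorer, data.variables, knowledge)
    ref_dag = _pdag_to_dag(cpdag.nodes, set(cpdag.directed), set(cpdag.undirected))

    parents: Dict[str, Set[str]] = {}
    pop_parents: Dict[str, Set[str]] = {}
    contexts: Dict[str, Dict[str, Dict[str, int]]] = {}
    import numpy as np

    for v in data.variables:
        pop = set(ref_dag.parents(v))
        pop_parents[v] = set(pop)
        current = set(pop)
        pruned_ctx: Dict[str, Dict[str, int]] = {}

        if pop:
            # an instance whose full parent context matches no rows gives
            # the pruning step nothing to work with: keep the population
            # family untouched
            mask = np.ones(data.n, dtype=bool)
            for u in pop:
                mask &= data.column(u) == int(instance[u])
            if not mask.any():
                parents[v] = current
                contexts[v] = pruned_ctx
                continue

        def score_of(ps: Set[str]) -> float:
            return instance_family_score(
                data, v, ps, instance, penalty_discount, reference_parents=pop
            ).value

        cur_score = score_of(current)
        while current:
            gains = []
            for u in sorted(current):
                gain = score_of(current - {u}) - cur_score
                gains.append((gain, u))
            gains.sort(key=lambda t: (-t[0], t[1]))
            best_gain, best_u = gains[0]
            if best_gain <= 0:
                break
            current = current - {best_u}
            cur_score += best_gain
            pruned_ctx[best_u] = {w: int(instance[w]) for w in sorted(current)}
        parents[v] = current
        contexts[v] = pruned_ctx
    return CsiBn(list(data.variables), parents, pop_parents, contexts)


def context_test_on(
    data: DiscreteDataset,
    instance: Instance,
    alpha: float = DEFAULT_ALPHA,
    min_rows: int = MIN_CONTEXT_ROWS,
):
    """A CI-test callable whose conditioning sets are evaluated at the
    values the instance assigns to them."""

    def test(x: str, y: str, z: Tuple[str, ...]):
        z_values = {v: int(instance[v]) for v in z}
        return context_ci_test(data, x, y, z, z_values, alpha, min_rows)

    return test


def igfci(
    data: DiscreteDataset,
    instance: Instance,
    scorer: Optional[DiscreteBicScorer] = None,
    alpha: float = DEFAULT_ALPHA,
    knowledge: Optional[Knowledge] = None,
    penalty_discount: float = 1.0,
    max_cond_size: Optional[int] = None,
    min_rows: int = MIN_CONTEXT_ROWS,
) -> Pag:
    """Individualized GFCI: iGES adjacencies + context-specific FCI.

    Returns the instance-specific PAG for the given sample.
    """
    csibn = iges(data, instance, scorer, knowledge, penalty_discount)
    test = context_test_on(data, instance, alpha, min_rows)
    return fci(
        test,
        data.variables,
        knowledge,
        max_cond_size=max_cond_size,
        initial_adjacency=csibn.adjacencies(),
    )


def batch_igfci(
    data: DiscreteDataset,
    samples: Optional[Sequence[str]] = None,
    **kwargs,
) -> Dict[str, Pag]:
    """Run igfci for every listed sample (default: all), using each row's
    own values as the instance."""
    out: Dict[str, Pag] = {}
    for s in samples if samples is not None else data.samples:
        out[s] = igfci(data, instance_from_row(data, s), **kwargs)
    return out
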
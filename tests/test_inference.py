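"""Conditional-independence tests and family scores."""

import math

import numpy as np
import pandas as pd
import pytest

from icnlearn.examples import CSI_INSTANCE, csi_network
from icnlearn.graphs import Dag, DiscreteDataset, forward_sample
from icnlearn.inference_tests import (
    DiscreteBicScorer,
    GaussianBicScorer,
    context_ci_test,
    discrete_bic,
    fisher_z_test,
    g2_ci_test,
    graph_score,
    instance_family_score,
)
from icnlearn.simdata import mixture_cbn, random_cbn, random_dag


def _dataset(columns, arities=None):
    names = sorted(columns)
    values = np.column_stack([np.asarray(columns[c], dtype=np.int16) for c in names])
    if arities is None:
        arities = values.max(axis=0) + 1
    return DiscreteDataset(
        [f"s{i}" for i in range(values.shape[0])], names, values, np.asarray(arities)
    )


class TestG2:
    def test_dof_ternary_pair_with_ternary_conditioner(self):
        rng = np.random.default_rng(0)
        data = _dataset(
            {c: rng.integers(0, 3, 500) for c in ("X", "Y", "Z")}, [3, 3, 3]
        )
        res = g2_ci_test(data, "X", "Y", ["Z"])
        assert res.dof == 12

    def test_perfect_dependence_rejected(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 500)
        data = _dataset({"X": x, "Y": x.copy()}, [3, 3])
        res = g2_ci_test(data, "X", "Y")
        assert res.p_value < 1e-10 and not res.independent

    def test_degenerate_table_reports_independent(self):
        data = _dataset({"X": np.zeros(50, int), "Y": np.zeros(50, int)}, [3, 3])
        res = g2_ci_test(data, "X", "Y")
        assert res.independent and res.p_value == 1.0 and res.degenerate

    def test_type_i_error_near_alpha(self):
        rejections = 0
        n_sims = 400
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            data = _dataset(
                {"X": rng.integers(0, 3, 1000), "Y": rng.integers(0, 3, 1000)}, [3, 3]
            )
            rejections += not g2_ci_test(data, "X", "Y", alpha=0.05).independent
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_power_at_moderate_association(self):
        # dependence with Cramér's V >= 0.3 detected at n = 2000
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 3, 2000)
            noise = rng.integers(0, 3, 2000)
            flip = rng.random(2000) < 0.55
            y = np.where(flip, x, noise)
            data = _dataset({"X": x, "Y": y}, [3, 3])
            hits += not g2_ci_test(data, "X", "Y", alpha=0.01).independent
        assert hits >= 38


class TestFisherZ:
    def test_zero_correlation_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        scores = pd.DataFrame({"x": x, "y": np.zeros(200) + rng.normal(size=200)})
        # construct exactly-zero sample correlation via orthogonalization
        y = scores["y"] - np.polyval(np.polyfit(x, scores["y"], 1), x)
        scores["y"] = y
        res = fisher_z_test(scores, "x", "y")
        assert abs(res.statistic) < 1e-8 and res.p_value > 0.999

    def test_duplicate_column_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        scores = pd.DataFrame({"x": x, "y": x + 1e-9 * rng.normal(size=100)})
        res = fisher_z_test(scores, "x", "y")
        assert res.p_value < 1e-12

    def test_type_i_error_near_alpha(self):
        rejections = 0
        n_sims = 400
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=200)
            x = z + rng.normal(size=200)
            y = z + rng.normal(size=200)
            scores = pd.DataFrame({"x": x, "y": y, "z": z})
            rejections += not fisher_z_test(scores, "x", "y", ["z"], alpha=0.01).independent
        assert 0.002 <= rejections / n_sims <= 0.025

    def test_sample_size_guard(self):
        scores = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 1, 4, 3]})
        with pytest.raises(ValueError):
            fisher_z_test(scores, "x", "y", ["x"])  # n <= |z| + 3


class TestContextTest:
    def test_empty_context_equals_marginal(self):
        rng = np.random.default_rng(4)
        data = _dataset(
            {"X": rng.integers(0, 3, 400), "Y": rng.integers(0, 3, 400)}, [3, 3]
        )
        a = context_ci_test(data, "X", "Y", [], {})
        b = g2_ci_test(data, "X", "Y")
        assert (a.statistic, a.p_value) == (b.statistic, b.p_value)

    def test_small_context_falls_back_to_population(self):
        rng = np.random.default_rng(5)
        z = rng.integers(0, 2, 200)
        z[:4] = 2  # rare context
        data = _dataset(
            {"X": rng.integers(0, 3, 200), "Y": rng.integers(0, 3, 200), "Z": z},
            [3, 3, 3],
        )
        res = context_ci_test(data, "X", "Y", ["Z"], {"Z": 2})
        pop = g2_ci_test(data, "X", "Y", ["Z"])
        assert res.fallback and res.statistic == pop.statistic

    def test_csi_relationship_detected_per_context(self, csi_cbn):
        data = forward_sample(csi_cbn, 5000, 0)
        in_ctx = context_ci_test(data, "X4", "X3", ["X1", "X2"], {"X1": 1, "X2": 1})
        out_ctx = context_ci_test(data, "X4", "X3", ["X1", "X2"], {"X1": 0, "X2": 0})
        assert in_ctx.independent and not in_ctx.fallback
        assert not out_ctx.independent

    def test_context_free_generator_mostly_agrees_with_population(self):
        dag = random_dag(5, 2.0, 9)
        cbn = mixture_cbn(dag, seed=9)
        data = forward_sample(cbn, 5000, 9)
        rng = np.random.default_rng(9)
        agree = 0
        total = 40
        for _ in range(total):
            x, y = rng.choice(dag.nodes, size=2, replace=False)
            rest = [v for v in dag.nodes if v not in (x, y)]
            z = list(rng.choice(rest, size=2, replace=False))
            zv = {v: int(rng.integers(0, 3)) for v in z}
            ctx = context_ci_test(data, x, y, z, zv)
            pop = g2_ci_test(data, x, y, z)
            agree += ctx.independent == pop.independent
        assert agree / total >= 0.9


class TestDiscreteBic:
    def test_prefers_empty_parents_for_independent_pair(self):
        rng = np.random.default_rng(6)
        data = _dataset(
            {"X": rng.integers(0, 3, 5000), "Y": rng.integers(0, 3, 5000)}, [3, 3]
        )
        assert discrete_bic(data, "Y").value > discrete_bic(data, "Y", ["X"]).value

    def test_prefers_true_parent_for_deterministic_copy(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 3, 5000)
        data = _dataset({"X": x, "Y": x.copy()}, [3, 3])
        assert discrete_bic(data, "Y", ["X"]).value > discrete_bic(data, "Y").value

    def test_score_decreases_with_penalty_discount(self):
        rng = np.random.default_rng(8)
        data = _dataset(
            {"X": rng.integers(0, 3, 300), "Y": rng.integers(0, 3, 300)}, [3, 3]
        )
        assert (
            discrete_bic(data, "Y", ["X"], 2.0).value
            < discrete_bic(data, "Y", ["X"], 1.0).value
        )

    def test_decomposability_is_exact(self):
        dag = random_dag(5, 2.0, 10)
        cbn = random_cbn(dag, min_effect=0.0, seed=10)
        data = forward_sample(cbn, 1000, 10)
        parent_map = {v: sorted(dag.parents(v)) for v in dag.nodes}
        total = graph_score(data, parent_map)
        parts = sum(discrete_bic(data, v, ps).value for v, ps in parent_map.items())
        assert total == parts


class TestInstanceScore:
    def test_csi_instance_prefers_pruned_parents(self, csi_cbn):
        data = forward_sample(csi_cbn, 10000, 1)
        instance = dict(CSI_INSTANCE, X4=0)
        ref = ["X1", "X2", "X3"]
        scores = {
            tuple(sorted(ps)): instance_family_score(
                data, "X4", ps, instance, reference_parents=ref
            ).value
            for ps in (["X1", "X2", "X3"], ["X1", "X2"], ["X1", "X3"], ["X2", "X3"])
        }
        assert max(scores, key=scores.get) == ("X1", "X2")

    def test_no_csi_generator_agrees_with_population_argmax(self):
        agreements = 0
        n_runs = 10
        for seed in range(n_runs):
            dag = Dag(["A", "B", "C", "Y"], [("A", "Y"), ("B", "Y")])
            cbn = mixture_cbn(dag, seed=seed)
            data = forward_sample(cbn, 5000, seed)
            instance = {
                v: int(data.values[0, data.variables.index(v)]) for v in data.variables
            }
            cands = [["A", "B"], ["A"], ["B"], []]
            pop = max(cands, key=lambda ps: discrete_bic(data, "Y", ps).value)
            inst = max(
                cands,
                key=lambda ps: instance_family_score(
                    data, "Y", ps, instance, reference_parents=["A", "B"]
                ).value,
            )
            agreements += pop == inst
        assert agreements >= 9

    def test_empty_instance_block_reduces_to_population_bic(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 2, 500)
        data = _dataset({"X": x, "Y": rng.integers(0, 3, 500)}, [3, 3])
        instance = {"X": 2, "Y": 0}  # level 2 never occurs in X
        got = instance_family_score(data, "Y", ["X"], instance)
        expected = discrete_bic(data, "Y", ["X"])
        assert got.value == expected.value


class TestScorers:
    def test_discrete_scorer_diff_matches_local_scores(self):
        dag = random_dag(4, 2.0, 12)
        data = forward_sample(random_cbn(dag, seed=12), 500, 12)
        sc = DiscreteBicScorer(data)
        d = sc.diff("V0", "V1", frozenset({"V2"}))
        assert d == pytest.approx(
            sc.local_score("V1", {"V0", "V2"}) - sc.local_score("V1", {"V2"})
        )

    def test_gaussian_scorer_prefers_true_parent(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=1000)
        y = 0.8 * x + rng.normal(size=1000)
        scores = pd.DataFrame({"x": x, "y": y, "z": rng.normal(size=1000)})
        sc = GaussianBicScorer(scores)
        assert sc.diff("x", "y", frozenset()) > 0
        assert sc.diff("z", "y", frozenset()) < 0
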
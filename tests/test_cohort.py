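"""Edge vectors, consensus clustering, Markov boundaries, correlations."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from icnlearn.cohort import (
    consensus_cluster,
    cross_type_correlations,
    edge_vectorize,
    markov_boundary,
    mb_prediction_cv,
)
from icnlearn.ensemble import EdgeSet
from icnlearn.simdata import linear_gaussian_cohort


def _icn(edges):
    return EdgeSet(set(edges), {e: 1.0 for e in edges})


class TestEdgeVectorize:
    def test_union_columns_and_rows(self):
        mat = edge_vectorize([_icn({("A", "B")}), _icn({("B", "C")})], ["t0", "t1"])
        assert list(mat.columns) == ["A->B", "B->C"]
        assert mat.values.tolist() == [[1, 0], [0, 1]]

    def test_identical_icns_identical_rows(self):
        icn = _icn({("A", "B"), ("C", "D")})
        mat = edge_vectorize([icn, icn])
        assert (mat.iloc[0] == mat.iloc[1]).all()

    def test_empty_icn_is_zero_row(self):
        mat = edge_vectorize([_icn({("A", "B")}), _icn(set())])
        assert mat.iloc[1].sum() == 0

    def test_tumor_order_permutation_equivariance(self):
        icns = [_icn({("A", "B")}), _icn({("B", "C")}), _icn({("A", "B"), ("B", "C")})]
        ids = ["x", "y", "z"]
        mat = edge_vectorize(icns, ids)
        mat_perm = edge_vectorize(icns[::-1], ids[::-1])
        assert mat_perm.loc[ids].equals(mat)


class TestConsensusCluster:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (30, 5)), rng.normal(6, 1, (30, 5))])
        df = pd.DataFrame(X, index=[f"i{j}" for j in range(60)])
        truth = [0] * 30 + [1] * 30
        res = consensus_cluster(df, 2, 6, reps=50, seed=1, metric="euclidean")
        assert res.k_star == 2
        assert adjusted_rand_score(truth, res.assignments) == 1.0

    def test_consensus_matrix_invariants(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.integers(0, 2, size=(20, 6)).astype(float))
        res = consensus_cluster(df, 2, 4, reps=20, seed=2)
        for cons in res.consensus.values():
            assert (cons >= 0).all() and (cons <= 1).all()
            assert np.allclose(np.diag(cons), 1.0)
            assert np.allclose(cons, cons.T)

    def test_full_subsample_with_deterministic_clusterer_is_binary(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.3, (10, 3)), rng.normal(5, 0.3, (10, 3))])
        df = pd.DataFrame(X)
        res = consensus_cluster(df, 2, 3, reps=10, item_fraction=1.0, seed=3,
                               metric="euclidean")
        vals = res.consensus[2]
        assert np.isin(vals, [0.0, 1.0]).all()

    def test_binary_four_blocks_recovered(self):
        rng = np.random.default_rng(4)
        pats = np.array([[1, 1, 1, 1], [0, 1, 0, 1], [1, 0, 1, 0], [0, 0, 0, 0]])
        rows, truth = [], []
        for s in range(4):
            for _ in range(12):
                noise = (rng.random(6) < 0.1).astype(int)
                rows.append(np.concatenate([pats[s], noise]))
                truth.append(s)
        df = pd.DataFrame(rows)
        res = consensus_cluster(df, 2, 6, reps=50, seed=5)
        assert res.k_star == 4
        assert adjusted_rand_score(truth, res.assignments) >= 0.9

    def test_k_max_guard(self):
        df = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError):
            consensus_cluster(df, 2, 4, reps=10)


class TestMarkovBoundary:
    def test_spouse_via_common_child(self):
        assert markov_boundary({("A", "C"), ("B", "C")}, "A") == {"C", "B"}

    def test_chain_middle(self):
        assert markov_boundary({("A", "B"), ("B", "C")}, "B") == {"A", "C"}

    def test_isolated_target_empty(self):
        assert markov_boundary({("A", "B")}, "Q") == set()

    def test_unknown_target_with_universe(self):
        with pytest.raises(KeyError):
            markov_boundary({("A", "B")}, "Q", nodes=["A", "B"])


class TestMbPrediction:
    def test_noiseless_linear_target(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(2, 300))
        scores = pd.DataFrame({"A": a, "B": b, "T": 2 * a - b})
        r2 = mb_prediction_cv(scores, {("A", "T"), ("B", "T")}, "T", folds=10, seed=0)
        assert r2 >= 0.99

    def test_independent_target_near_zero(self):
        rng = np.random.default_rng(6)
        scores = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("ABCT"))
        r2 = mb_prediction_cv(scores, {("A", "T")}, "T", folds=10, seed=0)
        assert r2 <= 0.05

    def test_empty_boundary_returns_zero(self):
        rng = np.random.default_rng(7)
        scores = pd.DataFrame(rng.normal(size=(100, 2)), columns=["A", "T"])
        assert mb_prediction_cv(scores, set(), "T") == 0.0

    def test_boundary_is_predictively_sufficient(self):
        gaps = []
        advantages = []
        for seed in range(5):
            dag, scores = linear_gaussian_cohort(10, 500, seed)
            targets = [v for v in dag.nodes if len(markov_boundary(dag.edges, v)) >= 2]
            t = targets[len(targets) // 2]
            mb = sorted(markov_boundary(dag.edges, t))
            allp = [v for v in dag.nodes if v != t]
            rng = np.random.default_rng(100 + seed)
            pool = [v for v in allp if v not in mb] or allp
            rand = list(rng.choice(pool, size=min(len(mb), len(pool)), replace=False))
            r2_mb = mb_prediction_cv(scores, dag.edges, t, seed=seed)
            r2_all = mb_prediction_cv(scores, dag.edges, t, seed=seed, predictors=allp)
            r2_rand = mb_prediction_cv(scores, dag.edges, t, seed=seed, predictors=rand)
            gaps.append(abs(r2_all - r2_mb))
            advantages.append(r2_mb - r2_rand)
        assert float(np.mean(gaps)) <= 0.05
        assert float(np.mean(advantages)) >= 0.1

    def test_fold_guard(self):
        scores = pd.DataFrame({"A": [1.0, 2.0], "T": [0.5, 1.5]})
        with pytest.raises(ValueError):
            mb_prediction_cv(scores, {("A", "T")}, "T", folds=10)


class TestCrossTypeCorrelations:
    def test_identical_columns_across_categories_rank_first(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        scores = pd.DataFrame({"a1": x, "b1": x.copy(), "b2": rng.normal(size=200)})
        types = {"a1": "epithelial", "b1": "immune", "b2": "immune"}
        out = cross_type_correlations(scores, types, top_n=2)
        top = out[(out.module == "a1") & (out["rank"] == 1)].iloc[0]
        assert top.partner == "b1" and top.r == pytest.approx(1.0)

    def test_intra_category_pairs_never_reported(self):
        rng = np.random.default_rng(9)
        scores = pd.DataFrame(rng.normal(size=(100, 4)), columns=["a1", "a2", "b1", "b2"])
        types = {"a1": "x", "a2": "x", "b1": "y", "b2": "y"}
        out = cross_type_correlations(scores, types, top_n=3)
        for _, row in out.iterrows():
            assert types[row.module] != types[row.partner]

    def test_null_correlations_stay_small(self):
        small = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = pd.DataFrame(
                rng.normal(size=(500, 6)), columns=[f"m{i}" for i in range(6)]
            )
            types = {f"m{i}": ("u" if i < 3 else "v") for i in range(6)}
            out = cross_type_correlations(scores, types, top_n=1)
            small += out.r.abs().max() < 0.2
        assert small >= 19

    def test_single_category_rejected(self):
        rng = np.random.default_rng(10)
        scores = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            cross_type_correlations(scores, {"a": "x", "b": "x"})
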
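"""Graph structures, separation oracles, projection and enumeration."""

import itertools

import numpy as np
import pytest

from icnlearn.examples import PNEUMONIA_LATENT, pneumonia_dag
from icnlearn.graphs import (
    ARROW,
    CIRCLE,
    TAIL,
    Cbn,
    Dag,
    GraphError,
    Mag,
    Pag,
    brute_force_pag,
    d_separated,
    enumerate_mags,
    forward_sample,
    latent_project,
    m_separated,
    oracle_pag,
)
from icnlearn.simdata import plant_latents, random_cbn, random_dag

from conftest import path_enumeration_separated


class TestDSeparation:
    @pytest.mark.parametrize(
        "edges, x, y, z, expected",
        [
            ([("A", "B"), ("B", "C")], "A", "C", {"B"}, True),  # blocked chain
            ([("A", "B"), ("C", "B")], "A", "C", {"B"}, False),  # open collider
            ([("A", "B"), ("C", "B")], "A", "C", set(), True),  # marginal collider
            ([("B", "A"), ("B", "C")], "A", "C", {"B"}, True),  # blocked fork
        ],
    )
    def test_basic_patterns(self, edges, x, y, z, expected):
        dag = Dag(sorted({v for e in edges for v in e}), edges)
        assert d_separated(dag, x, y, z) is expected

    def test_pneumonia_cytokines_given_common_causes(self):
        dag = pneumonia_dag()
        assert d_separated(dag, "cytokine1", "cytokine2", {"pneumonia", "SNP1"})
        assert not d_separated(dag, "cytokine1", "cytokine2", set())

    def test_unknown_variable_raises(self):
        dag = Dag(["A", "B"], [("A", "B")])
        with pytest.raises(GraphError):
            d_separated(dag, "A", "Q", set())

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_path_enumeration(self, seed):
        dag = random_dag(6, 2.0, seed)
        rng = np.random.default_rng(seed)
        nodes = dag.nodes
        for _ in range(15):
            x, y = rng.choice(nodes, size=2, replace=False)
            rest = [v for v in nodes if v not in (x, y)]
            z = set(rng.choice(rest, size=rng.integers(0, 4), replace=False))
            assert d_separated(dag, x, y, z) == path_enumeration_separated(dag, x, y, z)


class TestMSeparation:
    def test_adjacent_never_separated(self):
        mag = Mag(["A", "B"])
        mag.add_edge("A", "B", ARROW, ARROW)
        assert not m_separated(mag, "A", "B", set())

    def test_bidirected_chain_collider_blocks(self):
        mag = Mag(["A", "B", "C"])
        mag.add_edge("A", "B", ARROW, ARROW)
        mag.add_edge("B", "C", ARROW, ARROW)
        assert m_separated(mag, "A", "C", set())
        assert not m_separated(mag, "A", "C", {"B"})

    def test_conditioning_on_collider_opens_confounded_path(self, pneumonia):
        mag = latent_project(pneumonia.dag, {PNEUMONIA_LATENT})
        assert not m_separated(mag, "SNP1", "cytokine2", {"cytokine1"})
        assert m_separated(mag, "SNP1", "cytokine2", set())

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_path_enumeration_on_projections(self, seed):
        base = random_dag(5, 2.0, seed)
        full, lat = plant_latents(base, 1 + seed % 2, seed)
        mag = latent_project(full, lat)
        rng = np.random.default_rng(seed)
        nodes = mag.nodes
        for _ in range(15):
            x, y = rng.choice(nodes, size=2, replace=False)
            rest = [v for v in nodes if v not in (x, y)]
            z = set(rng.choice(rest, size=rng.integers(0, 3), replace=False))
            assert m_separated(mag, x, y, z) == path_enumeration_separated(mag, x, y, z)


class TestLatentProjection:
    def test_pneumonia_projection_confounds_cytokines(self, pneumonia):
        mag = latent_project(pneumonia.dag, {PNEUMONIA_LATENT})
        assert mag.mark_at("cytokine1", "cytokine2") == ARROW
        assert mag.mark_at("cytokine2", "cytokine1") == ARROW
        directed = mag.directed_edges()
        assert directed == {
            ("SNP1", "cytokine1"),
            ("SNP2", "cytokine2"),
            ("cytokine1", "AKI"),
            ("cytokine2", "AKI"),
            ("AKI", "mortality"),
        }

    def test_no_latents_is_identity_on_structure(self):
        dag = random_dag(6, 2.0, 3)
        mag = latent_project(dag, set())
        assert mag.directed_edges() == dag.edges

    def test_confounder_absorbed_by_ancestral_edge(self):
        dag = Dag(["L", "A", "B"], [("L", "A"), ("L", "B"), ("A", "B")])
        mag = latent_project(dag, {"L"})
        assert mag.directed_edges() == {("A", "B")}
        assert len(mag.edges) == 1

    def test_projecting_out_everything_fails(self):
        dag = Dag(["A", "B"], [("A", "B")])
        with pytest.raises(GraphError):
            latent_project(dag, {"A", "B"})

    @pytest.mark.parametrize("seed", range(15))
    def test_projection_preserves_measured_independences(self, seed):
        base = random_dag(5, 1.8, seed)
        full, lat = plant_latents(base, seed % 3, 100 + seed)
        mag = latent_project(full, lat)
        measured = mag.nodes
        for x, y in itertools.combinations(measured, 2):
            rest = [v for v in measured if v not in (x, y)]
            for r in range(len(rest) + 1):
                for zs in itertools.combinations(rest, r):
                    assert m_separated(mag, x, y, set(zs)) == d_separated(
                        full, x, y, set(zs)
                    )


class TestEnumerationAndOraclePag:
    def test_pneumonia_class_has_four_mags(self, pneumonia):
        pag = oracle_pag(pneumonia.dag, {PNEUMONIA_LATENT})
        mags = enumerate_mags(pag)
        assert len(mags) == 4
        for m in mags:
            assert m.is_ancestral() and m.is_maximal()

    def test_fully_directed_pag_is_singleton(self):
        pag = Pag(["A", "B", "C"])
        pag.add_edge("A", "B", TAIL, ARROW)
        pag.add_edge("B", "C", TAIL, ARROW)
        assert len(enumerate_mags(pag)) == 1

    def test_single_circle_edge_yields_three_mags(self):
        pag = Pag(["X", "Y"])
        pag.add_edge("X", "Y", CIRCLE, CIRCLE)
        mags = enumerate_mags(pag)
        kinds = {m.edges[(0, 1)] for m in mags}
        assert kinds == {(TAIL, ARROW), (ARROW, TAIL), (ARROW, ARROW)}

    def test_single_edge_oracle_pag_is_fully_ambiguous(self):
        pag = oracle_pag(Dag(["A", "B"], [("A", "B")]), set())
        assert pag.edges[(0, 1)] == (CIRCLE, CIRCLE)

    def test_pneumonia_oracle_pag_marks(self, pneumonia):
        pag = oracle_pag(pneumonia.dag, {PNEUMONIA_LATENT})
        assert pag.mark_at("cytokine1", "SNP1") == CIRCLE
        assert pag.mark_at("SNP1", "cytokine1") == ARROW
        assert (pag.mark_at("cytokine2", "AKI"), pag.mark_at("AKI", "cytokine2")) == (
            ARROW,
            TAIL,
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_pag_matches_brute_force(self, seed):
        base = random_dag(5 + seed % 2, 2.0, seed)
        full, lat = plant_latents(base, seed % 3, 500 + seed)
        assert oracle_pag(full, lat) == brute_force_pag(full, lat)

    def test_class_members_share_msep_relations(self, pneumonia):
        from icnlearn.graphs import msep_fingerprint

        pag = oracle_pag(pneumonia.dag, {PNEUMONIA_LATENT})
        fps = {msep_fingerprint(m) for m in enumerate_mags(pag)}
        assert len(fps) == 1


class TestForwardSampling:
    def test_degenerate_cpts_yield_constant_columns(self):
        dag = Dag(["A", "B"], [("A", "B")])
        cbn = Cbn(
            dag,
            {"A": 2, "B": 2},
            {"A": np.array([[0.0, 1.0]]), "B": np.array([[1.0, 0.0], [0.0, 1.0]])},
        )
        ds = forward_sample(cbn, 100, 0)
        assert (ds.column("A") == 1).all()
        assert (ds.column("B") == 1).all()

    def test_conditional_frequency_within_binomial_error(self, pneumonia):
        ds = forward_sample(pneumonia, 10000, 3)
        aki = ds.column("AKI")
        mort = ds.column("mortality")
        p_hat = mort[aki == 1].mean()
        n1 = (aki == 1).sum()
        se = np.sqrt(0.6 * 0.4 / n1)
        assert abs(p_hat - 0.6) < 3 * se

    def test_independent_roots_have_near_zero_mi(self, pneumonia):
        ds = forward_sample(pneumonia, 20000, 11)
        s1, s2 = ds.column("SNP1"), ds.column("SNP2")
        # empirical mutual information of independent roots
        joint = np.histogram2d(s1, s2, bins=2)[0] / len(s1)
        px, py = joint.sum(1), joint.sum(0)
        mi = np.nansum(joint * np.log(joint / np.outer(px, py)))
        assert mi < 5e-4

    def test_same_seed_reproduces(self, pneumonia):
        a = forward_sample(pneumonia, 500, 42)
        b = forward_sample(pneumonia, 500, 42)
        assert (a.values == b.values).all()

    def test_invalid_cpt_rejected(self):
        dag = Dag(["A"], [])
        with pytest.raises(GraphError):
            Cbn(dag, {"A": 2}, {"A": np.array([[0.7, 0.6]])})
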
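"""File-format round-trips and the command-line pipeline."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from icnlearn import io as iomod
from icnlearn.cli import main
from icnlearn.discovery import Knowledge
from icnlearn.ensemble import EdgeSet
from icnlearn.examples import pneumonia_dag
from icnlearn.graphs import ARROW, CIRCLE, Pag, TAIL, latent_project


class TestRoundTrips:
    def test_dag(self, tmp_path):
        dag = pneumonia_dag()
        path = tmp_path / "g.txt"
        iomod.write_graph(dag, path)
        assert iomod.read_graph(path, "dag") == dag

    def test_mag_and_pag(self, tmp_path):
        mag = latent_project(pneumonia_dag(), {"pneumonia"})
        path = tmp_path / "m.txt"
        iomod.write_graph(mag, path)
        assert iomod.read_graph(path, "mag") == mag

        pag = Pag(["A", "B", "C"])
        pag.add_edge("A", "B", CIRCLE, ARROW)
        pag.add_edge("B", "C", TAIL, ARROW)
        path2 = tmp_path / "p.txt"
        iomod.write_graph(pag, path2)
        assert iomod.read_graph(path2, "pag") == pag

    def test_graph_json_mirror(self):
        pag = Pag(["A", "B"])
        pag.add_edge("A", "B", CIRCLE, CIRCLE)
        payload = json.loads(iomod.graph_to_json(pag))
        assert payload["nodes"] == ["A", "B"]
        assert payload["edges"][0]["mark_a"] == CIRCLE

    def test_knowledge(self, tmp_path):
        know = Knowledge({frozenset(("A", "B"))}, {("C", "D")})
        path = tmp_path / "k.txt"
        iomod.write_knowledge(know, path)
        back = iomod.read_knowledge(path)
        assert back.forbidden_pairs == know.forbidden_pairs
        assert back.required_edges == know.required_edges

    def test_malformed_knowledge_names_line(self, tmp_path):
        path = tmp_path / "k.txt"
        path.write_text("forbid A\n")
        with pytest.raises(ValueError, match=":1"):
            iomod.read_knowledge(path)

    def test_matrices(self, tmp_path):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(size=(5, 3)),
            index=[f"g{i}" for i in range(5)],
            columns=["s0", "s1", "s2"],
        )
        p = tmp_path / "e.tsv"
        iomod.write_expression(expr, p)
        assert np.allclose(iomod.read_expression(p).values, expr.values)

        from icnlearn.graphs import DiscreteDataset

        data = DiscreteDataset(
            ["s0", "s1"], ["V0", "V1"], np.array([[0, 2], [1, 0]], dtype=np.int16),
            np.array([3, 3])
        )
        p2 = tmp_path / "d.tsv"
        iomod.write_discrete(data, p2)
        back = iomod.read_discrete(p2)
        assert back.variables == data.variables and (back.values == data.values).all()

    def test_gmt(self, tmp_path):
        sigs = {"M0": [("gB", 0.9), ("gA", 0.7)], "M1": [("gC", 0.5)]}
        path = tmp_path / "s.gmt"
        iomod.write_gmt(sigs, path)
        back = iomod.read_gmt(path)
        assert back["M0"].genes == [("gB", 0.9), ("gA", 0.7)]
        assert back["M1"].module == "M1"

    def test_edge_set(self, tmp_path):
        es = EdgeSet({("A", "B")}, {("A", "B"): 0.84, ("B", "C"): 0.1})
        path = tmp_path / "edges.txt"
        iomod.write_edge_set(es, path)
        back = iomod.read_edge_set(path)
        assert back.edges == {("A", "B")}
        assert back.frequencies[("A", "B")] == pytest.approx(0.84)


class TestCli:
    def test_simulate_is_byte_identical_across_runs(self, tmp_path):
        runner = CliRunner()
        args = ["simulate", "csi-cohort", "--subtypes", "2", "--per-subtype", "50",
                "--seed", "7"]
        r1 = runner.invoke(main, args + ["--out", str(tmp_path / "a")])
        r2 = runner.invoke(main, args + ["--out", str(tmp_path / "b")])
        assert r1.exit_code == 0 and r2.exit_code == 0, r1.output + r2.output
        for name in ("data.tsv", "backbone.graph.txt", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_learn_cohort_with_forbid_all_knowledge_is_empty(self, tmp_path):
        runner = CliRunner()
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(
            rng.normal(size=(40, 3)), columns=["m0", "m1", "m2"],
            index=[f"t{i}" for i in range(40)],
        )
        iomod.write_scores(scores, tmp_path / "scores.tsv")
        r = runner.invoke(main, ["discretize", "--scores", str(tmp_path / "scores.tsv"),
                                 "--out", str(tmp_path / "disc.tsv")])
        assert r.exit_code == 0, r.output
        know = Knowledge({frozenset((a, b)) for a in ("m0", "m1", "m2")
                          for b in ("m0", "m1", "m2") if a < b})
        iomod.write_knowledge(know, tmp_path / "know.txt")
        r = runner.invoke(main, [
            "learn-cohort", "--data", str(tmp_path / "disc.tsv"),
            "--knowledge", str(tmp_path / "know.txt"),
            "--bootstraps", "3", "--out", str(tmp_path / "cohort")])
        assert r.exit_code == 0, r.output
        out = iomod.read_edge_set(tmp_path / "cohort" / "consensus.edges.txt")
        assert not out.edges

    def test_full_chain_on_small_fixture(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(main, ["simulate", "bulk-cohort", "--modules", "3",
                                 "--genes-per-module", "30", "--samples", "40",
                                 "--seed", "3", "--out", str(tmp_path / "bulk")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["gsva", "--expression", str(tmp_path / "bulk" / "expression.tsv"),
                                 "--signatures", str(tmp_path / "bulk" / "signatures.gmt"),
                                 "--top-k", "30", "--out", str(tmp_path / "scores.tsv")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["discretize", "--scores", str(tmp_path / "scores.tsv"),
                                 "--out", str(tmp_path / "disc.tsv")])
        assert r.exit_code == 0, r.output
        data = iomod.read_discrete(tmp_path / "disc.tsv")
        assert data.n == 40 and (data.arities == 3).all()

    def test_validate_mb_and_correlate(self, tmp_path):
        runner = CliRunner()
        rng = np.random.default_rng(5)
        a = rng.normal(size=100)
        scores = pd.DataFrame({"m0": a, "m1": a + 0.1 * rng.normal(size=100),
                               "m2": rng.normal(size=100)},
                              index=[f"t{i}" for i in range(100)])
        iomod.write_scores(scores, tmp_path / "scores.tsv")
        es = EdgeSet({("m0", "m1")}, {("m0", "m1"): 1.0})
        iomod.write_edge_set(es, tmp_path / "edges.txt")
        r = runner.invoke(main, ["validate-mb", "--scores", str(tmp_path / "scores.tsv"),
                                 "--edges", str(tmp_path / "edges.txt"),
                                 "--targets", "m1", "--folds", "5",
                                 "--out", str(tmp_path / "mb.tsv")])
        assert r.exit_code == 0, r.output
        result = pd.read_csv(tmp_path / "mb.tsv", sep="\t")
        assert result.loc[0, "r2"] > 0.9

        types = pd.DataFrame({"module": ["m0", "m1", "m2"],
                              "category": ["epi", "imm", "imm"]})
        types.to_csv(tmp_path / "types.tsv", sep="\t", index=False)
        r = runner.invoke(main, ["correlate", "--scores", str(tmp_path / "scores.tsv"),
                                 "--types", str(tmp_path / "types.tsv"),
                                 "--top-n", "2", "--out", str(tmp_path / "corr.tsv")])
        assert r.exit_code == 0, r.output
        corr = pd.read_csv(tmp_path / "corr.tsv", sep="\t")
        assert ((corr.module == "m0") & (corr.partner == "m1")).any()

    def test_malformed_input_fails_with_nonzero_exit(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("not\ta\tmatrix\nrow\tx\ty\n")
        runner = CliRunner()
        r = runner.invoke(main, ["learn-cohort", "--data", str(tmp_path / "bad.tsv"),
                                 "--out", str(tmp_path / "o")])
        assert r.exit_code != 0
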
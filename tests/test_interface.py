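"""CLI dispatch, report formatting, and provenance plumbing."""

import json
import math

import numpy as np
import pytest
from click.testing import CliRunner

from dupsel.cli import main
from dupsel.mk import MKCounts, MKRangeResult, MKResult
from dupsel.reports import write_report
from dupsel.trees import read_tree


@pytest.fixture()
def runner():
    return CliRunner()


@pytest.fixture()
def sim_dir(tmp_path, runner):
    out = tmp_path / "sim"
    res = runner.invoke(main, ["simulate", "--preset", "NF", "--n-codons", "30",
                               "--seed", "5", "--out", str(out)])
    assert res.exit_code == 0, res.output
    return out


class TestCLI:
    def test_validate_well_formed_inputs(self, runner, sim_dir):
        res = runner.invoke(main, ["validate", "--alignment", str(sim_dir / "NF.fasta"),
                                   "--tree", str(sim_dir / "NF.nwk")])
        assert res.exit_code == 0
        summary = json.loads(res.output)
        assert summary["n_seqs"] == 6 and summary["n_codons"] == 30
        assert set(summary["foreground"]) == {"dupB", "G2a", "G2b"}

    def test_validate_rejects_bad_alignment(self, runner, tmp_path):
        bad = tmp_path / "bad.fasta"
        bad.write_text(">a\nAAAT\n>b\nAAAT\n")
        res = runner.invoke(main, ["validate", "--alignment", str(bad)])
        assert res.exit_code != 0
        assert "error" in res.output or res.exception is not None

    def test_simulate_is_deterministic(self, runner, tmp_path):
        outs = []
        for name in ("s1", "s2"):
            out = tmp_path / name
            res = runner.invoke(main, ["simulate", "--preset", "neutral",
                                       "--n-codons", "25", "--seed", "9",
                                       "--out", str(out)])
            assert res.exit_code == 0
            outs.append((out / "neutral.fasta").read_bytes())
        assert outs[0] == outs[1]

    def test_classify_round_trip(self, runner, tmp_path):
        ev = tmp_path / "ev.json"
        ev.write_text(json.dumps({
            "daughter_a": {"branch_id": "dupA", "p_adjusted": 0.001,
                           "function": "novel"},
            "daughter_b": {"branch_id": "dupB", "p_adjusted": 0.5,
                           "function": "ancestral"},
        }))
        res = runner.invoke(main, ["classify", "--evidence", str(ev)])
        assert res.exit_code == 0
        assert json.loads(res.output)["mode"] == "NF"

    def test_mkt_report_matches_pairwise_layout(self, runner, tmp_path):
        from dupsel.simulate import PopulationScenario, simulate_population_sample

        base = "AAATTTGGGCCCATTGTTCAA" * 6
        for name, seed in (("a", 3), ("b", 4)):
            pop = simulate_population_sample(
                PopulationScenario(base, 8, 0.1, 0.05, seed=seed))
            pop.haplotypes.to_fasta(tmp_path / f"{name}.fasta")
        res = runner.invoke(main, ["pairwise-mkt",
                                   "--sample-a", str(tmp_path / "a.fasta"),
                                   "--sample-b", str(tmp_path / "b.fasta"),
                                   "--out", str(tmp_path / "pw")])
        assert res.exit_code == 0, res.output
        lines = (tmp_path / "pw.tsv").read_text().strip().split("\n")
        assert len(lines) == 2
        assert lines[0].split("\t") == ["comparison", "syn_poly", "nsyn_poly",
                                        "syn_sub", "nsyn_sub", "NI", "chi2", "P"]


class TestReadTree:
    def test_two_tip_tree(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:0.1,B:0.2);\n")
        tree = read_tree(p)
        assert tree.tip_names() == ["A", "B"] and tree.foreground == []

    def test_paml_tag_dialect(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:0.1,B:0.2 #1):0;\n")
        tree = read_tree(p)
        assert [n.label for n in tree.foreground] == ["B"]

    def test_round_trip_through_write(self, tmp_path):
        from dupsel.trees import write_tree

        p = tmp_path / "t.nwk"
        p.write_text("((A:0.1,B:0.2)90:0.05,C:0.3 #1,D:0.1);\n")
        tree = read_tree(p)
        q = tmp_path / "u.nwk"
        write_tree(tree, q)
        again = read_tree(q)
        assert again.tip_names() == tree.tip_names()
        assert [n.label for n in again.foreground] == ["C"]


class TestWriteReport:
    def _mk_result(self):
        counts = MKCounts(Ps=10.0, Pn=2.0, Ds_raw=8.0, Dn_raw=12.0,
                          Ds=8.5, Dn=12.6, syn_sites=120.0, nsyn_sites=340.0)
        return MKResult(counts=counts, NI=(2 / 10) / (12.6 / 8.5), chi2=4.2,
                        p=0.04, label="gA vs anc")

    def test_single_result_row_has_seven_value_columns(self, tmp_path):
        tsv, js = write_report([self._mk_result()], "table3", tmp_path / "r")
        lines = tsv.read_text().strip().split("\n")
        assert len(lines) == 2
        assert len(lines[1].split("\t")) == 8  # comparison label + 7 value columns
        payload = json.loads(js.read_text())
        assert payload["rows"][0]["syn_poly"] == 10.0

    def test_range_cells_render_with_dash_and_bounds(self, tmp_path):
        rng = MKRangeResult(Ps=56.0, Pn=3.0, Ds_range=(422.0, 508.0),
                            Dn_range=(278.0, 290.0), NI_max=0.10,
                            chi2_min=24.7, p_at_chi2_min=0.0002, label="SulfC")
        tsv, js = write_report([rng], "table2", tmp_path / "r")
        row = tsv.read_text().strip().split("\n")[1]
        assert "422.0–508.0" in row
        assert "≤0.10" in row and "≥24.7" in row

    def test_tsv_is_deterministic_formatting_of_json(self, tmp_path):
        res = self._mk_result()
        tsv, js = write_report([res], "table3", tmp_path / "r")
        row = tsv.read_text().strip().split("\n")[1].split("\t")
        payload = json.loads(js.read_text())["rows"][0]
        assert float(row[5]) == pytest.approx(payload["NI"], abs=0.005)
        assert float(row[6]) == pytest.approx(payload["chi2"], abs=0.05)

    def test_empty_results_are_refused(self, tmp_path):
        with pytest.raises(ValueError):
            write_report([], "table2", tmp_path / "r")
        assert not (tmp_path / "r.tsv").exists()

    def test_provenance_block_contains_hash_and_seed(self, tmp_path):
        from dupsel.reports import provenance

        meta = provenance({"alignment": "x.fasta"}, seed=7)
        tsv, js = write_report([self._mk_result()], "table3", tmp_path / "r",
                               meta=meta)
        payload = json.loads(js.read_text())
        assert payload["provenance"]["seed"] == 7
        assert len(payload["provenance"]["config_hash"]) == 16


class TestRunConfig:
    def test_yaml_round_trip_and_validation(self, tmp_path, sim_dir):
        from dupsel.config import load_config

        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text(
            f"alignment: {sim_dir / 'NF.fasta'}\n"
            f"tree: {sim_dir / 'NF.nwk'}\n"
            "alpha: 0.01\n"
            "frequency_mode: equal\n"
            "key_nodes: [dupA, dupB]\n")
        cfg = load_config(cfg_path)
        assert cfg.alpha == 0.01
        assert cfg.key_nodes == ["dupA", "dupB"]

    def test_bad_alpha_and_missing_paths_rejected(self, tmp_path):
        from dupsel.config import RunConfig, load_config

        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text("alignment: nowhere.fasta\ntree: nowhere.nwk\n")
        with pytest.raises(FileNotFoundError):
            load_config(cfg_path)
        with pytest.raises(ValueError):
            RunConfig(alignment="x", tree="y", alpha=2.0).validate()

    def test_unknown_keys_rejected(self, tmp_path):
        from dupsel.config import load_config

        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text("alignment: a\ntree: b\nbogus: 1\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            load_config(cfg_path)
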
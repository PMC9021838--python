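"""Model/results interface, pipeline orchestration and CLI plumbing.

Integration tests run on small synthetic GEMs with a reduced k grid and
few Gibbs sweeps so the whole file stays fast.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml

from geneshift.model import GeneShiftConfig, GeneShiftModel
from geneshift.synthetic import SyntheticConfig, generate_gem, null_config
from geneshift.workflow import RunConfig, load_config, run_pipeline

FAST = dict(k_grid=(3, 4, 5), n_init=2, dpgp_max_iterations=60, seed=9)


@pytest.fixture(scope="module")
def small_fit():
    cfg = SyntheticConfig(n_genes=60, n_shapes=4, seed=21,
                          replicate_discordance_prob=0.0)
    gem, truth = generate_gem(cfg)
    model = GeneShiftModel(gem, config=GeneShiftConfig(**FAST))
    return model, model.fit(), truth


class TestGeneShiftModel:
    def test_requires_fpkm_scale(self):
        from geneshift.gem import log_transform
        gem, _ = generate_gem(SyntheticConfig(n_genes=10, seed=0))
        with pytest.raises(ValueError, match="FPKM"):
            GeneShiftModel(log_transform(gem))

    def test_control_guessed_from_aliases(self, small_fit):
        model, _, _ = small_fit
        assert model.control == "control"
        assert model.treated == "treated"

    def test_from_tsv_roundtrip(self, tmp_path):
        gem, _ = generate_gem(SyntheticConfig(n_genes=15, seed=1))
        p = tmp_path / "gem.tsv"
        gem.to_tsv(p)
        model = GeneShiftModel.from_tsv(p, config=GeneShiftConfig(**FAST))
        assert len(model.gem.gene_ids) == 15

    def test_chosen_k_in_grid(self, small_fit):
        _, res, _ = small_fit
        assert res.k_report.chosen_k in res.k_report.grid

    def test_every_trajectory_gets_composite_label(self, small_fit):
        _, res, _ = small_fit
        assert len(res.composite_labels) == len(res.trajectories)
        assert all(lab.startswith("K") and "_D" in lab
                   for lab in res.composite_labels)

    def test_shift_counts_consistent(self, small_fit):
        _, res, _ = small_fit
        s = res.summary_counts
        assert s["n_shift"] == (s["n_shift_A_off_to_dynamic"]
                                + s["n_shift_B_dynamic_to_off"]
                                + s["n_shift_C_dynamic_to_dynamic"])
        assert s["n_qualified_both"] == s["n_shift"] + s["n_non_shift"]

    def test_low_noise_truth_recovery(self, small_fit):
        _, res, truth = small_fit
        detected = res.shift_genes()
        true = truth.shift_genes()
        tp = len(detected & true)
        assert tp / max(len(detected), 1) >= 0.8
        assert tp / max(len(true), 1) >= 0.8

    def test_summary_text_mentions_counts(self, small_fit):
        _, res, _ = small_fit
        text = res.summary()
        assert "Shift genes" in text
        assert str(res.summary_counts["n_shift"]) in text

    def test_save_writes_expected_artifacts(self, small_fit, tmp_path):
        _, res, _ = small_fit
        out = res.save(tmp_path / "run")
        for name in ("normalized_gem.tsv", "off_genes.tsv", "k_selection.tsv",
                     "assignments.tsv", "shift_table.tsv",
                     "trajectory_sets.tsv", "summary.json"):
            assert (out / name).exists(), name
        payload = json.loads((out / "summary.json").read_text())
        assert payload["counts"]["n_genes"] == 60

    def test_plot_trajectory_set(self, small_fit):
        _, res, _ = small_fit
        if not res.trajectory_sets:
            pytest.skip("no sets in this fit")
        ax = res.plot_trajectory_set(res.trajectory_sets[0].set_id)
        assert ax.get_xlabel() == "time (h)"


class TestEnrichmentIntegration:
    def test_annotations_produce_enrichment_table(self, tmp_path):
        cfg = SyntheticConfig(n_genes=40, n_shapes=3, seed=8,
                              replicate_discordance_prob=0.0)
        gem, truth = generate_gem(cfg)
        from geneshift.enrich import AnnotationTable
        # annotate the true shift genes with one term
        mapping = {g: {("GO", "GO:1", "response")} for g in truth.shift_genes()}
        for g in list(gem.gene_ids)[:10]:
            mapping.setdefault(g, set()).add(("GO", "GO:2", "housekeeping"))
        model = GeneShiftModel(gem, annotations=AnnotationTable(mapping),
                               config=GeneShiftConfig(**FAST))
        res = model.fit()
        assert res.enrichment is not None
        for r in res.enrichment:
            assert r.a + r.b + r.c + r.d == 40


class TestPipelineDeterminism:
    def make_run(self, tmp_path, name, seed=13):
        gem, _ = generate_gem(SyntheticConfig(n_genes=40, n_shapes=4, seed=2))
        gem_path = tmp_path / "gem.tsv"
        gem.to_tsv(gem_path)
        cfg = RunConfig(gem=str(gem_path), outdir=str(tmp_path / name),
                        model=GeneShiftConfig(k_grid=(3, 4), n_init=2,
                                              dpgp_max_iterations=50,
                                              seed=seed))
        return run_pipeline(cfg)

    def test_identical_config_byte_identical_outputs(self, tmp_path):
        self.make_run(tmp_path, "run1")
        self.make_run(tmp_path, "run2")
        for name in ("summary.json", "shift_table.tsv", "assignments.tsv",
                     "trajectory_sets.tsv", "k_selection.tsv"):
            b1 = (tmp_path / "run1" / name).read_bytes()
            b2 = (tmp_path / "run2" / name).read_bytes()
            assert b1 == b2, name

    def test_null_gem_reports_no_shifts(self, tmp_path):
        gem, _ = generate_gem(null_config(n_genes=80, n_shapes=4, seed=6,
                                          replicate_discordance_prob=0.0))
        model = GeneShiftModel(gem, config=GeneShiftConfig(
            k_grid=(3, 4, 5, 6), n_init=3, dpgp_max_iterations=80, seed=3))
        res = model.fit()
        qualified = res.summary_counts["n_qualified_both"]
        assert res.summary_counts["n_shift"] <= 0.02 * max(qualified, 1)


class TestWorkflowConfig:
    def test_yaml_round_trip(self, tmp_path):
        gem, _ = generate_gem(SyntheticConfig(n_genes=10, seed=0))
        gem_path = tmp_path / "gem.tsv"
        gem.to_tsv(gem_path)
        cfg_yaml = {"gem": str(gem_path), "outdir": str(tmp_path / "out"),
                    "model": {"k_grid": "3:5:1", "seed": 4,
                              "dpgp_max_iterations": 20}}
        p = tmp_path / "run.yaml"
        p.write_text(yaml.safe_dump(cfg_yaml))
        cfg = load_config(p)
        assert cfg.model.k_grid == (3, 4, 5)
        assert cfg.model.seed == 4

    def test_missing_gem_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            RunConfig(gem=str(tmp_path / "nope.tsv"), outdir=str(tmp_path))

    def test_unknown_model_key_rejected(self, tmp_path):
        gem, _ = generate_gem(SyntheticConfig(n_genes=5, seed=0))
        gem_path = tmp_path / "gem.tsv"
        gem.to_tsv(gem_path)
        p = tmp_path / "run.yaml"
        p.write_text(yaml.safe_dump({"gem": str(gem_path),
                                     "outdir": str(tmp_path),
                                     "model": {"bogus": 1}}))
        with pytest.raises(ValueError, match="bogus"):
            load_config(p)


class TestCLI:
    def test_simulate_and_run(self, tmp_path):
        from click.testing import CliRunner
        from geneshift.cli import main
        runner = CliRunner()
        gem_path = tmp_path / "sim.tsv"
        truth_path = tmp_path / "truth.tsv"
        r = runner.invoke(main, ["simulate", "--out", str(gem_path),
                                 "--truth", str(truth_path),
                                 "--n-genes", "25", "--seed", "3"])
        assert r.exit_code == 0, r.output
        assert gem_path.exists() and truth_path.exists()

        run_yaml = tmp_path / "run.yaml"
        run_yaml.write_text(yaml.safe_dump({
            "gem": str(gem_path), "outdir": str(tmp_path / "out"),
            "model": {"k_grid": [3, 4], "n_init": 2,
                      "dpgp_max_iterations": 30, "seed": 1}}))
        r = runner.invoke(main, ["run", "--config", str(run_yaml)])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "out" / "summary.json").exists()

    def test_enrich_command(self, tmp_path):
        from click.testing import CliRunner
        from geneshift.cli import main
        sets = pd.DataFrame({"set_id": ["S0", "S0", "S1"],
                             "gene_id": ["g1", "g2", "g3"]})
        sets_path = tmp_path / "sets.tsv"
        sets.to_csv(sets_path, sep="\t", index=False)
        ann = pd.DataFrame({
            "gene_id": ["g1", "g2", "g3", "g4"],
            "vocabulary": ["GO"] * 4,
            "term_id": ["T1", "T1", "T2", "T2"],
            "term_name": ["x", "x", "y", "y"]})
        ann_path = tmp_path / "ann.tsv"
        ann.to_csv(ann_path, sep="\t", index=False)
        out_path = tmp_path / "enr.tsv"
        runner = CliRunner()
        r = runner.invoke(main, ["enrich", "--sets", str(sets_path),
                                 "--annotations", str(ann_path),
                                 "--out", str(out_path)])
        assert r.exit_code == 0, r.output
        assert out_path.exists()
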
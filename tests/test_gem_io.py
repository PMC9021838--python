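"""GEM loading, quantile normalization, off-gene extraction, trajectories."""

import numpy as np
import pandas as pd
import pytest

from geneshift.gem import (build_trajectories, extract_off_genes,
                           log_transform, parse_sample_names,
                           quantile_normalize, read_gem)

from conftest import TIME_GRID, make_gem


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


class TestReadGem:
    def test_reads_matrix_and_parses_two_conditions(self, tmp_path):
        p = tmp_path / "gem.tsv"
        cols = ["gene", "control_0h_r1", "control_12h_r1",
                "treated_0h_r1", "treated_12h_r1"]
        write_tsv(p, cols, [["g1", 1, 2, 3, 4], ["g2", 0, 1, 0, 2],
                            ["g3", 5, 5, 5, 5]])
        gem = read_gem(p)
        assert gem.values.shape == (3, 4)
        assert gem.conditions == ["control", "treated"]
        assert list(gem.time_grid) == [0.0, 12.0]

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "gem.tsv"
        write_tsv(p, ["gene", "control_0h_r1", "treated_0h_r1"],
                  [["g1", 1, 2], ["g1", 3, 4]])
        with pytest.raises(ValueError, match="duplicate gene id"):
            read_gem(p)

    def test_unparseable_sample_name_is_named_in_error(self, tmp_path):
        p = tmp_path / "gem.tsv"
        write_tsv(p, ["gene", "control_0h_r1", "X_banana_7"],
                  [["g1", 1, 2]])
        with pytest.raises(ValueError, match="X_banana_7"):
            read_gem(p)

    def test_sample_sheet_overrides_name_parsing(self, tmp_path):
        p = tmp_path / "gem.tsv"
        write_tsv(p, ["gene", "s1", "s2"], [["g1", 1, 2]])
        sheet = tmp_path / "sheet.tsv"
        write_tsv(sheet, ["sample_id", "condition", "time", "replicate"],
                  [["s1", "control", 0, 1], ["s2", "treated", 0, 1]])
        gem = read_gem(p, sample_sheet=sheet)
        assert gem.conditions == ["control", "treated"]

    def test_missing_cells_rejected(self, tmp_path):
        p = tmp_path / "gem.tsv"
        p.write_text("gene\tcontrol_0h_r1\ttreated_0h_r1\ng1\t1\t\n")
        with pytest.raises(ValueError, match="missing"):
            read_gem(p)

    def test_parse_sample_names_template(self):
        metas = parse_sample_names(["ctrl_24h_r2"], "{condition}_{time}h_r{rep}")
        assert metas[0].condition == "ctrl"
        assert metas[0].time == 24.0
        assert metas[0].replicate == 2


class TestQuantileNormalize:
    def test_hand_oracle_two_columns(self):
        # columns [5,2,3] and [4,1,6] -> [5.5,1.5,3.5] and [3.5,1.5,5.5]
        gem = make_gem({
            "g1": {("control", 1): [5] * 5, ("treated", 1): [4] * 5},
            "g2": {("control", 1): [2] * 5, ("treated", 1): [1] * 5},
            "g3": {("control", 1): [3] * 5, ("treated", 1): [6] * 5},
        })
        out = quantile_normalize(gem)
        c0 = out.values.iloc[:, 0].to_numpy()
        # column order: control times then treated; every control column equal
        np.testing.assert_allclose(sorted(c0), [1.5, 3.5, 5.5])
        np.testing.assert_allclose(
            out.values.loc[["g1", "g2", "g3"], "control_0h_r1"],
            [5.5, 1.5, 3.5])
        np.testing.assert_allclose(
            out.values.loc[["g1", "g2", "g3"], "treated_0h_r1"],
            [3.5, 1.5, 5.5])

    @staticmethod
    def _tie_free_gem(rng):
        vals = rng.permuted(np.arange(120, dtype=float)).reshape(12, 10)
        prof = {f"g{i:02d}": {("control", 1): vals[i, :5].tolist(),
                              ("treated", 1): vals[i, 5:].tolist()}
                for i in range(12)}
        return make_gem(prof)

    def test_all_columns_share_value_multiset(self, rng):
        out = quantile_normalize(self._tie_free_gem(rng))
        arr = out.values.to_numpy()
        ref = np.sort(arr[:, 0])
        for j in range(arr.shape[1]):
            np.testing.assert_allclose(np.sort(arr[:, j]), ref)

    def test_idempotent(self, rng):
        once = quantile_normalize(self._tie_free_gem(rng))
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.values.to_numpy(),
                                   twice.values.to_numpy(), atol=1e-12)

    def test_ties_get_mean_of_reference_ranks(self):
        gem = make_gem({
            "g1": {("control", 1): [1] * 5, ("treated", 1): [1] * 5},
            "g2": {("control", 1): [1] * 5, ("treated", 1): [4] * 5},
            "g3": {("control", 1): [7] * 5, ("treated", 1): [9] * 5},
        })
        out = quantile_normalize(gem)
        ref = np.sort(gem.values.to_numpy(), axis=0).mean(axis=1)
        col = out.values["control_0h_r1"]
        assert col["g1"] == col["g2"] == pytest.approx(ref[:2].mean())
        assert col["g3"] == pytest.approx(ref[2])


class TestLogTransform:
    @pytest.mark.parametrize("v,expected", [(0, 0), (1, 1), (3, 2)])
    def test_log2_plus_one(self, v, expected):
        gem = make_gem({"g1": {("control", 1): [v] * 5,
                               ("treated", 1): [v] * 5}})
        out = log_transform(gem)
        assert out.scale == "quantile_log2"
        assert out.values.iloc[0, 0] == pytest.approx(expected)


class TestExtractOffGenes:
    def make(self):
        zeros = [0.0] * 5
        dyn = [1.0, 2.0, 3.0, 4.0, 5.0]
        return make_gem({
            # replicate 1 all-zero, others dynamic -> off at threshold 1
            "g_off1": {("control", 1): zeros, ("control", 2): dyn,
                       ("control", 3): dyn, ("treated", 1): dyn,
                       ("treated", 2): dyn, ("treated", 3): dyn},
            # a single zero at one time point only -> active
            "g_active": {("control", r): ([0.0] + dyn[1:] if r == 1 else dyn)
                         for r in (1, 2, 3)} |
                        {("treated", r): dyn for r in (1, 2, 3)},
            "g_on": {(c, r): dyn for c in ("control", "treated")
                     for r in (1, 2, 3)},
        })

    def test_one_zero_replicate_is_off(self):
        gem = self.make()
        off, active = extract_off_genes(gem, "control")
        assert off == {"g_off1"}
        assert active == {"g_active", "g_on"}

    def test_partition_and_all_on(self):
        gem = self.make()
        off, active = extract_off_genes(gem, "treated")
        assert off == set()
        assert active == set(gem.gene_ids)

    def test_impossible_threshold_empty_off(self):
        gem = self.make()
        off, active = extract_off_genes(gem, "control",
                                        min_zero_replicates=4)
        assert off == set()
        assert len(active) == 3

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="shoot"):
            extract_off_genes(self.make(), "shoot")


class TestBuildTrajectories:
    def test_count_is_genes_times_conditions_times_replicates(self, tiny_gem):
        normed = log_transform(tiny_gem)
        trajs = build_trajectories(normed, ["gA", "gB"])
        assert len(trajs) == 2 * 2 * 3

    def test_empty_gene_set(self, tiny_gem):
        assert build_trajectories(log_transform(tiny_gem), []) == []

    def test_absent_gene_rejected(self, tiny_gem):
        with pytest.raises(ValueError, match="gX"):
            build_trajectories(log_transform(tiny_gem), ["gX"])

    def test_values_time_sorted_even_with_shuffled_columns(self, tiny_gem):
        normed = log_transform(tiny_gem)
        perm = list(normed.values.columns)[::-1]
        shuffled = normed.values[perm]
        from geneshift.gem import ExpressionMatrix
        gem2 = ExpressionMatrix.__new__(ExpressionMatrix)
        gem2.values = shuffled
        gem2.samples = [s for c in perm for s in normed.samples
                        if s.sample_id == c]
        gem2.scale = "quantile_log2"
        ref = {(tr.gene_id, tr.condition, tr.replicate): tr.y
               for tr in build_trajectories(normed, ["gA"])}
        for tr in build_trajectories(gem2, ["gA"]):
            np.testing.assert_allclose(
                tr.y, ref[(tr.gene_id, tr.condition, tr.replicate)])

    def test_requires_analysis_scale(self, tiny_gem):
        with pytest.raises(ValueError, match="quantile_log2"):
            build_trajectories(tiny_gem, ["gA"])
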
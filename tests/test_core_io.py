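import json

import numpy as np
import pandas as pd
import pytest

from refstab import (
    CtMatrix,
    CtRecord,
    EfficiencyTable,
    ValidationError,
    aggregate_replicates,
    read_ct_table,
    read_expression_matrix,
    write_report,
)
from refstab.core_io import read_report, records_to_frame, validate_ct_records
from refstab.synthetic_data import simulate_ct, stress_design


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestExpressionMatrixReader:
    def test_reads_tsv_preserving_order(self, tmp_path, fpkm):
        path = _write(
            tmp_path,
            "m.tsv",
            "gene\tA\tB\ng2,x\t1.5\t2.5\ng1\t3\t4\n",
        )
        m = read_expression_matrix(path)
        assert m.gene_ids == ["g2,x", "g1"]
        assert m.condition_ids == ["A", "B"]
        # the bundled screening table parses to its documented shape
        assert fpkm.values.shape == (12, 4)

    def test_minimal_single_gene_csv(self, tmp_path):
        m = read_expression_matrix(_write(tmp_path, "m.csv", "gene,c1,c2\ng1,1.0,1.0\n"))
        assert m.values.shape == (1, 2)

    def test_negative_value_names_gene_and_condition(self, tmp_path):
        path = _write(tmp_path, "m.csv", "gene,c1,c2\ng1,1.0,-5.0\n")
        with pytest.raises(ValidationError, match="g1.*c2"):
            read_expression_matrix(path)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = _write(tmp_path, "m.csv", "gene,c1,c2\ng1,1,2\ng1,3,4\n")
        with pytest.raises(ValidationError, match="duplicate gene"):
            read_expression_matrix(path)

    def test_single_condition_rejected(self, tmp_path):
        path = _write(tmp_path, "m.csv", "gene,c1\ng1,1\n")
        with pytest.raises(ValidationError, match="2 conditions"):
            read_expression_matrix(path)


class TestCtTableReader:
    def test_full_factorial_row_count(self, tmp_path):
        records = simulate_ct(stress_design(seed=3))
        path = tmp_path / "ct.csv"
        records.to_csv(path, index=False)
        back = read_ct_table(path)
        # 12 genes x 13 samples x (3 bio x 3 tech) replicates
        assert len(back) == 12 * 13 * 9
        pd.testing.assert_frame_equal(back, records)

    def test_empty_data_section_is_not_an_error(self, tmp_path):
        path = _write(tmp_path, "ct.csv", "sample_id,group_label,gene_id,bio_rep,tech_rep,ct\n")
        assert len(read_ct_table(path)) == 0

    def test_duplicate_replicate_key_rejected(self, tmp_path):
        row = "s1,ck,g1,1,1,20\n"
        path = _write(
            tmp_path, "ct.csv", "sample_id,group_label,gene_id,bio_rep,tech_rep,ct\n" + row + row
        )
        with pytest.raises(ValidationError, match="duplicate replicate key"):
            read_ct_table(path)

    def test_non_numeric_ct_reports_row(self, tmp_path):
        path = _write(
            tmp_path,
            "ct.csv",
            "sample_id,group_label,gene_id,bio_rep,tech_rep,ct\ns1,ck,g1,1,1,oops\n",
        )
        with pytest.raises(ValidationError, match="row 1"):
            read_ct_table(path)

    def test_nonpositive_ct_rejected_and_extreme_ct_warns(self):
        base = dict(sample_id="s1", group_label="ck", gene_id="g1", bio_rep=1, tech_rep=1)
        with pytest.raises(ValidationError, match="finite and > 0"):
            records_to_frame([CtRecord(ct=-1.0, **base)])
        with pytest.warns(UserWarning, match="plausible range"):
            records_to_frame([CtRecord(ct=55.0, **base)])


class TestAggregateReplicates:
    @staticmethod
    def _records(cts_by_bio: dict) -> pd.DataFrame:
        recs = []
        for bio, cts in cts_by_bio.items():
            for t, ct in enumerate(cts, start=1):
                recs.append(CtRecord("s1", "ck", "g1", bio, t, ct))
        return records_to_frame(recs)

    def test_constant_replicates(self):
        ct = aggregate_replicates(self._records({1: [20, 20, 20]}))
        assert ct.mean_ct.at["g1", "s1"] == pytest.approx(20.0)
        assert ct.n_replicates.at["g1", "s1"] == 3

    def test_two_stage_vs_pooled_on_unbalanced_design(self):
        recs = self._records({1: [20, 22], 2: [25]})
        two_stage = aggregate_replicates(recs)
        pooled = aggregate_replicates(recs, method="pooled")
        assert two_stage.mean_ct.at["g1", "s1"] == pytest.approx(23.0)
        assert pooled.mean_ct.at["g1", "s1"] == pytest.approx(67 / 3)

    def test_two_stage_equals_pooled_when_balanced(self, sim_ct):
        records = simulate_ct(stress_design(seed=7))
        pooled = aggregate_replicates(records, method="pooled")
        pd.testing.assert_frame_equal(sim_ct.mean_ct, pooled.mean_ct)

    def test_record_order_permutation_invariance(self):
        records = simulate_ct(stress_design(seed=5))
        shuffled = records.sample(frac=1, random_state=0).reset_index(drop=True)
        a = aggregate_replicates(records).mean_ct
        b = aggregate_replicates(shuffled).mean_ct
        pd.testing.assert_frame_equal(a, b.loc[a.index, a.columns])

    def test_full_design_shape(self, sim_ct):
        assert sim_ct.mean_ct.shape == (12, 13)

    def test_missing_cell_is_a_completeness_error(self):
        recs = records_to_frame(
            [
                CtRecord("s1", "ck", "g1", 1, 1, 20.0),
                CtRecord("s2", "ck", "g1", 1, 1, 21.0),
                CtRecord("s1", "ck", "g2", 1, 1, 25.0),
            ]
        )
        with pytest.raises(ValidationError, match=r"\('g2', 's2'\)"):
            aggregate_replicates(recs)


class TestEfficiencyTable:
    def test_default_and_bounds(self):
        eff = EfficiencyTable({"g1": 1.9})
        assert eff["g1"] == 1.9
        assert eff["absent"] == 2.0
        with pytest.raises(ValidationError):
            EfficiencyTable({"bad": 0.9})
        with pytest.warns(UserWarning, match="outside the usual"):
            EfficiencyTable({"odd": 1.5})


class TestReports:
    def test_tsv_columns_and_rows(self, tmp_path, sim_ct):
        from refstab import bestkeeper_stats

        result = bestkeeper_stats(sim_ct)
        out = tmp_path / "bk.tsv"
        write_report(result, out)
        back = read_report(out)
        assert len(back) == 12
        assert list(back.columns) == list(result.summary.columns)

    def test_v_series_row_count_is_k_minus_2(self, tmp_path, sim_ct):
        from refstab import pairwise_variation_series, rank_stepwise, relative_quantities

        q = relative_quantities(sim_ct)
        vs = pairwise_variation_series(q, rank_stepwise(q))
        out = tmp_path / "v.tsv"
        write_report(vs, out)
        assert len(read_report(out)) == 12 - 2

    def test_json_round_trip_within_precision(self, tmp_path):
        df = pd.DataFrame({"x": [1.23456, 2.0], "y": [0.001234, 9.9]}, index=["a", "b"])
        out = tmp_path / "r.json"
        write_report(df, out, digits=3)
        back = read_report(out)
        assert np.allclose(back["x"], df["x"], atol=5e-4)
        assert json.loads(out.read_text())  # valid JSON document

    def test_sample_to_multiple_groups_rejected(self):
        recs = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "group_label": ["ck", "cold"],
                "gene_id": ["g1", "g2"],
                "bio_rep": [1, 1],
                "tech_rep": [1, 1],
                "ct": [20.0, 21.0],
            }
        )
        with pytest.raises(ValidationError, match="more than one group"):
            validate_ct_records(recs)
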
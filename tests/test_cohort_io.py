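"""Dictionary/patient-table readers, description cleaning and variable filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sonar import (
    ConfigurationError,
    DistributionVector,
    GoldStandard,
    SubgroupSchema,
    ValidationError,
    consolidate_identical,
    filter_complete_subgroups,
    filter_continuous,
    filter_nonzero,
    read_dictionary,
    strip_temporal,
)
from sonar.cohort_io import VariableRecord, patient_table_from_frame


def _record(acc, description, cohort="A", continuous=True):
    return VariableRecord(
        variable_accession=acc,
        variable_name=acc.upper(),
        description_raw=description,
        description_clean=strip_temporal(description),
        dataset_accession="pht0001",
        cohort_id=cohort,
        is_continuous=continuous,
    )


class TestStripTemporal:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("LDL cholesterol, visit 2", "LDL cholesterol"),
            ("Exam 5: systolic blood pressure", "systolic blood pressure"),
            ("LDL cholesterol", "LDL cholesterol"),
            ("Body weight at year 10", "Body weight at"),
            ("Fasting glucose - second visit", "Fasting glucose"),
            ("visit 2", ""),
            ("", ""),
        ],
    )
    def test_examples(self, raw, expected):
        assert strip_temporal(raw) == expected

    def test_empty_term_list_rejected(self):
        with pytest.raises(ValidationError):
            strip_temporal("anything", [])

    @given(st.text(max_size=60))
    def test_never_longer(self, text):
        assert len(strip_temporal(text)) <= len(text)

    @given(st.text(alphabet="abcdefgh visitexam0123,:", max_size=60))
    def test_only_removes_spans(self, text):
        # every non-space character of the output appears in the input in order
        out = strip_temporal(text).replace(" ", "")
        src = iter(text.replace(" ", ""))
        assert all(ch in src for ch in out)


class TestReadDictionary:
    def _write(self, tmp_path, text):
        path = tmp_path / "dict.csv"
        path.write_text(text)
        return path

    def test_roundtrip_identity(self, tmp_path):
        path = self._write(
            tmp_path,
            "variable_accession,variable_name,description,dataset_accession,is_continuous\n"
            "v1,N1,LDL cholesterol,d1,true\n"
            "v2,N2,HDL cholesterol,d1,1\n"
            "v3,N3,Weight,d2,false\n",
        )
        records = read_dictionary(path, "A")
        assert [r.variable_accession for r in records] == ["v1", "v2", "v3"]
        assert [r.is_continuous for r in records] == [True, True, False]

    def test_empty_description_retained(self, tmp_path):
        path = self._write(
            tmp_path,
            "variable_accession,variable_name,description,dataset_accession,is_continuous\n"
            "v1,N1,,d1,true\n",
        )
        (record,) = read_dictionary(path, "A")
        assert record.description_clean == ""

    def test_missing_column_named_in_error(self, tmp_path):
        path = self._write(
            tmp_path,
            "variable_accession,variable_name,dataset_accession,is_continuous\n"
            "v1,N1,d1,true\n",
        )
        with pytest.raises(ConfigurationError, match="description"):
            read_dictionary(path, "A")

    def test_duplicate_accession_rejected(self, tmp_path):
        path = self._write(
            tmp_path,
            "variable_accession,variable_name,description,dataset_accession,is_continuous\n"
            "v1,N1,x,d1,true\nv1,N2,y,d1,true\n",
        )
        with pytest.raises(ValidationError, match="v1"):
            read_dictionary(path, "A")

    def test_temporal_stripping_applied(self, tmp_path):
        path = self._write(
            tmp_path,
            "variable_accession,variable_name,description,dataset_accession,is_continuous\n"
            "v1,N1,\"CRP, visit 3\",d1,true\n",
        )
        (record,) = read_dictionary(path, "A")
        assert record.description_clean == "CRP"
        assert record.description_raw == "CRP, visit 3"


def _patient_frame(rows):
    frame = pd.DataFrame(rows)
    frame.index.name = "patient_id"
    return frame


class TestValueFilters:
    def test_filter_continuous(self):
        records = [
            _record("v1", "a"),
            _record("v2", "b", continuous=False),
            _record("v3", "c"),
        ]
        assert [r.variable_accession for r in filter_continuous(records)] == ["v1", "v3"]
        assert filter_continuous([]) == []
        assert filter_continuous(records[:1]) == records[:1]

    def test_complete_subgroups_rule(self, schema):
        # two-subgroup cohort (one race, one sex, two age buckets populated)
        rows = []
        for age in (50, 65):
            for i in range(3):
                rows.append({"age": age, "race": "White", "sex": "female",
                             "v_full": 1.0, "v_gap": 2.0 if age == 50 else np.nan,
                             "v_empty": np.nan})
        table = patient_table_from_frame(_patient_frame(rows), "A")
        kept = filter_complete_subgroups(table, schema)
        assert kept == {"v_full"}

    def test_single_populated_subgroup_boundary(self, schema):
        rows = [{"age": 50, "race": "White", "sex": "female", "v1": 3.0}]
        table = patient_table_from_frame(_patient_frame(rows), "A")
        assert filter_complete_subgroups(table, schema) == {"v1"}

    def test_nonzero_rule(self, schema):
        rows = [
            {"age": 50, "race": "White", "sex": "female", "z": 0.0, "nz": 0.0, "sg": -1.0},
            {"age": 51, "race": "White", "sex": "female", "z": 0.0, "nz": 1.0, "sg": 1.0},
            {"age": 52, "race": "White", "sex": "female", "z": 0.0, "nz": 0.0, "sg": 1.0},
        ]
        table = patient_table_from_frame(_patient_frame(rows), "A")
        assert filter_nonzero(table, {"z", "nz", "sg"}) == {"nz", "sg"}

    def test_filter_order_insensitive(self, schema):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(40):
            rows.append({
                "age": int(rng.integers(45, 95)),
                "race": rng.choice(["White", "Black"]),
                "sex": rng.choice(["female", "male"]),
                **{f"v{i}": (0.0 if i % 3 == 0 else float(rng.normal()))
                   if rng.random() > 0.2 else np.nan
                   for i in range(8)},
            })
        table = patient_table_from_frame(_patient_frame(rows), "A")
        all_vars = {f"v{i}" for i in range(8)}
        complete_first = filter_nonzero(table, filter_complete_subgroups(table, schema))
        nonzero_first = filter_complete_subgroups(table, schema) & filter_nonzero(
            table, all_vars
        )
        assert complete_first == nonzero_first


class TestConsolidation:
    def _dist(self, values):
        q = np.asarray(values, dtype=float).reshape(-1, 3)
        labels = tuple((f"a{i}", "White", "female") for i in range(q.shape[0]))
        return DistributionVector(labels, q)

    def test_elementwise_mean(self):
        records = [_record("v2", "Glucose"), _record("v1", "glucose  ")]
        dists = {"v1": self._dist([1, 2, 3]), "v2": self._dist([3, 4, 5])}
        result = consolidate_identical(records, dists)
        assert [r.variable_accession for r in result.records] == ["v1"]
        np.testing.assert_allclose(result.dist_vectors["v1"].quantiles, [[2, 3, 4]])
        assert result.merge_map == {"v2": "v1"}

    def test_unique_descriptions_identity(self):
        records = [_record("v1", "Glucose"), _record("v2", "Insulin")]
        dists = {"v1": self._dist([1, 2, 3]), "v2": self._dist([3, 4, 5])}
        result = consolidate_identical(records, dists)
        assert result.records == records
        assert result.merge_map == {}

    def test_cross_cohort_not_merged(self):
        records = [_record("v1", "Glucose", "A"), _record("v2", "Glucose", "B")]
        result = consolidate_identical(records, {})
        assert len(result.records) == 2

    def test_idempotent(self):
        records = [_record("v1", "Glucose"), _record("v2", "glucose"),
                   _record("v3", "Insulin")]
        dists = {a: self._dist([1, 2, 3]) for a in ("v1", "v2", "v3")}
        once = consolidate_identical(records, dists)
        twice = consolidate_identical(once.records, once.dist_vectors)
        assert twice.records == once.records
        assert twice.merge_map == {}

    def test_mismatched_subgroup_labels_rejected(self):
        records = [_record("v1", "Glucose"), _record("v2", "glucose")]
        bad = DistributionVector((("a0", "Black", "male"),), np.array([[1.0, 2, 3]]))
        with pytest.raises(ValidationError, match="subgroup"):
            consolidate_identical(records, {"v1": self._dist([1, 2, 3]), "v2": bad})


class TestGoldStandard:
    def test_variable_in_two_concepts_rejected(self):
        with pytest.raises(ValidationError):
            GoldStandard({"c1": {"v1"}, "c2": {"v1", "v2"}})

    def test_positive_pairs_scopes(self):
        gold = GoldStandard({"c1": {"a1", "a2", "b1"}, "c2": {"a3"}})
        intra = gold.positive_pairs(["a1", "a2", "a3"], ["a1", "a2", "a3"], True)
        assert intra == {"c1": [("a1", "a2")]}
        inter = gold.positive_pairs(["a1", "a2", "a3"], ["b1"], False)
        assert inter == {"c1": [("a1", "b1"), ("a2", "b1")]}

    def test_remap_after_consolidation(self):
        gold = GoldStandard({"c1": {"v1", "v2", "v3"}})
        remapped = gold.remapped({"v2": "v1"})
        assert remapped.assignments["c1"] == frozenset({"v1", "v3"})
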
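import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from replibayes.study_records import (
    SchemaError,
    StudyRecord,
    StudyTable,
    ValidationError,
    es_reduction_q,
    es_reduction_simple,
    log_sample_size,
    read_study_table,
    replication_success_flag,
    write_study_table,
)


def _record(i=0, **kw):
    base = dict(
        study_id=f"S{i}",
        internal_replication_count=i % 3,
        discipline="cognitive",
        effect_type="main",
        p_original=0.01,
        r_original=0.4,
        n_original=50,
        p_replication=0.2,
        r_replication=0.1,
        replication_power=0.92,
        surprisingness=3.0,
        challenge=0.0,
        power_analysis_present=False,
    )
    base.update(kw)
    return StudyRecord(**base)


class TestCSVRoundTrip:
    def test_roundtrip_preserves_values_and_missingness(self, tmp_path):
        table = StudyTable(
            [
                _record(0),
                _record(1, p_replication=None, r_replication=None),
                _record(2, surprisingness=None, challenge=None),
            ],
            provenance="unit test",
        )
        path = tmp_path / "t.csv"
        write_study_table(table, path)
        back = read_study_table(path, provenance="unit test")
        assert back.records == table.records
        assert back.records[1].p_replication is None
        assert back.records[2].challenge is None

    def test_column_mapping_adapts_external_headers(self, tmp_path):
        table = StudyTable([_record(0)])
        path = tmp_path / "t.csv"
        write_study_table(table, path)
        text = path.read_text().replace("p_original", "orig_p")
        path.write_text(text)
        with pytest.raises(SchemaError):
            read_study_table(path)
        back = read_study_table(path, column_map={"p_original": "orig_p"})
        assert back.records == table.records

    def test_out_of_range_value_names_field_and_row(self, tmp_path):
        table = StudyTable([_record(0), _record(1)])
        path = tmp_path / "t.csv"
        write_study_table(table, path)
        path.write_text(path.read_text().replace("0.01,0.4", "1.5,0.4"))
        with pytest.raises(ValidationError) as exc:
            read_study_table(path)
        report = exc.value.report
        assert any(e["field"] == "p_original" for e in report)
        assert all(isinstance(e["row"], int) for e in report)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            StudyTable([_record(0), _record(0)])


class TestDerivedMeasures:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.0017, True), (0.05, False), (0.049999, True), (None, None)],
    )
    def test_replication_success_uses_strict_threshold(self, p, expected):
        assert replication_success_flag(_record(p_replication=p)) is expected

    @pytest.mark.parametrize(
        "ro, rr, expected", [(0.4, 0.4, 0.0), (0.5, 0.3, 0.2), (0.1, 0.3, -0.2)]
    )
    def test_simple_reduction(self, ro, rr, expected):
        assert es_reduction_simple(ro, rr) == pytest.approx(expected)

    def test_cohens_q_example(self):
        # ½ln(1.5/0.5) − ½ln(1.3/0.7), evaluated independently
        assert es_reduction_q(0.5, 0.3) == pytest.approx(0.239787, abs=1e-6)

    @given(
        st.floats(-0.99, 0.99), st.floats(-0.99, 0.99)
    )
    def test_cohens_q_antisymmetry(self, a, b):
        assert es_reduction_q(a, b) == pytest.approx(-es_reduction_q(b, a))

    def test_cohens_q_domain_error_at_unit_correlation(self):
        with pytest.raises(ValueError):
            es_reduction_q(1.0, 0.3)

    def test_log_sample_size_flags_outlier_instead_of_dropping(self):
        table = StudyTable(
            [_record(0, n_original=1), _record(1, n_original=230_025)]
        )
        df = log_sample_size(table)
        assert len(df) == 2
        assert df.loc[0, "log_n"] == 0.0 and not df.loc[0, "excluded"]
        assert df.loc[1, "excluded"]
        kept = df[~df.excluded]
        assert np.allclose(np.exp(kept.log_n), kept.n_original)


class TestGrouping:
    def test_split_partitions_table(self, margins_table):
        rep, unrep = margins_table.split_by_internal_replication()
        assert len(rep) + len(unrep) == len(margins_table)
        assert all(r.internally_replicated for r in rep)
        assert not any(r.internally_replicated for r in unrep)

    def test_all_successes_give_unit_proportions(self):
        from replibayes.pipeline import build_success_table

        table = StudyTable(
            [_record(i, p_replication=0.01,
                     internal_replication_count=i % 2) for i in range(10)]
        )
        ct, _ = build_success_table(table)
        assert ct.proportions == (1.0, 1.0)


class TestPackagedFixture:
    def test_margins_match_published_tables(self, margins_table):
        from replibayes.pipeline import build_success_table

        assert len(margins_table) == 100
        assert sum(r.internally_replicated for r in margins_table) == 44
        counts = [r.internal_replication_count for r in margins_table]
        assert sorted(c for c in counts if c > 0).count(1) == 20
        ct, info = build_success_table(margins_table)
        assert ct.successes == (12, 22)
        assert ct.totals == (42, 54)
        assert info["excluded_missing"] == [2, 2]

    def test_fixture_roundtrips_through_csv(self, margins_table, tmp_path):
        path = tmp_path / "fixture.csv"
        write_study_table(margins_table, path)
        back = read_study_table(path)
        assert back.records == margins_table.records
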
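import importlib.resources
import warnings

import pytest

from lungstress import (
    InterfaceMode,
    PlausibilityWarning,
    SchemaError,
    build_hazard_report,
    cohort_to_frame,
    generate_synthetic_cohort,
    high_risk_interface_fraction,
    lung_partition,
    oxygen_contents,
    read_patient_table,
    read_reports,
    true_shunt_fraction,
    venous_admixture,
    write_report,
)
from lungstress.cohort import CSV_COLUMNS


@pytest.fixture(scope="module")
def cohort20():
    return generate_synthetic_cohort(20, seed=7)


class TestSyntheticCohort:
    def test_size_and_validity(self, cohort20):
        assert len(cohort20) == 20
        assert len({r.identifier for r in cohort20}) == 20

    def test_deterministic_per_seed(self, cohort20):
        again = generate_synthetic_cohort(20, seed=7)
        assert [r.model_dump() for r in again] == [r.model_dump() for r in cohort20]
        different = generate_synthetic_cohort(20, seed=8)
        assert different[0].model_dump() != cohort20[0].model_dump()

    def test_panels_coherent_and_refined_fraction_in_range(self, cohort20):
        """Construction guarantees Cv <= Ca <= Cc and admixture >= true shunt."""
        for rec in cohort20:
            contents = oxygen_contents(rec.ambient_panel)  # raises if unordered
            qva = venous_admixture(contents)
            shunt = true_shunt_fraction(rec.pure_o2_panel)
            frac = high_risk_interface_fraction(qva, shunt, InterfaceMode.REFINED)
            assert 0.0 <= frac <= 1.0
            assert qva >= shunt - 1e-12

    def test_every_record_yields_a_hazard_report(self, cohort20):
        for rec in cohort20:
            qva = venous_admixture(oxygen_contents(rec.ambient_panel))
            shunt = true_shunt_fraction(rec.pure_o2_panel)
            report = build_hazard_report(rec.mechanics, rec.interface_pair, qva, shunt)
            assert report.specific_power > 0

    def test_lung_partition_never_oversubscribed(self, cohort20):
        for rec in cohort20:
            qva = venous_admixture(oxygen_contents(rec.ambient_panel))
            shunt = true_shunt_fraction(rec.pure_o2_panel)
            part = lung_partition(
                rec.mechanics.c_obs, rec.mechanics.c_pred, shunt, qva - shunt
            )
            assert part.total <= 1.0 + 1e-9

    def test_invalid_size_rejected(self):
        with pytest.raises(SchemaError):
            generate_synthetic_cohort(0)


class TestPatientTable:
    def test_packaged_fixture_round_trip(self):
        path = importlib.resources.files("lungstress.data") / "synthetic_cohort.csv"
        records = read_patient_table(str(path))
        assert len(records) == 20

    def test_csv_round_trip_matches_generator(self, cohort20, tmp_path):
        path = tmp_path / "cohort.csv"
        cohort_to_frame(cohort20).to_csv(path, index=False)
        records = read_patient_table(path)
        assert len(records) == 20
        assert records[0].mechanics.c_obs == pytest.approx(cohort20[0].mechanics.c_obs)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert read_patient_table(path) == []

    def test_invalid_row_error_names_row_and_field(self, cohort20, tmp_path):
        frame = cohort_to_frame(cohort20[:3])
        frame.loc[1, "c_obs"] = -5.0
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(SchemaError) as err:
            read_patient_table(path)
        assert "row 1" in str(err.value)
        assert "c_obs" in str(err.value) or "compliance" in str(err.value)

    def test_missing_column_schema_error(self, cohort20, tmp_path):
        frame = cohort_to_frame(cohort20[:2]).drop(columns=["hb"])
        path = tmp_path / "missing.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="hb"):
            read_patient_table(path)

    def test_json_records(self, cohort20, tmp_path):
        import json

        path = tmp_path / "cohort.json"
        path.write_text(json.dumps([r.model_dump() for r in cohort20[:5]]))
        assert len(read_patient_table(path)) == 5

    def test_unknown_field_rejected(self, cohort20, tmp_path):
        import json

        rec = cohort20[0].model_dump()
        rec["bogus_field"] = 1
        path = tmp_path / "extra.json"
        path.write_text(json.dumps([rec]))
        with pytest.raises(SchemaError, match="bogus_field"):
            read_patient_table(path)


class TestReportIO:
    @pytest.fixture
    def reports(self, cohort20):
        out = []
        for rec in cohort20[:4]:
            qva = venous_admixture(oxygen_contents(rec.ambient_panel))
            shunt = true_shunt_fraction(rec.pure_o2_panel)
            out.append(build_hazard_report(rec.mechanics, rec.interface_pair, qva, shunt))
        return out

    @pytest.mark.parametrize("fmt", ["json", "csv"])
    def test_lossless_round_trip(self, reports, tmp_path, fmt):
        path = tmp_path / f"reports.{fmt}"
        write_report(reports, path)
        back = read_reports(path)
        assert len(back) == len(reports)
        for a, b in zip(reports, back):
            for field in (
                "stress_multiplier",
                "strain_multiplier",
                "surface_energy_ratio",
                "baby_lung_fraction",
                "interface_fraction",
                "specific_power",
                "total_power",
            ):
                assert getattr(b, field) == pytest.approx(getattr(a, field), rel=1e-12)

    def test_csv_column_order_stable(self, reports, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_report(reports, p1)
        write_report(list(reports), p2)
        assert p1.read_text().splitlines()[0] == p2.read_text().splitlines()[0]

    def test_empty_report_list(self, tmp_path):
        path = tmp_path / "none.json"
        write_report([], path)
        assert read_reports(path) == []
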
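"""Burden-table data model: parsing, round-trips, validation, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from qcindex.errors import ContractError, FormatError
from qcindex.gbd_tables import (BurdenTable, aggregate, format_age_label,
                                parse_age_label, read_burden_csv,
                                validate_table, write_burden_csv)


@pytest.mark.parametrize("label, bounds", [
    ("95 plus", (95.0, math.inf)),
    ("95+", (95.0, math.inf)),
    ("15 to 19", (15.0, 20.0)),
    ("15-19", (15.0, 20.0)),
    ("<5", (0.0, 5.0)),
    ("Under 1", (0.0, 1.0)),
])
def test_age_label_parsing(label, bounds):
    assert parse_age_label(label) == bounds


def test_age_label_rejects_garbage():
    with pytest.raises(FormatError):
        parse_age_label("working age")


def test_age_label_roundtrip():
    for lo, hi in [(0.0, 5.0), (15.0, 20.0), (95.0, math.inf)]:
        assert parse_age_label(format_age_label(lo, hi)) == (lo, hi)


SIX_ROW_CSV = """measure,location,sex,age,year,metric,val
Incidence,Atlantis,Male,50 to 54,2010,Number,100
Prevalence,Atlantis,Male,50 to 54,2010,Number,300
Deaths,Atlantis,Male,50 to 54,2010,Number,50
YLLs (Years of Life Lost),Atlantis,Male,50 to 54,2010,Number,450
YLDs (Years Lived with Disability),Atlantis,Male,50 to 54,2010,Number,150
DALYs (Disability-Adjusted Life Years),Atlantis,Male,50 to 54,2010,Number,600
"""


def test_read_gbd_dialect(tmp_path):
    path = tmp_path / "six.csv"
    path.write_text(SIX_ROW_CSV)
    table = read_burden_csv(path)
    assert len(table) == 6
    assert set(table.data["measure"]) == {"incidence", "prevalence",
                                          "deaths", "yll", "yld", "daly"}
    assert (table.data["age_group"] == "50 to 54").all()
    assert (table.data["age_lo"] == 50.0).all()
    assert (table.data["age_hi"] == 55.0).all()


def test_read_open_ended_age(tmp_path):
    path = tmp_path / "open.csv"
    path.write_text(SIX_ROW_CSV.replace("50 to 54", "95 plus"))
    table = read_burden_csv(path)
    assert (table.data["age_lo"] == 95.0).all()
    assert np.isinf(table.data["age_hi"]).all()


def test_read_rejects_duplicate_key(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text(SIX_ROW_CSV + "Incidence,Atlantis,Male,50 to 54,2010,"
                    "Number,101\n")
    with pytest.raises(FormatError, match="duplicate"):
        read_burden_csv(path)


def test_read_rejects_missing_column(tmp_path):
    path = tmp_path / "nocol.csv"
    path.write_text(SIX_ROW_CSV.replace("metric,", "met,"))
    with pytest.raises(FormatError, match="metric"):
        read_burden_csv(path)


def test_read_rejects_negative_value(tmp_path):
    path = tmp_path / "neg.csv"
    path.write_text(SIX_ROW_CSV.replace(",600", ",-600"))
    with pytest.raises(FormatError, match="negative"):
        read_burden_csv(path)


def test_write_read_roundtrip(tmp_path, small_world):
    _, table, _ = small_world
    sub = table.subset(year=[2000, 2001])
    path = tmp_path / "world.csv"
    write_burden_csv(sub, path)
    back = read_burden_csv(path)
    assert back.equals(sub)


def test_write_empty_table(tmp_path):
    empty = BurdenTable(pd.DataFrame(columns=["location", "year", "sex",
                                              "age_group", "age_lo",
                                              "age_hi", "measure", "metric",
                                              "value"]))
    path = tmp_path / "empty.csv"
    write_burden_csv(empty, path)
    assert path.read_text().strip() == "measure,location,sex,age,year,metric,val"
    assert len(read_burden_csv(path)) == 0


def test_terminal_label_restored(tmp_path, small_world):
    _, table, _ = small_world
    sub = table.subset(year=2000, age_group="95 plus")
    path = tmp_path / "terminal.csv"
    write_burden_csv(sub, path)
    assert "95 plus" in path.read_text()


class TestValidateTable:
    def test_clean_world_passes(self, small_world):
        _, table, _ = small_world
        assert validate_table(table).ok

    def test_daly_inconsistency_flagged(self, small_world):
        _, table, _ = small_world
        df = table.data.copy()
        mask = df["measure"] == "daly"
        df.loc[mask.idxmax(), "value"] *= 1.1
        report = validate_table(BurdenTable(df))
        assert any(rule == "daly_consistency"
                   for rule, _, _ in report.errors)

    def test_negative_value_flagged(self, small_world):
        _, table, _ = small_world
        df = table.data.copy()
        idx = (df["measure"] == "prevalence").idxmax()
        df.loc[idx, "value"] = -1.0
        report = validate_table(BurdenTable(df))
        assert any(rule == "nonnegative" for rule, _, _ in report.errors)

    def test_duplicate_key_flagged(self, small_world):
        _, table, _ = small_world
        df = pd.concat([table.data, table.data.iloc[[0]]],
                       ignore_index=True)
        report = validate_table(BurdenTable(df))
        assert any(rule == "unique_key" for rule, _, _ in report.errors)


def _cells(rows):
    recs = []
    for loc, sex, value in rows:
        recs.append({"location": loc, "year": 2010, "sex": sex,
                     "age_group": "50 to 54", "age_lo": 50.0,
                     "age_hi": 55.0, "measure": "deaths",
                     "metric": "count", "value": value})
    return BurdenTable(pd.DataFrame(recs))


class TestAggregate:
    def test_counts_add(self):
        table = _cells([("A", "male", 10.0), ("B", "male", 20.0)])
        agg = aggregate(table, ["year", "sex", "age_group"])
        assert agg.data["value"].tolist() == [30.0]
        assert validate_table(agg).ok

    def test_single_member_identity(self):
        table = _cells([("A", "male", 10.0)])
        agg = aggregate(table, ["location", "year", "sex", "age_group"])
        assert agg.data["value"].tolist() == [10.0]

    def test_sex_sum_matches_both_stratum(self, small_world):
        _, table, _ = small_world
        counts = table.subset(metric="count", year=2000)
        agg = aggregate(counts.subset(sex=["male", "female"]),
                        ["location", "year", "age_group"])
        both = counts.subset(sex="both").data.set_index(
            ["location", "age_group", "measure"])["value"]
        merged = agg.data.set_index(["location", "age_group", "measure"])
        assert np.allclose(merged["value"], both.loc[merged.index], rtol=1e-12)

    def test_rates_refused(self, small_world):
        _, table, _ = small_world
        with pytest.raises(ContractError, match="rate"):
            aggregate(table.subset(metric="rate_per_100k"),
                      ["location", "year", "sex", "age_group"])

    def test_unknown_dimension_refused(self):
        table = _cells([("A", "male", 1.0)])
        with pytest.raises(ContractError):
            aggregate(table, ["location", "measure"])
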
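"""Database loading, validation and the analysis-subset filters."""

import pandas as pd
import pytest

from phytomacro.database import (MissingColumnsError, count_summary,
                                 filter_condition, phylum_analysis_sets,
                                 read_database)
from phytomacro.synthetic import generate_fixture_csv, tiny_design

HEADER = ("source,phylum,genus,species,strain,habitat,culture.system,"
          "growth.phase,nutrient.status,macromolecule,units,value,"
          "protein.method,replicate")


def _row(**kw):
    base = dict(source="S1", phylum="Chlorophyta", genus="Dunaliella",
                species="tertiolecta", strain="", habitat="marine",
                cs="batch", gp="exponential", ns="sufficient",
                pool="lipid", units="percent.dw", value="12.5",
                method="", rep="")
    base.update(kw)
    return (f"{base['source']},{base['phylum']},{base['genus']},{base['species']},"
            f"{base['strain']},{base['habitat']},{base['cs']},{base['gp']},"
            f"{base['ns']},{base['pool']},{base['units']},{base['value']},"
            f"{base['method']},{base['rep']}")


def _write(tmp_path, rows, name="db.csv"):
    path = tmp_path / name
    path.write_text("\n".join([HEADER] + rows) + "\n", encoding="utf-8")
    return path


def test_fixture_roundtrips_with_zero_rejections(tmp_path):
    design = tiny_design(seed=3)
    truth = generate_fixture_csv(design, tmp_path / "fix.csv")
    table, report = read_database(tmp_path / "fix.csv")
    assert report.n_rejected == 0
    assert len(table) == sum(truth.n_obs.values()) == design.n_obs_per_pool * len(design.pools)
    # truth sidecar written next to the fixture
    assert (tmp_path / "fix.truth.json").exists()


def test_empty_file_with_header_loads_zero_records(tmp_path):
    table, report = read_database(_write(tmp_path, []))
    assert len(table) == 0 and report.n_loaded == 0 and report.n_rejected == 0


@pytest.mark.parametrize(
    "bad_row, reason_fragment",
    [
        (_row(value="-3.0"), "negative"),
        (_row(value="not-a-number"), "unparseable"),
        (_row(value="105"), "> 100"),
        (_row(phylum="Klingonophyta"), "unknown phylum"),
        (_row(pool="protein", method=""), "protein"),
    ],
)
def test_invalid_rows_are_rejected_with_reasons(tmp_path, bad_row, reason_fragment):
    path = _write(tmp_path, [_row(), bad_row, _row(species="salina")])
    table, report = read_database(path)
    assert len(table) == 2
    assert report.n_rejected == 1
    assert report.n_loaded + report.n_rejected == 3
    assert reason_fragment in report.rejection_reasons[0][1]


def test_missing_mandatory_column_is_fatal(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("source,genus,species\nS1,Dunaliella,salina\n", encoding="utf-8")
    with pytest.raises(MissingColumnsError, match="phylum"):
        read_database(path)


def test_duplicate_rows_deduplicated_keep_first(tmp_path):
    path = _write(tmp_path, [_row(), _row(), _row(value="13.0")])
    table, report = read_database(path)
    assert len(table) == 2
    assert report.n_deduplicated == 1


def test_coastal_habitat_maps_to_marine(tmp_path):
    path = _write(tmp_path, [_row(habitat="estuarine"), _row(habitat="brackish")])
    table, _ = read_database(path)
    assert (table.df["habitat"] == "marine").all()


def test_active_growth_filter_keeps_only_qualifying_rows(tmp_path):
    rows = [
        _row(),                                   # qualifies
        _row(cs="turbidostat"),                   # qualifies
        _row(cs="semi.continuous"),               # qualifies
        _row(cs="chemostat"),                     # chemostat excluded
        _row(gp="stationary"),                    # wrong phase
        _row(gp="lag"),                           # wrong phase
        _row(ns="limited"),                       # not nutrient-sufficient
        _row(gp=""),                              # unknown phase excluded
        _row(ns=""),                              # unknown status excluded
    ]
    table, _ = read_database(_write(tmp_path, rows))
    active = filter_condition(table, "active_growth")
    assert len(active) == 3
    assert set(active.df["culture_system"]) == {"batch", "turbidostat", "semi_continuous"}

    stationary = filter_condition(table, "stationary")
    assert len(stationary) == 1

    only_lag, _ = read_database(_write(tmp_path, [_row(gp="lag")], "lag.csv"))
    assert len(filter_condition(only_lag, "active_growth")) == 0


def test_filtering_is_idempotent(tiny_table):
    table, _ = tiny_table
    once = filter_condition(table, "active_growth")
    twice = filter_condition(once, "active_growth")
    pd.testing.assert_frame_equal(once.df, twice.df)


def test_unknown_regime_rejected(tiny_table):
    with pytest.raises(ValueError, match="regime"):
        filter_condition(tiny_table[0], "lagging")


def test_phylum_sets_partition_consistently(tmp_path):
    rows = [_row(phylum="Euglenozoa", genus="Euglena", species="gracilis")] + \
           [_row(phylum="Rhodophyta", genus="Porphyridium", species="cruentum",
                 value=str(8.0 + i)) for i in range(2)] + \
           [_row(phylum="Bacillariophyta", genus="Thalassiosira", species=f"sp{i}")
            for i in range(10)]
    table, _ = read_database(_write(tmp_path, rows))
    comparison, grand = phylum_analysis_sets(table)
    assert len(comparison) == 10
    assert len(grand) == 13
    dropped = set(grand.df["phylum"]) - set(comparison.df["phylum"])
    assert dropped == {"Euglenozoa", "Rhodophyta"}


def test_phylum_sets_identical_without_excluded_phyla(tiny_table):
    table, _ = tiny_table
    comparison, grand = phylum_analysis_sets(table)
    pd.testing.assert_frame_equal(comparison.df, grand.df)


@pytest.mark.parametrize("seed", [0, 5])
def test_count_summary_totals_match_table_size(tmp_path, seed):
    generate_fixture_csv(tiny_design(seed=seed), tmp_path / "f.csv")
    table, _ = read_database(tmp_path / "f.csv")
    counts = count_summary(table)
    assert int(counts["n"].sum()) == len(table)
    assert set(counts["pool"]) == {"protein", "lipid", "carbohydrate"}
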
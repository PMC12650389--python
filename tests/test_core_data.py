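import numpy as np
import pandas as pd
import pytest

from krillstruct import core_data
from krillstruct.core_data import (
    ColumnError,
    Dialect,
    HaulRecord,
    haul_mean_lengths,
    quantize_length,
    read_hauls,
    read_lengths,
    summarize_inventory,
    write_hauls,
    write_lengths,
)


def _haul_rows(n, **overrides):
    base = dict(
        haul_id=[f"h{i}" for i in range(n)],
        vessel="V",
        year=2018,
        month=3,
        duration_h=2.0,
        latitude_deg=-62.0,
        longitude_deg=-58.0,
        catch_t=5.0,
        speed_mps=1.6,
        net_width_m=100.0,
        cluster_depth_m=150.0,
        cluster_temp_c=-0.5,
    )
    base.update(overrides)
    return pd.DataFrame(base)


class TestReadHauls:
    def test_invariant_violation_row_becomes_issue(self, tmp_path):
        df = _haul_rows(6)
        df.loc[3, "catch_t"] = -2.0
        p = tmp_path / "hauls.csv"
        df.to_csv(p, index=False)
        hauls, issues = read_hauls(p)
        assert len(hauls) == 5
        assert len(issues) == 1
        assert issues[0].record_id == "h3"
        assert "catch_t" in issues[0].rule

    def test_strict_mode_raises_on_bad_row(self, tmp_path):
        df = _haul_rows(3)
        df.loc[1, "duration_h"] = 0.0
        p = tmp_path / "hauls.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError):
            read_hauls(p, strict=True)

    def test_missing_column_is_hard_error_naming_it(self, tmp_path):
        df = _haul_rows(2).drop(columns=["speed_mps"])
        p = tmp_path / "hauls.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ColumnError, match="speed_mps"):
            read_hauls(p)

    def test_minutes_dialect_converts_duration(self, tmp_path):
        df = _haul_rows(1).rename(columns={"duration_h": "tow_min"})
        df["tow_min"] = 30.0
        p = tmp_path / "hauls.csv"
        df.to_csv(p, index=False)
        hauls, issues = read_hauls(
            p, Dialect(columns={"duration_h": "tow_min"}, units={"duration_h": "min"})
        )
        assert not issues
        assert hauls["duration_h"].iloc[0] == pytest.approx(0.5)
        assert hauls.attrs["provenance"]["unit_conversions"]["duration_h"] == pytest.approx(1 / 60)

    def test_round_trip_is_lossless(self, tmp_path, small_fleet):
        hauls, lengths, _ = small_fleet
        hp, lp = tmp_path / "h.csv", tmp_path / "l.csv"
        write_hauls(hauls, hp)
        write_lengths(lengths, lp)
        h2, hi = read_hauls(hp)
        l2, li = read_lengths(lp)
        assert not hi and not li
        pd.testing.assert_frame_equal(hauls.reset_index(drop=True), h2, check_dtype=False)
        np.testing.assert_allclose(lengths["length_mm"], l2["length_mm"])


class TestReadLengths:
    def test_quantized_to_tenth_mm(self, tmp_path):
        p = tmp_path / "l.csv"
        pd.DataFrame({"haul_id": ["h0"], "length_mm": [44.8349]}).to_csv(p, index=False)
        df, _ = read_lengths(p)
        assert df["length_mm"].iloc[0] == pytest.approx(44.8)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "l.csv"
        pd.DataFrame({"haul_id": [], "length_mm": []}).to_csv(p, index=False)
        with pytest.warns(UserWarning):
            df, _ = read_lengths(p)
        assert len(df) == 0

    def test_nonpositive_length_is_issue(self, tmp_path):
        p = tmp_path / "l.csv"
        pd.DataFrame({"haul_id": ["a", "b"], "length_mm": [-1.0, 40.0]}).to_csv(p, index=False)
        df, issues = read_lengths(p)
        assert len(df) == 1 and len(issues) == 1


class TestInventory:
    def test_full_design_accounting(self, paper_fleet):
        hauls, lengths, _ = paper_fleet
        rep = summarize_inventory(hauls, lengths)
        assert rep.n_hauls == 4491
        assert rep.n_lengths == 162_200
        assert rep.n_measured_hauls == 811
        per_year = rep.per_year_counts.set_index("year")
        assert per_year.loc[2016, "hauls"] == 1084
        assert 2020 not in per_year.index

    def test_length_conservation(self, small_fleet):
        hauls, lengths, _ = small_fleet
        rep = summarize_inventory(hauls, lengths)
        assert rep.per_year_counts["lengths"].sum() == rep.n_lengths == len(lengths)

    def test_orphan_haul_ids_reported_not_dropped(self, small_fleet):
        hauls, lengths, _ = small_fleet
        extra = pd.concat(
            [lengths, pd.DataFrame({"haul_id": ["ghost"], "length_mm": [40.0]})],
            ignore_index=True,
        )
        rep = summarize_inventory(hauls, extra)
        assert any("unknown haul" in i.rule for i in rep.issues)


class TestHaulMeans:
    def test_simple_means(self):
        hauls = _haul_rows(2)
        lengths = pd.DataFrame(
            {"haul_id": ["h0", "h0", "h1"], "length_mm": [40.0, 42.0, 39.4]}
        )
        out = haul_mean_lengths(hauls, lengths).set_index("haul_id")
        assert out.loc["h0", "mean_length_mm"] == pytest.approx(41.0)
        assert out.loc["h1", "mean_length_mm"] == pytest.approx(39.4)
        assert out.loc["h0", "n_measured"] == 2

    def test_mean_close_to_generating_value(self):
        rng = np.random.default_rng(42)
        draws = quantize_length(rng.normal(40.0, 6.0, 200))
        hauls = _haul_rows(1)
        lengths = pd.DataFrame({"haul_id": "h0", "length_mm": draws})
        m = haul_mean_lengths(hauls, lengths)["mean_length_mm"].iloc[0]
        assert abs(m - 40.0) < 3 * 6.0 / np.sqrt(200)


def test_haul_record_violation_list():
    rec = HaulRecord("x", "V", 2018, 13, -1.0, -62.0, -58.0, 1.0, 1.5, 100.0, 150.0, 0.0)
    rules = rec.violations()
    assert any("month" in r for r in rules) and any("duration" in r for r in rules)
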
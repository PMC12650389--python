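import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from krillstruct.core_data import quantize_length
from krillstruct.population_structure import (
    CANDY_KAWAGUCHI,
    AgeClassScheme,
    age_composition,
    annual_summary,
    anova_tukey,
    assign_age,
    length_frequency,
)


def _hauls_for(years):
    return pd.DataFrame(
        {
            "haul_id": [f"h{y}" for y in years],
            "year": years,
            "latitude_deg": -62.0,
            "longitude_deg": -58.0,
        }
    )


class TestAssignAge:
    @pytest.mark.parametrize(
        "length,label",
        [
            (44.83, "Age2+"),   # the 2016 median falls in 40–47.9
            (26.0, "Age1+"),    # lower edge inclusive
            (39.95, "Age1+"),   # just under the 40 boundary
            (40.0, "Age2+"),
            (55.0, "Age6+"),
            (70.0, "Age6+"),    # scheme upper bound inclusive
            (12.5, "Age0"),
        ],
    )
    def test_published_bins(self, length, label):
        assert assign_age(length) == label

    def test_out_of_range_strict_raises(self):
        with pytest.raises(ValueError):
            assign_age(70.1)

    def test_out_of_range_clamps_when_lenient(self):
        assert assign_age(75.0, strict=False) == "Age6+"

    @given(st.floats(0.1, 70.0))
    @settings(max_examples=200, deadline=None)
    def test_every_length_maps_to_exactly_one_class(self, length):
        label = assign_age(quantize_length(max(length, 0.1)))
        assert label in CANDY_KAWAGUCHI.labels

    def test_non_contiguous_scheme_rejected(self):
        with pytest.raises(ValueError):
            AgeClassScheme(bins=(("a", 0.0, 10.0), ("b", 11.0, 20.0)))


class TestAgeComposition:
    def test_single_class(self):
        lengths = pd.DataFrame({"haul_id": "h", "length_mm": [30.0] * 5})
        props = age_composition(lengths, by="overall")
        assert props["Age1+"].iloc[0] == pytest.approx(1.0)

    def test_mixture_recovered_within_binomial_error(self):
        rng = np.random.default_rng(12)
        n = 10_000
        frac1 = 0.4
        a = rng.uniform(26.0, 39.9, int(n * frac1))
        b = rng.uniform(40.0, 47.9, n - int(n * frac1))
        lengths = pd.DataFrame({"haul_id": "h", "length_mm": quantize_length(np.concatenate([a, b]))})
        props = age_composition(lengths, by="overall").iloc[0]
        se = np.sqrt(frac1 * (1 - frac1) / n)
        assert abs(props["Age1+"] - frac1) < 3 * se
        assert abs(props["Age2+"] - (1 - frac1)) < 3 * se
        assert props["juvenile_share"] == pytest.approx(1.0)

    def test_group_proportions_sum_to_one(self, small_fleet):
        hauls, lengths, _ = small_fleet
        props = age_composition(lengths, by="year", hauls=hauls)
        sums = props[CANDY_KAWAGUCHI.labels].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


class TestLengthFrequency:
    def test_half_open_one_mm_bins(self):
        lengths = pd.DataFrame({"haul_id": "h", "length_mm": [40.0, 40.9, 41.0]})
        lf = length_frequency(lengths, by="overall").set_index("bin_low_mm")["count"]
        assert lf.loc[40.0] == 2
        assert lf.loc[41.0] == 1

    def test_counts_conserve_n(self, small_fleet):
        hauls, lengths, _ = small_fleet
        lf = length_frequency(lengths, by="year", hauls=hauls)
        assert lf["count"].sum() == len(lengths)

    def test_default_scenario_unimodal_per_year(self, paper_fleet):
        hauls, lengths, _ = paper_fleet
        lf = length_frequency(lengths, by="year", hauls=hauls)
        for year, grp in lf.groupby("group"):
            counts = grp.sort_values("bin_low_mm")["count"].to_numpy(dtype=float)
            # smooth tiny sampling jitter before counting interior peaks
            kernel = np.ones(5) / 5
            sm = np.convolve(counts, kernel, mode="same")
            peaks = (
                (sm[1:-1] > sm[:-2]) & (sm[1:-1] >= sm[2:]) & (sm[1:-1] > 0.25 * sm.max())
            ).sum()
            assert peaks <= 2, f"year {year} not unimodal"


class TestAnnualSummary:
    def test_small_sample_moments(self):
        lengths = pd.DataFrame({"haul_id": "h2018", "length_mm": [40.0, 40.0, 50.0]})
        row = annual_summary(lengths, _hauls_for([2018])).iloc[0]
        assert row["mode"] == pytest.approx(40.0)
        assert row["mean"] == pytest.approx(130.0 / 3.0)
        assert row["sd"] == pytest.approx(np.std([40, 40, 50], ddof=1))

    def test_normal_draws_have_near_zero_shape_moments(self):
        rng = np.random.default_rng(99)
        n = 100_000
        lengths = pd.DataFrame(
            {"haul_id": "h2018", "length_mm": quantize_length(rng.normal(40, 6, n))}
        )
        row = annual_summary(lengths, _hauls_for([2018])).iloc[0]
        se_skew = np.sqrt(6.0 / n)
        se_kurt = np.sqrt(24.0 / n)
        assert abs(row["skew"]) < 3 * se_skew + 0.01
        assert abs(row["kurt"]) < 3 * se_kurt + 0.02

    def test_constant_sample_flagged(self):
        lengths = pd.DataFrame({"haul_id": "h2018", "length_mm": [40.0, 40.0, 40.0]})
        row = annual_summary(lengths, _hauls_for([2018])).iloc[0]
        assert row["sd"] == 0.0
        assert "undefined" in row["flag"]
        assert np.isnan(row["skew"])

    def test_order_statistics_ordered(self, small_fleet):
        hauls, lengths, _ = small_fleet
        for _, r in annual_summary(lengths, hauls).iterrows():
            assert r["min"] <= r["q25"] <= r["median"] <= r["q75"] <= r["max"]


class TestAnovaTukey:
    def _two_groups(self, x1, x2):
        hauls = _hauls_for([2016, 2017])
        lengths = pd.DataFrame(
            {
                "haul_id": ["h2016"] * len(x1) + ["h2017"] * len(x2),
                "length_mm": np.concatenate([x1, x2]),
            }
        )
        return lengths, hauls

    def test_identical_groups_zero_diff(self):
        x = np.array([40.0, 41.0, 42.0, 43.0])
        lengths, hauls = self._two_groups(x, x)
        _, pairs = anova_tukey(lengths, hauls)
        assert pairs["diff"].iloc[0] == pytest.approx(0.0)
        assert pairs["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_diff_equals_difference_of_group_means(self):
        rng = np.random.default_rng(4)
        # sized and located like the first and second survey seasons
        x16 = rng.normal(44.16, 6.0, 46_200)
        x17 = rng.normal(39.62, 6.0, 19_600)
        lengths, hauls = self._two_groups(x16, x17)
        _, pairs = anova_tukey(lengths, hauls)
        row = pairs.iloc[0]
        assert (row["group_a"], row["group_b"]) == (2016, 2017)
        assert row["diff"] == pytest.approx(x16.mean() - x17.mean(), abs=1e-9)
        assert abs(row["diff"] - 4.54) < 0.15
        assert row["lwr"] < row["diff"] < row["upr"]

    def test_pairwise_diffs_antisymmetric_in_convention(self, small_fleet):
        hauls, lengths, _ = small_fleet
        anova, pairs = anova_tukey(lengths, hauls)
        means = (
            lengths.assign(year=lengths["haul_id"].map(hauls.set_index("haul_id")["year"]))
            .groupby("year")["length_mm"]
            .mean()
        )
        for _, r in pairs.iterrows():
            assert r["diff"] == pytest.approx(
                means[r["group_a"]] - means[r["group_b"]], abs=1e-9
            )
        assert anova.loc[0, "p"] <= 1.0

    def test_single_group_rejected(self):
        lengths = pd.DataFrame({"haul_id": "h2016", "length_mm": [40.0, 41.0]})
        with pytest.raises(ValueError):
            anova_tukey(lengths, _hauls_for([2016]))
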
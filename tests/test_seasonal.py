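"""Duration binning, composites, extremes and geographic regression."""

import numpy as np
import pandas as pd
import pytest

from stemgrowth.seasonal import (
    bin_by_duration,
    composite_traits,
    extremes_table,
    geographic_regression,
    within_bin_correlation,
)
from stemgrowth.simulate import simulate_binned_population, simulate_geographic_timing


def table_of(durations, **cols):
    df = pd.DataFrame({"plant_id": [f"p{i}" for i in range(len(durations))],
                       "duration": durations})
    for k, v in cols.items():
        df[k] = v
    return df


class TestBinning:
    def test_below_min_count_discarded(self):
        assert bin_by_duration(table_of([45.0] * 9), 10, 10) == []

    def test_threshold_boundary_retained(self):
        bins = bin_by_duration(table_of([45.0] * 10), 10, 10)
        assert len(bins) == 1
        assert (bins[0].lo, bins[0].hi, bins[0].n) == (40.0, 50.0, 10)

    def test_memberships_match_floor_division_oracle(self):
        rng = np.random.default_rng(17)
        dur = rng.normal(75, 20, 500)
        df = table_of(dur)
        bins = bin_by_duration(df, 10, 10)
        oracle = df.groupby(np.floor(df["duration"] / 10).astype(int))["plant_id"]
        oracle = {k * 10.0: set(v) for k, v in oracle.agg(set).items() if len(v) >= 10}
        assert {b.lo: set(b.plant_ids) for b in bins} == oracle

    def test_partition_no_plant_in_two_bins(self):
        rng = np.random.default_rng(23)
        df = table_of(rng.uniform(30, 130, 400))
        bins = bin_by_duration(df, 10, 1)  # min_count 1: every plant retained
        ids = [p for b in bins for p in b.plant_ids]
        assert len(ids) == len(set(ids)) == 400

    def test_empty_table(self):
        assert bin_by_duration(table_of([]), 10, 10) == []


class TestWithinBinCorrelation:
    def test_exact_negative_line(self):
        df = table_of([45.0] * 12, start_logg=np.arange(12.0))
        df["dw"] = -2 * df["start_logg"] + 400
        bins = bin_by_duration(df, 10, 10)
        out = within_bin_correlation(bins, df)
        assert out.loc[0, "r"] == pytest.approx(-1.0)
        assert bool(out.loc[0, "significant"])

    def test_constant_x_flagged_undefined(self):
        df = table_of([45.0] * 12, start_logg=np.ones(12), dw=np.arange(12.0))
        out = within_bin_correlation(bin_by_duration(df, 10, 10), df)
        assert np.isnan(out.loc[0, "r"]) and out.loc[0, "note"] == "zero variance"

    def test_planted_sign_pattern(self):
        tab = simulate_binned_population(n=600, seed=31)
        bins = bin_by_duration(tab, 10, 10)
        out = within_bin_correlation(bins, tab)
        low = out[out["bin_hi"] <= 110]
        high = out[out["bin_lo"] >= 110]
        assert (low["r"] < 0).all()
        assert low["significant"].mean() >= 0.8
        assert (~high["significant"]).mean() >= 2 / 3

    def test_binning_controls_rate_duration_confound(self):
        # MaxGR depends only on Duration: within bins, r(StartLogG, MaxGR) ~ 0
        tab = simulate_binned_population(n=2000, seed=37)
        bins = bin_by_duration(tab, 10, 10)
        out = within_bin_correlation(bins, tab, y_trait="max_gr")
        assert abs(out["r"].mean()) < 0.05


class TestComposites:
    def test_hand_checkable_pair(self):
        df = table_of([50.0, 100.0], max_gr=[2.0, 1.0])
        out = composite_traits(df)
        assert list(out["maxgr_duration_ratio"]) == [0.04, 0.01]
        assert list(out["rank_sum"]) == [3.0, 3.0]

    def test_ties_get_average_ranks(self):
        df = table_of([60.0] * 4, max_gr=[2.0] * 4)
        out = composite_traits(df)
        assert (out["rank_sum"] == 5.0).all()

    def test_rank_sums_match_sort_oracle(self):
        rng = np.random.default_rng(41)
        df = table_of(rng.uniform(40, 120, 50), max_gr=rng.uniform(0.5, 4, 50))
        out = composite_traits(df)
        oracle = (pd.Series(df["max_gr"]).rank() + pd.Series(df["duration"]).rank())
        assert np.allclose(out["rank_sum"], oracle)

    def test_nonpositive_duration_excluded(self):
        df = table_of([50.0, 0.0], max_gr=[1.0, 1.0])
        assert len(composite_traits(df)) == 1


class TestExtremes:
    @staticmethod
    def toy_population():
        # 40 plants, two species of 20; species A holds the top-2 MaxGR
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.uniform(1, 2, 18), [9.0, 9.5],
                               rng.uniform(1, 2, 20)])
        return pd.DataFrame({
            "plant_id": [f"p{i}" for i in range(40)],
            "species_group": ["A"] * 20 + ["B"] * 20,
            "max_gr": vals,
        })

    def test_toy_population_matches_enumeration(self):
        out = extremes_table(self.toy_population(), ["max_gr"], 0.05)
        cell = out.set_index(["species_group", "trait", "tail"])
        assert cell.loc[("A", "max_gr", "high"), "percent"] == 10.0
        assert cell.loc[("B", "max_gr", "high"), "percent"] == 0.0

    def test_tail_counts_sum_to_tail_size(self):
        out = extremes_table(self.toy_population(), ["max_gr"], 0.05)
        k = round(0.05 * 40)
        for tail in ("high", "low"):
            assert out[out["tail"] == tail]["count"].sum() == k

    def test_single_species_percent_is_k_over_n(self):
        df = self.toy_population().assign(species_group="only")
        out = extremes_table(df, ["max_gr"], 0.05)
        assert (out["percent"] == 100.0 * 2 / 40).all()

    def test_fraction_domain(self):
        with pytest.raises(ValueError):
            extremes_table(self.toy_population(), ["max_gr"], 0.6)

    def test_planted_species_shift_dominates_high_tail(self):
        rng = np.random.default_rng(43)
        df = pd.DataFrame({
            "plant_id": [f"p{i}" for i in range(300)],
            "species_group": ["fast"] * 60 + ["slow"] * 240,
            "max_gr": np.concatenate([rng.normal(3, 0.3, 60), rng.normal(1.5, 0.3, 240)]),
        })
        out = extremes_table(df, ["max_gr"], 0.05).set_index(
            ["species_group", "trait", "tail"])
        assert (out.loc[("fast", "max_gr", "high"), "percent"]
                > out.loc[("slow", "max_gr", "high"), "percent"])


class TestGeographicRegression:
    def test_exact_linear_latitude(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"lat": rng.uniform(25, 45, 30),
                           "lon": rng.uniform(100, 140, 30),
                           "alt_m": rng.uniform(0, 1000, 30)})
        df["day_at_15cm"] = 2 * df["lat"]
        res = geographic_regression(df, "day_at_15cm")
        row = res["table"].set_index("predictor").loc["lat"]
        assert row["slope"] == pytest.approx(2.0, rel=1e-9)
        assert row["adj_r2"] == pytest.approx(1.0, abs=1e-9)
        assert res["selected"] == "lat"

    def test_null_response_selects_none(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"lat": rng.uniform(25, 45, 60),
                           "lon": rng.uniform(100, 140, 60),
                           "alt_m": rng.uniform(0, 1000, 60),
                           "day_at_15cm": rng.normal(120, 5, 60)})
        res = geographic_regression(df, "day_at_15cm")
        assert res["selected"] == "none"

    def test_planted_latitude_slope_recovered(self):
        df = simulate_geographic_timing(n=200, lat_slope=1.2, noise_sd=3.0, seed=5)
        res = geographic_regression(df, "day_at_15cm")
        row = res["table"].set_index("predictor").loc["lat"]
        # closed-form OLS oracle on the generated design
        x, y = df["lat"].to_numpy(), df["day_at_15cm"].to_numpy()
        slope_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert row["slope"] == pytest.approx(slope_oracle, rel=1e-9)
        assert abs(row["slope"] - 1.2) < 0.2
        assert res["selected"] == "lat"

    def test_constant_predictor_non_estimable(self):
        df = pd.DataFrame({"lat": [30.0] * 10, "lon": np.arange(10.0),
                           "alt_m": np.arange(10.0),
                           "day_at_15cm": np.arange(10.0)})
        res = geographic_regression(df, "day_at_15cm", include_lat_alt2=False)
        row = res["table"].set_index("predictor").loc["lat"]
        assert row["note"] == "non-estimable" and np.isnan(row["p"])
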
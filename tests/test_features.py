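"""Feature construction: shares, filters, exposure bins, normals, obligations."""

import numpy as np
import pandas as pd
import pytest

from agtarget.features import (
    SeasonSpec,
    TEMP_BIN_EDGES,
    assemble_design_matrix,
    cropland_filter,
    normals_and_deviations,
    obligation_features,
    practice_shares,
    precipitation_totals,
    temperature_exposure,
)


def weather_frame(dates, tmax, tmin, prcp=None, county="C01"):
    dates = pd.to_datetime(dates)
    n = len(dates)
    return pd.DataFrame(
        {
            "county_id": county,
            "date": dates,
            "tmax_c": np.broadcast_to(np.asarray(tmax, dtype=float), (n,)).copy(),
            "tmin_c": np.broadcast_to(np.asarray(tmin, dtype=float), (n,)).copy(),
            "prcp_mm": np.zeros(n) if prcp is None else np.asarray(prcp, dtype=float),
        }
    )


class TestPracticeShares:
    @pytest.fixture
    def census(self):
        return pd.DataFrame(
            {
                "county_id": ["C01", "C01", "C02", "C02"],
                "wave_year": [2012, 2017, 2012, 2017],
                "cropland_acres": [100.0, 120.0, 200.0, 180.0],
                "acres_cover_crop": [10.0, 12.0, np.nan, 20.0],
                "acres_no_till": [40.0, 60.0, 50.0, 50.0],
                "acres_conservation_till": [20.0, 12.0, 30.0, 40.0],
            }
        )

    def test_reduced_till_combines_no_till_and_conservation(self, census):
        shares = practice_shares(census)
        row = shares[
            (shares.county_id == "C02")
            & (shares.practice == "reduced_till")
            & (shares.wave_year == 2012)
        ].iloc[0]
        assert row["acres"] == 80.0
        assert row["share"] == pytest.approx(80.0 / 200.0)

    def test_max_cropland_is_shared_denominator(self, census):
        shares = practice_shares(census)
        c1 = shares[shares.county_id == "C01"]
        assert (c1["cropland_max"] == 120.0).all()
        early = c1[(c1.practice == "cover_crop") & (c1.wave_year == 2012)].iloc[0]
        assert early["share"] == pytest.approx(10.0 / 120.0)

    def test_missing_cells_flagged(self, census):
        shares = practice_shares(census)
        row = shares[
            (shares.county_id == "C02")
            & (shares.practice == "cover_crop")
            & (shares.wave_year == 2012)
        ].iloc[0]
        assert row["missing"] and np.isnan(row["share"])

    def test_nonpositive_cropland_excluded(self, census, caplog):
        census.loc[census.county_id == "C02", "cropland_acres"] = 0.0
        with caplog.at_level("WARNING"):
            shares = practice_shares(census)
        assert "C02" not in set(shares["county_id"])
        assert "non-positive cropland" in caplog.text


class TestCroplandFilter:
    def test_hundred_distinct_ratios_keep_ninety(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "county_id": [f"C{i}" for i in range(100)],
                "cropland_max": rng.uniform(10, 100, 100),
                "land_area_acres": 100.0,
            }
        )
        kept, drop_log = cropland_filter(df)
        assert len(kept) == 90
        assert len(drop_log) == 10

    def test_matches_brute_force_quantile(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            ratios = rng.uniform(0.01, 0.9, size=73)
            df = pd.DataFrame(
                {
                    "county_id": [f"C{i}" for i in range(73)],
                    "cropland_max": ratios,
                    "land_area_acres": 1.0,
                }
            )
            kept, _ = cropland_filter(df)
            cutoff = np.quantile(ratios, 0.10)
            brute = {i for i, r in enumerate(ratios) if r > cutoff}
            assert set(kept) == brute

    def test_identical_ratios_all_dropped_with_flag(self, caplog):
        df = pd.DataFrame(
            {
                "county_id": [f"C{i}" for i in range(20)],
                "cropland_max": 50.0,
                "land_area_acres": 100.0,
            }
        )
        with caplog.at_level("WARNING"):
            kept, drop_log = cropland_filter(df)
        assert len(kept) == 0
        assert "pathological" in caplog.text

    def test_above_median_always_kept(self):
        rng = np.random.default_rng(1)
        ratios = rng.uniform(0.05, 0.8, size=50)
        df = pd.DataFrame(
            {
                "county_id": [f"C{i}" for i in range(50)],
                "cropland_max": ratios,
                "land_area_acres": 1.0,
            }
        )
        kept, _ = cropland_filter(df)
        assert set(np.flatnonzero(ratios > np.median(ratios))) <= set(kept)

    def test_small_input_skips_filter(self, caplog):
        df = pd.DataFrame(
            {
                "county_id": ["C1", "C2"],
                "cropland_max": [1.0, 2.0],
                "land_area_acres": [10.0, 10.0],
            }
        )
        with caplog.at_level("WARNING"):
            kept, _ = cropland_filter(df)
        assert len(kept) == 2
        assert "skipped" in caplog.text


class TestTemperatureExposure:
    def test_cold_preseason_block(self):
        dates = pd.date_range("2015-01-01", "2015-02-28")
        w = weather_frame(dates, tmax=-3.0, tmin=-7.0)  # mean -5C every day
        out = temperature_exposure(w).set_index(["county_id", "year"])
        row = out.loc[("C01", 2015)]
        assert row["pre_tlt0"] == 59
        assert row[[c for c in out.columns if c.startswith(("grow", "post"))]].sum() == 0

    def test_exact_30_is_extreme_heat(self):
        w = weather_frame(["2015-07-01"], tmax=35.0, tmin=25.0)  # mean exactly 30
        out = temperature_exposure(w)
        assert out.loc[0, "grow_tge30"] == 1
        assert out.loc[0, "grow_t20_30"] == 0

    def test_matches_per_day_brute_force(self):
        rng = np.random.default_rng(3)
        dates = pd.date_range("2014-01-01", "2014-12-31")
        tmean = rng.uniform(-15, 40, len(dates))
        half = rng.uniform(1, 8, len(dates))
        w = weather_frame(dates, tmean + half, tmean - half)
        out = temperature_exposure(w).set_index(["county_id", "year"]).loc[("C01", 2014)]

        spec = SeasonSpec()
        brute = {}
        for d, t in zip(dates, tmean):
            season = spec.assign(pd.Series([d]))[0]
            edges = (-np.inf, *TEMP_BIN_EDGES, np.inf)
            labels = ("tlt0", "t0_10", "t10_20", "t20_30", "tge30")
            for lo, hi, lab in zip(edges[:-1], edges[1:], labels):
                if lo <= t < hi:
                    key = f"{season}_{lab}"
                    brute[key] = brute.get(key, 0) + 1
        for key, count in brute.items():
            assert out[key] == count, key

    def test_season_counts_conserve_calendar(self):
        for year, n_days in ((2014, 365), (2016, 366)):
            dates = pd.date_range(f"{year}-01-01", f"{year}-12-31")
            w = weather_frame(dates, 15.0, 5.0)
            out = temperature_exposure(w)
            bins = [c for c in out.columns if c not in ("county_id", "year", "missing_days")]
            assert out[bins].to_numpy().sum() == n_days

    def test_missing_day_tallied_not_imputed(self):
        dates = pd.date_range("2015-06-01", periods=3)
        w = weather_frame(dates, 20.0, 10.0)
        w.loc[1, ["tmax_c", "tmin_c"]] = np.nan
        out = temperature_exposure(w)
        assert out.loc[0, "missing_days"] == 1
        assert out.loc[0, "grow_t10_20"] == 2

    def test_tmax_basis_switch(self):
        w = weather_frame(["2015-07-01"], tmax=32.0, tmin=20.0)  # mean 26, tmax 32
        mean_based = temperature_exposure(w, basis="mean")
        tmax_based = temperature_exposure(w, basis="tmax")
        assert mean_based.loc[0, "grow_t20_30"] == 1
        assert tmax_based.loc[0, "grow_tge30"] == 1


class TestPrecipitationTotals:
    def test_uniform_non_leap_year(self):
        dates = pd.date_range("2015-01-01", "2015-12-31")
        w = weather_frame(dates, 15.0, 5.0, prcp=np.ones(len(dates)))
        out = precipitation_totals(w).iloc[0]
        assert out["pre_prcp_mm"] == 59
        assert out["grow_prcp_mm"] == 184
        assert out["post_prcp_mm"] == 122

    def test_all_zero_series(self):
        dates = pd.date_range("2015-01-01", "2015-12-31")
        out = precipitation_totals(weather_frame(dates, 15.0, 5.0)).iloc[0]
        assert (out[["pre_prcp_mm", "grow_prcp_mm", "post_prcp_mm"]] == 0).all()

    def test_september_first_is_post_season(self):
        w = weather_frame(["2015-09-01"], 25.0, 15.0, prcp=[10.0])
        out = precipitation_totals(w).iloc[0]
        assert out["post_prcp_mm"] == 10.0


class TestNormalsAndDeviations:
    def annual_frame(self, values_by_year, county="C01"):
        return pd.DataFrame(
            {
                "county_id": county,
                "year": list(values_by_year),
                "grow_prcp_mm": [values_by_year[y] for y in values_by_year],
            }
        )

    def test_constant_series_zero_deviation(self):
        annual = self.annual_frame({y: 500.0 for y in range(1992, 2018)})
        out = normals_and_deviations(annual, reference_year=2017).iloc[0]
        assert out["grow_prcp_mm_normal"] == 500.0
        assert out["grow_prcp_mm_dev"] == 0.0

    def test_shifted_window_deviation_equals_shift(self):
        vals = {y: 500.0 for y in range(1997, 2013)}
        vals.update({y: 530.0 for y in range(2013, 2018)})
        # normal window 1997-2016 contains 16 years at 500 and 4 at 530
        annual = self.annual_frame(vals)
        out = normals_and_deviations(annual, reference_year=2017).iloc[0]
        normal = (16 * 500 + 4 * 530) / 20
        assert out["grow_prcp_mm_normal"] == pytest.approx(normal)
        assert out["grow_prcp_mm_dev"] == pytest.approx(530.0 - normal)

    def test_trend_matches_brute_force(self):
        rng = np.random.default_rng(5)
        vals = {y: 400 + 3 * (y - 1990) + rng.normal(0, 20) for y in range(1990, 2018)}
        annual = self.annual_frame(vals)
        out = normals_and_deviations(annual, reference_year=2017).iloc[0]
        normal = np.mean([vals[y] for y in range(1997, 2017)])
        dev = np.mean([vals[y] - normal for y in range(2013, 2018)])
        assert out["grow_prcp_mm_normal"] == pytest.approx(normal)
        assert out["grow_prcp_mm_dev"] == pytest.approx(dev)

    def test_insufficient_history_flagged_missing(self, caplog):
        annual = self.annual_frame({y: 500.0 for y in range(2010, 2018)})
        with caplog.at_level("WARNING"):
            out = normals_and_deviations(annual, reference_year=2017)
        assert len(out) == 0 or out["grow_prcp_mm_normal"].isna().all()
        assert "normal window" in caplog.text


class TestObligationFeatures:
    def test_two_year_mean_per_acre(self):
        obligations = pd.DataFrame(
            {
                "county_id": ["C01", "C01"],
                "year": [2014, 2015],
                "measure": ["all_programs", "all_programs"],
                "dollars": [100.0, 200.0],
            }
        )
        cropland = pd.Series({"C01": 1000.0})
        out = obligation_features(obligations, cropland, (2014, 2015)).iloc[0]
        assert out["obl_all_programs_per_acre"] == pytest.approx(0.15)
        assert out["obl_all_programs_n_years"] == 2

    def test_missing_measure_stays_missing(self):
        obligations = pd.DataFrame(
            {
                "county_id": ["C01"],
                "year": [2014],
                "measure": ["all_programs"],
                "dollars": [100.0],
            }
        )
        cropland = pd.Series({"C01": 1000.0, "C02": 500.0})
        out = obligation_features(obligations, cropland, (2014, 2017)).set_index("county_id")
        assert np.isnan(out.loc["C02", "obl_all_programs_per_acre"])
        assert out.loc["C01", "obl_all_programs_n_years"] == 1

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(7)
        rows = []
        for cid in ["C01", "C02", "C03"]:
            for year in range(2014, 2018):
                for measure in ["all_programs", "cover_crop"]:
                    if rng.random() < 0.8:
                        rows.append((cid, year, measure, rng.uniform(0, 5000)))
        obligations = pd.DataFrame(rows, columns=["county_id", "year", "measure", "dollars"])
        cropland = pd.Series({"C01": 900.0, "C02": 1100.0, "C03": 400.0})
        out = obligation_features(obligations, cropland, (2014, 2017)).set_index("county_id")
        for cid in cropland.index:
            for measure in ["all_programs", "cover_crop"]:
                cells = [
                    d / cropland[cid]
                    for c, y, m, d in rows
                    if c == cid and m == measure and 2014 <= y <= 2017
                ]
                expected = np.mean(cells) if cells else np.nan
                got = out.loc[cid, f"obl_{measure}_per_acre"]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected)


class TestAssembleDesignMatrix:
    @pytest.fixture
    def blocks(self):
        shares = pd.DataFrame(
            {
                "county_id": ["C01", "C01", "C02", "C02", "C03", "C03"],
                "wave_year": [2012, 2017] * 3,
                "practice": "cover_crop",
                "acres": [100.0, 120.0, 0.0, 50.0, 30.0, 45.0],
                "cropland_max": [400.0, 400.0, 300.0, 300.0, 200.0, 200.0],
                "share": [0.25, 0.30, 0.0, 50 / 300, 0.15, 0.225],
                "missing": False,
            }
        )
        climate = pd.DataFrame({"county_id": ["C01", "C02", "C03"], "grow_prcp_mm_normal": [400.0, 500.0, 450.0]})
        soils = pd.DataFrame({"county_id": ["C01", "C02", "C03"], "soil_1": [0.1, -0.2, 0.5]})
        obligations = pd.DataFrame(
            {"county_id": ["C01", "C02", "C03"], "obl_all_programs_per_acre": [1.0, 2.0, np.nan]}
        )
        regions = pd.DataFrame(
            {"county_id": ["C01", "C02", "C03"], "region_code": ["heartland", "fruitful_rim", "heartland"]}
        )
        return shares, climate, soils, obligations, regions

    def test_lagged_columns_and_target(self, blocks):
        X, manifest = assemble_design_matrix(*blocks, practice="cover_crop", wave_pair=(2012, 2017))
        assert X.loc["C01", "lagged_share"] == pytest.approx(0.25)
        assert X.loc["C01", "log_lagged_acres"] == pytest.approx(np.log(100.0))
        assert X.loc["C01", "target_log_ratio"] == pytest.approx(np.log(1.2))
        assert "region_heartland" in X.columns

    def test_zero_lagged_acres_dropped_and_logged(self, blocks):
        X, manifest = assemble_design_matrix(*blocks, practice="cover_crop", wave_pair=(2012, 2017))
        assert "C02" not in X.index
        assert "C02" in manifest["dropped"]["nonpositive_lagged_acres"]
        assert manifest["n_rows"] == 2

    def test_manifest_covers_all_feature_columns(self, blocks, tmp_path):
        path = tmp_path / "manifest.json"
        X, manifest = assemble_design_matrix(
            *blocks, practice="cover_crop", wave_pair=(2012, 2017), manifest_path=path
        )
        assert set(manifest["feature_columns"]) == set(X.columns) - {"target_log_ratio"}
        assert path.exists()

    def test_disjoint_keys_raise(self, blocks):
        shares, climate, soils, obligations, regions = blocks
        climate = climate.assign(county_id=["X1", "X2", "X3"])
        with pytest.raises(KeyError, match="climate"):
            assemble_design_matrix(
                shares, climate, soils, obligations, regions,
                practice="cover_crop", wave_pair=(2012, 2017),
            )
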
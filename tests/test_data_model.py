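"""Detection-event I/O, independence filtering, occasion binning and the
covariate screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camtrap_cooccur import data_model as dm

from conftest import make_events, make_stations


class TestReadEvents:
    def test_well_formed_csv_parses_sorted(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(
            "station_id,species,timestamp\n"
            "S1,red_deer,2022-06-03T10:00:00\n"
            "S1,cattle,2022-06-01T08:00:00\n"
            "S2,red_deer,2022-06-02T09:30:00\n"
        )
        ev = dm.read_events(p)
        assert len(ev) == 3
        assert ev["timestamp"].is_monotonic_increasing
        assert list(ev["species"])[0] == "cattle"

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text("station_id,species,timestamp\n")
        assert len(dm.read_events(p)) == 0

    def test_malformed_timestamp_names_row(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(
            "station_id,species,timestamp\n"
            "S1,red_deer,2022-06-03T10:00:00\n"
            "S1,red_deer,not-a-time\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            dm.read_events(p)

    def test_timestamp_outside_deployment_names_row_and_station(self, tmp_path):
        stations = make_stations(n=1, survey_days=30, start="2022-06-01")
        p = tmp_path / "ev.csv"
        p.write_text(
            "station_id,species,timestamp\nS1,red_deer,2022-08-15T10:00:00\n"
        )
        with pytest.raises(ValueError, match="row 2.*S1"):
            dm.read_events(p, stations)

    def test_unknown_station_rejected(self, tmp_path):
        stations = make_stations(n=1)
        p = tmp_path / "ev.csv"
        p.write_text(
            "station_id,species,timestamp\nS9,red_deer,2022-06-05T10:00:00\n"
        )
        with pytest.raises(ValueError, match="unknown station"):
            dm.read_events(p, stations)


class TestIndependenceFilter:
    def test_all_within_one_window_collapse_to_first(self):
        ev = make_events(
            [("S1", "red_deer", f"2022-06-01T00:{m:02d}:00") for m in (0, 10, 29)]
        )
        assert len(dm.filter_independent(ev)) == 1

    def test_retained_anchor_rule(self):
        # minutes {0, 20, 40, 70}: 20 is within 30 min of retained 0; 40 is
        # 40 min after retained 0 so kept; 70 is 30 min after retained 40.
        ev = make_events(
            [("S1", "red_deer", f"2022-06-01T{m // 60}:{m % 60:02d}:00")
             for m in (0, 20, 40, 70)]
        )
        kept = dm.filter_independent(ev)
        minutes = (
            (kept["timestamp"] - kept["timestamp"].iloc[0]).dt.total_seconds() / 60
        )
        assert list(minutes) == [0, 40, 70]

    def test_species_filtered_independently(self):
        ev = make_events(
            [
                ("S1", "red_deer", "2022-06-01T00:00:00"),
                ("S1", "cattle", "2022-06-01T00:05:00"),
                ("S1", "red_deer", "2022-06-01T00:10:00"),
            ]
        )
        kept = dm.filter_independent(ev)
        assert sorted(kept["species"]) == ["cattle", "red_deer"]

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            dm.filter_independent(make_events([]), window_minutes=-5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=600), min_size=1, max_size=25)
    )
    def test_idempotent(self, minutes):
        ev = make_events(
            [("S1", "red_deer", str(pd.Timestamp("2022-06-01") + pd.Timedelta(minutes=m)))
             for m in sorted(minutes)]
        )
        once = dm.filter_independent(ev)
        twice = dm.filter_independent(once)
        pd.testing.assert_frame_equal(once, twice)


class TestExcludeRare:
    def test_low_count_species_removed(self):
        rows = [("S1", "brown_bear", f"2022-06-{d + 1:02d}T10:00:00") for d in range(10)]
        rows += [("S1", "red_deer", f"2022-06-01T{h:02d}:00:00") for h in range(12)]
        ev = make_events(rows)
        out = dm.exclude_rare_species(ev, min_detections=11)
        assert set(out["species"]) == {"red_deer"}

    def test_zero_threshold_is_identity(self):
        ev = make_events([("S1", "lynx", "2022-06-01T10:00:00")])
        assert len(dm.exclude_rare_species(ev, 0)) == 1

    def test_all_below_threshold_yields_empty(self):
        ev = make_events([("S1", "lynx", "2022-06-01T10:00:00")])
        assert len(dm.exclude_rare_species(ev, 5)) == 0


class TestBuildHistory:
    def test_360_day_survey_has_36_occasions(self):
        stations = make_stations(n=2, survey_days=360)
        ev = make_events([("S1", "red_deer", "2022-06-05T10:00:00")])
        hist = dm.build_history(
            ev, stations, "2022-06-01", pd.Timestamp("2022-06-01") + pd.Timedelta(days=360)
        )["red_deer"]
        assert hist.n_occasions == 36

    def test_partial_deployment_binning(self):
        # active days 0-15 of a 30-day survey, one detection on day 12
        stations = make_stations(n=1, survey_days=15, start="2022-06-01")
        ev = make_events([("S1", "red_deer", "2022-06-13T09:00:00")])
        hist = dm.build_history(
            ev, stations, "2022-06-01", "2022-07-01", occasion_days=10
        )["red_deer"]
        row = hist.matrix.iloc[0]
        assert row.iloc[0] == 0 and row.iloc[1] == 1 and np.isnan(row.iloc[2])

    def test_active_station_without_events_is_all_zero(self):
        stations = make_stations(n=1, survey_days=30)
        ev = make_events([])
        ev["timestamp"] = pd.to_datetime(ev["timestamp"])
        hist = dm.build_history(
            ev, stations, "2022-06-01", "2022-07-01", species=["red_deer"]
        )["red_deer"]
        assert (hist.matrix.to_numpy() == 0).all()

    def test_ones_bounded_by_detection_count_and_shared_na(self, small_survey):
        cfg, stations, _, events = small_survey
        ev = dm.filter_independent(events)
        start = stations["deploy_start"].min()
        end = stations["deploy_end"].max()
        hists = dm.build_history(ev, stations, start, end, species=cfg.species_names)
        na_ref = np.isnan(hists[cfg.species_names[0]].matrix.to_numpy())
        for sp in cfg.species_names:
            mat = hists[sp].matrix.to_numpy()
            assert np.nansum(mat) <= (ev["species"] == sp).sum()
            assert np.array_equal(np.isnan(mat), na_ref)

    def test_invalid_occasion_length_rejected(self):
        stations = make_stations()
        with pytest.raises(ValueError):
            dm.build_history(make_events([]), stations, "2022-06-01", "2022-07-01", 0)


class TestGrazingCovariate:
    @pytest.mark.parametrize(
        "start,expected",
        [
            ("2022-07-05", 1),   # fully inside July
            ("2022-12-01", 0),   # fully inside December
            ("2022-04-28", 1),   # Apr 28 - May 7: 6 of 10 days in season
            ("2022-04-26", 0),   # Apr 26 - May 5: 5 of 10 days, no majority
        ],
    )
    def test_majority_rule(self, start, expected):
        occ = pd.DataFrame(
            {
                "start": [pd.Timestamp(start)],
                "end": [pd.Timestamp(start) + pd.Timedelta(days=10)],
                "n_days": [10.0],
            }
        )
        assert dm.grazing_covariate(occ)[0] == expected


class TestPrepareDesign:
    def _stations(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        ele = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "station_id": [f"S{i}" for i in range(n)],
                "Dtr": rng.normal(800, 300, n),
                "Ele": 1600 + 150 * ele,
                "Slo": rng.normal(20, 5, n),
                "Lon": 87 + 0.1 * (0.9 * ele + 0.3 * rng.normal(size=n)),
                "Lat": 48 + 0.1 * (0.9 * ele + 0.3 * rng.normal(size=n)),
                "Dtw": rng.choice(["le100", "gt100"], n),
                "Vt": rng.choice(["mixed", "coniferous"], n),
                "Asp": rng.choice(["sunny", "shady", "flat"], n),
                "Td": rng.choice(["dense", "sparse"], n),
            }
        ).set_index("station_id")
        return df

    def test_standardization_and_contrast_codes(self):
        design, _ = dm.prepare_design(self._stations())
        for cov in design.columns:
            col = design[cov].to_numpy()
            if cov in dm.CONTINUOUS_COVARIATES:
                assert abs(col.mean()) < 1e-9
                assert abs(col.std(ddof=1) - 1) < 1e-9
            else:
                assert set(np.unique(col)) <= {-1.0, 0.0, 1.0}

    def test_perfectly_collinear_column_dropped(self):
        df = self._stations()
        df["Slo"] = df["Ele"] * 2.0  # r = 1 with Ele
        design, report = dm.prepare_design(df)
        assert "Slo" not in design.columns
        assert any(c == "Slo" for c, _ in report.dropped)

    def test_orthogonal_design_all_kept_with_unit_vif(self):
        # orthogonal continuous columns: VIF exactly 1, nothing dropped
        # 2^3 factorial +/-1 columns: mean zero and mutually orthogonal
        levels = np.array(
            [[(-1) ** (i >> b & 1) for b in range(3)] for i in range(8)], dtype=float
        )
        df = pd.DataFrame(
            {
                "station_id": [f"S{i}" for i in range(8)],
                "Dtr": levels[:, 0],
                "Ele": levels[:, 1],
                "Slo": levels[:, 2],
            }
        ).set_index("station_id")
        design, report = dm.prepare_design(df)
        assert list(design.columns) == ["Dtr", "Ele", "Slo"]
        assert np.allclose(report.vif.to_numpy(), 1.0, atol=1e-8)

    def test_screen_mimicking_the_study_keeps_seven(self):
        # Lon/Lat ride the elevation gradient, so the screen should keep
        # exactly the seven ecologically prioritized covariates
        design, report = dm.prepare_design(self._stations(seed=3))
        assert sorted(report.kept) == sorted(
            ["Dtr", "Ele", "Slo", "Dtw", "Vt", "Asp", "Td"]
        )
        assert (report.vif < 3).all()
        corr = design.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.5

    def test_zero_variance_covariate_rejected_by_name(self):
        df = self._stations()
        df["Dtr"] = 5.0
        with pytest.raises(ValueError, match="Dtr"):
            dm.prepare_design(df)
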
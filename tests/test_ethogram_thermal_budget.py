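import numpy as np
import pandas as pd
import pytest

from heatacc.budget import (
    add_local_time,
    afternoon_filter,
    diel_budget,
    join_weather,
    mean_odba_cells,
    time_budget,
)
from heatacc.ethogram import (
    ANALYSIS_CATEGORIES,
    CONSOLIDATION_MAP,
    ETHOGRAM_LABELS,
    EXCLUDED,
    consolidate,
    consolidate_records,
)
from heatacc.thermal import (
    DEFAULT_BLACKGLOBE_COEFFS,
    ExtremeDays,
    add_blackglobe,
    blackglobe,
    daily_max,
    select_extreme_days,
)


class TestConsolidation:
    def test_map_is_total_over_the_twelve_labels(self):
        assert set(CONSOLIDATION_MAP) == set(ETHOGRAM_LABELS)

    @pytest.mark.parametrize(
        "label,category",
        [
            ("foraging", "walking"),
            ("sleeping", "resting"),
            ("low-activity", "resting"),
            ("trotting", EXCLUDED),
            ("drinking", EXCLUDED),
            ("salt-licking", EXCLUDED),
            ("grooming", EXCLUDED),
            ("running", EXCLUDED),
            ("browsing", "browsing"),
            ("grazing", "grazing"),
            ("walking", "walking"),
            ("ruminating", "ruminating"),
        ],
    )
    def test_mapping(self, label, category):
        assert consolidate(label) == category

    def test_idempotent_on_analysis_categories(self):
        for cat in ANALYSIS_CATEGORIES:
            assert consolidate(cat) == cat

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            consolidate("flying")

    def test_consolidate_records_counts_and_fraction(self):
        frame = pd.DataFrame({"behaviour": ["walking"] * 98 + ["drinking"] * 2})
        out, report = consolidate_records(frame)
        assert len(out) == 98
        assert report.excluded_fraction == pytest.approx(0.02)
        assert set(out["category"]) <= set(ANALYSIS_CATEGORIES)

    def test_all_walking_unchanged(self):
        frame = pd.DataFrame({"behaviour": ["walking"] * 10})
        out, report = consolidate_records(frame)
        assert len(out) == 10 and report.n_excluded == 0


class TestBlackglobe:
    def test_identity_fallback_equals_air_temp(self):
        assert blackglobe(31.5, 0.0, 40.0, None) == pytest.approx(31.5)

    def test_missing_coefficients_named(self):
        with pytest.raises(KeyError, match="solar"):
            blackglobe(30, 500, 40, {"intercept": 0, "air_temp": 1, "rh": 0})

    def test_monotone_in_solar_and_air_temp(self):
        solar = np.linspace(0, 1000, 50)
        out = blackglobe(35.0, solar, 30.0, DEFAULT_BLACKGLOBE_COEFFS)
        assert (np.diff(out) >= 0).all()
        temps = np.linspace(10, 45, 50)
        out = blackglobe(temps, 500.0, 30.0, DEFAULT_BLACKGLOBE_COEFFS)
        assert (np.diff(out) > 0).all()

    def test_vectorized_matches_scalar(self):
        temps, solar, rh = np.array([20.0, 30.0]), np.array([100.0, 800.0]), np.array([20.0, 70.0])
        vec = blackglobe(temps, solar, rh, DEFAULT_BLACKGLOBE_COEFFS)
        for i in range(2):
            assert vec[i] == pytest.approx(
                blackglobe(temps[i], solar[i], rh[i], DEFAULT_BLACKGLOBE_COEFFS)
            )

    def test_at_least_air_temp_in_sunshine(self):
        rng = np.random.default_rng(0)
        temps = rng.uniform(10, 45, 200)
        solar = rng.uniform(1, 1000, 200)
        rh = rng.uniform(0, 100, 200)
        assert (blackglobe(temps, solar, rh, DEFAULT_BLACKGLOBE_COEFFS) >= temps).all()

    def test_rh_bounds_enforced(self):
        with pytest.raises(ValueError):
            blackglobe(30, 500, 120, DEFAULT_BLACKGLOBE_COEFFS)


def _weather_days(day_maxima, start="2020-10-01"):
    rows = []
    for d, mx in enumerate(day_maxima):
        for h in range(24):
            rows.append(
                {
                    "timestamp": pd.Timestamp(start, tz="UTC")
                    + pd.Timedelta(days=d, hours=h),
                    "air_temp": mx - 10 + 10 * np.exp(-((h - 14) ** 2) / 8),
                    "solar": 0.0,
                    "rh": 30.0,
                }
            )
    return pd.DataFrame(rows)


class TestDailyMaxAndExtremeDays:
    def test_hourly_fixture_max_at_14h(self):
        frame = _weather_days([35.0])
        dm = daily_max(frame)
        assert len(dm) == 1
        assert dm.iloc[0] == pytest.approx(35.0)

    def test_one_record_per_day_is_identity(self):
        frame = pd.DataFrame(
            {
                "timestamp": pd.date_range("2020-10-01", periods=5, freq="D", tz="UTC"),
                "air_temp": [30.0, 31, 29, 33, 28],
            }
        )
        assert (daily_max(frame).to_numpy() == frame["air_temp"].to_numpy()).all()
        assert len(daily_max(frame)) == frame["timestamp"].dt.date.nunique()

    def test_strictly_ordered_days_split_into_halves(self):
        maxima = np.arange(20) + 25.0
        dm = daily_max(_weather_days(maxima))
        ext = select_extreme_days(dm, n=10)
        hottest_vals = sorted(dm[list(ext.hottest)])
        coolest_vals = sorted(dm[list(ext.coolest)])
        assert min(hottest_vals) > max(coolest_vals)
        assert len(ext.hottest) == len(ext.coolest) == 10
        assert not set(ext.hottest) & set(ext.coolest)

    def test_coolest_mean_hand_computed(self):
        maxima = [30.0, 31, 32, 33, 40, 41, 42, 43]
        dm = daily_max(_weather_days(maxima))
        ext = select_extreme_days(dm, n=4)
        assert np.mean([dm[d] for d in ext.coolest]) == pytest.approx(31.5)

    def test_window_excludes_other_months(self):
        dm = daily_max(_weather_days(np.arange(25) + 20.0, start="2020-09-20"))
        ext = select_extreme_days(dm, n=5, window_months={10})
        for d in list(ext.hottest) + list(ext.coolest):
            assert pd.Timestamp(d).month == 10

    def test_too_few_days_rejected(self):
        dm = daily_max(_weather_days([30.0] * 5))
        with pytest.raises(ValueError, match=">="):
            select_extreme_days(dm, n=10)

    def test_tie_broken_by_earlier_date(self):
        dm = daily_max(_weather_days([30.0, 30.0, 35.0, 35.0]))
        ext = select_extreme_days(dm, n=1, window_months={10})
        assert pd.Timestamp(list(ext.hottest)[0]).day == 3
        assert pd.Timestamp(list(ext.coolest)[0]).day == 1

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            ExtremeDays(hottest=("2020-10-01",), coolest=("2020-10-01",))


def _records(hours, categories, individual="a", odba=10.0, start="2020-10-05"):
    ts = [
        pd.Timestamp(start, tz="UTC") + pd.Timedelta(hours=h) for h in hours
    ]
    return pd.DataFrame(
        {
            "individual_id": individual,
            "timestamp": ts,
            "category": categories,
            "odba": odba,
        }
    )


class TestJoinAndFilters:
    def test_exact_timestamp_gets_that_blackglobe(self):
        recs = _records([0], ["grazing"])
        thermal = pd.DataFrame(
            {"timestamp": recs["timestamp"], "blackglobe": [44.4]}
        )
        out = join_weather(recs, thermal)
        assert out["blackglobe"].iloc[0] == 44.4

    def test_record_beyond_tolerance_dropped(self):
        recs = _records([0], ["grazing"])
        thermal = pd.DataFrame(
            {
                "timestamp": [recs["timestamp"].iloc[0] + pd.Timedelta(minutes=31)],
                "blackglobe": [44.4],
            }
        )
        out = join_weather(recs, thermal, tolerance=pd.Timedelta(minutes=30))
        assert len(out) == 0

    def test_output_never_exceeds_input(self):
        recs = _records(range(10), ["grazing"] * 10)
        thermal = pd.DataFrame(
            {"timestamp": recs["timestamp"][:3], "blackglobe": [40.0, 41, 42]}
        )
        assert len(join_weather(recs, thermal)) <= len(recs)

    def test_empty_thermal_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            join_weather(_records([0], ["grazing"]), pd.DataFrame(columns=["timestamp", "blackglobe"]))

    def test_afternoon_boundaries(self):
        recs = add_local_time(_records([10, 16], ["grazing", "grazing"]), 2)
        # local hours are 12 and 18: only the first is an afternoon record
        out = afternoon_filter(recs)
        assert list(out["hour"]) == [12]

    def test_uniform_day_keeps_quarter(self):
        recs = add_local_time(_records(range(24), ["grazing"] * 24), 0)
        assert len(afternoon_filter(recs)) == 6

    def test_empty_passthrough(self):
        recs = add_local_time(_records([], []), 2)
        assert len(afternoon_filter(recs)) == 0


class TestBudgetCells:
    def _cells(self, cats, **kw):
        recs = add_local_time(_records(range(len(cats)), cats, **kw), 0)
        recs["blackglobe"] = 45.0
        return time_budget(recs, keys=["individual_id"])

    def test_single_category_cell(self):
        cells = self._cells(["grazing"] * 4)
        assert cells["grazing"].iloc[0] == 1.0
        assert cells["resting"].iloc[0] == 0.0

    def test_three_to_one_split(self):
        cells = self._cells(["grazing"] * 3 + ["resting"])
        assert cells["grazing"].iloc[0] == pytest.approx(0.75)
        assert cells["resting"].iloc[0] == pytest.approx(0.25)

    def test_proportions_sum_to_one_and_counts_conserved(self):
        rng = np.random.default_rng(1)
        cats = rng.choice(list(ANALYSIS_CATEGORIES), 200)
        recs = add_local_time(_records(range(200), cats), 0)
        recs["blackglobe"] = rng.uniform(40, 50, 200)
        cells = time_budget(recs)
        sums = cells[list(ANALYSIS_CATEGORIES)].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert cells["n_records"].sum() == 200

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        cats = rng.choice(list(ANALYSIS_CATEGORIES), 50)
        recs = add_local_time(_records(range(50), cats), 0)
        recs["blackglobe"] = 45.0
        a = time_budget(recs)
        b = time_budget(recs.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(
            a.sort_index(axis=1), b.sort_index(axis=1), check_like=True
        )

    def test_blackglobe_floor_binning(self):
        recs = add_local_time(_records([0, 1], ["grazing", "grazing"]), 0)
        recs["blackglobe"] = [45.9, 45.1]
        cells = time_budget(recs, keys=["blackglobe_bin"])
        assert list(cells["blackglobe_bin"]) == [45]


class TestMeanOdba:
    def test_threshold_boundary(self):
        recs29 = add_local_time(_records(np.arange(29) / 60, ["grazing"] * 29), 0)
        recs30 = add_local_time(
            _records(np.arange(30) / 60, ["grazing"] * 30, odba=1.0), 0
        )
        recs30["odba"] = np.arange(1, 31, dtype=float)
        for recs in (recs29, recs30):
            recs["blackglobe"] = 45.0
        assert len(mean_odba_cells(recs29, keys=["individual_id"])) == 0
        cells = mean_odba_cells(recs30, keys=["individual_id"])
        assert len(cells) == 1
        assert cells["mean_odba"].iloc[0] == pytest.approx(15.5)

    def test_default_min_n(self):
        from heatacc.budget import DEFAULT_MIN_RECORDINGS

        assert DEFAULT_MIN_RECORDINGS == 30


class TestDielBudget:
    def test_non_extreme_days_absent_and_classes_labelled(self):
        ext = ExtremeDays(
            hottest=(pd.Timestamp("2020-10-05").date(),),
            coolest=(pd.Timestamp("2020-10-06").date(),),
        )
        recs = pd.concat(
            [
                _records(range(24), ["grazing"] * 24, start="2020-10-05"),
                _records(range(24), ["resting"] * 24, start="2020-10-06"),
                _records(range(24), ["walking"] * 24, start="2020-10-07"),
            ]
        )
        recs = add_local_time(recs, 0)
        cells = diel_budget(recs, ext)
        assert set(cells["day_class"]) == {"hot", "cool"}
        assert cells["n_records"].sum() == 48  # the 10-07 day is dropped
        hot = cells[cells["day_class"] == "hot"]
        assert (hot["grazing"] == 1.0).all()
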
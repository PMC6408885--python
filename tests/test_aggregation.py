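from datetime import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feedercalls import aggregation
from feedercalls.aggregation import (AggregationError, bin_hourly, derive_latency,
                                     initial_recruitment, label_ampm,
                                     profile_across_sites, total_birds)

from .conftest import TRIAL_START, make_calls, make_visits


class TestLabelAmPm:
    @pytest.mark.parametrize("hour,expected", [
        (0, "AM"), (11, "AM"), (12, "PM"), (23, "PM"),
    ])
    def test_noon_belongs_to_the_afternoon(self, hour, expected):
        assert label_ampm(hour) == expected

    def test_total_on_all_clock_hours(self):
        assert {label_ampm(h) for h in range(24)} == {"AM", "PM"}

    @pytest.mark.parametrize("hour", [-1, 24])
    def test_out_of_range_rejected(self, hour):
        with pytest.raises(AggregationError):
            label_ampm(hour)


class TestBinHourly:
    def test_empty_hours_have_zero_counts_and_undefined_rate(self):
        visits = make_visits([("S01", "2016-02-15T08:10:00", "T1", "GRETI")])
        calls = make_calls([])
        out = bin_hourly(visits, calls, "S01", 7.0, 17.75)
        empty = out[out["clock_hour"] != 8]
        assert (empty[["n_calls", "n_visits", "n_individuals"]] == 0).all().all()
        assert empty["calls_per_visit"].isna().all()

    def test_hand_counted_example(self):
        visits = make_visits([
            ("S01", "2016-02-15T08:10:00", "T1", "GRETI"),
            ("S01", "2016-02-15T08:40:00", "T1", "GRETI"),
        ])
        calls = make_calls([
            ("S01", "2016-02-15T08:05:00", "CHIRP", 3),
            ("S01", "2016-02-15T08:15:00", "CHIRP", 2),
            ("S01", "2016-02-15T08:45:00", "DAD", 4),
        ])
        row = bin_hourly(visits, calls, "S01").set_index("clock_hour").loc[8]
        assert row["n_visits"] == 2
        assert row["n_individuals"] == 1
        assert row["n_calls"] == 3
        assert row["calls_per_visit"] == pytest.approx(1.5)

    def test_hour_bins_are_left_closed(self):
        visits = make_visits([
            ("S01", "2016-02-15T08:59:59", "T1", "GRETI"),
            ("S01", "2016-02-15T09:00:00", "T2", "BLUTI"),
        ])
        out = bin_hourly(visits, make_calls([]), "S01").set_index("clock_hour")
        assert out.loc[8, "n_visits"] == 1
        assert out.loc[9, "n_visits"] == 1

    def test_untagged_visits_count_as_visits_not_individuals(self):
        visits = make_visits([
            ("S01", "2016-02-15T08:10:00", "", "UNKNOWN"),
            ("S01", "2016-02-15T08:20:00", "T1", "GRETI"),
        ])
        row = bin_hourly(visits, make_calls([]), "S01").set_index("clock_hour").loc[8]
        assert row["n_visits"] == 2
        assert row["n_individuals"] == 1

    def test_multiple_sites_rejected(self):
        visits = make_visits([
            ("S01", "2016-02-15T08:10:00", "T1", "GRETI"),
            ("S02", "2016-02-15T08:20:00", "T2", "GRETI"),
        ])
        with pytest.raises(AggregationError, match="multiple sites"):
            bin_hourly(visits, make_calls([]))

    @settings(deadline=None, max_examples=25)
    @given(st.data())
    def test_counts_partition_events_and_ignore_input_order(self, data):
        n = data.draw(st.integers(1, 40))
        hours = data.draw(st.lists(st.integers(7, 17), min_size=n, max_size=n))
        minutes = data.draw(st.lists(st.integers(0, 59), min_size=n, max_size=n))
        visits = make_visits([
            ("S01", f"2016-02-15T{h:02d}:{m:02d}:00", f"T{i%5}", "GRETI")
            for i, (h, m) in enumerate(zip(hours, minutes))
        ])
        out = bin_hourly(visits, make_calls([]), "S01", 7.0, 17.75)
        assert out["n_visits"].sum() == n
        assert (out["n_individuals"] <= out["n_visits"]).all()
        shuffled = visits.sample(frac=1.0, random_state=1).reset_index(drop=True)
        out2 = bin_hourly(shuffled, make_calls([]), "S01", 7.0, 17.75)
        pd.testing.assert_frame_equal(out, out2)


class TestProfileAcrossSites:
    def _two_site_table(self, calls_a, calls_b):
        rows = []
        for site, c in (("S01", calls_a), ("S02", calls_b)):
            rows.append({"site_id": site, "clock_hour": 9, "n_calls": c,
                         "n_visits": 4, "n_individuals": 2})
        return pd.DataFrame(rows)

    def test_identical_sites_have_zero_se(self):
        prof = profile_across_sites(self._two_site_table(2, 2))
        assert prof["se_n_calls"].iloc[0] == 0

    def test_mean_and_se_hand_computed(self):
        prof = profile_across_sites(self._two_site_table(2, 4))
        assert prof["mean_n_calls"].iloc[0] == pytest.approx(3.0)
        assert prof["se_n_calls"].iloc[0] == pytest.approx(1.0)  # sd sqrt(2), n=2

    def test_single_site_hour_flagged_without_se(self):
        table = self._two_site_table(2, 4)
        table = pd.concat([table, pd.DataFrame([{
            "site_id": "S01", "clock_hour": 10, "n_calls": 1,
            "n_visits": 1, "n_individuals": 1}])], ignore_index=True)
        prof = profile_across_sites(table).set_index("clock_hour")
        assert bool(prof.loc[10, "flagged"])
        assert np.isnan(prof.loc[10, "se_n_calls"])
        assert not bool(prof.loc[9, "flagged"])


class TestLatency:
    def test_no_visits_is_censored_at_60(self):
        lat, censored = derive_latency(make_visits([]), TRIAL_START)
        assert (lat, censored) == (60.0, True)

    def test_early_discovery_is_uncensored(self):
        visits = make_visits([("S01", "2017-02-10T08:31:54", "T1", "GRETI")])
        lat, censored = derive_latency(visits, TRIAL_START)
        assert lat == pytest.approx(1.9)
        assert not censored

    def test_discovery_after_window_is_censored_to_60(self):
        visits = make_visits([("S01", "2017-02-10T09:45:00", "T1", "GRETI")])
        lat, censored = derive_latency(visits, TRIAL_START)  # +75 min
        assert (lat, censored) == (60.0, True)


class TestRecruitmentCounts:
    DISCOVERY = datetime(2017, 2, 10, 8, 35)

    def test_lone_discoverer_counts_one(self):
        visits = make_visits([("S01", "2017-02-10T08:35:00", "T1", "GRETI")])
        assert initial_recruitment(visits, self.DISCOVERY) == 1

    def test_repeat_visits_count_once(self):
        visits = make_visits([
            ("S01", "2017-02-10T08:35:00", "T1", "GRETI"),
            ("S01", "2017-02-10T08:36:00", "T1", "GRETI"),
        ])
        assert initial_recruitment(visits, self.DISCOVERY) == 1

    def test_closed_two_minute_window_hand_count(self):
        visits = make_visits([
            ("S01", "2017-02-10T08:35:00", "T1", "GRETI"),
            ("S01", "2017-02-10T08:36:00", "T2", "BLUTI"),
            ("S01", "2017-02-10T08:36:54", "T3", "MARTI"),
            ("S01", "2017-02-10T08:37:30", "T4", "GRETI"),  # +2.5 min: outside
        ])
        assert initial_recruitment(visits, self.DISCOVERY) == 3

    def test_undefined_for_censored_trial(self):
        with pytest.raises(AggregationError):
            initial_recruitment(make_visits([]), self.DISCOVERY)

    def test_total_birds_zero_on_censored_trial(self):
        assert total_birds(make_visits([]), TRIAL_START) == 0

    def test_total_birds_unique_tags_despite_revisits(self):
        rows = [("S01", f"2017-02-10T08:{31+i:02d}:00", f"T{i}", "GRETI")
                for i in range(5)]
        rows += [("S01", f"2017-02-10T08:{40+i:02d}:00", "T0", "GRETI")
                 for i in range(10)]
        assert total_birds(make_visits(rows), TRIAL_START) == 5

    def test_sixty_minute_window_open_on_the_right(self):
        visits = make_visits([
            ("S01", "2017-02-10T09:29:54", "T1", "GRETI"),  # +59.9
            ("S01", "2017-02-10T09:30:06", "T2", "GRETI"),  # +60.1
        ])
        assert total_birds(visits, TRIAL_START) == 1

    def test_recruitment_never_exceeds_total(self, playback_experiment):
        trials, visits_by_trial = playback_experiment
        recs = aggregation.playback_records(trials, visits_by_trial)
        ok = recs.dropna(subset=["initial_recruitment", "total_birds"])
        assert (ok["initial_recruitment"] <= ok["total_birds"]).all()
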
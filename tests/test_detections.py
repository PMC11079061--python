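"""Independent-event extraction, season labelling and event bookkeeping."""

from datetime import datetime, timedelta
from io import StringIO

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dielniche.detections import (
    COLD, WARM, DetectionReadError, DetectionRecord, SeasonConfig,
    assign_season, filter_independent_events, read_detections,
    records_to_frame, summarize_events,
)


def _records(times, site="s1", species="boar"):
    return [DetectionRecord(site, species, t) for t in times]


def _at(*hhmm):
    base = datetime(2016, 5, 1)
    return [base.replace(hour=h, minute=m) for h, m in hhmm]


class TestIndependenceFilter:
    @pytest.mark.parametrize(
        "times, expected_starts",
        [
            # all gaps <= 30 min collapse into one event
            (_at((10, 0), (10, 10), (10, 20)), _at((10, 0))),
            # 31-min gap opens a second event
            (_at((10, 0), (10, 31)), _at((10, 0), (10, 31))),
            # chain rule: 10:40 chains through 10:20; the 40-min gap breaks
            (_at((10, 0), (10, 20), (10, 40), (11, 20)), _at((10, 0), (11, 20))),
            # a gap of exactly 30 min is not "more than" the threshold
            (_at((10, 0), (10, 30)), _at((10, 0))),
        ],
    )
    def test_chain_rule(self, times, expected_starts):
        table = filter_independent_events(_records(times))
        assert list(table.events["event_time"]) == expected_starts

    def test_groups_are_independent_per_site_and_species(self):
        recs = (_records(_at((10, 0))) + _records(_at((10, 5)), site="s2")
                + _records(_at((10, 10)), species="goral"))
        assert len(filter_independent_events(recs)) == 3

    def test_empty_input_and_bad_interval(self):
        assert len(filter_independent_events([])) == 0
        with pytest.raises(ValueError):
            filter_independent_events([], interval_minutes=0)

    @given(
        gaps=st.lists(st.integers(min_value=1, max_value=90), min_size=1, max_size=30),
        interval=st.integers(min_value=5, max_value=60),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_properties(self, gaps, interval):
        """Permutation invariance, idempotence, and monotonicity in the interval."""
        times = [datetime(2016, 5, 1)]
        for g in gaps:
            times.append(times[-1] + timedelta(minutes=g))
        recs = records_to_frame(_records(times))
        table = filter_independent_events(recs, interval)

        shuffled = recs.sample(frac=1, random_state=1).reset_index(drop=True)
        assert filter_independent_events(shuffled, interval).events.equals(table.events)

        again = filter_independent_events(
            table.events.rename(columns={"event_time": "timestamp"}), interval
        )
        assert list(again.events["event_time"]) == list(table.events["event_time"])

        looser = filter_independent_events(recs, interval + 10)
        assert len(looser) <= len(table)


class TestSeasons:
    def test_partition_invariant(self):
        with pytest.raises(ValueError):
            SeasonConfig(frozenset({1, 2}), frozenset({2, 3}))
        with pytest.raises(ValueError):
            SeasonConfig(frozenset({1}), frozenset({2}))

    @pytest.mark.parametrize(
        "when, season",
        [
            (datetime(2016, 7, 15), WARM),
            (datetime(2016, 1, 15), COLD),
            (datetime(2016, 4, 1), WARM),
            (datetime(2016, 3, 31), COLD),
        ],
    )
    def test_month_assignment(self, when, season):
        table = filter_independent_events(_records([when]))
        labelled = assign_season(table, SeasonConfig())
        assert labelled.events["season"].iloc[0] == season

    def test_counts_conserved_across_seasons(self):
        times = [datetime(2016, m, 10) for m in range(1, 13)]
        recs = [DetectionRecord("s1", "boar", t) for t in times]
        labelled = assign_season(filter_independent_events(recs))
        summary = summarize_events(labelled)
        assert summary.total == 12
        assert sum(summary.per_species_season.values()) == 12


class TestReadDetections:
    CSV = "site_id,species,timestamp\n" + "\n".join(
        f"s1,boar,2016-05-01 10:{m:02d}:00" for m in range(3)
    )

    def test_well_formed(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(self.CSV + "\n")
        frame, failures = read_detections(p)
        assert len(frame) == 3 and not failures

    def test_malformed_row_reported(self, tmp_path):
        rows = [f"s1,boar,2016-05-01 10:{m:02d}:00" for m in range(10)]
        rows[4] = "s1,boar,not-a-date"
        p = tmp_path / "d.csv"
        p.write_text("site_id,species,timestamp\n" + "\n".join(rows) + "\n")
        frame, failures = read_detections(p, max_failure_fraction=0.2)
        assert len(frame) == 9
        assert [f.row for f in failures] == [5]

    def test_header_only(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("site_id,species,timestamp\n")
        frame, failures = read_detections(p)
        assert frame.empty and not failures

    def test_too_many_failures_abort(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("site_id,species,timestamp\ns1,boar,nope\n")
        with pytest.raises(DetectionReadError):
            read_detections(p, max_failure_fraction=0.1)

    def test_missing_file_and_column(self, tmp_path):
        with pytest.raises(DetectionReadError):
            read_detections(tmp_path / "absent.csv")
        p = tmp_path / "d.csv"
        p.write_text("camera,species,timestamp\n")
        with pytest.raises(DetectionReadError):
            read_detections(p)

    def test_column_mapping(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("cam,sp,when\nK07,goral,01/05/2016 08:30\n")
        frame, _ = read_detections(
            p, {"site_id": "cam", "species": "sp", "timestamp": "when"},
            datetime_format="%d/%m/%Y %H:%M",
        )
        assert frame["site_id"].iloc[0] == "K07"
        assert frame["timestamp"].iloc[0] == pd.Timestamp(2016, 5, 1, 8, 30)

    def test_conservation(self, tmp_path):
        """Input rows = parsed records + reported failures."""
        rows = [f"s1,boar,2016-05-01 10:{m:02d}:00" for m in range(8)]
        rows[2] = "s1,boar,xx"
        rows[6] = "s1,boar,yy"
        p = tmp_path / "d.csv"
        p.write_text("site_id,species,timestamp\n" + "\n".join(rows) + "\n")
        frame, failures = read_detections(p, max_failure_fraction=0.5)
        assert len(frame) + len(failures) == 8


def test_summary_totals():
    assert summarize_events(filter_independent_events([])).total == 0
    recs = [DetectionRecord("s1", "goral", datetime(2016, 5, 1, h)) for h in range(5)]
    summary = summarize_events(filter_independent_events(recs))
    assert summary.per_species == {"goral": 5}
    assert summary.total == 5
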
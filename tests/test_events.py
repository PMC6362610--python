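"""Event coding, first-capture conditioning and file formats."""

import datetime

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mered import (
    Dataset,
    EncounterHistory,
    ResightRecord,
    BREEDING_EVENTS,
    classify_capture_period,
    collapse_to_event,
    build_histories,
    read_histories_csv,
    write_histories_csv,
    write_mark_inp,
)
from mered.errors import ValidationError
from mered.events import (
    SeasonCalendar,
    condition_event_matrix,
    event_from_periods,
    read_resights_csv,
    write_resights_csv,
)


class TestCapturePeriods:
    @pytest.mark.parametrize("context,period", [
        ("breed_week_1", "U"), ("breed_week_3", "U"), ("breed_week_5", "U"),
        ("breed_week_7", "U"), ("breed_week_2", "E"), ("breed_week_4", "E"),
        ("breed_week_6", "E"), ("breed_week_8", "E"),
        ("moult", "M"), ("winter", "M"),
    ])
    def test_week_parity_and_nonbreeding(self, context, period):
        assert classify_capture_period(context) == period

    def test_unknown_context_rejected_by_name(self):
        with pytest.raises(ValidationError, match="breed_week_9"):
            classify_capture_period("breed_week_9")
        with pytest.raises(ValidationError, match="summer"):
            ResightRecord("A1", 2000, "summer")


class TestCollapseToEvent:
    @pytest.mark.parametrize("periods,code", [
        (set(), 0), ({"M", "U", "E"}, 1), ({"M", "U"}, 2), ({"M", "E"}, 3),
        ({"M"}, 4), ({"U", "E"}, 5), ({"U"}, 6), ({"E"}, 7),
    ])
    def test_period_subset_mapping(self, periods, code):
        assert event_from_periods(periods) == code

    def test_examples(self):
        recs = [ResightRecord("A", 2000, c)
                for c in ("breed_week_1", "breed_week_5", "moult")]
        assert collapse_to_event(recs) == 2  # MU
        assert collapse_to_event([]) == 0
        recs = [ResightRecord("A", 2000, c) for c in ("breed_week_2", "breed_week_4")]
        assert collapse_to_event(recs) == 7  # E only
        recs = [ResightRecord("A", 2000, "breed_week_3"),
                ResightRecord("A", 2000, "winter")]
        assert collapse_to_event(recs) == 2  # week 3 -> U, winter -> M

    def test_mixed_animal_years_rejected(self):
        recs = [ResightRecord("A", 2000, "moult"), ResightRecord("B", 2000, "moult")]
        with pytest.raises(ValidationError, match="multiple animal-years"):
            collapse_to_event(recs)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(
        [f"breed_week_{k}" for k in range(1, 9)] + ["moult", "winter"]),
        min_size=0, max_size=12),
        st.randoms(use_true_random=False))
    def test_pure_in_period_set_and_order(self, contexts, rnd):
        """Duplicates collapse silently and record order never matters."""
        recs = [ResightRecord("A", 2000, c) for c in contexts]
        code = collapse_to_event(recs)
        shuffled = list(recs)
        rnd.shuffle(shuffled)
        assert collapse_to_event(shuffled + recs) == code


class TestBuildHistories:
    def _records_for_events(self, animal, years, events):
        # emit a minimal record set realizing each composite event code
        reps = {1: ("moult", "breed_week_1", "breed_week_2"),
                2: ("moult", "breed_week_1"), 3: ("moult", "breed_week_2"),
                4: ("moult",), 5: ("breed_week_1", "breed_week_2"),
                6: ("breed_week_1",), 7: ("breed_week_2",), 0: ()}
        return [ResightRecord(animal, y, c)
                for y, e in zip(years, events) for c in reps[e]]

    def test_prefix_truncation(self):
        years = [2000, 2001, 2002, 2003]
        recs = self._records_for_events("A", years, (4, 0, 5, 4))
        dataset, report = build_histories(recs, years)
        (h,) = dataset.histories
        assert h.first_occasion == 2
        assert h.events == (5, 4)
        assert report.truncated_prefix_occasions == 2

    def test_never_breeding_individual_excluded(self):
        years = [2000, 2001]
        recs = self._records_for_events("A", years, (4, 4)) + \
            self._records_for_events("B", years, (6, 0))
        dataset, report = build_histories(recs, years)
        assert [h.animal_id for h in dataset.histories] == ["B"]
        assert report.excluded_ids == ["A"]
        assert dataset.histories[0].events == (6, 0)
        assert dataset.histories[0].first_occasion == 0

    def test_record_outside_axis_rejected(self):
        recs = [ResightRecord("A", 1999, "breed_week_1")]
        with pytest.raises(ValidationError, match="1999"):
            build_histories(recs, [2000, 2001])

    def test_every_history_starts_with_breeding_event(self, rng):
        contexts = [f"breed_week_{k}" for k in range(1, 9)] + ["moult", "winter"]
        years = list(range(2000, 2006))
        recs = [ResightRecord(f"A{i}", int(rng.choice(years)), str(rng.choice(contexts)))
                for i in range(400)]
        dataset, _ = build_histories(recs, years)
        assert all(h.events[0] in BREEDING_EVENTS for h in dataset.histories)

    def test_history_must_start_with_breeding_event(self):
        with pytest.raises(ValidationError, match="breeding-season"):
            EncounterHistory("A", 0, (4, 1))


class TestDataset:
    def test_aggregation_pools_multiplicities(self):
        years = [0, 1, 2]
        hists = [EncounterHistory("a", 0, (5, 4, 0)),
                 EncounterHistory("b", 0, (5, 4, 0)),
                 EncounterHistory("c", 1, (6, 2))]
        ds = Dataset(years, hists).aggregated()
        assert len(ds) == 2
        assert sorted(ds.counts.tolist()) == [1, 2]
        assert ds.n_individuals == 3

    def test_history_span_validated(self):
        with pytest.raises(ValidationError, match="last occasion"):
            Dataset([0, 1, 2], [EncounterHistory("a", 0, (5, 4))])


class TestFileFormats:
    def test_histories_csv_round_trip(self, tmp_path, recovery_small):
        dataset, _ = recovery_small
        path = tmp_path / "hist.csv"
        write_histories_csv(dataset, path)
        loaded, report = read_histories_csv(path)
        assert loaded.years == dataset.years
        assert report.n_excluded == 0
        f0, e0, c0 = dataset.dense_arrays()
        f1, e1, c1 = loaded.dense_arrays()
        assert np.array_equal(e0, e1) and np.array_equal(f0, f1)
        assert np.array_equal(c0, c1)

    def test_resights_csv_round_trip(self, tmp_path):
        recs = [ResightRecord("A", 2000, "breed_week_1"),
                ResightRecord("A", 2001, "moult")]
        path = tmp_path / "resights.csv"
        write_resights_csv(recs, path)
        assert read_resights_csv(path) == recs

    def test_resights_csv_unknown_context_names_lines(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("animal_id,year,context\nA,2000,breed_week_1\nB,2000,spring\n")
        with pytest.raises(ValidationError, match=r"spring.*line.*3"):
            read_resights_csv(path)

    def test_mark_inp_writer(self, tmp_path):
        ds = Dataset([0, 1, 2], [EncounterHistory("a1", 1, (5, 4))], [3])
        path = tmp_path / "hist.inp"
        write_mark_inp(ds, path)
        assert path.read_text() == "/* a1 */ 054 3 ;\n"


class TestSeasonCalendar:
    def test_date_to_context(self):
        cal = SeasonCalendar()
        assert cal.context(datetime.date(2000, 9, 15)) == "breed_week_1"
        assert cal.context(datetime.date(2000, 9, 22)) == "breed_week_2"
        assert cal.context(datetime.date(2000, 11, 8)) == "breed_week_8"
        assert cal.context(datetime.date(2000, 12, 25)) == "moult"
        assert cal.context(datetime.date(2001, 6, 1)) == "winter"

    def test_seal_year_spans_september_to_august(self):
        cal = SeasonCalendar()
        assert cal.seal_year(datetime.date(2000, 9, 1)) == 2000
        assert cal.seal_year(datetime.date(2001, 8, 31)) == 2000
        rec = cal.record("A", datetime.date(2001, 1, 10))
        assert (rec.year, rec.context) == (2000, "moult")


def test_condition_event_matrix_matches_build(rng):
    """Dense-matrix conditioning agrees with the record-level encoder rule."""
    events = rng.integers(0, 8, size=(50, 6))
    ds, report = condition_event_matrix([f"x{i}" for i in range(50)], events, range(6))
    assert report.n_individuals_kept + report.n_excluded == 50
    for h in ds.histories:
        i = int(h.animal_id[1:])
        assert events[i, h.first_occasion] in BREEDING_EVENTS
        assert not np.isin(events[i, :h.first_occasion], sorted(BREEDING_EVENTS)).any()
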
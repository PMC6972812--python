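"""Time-to-event construction, midpoint death dating, and bookkeeping."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from incsurv.records import (
    EncounterRecord,
    ValidationError,
    frame_to_records,
    group_index,
    records_to_frame,
    read_encounters_csv,
    validate_records,
    write_encounters_csv,
)
from incsurv.tte import (
    DEATH,
    RIGHT_CENSORED,
    build_time_to_event,
    censoring_proportions,
    group_table_totals,
    mayfield_death_date,
    read_tte_csv,
    summarize_groups,
    sufficient_statistics,
    write_tte_csv,
)

from conftest import STUDY_END, make_record

dates = st.dates(min_value=dt.date(2013, 1, 1), max_value=dt.date(2018, 1, 1))


class TestMayfieldMidpoint:
    @pytest.mark.parametrize(
        "last_alive, first_dead, expected",
        [
            # identical dates map to themselves
            (dt.date(2015, 3, 3), dt.date(2015, 3, 3), dt.date(2015, 3, 3)),
            # even gap: exact calendar midpoint (14 days -> +7)
            (dt.date(2015, 1, 1), dt.date(2015, 1, 15), dt.date(2015, 1, 8)),
            # odd gap rounds toward the last-alive date
            (dt.date(2015, 1, 1), dt.date(2015, 1, 2), dt.date(2015, 1, 1)),
        ],
    )
    def test_examples(self, last_alive, first_dead, expected):
        assert mayfield_death_date(last_alive, first_dead) == expected

    def test_reversed_dates_name_the_individual(self):
        with pytest.raises(ValidationError, match="t-099"):
            mayfield_death_date(dt.date(2015, 2, 1), dt.date(2015, 1, 1), "t-099")

    @given(a=dates, gap=st.integers(min_value=0, max_value=2000))
    def test_midpoint_lies_between_and_splits_evenly(self, a, gap):
        b = a + dt.timedelta(days=gap)
        mid = mayfield_death_date(a, b)
        assert a <= mid <= b
        # round-toward-last-alive: the two halves differ by at most one day
        assert 0 <= (b - mid).days - (mid - a).days <= 1


class TestBuildTimeToEvent:
    def test_censored_survivor_duration(self):
        rec = make_record(
            first_observed=dt.date(2015, 1, 1), last_alive=dt.date(2015, 3, 12)
        )
        built = build_time_to_event([rec], STUDY_END)
        (r,) = built.records
        assert r.event == RIGHT_CENSORED
        assert r.duration_weeks == pytest.approx(70 / 7)

    def test_death_uses_midpoint_of_surrounding_observations(self):
        # last alive at week 8, first found dead at week 10 -> death at week 9
        start = dt.date(2015, 1, 1)
        rec = make_record(
            first_observed=start,
            last_alive=start + dt.timedelta(weeks=8),
            first_dead=start + dt.timedelta(weeks=10),
        )
        built = build_time_to_event([rec], STUDY_END)
        (r,) = built.records
        assert r.event == DEATH
        assert r.duration_weeks == pytest.approx(9.0)

    def test_single_encounter_excluded_and_counted(self):
        d = dt.date(2015, 5, 1)
        single = make_record(individual_id="s-1", first_observed=d, last_alive=d)
        kept = make_record(individual_id="k-1")
        built = build_time_to_event([single, kept], STUDY_END)
        assert built.excluded_single_encounter == ["s-1"]
        assert [r.individual_id for r in built.records] == ["k-1"]

    def test_observation_after_study_end_rejected(self):
        rec = make_record(last_alive=dt.date(2018, 6, 1))
        with pytest.raises(ValidationError):
            build_time_to_event([rec], STUDY_END)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            build_time_to_event([], STUDY_END)

    @given(
        st.lists(
            st.tuples(dates, st.integers(0, 600), st.booleans()),
            min_size=1,
            max_size=30,
        )
    )
    def test_exclusion_accounting_and_positive_durations(self, raw):
        records = []
        for i, (start, span, died) in enumerate(raw):
            last = start + dt.timedelta(days=span)
            records.append(
                make_record(
                    individual_id=f"h-{i}",
                    first_observed=start,
                    last_alive=last,
                    first_dead=last + dt.timedelta(days=3) if died else None,
                )
            )
        built = build_time_to_event(records, dt.date(2020, 12, 31))
        assert len(built.records) + built.n_excluded == len(records)
        assert all(r.duration_weeks > 0 for r in built.records)


class TestBookkeeping:
    def _mixed_records(self):
        records = []
        k = 0
        # 3 radio translocated adults north (1 death), 2 M-E resident adults south
        for died in (True, False, False):
            start = dt.date(2014, 10, 1)
            records.append(
                make_record(
                    individual_id=f"m-{k}",
                    first_observed=start,
                    last_alive=start + dt.timedelta(weeks=20),
                    first_dead=start + dt.timedelta(weeks=21) if died else None,
                )
            )
            k += 1
        for _ in range(2):
            records.append(
                make_record(
                    individual_id=f"m-{k}",
                    site="south",
                    residency="resident",
                    method="mark_encounter",
                    first_observed=dt.date(2014, 6, 1),
                    last_alive=dt.date(2015, 6, 1),
                )
            )
            k += 1
        return records

    def test_summarize_counts_and_totals(self):
        table = summarize_groups(self._mixed_records())
        assert table.loc[("north", "translocated", "adult"), "radiotelemetry"] == 3
        assert table.loc[("north", "translocated", "adult"), "mortalities"] == 1
        assert table.loc[("south", "resident", "adult"), "mark_encounter"] == 2
        totals = group_table_totals(table)
        assert totals["individuals"] == 5
        assert totals["translocated"] == 3 and totals["resident"] == 2

    def test_counts_invariant_under_permutation(self, rng):
        records = self._mixed_records()
        shuffled = [records[i] for i in rng.permutation(len(records))]
        assert summarize_groups(records).equals(summarize_groups(shuffled))

    def test_empty_cells_are_zero(self):
        table = summarize_groups(self._mixed_records())
        assert table.loc[("south", "translocated", "juvenile")].sum() == 0

    def test_censoring_proportions_and_empty_stratum_flag(self):
        built = build_time_to_event(self._mixed_records(), STUDY_END)
        props = censoring_proportions(built)
        row = props.loc[("radiotelemetry", "translocated")]
        assert row.proportion_censored == pytest.approx(1 - 1 / 3)
        # no deaths among M-E residents -> fully censored
        assert props.loc[("mark_encounter", "resident"), "proportion_censored"] == 1.0
        # empty stratum is flagged undefined, not 0 or 1
        empty = props.loc[("mark_encounter", "translocated")]
        assert not empty.defined and np.isnan(empty.proportion_censored)

    def test_sufficient_statistics_tally(self):
        built = build_time_to_event(self._mixed_records(), STUDY_END)
        deaths, exposure = sufficient_statistics(built)
        j = group_index("translocated", "adult", "north")
        assert deaths[j] == 1
        # 2 censored at 20 weeks + 1 death at the midpoint of a 7-day gap,
        # which rounds down to 3 days past last-alive
        assert exposure[j] == pytest.approx(20 + 20 + 20 + 3 / 7)


class TestValidationAndRoundTrip:
    def test_age_class_consistent_with_carapace_length(self):
        make_record(midline_carapace_length=200.0)  # adult at 200 mm: fine
        with pytest.raises(ValidationError):
            make_record(age_class="juvenile", midline_carapace_length=200.0)

    def test_date_ordering_enforced(self):
        with pytest.raises(ValidationError, match="t-001"):
            make_record(
                first_observed=dt.date(2015, 1, 1), last_alive=dt.date(2014, 1, 1)
            )

    def test_needs_some_observation(self):
        with pytest.raises(ValidationError):
            make_record(last_alive=None, first_dead=None)

    def test_duplicate_ids_reported(self):
        records = [make_record(), make_record()]
        report = validate_records(records)
        assert len(report) == 1 and "t-001" in report[0]

    def test_encounter_csv_round_trip(self, tmp_path):
        records = [
            make_record(individual_id="a", midline_carapace_length=210.0),
            make_record(
                individual_id="b",
                method="mark_encounter",
                first_dead=dt.date(2015, 11, 1),
            ),
        ]
        path = tmp_path / "enc.csv"
        write_encounters_csv(records, path)
        assert read_encounters_csv(path) == records

    def test_tte_csv_round_trip_bit_exact(self, tmp_path):
        built = build_time_to_event(
            [make_record(individual_id=f"r-{i}", last_alive=dt.date(2015, 3, 3 + i))
             for i in range(5)],
            STUDY_END,
        )
        path = tmp_path / "tte.csv"
        write_tte_csv(built.records, path)
        back = read_tte_csv(path)
        assert back == built.records
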
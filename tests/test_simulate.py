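"""Synthetic-data generator: death times, monitoring processes, determinism."""

import datetime as dt
import math

import numpy as np
import pytest

from incsurv.records import group_fields, group_index, records_to_frame
from incsurv.simulate import (
    MortalityPulse,
    SimulationConfig,
    TruthRecord,
    generate_dataset,
    simulate_death_times,
    simulate_incidental_encounters,
    simulate_radio_monitoring,
)
from incsurv.tte import DEATH, RIGHT_CENSORED, build_time_to_event


def _entries(n, group=0, entry=dt.date(2014, 10, 1)):
    return [(f"e-{i}", group, entry) for i in range(n)]


class TestDeathTimes:
    def test_tiny_hazard_everyone_survives(self, rng):
        cfg = SimulationConfig(true_weekly_hazard=(1e-9,) * 8)
        truths = simulate_death_times(cfg, _entries(200), rng)
        assert all(t.death is None for t in truths)

    def test_one_year_half_life_kills_about_half_within_a_year(self, rng):
        lam = math.log(2) / 52
        cfg = SimulationConfig(
            true_weekly_hazard=(lam,) * 8, study_end=dt.date(2030, 1, 1),
            resident_capture_end=dt.date(2015, 12, 31),
        )
        n = 2000
        truths = simulate_death_times(cfg, _entries(n), rng)
        entry = dt.date(2014, 10, 1)
        within_year = sum(
            t.death is not None and (t.death - entry).days <= 364 for t in truths
        )
        # binomial(2000, 0.5): 4 sigma ~ 45
        assert abs(within_year - n / 2) < 4.5 * math.sqrt(n * 0.25)

    def test_pulse_concentrates_deaths_in_window(self, rng):
        pulse = MortalityPulse(
            start=dt.date(2015, 3, 1), end=dt.date(2015, 8, 31), multiplier=10.0
        )
        cfg = SimulationConfig(
            true_weekly_hazard=(0.002,) * 8, pulse=pulse
        )
        truths = simulate_death_times(cfg, _entries(3000), rng)
        deaths = [t.death for t in truths if t.death is not None]
        in_window = sum(pulse.start <= d <= pulse.end for d in deaths)
        # window is ~26 of ~187 study weeks but carries 10x hazard; the
        # piecewise-exponential CDF puts the clear majority of deaths there
        assert in_window / len(deaths) > 0.6

    def test_pulse_only_applies_to_its_sites(self, rng):
        pulse = MortalityPulse(
            start=dt.date(2015, 3, 1),
            end=dt.date(2015, 8, 31),
            multiplier=10.0,
            sites=("north",),
        )
        cfg = SimulationConfig(true_weekly_hazard=(0.002,) * 8, pulse=pulse)
        north = group_index("translocated", "adult", "north")
        south = group_index("translocated", "adult", "south")
        tn = simulate_death_times(cfg, _entries(1500, group=north), rng)
        ts = simulate_death_times(cfg, _entries(1500, group=south), rng)
        died_n = sum(t.death is not None for t in tn)
        died_s = sum(t.death is not None for t in ts)
        assert died_n > 1.5 * died_s


class TestRadioMonitoring:
    cfg = SimulationConfig()

    def test_survivor_right_censored_near_study_end(self):
        tr = TruthRecord("a", 0, dt.date(2014, 10, 1), None)
        (rec,) = simulate_radio_monitoring([tr], self.cfg)
        assert rec.first_dead is None
        # last relocation is within one winter interval of study end
        assert (self.cfg.study_end - rec.last_alive).days <= 28

    def test_active_season_death_bracketed_within_a_week(self):
        tr = TruthRecord("a", 0, dt.date(2015, 3, 10), dt.date(2015, 6, 20))
        (rec,) = simulate_radio_monitoring([tr], self.cfg)
        assert rec.last_alive < tr.death <= rec.first_dead
        assert (rec.first_dead - rec.last_alive).days <= 7

    def test_winter_adult_death_gap_up_to_a_month(self):
        tr = TruthRecord("a", 0, dt.date(2014, 10, 1), dt.date(2014, 12, 20))
        (rec,) = simulate_radio_monitoring([tr], self.cfg)
        gap = (rec.first_dead - rec.last_alive).days
        assert 7 < gap <= 28

    def test_juvenile_winter_cadence_is_twice_monthly(self):
        j = group_index("translocated", "juvenile", "north")
        tr = TruthRecord("a", j, dt.date(2014, 10, 1), dt.date(2014, 12, 20))
        (rec,) = simulate_radio_monitoring([tr], self.cfg)
        assert (rec.first_dead - rec.last_alive).days <= 14


class TestIncidentalEncounters:
    def test_zero_rate_leaves_only_single_encounters(self, rng):
        cfg = SimulationConfig(encounter_rate_median=0.0, p_dead_found=0.0)
        truths = [TruthRecord(f"a{i}", 0, dt.date(2014, 10, 1), None) for i in range(20)]
        recs = simulate_incidental_encounters(truths, cfg, rng)
        built = build_time_to_event(recs, cfg.study_end)
        assert built.n_excluded == 20 and len(built.records) == 0

    def test_dead_never_found_means_all_censored(self, rng):
        cfg = SimulationConfig(p_dead_found=0.0, encounter_rate_median=0.2)
        truths = [
            TruthRecord(f"a{i}", 0, dt.date(2014, 10, 1), dt.date(2015, 10, 1))
            for i in range(50)
        ]
        recs = simulate_incidental_encounters(truths, cfg, rng)
        assert all(r.first_dead is None for r in recs)
        built = build_time_to_event(recs, cfg.study_end)
        assert all(r.event == RIGHT_CENSORED for r in built.records)

    def test_intense_sampling_with_certain_recovery_matches_known_fate(self, rng):
        """With every death recovered and very frequent sightings, the
        mark-encounter censoring proportion approaches the known-fate one."""
        cfg = SimulationConfig(p_dead_found=1.0, encounter_rate_median=5.0)
        rng2 = np.random.default_rng(7)
        truths = simulate_death_times(cfg, _entries(400), rng2)
        me = simulate_incidental_encounters(truths, cfg, rng)
        radio = simulate_radio_monitoring(truths, cfg)
        built_me = build_time_to_event(me, cfg.study_end)
        built_r = build_time_to_event(radio, cfg.study_end)
        prop_me = np.mean([r.event == RIGHT_CENSORED for r in built_me.records])
        prop_r = np.mean([r.event == RIGHT_CENSORED for r in built_r.records])
        assert abs(prop_me - prop_r) < 0.05

    def test_observation_dates_respect_truth(self, rng):
        cfg = SimulationConfig(p_dead_found=1.0, encounter_rate_median=0.1)
        truths = simulate_death_times(cfg, _entries(200), rng)
        for rec, tr in zip(simulate_incidental_encounters(truths, cfg, rng), truths):
            assert rec.first_observed == tr.entry
            assert rec.last_alive >= tr.entry
            if tr.death is not None:
                assert rec.last_alive <= tr.death


class TestGenerateDataset:
    def test_default_cohort_sizes_and_counts(self):
        records, truths = generate_dataset(seed=0)
        frame = records_to_frame(records)
        translocated = frame[frame.residency == "translocated"]
        releases = translocated.first_observed.value_counts()
        assert releases["2014-10-01"] == 110
        assert releases["2015-04-15"] == 22
        assert releases["2016-10-15"] == 3
        assert releases["2017-09-15"] == 18
        assert len(records) == 221
        assert (frame.method == "radiotelemetry").sum() == 139
        assert (frame.method == "mark_encounter").sum() == 82

    def test_same_seed_identical_output(self):
        a, ta = generate_dataset(seed=9)
        b, tb = generate_dataset(seed=9)
        assert a == b and ta == tb

    def test_different_seed_differs(self):
        a, _ = generate_dataset(seed=9)
        b, _ = generate_dataset(seed=10)
        assert a != b

    def test_zero_mark_encounter_reduces_to_radio_only(self):
        cfg = SimulationConfig(mark_encounter_counts=(0,) * 8)
        records, _ = generate_dataset(cfg, seed=1)
        assert all(r.method == "radiotelemetry" for r in records)

    def test_truth_consistency(self):
        cfg = SimulationConfig()
        records, truths = generate_dataset(cfg, seed=2)
        by_id = {t.individual_id: t for t in truths}
        for r in records:
            t = by_id[r.individual_id]
            assert t.group == group_index(r.residency, r.age_class, r.site)
            assert t.death is None or t.death <= cfg.study_end

    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ValueError):
            generate_dataset(SimulationConfig(p_dead_found=1.5), seed=0)
        with pytest.raises(ValueError):
            generate_dataset(
                SimulationConfig(true_weekly_hazard=(0.0,) * 8), seed=0
            )
        with pytest.raises(ValueError):
            MortalityPulse(dt.date(2015, 1, 1), dt.date(2015, 6, 1), 0.5)
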
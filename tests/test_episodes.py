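from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from adtrends.config import StudyConfig
from adtrends.drugs import classify_table
from adtrends.episodes import (
    build_episodes,
    classify_duration,
    compute_product_medians,
    duration_labels,
    flag_incident,
    prescription_duration,
    stitch_episodes,
)
from conftest import brute_force_episodes, make_patients, make_therapy, random_rx_stream


class TestProductMedians:
    def test_median_over_instruction_complete_scripts(self):
        rx = make_therapy(
            [
                ("a", date(2000, 1, 1), "fluoxetine", 20.0, 28, 1.0),
                ("a", date(2000, 2, 1), "fluoxetine", 20.0, 28, 1.0),
                ("b", date(2000, 3, 1), "fluoxetine", 20.0, 56, 1.0),
                ("b", date(2000, 4, 1), "fluoxetine", 20.0, 99, None),  # no instruction
            ]
        )
        assert compute_product_medians(rx) == {"fluoxetine": 28.0}

    def test_empty_input_gives_empty_map(self):
        assert compute_product_medians(make_therapy([])) == {}

    def test_singleton_median(self):
        rx = make_therapy([("a", date(2000, 1, 1), "sertraline", 50.0, 30, 1.0)])
        assert compute_product_medians(rx) == {"sertraline": 30.0}


class TestPrescriptionDuration:
    def test_instruction_arithmetic(self):
        rx = {"product_name": "citalopram", "quantity": 56, "units_per_day": 2.0}
        assert prescription_duration(rx, {}) == 28

    def test_one_unit_per_day(self):
        rx = {"product_name": "citalopram", "quantity": 28, "units_per_day": 1.0}
        assert prescription_duration(rx, {}) == 28

    def test_missing_instruction_uses_product_median(self):
        rx = {"product_name": "citalopram", "quantity": 28, "units_per_day": None}
        assert prescription_duration(rx, {"citalopram": 30.0}) == 30

    def test_missing_product_falls_back_to_global_median(self):
        rx = {"product_name": "citalopram", "quantity": 28, "units_per_day": None}
        assert prescription_duration(rx, {"fluoxetine": 28.0, "dosulepin": 56.0}) == 42

    def test_rounding_half_up_with_floor_one(self):
        assert prescription_duration(
            {"product_name": "x", "quantity": 7, "units_per_day": 2.0}, {}
        ) == 4  # 3.5 rounds up
        assert prescription_duration(
            {"product_name": "x", "quantity": 1, "units_per_day": 3.0}, {}
        ) == 1  # floored at one day


class TestStitching:
    def test_sub_threshold_gap_merges_into_one_episode(self, study):
        eps = stitch_episodes(
            [date(2000, 1, 1), date(2000, 4, 10)], [30, 30], study
        )  # 70-day gap < 4 months
        assert len(eps) == 1
        start, end, n = eps[0]
        assert (end - start).days == 130 and n == 2

    def test_four_month_gap_opens_a_new_episode(self, study):
        # expected end Jan 31; threshold May 31; second issue Jun 9
        eps = stitch_episodes([date(2000, 1, 1), date(2000, 6, 9)], [30, 30], study)
        assert len(eps) == 2

    def test_gap_boundary_is_strict(self, study):
        # expected end 2000-01-31 + 4 months = 2000-05-31: same day -> new episode
        assert len(stitch_episodes([date(2000, 1, 1), date(2000, 5, 31)], [30, 30], study)) == 2
        assert len(stitch_episodes([date(2000, 1, 1), date(2000, 5, 30)], [30, 30], study)) == 1

    def test_single_script(self, study):
        eps = stitch_episodes([date(2000, 3, 1)], [28], study)
        assert eps == [(date(2000, 3, 1), date(2000, 3, 29), 1)]

    def test_overlapping_scripts_extend_not_sum(self, study):
        # second script issued while the first still runs; end extends to
        # max(ends), not the sum of durations
        eps = stitch_episodes([date(2000, 1, 1), date(2000, 1, 15)], [60, 10], study)
        assert len(eps) == 1
        start, end, _ = eps[0]
        assert (end - start).days == 60

    def test_agrees_with_brute_force_oracle_on_random_streams(self, study):
        rng = np.random.default_rng(7)
        for _ in range(300):
            dates, durs = random_rx_stream(rng)
            got = [
                (s, e, n) for s, e, n in stitch_episodes(dates, durs, study)
            ]
            assert sorted(got) == brute_force_episodes(dates, durs, study)

    def test_idempotent_on_its_own_episode_intervals(self, study):
        rng = np.random.default_rng(21)
        for _ in range(100):
            dates, durs = random_rx_stream(rng)
            eps = stitch_episodes(dates, durs, study)
            again = stitch_episodes(
                [s for s, _, _ in eps], [(e - s).days for s, e, _ in eps], study
            )
            assert [(s, e) for s, e, _ in again] == [(s, e) for s, e, _ in eps]

    def test_wider_gap_never_increases_episode_count(self, study):
        rng = np.random.default_rng(40)
        wider = StudyConfig(gap_months=6)
        days30 = StudyConfig(gap_days=30)
        for _ in range(100):
            dates, durs = random_rx_stream(rng)
            n4 = len(stitch_episodes(dates, durs, study))
            assert len(stitch_episodes(dates, durs, wider)) <= n4
            assert len(stitch_episodes(dates, durs, days30)) >= n4

    def test_cross_product_scripts_stitch_together(self, study):
        rx = classify_table(
            make_therapy(
                [
                    ("a", date(2000, 1, 1), "fluoxetine", 20.0, 28, 1.0),
                    ("a", date(2000, 2, 1), "mirtazapine", 30.0, 28, 1.0),
                ]
            )
        )
        eps = build_episodes(rx, study)
        assert len(eps) == 1
        assert eps.loc[0, "classes_present"] == "OTHER+SSRI"
        assert eps.loc[0, "first_class"] == "SSRI"

    def test_build_episodes_censors_at_data_end(self, study):
        rx = classify_table(
            make_therapy([("a", date(2011, 12, 20), "fluoxetine", 20.0, 84, 1.0)])
        )
        eps = build_episodes(rx, study)
        assert eps.loc[0, "duration_days"] == 12  # Dec 20 to Jan 1


class TestDurationCategories:
    @pytest.mark.parametrize(
        "days, label",
        [
            (1, "<=30"),
            (30, "<=30"),
            (31, "31-60"),
            (60, "31-60"),
            (61, "61-180"),
            (180, "61-180"),
            (181, "181-365"),
            (365, "181-365"),
            (366, "366-730"),
            (730, "366-730"),
            (731, "731+"),
            (5000, "731+"),
        ],
    )
    def test_bin_boundaries(self, study, days, label):
        assert classify_duration(days, study) == label

    def test_categories_partition_positive_integers(self, study):
        labels = duration_labels(study)
        seen = [classify_duration(d, study) for d in range(1, 1000)]
        assert set(seen) == set(labels)
        # monotone: category index never decreases with duration
        idx = [labels.index(c) for c in seen]
        assert all(a <= b for a, b in zip(idx, idx[1:]))


class TestIncidentFlag:
    def _episodes(self, study, starts, pid="p1"):
        rx = classify_table(
            make_therapy(
                [(pid, d, "fluoxetine", 20.0, 28, 1.0) for d in starts]
            )
        )
        return build_episodes(rx, study)

    def test_first_episode_with_lookback_is_incident(self, study):
        pats = make_patients([("p1", "F", date(1960, 1, 1), date(1996, 1, 1), None)])
        eps = flag_incident(self._episodes(study, [date(2000, 7, 10)]), pats, study)
        assert eps["incident"].tolist() == [True]

    def test_second_episode_is_never_incident(self, study):
        pats = make_patients([("p1", "F", date(1960, 1, 1), date(1996, 1, 1), None)])
        eps = flag_incident(
            self._episodes(study, [date(2000, 7, 10), date(2003, 7, 10)]), pats, study
        )
        assert eps["incident"].tolist() == [True, False]

    def test_first_episode_without_lookback_is_not_incident(self, study):
        pats = make_patients([("p1", "F", date(1960, 1, 1), date(1998, 9, 1), None)])
        eps = flag_incident(self._episodes(study, [date(2000, 7, 10)]), pats, study)
        assert eps["incident"].tolist() == [False]

    def test_unknown_patient_raises(self, study):
        pats = make_patients([("p2", "F", date(1960, 1, 1), date(1996, 1, 1), None)])
        with pytest.raises(ValueError, match="unknown patient"):
            flag_incident(self._episodes(study, [date(2000, 7, 10)]), pats, study)
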
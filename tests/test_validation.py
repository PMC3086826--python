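"""Gold-standard sensitivity, episode matching, Wilson intervals."""

import math
import random
from datetime import date, timedelta

import pytest

from steplink import (ConfirmedEvent, Episode, Link, LinkageResult,
                      SensitivityReport, episode_matches, ground_truth_metrics,
                      sensitivity_analysis, wilson_ci)


def event(**overrides):
    base = dict(study_id="S1", hospital_name="ALFRED HOSPITAL",
                admission_date=date(2001, 3, 10),
                discharge_date=date(2001, 3, 15), event_type="AMI")
    base.update(overrides)
    return ConfirmedEvent(**base)


def episode(**overrides):
    base = dict(person_id="H1", hospital_name="ALFRED HOSPITAL",
                admission_date=date(2001, 3, 10),
                discharge_date=date(2001, 3, 15), event_flag="AMI")
    base.update(overrides)
    return Episode(**base)


class TestEpisodeMatches:
    def test_within_window_both_dates(self):
        ep = episode(admission_date=date(2001, 3, 13),
                     discharge_date=date(2001, 3, 17))
        assert episode_matches(event(), ep)

    @pytest.mark.parametrize("offset, expected", [(10, True), (11, False)])
    def test_ten_day_boundary_is_inclusive(self, offset, expected):
        shifted = episode(
            admission_date=date(2001, 3, 10) + timedelta(days=offset),
            discharge_date=date(2001, 3, 15) + timedelta(days=offset))
        assert episode_matches(event(), shifted) is expected

    def test_different_hospital_never_matches(self):
        assert not episode_matches(event(),
                                   episode(hospital_name="AUSTIN HOSPITAL"))

    def test_hospital_names_compared_canonically(self):
        assert episode_matches(event(hospital_name="St Vincent's  Hospital"),
                               episode(hospital_name="ST VINCENTS HOSPITAL"))

    def test_missing_gold_discharge_skips_discharge_comparison(self):
        ep = episode(discharge_date=date(2001, 6, 1),
                     admission_date=date(2001, 3, 10))
        assert episode_matches(event(discharge_date=None), ep)

    def test_widening_window_is_monotone(self):
        rng = random.Random(3)
        events = [event(admission_date=date(2001, 3, 10)
                        + timedelta(days=rng.randint(-30, 30)))
                  for _ in range(40)]
        eps = [episode()]
        counts = [sum(episode_matches(e, eps[0], window_days=w)
                      for e in events) for w in (0, 5, 10, 20, 40)]
        assert counts == sorted(counts)


class TestSensitivity:
    def test_published_scale_counts(self):
        """101 confirmed, 98 linked, 94 corroborated: sensitivity 93%,
        non-matched rate 4%, Wilson interval 86%-97%."""
        report = SensitivityReport(n_confirmed=101, n_linked=98, n_correct=94)
        assert report.sensitivity == pytest.approx(94 / 101)
        assert round(report.sensitivity * 100) == 93
        assert report.n_incorrect == 4
        assert round(report.non_matched_rate * 100) == 4
        lower, upper = report.ci95
        assert round(lower, 2) == 0.86
        assert round(upper, 2) == 0.97

    def test_all_matched_gives_one(self):
        result = LinkageResult("p", 2, links=[Link("S1", "H1", 1),
                                              Link("S2", "H2", 1)])
        eps = [episode(), episode(person_id="H2")]
        events = [event(), event(study_id="S2")]
        report = sensitivity_analysis(events, result, eps)
        assert report.sensitivity == 1.0

    def test_unlinked_and_uncorroborated_events_counted(self):
        result = LinkageResult("p", 3, links=[Link("S1", "H1", 1),
                                              Link("S2", "H2", 1)],
                               unmatched_cohort_ids=["S3"])
        eps = [episode(),  # corroborates S1
               episode(person_id="H2", hospital_name="AUSTIN HOSPITAL")]
        events = [event(), event(study_id="S2"), event(study_id="S3")]
        report = sensitivity_analysis(events, result, eps)
        assert (report.n_confirmed, report.n_linked, report.n_correct) == (3, 2, 1)
        assert report.n_incorrect == 1

    def test_invariant_to_event_and_episode_order(self):
        result = LinkageResult("p", 2, links=[Link("S1", "H1", 1),
                                              Link("S2", "H2", 1)])
        eps = [episode(), episode(person_id="H2"),
               episode(person_id="H1", hospital_name="MERCY HOSPITAL")]
        events = [event(), event(study_id="S2")]
        forward = sensitivity_analysis(events, result, eps)
        backward = sensitivity_analysis(events[::-1], result, eps[::-1])
        assert forward == backward

    def test_zero_error_world_has_perfect_sensitivity(
            self, zero_error_world, secret):
        from steplink import plan_final, run_plan
        result = run_plan(zero_error_world.cohort, zero_error_world.hospital,
                          plan_final(), secret)
        report = sensitivity_analysis(zero_error_world.truth_events, result,
                                      zero_error_world.episodes)
        assert report.sensitivity == 1.0


def _wilson_direct(successes, n, z=1.959963984540054):
    p = successes / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return centre - half, centre + half


class TestWilson:
    @pytest.mark.parametrize("successes, n", [(94, 101), (5, 10), (1, 30),
                                              (29, 30), (50, 200)])
    def test_agrees_with_direct_formula(self, successes, n):
        lower, upper = wilson_ci(successes, n)
        expected = _wilson_direct(successes, n)
        assert lower == pytest.approx(expected[0], abs=1e-9)
        assert upper == pytest.approx(expected[1], abs=1e-9)

    def test_zero_successes_lower_bound_is_zero(self):
        lower, _ = wilson_ci(0, 10)
        assert lower == 0.0

    def test_endpoints_bracket_point_estimate(self):
        for s, n in [(0, 10), (3, 7), (7, 7), (94, 101)]:
            lower, upper = wilson_ci(s, n)
            assert 0.0 <= lower <= s / n <= upper <= 1.0

    def test_approaches_normal_interval_at_large_n(self):
        n, s = 10_000, 4_321
        lower, upper = wilson_ci(s, n)
        p = s / n
        half = 1.959963984540054 * math.sqrt(p * (1 - p) / n)
        assert abs(lower - (p - half)) < 0.01
        assert abs(upper - (p + half)) < 0.01

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(5, 3)


class TestGroundTruthMetrics:
    TRUTH = [(f"S{i}", f"H{i}") for i in range(10)]

    def test_perfect_result(self):
        result = LinkageResult("p", 10,
                               links=[Link(s, p, 1) for s, p in self.TRUTH])
        metrics = ground_truth_metrics(result, self.TRUTH)
        assert metrics == {"sensitivity": 1.0, "ppv": 1.0,
                           "false_match_rate": 0.0, "missed_match_rate": 0.0}

    def test_empty_result(self):
        result = LinkageResult("p", 10,
                               unmatched_cohort_ids=[s for s, _ in self.TRUTH])
        metrics = ground_truth_metrics(result, self.TRUTH)
        assert metrics["sensitivity"] == 0.0
        assert metrics["missed_match_rate"] == 1.0

    def test_planted_false_match_gives_ppv(self):
        links = [Link(s, p, 1) for s, p in self.TRUTH[:9]]
        links.append(Link("S9", "H0X", 2))  # wrong person
        result = LinkageResult("p", 10, links=links)
        metrics = ground_truth_metrics(result, self.TRUTH)
        assert metrics["ppv"] == pytest.approx(0.9)
        assert metrics["false_match_rate"] == pytest.approx(0.1)
        assert metrics["sensitivity"] == pytest.approx(0.9)

    def test_non_one_to_one_truth_rejected(self):
        with pytest.raises(ValueError):
            ground_truth_metrics(LinkageResult("p", 2),
                                 [("S1", "H1"), ("S1", "H2")])
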
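"""Shipped plan construction, expansion rules, and config round-trips."""

from itertools import combinations
from pathlib import Path

import pytest

from steplink import (HospitalPerson, PersonRecord, SelectorKind, load_plan,
                      plan_final, plan_v1, plan_v2, plan_v2_plus_suffix,
                      run_plan, save_plan, shipped_plan)

DATA = Path(__file__).parent / "data"
K = SelectorKind


def kinds(spec):
    return [sel.kind for sel in spec.selectors]


class TestPlanV1:
    def test_ten_iterations(self):
        assert len(plan_v1()) == 10

    def test_first_iteration_is_stem_plus_suffix(self):
        assert kinds(plan_v1().iterations[0]) == [K.MEDICARE8, K.SUFFIX_FULL]

    def test_suffix_letter_variants_in_rows_2_to_4(self):
        positions = [spec.selectors[1].positions
                     for spec in plan_v1().iterations[1:4]]
        assert positions == [(1, 2), (2, 3), (1, 3)]

    def test_fifth_iteration_is_stem_year_sex(self):
        assert kinds(plan_v1().iterations[4]) == [K.MEDICARE8, K.YEAR, K.SEX]

    def test_demographic_postcode_sweep_then_fallback(self):
        slots = [spec.selectors[-1].slot for spec in plan_v1().iterations[5:9]]
        assert slots == [1, 2, 3, 4]
        last = plan_v1().iterations[9]
        assert kinds(last) == [K.YEAR, K.MONTH, K.DAY, K.SEX, K.COB,
                               K.POSTCODE_SLOT]


class TestPlanV2:
    def test_four_iterations_differing_only_in_postcode_slot(self):
        plan = plan_v2()
        assert len(plan) == 4
        for k, spec in enumerate(plan.iterations, start=1):
            assert kinds(spec) == [K.YEAR, K.MONTH, K.DAY, K.SEX, K.COB,
                                   K.POSTCODE_SLOT]
            assert spec.selectors[-1].slot == k

    def test_no_medicare_or_suffix_anywhere(self):
        for spec in plan_v2().iterations:
            assert not spec.uses(K.MEDICARE8)
            assert not spec.uses(K.SUFFIX_FULL)
            assert not spec.uses(K.SUFFIX_LETTERS)


class TestPlanV2PlusSuffix:
    def test_each_iteration_gains_the_full_suffix(self):
        plan = plan_v2_plus_suffix()
        assert len(plan) == 4
        for spec in plan.iterations:
            assert kinds(spec) == [K.SUFFIX_FULL, K.YEAR, K.MONTH, K.DAY,
                                   K.SEX, K.COB, K.POSTCODE_SLOT]

    def test_suffix_suppresses_demographic_twin_false_match(self):
        """A demographic twin steals the match when the true record's
        slot-1 postcode changed; adding the suffix prevents it."""
        member = PersonRecord("A", "Alison", "12345678", "ALI", 1950, 6, 15,
                              "F", "AUSTRALIA", ("3000",))
        true_person = HospitalPerson("X", "12345678", "ALI", 1950, 6, 15,
                                     "F", "AUSTRALIA", ("3888", "3000"))
        twin = HospitalPerson("Y", "99999999", "BET", 1950, 6, 15,
                              "F", "AUSTRALIA", ("3000",))
        hospital = [true_person, twin]
        with_demographics = run_plan([member], hospital, plan_v2(), b"s")
        with_suffix = run_plan([member], hospital, plan_v2_plus_suffix(), b"s")
        assert with_demographics.links_by_study_id() == {"A": "Y"}  # false
        assert with_suffix.links_by_study_id() == {}
        assert with_suffix.n_linked < with_demographics.n_linked


class TestPlanFinal:
    def test_first_iteration_is_the_full_key(self):
        first = plan_final().iterations[0]
        assert kinds(first) == [K.MEDICARE8, K.SUFFIX_FULL, K.YEAR, K.MONTH,
                                K.DAY, K.SEX, K.COB, K.POSTCODE_SLOT]
        assert first.selectors[-1].slot == 1

    def test_generated_iteration_count(self):
        assert len(plan_final()) == 174

    def test_last_stage_has_no_medicare(self):
        suffix_stage = [spec for spec in plan_final().iterations
                        if spec.label.startswith("C")]
        assert len(suffix_stage) == 4
        assert plan_final().iterations[-4:] == tuple(suffix_stage)
        for spec in suffix_stage:
            assert not spec.uses(K.MEDICARE8)
            assert spec.uses(K.SUFFIX_FULL)

    def test_never_more_than_two_demographics_dropped(self):
        # the demographic set is {year, month, day, sex, cob, postcode}
        for spec in plan_final().iterations:
            present = sum(spec.uses(k) for k in (K.YEAR, K.MONTH, K.DAY,
                                                 K.SEX, K.COB,
                                                 K.POSTCODE_SLOT))
            assert present >= 4

    def test_anchors_never_dropped_within_their_stage(self):
        for spec in plan_final().iterations:
            stage = spec.label[0]
            if stage == "A":
                assert spec.uses(K.MEDICARE8)
                assert spec.uses(K.SUFFIX_FULL) or spec.uses(K.SUFFIX_LETTERS)
            elif stage == "B":
                assert spec.uses(K.MEDICARE8)
                assert not (spec.uses(K.SUFFIX_FULL)
                            or spec.uses(K.SUFFIX_LETTERS))
            else:
                assert not spec.uses(K.MEDICARE8)

    def test_no_duplicate_selector_sets(self):
        sets = [frozenset(spec.selectors) for spec in plan_final().iterations]
        assert len(set(sets)) == len(sets)

    def test_drop_two_covers_all_pairs_once(self):
        # within stage A, drop-two with the full suffix: postcode pairs
        # collapse to single iterations, the rest sweep four slots
        demo = {K.YEAR, K.MONTH, K.DAY, K.SEX, K.COB, K.POSTCODE_SLOT}
        drop_two = [spec for spec in plan_final().iterations
                    if spec.label.startswith("A")
                    and spec.uses(K.SUFFIX_FULL)
                    and sum(spec.uses(k) for k in demo) == 4]
        assert len(drop_two) == 5 * 1 + 10 * 4


@pytest.mark.parametrize("name", ["v1", "v2", "v2s", "final"])
class TestConfigFiles:
    def test_round_trip(self, name, tmp_path):
        plan = shipped_plan(name)
        path = tmp_path / f"{name}.yaml"
        save_plan(plan, path)
        assert load_plan(path) == plan

    def test_golden_expansion_pinned(self, name, tmp_path):
        """Regression-pin the shipped plans' full expansions."""
        path = tmp_path / f"{name}.yaml"
        save_plan(shipped_plan(name), path)
        assert path.read_text() == (DATA / f"plan_{name}.yaml").read_text()


class TestConfigValidation:
    def test_out_of_range_postcode_slot(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("label: bad\niterations:\n"
                        "- label: i1\n  selectors: [POSTCODE_SLOT(5)]\n")
        with pytest.raises(ValueError):
            load_plan(path)

    def test_unknown_selector_kind(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("label: bad\niterations:\n"
                        "- label: i1\n  selectors: [SOUNDEX]\n")
        with pytest.raises(ValueError):
            load_plan(path)

    def test_duplicate_iteration_labels(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("label: bad\niterations:\n"
                        "- label: i1\n  selectors: [SEX]\n"
                        "- label: i1\n  selectors: [COB]\n")
        with pytest.raises(ValueError):
            load_plan(path)

    def test_hand_written_two_iteration_config(self, tmp_path):
        path = tmp_path / "mini.yaml"
        path.write_text("label: mini\niterations:\n"
                        "- label: i1\n  selectors: [MEDICARE8, SUFFIX_FULL]\n"
                        "- label: i2\n  selectors: [YEAR, SEX, POSTCODE_SLOT(1)]\n")
        plan = load_plan(path)
        assert len(plan) == 2
        assert kinds(plan.iterations[0]) == [K.MEDICARE8, K.SUFFIX_FULL]
        assert plan.iterations[1].selectors[-1].slot == 1

    def test_unknown_shipped_name(self):
        with pytest.raises(ValueError):
            shipped_plan("v3")
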
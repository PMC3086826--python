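"""Synthetic paired cohort/hospital datasets with known ground truth.

The generator emulates the data conditions of a cohort-to-admissions
linkage with limited identifiers:

* every cohort participant appears once in the hospital person index
  (ground truth is the identity mapping), alongside a much larger pool of
  hospital-only distractor persons;
* the Medicare stem is present for all cohort records but missing for a
  configurable share of hospital records (default 20%);
* Medicare numbers are shared within families, and family members can
  collide on the 3-letter name suffix as well (CHRISTOPHER / CHRISTINE);
* hospital-side entry errors: birth-date day offsets of 2-10 days, gross
  year shifts of up to 40 years, postcode churn (a new postcode pushed
  into slot 1), country-of-birth discrepancies, sex miscodes, and suffixes
  derived from a middle name instead of the given name;
* demographic "twins" — hospital-only persons sharing a cohort member's
  full date of birth, sex, country of birth and postcodes — which is the
  false-positive mode a demographics-only plan is exposed to.

All randomness flows through one ``numpy`` generator seeded by the
caller, so worlds are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from datetime import date, timedelta
from pathlib import Path
import csv

import numpy as np

from .records import (Episode, HospitalPerson, PersonRecord, derive_suffix,
                      write_cohort, write_episodes, write_hospital)
from .validation import ConfirmedEvent, write_confirmed_events

__all__ = ["ErrorModel", "SyntheticWorld", "generate", "inject_twins"]


# given names; the paired ones share a 3-letter prefix across sexes and are
# used to build family suffix collisions
_PAIRED_NAMES = [
    ("CHRISTOPHER", "CHRISTINE"), ("ALEXANDER", "ALEXANDRA"),
    ("SAMUEL", "SAMANTHA"), ("PATRICK", "PATRICIA"),
    ("FRANCIS", "FRANCES"), ("GEORGE", "GEORGIA"),
    ("NICHOLAS", "NICOLA"), ("JOSEPH", "JOSEPHINE"),
    ("DANIEL", "DANIELLE"), ("GABRIEL", "GABRIELLE"),
    ("PAUL", "PAULA"), ("ANTONIO", "ANTONIA"),
]
_MALE_NAMES = [m for m, _ in _PAIRED_NAMES] + [
    "JOHN", "PETER", "ROBERT", "WILLIAM", "JAMES", "DAVID", "RICHARD",
    "THOMAS", "CHARLES", "KENNETH", "STEPHEN", "ANDREW", "BRIAN", "KEVIN",
    "RONALD", "GRAHAM", "IAN", "COLIN", "BARRY", "NEIL", "GIUSEPPE",
    "GIOVANNI", "DIMITRIOS", "STAVROS", "HENDRIK", "WOLFGANG", "MARTIN",
    "GERALD", "LAWRENCE", "FREDERICK", "ALBERT", "ERNEST", "NORMAN",
]
_FEMALE_NAMES = [f for _, f in _PAIRED_NAMES] + [
    "MARGARET", "HELEN", "DOROTHY", "JOAN", "BETTY", "SHIRLEY", "JUDITH",
    "PAMELA", "CAROL", "JANET", "SUSAN", "LINDA", "BARBARA", "JENNIFER",
    "ALISON", "KATHLEEN", "MAUREEN", "VALERIE", "GILLIAN", "MARIA",
    "GIOVANNA", "ELENI", "SOPHIA", "JOHANNA", "INGRID", "ELIZABETH",
    "CATHERINE", "VERONICA", "ROSEMARY", "FLORENCE", "GLADYS", "IRENE",
]
_COUNTRIES = ["AUSTRALIA", "ITALY", "GREECE", "UNITED KINGDOM", "MALTA",
              "NETHERLANDS", "GERMANY", "NEW ZEALAND"]
_COUNTRY_WEIGHTS = [0.62, 0.10, 0.08, 0.08, 0.04, 0.03, 0.03, 0.02]
_HOSPITALS = [
    "ROYAL MELBOURNE HOSPITAL", "ALFRED HOSPITAL", "AUSTIN HOSPITAL",
    "MONASH MEDICAL CENTRE", "ST VINCENTS HOSPITAL", "BOX HILL HOSPITAL",
    "FRANKSTON HOSPITAL", "GEELONG HOSPITAL", "WESTERN GENERAL HOSPITAL",
    "NORTHERN HOSPITAL", "DANDENONG HOSPITAL", "EPWORTH HOSPITAL",
    "CABRINI HOSPITAL", "KNOX PRIVATE HOSPITAL", "MERCY HOSPITAL",
    "BALLARAT BASE HOSPITAL",
]

_BIRTH_LO = date(1915, 1, 1).toordinal()
_BIRTH_HI = date(1975, 12, 31).toordinal()
_STUDY_LO = date(1996, 7, 31).toordinal()
_STUDY_HI = date(2008, 12, 31).toordinal()


@dataclass(frozen=True)
class ErrorModel:
    """Rates of the data-entry error and missingness modes, applied
    independently per hospital-side record.

    Defaults reflect the conditions the generator emulates: the Medicare
    stem is available for 100% of cohort and ~80% of hospital records;
    day-of-birth entry errors offset the date by 2-10 days; gross errors
    shift the year by up to 40 years.  Rates the source data never
    quantified (postcode churn, family sharing, ...) default to values
    realistic for a multi-decade administrative dataset and are plain
    knobs.
    """

    hospital_medicare_missing_rate: float = 0.20
    cohort_medicare_missing_rate: float = 0.0
    dob_day_error_rate: float = 0.02
    dob_gross_error_rate: float = 0.005
    postcode_change_rate: float = 0.10
    cob_discrepancy_rate: float = 0.01
    sex_miscode_rate: float = 0.005
    suffix_middle_name_rate: float = 0.02
    family_share_rate: float = 0.05
    medicare_change_rate: float = 0.0  # card changes on family-circumstance change
    twin_rate: float = 0.0
    hospital_only_population_multiplier: float = 2.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name == "hospital_only_population_multiplier":
                if value < 0:
                    raise ValueError("multiplier must be >= 0")
            elif not 0.0 <= value <= 1.0:
                raise ValueError(f"{f.name} must be in [0,1], got {value}")

    @classmethod
    def zero(cls) -> "ErrorModel":
        """All error rates zero and no distractor population: the hospital
        index is an exact copy of the cohort."""
        return cls(hospital_medicare_missing_rate=0.0, dob_day_error_rate=0.0,
                   dob_gross_error_rate=0.0, postcode_change_rate=0.0,
                   cob_discrepancy_rate=0.0, sex_miscode_rate=0.0,
                   suffix_middle_name_rate=0.0, family_share_rate=0.0,
                   twin_rate=0.0, hospital_only_population_multiplier=0.0)


@dataclass
class SyntheticWorld:
    cohort: list[PersonRecord]
    hospital: list[HospitalPerson]
    episodes: list[Episode]
    truth_links: list[tuple[str, str]]
    truth_events: list[ConfirmedEvent]

    def write_csvs(self, out_dir) -> None:
        """Write the three standard tables plus truth and confirmed-event
        CSVs into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(self.cohort, out / "cohort.csv")
        write_hospital(self.hospital, out / "hospital.csv")
        write_episodes(self.episodes, out / "episodes.csv")
        write_confirmed_events(self.truth_events, out / "events.csv")
        with (out / "truth.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["study_id", "person_id"])
            writer.writerows(self.truth_links)


# ---------------------------------------------------------------------------
# sampling helpers

def _random_date(rng, lo: int, hi: int) -> date:
    return date.fromordinal(int(rng.integers(lo, hi + 1)))


def _random_postcode(rng) -> str:
    return str(3000 + int(rng.integers(0, 1000)))


def _sample_postcodes(rng) -> tuple[str, ...]:
    n = int(rng.choice([1, 2, 3, 4], p=[0.55, 0.25, 0.13, 0.07]))
    out: list[str] = []
    while len(out) < n:
        pc = _random_postcode(rng)
        if pc not in out:
            out.append(pc)
    return tuple(out)


def _given_name(rng, sex: str) -> str:
    pool = _MALE_NAMES if sex == "M" else _FEMALE_NAMES
    return pool[int(rng.integers(0, len(pool)))]


def _shift_year(d: date, years: int) -> date:
    try:
        return d.replace(year=d.year + years)
    except ValueError:  # 29 Feb in a non-leap target year
        return d.replace(year=d.year + years, day=28)


@dataclass
class _Person:
    """Internal fully-identified person; projected onto the two sides."""

    sex: str
    given_name: str
    middle_name: str
    medicare8: str
    birth: date
    cob: str
    postcodes: tuple[str, ...]


def _sample_person(rng, medicare_iter) -> _Person:
    sex = "M" if rng.random() < 0.5 else "F"
    return _Person(
        sex=sex,
        given_name=_given_name(rng, sex),
        middle_name=_given_name(rng, sex),
        medicare8=next(medicare_iter),
        birth=_random_date(rng, _BIRTH_LO, _BIRTH_HI),
        cob=str(rng.choice(_COUNTRIES, p=_COUNTRY_WEIGHTS)),
        postcodes=_sample_postcodes(rng),
    )


def _hospital_view(rng, person: _Person, person_id: str,
                   model: ErrorModel) -> HospitalPerson:
    """Project a person onto the hospital index, applying entry errors."""
    medicare = person.medicare8
    if rng.random() < model.hospital_medicare_missing_rate:
        medicare = None
    elif rng.random() < model.medicare_change_rate:
        medicare = f"{int(rng.integers(10_000_000, 100_000_000)):08d}"

    name = person.given_name
    if rng.random() < model.suffix_middle_name_rate:
        name = person.middle_name
    suffix = derive_suffix(name)

    birth = person.birth
    if rng.random() < model.dob_day_error_rate:
        offset = int(rng.integers(2, 11)) * (1 if rng.random() < 0.5 else -1)
        birth = birth + timedelta(days=offset)
    if rng.random() < model.dob_gross_error_rate:
        shift = int(rng.integers(1, 41)) * (1 if rng.random() < 0.5 else -1)
        birth = _shift_year(birth, shift)

    sex = person.sex
    if rng.random() < model.sex_miscode_rate:
        sex = "F" if sex == "M" else "M"

    cob = person.cob
    if rng.random() < model.cob_discrepancy_rate:
        others = [c for c in _COUNTRIES if c != cob]
        cob = others[int(rng.integers(0, len(others)))]

    postcodes = person.postcodes
    if rng.random() < model.postcode_change_rate:
        new_pc = _random_postcode(rng)
        while new_pc in postcodes:
            new_pc = _random_postcode(rng)
        postcodes = (new_pc, *postcodes)[:4]

    return HospitalPerson(
        person_id=person_id, medicare8=medicare, suffix=suffix,
        birth_year=birth.year, birth_month=birth.month, birth_day=birth.day,
        sex=sex, country_of_birth=cob, postcodes=postcodes)


def _family_member(rng, person: _Person, person_id: str,
                   model: ErrorModel) -> HospitalPerson:
    """A hospital-only relative sharing the Medicare stem — and, half the
    time, the 3-letter suffix (the family-mismatch mode)."""
    if rng.random() < 0.5:
        suffix = derive_suffix(person.given_name)
    else:
        suffix = derive_suffix(_given_name(rng, person.sex))
    birth = _shift_year(person.birth,
                        int(rng.integers(1, 8)) * (1 if rng.random() < 0.5 else -1))
    medicare = person.medicare8
    if rng.random() < model.hospital_medicare_missing_rate:
        medicare = None
    return HospitalPerson(
        person_id=person_id, medicare8=medicare, suffix=suffix,
        birth_year=birth.year, birth_month=birth.month, birth_day=birth.day,
        sex="M" if rng.random() < 0.5 else "F",
        country_of_birth=person.cob,
        postcodes=person.postcodes[:1] or (),
    )


def _twin_of(record: PersonRecord, person_id: str, rng,
             medicare_iter) -> HospitalPerson:
    """A hospital-only demographic twin of a cohort member: same date of
    birth, sex, country of birth and postcodes; different name and card."""
    suffix = record.suffix
    twin_suffix = suffix
    while twin_suffix == suffix:
        twin_suffix = derive_suffix(_given_name(rng, record.sex))
    return HospitalPerson(
        person_id=person_id, medicare8=next(medicare_iter), suffix=twin_suffix,
        birth_year=record.birth_year, birth_month=record.birth_month,
        birth_day=record.birth_day, sex=record.sex,
        country_of_birth=record.country_of_birth, postcodes=record.postcodes)


def _episodes_for(rng, person_id: str, n: int) -> list[Episode]:
    out = []
    for _ in range(n):
        admission = _random_date(rng, _STUDY_LO, _STUDY_HI - 15)
        stay = int(rng.integers(0, 15))
        hospital = _HOSPITALS[int(rng.integers(0, len(_HOSPITALS)))]
        out.append(Episode(person_id=person_id, hospital_name=hospital,
                           admission_date=admission,
                           discharge_date=admission + timedelta(days=stay)))
    return out


# ---------------------------------------------------------------------------
# public API

def generate(n_cohort: int, model: ErrorModel | None = None, seed: int = 0,
             confirmed_event_rate: float = 0.05) -> SyntheticWorld:
    """Generate a paired cohort/hospital world with ground truth.

    Every cohort participant has exactly one true hospital-side person;
    hospital-only distractors (relatives sharing the Medicare card,
    demographic twins, unrelated persons) are added per ``model``.  A
    ``confirmed_event_rate`` share of participants receive a cardiac or
    stroke admission recorded both as a hospital episode and as an
    independently confirmed event, supporting sensitivity analysis.

    Reproducible: the same ``(n_cohort, model, seed, rate)`` always yields
    the same world.
    """
    if n_cohort < 1:
        raise ValueError("n_cohort must be >= 1")
    model = model if model is not None else ErrorModel()
    rng = np.random.default_rng(seed)

    n_distract = round(model.hospital_only_population_multiplier * n_cohort)
    # unique Medicare stems for every card the world may need
    n_cards = n_cohort + n_distract + n_cohort  # cohort + distractors + twins
    cards = rng.choice(90_000_000, size=n_cards, replace=False) + 10_000_000
    medicare_iter = iter(f"{c:08d}" for c in cards)

    cohort: list[PersonRecord] = []
    hospital: list[HospitalPerson] = []
    truth_links: list[tuple[str, str]] = []
    persons: list[_Person] = []

    for i in range(n_cohort):
        person = _sample_person(rng, medicare_iter)
        persons.append(person)
        study_id, person_id = f"S{i:05d}", f"H{i:05d}"
        cohort_medicare = person.medicare8
        if rng.random() < model.cohort_medicare_missing_rate:
            cohort_medicare = None
        cohort.append(PersonRecord(
            study_id=study_id, given_name=person.given_name,
            medicare8=cohort_medicare, suffix=derive_suffix(person.given_name),
            birth_year=person.birth.year, birth_month=person.birth.month,
            birth_day=person.birth.day, sex=person.sex,
            country_of_birth=person.cob, postcodes=person.postcodes))
        hospital.append(_hospital_view(rng, person, person_id, model))
        truth_links.append((study_id, person_id))

    # relatives sharing the cohort member's Medicare card
    n_family = 0
    for i, person in enumerate(persons):
        if rng.random() < model.family_share_rate:
            hospital.append(_family_member(rng, person, f"F{n_family:05d}", model))
            n_family += 1

    # unrelated hospital-only persons
    for j in range(n_distract):
        distractor = _sample_person(rng, medicare_iter)
        hospital.append(_hospital_view(rng, distractor, f"D{j:05d}", model))

    # demographic twins of cohort members
    n_twin = 0
    for record in cohort:
        if rng.random() < model.twin_rate:
            hospital.append(_twin_of(record, f"T{n_twin:05d}", rng, medicare_iter))
            n_twin += 1

    # admission episodes for every hospital-side person
    episodes: list[Episode] = []
    for person_rec in hospital:
        episodes.extend(_episodes_for(rng, person_rec.person_id,
                                      int(rng.poisson(1.2))))

    # confirmed cardiovascular admissions for a sub-sample of the cohort
    truth_events: list[ConfirmedEvent] = []
    n_events = round(confirmed_event_rate * n_cohort)
    chosen = rng.choice(n_cohort, size=n_events, replace=False) if n_events else []
    for i in sorted(int(c) for c in np.asarray(chosen)):
        study_id, person_id = truth_links[i]
        admission = _random_date(rng, _STUDY_LO, _STUDY_HI - 15)
        stay = int(rng.integers(1, 15))
        hospital_name = _HOSPITALS[int(rng.integers(0, len(_HOSPITALS)))]
        event_type = "AMI" if rng.random() < 0.6 else "stroke"
        episodes.append(Episode(
            person_id=person_id, hospital_name=hospital_name,
            admission_date=admission,
            discharge_date=admission + timedelta(days=stay),
            event_flag=event_type))
        truth_events.append(ConfirmedEvent(
            study_id=study_id, hospital_name=hospital_name,
            admission_date=admission,
            discharge_date=admission + timedelta(days=stay),
            event_type=event_type))

    return SyntheticWorld(cohort=cohort, hospital=hospital, episodes=episodes,
                          truth_links=truth_links, truth_events=truth_events)


def inject_twins(world: SyntheticWorld, n_twins: int,
                 seed: int = 0) -> SyntheticWorld:
    """Return a copy of ``world`` with ``n_twins`` extra hospital-only
    persons, each duplicating a randomly chosen cohort member's date of
    birth, sex, country of birth and postcodes (but with a different name
    and Medicare card).  Ground truth is unchanged."""
    if n_twins > len(world.cohort):
        raise ValueError("n_twins exceeds cohort size")
    if n_twins == 0:
        return replace(world, hospital=list(world.hospital))
    rng = np.random.default_rng(seed)
    cards = rng.choice(90_000_000, size=n_twins, replace=False) + 10_000_000
    medicare_iter = iter(f"{c:08d}" for c in cards)
    chosen = rng.choice(len(world.cohort), size=n_twins, replace=False)
    twins = [_twin_of(world.cohort[int(i)], f"TW{k:05d}", rng, medicare_iter)
             for k, i in enumerate(sorted(int(c) for c in chosen))]
    return replace(world, hospital=list(world.hospital) + twins)
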
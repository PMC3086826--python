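"""Domain records, identifier normalisation, and delimited-file I/O.

The linkage problem joins two person-level tables that share no single
unique identifier:

* a **cohort roster** — one row per study participant, with given name,
  national health-insurance (Medicare) card number, date of birth, sex,
  country of birth and up to four known postcodes;
* a **hospital person index** — one row per internally-linked hospital
  person, de-identified (no names or addresses), carrying only the first
  eight digits of the Medicare number, a three-letter given-name suffix,
  and the same demographic variables.

Two derived identifiers do most of the work:

* ``medicare8`` — the first 8 digits of the Medicare card number.  The
  full number is unique to a *family*, not a person, so the 8-digit stem
  identifies the card.
* ``suffix`` — the first three letters of the given name, uppercased,
  which distinguishes individuals sharing one card.

Missing values are ``None`` in memory and the empty string on disk.  A
missing field never matches another missing field: any composite key that
selects a missing field is itself missing (see :mod:`steplink.keys`).
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PersonRecord",
    "HospitalPerson",
    "Episode",
    "RowDiagnostic",
    "ReadReport",
    "SchemaError",
    "derive_suffix",
    "derive_medicare8",
    "canonical_text",
    "read_cohort",
    "read_hospital",
    "read_episodes",
    "write_cohort",
    "write_hospital",
    "write_episodes",
]

#: Reserved composite-key separator; stripped from every text field at
#: normalisation so serialised keys cannot collide (("AB","C") vs ("A","BC")).
RESERVED_SEPARATOR = "|"

SEX_CODES = frozenset({"M", "F"})
EVENT_FLAGS = frozenset({"AMI", "stroke", "other"})

_NON_ALPHA = re.compile(r"[^A-Z]")
_NON_DIGIT = re.compile(r"[^0-9]")
_WS = re.compile(r"\s+")


# ---------------------------------------------------------------------------
# normalisation

def _strip_diacritics(text: str) -> str:
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def derive_suffix(given_name: str | None) -> str | None:
    """First three letters of a given name, uppercased.

    Diacritics are stripped and non-alphabetic characters removed before
    truncation, so ``"o'neil"`` yields ``"ONE"`` and ``"Zoë"`` yields
    ``"ZOE"``.  Returns ``None`` when fewer than three alphabetic
    characters remain.
    """
    if given_name is None:
        return None
    letters = _NON_ALPHA.sub("", _strip_diacritics(str(given_name)).upper())
    return letters[:3] if len(letters) >= 3 else None


def derive_medicare8(card_number: str | None) -> str | None:
    """First eight digits of a Medicare card number.

    Separators (spaces, dashes, anything non-numeric) are removed first;
    returns ``None`` when fewer than eight digits remain.
    """
    if card_number is None:
        return None
    digits = _NON_DIGIT.sub("", str(card_number))
    return digits[:8] if len(digits) >= 8 else None


def canonical_text(value: str | None) -> str | None:
    """Canonical form for exact-match text fields (country of birth etc.):
    uppercase, whitespace collapsed, reserved separator removed.
    Empty input maps to missing."""
    if value is None:
        return None
    cleaned = _WS.sub(" ", str(value).replace(RESERVED_SEPARATOR, " ")).strip().upper()
    return cleaned or None


def _canonical_postcodes(values: Iterable[str | None]) -> tuple[str, ...]:
    out: list[str] = []
    for v in values:
        if v is None:
            continue
        v = str(v).replace(RESERVED_SEPARATOR, "").strip()
        if v and v not in out:
            out.append(v)
    return tuple(out)


# ---------------------------------------------------------------------------
# domain types

def _check_identity_fields(medicare8, suffix, birth_year, birth_month,
                           birth_day, sex, postcodes) -> None:
    if medicare8 is not None and not re.fullmatch(r"[0-9]{8}", medicare8):
        raise ValueError(f"medicare8 must be 8 digits, got {medicare8!r}")
    if suffix is not None and not re.fullmatch(r"[A-Z]{3}", suffix):
        raise ValueError(f"suffix must be 3 letters A-Z, got {suffix!r}")
    date(birth_year, birth_month, birth_day)  # raises on impossible dates
    if sex not in SEX_CODES:
        raise ValueError(f"sex must be one of {sorted(SEX_CODES)}, got {sex!r}")
    if len(set(postcodes)) != len(postcodes):
        raise ValueError("postcodes must be distinct")
    if len(postcodes) > 4:
        raise ValueError("at most 4 postcodes")


@dataclass(frozen=True)
class PersonRecord:
    """One cohort participant's identifying variables."""

    study_id: str
    given_name: str | None
    medicare8: str | None
    suffix: str | None
    birth_year: int
    birth_month: int
    birth_day: int
    sex: str
    country_of_birth: str | None
    postcodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_identity_fields(self.medicare8, self.suffix, self.birth_year,
                               self.birth_month, self.birth_day, self.sex,
                               self.postcodes)

    @property
    def birth_date(self) -> date:
        return date(self.birth_year, self.birth_month, self.birth_day)


@dataclass(frozen=True)
class HospitalPerson:
    """One de-identified hospital-side person (the per-person linkage ID
    assigned to a group of admissions), with the identifying variables the
    admissions dataset retains."""

    person_id: str
    medicare8: str | None
    suffix: str | None
    birth_year: int
    birth_month: int
    birth_day: int
    sex: str
    country_of_birth: str | None
    postcodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_identity_fields(self.medicare8, self.suffix, self.birth_year,
                               self.birth_month, self.birth_day, self.sex,
                               self.postcodes)

    @property
    def birth_date(self) -> date:
        return date(self.birth_year, self.birth_month, self.birth_day)


@dataclass(frozen=True)
class Episode:
    """One hospital admission belonging to a hospital-side person."""

    person_id: str
    hospital_name: str
    admission_date: date
    discharge_date: date
    event_flag: str = "other"

    def __post_init__(self) -> None:
        if self.discharge_date < self.admission_date:
            raise ValueError("discharge_date before admission_date")
        if self.event_flag not in EVENT_FLAGS:
            raise ValueError(f"event_flag must be one of {sorted(EVENT_FLAGS)}")


# ---------------------------------------------------------------------------
# readers

class SchemaError(ValueError):
    """A file-level problem (missing mandatory columns)."""


@dataclass(frozen=True)
class RowDiagnostic:
    row_number: int  # 1-based, header is row 1
    record_id: str
    message: str


@dataclass
class ReadReport:
    """Parsed records plus row-level diagnostics.

    Every input row yields either one record or one diagnostic, so
    ``len(records) + len(diagnostics)`` equals the number of data rows.
    """

    records: list = field(default_factory=list)
    diagnostics: list[RowDiagnostic] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.records) + len(self.diagnostics)


class _RowError(ValueError):
    pass


COHORT_COLUMNS = [
    "study_id", "given_name", "medicare_number",
    "birth_year", "birth_month", "birth_day", "sex", "country_of_birth",
    "postcode1", "postcode2", "postcode3", "postcode4",
]
HOSPITAL_COLUMNS = [
    "person_id", "medicare8", "suffix",
    "birth_year", "birth_month", "birth_day", "sex", "country_of_birth",
    "postcode1", "postcode2", "postcode3", "postcode4",
]
EPISODE_COLUMNS = [
    "person_id", "hospital_name", "admission_date", "discharge_date",
    "event_flag",
]


def _cell(row: dict, name: str) -> str | None:
    value = (row.get(name) or "").strip()
    return value or None


def _parse_int(row: dict, name: str) -> int:
    raw = _cell(row, name)
    if raw is None:
        raise _RowError(f"{name} is required")
    try:
        return int(raw)
    except ValueError:
        raise _RowError(f"{name} is not an integer: {raw!r}") from None


def _parse_sex(row: dict) -> str:
    raw = (_cell(row, "sex") or "").upper()
    if raw not in SEX_CODES:
        raise _RowError(f"unknown sex code {raw!r}")
    return raw


def _parse_birth(row: dict) -> tuple[int, int, int]:
    y, m, d = (_parse_int(row, c) for c in ("birth_year", "birth_month", "birth_day"))
    try:
        date(y, m, d)
    except ValueError:
        raise _RowError(f"invalid birth date {y:04d}-{m:02d}-{d:02d}") from None
    return y, m, d


def _parse_iso_date(row: dict, name: str) -> date:
    raw = _cell(row, name)
    if raw is None:
        raise _RowError(f"{name} is required")
    try:
        return date.fromisoformat(raw)
    except ValueError:
        raise _RowError(f"{name} is not an ISO date: {raw!r}") from None


def _read_table(path, required: Sequence[str], delimiter: str):
    path = Path(path)
    handle = path.open(newline="", encoding="utf-8")
    reader = csv.DictReader(handle, delimiter=delimiter)
    missing = set(required) - set(reader.fieldnames or ())
    if missing:
        handle.close()
        raise SchemaError(f"{path}: missing mandatory columns {sorted(missing)}")
    return handle, reader


def read_cohort(path, *, delimiter: str = ",") -> ReadReport:
    """Read a cohort roster CSV into :class:`PersonRecord` objects.

    Normalisation happens on read: the suffix is derived from the given
    name, the 8-digit Medicare stem from the card number, country of birth
    is canonicalised.  Malformed rows (bad dates, unknown sex codes,
    duplicate IDs) become diagnostics, never silent drops.
    """
    handle, reader = _read_table(path, COHORT_COLUMNS, delimiter)
    report = ReadReport()
    seen: set[str] = set()
    with handle:
        for n, row in enumerate(reader, start=2):
            rid = _cell(row, "study_id") or ""
            try:
                if not rid:
                    raise _RowError("study_id is required")
                if rid in seen:
                    raise _RowError(f"duplicate study_id {rid!r}")
                y, m, d = _parse_birth(row)
                given = _cell(row, "given_name")
                record = PersonRecord(
                    study_id=rid,
                    given_name=given,
                    medicare8=derive_medicare8(_cell(row, "medicare_number")),
                    suffix=derive_suffix(given),
                    birth_year=y, birth_month=m, birth_day=d,
                    sex=_parse_sex(row),
                    country_of_birth=canonical_text(_cell(row, "country_of_birth")),
                    postcodes=_canonical_postcodes(
                        _cell(row, f"postcode{k}") for k in range(1, 5)),
                )
            except (_RowError, ValueError) as exc:
                report.diagnostics.append(RowDiagnostic(n, rid, str(exc)))
            else:
                seen.add(rid)
                report.records.append(record)
    return report


def read_hospital(path, *, delimiter: str = ",") -> ReadReport:
    """Read a hospital person-index CSV into :class:`HospitalPerson` objects."""
    handle, reader = _read_table(path, HOSPITAL_COLUMNS, delimiter)
    report = ReadReport()
    seen: set[str] = set()
    with handle:
        for n, row in enumerate(reader, start=2):
            rid = _cell(row, "person_id") or ""
            try:
                if not rid:
                    raise _RowError("person_id is required")
                if rid in seen:
                    raise _RowError(f"duplicate person_id {rid!r}")
                y, m, d = _parse_birth(row)
                record = HospitalPerson(
                    person_id=rid,
                    medicare8=derive_medicare8(_cell(row, "medicare8")),
                    suffix=derive_suffix(_cell(row, "suffix")),
                    birth_year=y, birth_month=m, birth_day=d,
                    sex=_parse_sex(row),
                    country_of_birth=canonical_text(_cell(row, "country_of_birth")),
                    postcodes=_canonical_postcodes(
                        _cell(row, f"postcode{k}") for k in range(1, 5)),
                )
            except (_RowError, ValueError) as exc:
                report.diagnostics.append(RowDiagnostic(n, rid, str(exc)))
            else:
                seen.add(rid)
                report.records.append(record)
    return report


def read_episodes(path, *, delimiter: str = ",",
                  known_person_ids: set[str] | None = None) -> ReadReport:
    """Read an admissions (episode) table.

    When ``known_person_ids`` is given, episodes referring to unknown
    persons become diagnostics.
    """
    handle, reader = _read_table(path, EPISODE_COLUMNS, delimiter)
    report = ReadReport()
    with handle:
        for n, row in enumerate(reader, start=2):
            rid = _cell(row, "person_id") or ""
            try:
                if not rid:
                    raise _RowError("person_id is required")
                if known_person_ids is not None and rid not in known_person_ids:
                    raise _RowError(f"person_id {rid!r} does not resolve")
                flag = _cell(row, "event_flag") or "other"
                if flag not in EVENT_FLAGS:
                    raise _RowError(f"unknown event_flag {flag!r}")
                episode = Episode(
                    person_id=rid,
                    hospital_name=canonical_text(_cell(row, "hospital_name")) or "",
                    admission_date=_parse_iso_date(row, "admission_date"),
                    discharge_date=_parse_iso_date(row, "discharge_date"),
                    event_flag=flag,
                )
                if not episode.hospital_name:
                    raise _RowError("hospital_name is required")
            except (_RowError, ValueError) as exc:
                report.diagnostics.append(RowDiagnostic(n, rid, str(exc)))
            else:
                report.records.append(episode)
    return report


# ---------------------------------------------------------------------------
# writers (missing -> empty string; round-trips with the readers)

def _write_rows(path, columns: Sequence[str], rows: Iterable[Sequence],
                delimiter: str) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(columns)
        writer.writerows(rows)


def _pc(record, k: int) -> str:
    return record.postcodes[k - 1] if len(record.postcodes) >= k else ""


def write_cohort(records: Iterable[PersonRecord], path, *,
                 delimiter: str = ",") -> None:
    _write_rows(path, COHORT_COLUMNS, (
        [r.study_id, r.given_name or "", r.medicare8 or "",
         r.birth_year, r.birth_month, r.birth_day, r.sex,
         r.country_of_birth or "",
         _pc(r, 1), _pc(r, 2), _pc(r, 3), _pc(r, 4)]
        for r in records), delimiter)


def write_hospital(records: Iterable[HospitalPerson], path, *,
                   delimiter: str = ",") -> None:
    _write_rows(path, HOSPITAL_COLUMNS, (
        [r.person_id, r.medicare8 or "", r.suffix or "",
         r.birth_year, r.birth_month, r.birth_day, r.sex,
         r.country_of_birth or "",
         _pc(r, 1), _pc(r, 2), _pc(r, 3), _pc(r, 4)]
        for r in records), delimiter)


def write_episodes(episodes: Iterable[Episode], path, *,
                   delimiter: str = ",") -> None:
    _write_rows(path, EPISODE_COLUMNS, (
        [e.person_id, e.hospital_name, e.admission_date.isoformat(),
         e.discharge_date.isoformat(), e.event_flag]
        for e in episodes), delimiter)
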
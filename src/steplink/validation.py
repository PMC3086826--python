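"""Linkage validation against a gold standard, and ground-truth metrics.

Two complementary evaluations live here:

* **Sensitivity against confirmed admissions.**  For a sub-sample of
  participants whose hospital admission was independently confirmed (e.g.
  by medical-record review), a linked hospital-side person should carry an
  episode matching the confirmed admission by hospital name and by
  admission/discharge dates within a tolerance window (default ±10 days,
  inclusive, to absorb abstraction slop).  Sensitivity is the number of
  confirmed admissions correctly found divided by all confirmed
  admissions, with a Wilson score confidence interval.

* **Ground-truth metrics on synthetic runs.**  When the true
  participant-to-person mapping is known (synthetic data), sensitivity,
  positive predictive value and the false/missed match rates are computed
  directly — the specificity-style evaluation that is impossible on real
  de-identified data.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

from statsmodels.stats.proportion import proportion_confint

from .engine import LinkageResult
from .records import Episode, ReadReport, RowDiagnostic, SchemaError, canonical_text

__all__ = [
    "ConfirmedEvent",
    "SensitivityReport",
    "episode_matches",
    "sensitivity_analysis",
    "wilson_ci",
    "ground_truth_metrics",
    "read_confirmed_events",
    "write_confirmed_events",
]

EVENT_TYPES = frozenset({"AMI", "stroke"})

_PUNCT = re.compile(r"[^A-Z0-9 ]")


def canonical_hospital(name: str | None) -> str | None:
    """Canonical hospital-name form for exact comparison: uppercase,
    punctuation stripped, whitespace collapsed.  No fuzzy matching."""
    upper = canonical_text(name)
    if upper is None:
        return None
    return canonical_text(_PUNCT.sub("", upper))


@dataclass(frozen=True)
class ConfirmedEvent:
    """One independently confirmed hospital admission for a participant."""

    study_id: str
    hospital_name: str
    admission_date: date
    discharge_date: date | None
    event_type: str = "AMI"

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"event_type must be one of {sorted(EVENT_TYPES)}")


def episode_matches(event: ConfirmedEvent, episode: Episode,
                    window_days: int = 10) -> bool:
    """Whether an admissions episode corroborates a confirmed event.

    True when the canonical hospital names are equal, the admission dates
    differ by at most ``window_days`` (inclusive), and — unless the gold
    record lacks a discharge date — the discharge dates do too.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    if canonical_hospital(event.hospital_name) != canonical_hospital(episode.hospital_name):
        return False
    if abs((event.admission_date - episode.admission_date).days) > window_days:
        return False
    if event.discharge_date is not None:
        if abs((event.discharge_date - episode.discharge_date).days) > window_days:
            return False
    return True


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be between 0 and n")
    lower, upper = proportion_confint(successes, n, alpha=1 - level,
                                      method="wilson")
    return float(lower), float(upper)


@dataclass(frozen=True)
class SensitivityReport:
    n_confirmed: int
    n_linked: int
    n_correct: int
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_linked <= self.n_confirmed:
            raise ValueError("need n_correct <= n_linked <= n_confirmed")

    @property
    def n_incorrect(self) -> int:
        """Linked participants whose episodes did not corroborate the
        confirmed admission."""
        return self.n_linked - self.n_correct

    @property
    def sensitivity(self) -> float:
        return self.n_correct / self.n_confirmed

    @property
    def non_matched_rate(self) -> float:
        """Incorrect matches as a share of all confirmed admissions."""
        return self.n_incorrect / self.n_confirmed

    @property
    def ci95(self) -> tuple[float, float]:
        return wilson_ci(self.n_correct, self.n_confirmed, self.ci_level)

    def to_dict(self) -> dict:
        lower, upper = self.ci95
        return {
            "n_confirmed": self.n_confirmed,
            "n_linked": self.n_linked,
            "n_correct": self.n_correct,
            "n_incorrect": self.n_incorrect,
            "sensitivity": self.sensitivity,
            "non_matched_rate": self.non_matched_rate,
            "ci95_lower": lower,
            "ci95_upper": upper,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def sensitivity_analysis(events: Sequence[ConfirmedEvent],
                         result: LinkageResult,
                         episodes: Iterable[Episode],
                         window_days: int = 10) -> SensitivityReport:
    """Gold-standard sensitivity of a linkage run.

    A confirmed event counts as *correct* when its participant was linked
    and at least one episode of the linked hospital-side person matches
    the event under :func:`episode_matches`.  Invariant to event and
    episode order.
    """
    link_map = result.links_by_study_id()
    by_person: dict[str, list[Episode]] = {}
    for ep in episodes:
        by_person.setdefault(ep.person_id, []).append(ep)

    n_linked = n_correct = 0
    for event in events:
        person_id = link_map.get(event.study_id)
        if person_id is None:
            continue
        n_linked += 1
        if any(episode_matches(event, ep, window_days)
               for ep in by_person.get(person_id, ())):
            n_correct += 1
    return SensitivityReport(n_confirmed=len(events), n_linked=n_linked,
                             n_correct=n_correct)


def ground_truth_metrics(result: LinkageResult,
                         truth: Iterable[tuple[str, str]]) -> dict[str, float]:
    """Evaluate a linkage run against a known one-to-one truth mapping.

    Returns ``sensitivity`` (true pairs recovered / true pairs), ``ppv``
    (true pairs recovered / links made), ``false_match_rate`` (1 - ppv)
    and ``missed_match_rate`` (1 - sensitivity).  With no links made, ppv
    is reported as 1.0 (no link is false) and the false-match rate as 0.
    """
    truth_pairs = set(truth)
    study_ids = [s for s, _ in truth_pairs]
    person_ids = [p for _, p in truth_pairs]
    if len(set(study_ids)) != len(truth_pairs) or \
            len(set(person_ids)) != len(truth_pairs):
        raise ValueError("truth mapping must be one-to-one")

    made = {(l.study_id, l.person_id) for l in result.links}
    found = made & truth_pairs
    sensitivity = len(found) / len(truth_pairs) if truth_pairs else 1.0
    ppv = len(found) / len(made) if made else 1.0
    return {
        "sensitivity": sensitivity,
        "ppv": ppv,
        "false_match_rate": 1.0 - ppv,
        "missed_match_rate": 1.0 - sensitivity,
    }


# ---------------------------------------------------------------------------
# confirmed-event I/O

EVENT_COLUMNS = ["study_id", "hospital_name", "admission_date",
                 "discharge_date", "event_type"]


def read_confirmed_events(path, *, delimiter: str = ",") -> ReadReport:
    """Read a confirmed-events CSV (discharge_date may be empty)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        missing = set(EVENT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns {sorted(missing)}")
        report = ReadReport()
        for n, row in enumerate(reader, start=2):
            sid = (row.get("study_id") or "").strip()
            try:
                if not sid:
                    raise ValueError("study_id is required")
                discharge_raw = (row.get("discharge_date") or "").strip()
                event = ConfirmedEvent(
                    study_id=sid,
                    hospital_name=canonical_text(row.get("hospital_name")) or "",
                    admission_date=date.fromisoformat(
                        (row.get("admission_date") or "").strip()),
                    discharge_date=(date.fromisoformat(discharge_raw)
                                    if discharge_raw else None),
                    event_type=(row.get("event_type") or "").strip(),
                )
                if not event.hospital_name:
                    raise ValueError("hospital_name is required")
            except ValueError as exc:
                report.diagnostics.append(RowDiagnostic(n, sid, str(exc)))
            else:
                report.records.append(event)
    return report


def write_confirmed_events(events: Iterable[ConfirmedEvent], path, *,
                           delimiter: str = ",") -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(EVENT_COLUMNS)
        for e in events:
            writer.writerow([
                e.study_id, e.hospital_name, e.admission_date.isoformat(),
                e.discharge_date.isoformat() if e.discharge_date else "",
                e.event_type])
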
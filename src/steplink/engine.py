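"""Stepwise deterministic linkage engine.

The method runs an ordered *plan* of iterations.  Each iteration names a
combination of identifying fields; a cohort record links to a hospital
person in that iteration only when their composite keys are both present
and identical, and that key value occurs exactly once on *each* side among
the records still unmatched.  Matched records are removed from both pools
before the next iteration, so earlier (more specific) iterations take
precedence over later (more relaxed) ones.

Key-value groups with two or more records on either side are ambiguous
under a one-to-one linkage: those records are left unmatched in that
iteration (they stay eligible for later iterations) and logged for audit.
Within an iteration all matches are determined simultaneously from the
key-group counts, so input row order never affects the result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .keys import KeySpec, build_key
from .records import HospitalPerson, PersonRecord

__all__ = [
    "IterationPlan",
    "Link",
    "IterationCount",
    "AmbiguityEntry",
    "LinkageResult",
    "run_iteration",
    "run_plan",
]


@dataclass(frozen=True)
class IterationPlan:
    """An ordered list of key specifications defining the stepwise strategy."""

    label: str
    iterations: tuple[KeySpec, ...]

    def __post_init__(self) -> None:
        labels = [spec.label for spec in self.iterations]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate iteration labels in plan {self.label!r}")

    def __len__(self) -> int:
        return len(self.iterations)

    def prefix(self, k: int) -> "IterationPlan":
        """The plan truncated to its first ``k`` iterations."""
        return IterationPlan(f"{self.label}[:{k}]", self.iterations[:k])


class Link(NamedTuple):
    study_id: str
    person_id: str
    iteration_index: int  # 1-based position in the plan


class IterationCount(NamedTuple):
    iteration_index: int
    label: str
    records_linked: int
    records_remaining: int  # cohort records still unmatched afterwards


class AmbiguityEntry(NamedTuple):
    iteration_index: int
    side: str  # "cohort" | "hospital"
    record_id: str
    candidate_count: int  # records on the opposite side sharing the key


@dataclass
class LinkageResult:
    """Accepted links with per-iteration provenance and counts."""

    plan_label: str
    cohort_size: int
    links: list[Link] = field(default_factory=list)
    per_iteration_counts: list[IterationCount] = field(default_factory=list)
    unmatched_cohort_ids: list[str] = field(default_factory=list)
    ambiguity_log: list[AmbiguityEntry] = field(default_factory=list)

    @property
    def n_linked(self) -> int:
        return len(self.links)

    @property
    def match_proportion(self) -> float:
        return self.n_linked / self.cohort_size if self.cohort_size else 0.0

    def links_by_study_id(self) -> dict[str, str]:
        return {l.study_id: l.person_id for l in self.links}

    def cohort_ids(self) -> set[str]:
        return {l.study_id for l in self.links} | set(self.unmatched_cohort_ids)

    # -- persistence -------------------------------------------------------

    def save(self, out_dir) -> None:
        """Write links, per-iteration counts, the ambiguity log (CSV) and a
        JSON run summary into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.links, columns=Link._fields).to_csv(
            out / "links.csv", index=False)
        pd.DataFrame(self.per_iteration_counts,
                     columns=IterationCount._fields).to_csv(
            out / "iteration_counts.csv", index=False)
        pd.DataFrame(self.ambiguity_log, columns=AmbiguityEntry._fields).to_csv(
            out / "ambiguities.csv", index=False)
        summary = {
            "plan_label": self.plan_label,
            "cohort_size": self.cohort_size,
            "n_linked": self.n_linked,
            "match_proportion": self.match_proportion,
            "unmatched_cohort_ids": list(self.unmatched_cohort_ids),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))

    @classmethod
    def load(cls, out_dir) -> "LinkageResult":
        out = Path(out_dir)
        summary = json.loads((out / "summary.json").read_text())
        links_df = pd.read_csv(out / "links.csv", dtype={"study_id": str,
                                                         "person_id": str})
        counts_df = pd.read_csv(out / "iteration_counts.csv",
                                dtype={"label": str})
        ambig_df = pd.read_csv(out / "ambiguities.csv",
                               dtype={"side": str, "record_id": str})
        return cls(
            plan_label=summary["plan_label"],
            cohort_size=summary["cohort_size"],
            links=[Link(r.study_id, r.person_id, int(r.iteration_index))
                   for r in links_df.itertuples()],
            per_iteration_counts=[
                IterationCount(int(r.iteration_index), r.label,
                               int(r.records_linked), int(r.records_remaining))
                for r in counts_df.itertuples()],
            unmatched_cohort_ids=[str(s) for s in summary["unmatched_cohort_ids"]],
            ambiguity_log=[
                AmbiguityEntry(int(r.iteration_index), r.side, r.record_id,
                               int(r.candidate_count))
                for r in ambig_df.itertuples()],
        )


def run_iteration(cohort: Sequence[PersonRecord],
                  hospital: Sequence[HospitalPerson],
                  spec: KeySpec, secret: bytes, *,
                  iteration_index: int = 1,
                  ) -> tuple[list[Link], list[AmbiguityEntry]]:
    """Execute one exact-match iteration over the still-unmatched records.

    Returns accepted one-to-one links plus ambiguity entries for every
    record caught in a key group with multiple candidates.
    """
    cohort_groups: dict[bytes, list[str]] = {}
    for record in cohort:
        key = build_key(record, spec, secret)
        if key is not None:
            cohort_groups.setdefault(key.digest, []).append(record.study_id)
    hospital_groups: dict[bytes, list[str]] = {}
    for person in hospital:
        key = build_key(person, spec, secret)
        if key is not None:
            hospital_groups.setdefault(key.digest, []).append(person.person_id)

    links: list[Link] = []
    ambiguities: list[AmbiguityEntry] = []
    for digest, study_ids in cohort_groups.items():
        person_ids = hospital_groups.get(digest)
        if person_ids is None:
            continue
        if len(study_ids) == 1 and len(person_ids) == 1:
            links.append(Link(study_ids[0], person_ids[0], iteration_index))
        else:
            for sid in study_ids:
                ambiguities.append(AmbiguityEntry(
                    iteration_index, "cohort", sid, len(person_ids)))
            for pid in person_ids:
                ambiguities.append(AmbiguityEntry(
                    iteration_index, "hospital", pid, len(study_ids)))
    links.sort()
    ambiguities.sort()
    return links, ambiguities


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} {i!r}")
        seen.add(i)


def run_plan(cohort: Sequence[PersonRecord],
             hospital: Sequence[HospitalPerson],
             plan: IterationPlan, secret: bytes) -> LinkageResult:
    """Run a full stepwise plan and return the linkage result.

    Deterministic for fixed inputs, plan and secret; input row order is
    irrelevant because each iteration uses set semantics.
    """
    if not plan.iterations:
        raise ValueError("plan has no iterations")
    _check_unique((r.study_id for r in cohort), "study_id")
    _check_unique((p.person_id for p in hospital), "person_id")

    result = LinkageResult(plan_label=plan.label, cohort_size=len(cohort))
    remaining_cohort = list(cohort)
    remaining_hospital = list(hospital)

    for index, spec in enumerate(plan.iterations, start=1):
        links, ambiguities = run_iteration(
            remaining_cohort, remaining_hospital, spec, secret,
            iteration_index=index)
        result.links.extend(links)
        result.ambiguity_log.extend(ambiguities)
        matched_c = {l.study_id for l in links}
        matched_h = {l.person_id for l in links}
        remaining_cohort = [r for r in remaining_cohort
                            if r.study_id not in matched_c]
        remaining_hospital = [p for p in remaining_hospital
                              if p.person_id not in matched_h]
        result.per_iteration_counts.append(IterationCount(
            index, spec.label, len(links), len(remaining_cohort)))

    result.unmatched_cohort_ids = sorted(r.study_id for r in remaining_cohort)
    return result
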
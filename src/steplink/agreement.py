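"""Agreement between two linkage runs over the same cohort.

When two algorithms are both believed to link correctly, each participant
should end up attached to the same hospital-side person under both.  The
comparison sorts every participant into one of five categories — same
person, different person, matched only by the first run, only by the
second, or by neither — and reports the *disagreement fraction*: the share
of the whole cohort assigned to different hospital-side persons by the two
runs.  Participants in the "different person" category are exported for
clerical inspection; at least one of the two links must be a false
positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .engine import LinkageResult

__all__ = ["AgreementReport", "compare"]


@dataclass
class AgreementReport:
    label_a: str
    label_b: str
    cohort_size: int
    same_id: int
    different_id: int
    only_in_a: int
    only_in_b: int
    unmatched_both: int
    different_id_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def disagreement_fraction(self) -> float:
        """Share of the cohort linked to different hospital-side persons."""
        return self.different_id / self.cohort_size if self.cohort_size else 0.0

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "cohort_size": self.cohort_size,
            "same_id": self.same_id,
            "different_id": self.different_id,
            "only_in_a": self.only_in_a,
            "only_in_b": self.only_in_b,
            "unmatched_both": self.unmatched_both,
            "disagreement_fraction": self.disagreement_fraction,
        }

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "agreement.json").write_text(json.dumps(self.to_dict(), indent=2))
        pd.DataFrame(self.different_id_pairs,
                     columns=["study_id", "person_id_a", "person_id_b"]).to_csv(
            out / "different_id_pairs.csv", index=False)


def compare(result_a: LinkageResult, result_b: LinkageResult) -> AgreementReport:
    """Categorise every cohort participant by how the two runs linked them.

    Both results must cover exactly the same cohort (the union of linked
    and unmatched study IDs); anything else is an error, since category
    counts would not partition a common denominator.
    """
    ids_a, ids_b = result_a.cohort_ids(), result_b.cohort_ids()
    if ids_a != ids_b:
        raise ValueError(
            f"results cover different cohorts "
            f"({len(ids_a - ids_b)} only in a, {len(ids_b - ids_a)} only in b)")
    map_a = result_a.links_by_study_id()
    map_b = result_b.links_by_study_id()

    same = diff = only_a = only_b = neither = 0
    pairs: list[tuple[str, str, str]] = []
    for sid in sorted(ids_a):
        pa, pb = map_a.get(sid), map_b.get(sid)
        if pa is not None and pb is not None:
            if pa == pb:
                same += 1
            else:
                diff += 1
                pairs.append((sid, pa, pb))
        elif pa is not None:
            only_a += 1
        elif pb is not None:
            only_b += 1
        else:
            neither += 1

    return AgreementReport(
        label_a=result_a.plan_label, label_b=result_b.plan_label,
        cohort_size=len(ids_a), same_id=same, different_id=diff,
        only_in_a=only_a, only_in_b=only_b, unmatched_both=neither,
        different_id_pairs=pairs)
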
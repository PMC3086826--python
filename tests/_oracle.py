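"""Brute-force per-iteration matcher used as an independent oracle.

Matches on plaintext field-value tuples (no serialisation, no digests)
and applies the acceptance rule directly: a pair links in an iteration
when its value tuple is complete on both records and occurs exactly once
on each side among still-unmatched records.  Matched records are removed
before the next iteration.
"""

from __future__ import annotations


def _value(record, selector):
    kind = selector.kind.value
    if kind == "MEDICARE8":
        return record.medicare8
    if kind == "SUFFIX_FULL":
        return record.suffix
    if kind == "SUFFIX_LETTERS":
        if record.suffix is None:
            return None
        return "".join(record.suffix[p - 1] for p in selector.positions)
    if kind == "YEAR":
        return record.birth_year
    if kind == "MONTH":
        return record.birth_month
    if kind == "DAY":
        return record.birth_day
    if kind == "SEX":
        return record.sex
    if kind == "COB":
        return record.country_of_birth
    if kind == "POSTCODE_SLOT":
        if len(record.postcodes) >= selector.slot:
            return record.postcodes[selector.slot - 1]
        return None
    raise AssertionError(kind)


def _tuples(records, spec, id_attr):
    groups: dict[tuple, list[str]] = {}
    for record in records:
        values = tuple(_value(record, sel) for sel in spec.selectors)
        if None not in values:
            groups.setdefault(values, []).append(getattr(record, id_attr))
    return groups


def brute_force_plan(cohort, hospital, plan) -> set[tuple[str, str, int]]:
    """All accepted (study_id, person_id, iteration_index) triples."""
    remaining_c = list(cohort)
    remaining_h = list(hospital)
    links: set[tuple[str, str, int]] = set()
    for index, spec in enumerate(plan.iterations, start=1):
        c_groups = _tuples(remaining_c, spec, "study_id")
        h_groups = _tuples(remaining_h, spec, "person_id")
        matched_c: set[str] = set()
        matched_h: set[str] = set()
        for values, study_ids in c_groups.items():
            person_ids = h_groups.get(values, [])
            if len(study_ids) == 1 and len(person_ids) == 1:
                links.add((study_ids[0], person_ids[0], index))
                matched_c.add(study_ids[0])
                matched_h.add(person_ids[0])
        remaining_c = [r for r in remaining_c if r.study_id not in matched_c]
        remaining_h = [p for p in remaining_h if p.person_id not in matched_h]
    return links
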
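"""Shipped iteration plans and plan-config (YAML) round-tripping.

Three plans ship with the package, mirroring a published validation study
of cohort-to-hospital linkage in an Australian state admissions dataset:

* ``plan_v1`` — 10 iterations anchored on the 8-digit Medicare stem and
  the 3-letter name suffix, falling back to demographics;
* ``plan_v2`` — 4 iterations using demographics only (date of birth, sex,
  country of birth, one of four postcode slots);
* ``plan_v2_plus_suffix`` — ``plan_v2`` with the name suffix added to every
  iteration, which suppresses demographic-twin false positives;
* ``plan_final`` — the production three-stage plan: a Medicare+suffix
  stage with suffix-letter variants and systematic drop-one/drop-two
  relaxations of the demographic variables, a Medicare-only stage with
  drop-one relaxations, and a suffix-only stage.

``plan_final`` is generated from the relaxation *rules* (anchor +
demographic sweep, suffix variants, never more than two demographic
variables relaxed at once) rather than from a hard-coded step table; the
generator yields 174 iterations and the expansion is pinned by golden
files in the test suite.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import yaml

from .engine import IterationPlan
from .keys import FieldSelector, KeySpec, SelectorKind

__all__ = [
    "plan_v1",
    "plan_v2",
    "plan_v2_plus_suffix",
    "plan_final",
    "shipped_plan",
    "SHIPPED_PLANS",
    "load_plan",
    "save_plan",
]

_K = SelectorKind
M8 = FieldSelector(_K.MEDICARE8)
SUF = FieldSelector(_K.SUFFIX_FULL)
YEAR = FieldSelector(_K.YEAR)
MONTH = FieldSelector(_K.MONTH)
DAY = FieldSelector(_K.DAY)
SEX = FieldSelector(_K.SEX)
COB = FieldSelector(_K.COB)


def suffix_letters(*positions: int) -> FieldSelector:
    return FieldSelector(_K.SUFFIX_LETTERS, positions=tuple(positions))


def postcode_slot(k: int) -> FieldSelector:
    return FieldSelector(_K.POSTCODE_SLOT, slot=k)


#: The three 2-letter suffix variants used to tolerate one mistyped letter.
SUFFIX_VARIANTS = (suffix_letters(1, 2), suffix_letters(2, 3),
                   suffix_letters(1, 3))

#: Demographic variables subject to drop-one / drop-two relaxation, in the
#: order relaxations are applied.  "PC" stands for the whole postcode
#: slot sweep: dropping it collapses the sweep to a single iteration with
#: no postcode selector.
_DROPPABLE = ("PC", "COB", "SEX", "DAY", "MONTH", "YEAR")
_DEMO = {"YEAR": YEAR, "MONTH": MONTH, "DAY": DAY, "SEX": SEX, "COB": COB}
_DEMO_ORDER = ("YEAR", "MONTH", "DAY", "SEX", "COB")


def _spec(label: str, selectors) -> KeySpec:
    return KeySpec(label, tuple(selectors))


def plan_v1() -> IterationPlan:
    """Medicare-and-suffix anchored plan (10 iterations)."""
    dob = (YEAR, MONTH, DAY)
    its = [
        _spec("v1-01 M8+SUF", (M8, SUF)),
        _spec("v1-02 M8+SUF(1,2)+SEX", (M8, suffix_letters(1, 2), SEX)),
        _spec("v1-03 M8+SUF(2,3)+SEX", (M8, suffix_letters(2, 3), SEX)),
        _spec("v1-04 M8+SUF(1,3)+SEX", (M8, suffix_letters(1, 3), SEX)),
        _spec("v1-05 M8+YEAR+SEX", (M8, YEAR, SEX)),
    ]
    for k in range(1, 5):
        its.append(_spec(f"v1-{5 + k:02d} SUF+DOB+SEX+COB+PC{k}",
                         (SUF, *dob, SEX, COB, postcode_slot(k))))
    its.append(_spec("v1-10 DOB+SEX+COB+PC1",
                     (*dob, SEX, COB, postcode_slot(1))))
    return IterationPlan("v1", tuple(its))


def plan_v2() -> IterationPlan:
    """Demographics-only plan: date of birth + sex + country of birth +
    one postcode slot, swept over the four slots."""
    its = [_spec(f"v2-{k:02d} DOB+SEX+COB+PC{k}",
                 (YEAR, MONTH, DAY, SEX, COB, postcode_slot(k)))
           for k in range(1, 5)]
    return IterationPlan("v2", tuple(its))


def plan_v2_plus_suffix() -> IterationPlan:
    """``plan_v2`` with the 3-letter name suffix added to every iteration."""
    its = [_spec(f"v2s-{k:02d} SUF+DOB+SEX+COB+PC{k}",
                 (SUF, YEAR, MONTH, DAY, SEX, COB, postcode_slot(k)))
           for k in range(1, 5)]
    return IterationPlan("v2s", tuple(its))


def _sweep(anchor: tuple[FieldSelector, ...],
           dropped: frozenset[str]) -> list[tuple[FieldSelector, ...]]:
    """Anchor + demographics with ``dropped`` variables removed, swept over
    postcode slots 1-4 (or one sweepless iteration when "PC" is dropped)."""
    demo = tuple(_DEMO[name] for name in _DEMO_ORDER if name not in dropped)
    if "PC" in dropped:
        return [(*anchor, *demo)]
    return [(*anchor, *demo, postcode_slot(k)) for k in range(1, 5)]


def plan_final() -> IterationPlan:
    """The production three-stage plan.

    Stage A (Medicare stem + suffix): the full-key sweep; the sweep under
    each 2-letter suffix variant; drop-one over {postcode sweep, COB, sex,
    day, month, year}; suffix variants with one dropped variable; drop-two
    over all 2-subsets.  Stage B (Medicare stem only): full sweep then
    drop-one.  Stage C (suffix only): full sweep.  At most two demographic
    variables are ever relaxed at once, and the stage anchors themselves
    are never dropped.
    """
    blocks: list[tuple[str, tuple[FieldSelector, ...], frozenset[str]]] = []

    def add(stage: str, anchor, dropped=frozenset()):
        blocks.append((stage, tuple(anchor), frozenset(dropped)))

    none = frozenset()
    # Stage A: Medicare8 + suffix group
    add("A", (M8, SUF), none)
    for variant in SUFFIX_VARIANTS:
        add("A", (M8, variant), none)
    for name in _DROPPABLE:
        add("A", (M8, SUF), {name})
    for variant in SUFFIX_VARIANTS:
        for name in _DROPPABLE:
            add("A", (M8, variant), {name})
    for pair in combinations(_DROPPABLE, 2):
        add("A", (M8, SUF), set(pair))
    # Stage B: Medicare8 group
    add("B", (M8,), none)
    for name in _DROPPABLE:
        add("B", (M8,), {name})
    # Stage C: suffix group
    add("C", (SUF,), none)

    its: list[KeySpec] = []
    seen: set[frozenset[FieldSelector]] = set()
    counter = 0
    for stage, anchor, dropped in blocks:
        for selectors in _sweep(anchor, dropped):
            key = frozenset(selectors)
            if key in seen:  # relaxation rules never coincide, but be safe
                continue
            seen.add(key)
            counter += 1
            label = f"{stage}{counter:03d} " + "+".join(
                sel.token() for sel in selectors)
            its.append(_spec(label, selectors))
    return IterationPlan("final", tuple(its))


def shipped_plan(name: str) -> IterationPlan:
    """Look up a shipped plan by short name (v1, v2, v2s, final)."""
    try:
        return SHIPPED_PLANS[name]()
    except KeyError:
        raise ValueError(f"unknown plan {name!r}; "
                         f"choose from {sorted(SHIPPED_PLANS)}") from None


SHIPPED_PLANS = {
    "v1": plan_v1,
    "v2": plan_v2,
    "v2s": plan_v2_plus_suffix,
    "final": plan_final,
}


# ---------------------------------------------------------------------------
# plan-config files

def save_plan(plan: IterationPlan, path) -> None:
    """Serialise a plan to a YAML config (round-trips with :func:`load_plan`)."""
    doc = {
        "label": plan.label,
        "iterations": [
            {"label": spec.label,
             "selectors": [sel.token() for sel in spec.selectors]}
            for spec in plan.iterations
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_plan(path) -> IterationPlan:
    """Load a plan from a YAML config.

    Raises ``ValueError`` on unknown selector kinds, malformed selector
    arguments, or duplicate iteration labels."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "iterations" not in doc:
        raise ValueError(f"{path}: not a plan config")
    its = []
    for entry in doc["iterations"]:
        selectors = tuple(FieldSelector.parse(tok)
                          for tok in entry["selectors"])
        its.append(KeySpec(str(entry["label"]), selectors))
    return IterationPlan(str(doc.get("label", Path(path).stem)), tuple(its))
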
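"""Composite linkage keys: field selection, serialisation, keyed digests.

A linkage key is an ordered combination of identifying fields (for
example ``medicare8 + suffix + sex``) serialised into a single string and
digested with HMAC-SHA-256 under a run-specific secret.  Linkage units can
then exchange and compare digests without ever exchanging reversible
identifiers; two digests compare equal exactly when the underlying
serialised values are equal (collisions are cryptographically negligible).

Missing-field policy: if *any* selected field is missing on a record the
whole key is missing and the record simply cannot match in that iteration.
Deterministic exact matching has no notion of a partial match.
"""

from __future__ import annotations

import hashlib
import hmac
import re
from dataclasses import dataclass
from enum import Enum

from .records import RESERVED_SEPARATOR

__all__ = [
    "SelectorKind",
    "FieldSelector",
    "KeySpec",
    "LinkageKey",
    "build_key",
    "digest_equal",
]


class SelectorKind(str, Enum):
    MEDICARE8 = "MEDICARE8"
    SUFFIX_FULL = "SUFFIX_FULL"
    SUFFIX_LETTERS = "SUFFIX_LETTERS"
    YEAR = "YEAR"
    MONTH = "MONTH"
    DAY = "DAY"
    SEX = "SEX"
    COB = "COB"
    POSTCODE_SLOT = "POSTCODE_SLOT"


_TOKEN_RE = re.compile(r"^([A-Z0-9_]+)(?:\(([0-9,\s]*)\))?$")


@dataclass(frozen=True, order=True)
class FieldSelector:
    """Selects one field (or part of one) from a record.

    ``SUFFIX_LETTERS`` takes 1-based letter positions within the 3-letter
    suffix (e.g. positions (1, 2) selects the first two letters);
    ``POSTCODE_SLOT`` takes a slot number 1-4 addressing the ordered list
    of postcodes known for the person.
    """

    kind: SelectorKind
    positions: tuple[int, ...] = ()
    slot: int = 0

    def __post_init__(self) -> None:
        if self.kind is SelectorKind.SUFFIX_LETTERS:
            if not self.positions or any(p not in (1, 2, 3) for p in self.positions):
                raise ValueError("SUFFIX_LETTERS positions must be a non-empty "
                                 "subset of {1,2,3}")
            if tuple(sorted(set(self.positions))) != self.positions:
                raise ValueError("SUFFIX_LETTERS positions must be sorted and "
                                 "distinct")
        elif self.positions:
            raise ValueError(f"{self.kind.value} takes no positions")
        if self.kind is SelectorKind.POSTCODE_SLOT:
            if self.slot not in (1, 2, 3, 4):
                raise ValueError("POSTCODE_SLOT slot must be 1-4")
        elif self.slot:
            raise ValueError(f"{self.kind.value} takes no slot")

    def token(self) -> str:
        """Compact text form, e.g. ``SUFFIX_LETTERS(1,2)`` or ``POSTCODE_SLOT(3)``."""
        if self.kind is SelectorKind.SUFFIX_LETTERS:
            return f"SUFFIX_LETTERS({','.join(map(str, self.positions))})"
        if self.kind is SelectorKind.POSTCODE_SLOT:
            return f"POSTCODE_SLOT({self.slot})"
        return self.kind.value

    @classmethod
    def parse(cls, token: str) -> "FieldSelector":
        match = _TOKEN_RE.match(token.strip())
        if not match:
            raise ValueError(f"malformed selector token {token!r}")
        name, args = match.groups()
        try:
            kind = SelectorKind(name)
        except ValueError:
            raise ValueError(f"unknown selector kind {name!r}") from None
        numbers = tuple(int(a) for a in args.split(",")) if args else ()
        if kind is SelectorKind.SUFFIX_LETTERS:
            return cls(kind, positions=numbers)
        if kind is SelectorKind.POSTCODE_SLOT:
            if len(numbers) != 1:
                raise ValueError(f"POSTCODE_SLOT takes one slot, got {token!r}")
            return cls(kind, slot=numbers[0])
        if numbers:
            raise ValueError(f"{name} takes no arguments, got {token!r}")
        return cls(kind)

    def extract(self, record) -> str | None:
        """Value of this selector on a cohort or hospital record, or
        ``None`` when the underlying field (or addressed part) is missing."""
        kind = self.kind
        if kind is SelectorKind.MEDICARE8:
            return record.medicare8
        if kind is SelectorKind.SUFFIX_FULL:
            return record.suffix
        if kind is SelectorKind.SUFFIX_LETTERS:
            if record.suffix is None:
                return None
            return "".join(record.suffix[p - 1] for p in self.positions)
        if kind is SelectorKind.YEAR:
            return f"{record.birth_year:04d}"
        if kind is SelectorKind.MONTH:
            return f"{record.birth_month:02d}"
        if kind is SelectorKind.DAY:
            return f"{record.birth_day:02d}"
        if kind is SelectorKind.SEX:
            return record.sex
        if kind is SelectorKind.COB:
            return record.country_of_birth
        if kind is SelectorKind.POSTCODE_SLOT:
            if len(record.postcodes) >= self.slot:
                return record.postcodes[self.slot - 1]
            return None
        raise AssertionError(kind)


@dataclass(frozen=True)
class KeySpec:
    """One iteration's key: an ordered, duplicate-free list of selectors."""

    label: str
    selectors: tuple[FieldSelector, ...]

    def __post_init__(self) -> None:
        if not self.selectors:
            raise ValueError("KeySpec needs at least one selector")
        if len(set(self.selectors)) != len(self.selectors):
            raise ValueError(f"duplicate selectors in {self.label!r}")

    def describe(self) -> str:
        return "+".join(sel.token() for sel in self.selectors)

    def uses(self, kind: SelectorKind) -> bool:
        return any(sel.kind is kind for sel in self.selectors)


@dataclass(frozen=True)
class LinkageKey:
    spec_label: str
    serialized: str
    digest: bytes

    def hex(self) -> str:
        return self.digest.hex()


def build_key(record, spec: KeySpec, secret: bytes) -> LinkageKey | None:
    """Build the composite key for ``record`` under ``spec``.

    Returns ``None`` when any selected field is missing.  The serialised
    form joins field values with ``"|"`` (which normalisation strips from
    data values, so the serialisation is injective); the digest is
    HMAC-SHA-256 of the serialised form under ``secret``.
    """
    if not secret:
        raise ValueError("secret must be non-empty")
    values = []
    for sel in spec.selectors:
        value = sel.extract(record)
        if value is None:
            return None
        values.append(value)
    serialized = RESERVED_SEPARATOR.join(values)
    digest = hmac.new(secret, serialized.encode("utf-8"), hashlib.sha256).digest()
    return LinkageKey(spec.label, serialized, digest)


def digest_equal(a: LinkageKey, b: LinkageKey) -> bool:
    """Compare two keys by digest.

    Keys from different iteration specs are never meaningfully comparable;
    doing so signals a programming bug and raises."""
    if a.spec_label != b.spec_label:
        raise ValueError(f"cannot compare keys from different specs "
                         f"({a.spec_label!r} vs {b.spec_label!r})")
    return hmac.compare_digest(a.digest, b.digest)
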
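"""Validity screening of smart pump records.

Pumps identify patients only through a hand-typed ID string and identify
the medication only when staff select a drug-library profile, so a large
share of pump records cannot be attached to an EHR order.  This module
classifies every SPR into the four validity quadrants (patient ID
valid/invalid x medication name present/absent) and categorizes each
invalid patient ID into one of nine observed failure modes:

1. date of birth entered instead of an ID (year outside 1965-2014),
2. patient name entered instead of an ID,
3. missing digits,
4. random numbers,
5. encounter ID entered instead of a patient ID,
6. invalid letters in the ID,
7. expired ID from a merged chart,
8. extra digits,
9. potential typographical error (one substituted digit).

An input string can match several of these patterns, so classification
runs a fixed specific-before-generic precedence chain (see
:func:`classify_invalid_id`) to make the categories mutually exclusive
and deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional

from .records import SPREntry
from .utils import round_half_up

#: The nine invalid-ID categories, in report order.
INVALID_ID_CATEGORIES = (
    "dob_out_of_range",
    "patient_name",
    "missing_digits",
    "random_number",
    "encounter_id",
    "invalid_letters",
    "expired_id",
    "extra_digits",
    "typographical",
)

#: Year range considered a plausible (in-range) date of birth; dates
#: with years outside this range are the "DOB out of range" category.
DOB_YEAR_RANGE = (1965, 2014)


@dataclass
class PatientRegistry:
    """The reference sets an institution would hold: active patient IDs,
    expired IDs mapped to their merged chart, encounter IDs, and patient
    names (as they might be typed into a pump)."""

    valid_ids: frozenset = frozenset()
    expired_ids: dict[str, str] = field(default_factory=dict)
    encounter_ids: frozenset = frozenset()
    patient_names: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.valid_ids = frozenset(self.valid_ids)
        self.encounter_ids = frozenset(self.encounter_ids)
        self.patient_names = frozenset(self.patient_names)
        if not self.valid_ids:
            raise ValueError("patient registry must contain at least one valid ID")
        overlap = self.valid_ids & set(self.expired_ids)
        if overlap:
            raise ValueError(f"expired IDs overlap valid IDs: {sorted(overlap)[:3]}")

    @property
    def id_length(self) -> int:
        """Canonical patient-ID length (the most common length among
        valid IDs); length-deficit/excess categories are judged against
        it."""
        counts = Counter(len(v) for v in self.valid_ids)
        return counts.most_common(1)[0][0]


@dataclass(frozen=True)
class ScreenResult:
    """Validity-quadrant assignment for one SPR."""

    spr_id: str
    id_valid: bool
    name_present: bool
    invalid_category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.id_valid and self.invalid_category is not None:
            raise ValueError("valid IDs carry no invalid category")
        if not self.id_valid and self.invalid_category is None:
            raise ValueError("invalid IDs must carry a category")


def _parse_date_8(digits: str) -> Optional[int]:
    """Return the year if an 8-digit string parses as YYYYMMDD or
    MMDDYYYY on the real calendar, else None (YYYYMMDD tried first)."""
    for y, m, d in ((digits[:4], digits[4:6], digits[6:]), (digits[4:], digits[:2], digits[2:4])):
        try:
            datetime(int(y), int(m), int(d))
        except ValueError:
            continue
        return int(y)
    return None


def looks_like_out_of_range_dob(raw: str) -> bool:
    """8 digits parseable as a calendar date with year outside the
    plausible DOB range."""
    if len(raw) != 8 or not raw.isdigit():
        return False
    year = _parse_date_8(raw)
    return year is not None and not (DOB_YEAR_RANGE[0] <= year <= DOB_YEAR_RANGE[1])


def _is_typo(raw: str, registry: PatientRegistry) -> bool:
    """One substituted character away from some valid ID (substitution
    only, keeping this category disjoint from the length-based ones)."""
    n = len(raw)
    for valid in registry.valid_ids:
        if len(valid) != n:
            continue
        if sum(a != b for a, b in zip(raw, valid)) == 1:
            return True
    return False


def classify_invalid_id(raw: str, registry: PatientRegistry) -> str:
    """Categorize an invalid patient-ID string.

    Precedence (specific before generic): empty/whitespace (degenerate
    length deficit) -> patient-name match -> encounter-ID match ->
    expired/merged-chart ID -> date-like with out-of-range year ->
    contains letters -> too few digits -> too many digits -> one
    substitution from a valid ID -> random number.
    """
    raw = raw.strip()
    if raw in registry.valid_ids:
        raise ValueError(f"{raw!r} is a valid patient ID; nothing to classify")
    if not raw:
        return "missing_digits"
    if raw in registry.patient_names:
        return "patient_name"
    if raw in registry.encounter_ids:
        return "encounter_id"
    if raw in registry.expired_ids:
        return "expired_id"
    if looks_like_out_of_range_dob(raw):
        return "dob_out_of_range"
    if any(c.isalpha() for c in raw):
        return "invalid_letters"
    if raw.isdigit():
        if len(raw) < registry.id_length:
            return "missing_digits"
        if len(raw) > registry.id_length:
            return "extra_digits"
        if _is_typo(raw, registry):
            return "typographical"
    return "random_number"


def screen_spr(
    spr: SPREntry, registry: PatientRegistry, drug_library: Iterable[str]
) -> ScreenResult:
    """Assign one SPR to its validity quadrant.

    The ID is valid iff the raw string is in the registry's active set;
    the medication name is present iff nonempty and in the pump drug
    library (a *basic* infusion leaves it empty).
    """
    library = set(drug_library)
    raw = spr.patient_id_raw.strip()
    id_valid = raw in registry.valid_ids
    name_present = bool(spr.medication) and spr.medication in library
    category = None if id_valid else classify_invalid_id(raw, registry)
    return ScreenResult(spr.spr_id, id_valid, name_present, category)


@dataclass(frozen=True)
class QuadrantTable:
    """2x2 validity counts with percentages of the grand total.

    Cells follow the report convention: rows = medication name present /
    absent, columns = patient ID valid / invalid.
    """

    n_id_name: int  # ID+ name+
    n_noid_name: int  # ID- name+
    n_id_noname: int  # ID+ name-
    n_noid_noname: int  # ID- name-

    @property
    def total(self) -> int:
        return self.n_id_name + self.n_noid_name + self.n_id_noname + self.n_noid_noname

    def percentages(self, ndigits: int = 2) -> tuple[float, float, float, float]:
        """Cell percentages of the grand total, in the same order as the
        count fields."""
        return tuple(
            round_half_up(100.0 * n / self.total, ndigits)
            for n in (self.n_id_name, self.n_noid_name, self.n_id_noname, self.n_noid_noname)
        )

    @property
    def n_invalid(self) -> int:
        """Records unusable for linkage (any quadrant except ID+ name+)."""
        return self.n_noid_name + self.n_id_noname + self.n_noid_noname

    def invalid_breakdown(self, ndigits: int = 1) -> dict[str, float]:
        """Shares of the invalid records attributable to an invalid
        patient ID (name still present), a missing medication name (ID
        still valid), and both identifiers missing/invalid."""
        if self.n_invalid == 0:
            return {}
        return {
            "invalid_patient_id": round_half_up(100.0 * self.n_noid_name / self.n_invalid, ndigits),
            "missing_medication_name": round_half_up(
                100.0 * self.n_id_noname / self.n_invalid, ndigits
            ),
            "both_missing": round_half_up(100.0 * self.n_noid_noname / self.n_invalid, ndigits),
        }


def quadrant_table(results: Iterable[ScreenResult]) -> QuadrantTable:
    """Tally screen results into the four validity quadrants."""
    results = list(results)
    if not results:
        raise ValueError("quadrant_table requires at least one screen result")
    counts = Counter((r.id_valid, r.name_present) for r in results)
    return QuadrantTable(
        n_id_name=counts[(True, True)],
        n_noid_name=counts[(False, True)],
        n_id_noname=counts[(True, False)],
        n_noid_noname=counts[(False, False)],
    )


def category_counts(results: Iterable[ScreenResult]) -> dict[str, int]:
    """Invalid-ID category tallies in report order."""
    counts = Counter(r.invalid_category for r in results if not r.id_valid)
    return {cat: counts.get(cat, 0) for cat in INVALID_ID_CATEGORIES}
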
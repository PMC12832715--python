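"""Sepsis classification of harmonized records.

Two rules, matching the data each registry can support:

* **single-cause (SCOD)** — one code per record (underlying cause of death
  or primary cause of hospitalization).  A record is sepsis-related if its
  code is an *explicit* sepsis code (e.g. A41.0, sepsis due to
  S. aureus) or an *implicit* one: an infection or an organ-dysfunction
  code from the configured lists.
* **multiple-cause (MCOD)** — all codes across certificate lines A-D.  A
  record is sepsis-related iff an explicit sepsis code appears on any line;
  implicit categories are not used in MCOD mode.

Lists are dot-free ICD-10 prefixes loaded from YAML; a 3-character prefix
covers its 4-character children, a 4-character entry matches only exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

from .icd import ICDCodeError, normalize_icd10
from .registry_io import PersonRecord

__all__ = [
    "CodeLists",
    "SepsisCall",
    "load_code_lists",
    "default_code_lists",
    "match_code",
    "is_sepsis_scod",
    "is_sepsis_mcod",
    "classify_record",
]

LABELS = ("explicit", "implicit_infection", "implicit_dysfunction", "not_sepsis")


class CodeListError(ValueError):
    pass


@dataclass(frozen=True)
class CodeLists:
    explicit: frozenset
    infection: frozenset
    organ_dysfunction: frozenset
    provenance: str = ""

    def __post_init__(self):
        seen: set[str] = set()
        for name in ("explicit", "infection", "organ_dysfunction"):
            for prefix in getattr(self, name):
                try:
                    norm = normalize_icd10(prefix)
                except ICDCodeError as exc:
                    raise CodeListError(f"{name} entry {prefix!r}: {exc.reason}") from exc
                if norm != prefix:
                    raise CodeListError(f"{name} entry {prefix!r} is not in normalized form")
                if prefix in seen:
                    raise CodeListError(f"duplicate entry {prefix!r} across lists")
                seen.add(prefix)


@dataclass(frozen=True)
class SepsisCall:
    """Outcome of matching one code: category label plus the matched code
    and list entry (both None iff not sepsis)."""

    label: str
    matched_code: str | None
    matched_prefix: str | None

    def __post_init__(self):
        if (self.label == "not_sepsis") != (self.matched_code is None):
            raise CodeListError("not_sepsis iff matched_code is None")


def _as_set(entries: Iterable[str]) -> frozenset:
    return frozenset(str(e).strip().upper().replace(".", "") for e in entries)


def load_code_lists(path: str | Path) -> CodeLists:
    """Load and validate the three code lists from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("explicit", "infection", "organ_dysfunction"):
        if key not in raw or not raw[key]:
            raise CodeListError(f"code-list file missing non-empty {key!r} array")
    return CodeLists(
        explicit=_as_set(raw["explicit"]),
        infection=_as_set(raw["infection"]),
        organ_dysfunction=_as_set(raw["organ_dysfunction"]),
        provenance=str(raw.get("provenance", "")),
    )


def default_code_lists() -> CodeLists:
    """The packaged sepsis code lists."""
    ref = resources.files("sepsisburden").joinpath("data/code_lists.yaml")
    with resources.as_file(ref) as path:
        return load_code_lists(path)


def _prefix_match(code: str, prefixes: frozenset) -> str | None:
    # prefer the most specific match: exact 4-char entry, then 3-char parent
    if code in prefixes:
        return code
    if code[:3] in prefixes:
        return code[:3]
    return None


def match_code(code: str, lists: CodeLists) -> SepsisCall:
    """Classify one normalized code with precedence
    explicit > infection > organ dysfunction."""
    code = normalize_icd10(code)
    for label, prefixes in (
        ("explicit", lists.explicit),
        ("implicit_infection", lists.infection),
        ("implicit_dysfunction", lists.organ_dysfunction),
    ):
        hit = _prefix_match(code, prefixes)
        if hit is not None:
            return SepsisCall(label=label, matched_code=code, matched_prefix=hit)
    return SepsisCall(label="not_sepsis", matched_code=None, matched_prefix=None)


def is_sepsis_scod(record: PersonRecord, lists: CodeLists, implicit_rule: str = "or") -> bool:
    """Single-cause sepsis call on a one-code record.

    With the default ``implicit_rule="or"`` a lone infection OR a lone
    organ-dysfunction code marks the record sepsis-related.  The stricter
    ``"and"`` rule (kept for sensitivity analyses) requires both an
    infection and a dysfunction code, which a single-code record can only
    satisfy through an explicit code.
    """
    if len(record.causes) != 1:
        raise CodeListError(
            f"single-cause classification requires exactly one code, got {len(record.causes)}"
        )
    call = match_code(record.causes[0], lists)
    if implicit_rule == "or":
        return call.label != "not_sepsis"
    if implicit_rule == "and":
        return call.label == "explicit"
    raise CodeListError(f"unknown implicit_rule {implicit_rule!r}")


def is_sepsis_mcod(record: PersonRecord, lists: CodeLists) -> bool:
    """Multiple-cause sepsis call: explicit code on any certificate line."""
    return any(match_code(c, lists).label == "explicit" for c in record.causes)


def classify_record(record: PersonRecord, lists: CodeLists) -> SepsisCall:
    """Best call across a record's codes (explicit beats implicit beats
    none); useful for labeling tables."""
    best = SepsisCall("not_sepsis", None, None)
    order = {label: i for i, label in enumerate(LABELS)}
    for code in record.causes:
        call = match_code(code, lists)
        if order[call.label] < order[best.label]:
            best = call
    return best
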
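"""ICD-10 code normalization, structural validation and chapter lookup.

Registry extracts ship cause-of-death / cause-of-hospitalization fields in a
variety of dialects: lowercase codes, dotted codes ("A41.0"), and
four-character codes padded with the "X" placeholder ("J18X").  Everything
downstream assumes a single canonical form: 3 or 4 characters, uppercase
letter followed by two digits, optional fourth digit, no dot, no placeholder.
"""

from __future__ import annotations

import re

__all__ = ["ICDCodeError", "normalize_icd10", "is_valid_icd10", "chapter_of", "CHAPTERS"]


class ICDCodeError(ValueError):
    """Structural violation in an ICD-10 code; ``reason`` is a stable token."""

    def __init__(self, raw: str, reason: str):
        self.raw = raw
        self.reason = reason
        super().__init__(f"invalid ICD-10 code {raw!r}: {reason}")


_VALID = re.compile(r"^[A-Z][0-9]{2}[0-9]?$")

# 22 ICD-10 chapters as (roman numeral, first 3-char code, last 3-char code).
# Chapter XIX spans S00-T98 and XX spans V01-Y98; comparisons are on the
# 3-character prefix, which is totally ordered lexicographically.
CHAPTERS: tuple[tuple[str, str, str], ...] = (
    ("I", "A00", "B99"),
    ("II", "C00", "D48"),
    ("III", "D50", "D89"),
    ("IV", "E00", "E90"),
    ("V", "F00", "F99"),
    ("VI", "G00", "G99"),
    ("VII", "H00", "H59"),
    ("VIII", "H60", "H95"),
    ("IX", "I00", "I99"),
    ("X", "J00", "J99"),
    ("XI", "K00", "K93"),
    ("XII", "L00", "L99"),
    ("XIII", "M00", "M99"),
    ("XIV", "N00", "N99"),
    ("XV", "O00", "O99"),
    ("XVI", "P00", "P96"),
    ("XVII", "Q00", "Q99"),
    ("XVIII", "R00", "R99"),
    ("XIX", "S00", "T98"),
    ("XX", "V01", "Y98"),
    ("XXI", "Z00", "Z99"),
    ("XXII", "U00", "U99"),
)


def normalize_icd10(raw: str) -> str:
    """Normalize a raw ICD-10 string to canonical 3/4-character form.

    Uppercases, strips whitespace and dots, and trims a trailing "X"
    placeholder from four-character codes ("J18X" -> "J18").  Raises
    :class:`ICDCodeError` with a reason token for codes that are empty,
    missing the leading letter, containing illegal characters, ending in a
    letter after normalization, or of length outside {3, 4}.
    """
    if raw is None:
        raise ICDCodeError("", "empty")
    code = str(raw).strip().upper().replace(".", "")
    if not code:
        raise ICDCodeError(raw, "empty")
    if len(code) == 4 and code[3] == "X":
        code = code[:3]
    if len(code) not in (3, 4):
        raise ICDCodeError(raw, "bad-length")
    if not code[0].isalpha():
        raise ICDCodeError(raw, "missing-first-letter")
    if not ("A" <= code[0] <= "Z"):
        raise ICDCodeError(raw, "illegal-character")
    if not (code[1].isdigit() and code[2].isdigit()):
        raise ICDCodeError(raw, "illegal-character")
    if len(code) == 4 and not code[3].isdigit():
        raise ICDCodeError(raw, "trailing-letter")
    return code


def is_valid_icd10(code: str) -> bool:
    """True iff ``code`` is already in canonical normalized form."""
    return bool(_VALID.match(code))


def chapter_of(code: str) -> str:
    """Roman-numeral ICD-10 chapter of a normalized code (e.g. "A00" -> "I")."""
    prefix = normalize_icd10(code)[:3]
    for numeral, lo, hi in CHAPTERS:
        if lo <= prefix <= hi:
            return numeral
    raise ICDCodeError(code, "no-chapter")
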
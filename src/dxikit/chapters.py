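"""WHO chapter structure of the ICD-10-CM code space.

Chapters are identified by the leading three characters of a code. The
emergency-use block (U00-U99) is carried as its own pseudo-chapter so that
COVID-19-era codes remain classifiable.
"""

from __future__ import annotations

import re

#: (range start, range end inclusive, abbreviation, label) per WHO chapter.
#: Ranges compare lexicographically on the first three characters of an
#: undotted uppercase code; ASCII ordering puts digits before letters, which
#: makes alphanumeric category codes such as O9A sort after O99 as intended.
CHAPTERS: list[tuple[str, str, str, str]] = [
    ("A00", "B99", "INF", "Certain infectious and parasitic diseases"),
    ("C00", "D49", "NEO", "Neoplasms"),
    ("D50", "D89", "BLD", "Diseases of the blood and blood-forming organs"),
    ("E00", "E89", "END", "Endocrine, nutritional, and metabolic diseases"),
    ("F01", "F99", "MBD", "Mental, behavioral, and neurodevelopmental disorders"),
    ("G00", "G99", "NVS", "Diseases of the nervous system"),
    ("H00", "H59", "EYE", "Diseases of the eye and adnexa"),
    ("H60", "H95", "EAR", "Diseases of the ear and mastoid process"),
    ("I00", "I99", "CIR", "Diseases of the circulatory system"),
    ("J00", "J99", "RSP", "Diseases of the respiratory system"),
    ("K00", "K95", "DIG", "Diseases of the digestive system"),
    ("L00", "L99", "SKN", "Diseases of the skin and subcutaneous tissue"),
    ("M00", "M99", "MSK", "Diseases of the musculoskeletal system and connective tissue"),
    ("N00", "N99", "GEN", "Diseases of the genitourinary system"),
    ("O00", "O9A", "PRG", "Pregnancy, childbirth, and the puerperium"),
    ("P00", "P96", "PNL", "Certain conditions originating in the perinatal period"),
    ("Q00", "Q99", "MAL", "Congenital malformations and chromosomal abnormalities"),
    ("R00", "R99", "SYM", "Symptoms, signs, and abnormal findings, NEC"),
    ("S00", "T88", "INJ", "Injury, poisoning, and other consequences of external causes"),
    ("U00", "U99", "SPL", "Emergency code additions"),
    ("V00", "Y99", "EXT", "External causes of morbidity"),
    ("Z00", "Z99", "FAC", "Factors influencing health status"),
]

CHAPTER_ABBREVS: list[str] = [abbrev for _, _, abbrev, _ in CHAPTERS]

#: Cross-cutting items (modifiers and some scales) declare this pseudo-chapter.
CROSS_CUTTING = "cross-cutting"

# Undotted uppercase; 3-7 characters; first char any letter (U is the
# emergency-use block), second char a digit.
_CODE_RE = re.compile(r"^[A-Z][0-9][0-9A-Z]{1,5}$")


class InvalidCodeError(ValueError):
    """A diagnosis code that does not follow ICD-10-CM syntax."""


def canonicalize_code(code: str) -> str:
    """Return the canonical (undotted, uppercase) spelling of *code*.

    Raises :class:`InvalidCodeError` for syntactically invalid input; codes
    are never silently dropped.
    """
    canonical = str(code).strip().upper().replace(".", "")
    if not _CODE_RE.match(canonical):
        raise InvalidCodeError(f"not a valid ICD-10-CM-shaped code: {code!r}")
    return canonical


def is_valid_code(code: str) -> bool:
    try:
        canonicalize_code(code)
    except InvalidCodeError:
        return False
    return True


def chapter_of(code: str) -> str:
    """Chapter abbreviation for a code, derived from its leading range."""
    canonical = canonicalize_code(code)
    head = canonical[:3]
    for start, end, abbrev, _ in CHAPTERS:
        if start <= head <= end:
            return abbrev
    raise InvalidCodeError(f"code {code!r} falls outside every chapter range")
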
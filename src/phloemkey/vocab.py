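"""Controlled vocabularies for cytological traits of minor-vein phloem.

Every categorical trait used by the classification key is a closed vocabulary
with an explicit UNKNOWN member.  Absence of evidence (UNKNOWN) is always kept
distinct from evidence of absence (ABSENT / NO / NOT_DETECTED): an UNKNOWN
value never constrains a rule, while a known-negative one does.

The canonical file tokens mirror the notation used in the anatomical
literature: abundance grades are written "-", "+", "++", "+++" and unknown
cells are "?".
"""

from __future__ import annotations

import enum
from functools import total_ordering
from typing import Mapping


class VocabularyError(ValueError):
    """An input token does not belong to the vocabulary of a trait."""


class _TokenEnum(enum.Enum):
    """Enum whose members carry a canonical file token."""

    def __init__(self, token: str):
        self._token = token

    @property
    def token(self) -> str:
        return self._token

    @classmethod
    def parse(cls, token: str, aliases: Mapping[str, str] | None = None):
        """Parse a file token (case-insensitive; ``aliases`` maps extra
        spellings to canonical tokens)."""
        tok = token.strip()
        if aliases and tok in aliases:
            tok = aliases[tok]
        low = tok.lower()
        for member in cls:
            if member.token == low or member.name.lower() == low:
                return member
        # grade symbols are case-sensitive in no useful way, but keep the
        # raw token in the message for error reporting
        raise VocabularyError(f"{cls.__name__}: unknown token {token!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


@total_ordering
class Grade(_TokenEnum):
    """Ordinal abundance grade for plasmodesmal fields and wall ingrowths.

    Encodes the "-, +, ++, +++" scale.  ABSENT < SPARSE < MODERATE < ABUNDANT;
    UNKNOWN is incomparable and comparisons involving it raise ``TypeError``.
    """

    ABSENT = "-"
    SPARSE = "+"
    MODERATE = "++"
    ABUNDANT = "+++"
    UNKNOWN = "?"

    @property
    def rank(self) -> int:
        if self is Grade.UNKNOWN:
            raise TypeError("UNKNOWN grade has no rank")
        return ("-", "+", "++", "+++").index(self.token)

    @property
    def is_known(self) -> bool:
        return self is not Grade.UNKNOWN

    def __lt__(self, other: "Grade") -> bool:
        if not isinstance(other, Grade):
            return NotImplemented
        return self.rank < other.rank


class Branching(_TokenEnum):
    """Branching pattern of plasmodesmata within plasmodesmal fields."""

    ASYMMETRIC_CC_SIDE = "asymmetric"   # more branches on the companion-cell side
    SYMMETRIC = "symmetric"
    SINGLE_UNBRANCHED = "single"        # many single plasmodesmata, no true fields
    UNKNOWN = "?"


class CWIMorphology(_TokenEnum):
    """Morphology of companion-cell wall ingrowths."""

    RETICULATE = "reticulate"
    FLANGE = "flange"
    NONE = "none"
    UNKNOWN = "?"


class Plastid(_TokenEnum):
    LEUCOPLAST = "leucoplast"
    CHLOROPLAST = "chloroplast"
    UNKNOWN = "?"


class Tristate(_TokenEnum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "?"


class Evidence(_TokenEnum):
    """Outcome of a sugar (RFO) analysis: detected / not detected / not done."""

    DETECTED = "detected"
    NOT_DETECTED = "not_detected"
    UNKNOWN = "?"


class SlotPosition(_TokenEnum):
    ADAXIAL = "adaxial"
    ABAXIAL = "abaxial"
    LATERAL = "lateral"
    UNSPECIFIED = "unspecified"


class Symmetry(_TokenEnum):
    """Whether the vein shows a well-defined spatial organization."""

    WELL_DEFINED = "well_defined"
    NOT_WELL_DEFINED = "not_well_defined"
    UNKNOWN = "?"


class DivisionPlane(_TokenEnum):
    """Orientation of the first divisions of the phloem initial."""

    ANTICLINAL = "anticlinal"
    PERICLINAL = "periclinal"
    UNORDERED = "unordered"
    UNKNOWN = "?"


class GrowthForm(_TokenEnum):
    TREE = "tree"
    SHRUB = "shrub"
    PERENNIAL_HERB = "perennial_herb"
    ANNUAL_HERB = "annual_herb"
    UNKNOWN = "?"
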
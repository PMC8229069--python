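"""Algebra of IUPAC nucleotide ambiguity codes and zygosity classification.

A Sanger consensus of a tandem-repeat PCR fragment reports each position as a
single IUPAC character.  A canonical base (A/C/G/T) is a *homozygous* call, a
two-base ambiguity code (R/Y/S/W/K/M) a *heterozygous* call, a three-base code
(B/D/H/V) a *triplet* heterozygous call, and N (or a gap) asserts nothing.
This module provides the bijection between codes and base sets and the
classification of a call relative to a reference base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

logger = logging.getLogger(__name__)

GAP = "-"

#: IUPAC nucleotide code -> set of canonical bases it denotes.
CODE_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in CODE_TO_BASES.items()}

#: 4-bit mask per code (A=1, C=2, G=4, T=8); used by the alignment kernel.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
CODE_TO_MASK: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in CODE_TO_BASES.items()
}
CODE_TO_MASK[GAP] = 0

VALID_CODES = frozenset(CODE_TO_BASES)


class Zygosity(str, Enum):
    """Classification of a consensus call relative to a canonical reference base."""

    HOM_REF = "HOM_REF"  # single base equal to the reference
    HOM_ALT = "HOM_ALT"  # single base different from the reference
    HET_WITH_REF = "HET_WITH_REF"  # two-base code containing the reference
    HET_ALT_ONLY = "HET_ALT_ONLY"  # two-base code excluding the reference
    HET3 = "HET3"  # three-base ("triplet") code
    MISSING = "MISSING"  # gap or N: no base call asserted


def base_set(code: str) -> frozenset[str]:
    """Return the set of canonical bases a (case-insensitive) IUPAC code denotes.

    Raises ``ValueError`` for any character outside the 15-letter alphabet.
    """
    c = code.upper()
    try:
        return CODE_TO_BASES[c]
    except KeyError:
        raise ValueError(f"invalid IUPAC nucleotide code: {code!r}") from None


def encode_set(bases) -> str:
    """Inverse of :func:`base_set`: encode a nonempty set of canonical bases.

    ``encode_set(base_set(c)) == c`` for every valid code.
    """
    fs = frozenset(b.upper() for b in bases)
    if not fs:
        raise ValueError("cannot encode an empty base set")
    try:
        return BASES_TO_CODE[fs]
    except KeyError:
        bad = sorted(fs - frozenset("ACGT"))
        raise ValueError(f"not a set of canonical bases: {bad}") from None


def classify_state(code: str, ref: str) -> Zygosity:
    """Classify a consensus call against a canonical reference base.

    The gap character and N both map to MISSING: neither asserts a base call.
    """
    if ref.upper() not in _BASE_BIT:
        raise ValueError(f"reference must be a canonical base, got {ref!r}")
    c = code.upper()
    if c == GAP or c == "N":
        return Zygosity.MISSING
    bases = base_set(c)
    r = ref.upper()
    if len(bases) == 1:
        return Zygosity.HOM_REF if r in bases else Zygosity.HOM_ALT
    if len(bases) == 2:
        return Zygosity.HET_WITH_REF if r in bases else Zygosity.HET_ALT_ONLY
    return Zygosity.HET3  # size 3; size 4 is N, handled above


@dataclass(frozen=True)
class NucleotideState:
    """One IUPAC consensus call, decomposable to its base set."""

    code: str

    def __post_init__(self):
        if self.code != GAP and self.code.upper() not in VALID_CODES:
            raise ValueError(f"invalid IUPAC nucleotide code: {self.code!r}")
        object.__setattr__(self, "code", self.code.upper() if self.code != GAP else GAP)

    @property
    def base_set(self) -> frozenset[str]:
        return frozenset() if self.code == GAP else CODE_TO_BASES[self.code]

    @classmethod
    def from_bases(cls, bases) -> "NucleotideState":
        return cls(encode_set(bases))

    def zygosity(self, ref: str) -> Zygosity:
        return classify_state(self.code, ref)


def clean_sequence(seq: str, name: str = "<sequence>") -> str:
    """Upper-case a nucleotide string, map U to T, and validate every character.

    Sequences are handled in DNA space; RNA-style U triggers a logged warning.
    Invalid characters are rejected with the offending character and its
    1-based position.
    """
    s = seq.upper()
    if "U" in s:
        logger.warning("%s: 'U' mapped to 'T' (working in DNA space)", name)
        s = s.replace("U", "T")
    for i, c in enumerate(s):
        if c not in VALID_CODES:
            raise ValueError(
                f"{name}: invalid IUPAC character {c!r} at position {i + 1}"
            )
    return s
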
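"""Small shared sequence utilities (IUPAC codes, reverse complement)."""

from __future__ import annotations

IUPAC_SETS: dict[str, frozenset[str]] = {
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

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_mismatches(primer: str, window: str) -> int:
    """Number of window positions not covered by the primer's IUPAC sets."""
    return sum(
        1
        for p, b in zip(primer, window)
        if b not in IUPAC_SETS.get(p, frozenset())
    )


def instantiate_iupac(primer: str) -> str:
    """Replace each ambiguity code by its alphabetically first base."""
    return "".join(min(IUPAC_SETS[p]) for p in primer.upper())
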
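"""IUPAC nucleotide code tables shared across modules."""

from __future__ import annotations

#: Concrete nucleotides.
BASES = frozenset("ACGT")

#: IUPAC ambiguity code -> set of compatible concrete bases.
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

#: Codes that denote more than one base (N included).
AMBIGUITY_CODES = frozenset(c for c, s in IUPAC_SETS.items() if len(s) > 1)

#: Full sequence alphabet accepted on input (gap allowed for re-ingested alignments).
ALPHABET = frozenset(IUPAC_SETS) | {"-"}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def code_for(bases: frozenset[str] | set[str]) -> str:
    """Return the IUPAC code for a set of concrete bases."""
    target = frozenset(bases)
    for code, s in IUPAC_SETS.items():
        if s == target:
            return code
    raise ValueError(f"no IUPAC code for base set {sorted(target)!r}")


def compatible(code_a: str, code_b: str) -> bool:
    """True if the two codes share at least one concrete base."""
    sa = IUPAC_SETS.get(code_a)
    sb = IUPAC_SETS.get(code_b)
    if sa is None or sb is None:
        return False
    return bool(sa & sb)
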
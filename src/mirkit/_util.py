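"""Shared sequence and coordinate helpers.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based inclusive convention used by GFF3 and report tables goes through
:func:`to_one_based` / :func:`from_one_based` only.
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGUN")
DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT_RNA = str.maketrans("ACGUN", "UGCAN")
_COMPLEMENT_DNA = str.maketrans("ACGTN", "TGCAN")

#: canonical pairs plus G:U wobble, as accepted by the fallback folder
CAN_PAIR = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

WC_PAIR = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
GU_PAIR = frozenset({("G", "U"), ("U", "G")})


def to_rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement; works for RNA or DNA, preserving the alphabet."""
    s = seq.upper()
    if "U" in s or ("T" not in s and s and set(s) <= RNA_ALPHABET):
        return s.translate(_COMPLEMENT_RNA)[::-1]
    return s.translate(_COMPLEMENT_DNA)[::-1]


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    if start0 >= end0:
        raise ValueError(f"empty or inverted interval [{start0}, {end0})")
    return start0 + 1, end0


def from_one_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start1 > end1 or start1 < 1:
        raise ValueError(f"invalid 1-based interval {start1}..{end1}")
    return start1 - 1, end1


def family_of(name: str) -> str:
    """miRNA family from a member name: "miR156a" -> "miR156", "new-11" -> "new-11".

    Conserved members carry trailing letters (miR166a, miR319cd); new miRNAs
    are numbered families whose members, if any, also carry letters
    (new-6ab -> new-6).
    """
    import re

    m = re.match(r"^(miR\d+)[a-z]*$", name)
    if m:
        return m.group(1)
    m = re.match(r"^(new-\d+)[a-z]*$", name)
    if m:
        return m.group(1)
    return name
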
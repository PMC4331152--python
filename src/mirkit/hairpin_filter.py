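"""Secondary-structure and duplex criteria for candidate miRNA precursors.

A candidate window passes when, after free-tail trimming, its structure has
at least 18 bp in matched regions, exactly one terminal (central) loop and a
folding energy <= -18 kcal/mol, and when the mature:star duplex implied by
the structure shows <= 4 mismatches, <= 2 bulged or asymmetrically unpaired
nucleotides and no run of more than 2 consecutive mismatches in the seed
region (mature positions 2-8 by default).

Structures can come from an external folder's dot-bracket report (authoritative
when supplied) or from the built-in base-pair-maximization fallback folder,
whose pseudo-energy scale is cruder than a thermodynamic MFE but is used
against the same -18 threshold (documented caveat).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional

from . import _fold
from .io_core import FormatError, RunConfig
from ._util import to_rna

_LOOP_RE = re.compile(r"\(\.*\)")


class StructureError(ValueError):
    """Invalid dot-bracket structure or mature placement."""


@dataclass(frozen=True)
class GenomeLocus:
    """Genomic placement of a precursor window (0-based half-open)."""

    contig: str
    start: int
    end: int
    strand: str
    id: str = ""


@dataclass(frozen=True)
class HairpinCandidate:
    """A candidate precursor: sequence, structure, energy and mature arm."""

    id: str
    seq: str
    structure: str
    mfe: float
    mature_span: tuple[int, int]
    locus: Optional[GenomeLocus] = None
    provenance: str = "external"  # or "fallback"

    def __post_init__(self):
        if len(self.structure) != len(self.seq):
            raise StructureError(
                f"{self.id}: structure length {len(self.structure)} != "
                f"sequence length {len(self.seq)}"
            )
        pair_table(self.structure)  # raises if unbalanced
        s, e = self.mature_span
        if not (0 <= s < e <= len(self.seq)):
            raise StructureError(f"{self.id}: mature_span {self.mature_span} outside sequence")

    @property
    def mature(self) -> str:
        s, e = self.mature_span
        return self.seq[s:e]


@dataclass(frozen=True)
class DuplexStats:
    """Mismatch/bulge accounting of the mature:star duplex.

    A mismatch is a pair of opposed unpaired positions; a G:U pair counts as
    paired (dot-bracket marks it paired). Bulged counts nucleotides unpaired
    on one strand with no opposed unpaired partner. Terminal unpaired mature
    positions, whose opposition is undefined, are counted as mismatches.
    """

    paired_bp: int
    n_loops: int
    mismatches: int
    bulged: int
    max_run_seed_mm: int
    seed_span: tuple[int, int]


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 when unpaired); error if unbalanced."""
    table = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[i], table[j] = j, i
        elif c != ".":
            raise StructureError(f"invalid character {c!r} at position {i}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return table


def count_loops(structure: str) -> int:
    """Number of terminal (hairpin) loops: innermost '(...)' spans of dots."""
    return len(_LOOP_RE.findall(structure))


def fold_fallback(seq: str) -> tuple[str, float]:
    """Fold with the built-in pair-maximization DP.

    Returns (dot-bracket, pseudo-energy) where pseudo-energy is
    -(2*GC + 1*AU + 1*GU) kcal/mol over paired positions. Candidates built
    from this folder carry provenance "fallback".
    """
    structure, energy = _fold.fold(to_rna(seq))
    return structure, float(energy)


def parse_vienna(text: str) -> list[HairpinCandidate]:
    """Parse a Vienna-style dot-bracket report.

    Records are ``>header`` / sequence / structure lines, the structure line
    ending in the energy in parentheses, e.g. ``((((....)))) (-19.20)``.
    A ``mature=a..b`` token in the header (1-based inclusive) records the
    mature span; otherwise the span defaults to the whole sequence.
    """
    candidates = []
    lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"expected '>' header, got {lines[i]!r}")
        header = lines[i][1:].strip()
        if i + 2 >= len(lines):
            raise FormatError(f"truncated record {header!r}")
        seq = to_rna(lines[i + 1].strip())
        m = re.match(r"^([.()]+)\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)$", lines[i + 2].strip())
        if not m:
            raise FormatError(f"{header}: malformed structure line {lines[i + 2]!r}")
        structure, energy = m.group(1), float(m.group(2))
        name = header.split()[0]
        span_m = re.search(r"mature=(\d+)\.\.(\d+)", header)
        if span_m:
            span = (int(span_m.group(1)) - 1, int(span_m.group(2)))
        else:
            span = (0, len(seq))
        candidates.append(
            HairpinCandidate(name, seq, structure, energy, span, provenance="external")
        )
        i += 3
    return candidates


def trim_free_tails(
    candidate: HairpinCandidate,
) -> tuple[Optional[HairpinCandidate], Optional[str]]:
    """Remove unpaired 5' and 3' terminal runs outside the outermost pair.

    Returns (trimmed candidate, None) on success. Failure modes return
    (None, reason): "empty_stem" when the structure has no pairs, and
    "mature_in_tail" when the mature span overlaps a trimmed tail.
    Idempotent; for fallback-derived candidates the pseudo-energy is
    recomputed from the (unchanged) retained pairs.
    """
    st = candidate.structure
    first = st.find("(")
    if first == -1:
        return None, "empty_stem"
    last = st.rfind(")")
    if first == 0 and last == len(st) - 1:
        return candidate, None
    s, e = candidate.mature_span
    if s < first or e > last + 1:
        return None, "mature_in_tail"
    trimmed = replace(
        candidate,
        seq=candidate.seq[first : last + 1],
        structure=st[first : last + 1],
        mature_span=(s - first, e - first),
        mfe=_pseudo_energy(candidate.seq[first : last + 1], st[first : last + 1])
        if candidate.provenance == "fallback"
        else candidate.mfe,
    )
    return trimmed, None


def _pseudo_energy(seq: str, structure: str) -> float:
    table = pair_table(structure)
    weight = {frozenset("GC"): 2, frozenset("AU"): 1, frozenset("GU"): 1}
    e = 0
    for i, j in enumerate(table):
        if j > i:
            e -= weight.get(frozenset((seq[i], seq[j])), 0)
    return float(e)


def duplex_stats(candidate: HairpinCandidate, config: RunConfig | None = None) -> DuplexStats:
    """Mature:star duplex statistics implied by the candidate's structure.

    Raises :class:`StructureError` ("mature_spans_loop") when mature pairing
    partners fall on both sides of the mature span or inside it.
    """
    config = config or RunConfig()
    table = pair_table(candidate.structure)
    s, e = candidate.mature_span
    partners = [(i, table[i]) for i in range(s, e) if table[i] != -1]
    for i, j in partners:
        if s <= j < e:
            raise StructureError(f"{candidate.id}: mature_spans_loop")
    sides = {j > i for i, j in partners}
    if len(sides) > 1:
        raise StructureError(f"{candidate.id}: mature_spans_loop")

    # classify each unpaired mature position as mismatch (opposed unpaired
    # star position exists) or bulge; terminal unpaired positions count as
    # mismatches
    is_mm = [False] * (e - s)
    mismatches = 0
    bulged = 0
    if not partners:
        mismatches = e - s
        is_mm = [True] * (e - s)
    else:
        first_p = partners[0][0]
        last_p = partners[-1][0]
        for i in list(range(s, first_p)) + list(range(last_p + 1, e)):
            mismatches += 1
            is_mm[i - s] = True
        for (i1, j1), (i2, j2) in zip(partners, partners[1:]):
            a = i2 - i1 - 1  # unpaired mature positions in the gap
            b = abs(j1 - j2) - 1  # opposed unpaired star positions
            mm = min(a, b)
            mismatches += mm
            bulged += abs(a - b)
            for k in range(i1 + 1, i1 + 1 + mm):  # left-assigned within the gap
                is_mm[k - s] = True

    lo1, hi1 = config.hairpin_seed_span  # 1-based inclusive mature positions
    run = best_run = 0
    for pos1 in range(lo1, min(hi1, e - s) + 1):
        if is_mm[pos1 - 1]:
            run += 1
            best_run = max(best_run, run)
        else:
            run = 0

    if config.matched_region == "duplex":
        paired = len(partners)
    else:
        paired = candidate.structure.count("(")
    return DuplexStats(
        paired_bp=paired,
        n_loops=count_loops(candidate.structure),
        mismatches=mismatches,
        bulged=bulged,
        max_run_seed_mm=best_run,
        seed_span=(lo1, hi1),
    )


def structure_filter(
    candidate: HairpinCandidate, config: RunConfig | None = None
) -> tuple[bool, list[str]]:
    """Stem-level filter: >=18 matched bp, one central loop, energy <= -18."""
    config = config or RunConfig()
    reasons = []
    if config.matched_region == "duplex":
        table = pair_table(candidate.structure)
        s, e = candidate.mature_span
        paired = sum(1 for i in range(s, e) if table[i] != -1)
    else:
        paired = candidate.structure.count("(")
    if paired < config.min_paired_bp:
        reasons.append("min_paired_bp")
    if count_loops(candidate.structure) != 1:
        reasons.append("one_central_loop")
    if candidate.mfe > config.energy_max_kcal:
        reasons.append("energy")
    return not reasons, reasons


def mircheck_filter(
    candidate: HairpinCandidate, config: RunConfig | None = None
) -> tuple[bool, DuplexStats, list[str]]:
    """Duplex-level filter: <=4 mismatches, <=2 bulges, <=2-long seed runs."""
    config = config or RunConfig()
    stats = duplex_stats(candidate, config)
    reasons = []
    if stats.mismatches > config.max_duplex_mismatches:
        reasons.append("max_mismatches")
    if stats.bulged > config.max_duplex_bulges:
        reasons.append("max_bulges")
    if stats.max_run_seed_mm > config.max_seed_run:
        reasons.append("seed_run")
    return not reasons, stats, reasons
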
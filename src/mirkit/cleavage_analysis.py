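"""Classification of RLM-RACE clone 5' ends against miRNA complementary regions.

RLM-RACE recovers the 5' end of the 3' remnant of a sliced mRNA. Each clone
position is classified into one of three zones relative to the miRNA's
complementary region (CR) on the target:

* ``CR``: inside the region; the offset is the pairing position counted from
  the miRNA 5' end, which pairs the CR's 3' boundary on the mRNA. Canonical
  RISC slicing falls at positions 10-12.
* ``upstream``: 5' of the CR on the mRNA; offsets are positive distances
  from the CR 5' boundary (the "+8th" style of reporting).
* ``downstream``: 3' of the CR; offsets are negative distances from the CR
  3' boundary ("-35th"). The +/- sign convention follows the way such
  tables are printed, even though it inverts genomic-orientation intuition.

Clone positions are mRNA coordinates (0-based) of the remnant's first
nucleotide. A half-integer position k+0.5 encodes a 5' end resolved only to
the two nucleotides it straddles; such records classify to an offset pair
and render as "10th/11th".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io_core import read_table, write_table


@dataclass(frozen=True)
class PairRecord:
    """One assayed miRNA:target pair with its CR placement on the target."""

    pair_id: str
    mirna_id: str
    target_id: str
    annotation: str
    cr: tuple[int, int]  # 0-based half-open on the target mRNA
    mirna_length: int
    mrna_length: Optional[int] = None

    def __post_init__(self):
        if self.cr[1] - self.cr[0] != self.mirna_length:
            raise ValueError(
                f"{self.pair_id}: CR length {self.cr[1] - self.cr[0]} != "
                f"miRNA length {self.mirna_length} (bulge-free CRs only)"
            )


@dataclass(frozen=True)
class CleavageClone:
    """Observed 5' end of a truncated mRNA; ``count`` clones at ``position``."""

    pair_id: str
    position: float  # 0-based; half-integers straddle two nucleotides
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError(f"{self.pair_id}: clone count must be >= 1")
        if self.position < 0:
            raise ValueError(f"{self.pair_id}: negative clone position")
        if (self.position * 2) != int(self.position * 2):
            raise ValueError(f"{self.pair_id}: position must be integer or half-integer")


@dataclass(frozen=True)
class ClassifiedCleavage:
    zone: str  # "upstream" | "CR" | "downstream"
    offsets: tuple[int, ...]  # 1 entry, or 2 for boundary ("p/p+1") records
    count: int


@dataclass
class PairSummary:
    pair_id: str
    has_slicing: bool
    n_upstream: int
    n_cr: int
    n_downstream: int
    canonical: bool  # >= 1 CR cleavage at offsets 10-12
    cr_positions: Counter = field(default_factory=Counter)


@dataclass(frozen=True)
class ExperimentSummary:
    n_pairs: int
    n_sliced: int
    n_canonical: int
    n_noncr_only: int  # sliced pairs with zero CR clones


CANONICAL_OFFSETS = frozenset({10, 11, 12})


def _offset_of(pos: int, cr: tuple[int, int]) -> tuple[str, int]:
    """Zone and offset of a single nucleotide coordinate."""
    s, e = cr
    if pos < s:
        return "upstream", s - pos
    if pos < e:
        return "CR", e - pos  # miRNA 5' end pairs the CR 3' boundary
    return "downstream", -(pos - e + 1)


def classify_clone(clone: CleavageClone, pair: PairRecord) -> ClassifiedCleavage:
    """Map a clone 5'-end position to (zone, offsets).

    Integer positions classify to a single offset. Half-integer positions
    straddle two adjacent nucleotides and classify to the ordered offset
    pair; the zone is that of the lower-coordinate nucleotide.
    """
    if pair.mrna_length is not None and clone.position >= pair.mrna_length:
        raise ValueError(
            f"{clone.pair_id}: position {clone.position} beyond mRNA length "
            f"{pair.mrna_length}"
        )
    pos = clone.position
    if pos == int(pos):
        zone, off = _offset_of(int(pos), pair.cr)
        return ClassifiedCleavage(zone=zone, offsets=(off,), count=clone.count)
    lo = int(pos)  # straddles nucleotides lo and lo+1
    zone, off_lo = _offset_of(lo, pair.cr)
    _, off_hi = _offset_of(lo + 1, pair.cr)
    offsets = tuple(sorted((off_lo, off_hi), key=abs))
    return ClassifiedCleavage(zone=zone, offsets=offsets, count=clone.count)


def summarize_pair(
    clones: Iterable[CleavageClone], pair: PairRecord
) -> PairSummary:
    """Zone tallies (weighted by clone count) and the canonical-slicing flag.

    Canonical means at least one CR cleavage at pairing offsets 10-12;
    boundary "p/p+1" records qualify if either side is in 10-12.
    """
    n = {"upstream": 0, "CR": 0, "downstream": 0}
    cr_positions: Counter = Counter()
    canonical = False
    for clone in clones:
        if clone.pair_id != pair.pair_id:
            raise ValueError(
                f"clone for {clone.pair_id} passed to pair {pair.pair_id}"
            )
        cc = classify_clone(clone, pair)
        n[cc.zone] += cc.count
        if cc.zone == "CR":
            cr_positions[cc.offsets] += cc.count
            if any(o in CANONICAL_OFFSETS for o in cc.offsets):
                canonical = True
    total = sum(n.values())
    return PairSummary(
        pair_id=pair.pair_id,
        has_slicing=total >= 1,
        n_upstream=n["upstream"],
        n_cr=n["CR"],
        n_downstream=n["downstream"],
        canonical=canonical,
        cr_positions=cr_positions,
    )


def summarize_experiment(summaries: Sequence[PairSummary]) -> ExperimentSummary:
    if not summaries:
        raise ValueError("need >= 1 pair summary")
    return ExperimentSummary(
        n_pairs=len(summaries),
        n_sliced=sum(1 for s in summaries if s.has_slicing),
        n_canonical=sum(1 for s in summaries if s.canonical),
        n_noncr_only=sum(1 for s in summaries if s.has_slicing and s.n_cr == 0),
    )


def ordinal(n: int) -> str:
    """1 -> "1st", -35 -> "-35th" (table-style ordinals)."""
    a = abs(n)
    if a % 100 in (11, 12, 13):
        suf = "th"
    else:
        suf = {1: "st", 2: "nd", 3: "rd"}.get(a % 10, "th")
    return f"{n}{suf}"


def render_label(cc: ClassifiedCleavage) -> str:
    """Table-style text for one classified cleavage, e.g. "10th/11th(8)"."""
    body = "/".join(ordinal(o) for o in cc.offsets)
    return f"{body}({cc.count})"


# -- TSV plumbing ------------------------------------------------------------

def pairs_to_tsv(pairs: Sequence[PairRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "miRNA": p.mirna_id,
                "target": p.target_id,
                "annotation": p.annotation,
                "cr_start": p.cr[0] + 1,  # 1-based inclusive on disk
                "cr_end": p.cr[1],
                "mirna_length": p.mirna_length,
                "mrna_length": p.mrna_length if p.mrna_length is not None else -1,
            }
            for p in pairs
        ]
    )
    write_table(df, path)


def pairs_from_tsv(path) -> list[PairRecord]:
    df, _ = read_table(
        path,
        schema={
            "pair_id": str, "miRNA": str, "target": str, "annotation": str,
            "cr_start": int, "cr_end": int, "mirna_length": int, "mrna_length": int,
        },
        required=["pair_id", "miRNA", "target", "cr_start", "cr_end", "mirna_length"],
    )
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PairRecord(
                pair_id=row.pair_id,
                mirna_id=row.miRNA,
                target_id=row.target,
                annotation=getattr(row, "annotation", ""),
                cr=(row.cr_start - 1, row.cr_end),
                mirna_length=row.mirna_length,
                mrna_length=None if getattr(row, "mrna_length", -1) < 0 else row.mrna_length,
            )
        )
    return out


def clones_to_tsv(clones: Sequence[CleavageClone], path) -> None:
    df = pd.DataFrame(
        [
            {"pair_id": c.pair_id, "position": c.position, "count": c.count}
            for c in clones
        ]
    )
    write_table(df, path)


def clones_from_tsv(path) -> list[CleavageClone]:
    df, _ = read_table(
        path,
        schema={"pair_id": str, "position": float, "count": int},
        required=["pair_id", "position", "count"],
    )
    return [
        CleavageClone(row.pair_id, float(row.position), int(row.count))
        for row in df.itertuples(index=False)
    ]


def summary_table(
    pairs: Sequence[PairRecord], clones: Sequence[CleavageClone]
) -> pd.DataFrame:
    """Per-pair summary rows plus rendered cleavage-site labels."""
    by_pair: dict[str, list[CleavageClone]] = {p.pair_id: [] for p in pairs}
    for c in clones:
        if c.pair_id not in by_pair:
            raise ValueError(f"clone references unknown pair {c.pair_id}")
        by_pair[c.pair_id].append(c)
    rows = []
    for p in pairs:
        summ = summarize_pair(by_pair[p.pair_id], p)
        labels: dict[str, list[str]] = {"upstream": [], "CR": [], "downstream": []}
        for c in sorted(by_pair[p.pair_id], key=lambda c: c.position):
            cc = classify_clone(c, p)
            labels[cc.zone].append(render_label(cc))
        rows.append(
            {
                "pair_id": p.pair_id,
                "miRNA": p.mirna_id,
                "target": p.target_id,
                "annotation": p.annotation,
                "upstream": ", ".join(labels["upstream"]) or "/",
                "CR": ", ".join(labels["CR"]) or "/",
                "downstream": ", ".join(labels["downstream"]) or "/",
                "n_clones": summ.n_upstream + summ.n_cr + summ.n_downstream,
                "has_slicing": summ.has_slicing,
                "canonical": summ.canonical,
            }
        )
    return pd.DataFrame(rows)
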
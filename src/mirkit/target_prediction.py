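"""Complementarity-based miRNA target-site search in coding sequences.

A modified local-alignment dynamic program aligns the miRNA against the
reverse-complement reading of candidate mRNA windows: Watson-Crick match
+1.0, G:U wobble +0.5 (costing 0.5 mismatch units), mismatch -1.0 (1 unit),
gap -2.0 (1 unit). Sites with at most 3 mismatch units are reported and
scored with rewards for sequence-specific determinants: a mismatch-free
seed block (miRNA positions 2-13 by default, +2) and local AU content in
the 10 nt of mRNA flanking the seed-pairing region (up to +1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._util import GU_PAIR, WC_PAIR, family_of, to_rna
from .io_core import RunConfig, SequenceRecord, stage_log

GAP_SCORE = -2.0
MISMATCH_SCORE = -1.0
WC_SCORE = 1.0
GU_SCORE = 0.5
_SCREEN_COST = 10.0  # ungapped prescreen ceiling; see methods note


@dataclass(frozen=True)
class DuplexAlignment:
    """Alignment of a miRNA against one mRNA window (antiparallel)."""

    pairing: str  # per miRNA position: '|' WC, 'o' G:U, ' ' mismatch, '-' gap
    raw_score: float
    mismatch_cost: float
    window_span: tuple[int, int]  # aligned interval on the window, 0-based half-open
    mrna_coords: tuple[int, ...]  # window coordinate opposite each miRNA position, -1 if gapped


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    family: str
    unigene_id: str
    cr: tuple[int, int]  # complementary region on the mRNA, 0-based half-open
    pairing: str
    mismatch_cost: float
    raw_score: float
    final_score: float


def _score_cost(a: str, b: str, gu_cost: float) -> tuple[float, float]:
    if (a, b) in WC_PAIR:
        return WC_SCORE, 0.0
    if (a, b) in GU_PAIR:
        return GU_SCORE, gu_cost
    return MISMATCH_SCORE, 1.0


def duplex_align(
    mirna: str, mrna_window: str, config: RunConfig | None = None
) -> DuplexAlignment:
    """Best complementarity alignment of the full miRNA within the window.

    The miRNA (5'->3') is aligned against the window read 3'->5', so pairing
    is antiparallel. The whole miRNA must align; window ends are free.
    Among score-optimal alignments the one with the lowest mismatch cost is
    returned, with deterministic diagonal-first traceback.
    """
    config = config or RunConfig()
    a = to_rna(mirna)
    w = to_rna(mrna_window)
    if set(a) - set("ACGUN") or set(w) - set("ACGUN"):
        raise ValueError("non-RNA characters in duplex_align input")
    t = w[::-1]  # window read 3'->5'
    m, n = len(a), len(t)
    NEG = float("-inf")
    # value[i][j] = (score, -cost) for miRNA prefix i vs t prefix ending at j
    val = [[(NEG, 0.0)] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        val[0][j] = (0.0, 0.0)  # free leading window
    for i in range(1, m + 1):
        val[i][0] = (i * GAP_SCORE, -float(i))
        for j in range(1, n + 1):
            s, c = _score_cost(a[i - 1], t[j - 1], config.gu_mismatch_cost)
            diag = (val[i - 1][j - 1][0] + s, val[i - 1][j - 1][1] - c)
            up = (val[i - 1][j][0] + GAP_SCORE, val[i - 1][j][1] - 1.0)
            left = (val[i][j - 1][0] + GAP_SCORE, val[i][j - 1][1] - 1.0)
            val[i][j] = max(diag, up, left)
    j_end = max(range(n + 1), key=lambda j: val[m][j])
    # traceback, diagonal > up > left preference
    pairing = [" "] * m
    coords = [-1] * m
    i, j = m, j_end
    j_start = j_end
    while i > 0:
        s, c = (
            _score_cost(a[i - 1], t[j - 1], config.gu_mismatch_cost) if j > 0 else (None, None)
        )
        cur = val[i][j]
        if (
            j > 0
            and val[i - 1][j - 1][0] + s == cur[0]
            and val[i - 1][j - 1][1] - c == cur[1]
        ):
            if s == WC_SCORE:
                pairing[i - 1] = "|"
            elif s == GU_SCORE:
                pairing[i - 1] = "o"
            coords[i - 1] = n - j  # back to window orientation
            i, j = i - 1, j - 1
            j_start = j
        elif (
            val[i - 1][j][0] + GAP_SCORE == cur[0] and val[i - 1][j][1] - 1.0 == cur[1]
        ):
            pairing[i - 1] = "-"
            i -= 1
        else:
            j -= 1
            j_start = j
    score, negcost = val[m][j_end]
    return DuplexAlignment(
        pairing="".join(pairing),
        raw_score=score,
        mismatch_cost=-negcost,
        window_span=(n - j_end, n - j_start),
        mrna_coords=tuple(coords),
    )


def score_site(
    aln: DuplexAlignment,
    mrna_seq: str,
    site_start: int,
    config: RunConfig | None = None,
) -> tuple[float, float, float]:
    """Final score = raw + seed bonus + AU bonus.

    Seed bonus +2 when the configured seed block (miRNA positions 2-13,
    1-based) contains no mismatch and no gap (G:U allowed). AU bonus is
    +1 times the A/U fraction of the 10 mRNA nucleotides (5 per side,
    clipped) flanking the seed-pairing region.
    """
    config = config or RunConfig()
    lo1, hi1 = config.target_seed_span
    block = aln.pairing[lo1 - 1 : hi1]
    seed_bonus = 2.0 if block and " " not in block and "-" not in block else 0.0
    seed_coords = [
        site_start + c for c in aln.mrna_coords[lo1 - 1 : hi1] if c >= 0
    ]
    au_bonus = 0.0
    if seed_coords:
        lo, hi = min(seed_coords), max(seed_coords) + 1
        flanks = mrna_seq[max(0, lo - 5) : lo] + mrna_seq[hi : hi + 5]
        if flanks:
            au_bonus = sum(1 for b in flanks if b in "AU") / len(flanks)
    return seed_bonus, au_bonus, aln.raw_score + seed_bonus + au_bonus


def _ungapped_cost_profile(mirna: str, useq: str, gu_cost: float) -> np.ndarray:
    """Cost of the ungapped antiparallel duplex at each window start."""
    enc = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
    lut = np.ones((5, 5), dtype=np.float64)
    for (x, y) in WC_PAIR:
        lut[enc[x], enc[y]] = 0.0
    for (x, y) in GU_PAIR:
        lut[enc[x], enc[y]] = gu_cost
    u = np.array([enc.get(c, 4) for c in useq], dtype=np.int8)
    ar = np.array([enc[c] for c in mirna[::-1]], dtype=np.int8)
    m = len(ar)
    npos = len(u) - m + 1
    if npos <= 0:
        return np.empty(0)
    cost = np.zeros(npos)
    for i in range(m):
        cost += lut[ar[i], u[i : i + npos]]
    return cost


def predict_targets(
    mirnas: Sequence[tuple[str, str]] | Sequence[SequenceRecord],
    unigenes: Sequence[SequenceRecord],
    config: RunConfig | None = None,
) -> list[TargetSite]:
    """Scan every unigene for complementary sites of every miRNA.

    ``mirnas`` is a sequence of (id, sequence) pairs or SequenceRecords.
    Sites with mismatch_cost <= 3 units are reported; overlapping windows
    are deduplicated keeping the best final_score, and output order is
    deterministic (unigene id, position).
    """
    config = config or RunConfig()
    pairs = [
        (m.id, m.seq) if isinstance(m, SequenceRecord) else (m[0], m[1]) for m in mirnas
    ]
    sites: list[TargetSite] = []
    n_scanned = 0
    for uni in unigenes:
        useq = to_rna(uni.seq)
        for mid, mseq in pairs:
            mseq = to_rna(mseq)
            m = len(mseq)
            profile = _ungapped_cost_profile(mseq, useq, config.gu_mismatch_cost)
            hits: list[TargetSite] = []
            for pos in np.flatnonzero(profile <= _SCREEN_COST):
                window = useq[pos : pos + m + 3]
                n_scanned += 1
                aln = duplex_align(mseq, window, config)
                if aln.mismatch_cost > config.max_target_mismatches:
                    continue
                ws, we = aln.window_span
                cr = (int(pos) + ws, int(pos) + we)
                _, _, final = score_site(aln, useq, int(pos), config)
                hits.append(
                    TargetSite(
                        mirna_id=mid,
                        family=family_of(mid),
                        unigene_id=uni.id,
                        cr=cr,
                        pairing=aln.pairing,
                        mismatch_cost=aln.mismatch_cost,
                        raw_score=aln.raw_score,
                        final_score=final,
                    )
                )
            sites.extend(_dedup_overlapping(hits))
    sites.sort(key=lambda s: (s.unigene_id, s.cr, s.mirna_id))
    stage_log("predict_targets", n_scanned, len(sites))
    return sites


def _dedup_overlapping(hits: list[TargetSite]) -> list[TargetSite]:
    """Among overlapping CRs of one miRNA on one unigene keep the best score."""
    kept: list[TargetSite] = []
    for hit in sorted(hits, key=lambda h: (-h.final_score, h.cr)):
        if all(hit.cr[1] <= k.cr[0] or hit.cr[0] >= k.cr[1] for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.cr)
    return kept


@dataclass(frozen=True)
class FamilyTargetSummary:
    family: str
    n_targets: int


def summarize_families(
    sites: Sequence[TargetSite], all_families: Sequence[str] | None = None
) -> tuple[list[FamilyTargetSummary], list[str]]:
    """Distinct-target counts per family.

    Returns (summaries for families with >= 1 target, families from
    ``all_families`` with no predicted target).
    """
    targets: dict[str, set[str]] = {}
    for s in sites:
        targets.setdefault(s.family, set()).add(s.unigene_id)
    summaries = [
        FamilyTargetSummary(fam, len(t)) for fam, t in sorted(targets.items())
    ]
    missing = [f for f in (all_families or []) if f not in targets]
    return summaries, missing


def target_count_stats(summaries: Sequence[FamilyTargetSummary]) -> tuple[int, int, float]:
    """(min, max, mean) targets per family over families with targets."""
    counts = [s.n_targets for s in summaries]
    if not counts:
        return 0, 0, 0.0
    return min(counts), max(counts), float(np.mean(counts))
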
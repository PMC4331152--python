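"""miRNA locus discovery: exact mature matching, flank-window folding,
homology search, read mapping, and conservation/novelty decision rules.

Conserved loci are found by placing known mature sequences on the genome,
folding windows with different upstream/downstream flank lengths and keeping
loci where at least one window passes both the stem and duplex filters.
New miRNAs are abundant reads whose loci pass the same filters and whose
mature shows no more than 70% identity to any known mature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Iterable, Optional, Sequence

from scipy.optimize import brentq

from ._util import family_of, revcomp, to_dna, to_rna
from .hairpin_filter import (
    GenomeLocus,
    HairpinCandidate,
    fold_fallback,
    mircheck_filter,
    structure_filter,
    trim_free_tails,
)
from .io_core import RunConfig, SequenceRecord, stage_log


@dataclass(frozen=True)
class MatureLocus:
    """An exact occurrence of a mature sequence on the genome."""

    query_id: str
    contig: str
    start: int  # 0-based half-open, plus-strand coordinates
    end: int
    strand: str


@dataclass(frozen=True)
class Window:
    """A flank-extended candidate window around a mature locus."""

    locus: MatureLocus
    up: int
    down: int
    seq: str  # mature-strand RNA
    mature_span: tuple[int, int]
    genomic_start: int
    genomic_end: int
    clipped: bool


@dataclass
class MiRNARecord:
    id: str
    family: str
    mature: str
    precursor: HairpinCandidate
    status: str  # "conserved" or "new"
    genotype_presence: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if self.mature not in self.precursor.seq:
            raise ValueError(f"{self.id}: mature not contained in precursor")
        if not self.family:
            raise ValueError(f"{self.id}: empty family")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    contig: str
    start: int
    end: int
    strand: str
    identity: float
    aln_len: int
    score: int
    significance: float


def match_known_matures(
    matures: Sequence[SequenceRecord], genome: Sequence[SequenceRecord]
) -> list[MatureLocus]:
    """Every exact occurrence of each mature on either genome strand."""
    loci = []
    for contig in genome:
        gseq = to_dna(contig.seq)
        for mat in matures:
            fwd = to_dna(mat.seq)
            for strand, pattern in (("+", fwd), ("-", to_dna(revcomp(fwd)))):
                pos = gseq.find(pattern)
                while pos != -1:
                    loci.append(
                        MatureLocus(mat.id, contig.id, pos, pos + len(pattern), strand)
                    )
                    pos = gseq.find(pattern, pos + 1)
    loci.sort(key=lambda l: (l.contig, l.start, l.strand, l.query_id))
    return loci


def extract_flank_windows(
    locus: MatureLocus,
    genome: Sequence[SequenceRecord],
    flank_lengths: Sequence[int],
) -> list[Window]:
    """One window per (upstream, downstream) flank combination, clipped at
    contig ends. Upstream/downstream are relative to the mature strand."""
    contig = next(c for c in genome if c.id == locus.contig)
    gseq = contig.seq
    windows = []
    for up in flank_lengths:
        for down in flank_lengths:
            if locus.strand == "+":
                ws = locus.start - up
                we = locus.end + down
            else:
                ws = locus.start - down
                we = locus.end + up
            clipped = ws < 0 or we > len(gseq)
            ws_c, we_c = max(ws, 0), min(we, len(gseq))
            seq = to_rna(gseq[ws_c:we_c])
            if locus.strand == "+":
                m0 = locus.start - ws_c
            else:
                seq = revcomp(seq)
                m0 = we_c - locus.end
            windows.append(
                Window(
                    locus=locus,
                    up=up,
                    down=down,
                    seq=seq,
                    mature_span=(m0, m0 + (locus.end - locus.start)),
                    genomic_start=ws_c,
                    genomic_end=we_c,
                    clipped=clipped,
                )
            )
    return windows


def evaluate_windows(
    windows: Iterable[Window],
    config: RunConfig,
    folder: Optional[Callable[[str], tuple[str, float]]] = None,
) -> list[HairpinCandidate]:
    """Fold, trim and filter windows; returns passing trimmed candidates."""
    provenance = "external" if folder else "fallback"
    folder = folder or fold_fallback
    passers = []
    for w in windows:
        structure, mfe = folder(w.seq)
        cand = HairpinCandidate(
            id=f"{w.locus.query_id}@{w.locus.contig}:{w.genomic_start}-"
            f"{w.genomic_end}{w.locus.strand}/u{w.up}d{w.down}",
            seq=w.seq,
            structure=structure,
            mfe=mfe,
            mature_span=w.mature_span,
            locus=GenomeLocus(
                w.locus.contig, w.genomic_start, w.genomic_end, w.locus.strand
            ),
            provenance=provenance,
        )
        trimmed, _reason = trim_free_tails(cand)
        if trimmed is None:
            continue
        ok_s, _ = structure_filter(trimmed, config)
        if not ok_s:
            continue
        try:
            ok_m, _, _ = mircheck_filter(trimmed, config)
        except Exception:
            continue
        if ok_m:
            passers.append(trimmed)
    return passers


def call_conserved(
    loci: Sequence[MatureLocus],
    genome: Sequence[SequenceRecord],
    config: RunConfig | None = None,
    folder: Optional[Callable[[str], tuple[str, float]]] = None,
) -> list[MiRNARecord]:
    """A locus yields a record iff >= 1 flank window passes both filters;
    the reported precursor is the lowest-energy passing window."""
    config = config or RunConfig()
    records = []
    for idx, locus in enumerate(loci):
        windows = extract_flank_windows(locus, genome, config.flank_lengths)
        passers = evaluate_windows(windows, config, folder)
        if not passers:
            continue
        best = min(passers, key=lambda c: (c.mfe, c.id))
        records.append(
            MiRNARecord(
                id=f"{locus.query_id}.L{idx}",
                family=family_of(locus.query_id),
                mature=best.mature,
                precursor=best,
                status="conserved",
            )
        )
    stage_log("call_conserved", len(loci), len(records))
    return records


# -- homology search ---------------------------------------------------------

_WORD = 7
_MATCH, _MISMATCH = 1, -2
_XDROP = 12
_KA_K = 0.621  # blastn tabulated K for the +1/-2 scheme


@lru_cache(maxsize=1)
def _ka_lambda() -> float:
    """Karlin-Altschul lambda for +1/-2 on uniform-composition DNA."""
    f = lambda lam: 0.25 * math.exp(lam * _MATCH) + 0.75 * math.exp(lam * _MISMATCH) - 1.0
    return float(brentq(f, 1e-6, 5.0))


def _extend(q: str, g: str, qpos: int, gpos: int) -> tuple[int, int, int, int, int]:
    """Greedy X-drop ungapped extension around a seeded word.

    Returns (qs, qe, gs, ge, score) with half-open query/genome intervals.
    """
    score = best = _WORD * _MATCH
    bl = br = 0
    # left
    cur = 0
    i = 1
    best_i = 0
    while qpos - i >= 0 and gpos - i >= 0:
        cur += _MATCH if q[qpos - i] == g[gpos - i] else _MISMATCH
        if cur > bl:
            bl, best_i = cur, i
        if cur < bl - _XDROP:
            break
        i += 1
    left = best_i
    # right
    cur = 0
    j = 0
    best_j = 0
    br = 0
    while qpos + _WORD + j < len(q) and gpos + _WORD + j < len(g):
        cur += _MATCH if q[qpos + _WORD + j] == g[gpos + _WORD + j] else _MISMATCH
        if cur > br:
            br, best_j = cur, j + 1
        if cur < br - _XDROP:
            break
        j += 1
    right = best_j
    score = _WORD * _MATCH + bl + br
    return qpos - left, qpos + _WORD + right, gpos - left, gpos + _WORD + right, score


def homology_search(
    query: str,
    genome: Sequence[SequenceRecord],
    config: RunConfig | None = None,
    query_id: str = "query",
) -> list[HomologyHit]:
    """Ungapped-seeded local alignment (word 7, +1/-2) with a Karlin-Altschul
    E-value style significance; hits below the 1e-10 threshold are kept."""
    config = config or RunConfig()
    q = to_dna(query)
    if not q:
        raise ValueError("empty query")
    lam = _ka_lambda()
    total_n = sum(len(c.seq) for c in genome) * 2
    words: dict[str, list[int]] = {}
    for i in range(len(q) - _WORD + 1):
        words.setdefault(q[i : i + _WORD], []).append(i)
    hits: dict[tuple, HomologyHit] = {}
    for contig in genome:
        for strand in "+-":
            g = to_dna(contig.seq) if strand == "+" else to_dna(revcomp(contig.seq))
            for gpos in range(len(g) - _WORD + 1):
                for qpos in words.get(g[gpos : gpos + _WORD], ()):
                    qs, qe, gs, ge, score = _extend(q, g, qpos, gpos)
                    sig = _KA_K * len(q) * total_n * math.exp(-lam * score)
                    if sig >= config.homology_significance:
                        continue
                    matches = sum(
                        1 for a, b in zip(q[qs:qe], g[gs:ge]) if a == b
                    )
                    if strand == "-":
                        gs, ge = len(g) - ge, len(g) - gs
                    key = (contig.id, strand, gs - qs)
                    hit = HomologyHit(
                        query_id=query_id,
                        contig=contig.id,
                        start=gs,
                        end=ge,
                        strand=strand,
                        identity=matches / (qe - qs),
                        aln_len=qe - qs,
                        score=score,
                        significance=sig,
                    )
                    prev = hits.get(key)
                    if prev is None or hit.score > prev.score:
                        hits[key] = hit
    out = sorted(hits.values(), key=lambda h: (h.contig, h.start, h.strand))
    return out


def map_reads(
    reads: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    max_mm: int | None = None,
    config: RunConfig | None = None,
) -> dict[str, int]:
    """Sum of collapsed counts of reads mapping to each reference.

    A read maps iff it aligns end-to-end (no indels) at some offset within
    the reference with <= max_mm substitutions; multi-reference reads are
    counted on every reference they hit.
    """
    config = config or RunConfig()
    if max_mm is None:
        max_mm = config.read_map_max_mm
    counts = {ref.id: 0 for ref in references}
    refseqs = [(ref.id, to_rna(ref.seq)) for ref in references]
    for read in reads:
        r = to_rna(read.seq)
        n = read.count if read.count is not None else 1
        for rid, ref in refseqs:
            if _maps(r, ref, max_mm):
                counts[rid] += n
    return counts


def _maps(read: str, ref: str, max_mm: int) -> bool:
    if len(read) > len(ref):
        return False
    for off in range(len(ref) - len(read) + 1):
        mm = 0
        for a, b in zip(read, ref[off : off + len(read)]):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return True
    return False


def call_conservation(
    has_hits: bool, normalized_reads: float, config: RunConfig | None = None
) -> str:
    """2x2 decision rule: not conserved only when there is no homologous
    sequence AND fewer than 10 normalised mappable reads."""
    config = config or RunConfig()
    if not has_hits and normalized_reads < config.conservation_min_reads:
        return "not_conserved"
    return "conserved_in_assembly"


def call_novelty(
    candidate_mature: str,
    known_matures: Sequence[SequenceRecord],
    config: RunConfig | None = None,
) -> str:
    """"new" iff the best local-alignment identity against every known mature,
    normalized by the candidate length, is <= 70%."""
    config = config or RunConfig()
    if not known_matures:
        raise ValueError("known mature set must be nonempty")
    best = max(
        _local_identity(to_rna(candidate_mature), to_rna(k.seq)) for k in known_matures
    )
    return "new" if best / len(candidate_mature) <= config.novelty_identity else "known"


def _local_identity(a: str, b: str) -> int:
    """Max identities in the best local alignment (match +1, mismatch/gap -1)."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-1,
        extend_gap_score=-1,
    )
    if aligner.score(a, b) <= 0:
        return 0
    aln = aligner.align(a, b)[0]
    ident = 0
    for (as_, ae), (bs, be) in zip(*aln.aligned):
        ident += sum(1 for x, y in zip(a[as_:ae], b[bs:be]) if x == y)
    return ident


def discover_new(
    reads: Sequence[SequenceRecord],
    genome: Sequence[SequenceRecord],
    known_matures: Sequence[SequenceRecord],
    config: RunConfig | None = None,
    min_count: int = 5,
    folder: Optional[Callable[[str], tuple[str, float]]] = None,
) -> list[MiRNARecord]:
    """Treat abundant 18-25 nt reads as putative matures, keep hairpin-passing
    loci, and label each either new (<= 70% identity to any known mature) or
    known."""
    config = config or RunConfig()
    candidates = [
        r
        for r in reads
        if 18 <= len(r.seq) <= 25 and (r.count or 1) >= min_count
    ]
    # drop reads identical to a known mature; those loci are conserved calls
    known_set = {to_rna(k.seq) for k in known_matures}
    candidates = [r for r in candidates if to_rna(r.seq) not in known_set]
    loci = match_known_matures(candidates, genome)
    records = call_conserved(loci, genome, config, folder)
    # one mature can seed several loci (e.g. both arms of one hairpin);
    # keep the lowest-energy precursor per distinct mature sequence
    best: dict[str, MiRNARecord] = {}
    for rec in records:
        cur = best.get(rec.mature)
        if cur is None or rec.precursor.mfe < cur.precursor.mfe:
            best[rec.mature] = rec
    new_records = []
    counter = 0
    for rec in sorted(
        best.values(),
        key=lambda r: (r.precursor.locus.contig, r.precursor.locus.start),
    ):
        status = call_novelty(rec.mature, known_matures, config)
        if status == "new":
            counter += 1
            rec.id = f"new-{counter}"
            rec.family = f"new-{counter}"
            rec.status = "new"
            new_records.append(rec)
    stage_log("discover_new", len(candidates), len(new_records))
    return new_records
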
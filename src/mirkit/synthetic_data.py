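"""Synthetic study generator: toy genome with planted hairpins, six small-RNA
libraries, unigenes with planted complementary sites, expression tables with
controlled correlation structure, and the built-in RACE clone fixture.

The generator emulates the study design — three genotypes (wild progenitor
W14 and cultivars Arg7 and KU50) x two organs (leaf, storage root) — at desk
scale, and records ground truth so every pipeline stage has recovery tests.

Planted precursors are constructed inverted repeats: a 21-nt balanced-
composition mature arm, a 12-nt low-pairing loop and the reverse-complement
star arm, embedded inside purine-only ({A, G}) buffer zones that cannot
base-pair internally in either reading orientation; each planting is
rejection-sampled until the pair-maximization fallback folder provably
returns the planted stem. Background between planted regions is i.i.d.
uniform. Read counts are Poisson around planted expectations (a noiseless
exact mode exists for identity tests).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import revcomp, to_dna, to_rna
from .cleavage_analysis import CleavageClone, PairRecord
from .expression import CULTIVARS, GENOTYPES, ORGANS, PROGENITOR, library_id
from .hairpin_filter import GenomeLocus
from .io_core import SequenceRecord

MATURE_LEN = 21
LOOP_LEN = 12
BUFFER_LEN = 260  # low-pairing {A,G} zone on each side of a planted precursor
SPACER_LEN = 150  # uniform background between planted regions

#: substitution that can pair the original base neither Watson-Crick nor G:U
_NONPAIRING = {"A": "C", "C": "A", "G": "A", "U": "C"}
#: substitution turning a Watson-Crick pair into a G:U wobble (None: impossible)
_WOBBLE = {"G": "U", "U": "G", "A": None, "C": None}


@dataclass
class PlantedMiRNA:
    id: str
    mature: str  # RNA
    arm: str  # "5p" or "3p"
    precursor: str  # RNA, mature-strand orientation
    locus: GenomeLocus  # precursor placement, plus-strand genome coords
    n_copies: int = 1
    star_mismatches: int = 0


@dataclass
class PlantedTarget:
    mirna_id: str
    unigene_id: str
    cr: tuple[int, int]  # 0-based half-open on the unigene
    n_mismatches: int
    n_wobbles: int

    @property
    def cost(self) -> float:
        return self.n_mismatches + 0.5 * self.n_wobbles


@dataclass
class LibrarySpec:
    genotype: str
    organ: str
    depth: int = 100_000
    background_rate: float = 0.1

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not (0 <= self.background_rate < 1):
            raise ValueError("background_rate must be in [0, 1)")

    @property
    def id(self) -> str:
        return library_id(self.genotype, self.organ)


def default_specs(
    depth: int = 100_000, background_rate: float = 0.1
) -> list[LibrarySpec]:
    """The six-library layout: 3 genotypes x 2 organs."""
    return [
        LibrarySpec(g, o, depth, background_rate) for g in GENOTYPES for o in ORGANS
    ]


@dataclass
class PlantedTruth:
    """Ground truth for every generated input."""

    mirnas: list[PlantedMiRNA] = field(default_factory=list)
    targets: list[PlantedTarget] = field(default_factory=list)
    abundance: dict[tuple[str, str], float] = field(default_factory=dict)
    de_truth: dict[str, dict[str, str]] = field(default_factory=dict)

    def mature_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(m.id, m.mature) for m in self.mirnas]

    def to_json(self, path) -> None:
        data = {
            "mirnas": [asdict(m) for m in self.mirnas],
            "targets": [asdict(t) for t in self.targets],
            "abundance": [
                {"mirna": k[0], "library": k[1], "expected": v}
                for k, v in self.abundance.items()
            ],
            "de_truth": self.de_truth,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, default=list)


def _balanced_arm(rng: np.random.Generator) -> str:
    """21-nt mature arm with near-balanced composition (5-6 of each base).

    Balance keeps the arm's G+U content well below the stem length, so no
    alternative flank-pairing structure can out-pair the planted stem.
    """
    extra = "ACGU"[rng.integers(4)]
    letters = list("ACGU" * 5 + extra)
    return "".join(rng.permutation(letters))


def _low_pairing(rng: np.random.Generator, n: int) -> str:
    """i.i.d. over {A, G}: pair-free within itself in both orientations.

    {A, G} admits no AU/GC/GU pair internally, and its reverse complement
    {U, C} is likewise pair-free, so buffers stay unstructured in windows
    read from either strand (an {A, C} buffer would fail on the minus
    strand, where it reads as G/U and wobble-pairs with itself).
    """
    return "".join(np.array(["A", "G"])[rng.integers(0, 2, n)])


def _uniform(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, n)])


def build_precursor(
    rng: np.random.Generator, n_star_mismatches: int = 0, minus: bool = False
) -> tuple[str, str, str]:
    """(precursor, mature, star): arm + low-pairing loop + complement arm.

    The loop is drawn so that it reads as {A, G} in the orientation the
    precursor is planted in (``minus`` plants the reverse complement): a
    pyrimidine-read loop would hand the {A, G} buffers 12 extra pairable
    bases and let buffer absorption out-pair the planted stem.
    """
    if n_star_mismatches > 2:
        raise ValueError("at most 2 injected star mismatches supported")
    arm = _balanced_arm(rng)
    loop = _low_pairing(rng, LOOP_LEN)
    if minus:
        loop = revcomp(loop)
    star = list(revcomp(arm))
    if n_star_mismatches:
        pos = rng.choice(MATURE_LEN, size=n_star_mismatches, replace=False)
        for p in pos:
            star[p] = _NONPAIRING[star[p]]
    return arm + loop + "".join(star), arm, "".join(star)


def make_genome(
    n_precursors: int = 5,
    contig_len: Optional[int] = None,
    seed: int = 0,
    n_star_mismatches: int = 0,
    n_multicopy: int = 0,
    minus_strand_every: int = 3,
    buffer_len: int = BUFFER_LEN,
) -> tuple[list[SequenceRecord], PlantedTruth]:
    """Build a single-contig genome with planted hairpin precursors.

    Every ``minus_strand_every``-th precursor is planted on the minus strand.
    ``n_multicopy`` precursors are planted at two loci (to exercise
    multi-mapping attribution). Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    cursor = 0
    truth = PlantedTruth()

    def emit(s: str) -> None:
        nonlocal cursor
        pieces.append(s)
        cursor += len(s)

    plant_plan: list[tuple[str, int]] = []  # (mirna id, copy index)
    for i in range(n_precursors):
        plant_plan.append((f"syn-miR{i + 1}", 0))
    for i in range(min(n_multicopy, n_precursors)):
        plant_plan.append((f"syn-miR{i + 1}", 1))

    built: dict[str, tuple[str, str, str]] = {}
    orient: dict[str, bool] = {}
    for idx, (mid, copy) in enumerate(plant_plan):
        if copy == 0:
            orient[mid] = minus_strand_every > 0 and (idx % minus_strand_every) == (
                minus_strand_every - 1
            )
        minus = orient[mid]  # copies keep the original's orientation
        # rejection-sample (precursor, buffers) until the fallback folder
        # returns the clean planted stem in both window orientations; every
        # discovery window is a substring of the tested full-buffer window,
        # so the guarantee carries over
        for _attempt in range(60):
            if copy == 0:
                candidate = build_precursor(rng, n_star_mismatches, minus=minus)
            else:
                candidate = built[mid]
            buf5 = _low_pairing(rng, buffer_len)
            buf3 = _low_pairing(rng, buffer_len)
            genomic = revcomp(candidate[0]) if minus else candidate[0]
            if _plant_ok(genomic, buf5, buf3, n_star_mismatches):
                built[mid] = candidate
                break
        else:  # pragma: no cover - generator guarantee violated
            raise RuntimeError(f"could not plant a clean precursor for {mid}")
        precursor, mature, _star = built[mid]
        emit(_uniform(rng, SPACER_LEN))
        emit(buf5)
        start = cursor
        emit(genomic)
        end = cursor
        emit(buf3)
        if copy == 0:
            truth.mirnas.append(
                PlantedMiRNA(
                    id=mid,
                    mature=mature,
                    arm="5p",
                    precursor=precursor,
                    locus=GenomeLocus("chr1", start, end, "-" if minus else "+", mid),
                    star_mismatches=n_star_mismatches,
                )
            )
        else:
            for m in truth.mirnas:
                if m.id == mid:
                    m.n_copies += 1
    emit(_uniform(rng, SPACER_LEN))
    seq = "".join(pieces)
    if contig_len is not None:
        if contig_len < len(seq):
            raise ValueError(
                f"contig_len {contig_len} cannot hold {n_precursors} spaced "
                f"precursors (need >= {len(seq)})"
            )
        seq = seq + _uniform(rng, contig_len - len(seq))
    genome = [SequenceRecord("chr1", to_dna(seq))]
    _default_abundance(truth, rng)
    return genome, truth


def _default_abundance(truth: PlantedTruth, rng: np.random.Generator) -> None:
    """Plant expression classes: 2.5-fold DE, equal, and absent-in-progenitor.

    The DE fold (2.5) sits outside the 1.9x/2.1x guard band around the
    2-fold call threshold, and planted counts are large enough that Poisson
    noise at depth 1e5 stays inside the band.
    """
    classes = ["de_up", "null", "absent_w14", "de_down", "null"]
    for i, m in enumerate(truth.mirnas):
        cls = classes[i % len(classes)]
        truth.de_truth[m.id] = {}
        for organ in ORGANS:
            if cls == "de_up":
                w, c = 2000.0, 5000.0
                truth.de_truth[m.id][organ] = "up_in_cultivars"
            elif cls == "de_down":
                w, c = 5000.0, 2000.0
                truth.de_truth[m.id][organ] = "up_in_progenitor"
            elif cls == "absent_w14":
                w, c = 0.0, 600.0
                truth.de_truth[m.id][organ] = "up_in_cultivars"
            else:
                w = c = 800.0
                truth.de_truth[m.id][organ] = "none"
            for g in GENOTYPES:
                lib = library_id(g, organ)
                truth.abundance[(m.id, lib)] = w if g == PROGENITOR else c


def _plant_ok(genomic: str, buf5: str, buf3: str, n_mm: int) -> bool:
    """True when the genomic insert folds to the clean planted stem inside
    its buffers in both reading orientations: one terminal loop, no pairs
    outside the insert, and both 21-nt arms paired up to injected
    mismatches. ``genomic`` is the insert exactly as planted."""
    from ._fold import fold
    from .hairpin_filter import count_loops, pair_table

    stem = MATURE_LEN - n_mm
    n_ins = len(genomic)
    for window, a0 in (
        (buf5 + genomic + buf3, len(buf5)),
        (revcomp(buf5 + genomic + buf3), len(buf3)),
    ):
        structure, _ = fold(window)
        if count_loops(structure) != 1:
            return False
        table = pair_table(structure)
        arm_paired = sum(1 for i in range(a0, a0 + MATURE_LEN) if table[i] != -1)
        star0 = a0 + n_ins - MATURE_LEN
        star_paired = sum(1 for i in range(star0, star0 + MATURE_LEN) if table[i] != -1)
        outside = sum(
            1
            for i in range(len(window))
            if table[i] != -1 and not (a0 <= i < a0 + n_ins)
        )
        if arm_paired < stem or star_paired < stem or outside > 0:
            return False
    return True


def make_libraries(
    truth: PlantedTruth,
    specs: Sequence[LibrarySpec],
    seed: int = 0,
    poisson: bool = True,
    genome: Optional[Sequence[SequenceRecord]] = None,
) -> dict[str, list[SequenceRecord]]:
    """Collapsed small-RNA reads per library.

    Planted-mature counts are Poisson draws around the truth abundance
    (or the exact expectation with ``poisson=False``); background reads are
    random genome substrings of 18-25 nt at ``background_rate`` of depth.
    Reads whose expected count is 0 in a library are absent from its file.
    """
    if not specs:
        raise ValueError("empty library specs")
    rng = np.random.default_rng(seed)
    libraries: dict[str, list[SequenceRecord]] = {}
    for spec in specs:
        reads: dict[str, int] = {}
        for m in truth.mirnas:
            expected = truth.abundance.get((m.id, spec.id), 0.0)
            count = int(rng.poisson(expected)) if poisson else int(round(expected))
            if count > 0:
                reads[m.mature] = reads.get(m.mature, 0) + count
        n_bg = int(round(spec.depth * spec.background_rate))
        if n_bg > 0:
            if genome is None:
                raise ValueError("background reads need the genome")
            gseq = to_rna(genome[0].seq)
            lens = rng.integers(18, 26, n_bg)
            starts = rng.integers(0, len(gseq) - 25, n_bg)
            strands = rng.integers(0, 2, n_bg)
            for length, start, strand in zip(lens, starts, strands):
                s = gseq[start : start + length]
                if strand:
                    s = revcomp(s)
                reads[s] = reads.get(s, 0) + 1
        records = [
            SequenceRecord(f"{spec.id}_r{i + 1}", seq, count)
            for i, (seq, count) in enumerate(sorted(reads.items()))
        ]
        libraries[spec.id] = records
    return libraries


def make_unigenes(
    truth: PlantedTruth,
    n_decoys: int = 5,
    seed: int = 0,
    site_plan: Optional[Sequence[tuple[int, int]]] = None,
    unigene_len: int = 400,
) -> list[SequenceRecord]:
    """Unigenes carrying planted complementary sites, plus clean decoys.

    ``site_plan`` lists (n_mismatches, n_wobbles) per planted site, cycled
    over miRNAs; the default plants recoverable sites (cost <= 3) and
    rejected ones (cost >= 4). Mismatch counts above 5 are refused (outside
    the tested regime). Populates ``truth.targets``.
    """
    rng = np.random.default_rng(seed)
    if site_plan is None:
        site_plan = [(0, 0), (1, 1), (3, 0), (2, 2), (4, 0), (0, 0)]
    for nm, nw in site_plan:
        if nm > 5:
            raise ValueError(f"{nm} mismatches refused: outside tested regime")
    truth.targets = []
    unigenes = []
    for i, m in enumerate(truth.mirnas):
        nm, nw = site_plan[i % len(site_plan)]
        uid = f"uni{i + 1}"
        site = _planted_site(m.mature, nm, nw, rng)
        pos = int(rng.integers(60, unigene_len - 60 - len(site)))
        body = _clean_random_rna(rng, unigene_len, [x.mature for x in truth.mirnas])
        seq = body[:pos] + site + body[pos + len(site) :]
        unigenes.append(SequenceRecord(uid, to_dna(seq)))
        truth.targets.append(
            PlantedTarget(
                mirna_id=m.id,
                unigene_id=uid,
                cr=(pos, pos + len(site)),
                n_mismatches=nm,
                n_wobbles=nw,
            )
        )
    for d in range(n_decoys):
        seq = _clean_random_rna(rng, unigene_len, [x.mature for x in truth.mirnas])
        unigenes.append(SequenceRecord(f"decoy{d + 1}", to_dna(seq)))
    return unigenes


def _planted_site(
    mature: str, n_mismatches: int, n_wobbles: int, rng: np.random.Generator
) -> str:
    """Reverse complement of the mature with injected mismatches/wobbles.

    Injection positions avoid the first and last two pairing positions so
    the alignment register stays unambiguous; wobbles need a G or U mature
    base and are placed on available positions.
    """
    site = list(revcomp(mature))  # site[j] pairs mature position len-1-j ... j maps
    m = len(mature)
    # candidate mature positions (0-based), interior only
    interior = list(range(2, m - 2))
    rng.shuffle(interior)
    wobble_ok = [p for p in interior if _WOBBLE[mature[p]] is not None]
    chosen_w = wobble_ok[:n_wobbles]
    remaining = [p for p in interior if p not in chosen_w]
    chosen_m = remaining[:n_mismatches]
    if len(chosen_w) < n_wobbles or len(chosen_m) < n_mismatches:
        raise ValueError("not enough interior positions for requested injections")
    for p in chosen_w:
        site[m - 1 - p] = _WOBBLE[mature[p]]
    for p in chosen_m:
        site[m - 1 - p] = _NONPAIRING[mature[p]]
    return "".join(site)


def _clean_random_rna(
    rng: np.random.Generator, n: int, matures: Sequence[str], max_tries: int = 20
) -> str:
    """Random RNA with no complementary site of cost <= 4 for any mature."""
    from .target_prediction import _ungapped_cost_profile

    for _ in range(max_tries):
        seq = _uniform(rng, n)
        clean = True
        for mat in matures:
            prof = _ungapped_cost_profile(mat, seq, 0.5)
            if prof.size and prof.min() <= 4.0:
                clean = False
                break
        if clean:
            return seq
    raise RuntimeError("could not generate a clean decoy sequence")


# -- expression tables -------------------------------------------------------

def make_expression_tables(
    pair_ids: Sequence[str],
    sign_truth: dict[str, str],
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """miRNA NNR and target FPKM tables with planted correlation structure.

    For each pair id p, rows ``p_mirna`` (NNR table) and ``p_target`` (FPKM
    table) are generated over the six conditions so that the log2 profiles
    have the requested relation: "neg" anti-phase, "pos" in-phase, "none"
    independent. ``noise_sd`` adds Gaussian noise on the log2 scale.
    """
    rng = np.random.default_rng(seed)
    conds = [library_id(g, o) for g in GENOTYPES for o in ORGANS]
    nnr_rows = {}
    fpkm_rows = {}
    for pid in pair_ids:
        sign = sign_truth.get(pid, "none")
        z = rng.normal(0.0, 1.0, len(conds))
        z -= z.mean()
        m = 400.0 * np.power(2.0, z + rng.normal(0, noise_sd, len(conds)))
        if sign == "neg":
            t_log = -z
        elif sign == "pos":
            t_log = z
        elif sign == "flat":
            t_log = np.zeros(len(conds))
            m = np.full(len(conds), 400.0)
        else:
            w = rng.normal(0.0, 1.0, len(conds))
            w -= w.mean()
            t_log = w
        t = 30.0 * np.power(2.0, t_log + rng.normal(0, noise_sd, len(conds)))
        nnr_rows[f"{pid}_mirna"] = m
        fpkm_rows[f"{pid}_target"] = t
    nnr = pd.DataFrame.from_dict(nnr_rows, orient="index", columns=conds)
    fpkm = pd.DataFrame.from_dict(fpkm_rows, orient="index", columns=conds)
    nnr.index.name = "miRNA"
    fpkm.index.name = "transcript"
    return nnr, fpkm


# -- RACE clone fixture ------------------------------------------------------

# Transcribed per-pair clone records: (miRNA, target accession, annotation,
# upstream, CR, downstream). Offsets are positive magnitudes; tuples are
# boundary records resolved only to two adjacent positions; counts follow.
_TABLE4 = [
    ("miR156/miR535", "cassava4.1_006419m", "SPL2",
     [], [((10, 11), 8), ((11, 12), 3)], [((35, 36), 1)]),
    ("miR156/miR535", "cassava4.1_009657m", "SPL13b",
     [], [((9, 10), 2), ((10, 11), 4), ((11, 12), 1)], [((1, 2), 1)]),
    ("miR159/miR319", "cassava4.1_004606m", "MYB33",
     [], [((11, 12), 10)], [((52, 53), 1), ((115, 116), 1)]),
    ("miR159/miR319", "cassava4.1_030321m", "MYB81",
     [], [((11, 12), 6)], [((59, 60), 1)]),
    ("miR394", "cassava4.1_021267m", "APL2",
     [(18, 1), (35, 3), (42, 1), (69, 2)], [(2, 3), (14, 1)],
     [(27, 1), (29, 1), (49, 1), (92, 1), (105, 1), (109, 1), (139, 1)]),
    ("miR394", "cassava4.1_007038m", "F-box",
     [], [(10, 2)],
     [(31, 1), (52, 1), (55, 1), (59, 1), (68, 1), (75, 1), (102, 1)]),
    ("miR160", "cassava4.1_002668m", "ARF10", [], [(11, 10)], []),
    ("miR167", "cassava4.1_009942m", "RD19",
     [(5, 1), (25, 1), (145, 1), (196, 1)], [], [(41, 1)]),
    ("miR169", "cassava4.1_011576m", "NF-YA3",
     [(30, 1), (6, 1)], [(11, 5), (15, 1)], []),
    ("miR396", "cassava4.1_003731m", "GRF1",
     [(69, 2)], [(6, 1), (11, 6)], [(45, 1), (60, 1), (188, 1)]),
    ("miR398", "cassava4.1_024493m", "DIR-like", [(8, 10)], [], []),
    ("miR477", "cassava4.1_008074m", "CLB", [(37, 8)], [], []),
    ("miR166", "cassava4.1_009671m", "GH17",
     [], [], [(8, 3), (16, 6), (34, 1)]),
    ("new-21", "cassava4.1_006393m", "EDR2",
     [], [], [(112, 6), (160, 2), (176, 1), (177, 1), (178, 1), (182, 1)]),
    # the 15th assayed pair yielded no clones; its identity is not recorded
    # in the source table, so this entry is a synthetic placeholder
    ("miR164", "synthetic_unigene_15", "NAC-like (synthetic)", [], [], []),
]


def table4_fixture(
    seed: int = 0, mirna_length: int = 21
) -> tuple[list[PairRecord], list[CleavageClone]]:
    """The built-in RACE fixture: 15 assayed pairs, 14 with clone records.

    Each pair's CR is placed at a seeded arbitrary position on its target
    (so classification must recompute zones); clone positions are absolute
    mRNA coordinates derived from the recorded zone/offset labels.
    """
    rng = np.random.default_rng(seed)
    pairs: list[PairRecord] = []
    clones: list[CleavageClone] = []
    for i, (mirna, target, annot, up, cr, down) in enumerate(_TABLE4):
        s = int(rng.integers(200, 401))
        e = s + mirna_length
        pid = f"{mirna}:{annot}"
        pairs.append(
            PairRecord(
                pair_id=pid,
                mirna_id=mirna,
                target_id=target,
                annotation=annot,
                cr=(s, e),
                mirna_length=mirna_length,
                mrna_length=e + 260,
            )
        )
        for off, count in up:
            if isinstance(off, tuple):
                clones.append(CleavageClone(pid, s - off[1] + 0.5, count))
            else:
                clones.append(CleavageClone(pid, s - off, count))
        for off, count in cr:
            if isinstance(off, tuple):
                clones.append(CleavageClone(pid, e - off[0] - 0.5, count))
            else:
                clones.append(CleavageClone(pid, e - off, count))
        for off, count in down:
            if isinstance(off, tuple):
                clones.append(CleavageClone(pid, e + off[0] - 0.5, count))
            else:
                clones.append(CleavageClone(pid, e + off - 1, count))
    return pairs, clones
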
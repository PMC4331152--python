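"""Readers/writers for the formats the pipeline touches, plus run configuration.

Formats: FASTA (reads with ``_xN`` collapsed-count headers, matures, genomes,
unigenes), GFF3 for predicted precursor loci, and TSV tables with optional
``#key: value`` metadata headers. All emitted GFF coordinates are 1-based
inclusive; in memory everything is 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import logging
import re
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from ._util import DNA_ALPHABET, RNA_ALPHABET, to_one_based, to_rna

log = logging.getLogger("mirkit")


class FormatError(ValueError):
    """Malformed input file."""


COUNT_RE = re.compile(r"_x(\d+)$")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, optionally with a collapsed-read count."""

    id: str
    seq: str
    count: int | None = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")
        if self.count is not None and self.count < 1:
            raise ValueError(f"{self.id}: count must be >= 1, got {self.count}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class RunConfig:
    """Thresholds and knobs for every pipeline stage.

    Defaults are the study's printed values: folding energy <= -18 kcal/mol,
    >= 18 bp in matched regions, NNR < 50 silent, 2-fold differential
    expression, FPKM < 3 unexpressed, <= 3 target mismatch units, 70%
    novelty-homology ceiling, < 10 normalised reads for conservation,
    homology significance 1e-10, and <= 2 read-mapping mismatches.
    """

    energy_max_kcal: float = -18.0
    min_paired_bp: int = 18
    silent_nnr: float = 50.0
    de_fold: float = 2.0
    fpkm_min: float = 3.0
    max_target_mismatches: float = 3.0
    novelty_identity: float = 0.70
    conservation_min_reads: float = 10.0
    homology_significance: float = 1e-10
    read_map_max_mm: int = 2
    flank_lengths: list[int] = field(default_factory=lambda: [20, 60, 100, 150, 200, 250])
    seed: int = 0

    # secondary knobs, each documented at its consuming operation
    hairpin_seed_span: tuple[int, int] = (2, 8)  # 1-based inclusive mature positions
    max_duplex_mismatches: int = 4
    max_duplex_bulges: int = 2
    max_seed_run: int = 2
    matched_region: str = "stem"  # or "duplex": what "matched regions" counts
    target_seed_span: tuple[int, int] = (2, 13)  # 1-based inclusive miRNA positions
    gu_mismatch_cost: float = 0.5
    de_mode: str = "mean"  # or "both": cultivar aggregation for DE calls
    coexpr_min_abs_r: float = 0.5
    coexpr_alpha: float = 0.05
    coexpr_mode: str = "pearson"  # or "ratio_sign"

    def __post_init__(self):
        import math

        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValueError(f"threshold {f.name} must be finite")
        if not self.flank_lengths:
            raise ValueError("flank_lengths must be nonempty")
        if isinstance(self.hairpin_seed_span, list):
            self.hairpin_seed_span = tuple(self.hairpin_seed_span)
        if isinstance(self.target_seed_span, list):
            self.target_seed_span = tuple(self.target_seed_span)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            elif isinstance(v, (list, tuple)):
                lines.append(f"{f.name} = [{', '.join(str(x) for x in v)}]")
            else:
                lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(
    path: str | Path,
    count_syntax: bool = False,
    rna: bool = False,
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    With ``count_syntax`` the header suffix ``_xN`` encodes a collapsed-read
    abundance N; headers without the suffix default to count 1. With ``rna``
    the sequence is normalized T -> U. Raises :class:`FormatError` naming the
    offending line for non-IUPAC characters or duplicate/malformed headers.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rna:
            seq = to_rna(seq)
        alphabet = RNA_ALPHABET if rna else (RNA_ALPHABET | DNA_ALPHABET)
        bad = set(seq) - alphabet
        if bad or not seq:
            lineno = _find_line(path, rec.id)
            what = f"non-IUPAC character(s) {sorted(bad)}" if bad else "empty sequence"
            raise FormatError(f"{path}:{lineno}: record '{rec.id}': {what}")
        rid = rec.id
        count = None
        if count_syntax:
            m = COUNT_RE.search(rid)
            if m:
                count = int(m.group(1))
                if count < 1:
                    lineno = _find_line(path, rec.id)
                    raise FormatError(f"{path}:{lineno}: count must be >= 1 in '{rid}'")
            else:
                count = 1
        if rid in seen:
            lineno = _find_line(path, rid)
            raise FormatError(f"{path}:{lineno}: duplicate id '{rid}'")
        seen.add(rid)
        records.append(SequenceRecord(rid, seq, count))
    return records


def _find_line(path: Path, rec_id: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[0] == rec_id:
                return i
    return 0


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.count is not None and not COUNT_RE.search(header):
                header = f"{header}_x{rec.count}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_gff(loci: Sequence, path: str | Path, source: str = "mirkit") -> None:
    """Write precursor loci as GFF3 ``miRNA_primary_transcript`` features.

    Each locus needs attributes ``contig``, ``start``, ``end`` (0-based
    half-open), ``strand`` and ``id``. Coordinates are serialized 1-based
    inclusive.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            if locus.start >= locus.end:
                raise ValueError(f"{locus.id}: start >= end ({locus.start}, {locus.end})")
            s1, e1 = to_one_based(locus.start, locus.end)
            fh.write(
                "\t".join(
                    [
                        locus.contig,
                        source,
                        "miRNA_primary_transcript",
                        str(s1),
                        str(e1),
                        ".",
                        locus.strand,
                        ".",
                        f"ID={locus.id}",
                    ]
                )
                + "\n"
            )


def read_table(
    path: str | Path,
    schema: dict[str, type] | None = None,
    required: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV with optional ``#key: value`` metadata lines and a header row.

    ``schema`` maps column names to types for coercion; ``required`` lists
    columns that must exist. Unknown columns are preserved with a logged
    warning. Returns (dataframe, metadata).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                body = line[1:].strip()
                if ":" in body:
                    # keys may themselves contain colons (N_sample:<lib>)
                    k, v = body.rsplit(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
    if schema:
        extra = [c for c in df.columns if c not in schema]
        if extra:
            log.warning("%s: unknown column(s) %s preserved", path, extra)
        for col, typ in schema.items():
            if col not in df.columns:
                continue
            try:
                df[col] = df[col].astype(typ)
            except (ValueError, TypeError) as exc:
                bad = None
                for idx, val in df[col].items():
                    try:
                        typ(val)
                    except (ValueError, TypeError):
                        bad = idx
                        break
                raise FormatError(
                    f"{path}: column '{col}' not coercible to {typ.__name__}"
                    + (f" at row {bad}" if bad is not None else "")
                ) from exc
    return df, meta


def write_table(
    df: pd.DataFrame, path: str | Path, meta: dict[str, str] | None = None
) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"#{k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def stage_log(stage: str, n_in: int, n_out: int, **extra) -> None:
    """One structured line per pipeline stage so filter attrition is auditable."""
    kv = " ".join(f"{k}={v}" for k, v in extra.items())
    log.info("stage=%s in=%d out=%d %s", stage, n_in, n_out, kv)
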
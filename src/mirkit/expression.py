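"""NNR normalization, silent/expressed flags, family presence tables and
fold-change differential-expression calls.

NNR (normalised number of reads) scales each raw count by mean library depth
over that library's depth: ``NNR = N_miRNA * C / N_sample``, where N_sample
is the number of qualified reads in the sample and C the mean N_sample over
all samples. A miRNA with NNR < 50 in a library is silent there. A miRNA is
differentially expressed between the cultivars and the wild progenitor when
the fold change is at least 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import family_of
from .io_core import FormatError, RunConfig, read_table, write_table

GENOTYPES = ("W14", "Arg7", "KU50")
CULTIVARS = ("Arg7", "KU50")
PROGENITOR = "W14"
ORGANS = ("leaf", "root")


def library_id(genotype: str, organ: str) -> str:
    return f"{genotype}_{organ}"


@dataclass
class CountMatrix:
    """Raw mapped counts per miRNA per library plus per-library depths."""

    counts: pd.DataFrame  # rows: miRNA ids, cols: library ids, int
    n_sample: pd.Series  # per-library qualified read totals

    def __post_init__(self):
        if list(self.counts.columns) != list(self.n_sample.index):
            raise ValueError("count columns and N_sample index differ")
        if (self.n_sample <= 0).any():
            raise ValueError("all N_sample must be > 0")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def C(self) -> float:
        """Mean of N_sample over libraries."""
        return float(self.n_sample.mean())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df, meta = read_table(path, required=["miRNA"])
        df = df.set_index("miRNA")
        depths = {}
        for col in df.columns:
            key = f"N_sample:{col}"
            if key not in meta:
                raise FormatError(f"{path}: missing '#{key}:' header line")
            depths[col] = float(meta[key])
        return cls(df.astype(int), pd.Series(depths))

    def to_tsv(self, path: str | Path) -> None:
        meta = {f"N_sample:{c}": str(int(v)) for c, v in self.n_sample.items()}
        write_table(self.counts.reset_index().rename(columns={"index": "miRNA"}), path, meta)


@dataclass
class NNRMatrix:
    nnr: pd.DataFrame
    silent: pd.DataFrame  # bool, same shape

    def expressed(self) -> pd.DataFrame:
        return ~self.silent


@dataclass(frozen=True)
class DECall:
    mirna: str
    organ: str
    direction: str  # up_in_cultivars | up_in_progenitor | none
    fold: float


def normalize_nnr(counts: CountMatrix, config: RunConfig | None = None) -> NNRMatrix:
    """Apply NNR = N_miRNA * C / N_sample cell-wise and flag silent cells."""
    config = config or RunConfig()
    C = counts.C
    nnr = counts.counts.astype(float) * C / counts.n_sample
    silent = nnr < config.silent_nnr
    return NNRMatrix(nnr=nnr, silent=silent)


def flag_expressed(nnr: NNRMatrix, config: RunConfig | None = None) -> pd.DataFrame:
    """Expressed iff NNR >= 50 (boundary inclusive)."""
    config = config or RunConfig()
    return nnr.nnr >= config.silent_nnr


def family_presence_table(
    families: dict[str, str],
    nnr: NNRMatrix,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-family count of expressed members in each genotype x organ library.

    ``families`` maps miRNA id -> family name. Cells hold the number of
    family members with NNR >= 50 in that library; 0 means none detected.
    """
    config = config or RunConfig()
    expressed = flag_expressed(nnr, config)
    fam = pd.Series({m: families.get(m, family_of(m)) for m in expressed.index})
    table = expressed.groupby(fam).sum().astype(int)
    return table


def call_de(
    nnr: NNRMatrix,
    organ: str,
    config: RunConfig | None = None,
) -> list[DECall]:
    """Fold-change DE calls between cultivars and the wild progenitor.

    Cultivar level is the mean NNR of the two cultivars (config.de_mode
    "mean"; mode "both" instead requires each cultivar individually to pass).
    Fold = (larger + 1) / (smaller + 1) with pseudocount 1; a direction is
    called when fold >= 2 and the larger side is expressed (NNR >= 50).
    Both sides silent -> none regardless of ratio.
    """
    config = config or RunConfig()
    cols = {g: library_id(g, organ) for g in GENOTYPES}
    for g, col in cols.items():
        if col not in nnr.nnr.columns:
            raise ValueError(f"missing genotype library {col}")
    calls = []
    for mirna in nnr.nnr.index:
        w = float(nnr.nnr.loc[mirna, cols[PROGENITOR]])
        cs = [float(nnr.nnr.loc[mirna, cols[c]]) for c in CULTIVARS]
        if config.de_mode == "both":
            folds = [_fold(c, w) for c in cs]
            fold = min(f for f, _ in folds)
            directions = {d for _, d in folds}
            direction = directions.pop() if len(directions) == 1 else "none"
            larger = max(max(cs), w)
        else:
            cmean = float(np.mean(cs))
            fold, direction = _fold(cmean, w)
            larger = max(cmean, w)
        silent_thr = config.silent_nnr
        both_silent = (max(cs) < silent_thr if config.de_mode == "both" else
                       float(np.mean(cs)) < silent_thr) and w < silent_thr
        if fold < config.de_fold or both_silent or larger < silent_thr:
            direction = "none"
        calls.append(DECall(mirna=mirna, organ=organ, direction=direction, fold=fold))
    return calls


def _fold(cultivar: float, progenitor: float) -> tuple[float, str]:
    hi, lo = max(cultivar, progenitor), min(cultivar, progenitor)
    fold = (hi + 1.0) / (lo + 1.0)
    direction = "up_in_cultivars" if cultivar >= progenitor else "up_in_progenitor"
    return fold, direction


def de_table(calls: list[DECall]) -> pd.DataFrame:
    rows = [
        {"miRNA": c.mirna, "organ": c.organ, "direction": c.direction, "fold": round(c.fold, 3)}
        for c in calls
        if c.direction != "none"
    ]
    return pd.DataFrame(rows, columns=["miRNA", "organ", "direction", "fold"])
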
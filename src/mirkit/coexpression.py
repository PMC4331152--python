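"""miRNA:target co-expression across genotype x organ conditions.

Relates a miRNA's NNR profile to its target's FPKM profile over the six
conditions (3 genotypes x 2 organs) and classifies each pair as negatively,
positively or un-correlated. The default procedure is Pearson correlation
on log2(x+1) values with |r| >= 0.5 AND a significance guard (p <= 0.05,
necessary with only six points); an alternative "ratio_sign" mode instead
votes on the signs of per-organ log2(cultivar/progenitor) ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .expression import CULTIVARS, ORGANS, PROGENITOR, library_id
from .io_core import RunConfig


@dataclass(frozen=True)
class ExpressionProfilePair:
    """Condition-matched miRNA NNR and target FPKM profiles."""

    pair_id: str
    mirna_nnr: dict[str, float]  # condition label -> NNR
    target_fpkm: dict[str, float]  # condition label -> FPKM

    def __post_init__(self):
        if set(self.mirna_nnr) != set(self.target_fpkm):
            raise ValueError(f"{self.pair_id}: condition sets differ")
        if any(v < 0 for v in self.target_fpkm.values()):
            raise ValueError(f"{self.pair_id}: negative FPKM")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.mirna_nnr)


@dataclass(frozen=True)
class CoexprCall:
    pair_id: str
    r: float
    call: str  # "negative" | "positive" | "none"
    reason: str = ""


def fpkm_expressed(fpkm: float, config: RunConfig | None = None) -> bool:
    """Transcripts with FPKM < 3 are considered not expressed at all."""
    config = config or RunConfig()
    if fpkm < 0:
        raise ValueError(f"negative FPKM {fpkm}")
    return fpkm >= config.fpkm_min


def log2_ratio_profile(
    pair: ExpressionProfilePair,
) -> dict[str, dict[str, list[float]]]:
    """Per-organ log2(cultivar/progenitor) ratio vectors for both sides.

    Ratios use a pseudocount of 1 on numerator and denominator. Returns
    {organ: {"mirna": [ratio per cultivar], "target": [...]}} with cultivars
    in the fixed order Arg7, KU50.
    """
    out: dict[str, dict[str, list[float]]] = {}
    for organ in ORGANS:
        w_cond = library_id(PROGENITOR, organ)
        if w_cond not in pair.mirna_nnr:
            raise ValueError(f"{pair.pair_id}: missing progenitor condition {w_cond}")
        ratios = {"mirna": [], "target": []}
        for cultivar in CULTIVARS:
            cond = library_id(cultivar, organ)
            if cond not in pair.mirna_nnr:
                continue
            ratios["mirna"].append(
                math.log2((pair.mirna_nnr[cond] + 1) / (pair.mirna_nnr[w_cond] + 1))
            )
            ratios["target"].append(
                math.log2((pair.target_fpkm[cond] + 1) / (pair.target_fpkm[w_cond] + 1))
            )
        out[organ] = ratios
    return out


def classify_pair(
    pair: ExpressionProfilePair, config: RunConfig | None = None
) -> CoexprCall:
    """Classify one miRNA:target pair as negative / positive / none."""
    config = config or RunConfig()
    conds = pair.conditions
    if len(conds) < 4:
        raise ValueError(f"{pair.pair_id}: need >= 4 usable conditions")
    m = np.array([pair.mirna_nnr[c] for c in conds], dtype=float)
    t = np.array([pair.target_fpkm[c] for c in conds], dtype=float)
    if (m < config.silent_nnr).all() or (t < config.fpkm_min).all():
        return CoexprCall(pair.pair_id, 0.0, "none", "unexpressed")
    lm, lt = np.log2(m + 1), np.log2(t + 1)
    if np.ptp(lm) == 0 or np.ptp(lt) == 0:
        return CoexprCall(pair.pair_id, 0.0, "none", "degenerate")

    if config.coexpr_mode == "ratio_sign":
        return _classify_ratio_sign(pair, config)

    r, p = stats.pearsonr(lm, lt)
    r = float(r)
    if abs(r) >= config.coexpr_min_abs_r and p <= config.coexpr_alpha:
        return CoexprCall(pair.pair_id, r, "negative" if r < 0 else "positive")
    return CoexprCall(pair.pair_id, r, "none")


def _classify_ratio_sign(
    pair: ExpressionProfilePair, config: RunConfig
) -> CoexprCall:
    """Vote on per-organ cultivar/progenitor ratio signs (alternative mode)."""
    profiles = log2_ratio_profile(pair)
    concord = discord = 0
    for organ, ratios in profiles.items():
        for rm, rt in zip(ratios["mirna"], ratios["target"]):
            if rm == 0 or rt == 0:
                continue
            if (rm > 0) == (rt > 0):
                concord += 1
            else:
                discord += 1
    if concord == discord:
        return CoexprCall(pair.pair_id, 0.0, "none", "tie")
    frac = (concord - discord) / (concord + discord)
    return CoexprCall(
        pair.pair_id, frac, "positive" if concord > discord else "negative"
    )


def classify_pairs(
    pairs: Sequence[ExpressionProfilePair], config: RunConfig | None = None
) -> list[CoexprCall]:
    return [classify_pair(p, config) for p in pairs]
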
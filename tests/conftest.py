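"""Shared fixtures: a small planted genome and a desk-scale configuration."""

import pytest

from mirkit import synthetic_data as sd
from mirkit.io_core import RunConfig


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    """Reduced flank set so window folding stays fast in tests."""
    return RunConfig(flank_lengths=[20, 60])


@pytest.fixture(scope="session")
def small_genome():
    """(genome, truth) with 5 planted precursors and narrow buffers."""
    return sd.make_genome(n_precursors=5, seed=11, buffer_len=80)


def enum_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Exhaustive enumeration of nested pairings; oracle for the folder.

    Plain recursion over all structures (no memoization, no DP tables);
    feasible for sequences up to ~14 nt.
    """
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

    def rec(i: int, j: int) -> int:
        # closed interval [i, j]
        if j - i < min_loop + 1:
            return 0
        best = rec(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in pairs:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)


def enum_best_duplex_score(
    mirna: str, window: str, gu_score: float = 0.5
) -> float:
    """Best semi-global duplex-alignment score by cached recursion.

    Aligns the full miRNA against the window read 3'->5' with free window
    ends; Watson-Crick +1, G:U +0.5, mismatch -1, gap -2. Independent
    top-down traversal used as the oracle for duplex_align.
    """
    from functools import lru_cache

    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "U"), ("U", "G")}
    a, t = mirna, window[::-1]
    m, n = len(a), len(t)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == m:
            return 0.0  # trailing window positions are free
        best = rec(i + 1, j) - 2.0  # miRNA base unopposed
        if j < n:
            pair = (a[i], t[j])
            s = 1.0 if pair in wc else gu_score if pair in gu else -1.0
            best = max(best, rec(i + 1, j + 1) + s)
            best = max(best, rec(i, j + 1) - 2.0)  # window base bulged
        return best

    return max(rec(0, j) for j in range(n + 1))
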
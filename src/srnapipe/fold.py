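"""Nested secondary-structure prediction by base-pair maximization.

A Nussinov-style dynamic program over Watson–Crick plus G·U wobble
pairs with a minimum hairpin loop of 3 nt.  Among structures with the
maximal number of pairs the DP prefers the one with the most stacked
pairs (a pair whose enclosed neighbours also pair), which favours long
uninterrupted helices — the geometry that matters when judging miRNA
precursor hairpins.  Thermodynamic folding (mfold/RNAfold) can be
plugged in through `fold_hairpin(engine=...)` but the base-pair DP is
the default: it is deterministic, dependency-free and exactly testable
against exhaustive enumeration.

The DP state is standard: F[i,j] is the best score on [i..j], C[i,j]
the best score given (i,j) pair, and Fex[i,j] the best score given
(i,j) do *not* pair with each other (needed to know whether a stacking
bonus applies).  Scores encode (pairs, stacks) lexicographically as
pairs * 4096 + stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HairpinStructure", "fold_hairpin", "pairable", "MIN_LOOP"]

MIN_LOOP = 3
_PAIR = 4096  # score weight of one pair; stacks are the low-order tie-break
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_CANPAIR = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _CANPAIR[_a, _b] = True


def pairable(a: str, b: str) -> bool:
    """Watson–Crick or G·U wobble."""
    return bool(_CANPAIR[_ENC[a.upper()], _ENC[b.upper()]])


def _fill(enc: np.ndarray, can: np.ndarray, F: np.ndarray, Fex: np.ndarray,
          C: np.ndarray) -> None:
    n = enc.shape[0]
    for d in range(MIN_LOOP + 1, n):
        for i in range(n - d):
            j = i + d
            # Fex: j unpaired, or j pairs some k > i
            best = F[i, j - 1]
            for k in range(i + 1, j - MIN_LOOP):
                if can[enc[k], enc[j]]:
                    left = F[i, k - 1] if k > i else 0
                    v = left + C[k, j]
                    if v > best:
                        best = v
            Fex[i, j] = best
            # C: (i,j) pair enclosing the best inner structure
            if can[enc[i], enc[j]]:
                if j - 1 - (i + 1) > MIN_LOOP:
                    inner = Fex[i + 1, j - 1]
                    if C[i + 1, j - 1] >= 0 and C[i + 1, j - 1] + 1 > inner:
                        inner = C[i + 1, j - 1] + 1  # stacking bonus
                else:
                    inner = 0
                C[i, j] = _PAIR + inner
            F[i, j] = C[i, j] if C[i, j] > Fex[i, j] else Fex[i, j]


try:  # optional jit; semantics identical either way
    from numba import njit

    _fill_fast = njit(cache=True)(_fill)
except Exception:  # pragma: no cover - numba simply not installed
    _fill_fast = _fill


@dataclass
class HairpinStructure:
    """A nested structure: pair_map[i] is i's partner or -1."""

    sequence: str
    pair_map: list[int]

    def __post_init__(self) -> None:
        pm = self.pair_map
        for i, j in enumerate(pm):
            if j >= 0 and (pm[j] != i or j == i):
                raise ValueError("pair_map is not an involution")

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pair_map) if j > i)

    @property
    def loop_span(self) -> tuple[int, int] | None:
        """Half-open unpaired interval enclosed by the innermost pair
        of the dominant hairpin (the pair with the smallest span)."""
        pairs = [(j - i, i, j) for i, j in enumerate(self.pair_map) if j > i]
        if not pairs:
            return None
        _, i, j = min(pairs)
        return (i + 1, j)

    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.pair_map):
            out.append("." if j < 0 else "(" if j > i else ")")
        return "".join(out)

    def longest_helix(self) -> int:
        """Longest run of directly stacked pairs."""
        best = run = 0
        prev = None
        for i, j in enumerate(self.pair_map):
            if j > i:
                if prev is not None and prev == (i - 1, j + 1):
                    run += 1
                else:
                    run = 1
                best = max(best, run)
                prev = (i, j)
        return best


def _traceback(enc, can, F, Fex, C) -> list[int]:
    n = enc.shape[0]
    pair = [-1] * n
    stack = [(0, n - 1, "F")]
    while stack:
        i, j, state = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        if state == "F":
            if C[i, j] >= 0 and F[i, j] == C[i, j]:
                stack.append((i, j, "C"))
                continue
            state = "Fex"
        if state == "Fex":
            if Fex[i, j] == F[i, j - 1]:
                stack.append((i, j - 1, "F"))
                continue
            for k in range(i + 1, j - MIN_LOOP):
                if can[enc[k], enc[j]]:
                    left = F[i, k - 1] if k > i else 0
                    if left + C[k, j] == Fex[i, j]:
                        if k > i:
                            stack.append((i, k - 1, "F"))
                        stack.append((k, j, "C"))
                        break
            continue
        # state == "C"
        pair[i], pair[j] = j, i
        if j - 1 - (i + 1) > MIN_LOOP:
            inner = C[i, j] - _PAIR
            if C[i + 1, j - 1] >= 0 and inner == C[i + 1, j - 1] + 1:
                stack.append((i + 1, j - 1, "C"))
            else:
                stack.append((i + 1, j - 1, "Fex"))
    return pair


def fold_hairpin(window_seq: str, engine=None) -> HairpinStructure:
    """Fold a candidate window into its maximum-base-pair nested structure.

    Parameters
    ----------
    window_seq
        RNA/DNA sequence (T and U equivalent), A/C/G/T/U only.
    engine
        Optional callable ``seq -> pair_map`` (e.g. a thermodynamic
        folder adapter); when given it replaces the internal DP.
    """
    seq = window_seq.upper().replace("U", "T")
    if not seq or any(c not in "ACGT" for c in seq):
        raise ValueError("sequence must be non-empty over A/C/G/T/U")
    if engine is not None:
        return HairpinStructure(seq, list(engine(seq)))
    n = len(seq)
    enc = np.array([_ENC[c] for c in seq], dtype=np.int8)
    F = np.zeros((n, n), dtype=np.int64)
    Fex = np.zeros((n, n), dtype=np.int64)
    C = np.full((n, n), -1, dtype=np.int64)
    _fill_fast(enc, _CANPAIR, F, Fex, C)
    return HairpinStructure(seq, _traceback(enc, _CANPAIR, F, Fex, C))
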
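"""Independent reference implementations used to check the fast paths.

These deliberately avoid the production code paths: alignment scores are
recomputed by exhaustive path enumeration or a memoized recursion,
primer sites by a character-by-character scan, and attribution labels by
a direct per-position rule application.
"""

from __future__ import annotations

import sys
from functools import lru_cache

from sipmosaic.pairalign import ScoringScheme
from sipmosaic.seqio import IUPAC_CODES


def enumerate_alignment_score(a: str, b: str, scoring: ScoringScheme) -> int:
    """Best score over ALL global alignments, by explicit enumeration.

    Gap costs are affine: the first gap column of a run costs
    gap_open + gap_extend, each further column gap_extend.  Exponential;
    only for tiny sequences.
    """
    best = -(10**9)
    open_cost = scoring.gap_open + scoring.gap_extend

    def step(i: int, j: int, prev: str, score: int) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = scoring.match if a[i] == b[j] else scoring.mismatch
            step(i + 1, j + 1, "M", score + s)
        if i < len(a):  # gap in b
            g = scoring.gap_extend if prev == "A" else open_cost
            step(i + 1, j, "A", score + g)
        if j < len(b):  # gap in a
            g = scoring.gap_extend if prev == "B" else open_cost
            step(i, j + 1, "B", score + g)

    step(0, 0, "M", 0)
    return best


def recursive_affine_score(a: str, b: str, scoring: ScoringScheme) -> int:
    """Memoized recursion over (i, j, previous column type).

    Independent of both the enumeration above and the production
    aligner; polynomial, usable up to a few hundred bases.
    """
    open_cost = scoring.gap_open + scoring.gap_extend
    sys.setrecursionlimit(100000)

    @lru_cache(maxsize=None)
    def f(i: int, j: int, prev: str) -> int:
        if i == len(a) and j == len(b):
            return 0
        best = -(10**9)
        if i < len(a) and j < len(b):
            s = scoring.match if a[i] == b[j] else scoring.mismatch
            best = max(best, s + f(i + 1, j + 1, "M"))
        if i < len(a):
            g = scoring.gap_extend if prev == "A" else open_cost
            best = max(best, g + f(i + 1, j, "A"))
        if j < len(b):
            g = scoring.gap_extend if prev == "B" else open_cost
            best = max(best, g + f(i, j + 1, "B"))
        return best

    return f(0, 0, "M")


def naive_primer_sites(template: str, primer: str, max_mismatch: int) -> list[tuple[int, int]]:
    """Character-by-character primer scan."""
    out = []
    m = len(primer)
    for i in range(len(template) - m + 1):
        mm = 0
        for t, p in zip(template[i : i + m], primer):
            allowed = IUPAC_CODES[p]
            if t != "N" and t not in allowed:
                mm += 1
        if mm <= max_mismatch:
            out.append((i, mm))
    return out


def rule_labels(query: str, proj_a: str, proj_b: str) -> list[str]:
    """The four-way attribution rule applied position by position."""
    out = []
    for q, a, b in zip(query, proj_a, proj_b):
        ma = a == q and a != "-"
        mb = b == q and b != "-"
        if ma and mb:
            out.append("SHARED")
        elif ma:
            out.append("A_SPECIFIC")
        elif mb:
            out.append("B_SPECIFIC")
        else:
            out.append("NOVEL")
    return out
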
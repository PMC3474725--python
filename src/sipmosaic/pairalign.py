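"""Global and semi-global pairwise alignment with affine gap costs.

The attribution, recruitment and primer modules all sit on top of the two
aligners here.  Scores follow the EDNAFULL-like default (match +5,
mismatch -4, gap open -10, gap extend -1); a gap of length k costs
``gap_open + k * gap_extend``.  Gaps are penalized strongly on purpose:
the operon variants under comparison are collinear, so most true
differences are substitutions.

The dynamic programming itself is delegated to Bio.Align.PairwiseAligner
(an exact affine-gap Needleman-Wunsch in C); this module owns the scoring
conventions, identity definition and the projection of an alignment onto
query coordinates.  The first alignment reported by the aligner is taken,
which makes results deterministic for identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .seqio import NucSequence

GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; a length-k gap costs gap_open + k * gap_extend."""

    match: int = 5
    mismatch: int = -4
    gap_open: int = -10
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if not (self.match > 0 and self.mismatch < 0):
            raise ValueError("need match > 0 and mismatch < 0")
        if not (self.gap_open <= 0 and self.gap_extend <= 0):
            raise ValueError("gap penalties must be <= 0")
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be <= gap_extend")

    def gap_cost(self, length: int) -> int:
        return self.gap_open + length * self.gap_extend if length else 0


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped query/target pair with score and column identity.

    identity = matching columns / all alignment columns (gap columns count
    as non-matches), which keeps identity monotone under added gaps.
    For semi-global alignments the columns are restricted to the query's
    aligned span (free target overhangs are excluded).
    """

    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: int
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_target):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True)
class QueryProjection:
    """Per query position, the target symbol aligned to it (or GAP).

    Target insertions (columns gapped in the query) are dropped from the
    projection but tallied in ``insertions``.
    """

    symbols: str  # length == query length, over {A,C,G,T,N,-}
    insertions: int


def _aligner(scoring: ScoringScheme, semi_global: bool) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open + scoring.gap_extend
    a.extend_gap_score = scoring.gap_extend
    if semi_global:
        # free end gaps on the target (reference) only: reference overhangs
        # appear as deletions relative to the query
        a.end_deletion_score = 0.0
    return a


def _identity(aq: str, at: str) -> float:
    ncol = len(aq)
    if ncol == 0:
        return 0.0
    matches = sum(1 for x, y in zip(aq, at) if x == y and x != GAP)
    return matches / ncol


def align_global(
    a: NucSequence, b: NucSequence, scoring: ScoringScheme = DEFAULT_SCORING
) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch) alignment of a (query) vs b (target)."""
    if not a.seq or not b.seq:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(scoring, semi_global=False)
    al = aligner.align(b.seq, a.seq)[0]  # target first in Bio.Align
    a_target, a_query = str(al[0]), str(al[1])
    return PairwiseAlignment(
        query_id=a.id,
        target_id=b.id,
        aligned_query=a_query,
        aligned_target=a_target,
        score=int(al.score),
        identity=_identity(a_query, a_target),
    )


def align_semi_global(
    read: NucSequence, ref: NucSequence, scoring: ScoringScheme = DEFAULT_SCORING
) -> PairwiseAlignment:
    """Align a read inside a reference with free reference end-gaps.

    The read is fully aligned; the reference may overhang at either end
    without penalty.  Identity is computed over the read's aligned span
    only (overhang columns excluded).
    """
    if not read.seq or not ref.seq:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(scoring, semi_global=True)
    al = aligner.align(ref.seq, read.seq)[0]
    a_target, a_query = str(al[0]), str(al[1])
    # trim free end-gap columns (gaps at the ends of the query row)
    lo = 0
    while lo < len(a_query) and a_query[lo] == GAP:
        lo += 1
    hi = len(a_query)
    while hi > lo and a_query[hi - 1] == GAP:
        hi -= 1
    return PairwiseAlignment(
        query_id=read.id,
        target_id=ref.id,
        aligned_query=a_query[lo:hi],
        aligned_target=a_target[lo:hi],
        score=int(al.score),
        identity=_identity(a_query[lo:hi], a_target[lo:hi]),
    )


def project(alignment: PairwiseAlignment) -> QueryProjection:
    """Project an alignment onto query coordinates.

    For every query position, report the target symbol sitting in the same
    column (GAP when the target is gapped there).  Columns gapped in the
    query (target insertions) carry no query position; they are counted in
    the insertion tally instead.
    """
    symbols = []
    insertions = 0
    for q, t in zip(alignment.aligned_query, alignment.aligned_target):
        if q == GAP:
            insertions += 1
        else:
            symbols.append(t)
    return QueryProjection("".join(symbols), insertions)


def dump_alignment(alignment: PairwiseAlignment) -> str:
    """3-line debug text: query row, match row, target row."""
    marks = "".join(
        "|" if x == y and x != GAP else " "
        for x, y in zip(alignment.aligned_query, alignment.aligned_target)
    )
    return "\n".join([alignment.aligned_query, marks, alignment.aligned_target])
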
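"""Parent-of-origin attribution for a mosaic operon.

The central analysis: every position of a query operon is compared with
its two candidate parent operons (here the naphthalene-degradation *nag*
clusters of *Ralstonia* sp. U2 and *P. naphthalenivorans* CJ2 style) via
two independent global alignments projected onto query coordinates.  Each
position is labelled

* ``A_SPECIFIC`` - matches parent A only (an informative site for A),
* ``B_SPECIFIC`` - matches parent B only,
* ``SHARED``     - matches both parents (uninformative),
* ``NOVEL``      - matches neither (a private mutation).

Gene-level summaries and maximal same-donor segments (with breakpoint
intervals between them) are derived from this track.  A parent gap at a
query position never matches: a query base absent from a parent counts
as "no homology" with that parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .pairalign import DEFAULT_SCORING, GAP, QueryProjection, ScoringScheme, align_global, project
from .seqio import AnnotatedOperon, GeneInterval


class SiteLabel(str, Enum):
    A_SPECIFIC = "A_SPECIFIC"
    B_SPECIFIC = "B_SPECIFIC"
    SHARED = "SHARED"
    NOVEL = "NOVEL"


class GeneCall(str, Enum):
    A_LIKE = "A_LIKE"
    B_LIKE = "B_LIKE"
    MOSAIC = "MOSAIC"
    NOVEL = "NOVEL"
    UNINFORMATIVE = "UNINFORMATIVE"


# compact integer codes for the numpy track
_A, _B, _S, _N = 0, 1, 2, 3
_CODE_TO_LABEL = {_A: SiteLabel.A_SPECIFIC, _B: SiteLabel.B_SPECIFIC,
                  _S: SiteLabel.SHARED, _N: SiteLabel.NOVEL}


@dataclass(frozen=True)
class SiteAttributionTrack:
    """Per-position donor labels for a query operon, plus the projections used."""

    query_id: str
    query_seq: str
    codes: np.ndarray  # uint8, one of {_A,_B,_S,_N} per query position
    projection_a: QueryProjection
    projection_b: QueryProjection

    def __len__(self) -> int:
        return len(self.codes)

    def labels(self) -> list[SiteLabel]:
        return [_CODE_TO_LABEL[int(c)] for c in self.codes]

    def counts(self, start: int = 0, end: int | None = None) -> dict[SiteLabel, int]:
        end = len(self.codes) if end is None else end
        window = self.codes[start:end]
        return {lab: int(np.sum(window == code)) for code, lab in _CODE_TO_LABEL.items()}


@dataclass(frozen=True)
class GeneSimilarityReport:
    gene_name: str
    pct_a_specific: float
    pct_b_specific: float
    pct_shared: float
    pct_novel: float
    identity_to_a: float  # percent
    identity_to_b: float
    gene_call: GeneCall


@dataclass(frozen=True)
class SegmentCall:
    donor: str  # "A" or "B"
    start: int  # query coordinates of first/last informative site, half-open
    end: int
    n_informative_sites: int


@dataclass(frozen=True)
class Breakpoint:
    """The switch lies somewhere in [start, end): between the last
    informative site of the left segment and the first of the right."""

    left_donor: str
    right_donor: str
    start: int
    end: int


def attribute_sites(
    query: AnnotatedOperon | "object",
    parent_a: AnnotatedOperon | "object",
    parent_b: AnnotatedOperon | "object",
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> SiteAttributionTrack:
    """Label every query position by parent-of-origin evidence.

    The query is globally aligned to each parent independently; both
    alignments are projected onto query coordinates and the four-way rule
    applied per position.
    """
    qseq = _seq_of(query)
    aseq = _seq_of(parent_a)
    bseq = _seq_of(parent_b)
    proj_a = project(align_global(qseq, aseq, scoring))
    proj_b = project(align_global(qseq, bseq, scoring))
    return attribute_from_projections(qseq.id, qseq.seq, proj_a, proj_b)


def attribute_from_projections(
    query_id: str, query_seq: str, proj_a: QueryProjection, proj_b: QueryProjection
) -> SiteAttributionTrack:
    """The per-position rule, separated out so it can be applied to
    pre-computed projections."""
    if len(proj_a.symbols) != len(query_seq) or len(proj_b.symbols) != len(query_seq):
        raise ValueError("projection length must equal query length")
    q = np.frombuffer(query_seq.encode(), dtype="S1")
    a = np.frombuffer(proj_a.symbols.encode(), dtype="S1")
    b = np.frombuffer(proj_b.symbols.encode(), dtype="S1")
    gap = GAP.encode()
    match_a = (q == a) & (a != gap)
    match_b = (q == b) & (b != gap)
    codes = np.full(len(query_seq), _N, dtype=np.uint8)
    codes[match_a & ~match_b] = _A
    codes[~match_a & match_b] = _B
    codes[match_a & match_b] = _S
    return SiteAttributionTrack(query_id, query_seq, codes, proj_a, proj_b)


def summarize_gene(
    track: SiteAttributionTrack,
    gene: GeneInterval,
    call_margin: float = 2.0,
    min_run: int = 3,
    novel_threshold: float = 5.0,
) -> GeneSimilarityReport:
    """Percentages of the four site classes over a gene, pairwise
    identities, and a categorical call.

    Call precedence: MOSAIC (informative runs of length >= min_run from
    BOTH donors inside the gene) is tested first, so that an unbalanced
    within-gene recombinant is not masked by the identity margin; then
    A_LIKE/B_LIKE on the identity margin (percentage points); then NOVEL
    if the private-mutation share exceeds ``novel_threshold``; else
    UNINFORMATIVE.
    """
    if gene.start < 0 or gene.end > len(track):
        raise ValueError(f"gene {gene.gene_name!r} outside the attribution track")
    counts = track.counts(gene.start, gene.end)
    n = len(gene)
    pct = {lab: 100.0 * c / n for lab, c in counts.items()}
    identity_a = pct[SiteLabel.A_SPECIFIC] + pct[SiteLabel.SHARED]
    identity_b = pct[SiteLabel.B_SPECIFIC] + pct[SiteLabel.SHARED]

    window = track.codes[gene.start:gene.end]
    informative = window[(window == _A) | (window == _B)]
    call = GeneCall.UNINFORMATIVE
    if _has_run(informative, _A, min_run) and _has_run(informative, _B, min_run):
        call = GeneCall.MOSAIC
    elif identity_a - identity_b >= call_margin:
        call = GeneCall.A_LIKE
    elif identity_b - identity_a >= call_margin:
        call = GeneCall.B_LIKE
    elif pct[SiteLabel.NOVEL] > novel_threshold:
        call = GeneCall.NOVEL

    return GeneSimilarityReport(
        gene_name=gene.gene_name,
        pct_a_specific=pct[SiteLabel.A_SPECIFIC],
        pct_b_specific=pct[SiteLabel.B_SPECIFIC],
        pct_shared=pct[SiteLabel.SHARED],
        pct_novel=pct[SiteLabel.NOVEL],
        identity_to_a=identity_a,
        identity_to_b=identity_b,
        gene_call=call,
    )


def _has_run(informative: np.ndarray, code: int, min_run: int) -> bool:
    """Run of >= min_run consecutive informative sites of one donor
    (consecutive in informative-site order, positions may be spread out)."""
    run = 0
    for c in informative:
        if c == code:
            run += 1
            if run >= min_run:
                return True
        else:
            run = 0
    return False


def detect_segments(
    track: SiteAttributionTrack, min_run: int = 3
) -> tuple[list[SegmentCall], list[Breakpoint]]:
    """Partition the informative sites into maximal same-donor segments.

    Informative sites (A/B specific only) are taken in order; maximal
    same-donor runs of >= min_run sites become segments; shorter runs are
    absorbed into the flanking run with more informative sites (ties go to
    the preceding run).  Breakpoints are reported as the interval between
    the last informative site of one segment and the first of the next --
    the true switch position is unidentifiable inside that gap.
    """
    positions = np.nonzero((track.codes == _A) | (track.codes == _B))[0]
    if positions.size == 0:
        return [], []
    donors = track.codes[positions]  # _A or _B

    # initial maximal same-donor runs as (donor, [site indices])
    runs: list[list] = []
    for idx, d in zip(positions, donors):
        if runs and runs[-1][0] == d:
            runs[-1][1].append(int(idx))
        else:
            runs.append([int(d), [int(idx)]])

    # absorb short runs into the larger flank until stable
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, (d, sites) in enumerate(runs):
            if len(sites) >= min_run:
                continue
            left = runs[i - 1] if i > 0 else None
            right = runs[i + 1] if i + 1 < len(runs) else None
            if left is None and right is None:
                continue
            if right is None or (left is not None and len(left[1]) >= len(right[1])):
                target = left
            else:
                target = right
            target[1].extend(sites)  # absorbed sites keep their position, lose their donor vote
            target[1].sort()
            runs.pop(i)
            # merge neighbours that now share a donor
            j = 1
            while j < len(runs):
                if runs[j][0] == runs[j - 1][0]:
                    runs[j - 1][1].extend(runs[j][1])
                    runs[j - 1][1].sort()
                    runs.pop(j)
                else:
                    j += 1
            changed = True
            break

    segments = []
    donor_name = {_A: "A", _B: "B"}
    for d, sites in runs:
        n_support = int(np.sum(track.codes[np.array(sites)] == d))
        segments.append(
            SegmentCall(
                donor=donor_name[d],
                start=sites[0],
                end=sites[-1] + 1,
                n_informative_sites=n_support,
            )
        )

    breakpoints = []
    for left, right in zip(segments, segments[1:]):
        breakpoints.append(
            Breakpoint(
                left_donor=left.donor,
                right_donor=right.donor,
                start=left.end,  # one past the last informative site of the left segment
                end=right.start + 1,  # includes the first informative site of the right
            )
        )
    return segments, breakpoints


# ---------------------------------------------------------------------------
# exports

def track_to_bed(track: SiteAttributionTrack) -> str:
    """One BED record per maximal same-label run (BED is 0-based half-open)."""
    lines = []
    codes = track.codes
    start = 0
    for i in range(1, len(codes) + 1):
        if i == len(codes) or codes[i] != codes[start]:
            lab = _CODE_TO_LABEL[int(codes[start])].value
            lines.append(f"{track.query_id}\t{start}\t{i}\t{lab}")
            start = i
    return "\n".join(lines) + "\n"


def gene_reports_to_tsv(reports: Sequence[GeneSimilarityReport]) -> str:
    """Per-gene TSV with the four-way partition and both pairwise identities."""
    header = (
        "gene\tpct_A_specific\tpct_B_specific\tpct_shared\tpct_novel\t"
        "identity_to_A\tidentity_to_B\tcall"
    )
    rows = [header]
    for r in reports:
        rows.append(
            f"{r.gene_name}\t{r.pct_a_specific:.2f}\t{r.pct_b_specific:.2f}\t"
            f"{r.pct_shared:.2f}\t{r.pct_novel:.2f}\t{r.identity_to_a:.2f}\t"
            f"{r.identity_to_b:.2f}\t{r.gene_call.value}"
        )
    return "\n".join(rows) + "\n"


def segments_to_tsv(segments: Sequence[SegmentCall], breakpoints: Sequence[Breakpoint]) -> str:
    """Segments and breakpoint intervals, 1-based inclusive for humans."""
    rows = ["type\tdonor\tstart_1based\tend_1based\tn_informative_sites"]
    for s in segments:
        rows.append(f"segment\t{s.donor}\t{s.start + 1}\t{s.end}\t{s.n_informative_sites}")
    for b in breakpoints:
        rows.append(f"breakpoint\t{b.left_donor}->{b.right_donor}\t{b.start + 1}\t{b.end}\t.")
    return "\n".join(rows) + "\n"


def _seq_of(obj):
    """Accept AnnotatedOperon or bare NucSequence."""
    return obj.sequence if isinstance(obj, AnnotatedOperon) else obj
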
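"""IUPAC-aware in-silico PCR: primer site search and virtual amplicons.

Reproduces, computationally, the naphthalene-dioxygenase primer screen:
given a template and a primer pair, find every placement where the
forward primer matches the plus strand and the reverse primer's reverse
complement matches downstream, within a product-size cap and a per-primer
mismatch budget.  Degenerate IUPAC codes in primers match their whole
degeneracy set; mismatch weighting is positionally uniform (no 3'
anchoring -- this is a sequence screen, not a thermodynamic model).
Both template orientations are scanned and minus-strand products are
mapped back to plus-strand coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqio import IUPAC_CODES, NucSequence, PrimerPair, revcomp

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"


@dataclass(frozen=True)
class Amplicon:
    """A virtual PCR product spanning both primer footprints,
    0-based half-open on the template as given."""

    template_id: str
    start: int
    end: int
    length: int
    fwd_mismatches: int
    rev_mismatches: int
    template_strand: str = "+"  # strand carrying the forward primer


def _mismatch_profile(template: str, primer: str) -> np.ndarray:
    """mismatches[i] = count of primer positions not matching template[i:i+len]."""
    n, m = len(template), len(primer)
    if n < m:
        return np.empty(0, dtype=np.int32)
    t = np.frombuffer(template.encode(), dtype="S1")
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for j, code in enumerate(primer):
        allowed = IUPAC_CODES.get(code)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {code!r} in primer")
        window = t[j : j + n - m + 1]
        ok = np.zeros(n - m + 1, dtype=bool)
        for base in allowed:
            ok |= window == base.encode()
        # template N is treated as matching any primer code
        ok |= window == b"N"
        mism += ~ok
    return mism


def primer_sites(template: str, primer: str, max_mismatch: int = 0) -> list[tuple[int, int]]:
    """(offset, mismatches) for every primer placement within budget."""
    mism = _mismatch_profile(template, primer)
    return [(int(i), int(mism[i])) for i in np.nonzero(mism <= max_mismatch)[0]]


def find_amplicons(
    template: NucSequence,
    primers: PrimerPair,
    max_mismatch: int = 0,
    max_product_len: int = 10_000,
) -> list[Amplicon]:
    """All virtual products of a primer pair on a template.

    The forward primer anneals to the plus strand and the reverse
    primer's reverse complement lies downstream; products longer than
    ``max_product_len`` or shorter than the two footprints are dropped.
    The reverse orientation (forward primer on the minus strand) is
    scanned too and mapped back to template coordinates.
    """
    if max_product_len < len(primers.fwd) + len(primers.rev):
        raise ValueError("max_product_len smaller than the primer footprints")
    out = []
    n = len(template.seq)
    for strand, tpl in (("+", template.seq), ("-", revcomp(template.seq))):
        fwd_sites = primer_sites(tpl, primers.fwd, max_mismatch)
        rev_sites = primer_sites(tpl, revcomp(primers.rev), max_mismatch)
        min_len = len(primers.fwd) + len(primers.rev)
        for fstart, fmm in fwd_sites:
            for rstart, rmm in rev_sites:
                end = rstart + len(primers.rev)
                length = end - fstart
                if length < min_len or length > max_product_len:
                    continue
                if strand == "+":
                    s, e = fstart, end
                else:
                    s, e = n - end, n - fstart
                out.append(
                    Amplicon(template.id, s, e, length, fmm, rmm, template_strand=strand)
                )
    # a palindromic placement can be found in both orientations; keep one
    seen = set()
    unique = []
    for a in sorted(out, key=lambda a: (a.start, a.end, a.template_strand)):
        key = (a.start, a.end, a.fwd_mismatches, a.rev_mismatches)
        if key not in seen:
            seen.add(key)
            unique.append(a)
    return unique


@dataclass(frozen=True)
class ScreenResult:
    pair_name: str
    verdict: str  # POSITIVE / NEGATIVE
    hit_reads: int
    fwd_hit_reads: int
    rev_hit_reads: int


def screen_readset(
    reads: Iterable[NucSequence],
    primer_pairs: Sequence[PrimerPair],
    min_hit_reads: int = 5,
    max_mismatch: int = 0,
) -> list[ScreenResult]:
    """Fragment-tolerant primer screen over a read set.

    A read supports a pair when it contains a site for EITHER primer on
    either strand (reads are short, so one footprint is evidence enough);
    a pair is POSITIVE when >= min_hit_reads reads support it.  With
    min_hit_reads = 0 every pair is trivially POSITIVE (degenerate
    configuration, kept for completeness).
    """
    reads = list(reads)
    results = []
    for pair in primer_pairs:
        fwd_hits = rev_hits = either = 0
        for read in reads:
            seq = read.seq
            rc = revcomp(seq)
            f = bool(
                primer_sites(seq, pair.fwd, max_mismatch)
                or primer_sites(rc, pair.fwd, max_mismatch)
            )
            r = bool(
                primer_sites(seq, pair.rev, max_mismatch)
                or primer_sites(rc, pair.rev, max_mismatch)
            )
            fwd_hits += f
            rev_hits += r
            either += f or r
        results.append(
            ScreenResult(
                pair_name=pair.name,
                verdict=POSITIVE if either >= min_hit_reads else NEGATIVE,
                hit_reads=either,
                fwd_hit_reads=fwd_hits,
                rev_hit_reads=rev_hits,
            )
        )
    return results


def amplicons_to_tsv(amplicons: Sequence[Amplicon]) -> str:
    rows = ["template\tstart_1based\tend_1based\tlength\tfwd_mismatches\trev_mismatches\tstrand"]
    for a in amplicons:
        rows.append(
            f"{a.template_id}\t{a.start + 1}\t{a.end}\t{a.length}\t"
            f"{a.fwd_mismatches}\t{a.rev_mismatches}\t{a.template_strand}"
        )
    return "\n".join(rows) + "\n"


def screen_to_tsv(results: Sequence[ScreenResult]) -> str:
    rows = ["pair\tverdict\thit_reads\tfwd_hit_reads\trev_hit_reads"]
    for r in results:
        rows.append(f"{r.pair_name}\t{r.verdict}\t{r.hit_reads}\t{r.fwd_hit_reads}\t{r.rev_hit_reads}")
    return "\n".join(rows) + "\n"
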
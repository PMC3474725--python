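"""16S read classification and heavy/light-fraction enrichment calling.

A nearest-reference classifier stands in for database-scale taxonomic
profilers: each read is aligned (semi-global, both strands) to a small
user-supplied panel of 16S references labelled ``taxon|id`` and takes the
taxon of its best reference if the identity clears a species-level floor
(default 0.97).  Identity ties between different taxa are left
UNCLASSIFIED rather than broken arbitrarily.

Enrichment across a stable-isotope-probing gradient is called from the
heavy (13C) vs light (12C) relative-abundance tables: a taxon is
enriched when its pseudocounted heavy/light abundance ratio clears
``min_ratio`` and its heavy abundance clears ``min_heavy_abundance``.
These are declared heuristics; the underlying experiment reads
enrichment off band dominance, not a numeric rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .seqio import NucSequence, revcomp
from .variant_quantify import _align_read

UNCLASSIFIED = "UNCLASSIFIED"
LIGHT_12C = "light_12C"
HEAVY_13C = "heavy_13C"


def taxon_of(ref: NucSequence) -> str:
    """Panel headers are 'taxon|id'; a header without '|' is its own taxon."""
    return ref.id.split("|", 1)[0]


def classify_16s(
    reads: Iterable[NucSequence],
    references: Sequence[NucSequence],
    min_identity: float = 0.97,
) -> dict[str, str]:
    """Map read id -> taxon (or UNCLASSIFIED).

    Best-identity nearest reference over both strands; reads below
    ``min_identity`` or tied between different taxa are UNCLASSIFIED.
    """
    if not references:
        raise ValueError("empty 16S reference panel")
    panel = [(taxon_of(r), r.seq) for r in references]
    result: dict[str, str] = {}
    for read in reads:
        strands = (read.seq, revcomp(read.seq))
        # cheap k-bounded edit-distance screen; identity floor implies an
        # edit-distance ceiling (columns >= read length), padded generously
        k = math.ceil((1.0 - min_identity) * 1.3 * len(read.seq)) + 3
        candidates: list[tuple[int, str, str, str]] = []
        for taxon, ref_seq in panel:
            for seq in strands:
                d = edlib.align(seq, ref_seq, mode="HW", task="distance", k=k)["editDistance"]
                if d >= 0:
                    candidates.append((d, taxon, seq, ref_seq))
        if not candidates:
            result[read.id] = UNCLASSIFIED
            continue
        dmin = min(c[0] for c in candidates)
        # exact column identity only for near-best hits (a distance gap of
        # > 2 cannot be overturned by the column normalization at this scale)
        best_taxon = None
        best_id = -1.0
        tied = False
        for d, taxon, seq, ref_seq in candidates:
            if d > dmin + 2:
                continue
            ident = _align_read(seq, ref_seq)[0]
            if ident > best_id:
                best_id, best_taxon, tied = ident, taxon, False
            elif ident == best_id and taxon != best_taxon:
                tied = True
        if best_id < min_identity or tied:
            result[read.id] = UNCLASSIFIED
        else:
            result[read.id] = best_taxon
    return result


@dataclass(frozen=True)
class TaxonAbundanceTable:
    """Per-taxon counts and relative abundance (% of classified reads)
    for one gradient fraction."""

    fraction: str  # light_12C or heavy_13C
    counts: dict[str, int]
    abundance_pct: dict[str, float]
    unclassified: int
    denominator_note: str = (
        "abundances are % of classified reads; unclassified reads are "
        "reported separately (a total-read denominator would differ)"
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": list(self.counts),
                "fraction": self.fraction,
                "read_count": list(self.counts.values()),
                "abundance_pct": [self.abundance_pct[t] for t in self.counts],
            }
        )


def relative_abundance(
    classifications: Mapping[str, str], fraction_label: str
) -> TaxonAbundanceTable:
    """Tally classifications into a per-taxon abundance table."""
    counts: dict[str, int] = {}
    unclassified = 0
    for taxon in classifications.values():
        if taxon == UNCLASSIFIED:
            unclassified += 1
        else:
            counts[taxon] = counts.get(taxon, 0) + 1
    total = sum(counts.values())
    abundance = {t: 100.0 * c / total for t, c in counts.items()} if total else {}
    return TaxonAbundanceTable(fraction_label, counts, abundance, unclassified)


@dataclass(frozen=True)
class EnrichmentResult:
    taxon: str
    heavy_pct: float
    light_pct: float
    ratio: float
    enriched: bool


def call_enrichment(
    heavy: TaxonAbundanceTable,
    light: TaxonAbundanceTable,
    pseudocount: float = 0.5,
    min_ratio: float = 5.0,
    min_heavy_abundance: float = 1.0,
) -> list[EnrichmentResult]:
    """Flag taxa over-represented in the heavy (13C) fraction.

    ratio = (heavy% + pseudocount) / (light% + pseudocount); enriched
    iff ratio >= min_ratio and heavy% >= min_heavy_abundance.  The
    pseudocount (percentage points) bounds the ratio for taxa absent
    from one fraction.
    """
    taxa = sorted(set(heavy.abundance_pct) | set(light.abundance_pct))
    results = []
    for t in taxa:
        h = heavy.abundance_pct.get(t, 0.0)
        l = light.abundance_pct.get(t, 0.0)
        ratio = (h + pseudocount) / (l + pseudocount)
        results.append(
            EnrichmentResult(
                taxon=t,
                heavy_pct=h,
                light_pct=l,
                ratio=ratio,
                enriched=bool(ratio >= min_ratio and h >= min_heavy_abundance),
            )
        )
    return results


def enrichment_to_tsv(results: Sequence[EnrichmentResult]) -> str:
    rows = ["taxon\theavy_pct\tlight_pct\tratio\tenriched"]
    for r in results:
        rows.append(
            f"{r.taxon}\t{r.heavy_pct:.3f}\t{r.light_pct:.3f}\t{r.ratio:.3f}\t"
            f"{'yes' if r.enriched else 'no'}"
        )
    return "\n".join(rows) + "\n"


def abundance_to_tsv(table: TaxonAbundanceTable) -> str:
    rows = [f"# {table.denominator_note}", "taxon\tfraction\tread_count\tabundance_pct"]
    for t in sorted(table.counts, key=lambda t: -table.counts[t]):
        rows.append(f"{t}\t{table.fraction}\t{table.counts[t]}\t{table.abundance_pct[t]:.3f}")
    rows.append(f"UNCLASSIFIED\t{table.fraction}\t{table.unclassified}\t.")
    return "\n".join(rows) + "\n"
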
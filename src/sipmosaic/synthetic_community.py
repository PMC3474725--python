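"""Synthetic data with exact ground truth for every pipeline stage.

The generator emulates the study conditions this pipeline was built for:

* two diverged but collinear parent operons with the canonical *nag*
  gene layout (*nagAa-nagG-nagH-nagAb-nagAc-nagAd-nagB-nagF-nagC-nagQ-
  nagE-nagD*),
* a recombinant mosaic of the two with sparse private point mutations,
* pyrosequencing-style read sets, 30-530 bp, drawn from a mixture of
  operon variants at set proportions with substitution and single-base
  indel errors,
* heavy (13C) / light (12C) 16S read pools in which isotope-labelled
  taxa dominate the heavy pool, with a leakage parameter modelling
  carry-over of unlabelled DNA into the heavy fraction.

Every generator is a pure function of its integer seed (independent
child streams per output, so regenerating one file leaves the others
byte-identical), and every generator returns a truth record sufficient
to recompute the expected downstream result without re-reading the
sequence output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import primers
from .seqio import AnnotatedOperon, GeneInterval, NucSequence, revcomp

BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
_BASE_STR = "ACGT"

#: default gene lengths (bp); round stand-ins for the real *nag* genes,
#: with the literature gene order -- the synthetic operon never claims to
#: equal the deposited sequences.
DEFAULT_GENE_LAYOUT: tuple[tuple[str, int], ...] = (
    ("nagAa", 1500), ("nagG", 1300), ("nagH", 500), ("nagAb", 350),
    ("nagAc", 1350), ("nagAd", 600), ("nagB", 800), ("nagF", 800),
    ("nagC", 800), ("nagQ", 350), ("nagE", 950), ("nagD", 900),
)


def scaled_gene_layout(factor: float) -> tuple[tuple[str, int], ...]:
    """The default layout with lengths scaled down for desk-scale runs."""
    return tuple((name, max(30, int(round(length * factor)))) for name, length in DEFAULT_GENE_LAYOUT)


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# parent operons and the mosaic

def generate_parent_pair(
    gene_layout: Sequence[tuple[str, int]] = DEFAULT_GENE_LAYOUT,
    per_gene_divergence: float | Mapping[str, float] = 0.1,
    seed: int = 0,
    labels: tuple[str, str] = ("parentA", "parentB"),
) -> tuple[AnnotatedOperon, AnnotatedOperon]:
    """Two equal-length collinear parents: A uniform random, B derived by
    per-gene independent substitutions at the stated divergence."""
    def div_of(gene: str) -> float:
        d = per_gene_divergence[gene] if isinstance(per_gene_divergence, Mapping) else per_gene_divergence
        if not (0.0 <= d <= 0.3):
            raise ValueError(f"divergence for {gene!r} outside [0, 0.3]")
        return d

    rng_a, rng_b = _rng_children(seed, 2)
    genes = []
    pos = 0
    for name, length in gene_layout:
        genes.append(GeneInterval(name, pos, pos + length))
        pos += length
    total = pos
    a = _random_seq(rng_a, total)
    b = a.copy()
    for g in genes:
        d = div_of(g.gene_name)
        if d == 0:
            continue
        hit = np.nonzero(rng_b.random(len(g)) < d)[0] + g.start
        # substitute to a uniformly chosen *different* base
        shift = rng_b.integers(1, 4, size=hit.size)
        cur = np.searchsorted(BASES, b[hit])
        b[hit] = BASES[(cur + shift) % 4]
    pa = AnnotatedOperon(NucSequence(labels[0], _to_str(a)), tuple(genes), labels[0])
    pb = AnnotatedOperon(NucSequence(labels[1], _to_str(b)), tuple(genes), labels[1])
    return pa, pb


@dataclass(frozen=True)
class MosaicPlan:
    """Planned donor segments (donor, length) plus a private-mutation rate."""

    segments: tuple[tuple[str, int], ...]
    novel_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.novel_rate < 0.2):
            raise ValueError("novel_rate must be in [0, 0.2)")
        for donor, length in self.segments:
            if donor not in ("A", "B") or length <= 0:
                raise ValueError(f"bad plan segment ({donor!r}, {length})")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.segments)

    def true_breakpoints(self) -> list[int]:
        """Query positions where the donor switches (first position of the
        new segment); consecutive same-donor segments do not switch."""
        bps = []
        pos = 0
        for (d1, l1), (d2, _l2) in zip(self.segments, self.segments[1:]):
            pos += l1
            if d1 != d2:
                bps.append(pos)
        return bps


@dataclass(frozen=True)
class MosaicTruth:
    """Ground truth for one generated mosaic."""

    donors: str  # 'A'/'B' per position
    novel_sites: tuple[int, ...]
    plan: MosaicPlan

    def to_json(self) -> str:
        return json.dumps(
            {
                "donors": self.donors,
                "novel_sites": list(self.novel_sites),
                "segments": [list(s) for s in self.plan.segments],
                "novel_rate": self.plan.novel_rate,
                "seed": self.plan.seed,
            }
        )


def generate_mosaic(
    parents: tuple[AnnotatedOperon, AnnotatedOperon],
    plan: MosaicPlan,
    label: str = "mosaic",
) -> tuple[AnnotatedOperon, MosaicTruth]:
    """Copy each planned segment from its donor, then sprinkle private
    mutations that match neither parent at rate ``novel_rate``."""
    pa, pb = parents
    if len(pa) != len(pb):
        raise ValueError("v1 requires equal-length parents")
    if plan.total_length != len(pa):
        raise ValueError(
            f"plan length {plan.total_length} != parent length {len(pa)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed))
    a = np.frombuffer(pa.sequence.seq.encode(), dtype="S1")
    b = np.frombuffer(pb.sequence.seq.encode(), dtype="S1")
    mosaic = np.empty(len(pa), dtype="S1")
    donors = []
    pos = 0
    for donor, length in plan.segments:
        src = a if donor == "A" else b
        mosaic[pos : pos + length] = src[pos : pos + length]
        donors.append(donor * length)
        pos += length

    novel_positions = np.nonzero(rng.random(len(pa)) < plan.novel_rate)[0]
    for p in novel_positions:
        forbidden = {a[p], b[p]}
        choices = [base for base in BASES if base not in forbidden]
        mosaic[p] = choices[rng.integers(0, len(choices))]
    truth = MosaicTruth("".join(donors), tuple(int(p) for p in novel_positions), plan)
    op = AnnotatedOperon(NucSequence(label, _to_str(mosaic)), pa.genes, label)
    return op, truth


# ---------------------------------------------------------------------------
# read simulation

@dataclass(frozen=True)
class ReadLengthModel:
    """Pyrosequencing-style read lengths, 30-530 bp by default."""

    min_len: int = 30
    max_len: int = 530
    distribution: str = "uniform"  # or "truncated_lognormal"

    def __post_init__(self) -> None:
        if not (30 <= self.min_len <= self.max_len):
            raise ValueError("need 30 <= min_len <= max_len")
        if self.distribution not in ("uniform", "truncated_lognormal"):
            raise ValueError(f"unknown length distribution {self.distribution!r}")

    def draw(self, rng: np.random.Generator) -> int:
        if self.distribution == "uniform":
            return int(rng.integers(self.min_len, self.max_len + 1))
        # lognormal centred near 250 bp, truncated to [min_len, max_len]
        while True:
            x = int(rng.lognormal(mean=np.log(250.0), sigma=0.45))
            if self.min_len <= x <= self.max_len:
                return x


@dataclass(frozen=True)
class ReadOrigin:
    read_id: str
    variant: str
    start: int  # template coordinates of the error-free window, half-open
    end: int
    strand: str


def _apply_errors(
    window: np.ndarray, rng: np.random.Generator, sub_rate: float, indel_rate: float
) -> np.ndarray:
    out = window
    if sub_rate > 0:
        out = out.copy()
        hit = np.nonzero(rng.random(out.size) < sub_rate)[0]
        if hit.size:
            shift = rng.integers(1, 4, size=hit.size)
            cur = np.searchsorted(BASES, out[hit])
            out[hit] = BASES[(cur + shift) % 4]
    if indel_rate > 0:
        pieces = []
        half = indel_rate / 2.0
        events = rng.random(out.size)
        last = 0
        for i in range(out.size):
            if events[i] < half:  # delete this base
                pieces.append(out[last:i])
                last = i + 1
            elif events[i] < indel_rate:  # insert a random base before it
                pieces.append(out[last:i])
                pieces.append(BASES[[int(rng.integers(0, 4))]])
                last = i
        pieces.append(out[last:])
        out = np.concatenate(pieces) if len(pieces) > 1 else out
    return out


def simulate_reads(
    variants: Sequence[AnnotatedOperon | NucSequence],
    weights: Sequence[float],
    n_reads: int,
    length_model: ReadLengthModel = ReadLengthModel(),
    sub_rate: float = 0.005,
    indel_rate: float = 0.001,
    seed: int = 0,
    min_informative: int = 0,
    read_prefix: str = "read",
) -> tuple[list[NucSequence], list[ReadOrigin]]:
    """Draw reads from a mixture of operon variants with 454-like errors.

    ``min_informative > 0`` restricts sampling to variant-specific
    regions: a window is resampled until it differs from every *other*
    variant in at least that many positions (equal-length variants only).
    Truth records the error-free template window and strand per read.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if len(variants) != len(weights) or not variants:
        raise ValueError("need one weight per variant")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    if not (0 <= sub_rate < 0.1 and 0 <= indel_rate < 0.1):
        raise ValueError("error rates must be < 0.1")

    seqs = [
        np.frombuffer(
            (v.sequence.seq if isinstance(v, AnnotatedOperon) else v.seq).encode(), dtype="S1"
        )
        for v in variants
    ]
    labels = [v.label if isinstance(v, AnnotatedOperon) else v.id for v in variants]
    if min_informative > 0 and len({s.size for s in seqs}) != 1:
        raise ValueError("min_informative requires equal-length variants")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    choices = rng.choice(len(variants), size=n_reads, p=w)
    reads: list[NucSequence] = []
    origins: list[ReadOrigin] = []
    for i in range(n_reads):
        vi = int(choices[i])
        template = seqs[vi]
        for _attempt in range(1000):
            length = min(length_model.draw(rng), template.size)
            start = int(rng.integers(0, template.size - length + 1))
            if min_informative == 0:
                break
            window_ok = True
            for vj, other in enumerate(seqs):
                if vj == vi:
                    continue
                diffs = int(np.sum(template[start : start + length] != other[start : start + length]))
                if diffs < min_informative:
                    window_ok = False
                    break
            if window_ok:
                break
        else:
            raise RuntimeError("could not sample a variant-specific window")
        window = template[start : start + length]
        window = _apply_errors(window, rng, sub_rate, indel_rate)
        # indels may push the read outside the length band; keep the
        # emitted lengths within [min_len, max_len] as the model promises
        while window.size < min(length_model.min_len, template.size):
            window = _apply_errors(template[start : start + length], rng, sub_rate, indel_rate)
        if window.size > length_model.max_len:
            window = window[: length_model.max_len]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = _to_str(window)
        if strand == "-":
            seq = revcomp(seq)
        rid = f"{read_prefix}{i:06d}"
        reads.append(NucSequence(rid, seq))
        origins.append(ReadOrigin(rid, labels[vi], start, start + length, strand))
    return reads, origins


def take_read(
    variant: AnnotatedOperon, start: int, length: int, strand: str = "+", read_id: str = "planted"
) -> tuple[NucSequence, ReadOrigin]:
    """Extract one error-free read at a chosen location (e.g. planted
    across a gene junction)."""
    seq = variant.sequence.seq[start : start + length]
    if strand == "-":
        seq = revcomp(seq)
    return (
        NucSequence(read_id, seq),
        ReadOrigin(read_id, variant.label, start, start + length, strand),
    )


# ---------------------------------------------------------------------------
# SIP pools

@dataclass(frozen=True)
class TaxonSpec:
    name: str
    abundance: float  # community (light-fraction) relative abundance
    labelled: bool  # incorporates the 13C substrate


def default_sip_community() -> tuple[TaxonSpec, ...]:
    """Default SIP scenario: three labelled degrader taxa that are a
    minority of the community but dominate the heavy pool after
    renormalization, over an unlabelled background."""
    return (
        TaxonSpec("Acidovorax", 0.050, True),
        TaxonSpec("Ralstonia", 0.015, True),
        TaxonSpec("Polaromonas", 0.010, True),
        TaxonSpec("Pseudomonas", 0.600, False),
        TaxonSpec("Burkholderia", 0.200, False),
        TaxonSpec("Rhodoferax", 0.125, False),
    )


def heavy_fraction_community() -> tuple[TaxonSpec, ...]:
    """A single-pool community with the dominance pattern reported for
    the heavy fraction: 55% / 1% / 0.1% degraders plus background."""
    return (
        TaxonSpec("Acidovorax", 0.550, True),
        TaxonSpec("Ralstonia", 0.010, True),
        TaxonSpec("Polaromonas", 0.001, True),
        TaxonSpec("Pseudomonas", 0.250, False),
        TaxonSpec("Burkholderia", 0.189, False),
    )


def diverged_variants(
    labels: Sequence[str], length: int = 1500, divergence: float = 0.05, seed: int = 0
) -> list[NucSequence]:
    """Equal-length sequences derived from one random ancestor by
    independent substitutions at ``divergence`` per variant (pairwise
    divergence ~= 2 x divergence)."""
    rngs = _rng_children(seed, len(labels) + 1)
    ancestor = _random_seq(rngs[0], length)
    out = []
    for label, rng in zip(labels, rngs[1:]):
        seq = ancestor.copy()
        hit = np.nonzero(rng.random(length) < divergence)[0]
        if hit.size:
            shift = rng.integers(1, 4, size=hit.size)
            cur = np.searchsorted(BASES, seq[hit])
            seq[hit] = BASES[(cur + shift) % 4]
        out.append(NucSequence(label, _to_str(seq)))
    return out


def make_16s_panel(
    taxa: Sequence[str], seed: int = 0, length: int = 1500, divergence: float = 0.05
) -> list[NucSequence]:
    """Synthetic 16S reference panel: one gene per taxon, each derived
    from a common ancestor by independent substitutions (pairwise
    divergence ~= 2 x ``divergence``), headers ``taxon|synthetic_16s``."""
    return [
        NucSequence(f"{s.id}|synthetic_16s", s.seq)
        for s in diverged_variants(taxa, length, divergence, seed)
    ]


@dataclass(frozen=True)
class SipTruth:
    """Per-pool true taxon per read plus the scenario parameters."""

    heavy_origin: dict[str, str]  # read id -> taxon
    light_origin: dict[str, str]
    taxa: tuple[TaxonSpec, ...]
    leakage: float

    def true_heavy_fractions(self) -> dict[str, float]:
        labelled = [t for t in self.taxa if t.labelled]
        s = sum(t.abundance for t in labelled)
        bg = [t for t in self.taxa if not t.labelled]
        sbg = sum(t.abundance for t in bg)
        out = {t.name: (1 - self.leakage) * t.abundance / s for t in labelled}
        out.update({t.name: self.leakage * t.abundance / sbg for t in bg})
        return out


def simulate_sip_pools(
    taxa: Sequence[TaxonSpec],
    references: Sequence[NucSequence],
    n_reads: int,
    leakage: float = 0.05,
    length_model: ReadLengthModel = ReadLengthModel(),
    sub_rate: float = 0.01,
    indel_rate: float = 0.001,
    seed: int = 0,
) -> tuple[list[NucSequence], list[NucSequence], SipTruth]:
    """Heavy (13C) and light (12C) 16S read pools.

    The light pool samples the whole community at the stated abundances.
    Each heavy-pool read comes from the unlabelled background with
    probability ``leakage`` (carry-over of unlabelled DNA into heavy
    gradient fractions), otherwise from the labelled taxa renormalized.
    """
    abundances = np.array([t.abundance for t in taxa], dtype=float)
    if abs(abundances.sum() - 1.0) > 1e-9:
        raise ValueError("taxon abundances must sum to 1")
    if not (0.0 <= leakage < 0.5):
        raise ValueError("leakage must be in [0, 0.5)")
    labelled = np.array([t.labelled for t in taxa], dtype=bool)
    if not labelled.any():
        raise ValueError("heavy pool requested but no taxon is labelled")
    ref_by_taxon = {r.id.split("|", 1)[0]: r for r in references}
    missing = [t.name for t in taxa if t.name not in ref_by_taxon]
    if missing:
        raise ValueError(f"no 16S reference for taxa {missing}")

    heavy_w = np.where(labelled, abundances, 0.0)
    heavy_w = (1 - leakage) * heavy_w / heavy_w.sum()
    bg_w = np.where(~labelled, abundances, 0.0)
    if bg_w.sum() > 0:
        heavy_w = heavy_w + leakage * bg_w / bg_w.sum()
    heavy_w = heavy_w / heavy_w.sum()

    seed_light, seed_heavy = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(2)]
    refs = [ref_by_taxon[t.name] for t in taxa]
    light_reads, light_orig = simulate_reads(
        refs, abundances, n_reads, length_model, sub_rate, indel_rate, seed_light,
        read_prefix="light_",
    )
    heavy_reads, heavy_orig = simulate_reads(
        refs, heavy_w, n_reads, length_model, sub_rate, indel_rate, seed_heavy,
        read_prefix="heavy_",
    )
    truth = SipTruth(
        heavy_origin={o.read_id: o.variant.split("|", 1)[0] for o in heavy_orig},
        light_origin={o.read_id: o.variant.split("|", 1)[0] for o in light_orig},
        taxa=tuple(taxa),
        leakage=leakage,
    )
    return heavy_reads, light_reads, truth


# ---------------------------------------------------------------------------
# synthetic worked-example templates

def synthetic_nagfcqed_record(seed: int = 0, product_len: int = 4973) -> NucSequence:
    """SYNTHETIC stand-in for the deposited *nag* gene-cluster record.

    The real record is a GenBank accession that cannot be redistributed
    here; this stand-in embeds the published cloning primers (NagF1_For /
    NagD_Rev) in random sequence so that the primer pair produces a
    single product of ``product_len`` bp (the published *nagFCQED*
    cluster length).  It exercises the full in-silico PCR machinery but
    is NOT the deposited sequence.
    """
    fwd = primers.NAGF1_FOR
    rev_site = revcomp(primers.NAGD_REV)
    filler_len = product_len - len(fwd) - len(rev_site)
    if filler_len < 0:
        raise ValueError("product_len shorter than the primer footprints")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for _ in range(100):
        left = _to_str(_random_seq(rng, 400))
        filler = _to_str(_random_seq(rng, filler_len))
        right = _to_str(_random_seq(rng, 400))
        template = left + fwd + filler + rev_site + right
        # reject the (astronomically unlikely) spurious extra primer site
        if (
            template.count(fwd) == 1
            and template.count(rev_site) == 1
            and template.count(revcomp(fwd)) == 0
            and template.count(primers.NAGD_REV) == 0
        ):
            return NucSequence("synthetic_nag_cluster", template)
    raise RuntimeError("could not build a clean synthetic template")


def synthetic_ndo_genome(seed: int = 0, genome_len: int = 8000, product_len: int = 900) -> tuple[NucSequence, tuple[int, int]]:
    """SYNTHETIC *nag*-bearing genome fragment with one Comamonas-type
    NDO amplicon (COM1 primer pair) planted; returns (record, (start,
    end) of the amplicon).  Carries no Pseudomonas-type (PSE1) sites."""
    pair = primers.COM1
    fwd = pair.fwd
    rev_site = revcomp(pair.rev)
    inner = product_len - len(fwd) - len(rev_site)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    flank = (genome_len - product_len) // 2
    for _ in range(100):
        left = _to_str(_random_seq(rng, flank))
        mid = _to_str(_random_seq(rng, inner))
        right = _to_str(_random_seq(rng, genome_len - flank - product_len))
        genome = left + fwd + mid + rev_site + right
        probes = [fwd, rev_site, revcomp(fwd), pair.rev]
        clean = all(genome.count(p) == 1 for p in probes[:2]) and all(
            genome.count(p) == 0 for p in probes[2:]
        )
        pse = [primers.PSE1.fwd, primers.PSE1.rev, revcomp(primers.PSE1.fwd), revcomp(primers.PSE1.rev)]
        clean = clean and all(genome.count(p) == 0 for p in pse)
        if clean:
            return NucSequence("synthetic_ndo_genome", genome), (flank, flank + product_len)
    raise RuntimeError("could not build a clean synthetic genome")


# ---------------------------------------------------------------------------
# truth serialization

def origins_to_tsv(origins: Sequence[ReadOrigin]) -> str:
    rows = ["read_id\tvariant\tstart_1based\tend_1based\tstrand"]
    for o in origins:
        rows.append(f"{o.read_id}\t{o.variant}\t{o.start + 1}\t{o.end}\t{o.strand}")
    return "\n".join(rows) + "\n"
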
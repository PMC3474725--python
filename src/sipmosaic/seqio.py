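"""Sequence and annotation I/O plus the core domain types.

All other modules build on the types defined here: plain nucleotide
sequences, gene intervals on an operon, annotated operons (an operon
sequence plus its ordered gene layout) and IUPAC primer pairs.

Coordinate convention: everything in memory is 0-based half-open;
everything written for humans (TSV/BED reports) is 1-based inclusive,
following the GenBank style used for gene coordinates in this field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

READ_ALPHABET = frozenset("ACGTN")
REFERENCE_ALPHABET = frozenset("ACGT")

IUPAC_CODES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


class FormatError(ValueError):
    """Malformed input file or record."""


class ValidationError(ValueError):
    """Inconsistent annotations or coordinates."""


def normalize_seq(raw: str) -> str:
    """Upper-case and map U->T (RNA input is tolerated, stored as DNA)."""
    return raw.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - READ_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains illegal characters {sorted(bad)} "
                "after normalization"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, revcomp(self.seq))


@dataclass(frozen=True)
class GeneInterval:
    """A gene on an operon, 0-based half-open, stranded."""

    gene_name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_name!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotatedOperon:
    """An operon sequence plus its ordered, non-overlapping gene intervals."""

    sequence: NucSequence
    genes: tuple[GeneInterval, ...]
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        seen: set[str] = set()
        prev_end = 0
        for g in sorted(self.genes, key=lambda g: g.start):
            if g.gene_name in seen:
                raise ValidationError(f"{self.label}: duplicate gene name {g.gene_name!r}")
            seen.add(g.gene_name)
            if g.start < prev_end:
                raise ValidationError(f"{self.label}: gene {g.gene_name!r} overlaps its neighbour")
            if g.end > len(self.sequence):
                raise ValidationError(
                    f"{self.label}: gene {g.gene_name!r} extends past the operon end"
                )
            prev_end = g.end
        object.__setattr__(
            self, "genes", tuple(sorted(self.genes, key=lambda g: g.start))
        )
        if "N" in self.sequence.seq:
            raise ValidationError(
                f"{self.label}: reference operons may not contain 'N' "
                "(ambiguity would poison site attribution)"
            )

    def gene(self, name: str) -> GeneInterval:
        for g in self.genes:
            if g.gene_name == name:
                return g
        raise KeyError(f"{self.label}: no gene named {name!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """A named forward/reverse primer pair over IUPAC codes (5'->3')."""

    name: str
    fwd: str
    rev: str

    def __post_init__(self) -> None:
        for which, p in (("fwd", self.fwd), ("rev", self.rev)):
            if len(p) < 10:
                raise ValidationError(f"primer {self.name}/{which}: shorter than 10 nt")
            bad = set(p) - set(IUPAC_CODES)
            if bad:
                raise ValidationError(
                    f"primer {self.name}/{which}: invalid IUPAC codes {sorted(bad)}"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> list[NucSequence]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        try:
            records.append(NucSequence(rec.id, normalize_seq(str(rec.seq))))
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | os.PathLike, seqs: Iterable[NucSequence]) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Annotations

def read_annotations(
    path: str | os.PathLike,
    dialect: str = "tsv",
    seq_lengths: Mapping[str, int] | None = None,
) -> dict[str, list[GeneInterval]]:
    """Read gene intervals per operon label.

    dialect "tsv": 4 columns (seqid, gene_name, start_1based, end_1based),
    optional 5th column strand.  dialect "gff3": features of type "gene";
    the gene name is taken from the Name=, gene= or ID= attribute.
    Coordinates are converted to 0-based half-open internally.
    """
    if dialect == "tsv":
        rows = _read_tsv_rows(path)
    elif dialect == "gff3":
        rows = _read_gff3_rows(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    result: dict[str, list[GeneInterval]] = {}
    for seqid, name, start1, end1, strand in rows:
        iv = GeneInterval(name, start1 - 1, end1, strand)
        result.setdefault(seqid, []).append(iv)

    for seqid, ivs in result.items():
        ivs.sort(key=lambda g: g.start)
        seen: set[str] = set()
        prev = None
        for g in ivs:
            if g.gene_name in seen:
                raise ValidationError(f"{path}: duplicate gene {g.gene_name!r} on {seqid}")
            seen.add(g.gene_name)
            if prev is not None and g.start < prev.end:
                raise ValidationError(
                    f"{path}: genes {prev.gene_name!r} and {g.gene_name!r} overlap on {seqid}"
                )
            if seq_lengths is not None and seqid in seq_lengths and g.end > seq_lengths[seqid]:
                raise ValidationError(
                    f"{path}: gene {g.gene_name!r} out of range on {seqid}"
                )
            prev = g
    return result


def _read_tsv_rows(path) -> list[tuple[str, str, int, int, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 tab-separated columns")
            seqid, name, s, e = parts[:4]
            strand = parts[4] if len(parts) > 4 and parts[4] else "+"
            try:
                rows.append((seqid, name, int(s), int(e), strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
    return rows


def _read_gff3_rows(path) -> list[tuple[str, str, int, int, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 lines need 9 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            name = None
            for kv in attrs.rstrip(";").split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    if k in ("Name", "gene"):
                        name = v
                        break
                    if k == "ID" and name is None:
                        name = v
            if name is None:
                raise FormatError(f"{path}:{lineno}: gene feature without Name/gene/ID")
            rows.append((seqid, name, int(start), int(end), strand if strand in "+-" else "+"))
    return rows


def write_annotations(path: str | os.PathLike, annots: Mapping[str, Sequence[GeneInterval]]) -> None:
    """Write the 4(+strand)-column TSV dialect, 1-based inclusive."""
    with open(path, "w") as fh:
        for seqid in annots:
            for g in annots[seqid]:
                fh.write(f"{seqid}\t{g.gene_name}\t{g.start + 1}\t{g.end}\t{g.strand}\n")


def annotated_operon(
    seq: NucSequence, annots: Mapping[str, Sequence[GeneInterval]], label: str | None = None
) -> AnnotatedOperon:
    """Pair a sequence with its annotation rows (keyed by sequence id)."""
    key = label or seq.id
    return AnnotatedOperon(seq, tuple(annots.get(key, ())), key)


# ---------------------------------------------------------------------------
# Primers

def read_primers(path: str | os.PathLike) -> list[PrimerPair]:
    """3-column TSV: name, fwd, rev."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns (name, fwd, rev)")
            name, fwd, rev = parts[:3]
            pairs.append(PrimerPair(name, normalize_seq(fwd), normalize_seq(rev)))
    if not pairs:
        raise FormatError(f"{path}: no primer pairs found")
    return pairs
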
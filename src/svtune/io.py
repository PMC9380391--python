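"""Readers/writers for the standard formats used across the package.

Coordinate convention: every in-memory and on-disk BED/BEDPE/TSV coordinate is
0-based half-open.  VCF is 1-based; the conversion happens only inside the VCF
emitters/parsers (see :mod:`svtune.breakends` and :mod:`svtune.cnv`).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("svtune")


class ParseError(ValueError):
    """Raised when an input file cannot be decoded."""


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig: an id plus an uppercase nucleotide string."""

    id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


class Genome(dict):
    """Mapping of chromosome id -> GenomeSequence, preserving insertion order."""

    @classmethod
    def from_sequences(cls, seqs: Iterable[GenomeSequence]) -> "Genome":
        g = cls()
        for s in seqs:
            if s.id in g:
                raise ParseError(f"duplicate sequence id {s.id!r}")
            g[s.id] = s
        return g

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.values())

    def lengths(self) -> dict[str, int]:
        return {cid: s.length for cid, s in self.items()}


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class RunConfig:
    """Global run settings; a single integer seed drives all stochastic stages."""

    seed: int = 0
    window_size: int = 300
    outdir: str = "."
    verbose: bool = False
    extra: dict = field(default_factory=dict)

    def substream(self, name: str) -> np.random.Generator:
        return substream(self.seed, name)


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministically derive an independent RNG stream from (seed, name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode())])
    )


# --------------------------------------------------------------------------- #
# FASTA
# --------------------------------------------------------------------------- #

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Load a FASTA file; soft-masked (lowercase) bases are uppercased."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            out.append(GenomeSequence(id=rec.id, sequence=str(rec.seq)))
    except ValueError as exc:  # biopython signals malformed records this way
        raise ParseError(f"malformed FASTA {path}: {exc}") from exc
    return out


def read_genome(path: str | Path) -> Genome:
    return Genome.from_sequences(read_fasta(path))


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, width: int = 80):
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# --------------------------------------------------------------------------- #
# BED / BEDPE
# --------------------------------------------------------------------------- #

def write_bed(intervals: Iterable[GenomicInterval], path: str | Path):
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bedpe(
    pairs: Sequence[tuple[GenomicInterval, GenomicInterval]],
    path: str | Path,
    lengths: dict[str, int] | None = None,
):
    """Write interval pairs as 6-column BEDPE (0-based half-open)."""
    if lengths is not None:
        for a, b in pairs:
            for iv in (a, b):
                if iv.chrom in lengths and iv.end > lengths[iv.chrom]:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} beyond "
                        f"chromosome length {lengths[iv.chrom]}"
                    )
    with open(path, "w") as fh:
        for i, (a, b) in enumerate(pairs):
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\tpair_{i}\t.\t{a.strand or '.'}\t{b.strand or '.'}\n"
            )


def read_bedpe(path: str | Path) -> list[tuple[GenomicInterval, GenomicInterval]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if len(p) < 6:
                raise ParseError(f"{path}:{lineno}: BEDPE line has <6 columns")
            try:
                a = GenomicInterval(p[0], int(p[1]), int(p[2]))
                b = GenomicInterval(p[3], int(p[4]), int(p[5]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append((a, b))
    return out


# --------------------------------------------------------------------------- #
# Coordinate conversion helpers (VCF is 1-based, closed)
# --------------------------------------------------------------------------- #

def to_vcf_pos(pos0: int) -> int:
    """0-based position -> 1-based VCF POS."""
    return pos0 + 1


def from_vcf_pos(pos1: int) -> int:
    """1-based VCF POS -> 0-based position."""
    return pos1 - 1


REVCOMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]
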
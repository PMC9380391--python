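"""Gridss-style breakend calls: VCF BND parsing/writing and a caller emulator.

A *breakend* is one side of a novel adjacency: a position plus the side of that
position on which the junction extends (``orientation``: "right" means the
adjacency departs to the right of the position, "left" the converse).  A
*breakpoint* is the pair of joined breakends.  Orientations determine the
breakpoint class: an intrachromosomal junction whose lower breakend is
right-oriented and whose higher breakend is left-oriented is DEL-like, the
converse is TAN-like, equal orientations are INV-like.

Internal positions are 0-based; the VCF reader/writer performs the 1-based
conversion.  The emulator fabricates annotated breakpoints from a truth set
plus a noise model, standing in for an external caller so the optimizer can be
exercised end to end.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .io import Genome, substream
from .simulate import ReadSimParams, SVRecord, SVTruthSet

logger = logging.getLogger("svtune")

LEFT = "left"
RIGHT = "right"


@dataclass
class BreakendRecord:
    """One breakend with every annotation the filter engine consumes."""

    id: str
    chrom: str
    pos: int  # 0-based
    orientation: str  # "left" | "right": side on which the adjacency extends
    partner_id: str
    qual: float = 1000.0
    filter_tags: frozenset[str] = frozenset()
    fragments: int = 30
    vaf_small: float = 1.0
    vaf_large: float = 1.0
    inexact_homology: int = 0
    microhomology: int = 0
    strand_bias: float = 0.5
    has_read_pairs: bool = True
    has_split_reads: bool = True
    inserted_seq: str = ""
    overlaps_repeat: bool = False

    def __post_init__(self):
        if self.orientation not in (LEFT, RIGHT):
            raise ValueError(f"orientation must be 'left' or 'right', got {self.orientation!r}")
        for name in ("vaf_small", "vaf_large"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.inexact_homology < 0 or self.microhomology < 0:
            raise ValueError("homology lengths must be >= 0")


@dataclass
class Breakpoint:
    """A pair of joined breakends, ordered by (chrom, pos)."""

    be1: BreakendRecord
    be2: BreakendRecord

    def __post_init__(self):
        if (self.be2.chrom, self.be2.pos) < (self.be1.chrom, self.be1.pos):
            self.be1, self.be2 = self.be2, self.be1

    @property
    def id(self) -> str:
        return self.be1.id.rsplit("_", 1)[0]

    @property
    def intrachromosomal(self) -> bool:
        return self.be1.chrom == self.be2.chrom

    @property
    def length(self) -> int | None:
        """Event length |pos2 - pos1|; undefined across chromosomes."""
        if not self.intrachromosomal:
            return None
        return abs(self.be2.pos - self.be1.pos)

    def type_hint(self) -> str:
        if not self.intrachromosomal:
            return "interchromosomal"
        lo, hi = self.be1, self.be2
        if lo.orientation == hi.orientation:
            return "INV-like"
        if lo.orientation == RIGHT and hi.orientation == LEFT:
            return "DEL-like"
        return "TAN-like"

    def breakends(self) -> tuple[BreakendRecord, BreakendRecord]:
        return (self.be1, self.be2)


@dataclass(frozen=True)
class InsertSizeStats:
    median: float
    mad: float

    def __post_init__(self):
        if self.median <= 0 or self.mad < 0:
            raise ValueError("insert size median must be > 0 and MAD >= 0")

    @property
    def large_event_threshold(self) -> float:
        """Event length above which the large-event VAF applies."""
        return self.median + self.mad


def compute_insert_stats(fragment_lengths: Sequence[float]) -> InsertSizeStats:
    """Median and (unscaled) median absolute deviation of fragment lengths."""
    arr = np.asarray(fragment_lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute insert stats from an empty sample")
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    return InsertSizeStats(median=med, mad=mad)


def insert_stats_from_params(params: ReadSimParams) -> InsertSizeStats:
    return InsertSizeStats(median=params.insert_median, mad=params.insert_mad)


# --------------------------------------------------------------------------- #
# VCF 4.2 BND dialect
# --------------------------------------------------------------------------- #

_INFO_FIELDS = [
    ("MATEID", "1", "String", "ID of the mate breakend"),
    ("SVTYPE", "1", "String", "Type of structural variant"),
    ("FRAGS", "1", "Integer", "Fragments supporting the breakend"),
    ("VAFS", "1", "Float", "Variant allele frequency computed for a small event"),
    ("VAFL", "1", "Float", "Variant allele frequency computed for a large event"),
    ("IHOMLEN", "1", "Integer", "Length of inexact homology around the junction"),
    ("MHOMLEN", "1", "Integer", "Length of exact microhomology around the junction"),
    ("SB", "1", "Float", "Strand bias"),
    ("RPS", "1", "Integer", "1 if discordant read pairs support the breakend"),
    ("SRS", "1", "Integer", "1 if split reads support the breakend"),
    ("REPEAT", "0", "Flag", "Breakend overlaps an annotated repeat"),
]

_BND_RE = re.compile(
    r"^(?P<head>[ACGTN]*)"
    r"(?P<b1>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)(?P<b2>[\[\]])"
    r"(?P<tail>[ACGTN]*)$",
    re.IGNORECASE,
)


def _alt_string(be: BreakendRecord, mate: BreakendRecord) -> str:
    # bracket type encodes the mate orientation, bracket side encodes ours
    mate_pos1 = mate.pos + (0 if mate.orientation == RIGHT else 1)
    bracket = "[" if mate.orientation == LEFT else "]"
    locus = f"{bracket}{mate.chrom}:{mate_pos1}{bracket}"
    if be.orientation == RIGHT:
        return f"N{be.inserted_seq}{locus}"
    return f"{locus}{be.inserted_seq}N"


def write_breakend_vcf(
    breakpoints: Iterable[Breakpoint],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
):
    """Write paired BND records carrying the full annotation dialect."""
    breakpoints = list(breakpoints)
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    tags = {"NO_ASSEMBLY"}
    for bp in breakpoints:
        for be in bp.breakends():
            tags |= set(be.filter_tags)
    for tag in sorted(tags):
        header.filters.add(tag, None, None, f"breakend flagged {tag}")
    for name, number, vtype, desc in _INFO_FIELDS:
        header.info.add(name, number, vtype, desc)
    if contig_lengths is None:
        contig_lengths = {}
        for bp in breakpoints:
            for be in bp.breakends():
                contig_lengths[be.chrom] = max(
                    contig_lengths.get(be.chrom, 0), be.pos + 1000
                )
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for bp in breakpoints:
            for be, mate in ((bp.be1, bp.be2), (bp.be2, bp.be1)):
                pos1 = be.pos + (0 if be.orientation == RIGHT else 1)
                rec = vcf.new_record(
                    contig=be.chrom,
                    start=max(pos1 - 1, 0),
                    alleles=("N", _alt_string(be, mate)),
                    id=be.id,
                    qual=be.qual,
                )
                if be.filter_tags:
                    for t in sorted(be.filter_tags):
                        rec.filter.add(t)
                else:
                    rec.filter.add("PASS")
                rec.info["MATEID"] = be.partner_id
                rec.info["SVTYPE"] = "BND"
                rec.info["FRAGS"] = int(be.fragments)
                rec.info["VAFS"] = float(be.vaf_small)
                rec.info["VAFL"] = float(be.vaf_large)
                rec.info["IHOMLEN"] = int(be.inexact_homology)
                rec.info["MHOMLEN"] = int(be.microhomology)
                rec.info["SB"] = float(be.strand_bias)
                rec.info["RPS"] = int(be.has_read_pairs)
                rec.info["SRS"] = int(be.has_split_reads)
                if be.overlaps_repeat:
                    rec.info["REPEAT"] = True
                vcf.write(rec)


@dataclass
class ParseResult:
    breakpoints: list[Breakpoint]
    n_dropped: int = 0
    dropped_ids: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.breakpoints)

    def __len__(self):
        return len(self.breakpoints)


def parse_breakend_vcf(path: str | Path) -> ParseResult:
    """Parse paired BND records into breakpoints.

    Orientation is decoded from the bracket notation; records whose mate is
    missing are dropped and counted in the result.  Missing annotation fields
    fall back to permissive defaults (documented on :class:`BreakendRecord`).
    """
    singles: dict[str, BreakendRecord] = {}
    order: list[str] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else ""
            m = _BND_RE.match(alt)
            if not m:
                raise ValueError(
                    f"record {rec.id!r}: malformed BND ALT {alt!r}"
                )
            if m.group("head"):
                orientation = RIGHT
                ins = m.group("head")[1:]
            else:
                orientation = LEFT
                ins = m.group("tail")[:-1] if m.group("tail") else ""
            pos1 = rec.pos  # pysam .pos is 1-based here
            pos0 = pos1 if orientation == RIGHT else pos1 - 1
            info = rec.info

            def iget(key, default):
                # tolerate annotations absent from the record or the header
                try:
                    v = info.get(key, default)
                except (KeyError, ValueError):
                    return default
                if isinstance(v, tuple):
                    v = v[0]
                return v if v is not None else default

            mateid = iget("MATEID", "")
            tags = frozenset(t for t in rec.filter.keys() if t != "PASS")
            be = BreakendRecord(
                id=rec.id or f"be_{len(order)}",
                chrom=rec.chrom,
                pos=pos0,
                orientation=orientation,
                partner_id=mateid,
                qual=float(rec.qual) if rec.qual is not None else 0.0,
                filter_tags=tags,
                fragments=int(iget("FRAGS", 0)),
                vaf_small=float(iget("VAFS", 1.0)),
                vaf_large=float(iget("VAFL", 1.0)),
                inexact_homology=int(iget("IHOMLEN", 0)),
                microhomology=int(iget("MHOMLEN", 0)),
                strand_bias=float(iget("SB", 0.5)),
                has_read_pairs=bool(int(iget("RPS", 1))),
                has_split_reads=bool(int(iget("SRS", 1))),
                inserted_seq=ins,
                overlaps_repeat=bool(iget("REPEAT", False)),
            )
            singles[be.id] = be
            order.append(be.id)

    breakpoints, seen, dropped = [], set(), []
    for bid in order:
        if bid in seen:
            continue
        be = singles[bid]
        mate = singles.get(be.partner_id)
        if mate is None or mate.partner_id != be.id:
            dropped.append(bid)
            seen.add(bid)
            continue
        breakpoints.append(Breakpoint(be, mate))
        seen.update((bid, mate.id))
    if dropped:
        logger.warning("dropped %d unpaired breakend records", len(dropped))
    return ParseResult(breakpoints, n_dropped=len(dropped), dropped_ids=dropped)


# --------------------------------------------------------------------------- #
# Caller emulator
# --------------------------------------------------------------------------- #

@dataclass
class EmulatorNoiseModel:
    """Noise model for the caller emulator.

    ``perfect`` annotations (the noiseless limit) make every true junction an
    exactly placed, maximally supported breakpoint; otherwise annotations are
    drawn from separate distributions for true and false breakends, creating a
    separable but imperfect filtering problem.
    """

    detection_prob: float = 0.95
    false_rate_per_mb: float = 2.0
    jitter_sd: float = 3.0
    perfect: bool = False

    # true-breakend annotation distributions
    true_qual_logmean: float = 7.0
    true_qual_logsd: float = 0.5
    true_no_assembly_prob: float = 0.1
    true_homology_mean: float = 3.0
    true_strand_bias_conc: float = 20.0
    true_support_prob: float = 0.95
    true_insseq_prob: float = 0.1
    true_insseq_mean: float = 3.0
    vaf_noise_sd: float = 0.05

    # false-breakend annotation distributions
    false_qual_logmean: float = 4.0
    false_qual_logsd: float = 0.7
    false_fragments_mean: float = 2.0
    false_no_assembly_prob: float = 0.6
    false_homology_mean: float = 20.0
    false_strand_bias_conc: float = 0.5
    false_support_prob: float = 0.4
    false_vaf_mean: float = 0.15
    false_insseq_prob: float = 0.3
    false_insseq_mean: float = 8.0
    false_polyg_prob: float = 0.1
    # fraction of false events emitted as coordinated junction pairs that
    # mimic an inversion or a balanced translocation (caller-consistent
    # artifacts, which coverage thresholds cannot remove)
    false_coordinated_prob: float = 0.2

    # planted separating rule (optional): true breakends get >= this many
    # fragments while false ones stay below it, with every other annotation
    # drawn from the *true* distributions (fragment count is then the only
    # separator)
    planted_min_fragments: int | None = None

    def __post_init__(self):
        for name in ("detection_prob", "true_no_assembly_prob", "false_no_assembly_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.false_rate_per_mb < 0 or self.jitter_sd < 0:
            raise ValueError("rates must be >= 0")

    @classmethod
    def noiseless(cls) -> "EmulatorNoiseModel":
        return cls(detection_prob=1.0, false_rate_per_mb=0.0, jitter_sd=0.0, perfect=True)

    @classmethod
    def planted_fragments(cls, min_fragments: int = 10, **kw) -> "EmulatorNoiseModel":
        """A model where supporting-fragment count separates true from false."""
        kw.setdefault("detection_prob", 1.0)
        kw.setdefault("false_rate_per_mb", 40.0)
        kw.setdefault("jitter_sd", 0.0)
        kw.setdefault("false_coordinated_prob", 0.7)
        return cls(planted_min_fragments=min_fragments, **kw)


def _true_annotations(
    noise: EmulatorNoiseModel, rng: np.random.Generator, coverage: float, vaf: float
) -> dict:
    if noise.perfect:
        return dict(
            qual=1000.0, fragments=max(1, int(round(coverage * vaf))),
            vaf_small=vaf, vaf_large=vaf, inexact_homology=0, microhomology=0,
            strand_bias=0.5, has_read_pairs=True, has_split_reads=True,
            filter_tags=frozenset(), inserted_seq="",
        )
    frags = int(rng.poisson(max(coverage * vaf, 1e-9)))
    if noise.planted_min_fragments is not None:
        frags = noise.planted_min_fragments + int(rng.poisson(max(coverage * vaf, 1.0)))
    vs = float(np.clip(vaf + rng.normal(0, noise.vaf_noise_sd), 0, 1))
    vl = float(np.clip(vaf + rng.normal(0, noise.vaf_noise_sd), 0, 1))
    c = noise.true_strand_bias_conc
    ins = ""
    if rng.random() < noise.true_insseq_prob:
        n = 1 + int(rng.poisson(noise.true_insseq_mean))
        ins = "".join(rng.choice(list("ACGT"), size=n))
    tags = frozenset(
        ["NO_ASSEMBLY"] if rng.random() < noise.true_no_assembly_prob else []
    )
    return dict(
        qual=float(rng.lognormal(noise.true_qual_logmean, noise.true_qual_logsd)),
        fragments=frags, vaf_small=vs, vaf_large=vl,
        inexact_homology=int(rng.exponential(noise.true_homology_mean)),
        microhomology=int(rng.exponential(noise.true_homology_mean)),
        strand_bias=float(rng.beta(c, c)),
        has_read_pairs=bool(rng.random() < noise.true_support_prob),
        has_split_reads=bool(rng.random() < noise.true_support_prob),
        filter_tags=tags, inserted_seq=ins,
    )


def _false_annotations(
    noise: EmulatorNoiseModel, rng: np.random.Generator,
    coverage: float = 30.0, vaf: float = 1.0,
) -> dict:
    if noise.planted_min_fragments is not None:
        # only the fragment count separates true from false
        ann = _true_annotations(noise, rng, coverage, vaf)
        ann["fragments"] = int(rng.integers(0, noise.planted_min_fragments))
        return ann
    frags = int(rng.poisson(noise.false_fragments_mean))
    vs = float(np.clip(rng.exponential(noise.false_vaf_mean), 0, 1))
    vl = float(np.clip(rng.exponential(noise.false_vaf_mean), 0, 1))
    c = max(noise.false_strand_bias_conc, 1e-3)
    ins = ""
    if rng.random() < noise.false_insseq_prob:
        n = 1 + int(rng.poisson(noise.false_insseq_mean))
        if rng.random() < noise.false_polyg_prob:
            ins = ("G" if rng.random() < 0.5 else "C") * max(n, 16)
        else:
            ins = "".join(rng.choice(list("ACGT"), size=n))
    tags = frozenset(
        ["NO_ASSEMBLY"] if rng.random() < noise.false_no_assembly_prob else []
    )
    return dict(
        qual=float(rng.lognormal(noise.false_qual_logmean, noise.false_qual_logsd)),
        fragments=frags, vaf_small=vs, vaf_large=vl,
        inexact_homology=int(rng.exponential(noise.false_homology_mean)),
        microhomology=int(rng.exponential(noise.false_homology_mean)),
        strand_bias=float(rng.beta(c, c)),
        has_read_pairs=bool(rng.random() < noise.false_support_prob),
        has_split_reads=bool(rng.random() < noise.false_support_prob),
        filter_tags=tags, inserted_seq=ins,
    )


def truth_junctions(truth: SVTruthSet) -> list[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    """The defining junctions of each truth SV as ((chrom, pos, orient), ...)."""
    out = []
    for rec in truth.records:
        t = rec.svtype
        if t == "deletion":
            out.append(((rec.chrom, rec.start, RIGHT), (rec.chrom, rec.end, LEFT)))
        elif t == "tandem_duplication":
            out.append(((rec.chrom, rec.start, LEFT), (rec.chrom, rec.end, RIGHT)))
        elif t == "inversion":
            out.append(((rec.chrom, rec.start, RIGHT), (rec.chrom, rec.end, RIGHT)))
            out.append(((rec.chrom, rec.start, LEFT), (rec.chrom, rec.end, LEFT)))
        elif t == "translocation":
            if rec.inverted:
                out.append(((rec.chrom, rec.start, RIGHT), (rec.chrom2, rec.pos2, RIGHT)))
                out.append(((rec.chrom, rec.start, LEFT), (rec.chrom2, rec.pos2, LEFT)))
            else:
                out.append(((rec.chrom, rec.start, RIGHT), (rec.chrom2, rec.pos2, LEFT)))
                out.append(((rec.chrom2, rec.pos2, RIGHT), (rec.chrom, rec.start, LEFT)))
        elif t == "insertion":
            out.append(((rec.chrom2, rec.pos2, RIGHT), (rec.chrom, rec.start, LEFT)))
            out.append(((rec.chrom, rec.end, RIGHT), (rec.chrom2, rec.pos2, LEFT)))
            if not rec.is_copy:
                out.append(((rec.chrom, rec.start, RIGHT), (rec.chrom, rec.end, LEFT)))
    return out


def emulate_caller(
    truth: SVTruthSet,
    genome: Genome,
    coverage: float,
    insert_stats: InsertSizeStats,
    noise: EmulatorNoiseModel,
    ploidy: str = "haploid",
    seed: int = 0,
) -> list[Breakpoint]:
    """Generate an annotated breakend catalog from a truth set plus noise.

    Each truth junction is emitted with probability ``detection_prob`` with
    positions jittered by Normal(0, jitter_sd); false junctions are added at
    ``false_rate_per_mb`` per megabase.  Deterministic under ``seed``.
    """
    rng = substream(seed, "emulate_caller")
    vaf = ReadSimParams(ploidy=ploidy).variant_fraction()
    lengths = genome.lengths()
    chroms = list(genome)
    breakpoints: list[Breakpoint] = []
    counter = 0

    def make_bp(j1, j2, ann_factory) -> Breakpoint:
        nonlocal counter
        ids = (f"bnd_{counter}_1", f"bnd_{counter}_2")
        counter += 1
        bes = []
        for (chrom, pos, orient), bid, pid in zip((j1, j2), ids, ids[::-1]):
            if noise.jitter_sd > 0:
                pos = int(round(pos + rng.normal(0, noise.jitter_sd)))
            pos = int(np.clip(pos, 1, lengths[chrom] - 1))
            bes.append(
                BreakendRecord(
                    id=bid, chrom=chrom, pos=pos, orientation=orient,
                    partner_id=pid, **ann_factory(),
                )
            )
        return Breakpoint(*bes)

    for j1, j2 in truth_junctions(truth):
        if rng.random() >= noise.detection_prob:
            continue
        ann = _true_annotations(noise, rng, coverage, vaf)
        breakpoints.append(make_bp(j1, j2, lambda a=ann: dict(a)))

    n_false = int(rng.poisson(noise.false_rate_per_mb * genome.total_length / 1e6))
    for _ in range(n_false):
        c1 = chroms[rng.integers(len(chroms))]
        if rng.random() < noise.false_coordinated_prob:
            # caller-consistent artifact: a fake inversion or translocation
            if rng.random() < 0.5 or len(chroms) == 1:
                length = int(rng.integers(500, max(501, lengths[c1] // 20)))
                a = int(rng.integers(1, max(2, lengths[c1] - length - 1)))
                b = a + length
                for orient in (RIGHT, LEFT):
                    ann = _false_annotations(noise, rng, coverage, vaf)
                    breakpoints.append(
                        make_bp((c1, a, orient), (c1, b, orient), lambda x=ann: dict(x))
                    )
            else:
                others = [c for c in chroms if c != c1]
                c2 = others[rng.integers(len(others))]
                pa = int(rng.integers(1, lengths[c1] - 1))
                pb = int(rng.integers(1, lengths[c2] - 1))
                for j1, j2 in (((c1, pa, RIGHT), (c2, pb, LEFT)),
                               ((c2, pb, RIGHT), (c1, pa, LEFT))):
                    ann = _false_annotations(noise, rng, coverage, vaf)
                    breakpoints.append(make_bp(j1, j2, lambda x=ann: dict(x)))
            continue
        if rng.random() < 0.7 or len(chroms) == 1:
            c2 = c1
        else:
            others = [c for c in chroms if c != c1]
            c2 = others[rng.integers(len(others))]
        p1 = int(rng.integers(1, lengths[c1] - 1))
        p2 = int(rng.integers(1, lengths[c2] - 1))
        o1 = RIGHT if rng.random() < 0.5 else LEFT
        o2 = RIGHT if rng.random() < 0.5 else LEFT
        ann = _false_annotations(noise, rng, coverage, vaf)
        breakpoints.append(make_bp((c1, p1, o1), (c2, p2, o2), lambda a=ann: dict(a)))
    return breakpoints
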
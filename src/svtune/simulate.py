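"""Simulation of structural variants and short paired-end reads.

Template genomes are produced by planting a set of non-conflicting SVs
(deletions, inversions, tandem duplications, whole-arm balanced translocations
and interspersed insertions) into a reference genome; reads are then drawn from
a mix of the reference and the rearranged genome according to a ploidy spec,
which is how heterozygous and polyploid samples are emulated.
"""

from __future__ import annotations

import bisect
import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Genome, GenomeSequence, GenomicInterval, revcomp, substream

logger = logging.getLogger("svtune")

SV_TYPES = ("deletion", "inversion", "tandem_duplication", "translocation", "insertion")

# minimum clearance (bp) kept between any two planted edits so that junction
# flanks stay locally unique
EDIT_GAP = 200


@dataclass(frozen=True)
class SVRecord:
    """A typed structural variant.

    Coordinates are 0-based half-open on the *reference* genome.

    * deletion / inversion / tandem_duplication: ``chrom:[start, end)`` is the
      affected region.
    * insertion: ``chrom:[start, end)`` is the origin region, ``chrom2:pos2``
      the destination; ``is_copy`` separates copy-and-paste from cut-and-paste.
    * translocation: ``chrom:start`` and ``chrom2:pos2`` are the two breakpoint
      positions; ``inverted`` flips one of the swapped arms.
    """

    id: str
    svtype: str
    chrom: str
    start: int
    end: int | None = None
    chrom2: str | None = None
    pos2: int | None = None
    is_copy: bool | None = None
    inverted: bool | None = None

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")

    @property
    def length(self) -> int | None:
        if self.svtype in ("deletion", "inversion", "tandem_duplication", "insertion"):
            return self.end - self.start
        return None

    def breakends(self) -> list[tuple[str, int]]:
        """All reference positions at which this SV creates a junction."""
        if self.svtype in ("deletion", "inversion", "tandem_duplication"):
            return [(self.chrom, self.start), (self.chrom, self.end)]
        if self.svtype == "insertion":
            return [
                (self.chrom, self.start),
                (self.chrom, self.end),
                (self.chrom2, self.pos2),
            ]
        return [(self.chrom, self.start), (self.chrom2, self.pos2)]

    def edited_intervals(self) -> list[GenomicInterval]:
        """Reference intervals this SV occupies (used for conflict checks)."""
        if self.svtype in ("deletion", "inversion", "tandem_duplication"):
            return [GenomicInterval(self.chrom, self.start, self.end)]
        if self.svtype == "insertion":
            return [
                GenomicInterval(self.chrom, self.start, self.end),
                GenomicInterval(self.chrom2, self.pos2, self.pos2 + 1),
            ]
        return [
            GenomicInterval(self.chrom, self.start, self.start + 1),
            GenomicInterval(self.chrom2, self.pos2, self.pos2 + 1),
        ]


@dataclass
class SVTruthSet:
    """A set of planted SVs for one template genome."""

    records: list[SVRecord]
    genome_id: str = "genome"
    label: str = "random"  # random | known | homologous

    def by_type(self) -> dict[str, list[SVRecord]]:
        out: dict[str, list[SVRecord]] = {t: [] for t in SV_TYPES}
        for r in self.records:
            out[r.svtype].append(r)
        return out

    def __len__(self):
        return len(self.records)


@dataclass
class ReadSimParams:
    """Paired-end read simulation settings.

    ``ploidy`` is one of ``haploid``, ``diploid_homo``, ``diploid_hetero`` or
    ``ref:<nref>_var:<nvar>`` and controls the mixing ratio of fragments drawn
    from the reference vs the SV-carrying genome.
    """

    read_length: int = 100
    insert_median: int = 400
    insert_mad: int = 50
    coverage: float = 30.0
    ploidy: str = "haploid"
    error_rate: float = 0.001

    def __post_init__(self):
        if self.read_length >= self.insert_median:
            raise ValueError("read length must be smaller than the insert median")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        self.variant_fraction()  # validates the ploidy string

    def variant_fraction(self) -> float:
        """Fraction of fragments drawn from the SV-carrying genome."""
        p = self.ploidy
        if p in ("haploid", "diploid_homo"):
            return 1.0
        if p == "diploid_hetero":
            return 0.5
        if p.startswith("ref:") and "_var:" in p:
            try:
                nref = int(p.split("ref:")[1].split("_var:")[0])
                nvar = int(p.split("_var:")[1])
            except ValueError as exc:
                raise ValueError(f"malformed ploidy spec {p!r}") from exc
            if nref < 1 or nvar < 1:
                raise ValueError("nref and nvar must be positive integers")
            return nvar / (nref + nvar)
        raise ValueError(f"unknown ploidy spec {p!r}")


# --------------------------------------------------------------------------- #
# SV placement
# --------------------------------------------------------------------------- #

class _Occupancy:
    """Sorted per-chromosome interval sets for overlap-free placement."""

    def __init__(self):
        self._iv: dict[str, list[tuple[int, int]]] = {}

    def conflicts(self, chrom: str, start: int, end: int, gap: int = EDIT_GAP) -> bool:
        ivs = self._iv.get(chrom, [])
        i = bisect.bisect_left(ivs, (start - gap, -1))
        for j in (i - 1, i):
            if 0 <= j < len(ivs):
                s, e = ivs[j]
                if start - gap < e and s < end + gap:
                    return True
        return False

    def add(self, chrom: str, start: int, end: int):
        ivs = self._iv.setdefault(chrom, [])
        bisect.insort(ivs, (start, end))


def _weighted_chrom(rng: np.random.Generator, genome: Genome) -> str:
    ids = list(genome)
    w = np.array([genome[c].length for c in ids], dtype=float)
    return ids[rng.choice(len(ids), p=w / w.sum())]


def simulate_svs(
    genome: Genome,
    counts: dict[str, int] | int | None = None,
    regions: Sequence[tuple[GenomicInterval, GenomicInterval]] | None = None,
    seed: int = 0,
    rel_size_range: tuple[float, float] = (1e-4, 1.5e-3),
    min_size: int = 50,
    max_attempts: int = 1000,
    label: str | None = None,
) -> SVTruthSet:
    """Plant up to ``counts[svtype]`` SVs of each type on the genome.

    SV lengths are drawn proportional to total genome length (uniform in
    ``rel_size_range`` times the genome length, floored at ``min_size``), so
    longer genomes receive proportionally larger variants.  When ``regions``
    pairs are provided every breakend falls inside one of the given intervals.
    Placement failures reduce the emitted count (with a warning), they never
    raise.
    """
    if counts is None:
        counts = 50
    if isinstance(counts, int):
        counts = {t: counts for t in SV_TYPES}
    rng = substream(seed, "simulate_svs")
    occ = _Occupancy()
    records: list[SVRecord] = []
    total = genome.total_length
    lo = max(min_size, int(rel_size_range[0] * total))
    hi = max(lo + 1, int(rel_size_range[1] * total))
    chroms = list(genome)
    used_in_translocation: set[str] = set()

    def draw_len() -> int:
        return int(rng.integers(lo, hi + 1))

    def place_interval(svtype: str, idx: int) -> SVRecord | None:
        for _ in range(max_attempts):
            if regions is not None:
                a_iv, b_iv = regions[rng.integers(len(regions))]
                if a_iv.chrom != b_iv.chrom:
                    continue
                if a_iv.start > b_iv.start:
                    a_iv, b_iv = b_iv, a_iv
                a = int(rng.integers(a_iv.start, a_iv.end))
                b = int(rng.integers(b_iv.start, b_iv.end))
                if b <= a:
                    a, b = b, a
                chrom = a_iv.chrom
                if b - a < min_size:
                    continue
            else:
                chrom = _weighted_chrom(rng, genome)
                clen = genome[chrom].length
                length = min(draw_len(), clen // 3)
                if length < min_size or clen < length + 2 * EDIT_GAP:
                    continue
                a = int(rng.integers(EDIT_GAP, clen - length - EDIT_GAP))
                b = a + length
            if b > genome[chrom].length or occ.conflicts(chrom, a, b):
                continue
            occ.add(chrom, a, b)
            return SVRecord(f"{svtype}_{idx}", svtype, chrom, a, b)
        return None

    def place_insertion(idx: int) -> SVRecord | None:
        for _ in range(max_attempts):
            if regions is not None:
                o_iv, d_iv = regions[rng.integers(len(regions))]
                if o_iv.length < min_size:
                    continue
                a = int(rng.integers(o_iv.start, o_iv.end - min_size + 1))
                b = min(a + max(min_size, min(draw_len(), o_iv.end - a)), o_iv.end)
                d_chrom = d_iv.chrom
                d = int(rng.integers(d_iv.start, d_iv.end))
                o_chrom = o_iv.chrom
            else:
                o_chrom = _weighted_chrom(rng, genome)
                clen = genome[o_chrom].length
                length = min(draw_len(), clen // 3)
                if length < min_size or clen < length + 2 * EDIT_GAP:
                    continue
                a = int(rng.integers(EDIT_GAP, clen - length - EDIT_GAP))
                b = a + length
                others = [c for c in chroms if c != o_chrom]
                d_chrom = others[rng.integers(len(others))] if others else o_chrom
                dlen = genome[d_chrom].length
                if dlen < 2 * EDIT_GAP + 2:
                    continue
                d = int(rng.integers(EDIT_GAP, dlen - EDIT_GAP))
            if b - a < min_size:
                continue
            if occ.conflicts(o_chrom, a, b) or occ.conflicts(d_chrom, d, d + 1):
                continue
            if o_chrom == d_chrom and a - EDIT_GAP <= d <= b + EDIT_GAP:
                continue
            occ.add(o_chrom, a, b)
            occ.add(d_chrom, d, d + 1)
            return SVRecord(
                f"insertion_{idx}", "insertion", o_chrom, a, b,
                chrom2=d_chrom, pos2=d, is_copy=bool(rng.integers(2)),
            )
        return None

    def place_translocation(idx: int) -> SVRecord | None:
        # whole-arm balanced swap; one breakpoint per chromosome, uniform in
        # the central 80% (no centromere annotation is assumed)
        avail = [c for c in chroms if c not in used_in_translocation]
        if len(avail) < 2:
            return None
        for _ in range(max_attempts):
            ca, cb = [avail[i] for i in rng.choice(len(avail), 2, replace=False)]
            if regions is not None:
                a_iv, b_iv = regions[rng.integers(len(regions))]
                if a_iv.chrom == b_iv.chrom:
                    continue
                ca, cb = a_iv.chrom, b_iv.chrom
                if ca in used_in_translocation or cb in used_in_translocation:
                    return None
                pa = int(rng.integers(a_iv.start, a_iv.end))
                pb = int(rng.integers(b_iv.start, b_iv.end))
            else:
                la, lb = genome[ca].length, genome[cb].length
                pa = int(rng.integers(int(0.1 * la), int(0.9 * la)))
                pb = int(rng.integers(int(0.1 * lb), int(0.9 * lb)))
            if occ.conflicts(ca, pa, pa + 1) or occ.conflicts(cb, pb, pb + 1):
                continue
            occ.add(ca, pa, pa + 1)
            occ.add(cb, pb, pb + 1)
            used_in_translocation.update((ca, cb))
            return SVRecord(
                f"translocation_{idx}", "translocation", ca, pa,
                chrom2=cb, pos2=pb, inverted=bool(rng.integers(2)),
            )
        return None

    for svtype in SV_TYPES:
        want = counts.get(svtype, 0)
        got = 0
        for i in range(want):
            if svtype == "insertion":
                rec = place_insertion(i)
            elif svtype == "translocation":
                rec = place_translocation(i)
            else:
                rec = place_interval(svtype, i)
            if rec is None:
                break
            records.append(rec)
            got += 1
        if got < want:
            logger.warning(
                "placed %d/%d %s records (placement exhausted)", got, want, svtype
            )
    return SVTruthSet(
        records=records,
        label=label or ("known" if regions is not None else "random"),
    )


# --------------------------------------------------------------------------- #
# Applying SVs to a genome
# --------------------------------------------------------------------------- #

class _OffsetMap:
    """Maps reference coordinates (outside edits) to rearranged coordinates."""

    def __init__(self):
        self._orig = [0]
        self._new = [0]

    def add_break(self, orig: int, new: int):
        self._orig.append(orig)
        self._new.append(new)

    def map(self, pos: int) -> int:
        i = bisect.bisect_right(self._orig, pos) - 1
        return self._new[i] + (pos - self._orig[i])


def _check_conflicts(truth: SVTruthSet):
    per_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for rec in truth.records:
        for iv in rec.edited_intervals():
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, rec.id))
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        for (s1, e1, id1), (s2, e2, id2) in zip(ivs, ivs[1:]):
            if s2 < e1 and id1 != id2:
                raise ValueError(
                    f"conflicting edits on {chrom}: {id1} and {id2} overlap"
                )


def apply_svs(genome: Genome, truth: SVTruthSet) -> Genome:
    """Derive the rearranged (template) genome carrying every SV in ``truth``."""
    _check_conflicts(truth)
    by_chrom: dict[str, list[SVRecord]] = {c: [] for c in genome}
    insertions = [r for r in truth.records if r.svtype == "insertion"]
    translocations = [r for r in truth.records if r.svtype == "translocation"]
    for rec in truth.records:
        if rec.svtype in ("deletion", "inversion", "tandem_duplication"):
            by_chrom[rec.chrom].append(rec)
        elif rec.svtype == "insertion" and not rec.is_copy:
            by_chrom[rec.chrom].append(rec)  # cut: origin is excised locally

    new_seq: dict[str, str] = {}
    maps: dict[str, _OffsetMap] = {}
    for chrom, gseq in genome.items():
        seq = gseq.sequence
        edits = sorted(by_chrom[chrom], key=lambda r: r.start)
        pieces: list[str] = []
        omap = _OffsetMap()
        cur = new_len = 0
        for rec in edits:
            pieces.append(seq[cur:rec.start])
            new_len += rec.start - cur
            seg = seq[rec.start:rec.end]
            if rec.svtype == "inversion":
                pieces.append(revcomp(seg))
                new_len += len(seg)
            elif rec.svtype == "tandem_duplication":
                pieces.append(seg + seg)
                new_len += 2 * len(seg)
            # deletion and cut-insertion origin: segment dropped
            cur = rec.end
            omap.add_break(rec.end, new_len)
        pieces.append(seq[cur:])
        new_seq[chrom] = "".join(pieces)
        maps[chrom] = omap

    # interspersed insertions (destination coordinates mapped through phase 1)
    per_dest: dict[str, list[tuple[int, str]]] = {}
    for rec in insertions:
        seg = genome[rec.chrom].sequence[rec.start:rec.end]
        per_dest.setdefault(rec.chrom2, []).append((maps[rec.chrom2].map(rec.pos2), seg))
    extra_shift: dict[str, list[tuple[int, int]]] = {}
    for chrom, ins in per_dest.items():
        s = new_seq[chrom]
        for pos, seg in sorted(ins, reverse=True):
            s = s[:pos] + seg + s[pos:]
        new_seq[chrom] = s
        extra_shift[chrom] = sorted((p, len(seg)) for p, seg in ins)

    def final_pos(chrom: str, pos: int) -> int:
        p = maps[chrom].map(pos)
        return p + sum(l for q, l in extra_shift.get(chrom, []) if q <= p)

    for rec in translocations:
        pa = final_pos(rec.chrom, rec.start)
        pb = final_pos(rec.chrom2, rec.pos2)
        a, b = new_seq[rec.chrom], new_seq[rec.chrom2]
        if rec.inverted:
            new_seq[rec.chrom] = a[:pa] + revcomp(b[:pb])
            new_seq[rec.chrom2] = revcomp(a[pa:]) + b[pb:]
        else:
            new_seq[rec.chrom] = a[:pa] + b[pb:]
            new_seq[rec.chrom2] = b[:pb] + a[pa:]

    return Genome.from_sequences(
        GenomeSequence(chrom, new_seq[chrom]) for chrom in genome
    )


# --------------------------------------------------------------------------- #
# Read simulation
# --------------------------------------------------------------------------- #

@dataclass
class SimulatedReads:
    """In-memory paired reads; names encode the source genome (ref or var)."""

    pairs: list[tuple[str, str, str]]  # (name, read1, read2)
    params: ReadSimParams

    def __len__(self):
        return len(self.pairs)

    def variant_origin_fraction(self) -> float:
        n_var = sum(1 for name, _, _ in self.pairs if name.split(".")[1] == "var")
        return n_var / len(self.pairs) if self.pairs else 0.0

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        p1 = Path(f"{prefix}_1.fastq.gz")
        p2 = Path(f"{prefix}_2.fastq.gz")
        for path, idx in ((p1, 1), (p2, 2)):
            with gzip.open(path, "wt") as fh:
                for name, r1, r2 in self.pairs:
                    read = r1 if idx == 1 else r2
                    fh.write(f"@{name}/{idx}\n{read}\n+\n{'I' * len(read)}\n")
        return p1, p2


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    arr[pos] = _BASES[rng.integers(0, 4, size=n_err)]
    return arr.tobytes().decode()


def simulate_reads(
    ref_genome: Genome,
    var_genome: Genome,
    params: ReadSimParams,
    seed: int = 0,
) -> SimulatedReads:
    """Draw paired-end reads from a ploidy-weighted mix of two genomes.

    The expected pair count is ``coverage * genome_length / (2 * read_length)``
    and fragment lengths follow Normal(median, 1.4826 * MAD), truncated below
    at the read length.
    """
    rng = substream(seed, "simulate_reads")
    n_pairs = int(round(params.coverage * ref_genome.total_length / (2 * params.read_length)))
    frac_var = params.variant_fraction()
    sources = {"ref": ref_genome, "var": var_genome}
    usable = {
        label: [c for c in g if g[c].length > params.read_length]
        for label, g in sources.items()
    }
    for label, g in sources.items():
        skipped = set(g) - set(usable[label])
        if skipped:
            logger.warning(
                "%s genome: skipping short chromosomes %s", label, sorted(skipped)
            )
    sigma = 1.4826 * params.insert_mad
    pairs: list[tuple[str, str, str]] = []
    which = rng.random(n_pairs) < frac_var
    for i in range(n_pairs):
        label = "var" if which[i] else "ref"
        g = sources[label]
        chroms = usable[label]
        if not chroms:
            continue
        w = np.array([g[c].length for c in chroms], dtype=float)
        chrom = chroms[rng.choice(len(chroms), p=w / w.sum())]
        clen = g[chrom].length
        isize = int(round(rng.normal(params.insert_median, sigma)))
        isize = max(params.read_length, min(isize, clen))
        start = int(rng.integers(0, clen - isize + 1))
        frag = g[chrom].sequence[start:start + isize]
        r1 = _add_errors(frag[: params.read_length], params.error_rate, rng)
        r2 = _add_errors(revcomp(frag)[: params.read_length], params.error_rate, rng)
        pairs.append((f"sim.{label}.{i}.{chrom}.{start}.{isize}", r1, r2))
    return SimulatedReads(pairs=pairs, params=params)


def downsample_reads(
    reads: SimulatedReads,
    target_coverage: float,
    current_coverage: float | None = None,
    seed: int = 0,
) -> SimulatedReads:
    """Randomly keep ``target/current`` of the read pairs, pairing preserved."""
    current = current_coverage if current_coverage is not None else reads.params.coverage
    if target_coverage > current:
        raise ValueError(
            f"target coverage {target_coverage} exceeds current {current}"
        )
    if target_coverage == current:
        return reads
    frac = target_coverage / current
    rng = substream(seed, "downsample_reads")
    keep = rng.random(len(reads.pairs)) < frac
    new_params = replace(reads.params, coverage=target_coverage)
    return SimulatedReads(
        pairs=[p for p, k in zip(reads.pairs, keep) if k], params=new_params
    )


def downsample_fastq(
    in1: str | Path, in2: str | Path, out1: str | Path, out2: str | Path,
    fraction: float, seed: int = 0,
) -> int:
    """File-based pair downsampling (plain or gzipped FASTQ); returns pairs kept."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = substream(seed, "downsample_fastq")

    def opener(p, mode):
        p = str(p)
        return gzip.open(p, mode + "t") if p.endswith(".gz") else open(p, mode)

    kept = 0
    with opener(in1, "r") as f1, opener(in2, "r") as f2, \
            opener(out1, "w") as o1, opener(out2, "w") as o2:
        while True:
            q1 = [f1.readline() for _ in range(4)]
            q2 = [f2.readline() for _ in range(4)]
            if not q1[0]:
                break
            if rng.random() < fraction:
                o1.writelines(q1)
                o2.writelines(q2)
                kept += 1
    return kept


# --------------------------------------------------------------------------- #
# Truth table I/O (one TSV per SV type)
# --------------------------------------------------------------------------- #

_TRUTH_COLUMNS = [
    "id", "svtype", "chrom", "start", "end", "chrom2", "pos2", "is_copy", "inverted",
]


def truth_to_frame(truth: SVTruthSet | Iterable[SVRecord]) -> pd.DataFrame:
    records = truth.records if isinstance(truth, SVTruthSet) else list(truth)
    rows = [
        {
            "id": r.id, "svtype": r.svtype, "chrom": r.chrom, "start": r.start,
            "end": r.end, "chrom2": r.chrom2, "pos2": r.pos2,
            "is_copy": r.is_copy, "inverted": r.inverted,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_TRUTH_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SVRecord]:
    def _opt(v, cast):
        return None if pd.isna(v) else cast(v)

    return [
        SVRecord(
            id=str(row["id"]), svtype=str(row["svtype"]), chrom=str(row["chrom"]),
            start=int(row["start"]), end=_opt(row.get("end"), int),
            chrom2=_opt(row.get("chrom2"), str), pos2=_opt(row.get("pos2"), int),
            is_copy=_opt(row.get("is_copy"), bool), inverted=_opt(row.get("inverted"), bool),
        )
        for _, row in df.iterrows()
    ]


def write_truth_tables(truth: SVTruthSet, outdir: str | Path) -> dict[str, Path]:
    """One ``<svtype>.tab`` file per SV type, mirroring the caller's taxonomy."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for svtype, recs in truth.by_type().items():
        path = outdir / f"{svtype}s.tab"
        truth_to_frame(recs).to_csv(path, sep="\t", index=False)
        paths[svtype] = path
    return paths


def read_sv_table(path: str | Path) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t")
    return frame_to_records(df)
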
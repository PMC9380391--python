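"""The breakend/breakpoint filter engine and breakpoint-to-SV summarization.

Implements the full set of tunable breakend filters, the orientation-based
breakpoint typer, the coverage-based confirmation of DEL-like/TAN-like
breakpoints, and the grouping of junction pairs into translocations and
interspersed insertions.

Threshold wording is applied literally: "minimum"/"maximum" bounds are
inclusive (a value *below* a minimum or *above* a maximum is rejected,
strictly), coverage comparisons ("below"/"above") are strict, and the DEL
length range is inclusive at both ends.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .breakends import (
    LEFT, RIGHT, BreakendRecord, Breakpoint, InsertSizeStats,
)
from .io import Genome, GenomicInterval, substream
from .simulate import ReadSimParams, SVRecord, SVTruthSet

logger = logging.getLogger("svtune")

INF = math.inf


@dataclass(frozen=True)
class FilterParameters:
    """The tunable filter configuration.

    Defaults are the conservative baseline adapted to haploid genomes or
    homozygous variants; :meth:`unconservative` gives the most permissive value
    of every filter (the baseline used for grid pruning).
    """

    min_Nfragments: int = 5
    min_af: float = 0.25
    min_af_EitherSmallOrLargeEvent: float = 0.25
    min_QUAL: float = 0.0
    max_to_be_considered_small_event: int = 1000
    min_length_inversions: int = 40
    maximum_length_inexactHomology: float = 50
    maximum_microhomology: float = 50
    maximum_strand_bias: float = 0.99
    filter_noReadPairs: bool = False
    filter_noSplitReads: bool = False
    filter_overlappingRepeats: bool = False
    filter_polyGC: bool = True
    wrong_FILTERtags: tuple[str, ...] = ("NO_ASSEMBLY",)
    range_filt_DEL_breakpoints: tuple[int, int] = (0, 1)
    dif_between_insert_and_del: float | None = 5
    max_rel_coverage_to_consider_del: float = 0.1
    min_rel_coverage_to_consider_dup: float = 1.8

    def __post_init__(self):
        numeric = (
            self.min_Nfragments, self.min_af, self.min_af_EitherSmallOrLargeEvent,
            self.min_QUAL, self.max_to_be_considered_small_event,
            self.min_length_inversions, self.maximum_microhomology,
            self.maximum_strand_bias, self.max_rel_coverage_to_consider_del,
            self.min_rel_coverage_to_consider_dup,
        )
        if any(v < 0 for v in numeric):
            raise ValueError("numeric filter parameters must be >= 0")
        if not (0 <= self.min_af <= 1 and 0 <= self.min_af_EitherSmallOrLargeEvent <= 1):
            raise ValueError("VAF thresholds must lie in [0, 1]")
        if self.maximum_strand_bias > 1:
            raise ValueError("maximum_strand_bias must lie in [0, 1]")
        lo, hi = self.range_filt_DEL_breakpoints
        if hi < lo:
            raise ValueError("range_filt_DEL_breakpoints must be a valid interval")
        object.__setattr__(self, "wrong_FILTERtags", tuple(self.wrong_FILTERtags))
        object.__setattr__(
            self, "range_filt_DEL_breakpoints", tuple(self.range_filt_DEL_breakpoints)
        )

    @classmethod
    def unconservative(cls) -> "FilterParameters":
        """Most permissive value of every filter; passes any valid breakend."""
        return cls(
            min_Nfragments=0, min_af=0.0, min_af_EitherSmallOrLargeEvent=0.0,
            min_QUAL=0.0, min_length_inversions=0,
            maximum_length_inexactHomology=INF, maximum_microhomology=INF,
            maximum_strand_bias=1.0,
            filter_noReadPairs=False, filter_noSplitReads=False,
            filter_overlappingRepeats=False, filter_polyGC=False,
            wrong_FILTERtags=(),
            range_filt_DEL_breakpoints=(-1, -1),
            dif_between_insert_and_del=None,
            max_rel_coverage_to_consider_del=1.0,
            min_rel_coverage_to_consider_dup=1.0,
        )

    def n_active_filters(self) -> int:
        """How many discard rules can fire (used as an optimizer tie-break)."""
        n = 0
        n += self.min_Nfragments > 0
        n += self.min_af > 0
        n += self.min_af_EitherSmallOrLargeEvent > 0
        n += self.min_QUAL > 0
        n += self.min_length_inversions > 0
        n += math.isfinite(self.maximum_length_inexactHomology)
        n += math.isfinite(self.maximum_microhomology)
        n += self.maximum_strand_bias < 1
        n += self.filter_noReadPairs
        n += self.filter_noSplitReads
        n += self.filter_overlappingRepeats
        n += self.filter_polyGC
        n += bool(self.wrong_FILTERtags)
        n += self.range_filt_DEL_breakpoints != (-1, -1)
        n += self.dif_between_insert_and_del is not None
        return int(n)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wrong_FILTERtags"] = list(self.wrong_FILTERtags)
        d["range_filt_DEL_breakpoints"] = list(self.range_filt_DEL_breakpoints)
        for k in ("maximum_length_inexactHomology", "maximum_microhomology"):
            if math.isinf(d[k]):
                d[k] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FilterParameters":
        d = dict(d)
        for k in ("maximum_length_inexactHomology", "maximum_microhomology"):
            if d.get(k) == "inf":
                d[k] = INF
        if "wrong_FILTERtags" in d:
            d["wrong_FILTERtags"] = tuple(d["wrong_FILTERtags"])
        if "range_filt_DEL_breakpoints" in d:
            d["range_filt_DEL_breakpoints"] = tuple(d["range_filt_DEL_breakpoints"])
        return cls(**d)

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


_GC_RUN = re.compile(r"G{16,}|C{16,}")


def has_long_gc_run(seq: str, min_len: int = 15) -> bool:
    """True if the sequence contains a G or C homopolymer run longer than 15 bp."""
    if min_len == 15:
        return bool(_GC_RUN.search(seq.upper()))
    return bool(re.search(rf"G{{{min_len + 1},}}|C{{{min_len + 1},}}", seq.upper()))


def type_breakpoint(bp: Breakpoint) -> str:
    """Orientation-based class: DEL-like / TAN-like / INV-like / interchromosomal."""
    return bp.type_hint()


def is_small_event(bp: Breakpoint, params: FilterParameters) -> bool:
    """Small events are intrachromosomal and shorter than the smallness cutoff.

    Interchromosomal breakpoints have no event length and are never small.
    """
    return bp.intrachromosomal and bp.length < params.max_to_be_considered_small_event


def breakend_passes(
    be: BreakendRecord,
    bp: Breakpoint,
    params: FilterParameters,
    insert_stats: InsertSizeStats,
) -> tuple[bool, list[str]]:
    """Evaluate every enabled rule on one breakend; returns (pass, reject reasons).

    Rule applicability: the inexact-homology cap and the read-pair requirement
    apply only to non-small events; the strand-bias cap, the split-read
    requirement and the insert-vs-deletion length margin apply only to small
    events.  The size-appropriate VAF is ``vaf_large`` when the event length
    exceeds insert median + MAD (interchromosomal events count as large),
    ``vaf_small`` otherwise.
    """
    reasons: list[str] = []
    small = is_small_event(bp, params)
    hint = bp.type_hint()
    length = bp.length

    if be.fragments < params.min_Nfragments:
        reasons.append("min_Nfragments")
    if be.qual < params.min_QUAL:
        reasons.append("min_QUAL")
    if set(be.filter_tags) & set(params.wrong_FILTERtags):
        reasons.append("wrong_FILTERtags")
    large = (not bp.intrachromosomal) or (length > insert_stats.large_event_threshold)
    vaf = be.vaf_large if large else be.vaf_small
    if vaf < params.min_af:
        reasons.append("min_af")
    t = params.min_af_EitherSmallOrLargeEvent
    if be.vaf_small < t and be.vaf_large < t:
        reasons.append("min_af_EitherSmallOrLargeEvent")
    if not small and be.inexact_homology > params.maximum_length_inexactHomology:
        reasons.append("maximum_length_inexactHomology")
    if be.microhomology > params.maximum_microhomology:
        reasons.append("maximum_microhomology")
    if small and max(be.strand_bias, 1 - be.strand_bias) > params.maximum_strand_bias:
        reasons.append("maximum_strand_bias")
    if params.filter_noReadPairs and not small and not be.has_read_pairs:
        reasons.append("filter_noReadPairs")
    if params.filter_noSplitReads and small and not be.has_split_reads:
        reasons.append("filter_noSplitReads")
    if params.filter_overlappingRepeats and be.overlaps_repeat:
        reasons.append("filter_overlappingRepeats")
    if params.filter_polyGC and has_long_gc_run(be.inserted_seq):
        reasons.append("filter_polyGC")
    if hint == "INV-like" and length < params.min_length_inversions:
        reasons.append("min_length_inversions")
    if hint == "DEL-like":
        lo, hi = params.range_filt_DEL_breakpoints
        if lo <= length <= hi and be.inexact_homology > 5:
            reasons.append("range_filt_DEL_breakpoints")
        dif = params.dif_between_insert_and_del
        if small and dif is not None and len(be.inserted_seq) > length - dif:
            reasons.append("dif_between_insert_and_del")
    return (not reasons, reasons)


def breakpoint_passes(
    bp: Breakpoint,
    params: FilterParameters,
    insert_stats: InsertSizeStats,
) -> tuple[bool, dict[str, list[str]]]:
    """A breakpoint is kept iff *both* of its breakends pass every filter."""
    ok1, r1 = breakend_passes(bp.be1, bp, params, insert_stats)
    ok2, r2 = breakend_passes(bp.be2, bp, params, insert_stats)
    return ok1 and ok2, {bp.be1.id: r1, bp.be2.id: r2}


def filter_breakpoints(
    breakpoints: Iterable[Breakpoint],
    params: FilterParameters,
    insert_stats: InsertSizeStats,
) -> list[Breakpoint]:
    return [
        bp for bp in breakpoints if breakpoint_passes(bp, params, insert_stats)[0]
    ]


def annotate_repeats(
    breakpoints: Iterable[Breakpoint],
    repeats: Sequence[GenomicInterval],
):
    """Set ``overlaps_repeat`` on every breakend falling inside a repeat."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in repeats:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for ivs in by_chrom.values():
        ivs.sort()
    import bisect

    for bp in breakpoints:
        for be in bp.breakends():
            ivs = by_chrom.get(be.chrom, [])
            i = bisect.bisect_right(ivs, (be.pos, math.inf))
            hit = False
            if i > 0:
                s, e = ivs[i - 1]
                hit = s <= be.pos < e
            be.overlaps_repeat = hit


# --------------------------------------------------------------------------- #
# Coverage
# --------------------------------------------------------------------------- #

class CoverageTable:
    """Per-window relative coverage (fraction of the genome-wide median)."""

    def __init__(self, frame: pd.DataFrame):
        req = {"chrom", "start", "end", "relative_coverage"}
        if not req <= set(frame.columns):
            raise ValueError(f"coverage frame needs columns {sorted(req)}")
        if (frame["relative_coverage"] < 0).any():
            raise ValueError("relative coverage must be >= 0")
        self.frame = frame.reset_index(drop=True)
        self._per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            self._per_chrom[str(chrom)] = (
                sub["start"].to_numpy(), sub["end"].to_numpy(),
                sub["relative_coverage"].to_numpy(float),
            )

    @classmethod
    def from_depths(cls, frame: pd.DataFrame, depth_col: str = "depth") -> "CoverageTable":
        med = float(np.median(frame[depth_col]))
        if med <= 0:
            raise ValueError("genome-wide median depth is zero")
        out = frame.copy()
        out["relative_coverage"] = out[depth_col] / med
        return cls(out)

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean relative coverage over [start, end)."""
        if chrom not in self._per_chrom:
            raise KeyError(f"no coverage for chromosome {chrom!r}")
        starts, ends, vals = self._per_chrom[chrom]
        ov = np.minimum(ends, end) - np.maximum(starts, start)
        mask = ov > 0
        if not mask.any():
            raise KeyError(f"no coverage windows overlap {chrom}:{start}-{end}")
        return float(np.average(vals[mask], weights=ov[mask]))


def expected_coverage_table(
    truth: SVTruthSet,
    genome: Genome,
    window_size: int = 100,
    ploidy: str = "haploid",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CoverageTable:
    """Idealized read-depth table implied by a truth set and a ploidy.

    Deleted regions (and cut-and-paste insertion origins) drop to ``1 - vaf``,
    tandem-duplicated regions (and copy-and-paste origins) rise to ``1 + vaf``;
    everything else sits at 1, plus optional Gaussian noise.
    """
    vaf = ReadSimParams(ploidy=ploidy).variant_fraction()
    rng = substream(seed, "expected_coverage")
    rows = []
    deltas: dict[str, list[tuple[int, int, float]]] = {}
    for rec in truth.records:
        if rec.svtype == "deletion":
            deltas.setdefault(rec.chrom, []).append((rec.start, rec.end, -vaf))
        elif rec.svtype == "tandem_duplication":
            deltas.setdefault(rec.chrom, []).append((rec.start, rec.end, +vaf))
        elif rec.svtype == "insertion":
            sign = +vaf if rec.is_copy else -vaf
            deltas.setdefault(rec.chrom, []).append((rec.start, rec.end, sign))
    for chrom, gseq in genome.items():
        edges = np.arange(0, gseq.length + window_size, window_size)
        for s, e in zip(edges[:-1], edges[1:]):
            e = min(int(e), gseq.length)
            s = int(s)
            if e <= s:
                continue
            val = 1.0
            for ds, de, dv in deltas.get(chrom, []):
                ov = min(de, e) - max(ds, s)
                if ov > 0:
                    val += dv * ov / (e - s)
            if noise_sd > 0:
                val = max(0.0, val + rng.normal(0, noise_sd))
            rows.append({"chrom": chrom, "start": s, "end": e, "relative_coverage": val})
    return CoverageTable(pd.DataFrame(rows))


# --------------------------------------------------------------------------- #
# DEL/TAN classification and SV summarization
# --------------------------------------------------------------------------- #

def classify_del_tan(
    breakpoints: Sequence[Breakpoint],
    coverage: CoverageTable,
    params: FilterParameters,
) -> tuple[list[Breakpoint], list[Breakpoint], list[Breakpoint]]:
    """Confirm DEL-like / TAN-like breakpoints by spanned relative coverage.

    Returns (deletions, tandem duplications, remaining); the three lists
    partition the input.
    """
    dels, tans, rest = [], [], []
    for bp in breakpoints:
        hint = bp.type_hint()
        if hint in ("DEL-like", "TAN-like") and bp.intrachromosomal and bp.length > 0:
            rel = coverage.region_mean(bp.be1.chrom, bp.be1.pos, bp.be2.pos)
            if hint == "DEL-like" and rel < params.max_rel_coverage_to_consider_del:
                dels.append(bp)
                continue
            if hint == "TAN-like" and rel > params.min_rel_coverage_to_consider_dup:
                tans.append(bp)
                continue
        rest.append(bp)
    return dels, tans, rest


@dataclass
class CallResult:
    """Typed SV calls plus the breakpoints that could not be classified."""

    svs: dict[str, list[SVRecord]]
    unclassified: list[Breakpoint] = field(default_factory=list)
    n_input: int = 0
    n_filtered: int = 0

    def all_records(self) -> list[SVRecord]:
        return [r for recs in self.svs.values() for r in recs]


def _r_side(bp: Breakpoint) -> BreakendRecord:
    return bp.be1 if bp.be1.orientation == RIGHT else bp.be2


def _l_side(bp: Breakpoint) -> BreakendRecord:
    return bp.be1 if bp.be1.orientation == LEFT else bp.be2


def _mixed_orientation(bp: Breakpoint) -> bool:
    return bp.be1.orientation != bp.be2.orientation


def call_svs(
    breakpoints: Sequence[Breakpoint],
    params: FilterParameters,
    coverage: CoverageTable,
    insert_stats: InsertSizeStats,
    repeats: Sequence[GenomicInterval] | None = None,
    pair_tolerance: int = 1000,
    dest_tolerance: int = 50,
) -> CallResult:
    """Filter a breakend catalog and summarize it into typed SV calls.

    Pipeline: per-breakend filters -> orientation typing -> grouping of
    coordinated junction pairs into interspersed insertions (shared insertion
    site, copy/cut decided by origin coverage) and balanced translocations ->
    coverage confirmation of the remaining DEL-like/TAN-like junctions ->
    pairing of INV-like junctions into inversions.  Whatever is left lands in
    the unclassified table.
    """
    breakpoints = list(breakpoints)
    if repeats is not None:
        annotate_repeats(breakpoints, repeats)
    passing = filter_breakpoints(breakpoints, params, insert_stats)
    consumed: set[int] = set()
    svs: dict[str, list[SVRecord]] = {
        t: [] for t in ("deletion", "inversion", "tandem_duplication",
                        "translocation", "insertion")
    }
    counter = {t: 0 for t in svs}

    def new_id(t: str) -> str:
        counter[t] += 1
        return f"called_{t}_{counter[t]}"

    mixed = [
        (i, bp) for i, bp in enumerate(passing) if _mixed_orientation(bp)
    ]

    # ---- interspersed insertions: J1 = (dest R, origin-start L), J2 =
    # (origin-end R, dest L); the two dest positions must nearly coincide.
    # J2 candidates are indexed by their L-side chromosome for fast lookup.
    import bisect as _bisect

    l_index: dict[str, list[tuple[int, int]]] = {}
    for k, j2 in mixed:
        l2 = _l_side(j2)
        l_index.setdefault(l2.chrom, []).append((l2.pos, k))
    for lst in l_index.values():
        lst.sort()
    mixed_by_idx = dict(mixed)

    candidates = []
    for i, j1 in mixed:
        r1, l1 = _r_side(j1), _l_side(j1)
        lst = l_index.get(r1.chrom, [])
        lo = _bisect.bisect_left(lst, (r1.pos - dest_tolerance, -1))
        hi = _bisect.bisect_right(lst, (r1.pos + dest_tolerance, len(passing)))
        for pos2, k in lst[lo:hi]:
            if k == i:
                continue
            j2 = mixed_by_idx[k]
            r2, l2 = _r_side(j2), _l_side(j2)
            if r2.chrom != l1.chrom or l2.chrom != r1.chrom:
                continue
            d, a, b, d2 = r1.pos, l1.pos, r2.pos, l2.pos
            if abs(d - d2) > dest_tolerance or b <= a:
                continue
            if r1.chrom == l1.chrom and a <= d <= b:
                continue  # destination inside its own origin is not an insertion
            candidates.append((abs(d - d2), i, k, l1.chrom, a, b, r1.chrom, d))
    for dist, i, k, o_chrom, a, b, d_chrom, d in sorted(candidates):
        if i in consumed or k in consumed:
            continue
        try:
            rel = coverage.region_mean(o_chrom, a, b)
        except KeyError:
            continue
        if rel >= params.min_rel_coverage_to_consider_dup:
            is_copy = True
        elif rel <= params.max_rel_coverage_to_consider_del:
            is_copy = False
        else:
            continue  # undecided: junctions stay for later stages/unclassified
        consumed.update((i, k))
        if not is_copy:
            # consume the nearest matching origin excision junction
            # (the DEL-like breakpoint at [a, b))
            best_m, best_d = None, None
            for m, bp in enumerate(passing):
                if m in consumed or bp.type_hint() != "DEL-like":
                    continue
                if bp.be1.chrom != o_chrom:
                    continue
                d1, d2 = abs(bp.be1.pos - a), abs(bp.be2.pos - b)
                if d1 <= pair_tolerance and d2 <= pair_tolerance:
                    if best_d is None or d1 + d2 < best_d:
                        best_m, best_d = m, d1 + d2
            if best_m is not None:
                consumed.add(best_m)
        svs["insertion"].append(
            SVRecord(new_id("insertion"), "insertion", o_chrom, a, b,
                     chrom2=d_chrom, pos2=d, is_copy=is_copy)
        )

    # ---- balanced translocations: two interchromosomal junctions sharing loci
    inter = [
        (i, bp) for i, bp in enumerate(passing)
        if i not in consumed and not bp.intrachromosomal
    ]
    tr_candidates = []
    for ii in range(len(inter)):
        i, j1 = inter[ii]
        for kk in range(ii + 1, len(inter)):
            k, j2 = inter[kk]
            if (j1.be1.chrom, j1.be2.chrom) != (j2.be1.chrom, j2.be2.chrom):
                continue
            d1 = abs(j1.be1.pos - j2.be1.pos)
            d2 = abs(j1.be2.pos - j2.be2.pos)
            if d1 > pair_tolerance or d2 > pair_tolerance:
                continue
            inv1 = j1.be1.orientation == j1.be2.orientation
            inv2 = j2.be1.orientation == j2.be2.orientation
            if inv1 != inv2:
                continue
            if not inv1:
                # the two junctions must be complementary (R,L) and (L,R)
                if j1.be1.orientation == j2.be1.orientation:
                    continue
            else:
                # inverted: one (R,R) junction and one (L,L) junction
                if j1.be1.orientation == j2.be1.orientation:
                    continue
            tr_candidates.append((d1 + d2, i, k, j1, inv1))
    for dist, i, k, j1, inv in sorted(tr_candidates, key=lambda x: (x[0], x[1], x[2])):
        if i in consumed or k in consumed:
            continue
        consumed.update((i, k))
        svs["translocation"].append(
            SVRecord(new_id("translocation"), "translocation",
                     j1.be1.chrom, j1.be1.pos,
                     chrom2=j1.be2.chrom, pos2=j1.be2.pos, inverted=bool(inv))
        )

    # ---- inversions: an (R,R) junction paired with an (L,L) junction
    invlike = [
        (i, bp) for i, bp in enumerate(passing)
        if i not in consumed and bp.type_hint() == "INV-like"
    ]
    inv_candidates = []
    for ii in range(len(invlike)):
        i, j1 = invlike[ii]
        for kk in range(ii + 1, len(invlike)):
            k, j2 = invlike[kk]
            if j1.be1.chrom != j2.be1.chrom:
                continue
            if j1.be1.orientation == j2.be1.orientation:
                continue
            d1 = abs(j1.be1.pos - j2.be1.pos)
            d2 = abs(j1.be2.pos - j2.be2.pos)
            if d1 > pair_tolerance or d2 > pair_tolerance:
                continue
            inv_candidates.append((d1 + d2, i, k, j1, j2))
    for dist, i, k, j1, j2 in sorted(inv_candidates, key=lambda x: (x[0], x[1], x[2])):
        if i in consumed or k in consumed:
            continue
        consumed.update((i, k))
        rr = j1 if j1.be1.orientation == RIGHT else j2
        svs["inversion"].append(
            SVRecord(new_id("inversion"), "inversion",
                     rr.be1.chrom, rr.be1.pos, rr.be2.pos)
        )

    # ---- coverage confirmation of remaining DEL-like / TAN-like junctions
    remaining = [bp for i, bp in enumerate(passing) if i not in consumed]
    deltan = [bp for bp in remaining if bp.type_hint() in ("DEL-like", "TAN-like")]
    others = [bp for bp in remaining if bp.type_hint() not in ("DEL-like", "TAN-like")]
    dels, tans, rest = classify_del_tan(deltan, coverage, params)
    for bp in dels:
        svs["deletion"].append(
            SVRecord(new_id("deletion"), "deletion", bp.be1.chrom, bp.be1.pos, bp.be2.pos)
        )
    for bp in tans:
        svs["tandem_duplication"].append(
            SVRecord(new_id("tandem_duplication"), "tandem_duplication",
                     bp.be1.chrom, bp.be1.pos, bp.be2.pos)
        )

    return CallResult(
        svs=svs,
        unclassified=rest + others,
        n_input=len(breakpoints),
        n_filtered=len(breakpoints) - len(passing),
    )


def write_sv_tables(result: CallResult, outdir: str | Path) -> dict[str, Path]:
    """One TSV per variant type plus the unclassified table."""
    from .simulate import truth_to_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for svtype, recs in result.svs.items():
        path = outdir / f"{svtype}s.tab"
        truth_to_frame(recs).to_csv(path, sep="\t", index=False)
        paths[svtype] = path
    rows = [
        {
            "id": bp.id, "chrom1": bp.be1.chrom, "pos1": bp.be1.pos,
            "orient1": bp.be1.orientation, "chrom2": bp.be2.chrom,
            "pos2": bp.be2.pos, "orient2": bp.be2.orientation,
            "type_hint": bp.type_hint(),
        }
        for bp in result.unclassified
    ]
    upath = outdir / "unclassified_SVs.tab"
    pd.DataFrame(
        rows, columns=["id", "chrom1", "pos1", "orient1", "chrom2", "pos2",
                       "orient2", "type_hint"],
    ).to_csv(upath, sep="\t", index=False)
    paths["unclassified"] = upath
    return paths
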
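"""Read-depth CNV support: coverage correction, consensus, and unified VCF.

Relative per-window coverage is corrected for GC content, mappability and
distance to the chromosome end (a telomere proxy) by sequential lowess
regression: each step divides the signal by the fitted trend (multiplicative
model), and the result is renormalized to a genome-wide median of 1.

Consensus across CNV caller tracks is conservative: per bin, the copy number
closest to 1 wins.  Coverage-derived CNVs that reciprocally overlap an
SV-derived CNV by at least 80% are dropped as redundant, and all calls are
exported to a single VEP-compatible VCF where each SV is decomposed into
DEL/DUP/TDUP/BND/insertionBND rows sharing a variantID.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import Genome, GenomicInterval, to_vcf_pos
from .simulate import SVRecord

logger = logging.getLogger("svtune")

MIN_WINDOWS_FOR_CORRECTION = 30


# --------------------------------------------------------------------------- #
# Window construction and predictors
# --------------------------------------------------------------------------- #

def make_windows(genome: Genome, window_size: int = 300) -> pd.DataFrame:
    rows = []
    for chrom, gseq in genome.items():
        for s in range(0, gseq.length, window_size):
            e = min(s + window_size, gseq.length)
            rows.append({"chrom": chrom, "start": s, "end": e})
    return pd.DataFrame(rows)


def add_gc_content(windows: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    gc = []
    for _, row in windows.iterrows():
        seq = genome[row.chrom].sequence[row.start:row.end]
        gc.append((seq.count("G") + seq.count("C")) / max(len(seq), 1))
    out = windows.copy()
    out["gc"] = gc
    return out


def add_mappability(
    windows: pd.DataFrame, genome: Genome, k: int = 50
) -> pd.DataFrame:
    """Exact k-mer uniqueness per window as a mappability stand-in.

    The fraction of k-mers starting in the window that occur exactly once in
    the genome (both strands collapsed by canonical form).
    """
    from .io import revcomp

    counts: dict[str, int] = {}
    for gseq in genome.values():
        s = gseq.sequence
        for i in range(0, len(s) - k + 1):
            kmer = s[i:i + k]
            canon = min(kmer, revcomp(kmer))
            counts[canon] = counts.get(canon, 0) + 1
    vals = []
    for _, row in windows.iterrows():
        s = genome[row.chrom].sequence
        lo, hi = row.start, min(row.end, len(s) - k + 1)
        if hi <= lo:
            vals.append(1.0)
            continue
        uniq = 0
        n = 0
        for i in range(lo, hi):
            kmer = s[i:i + k]
            canon = min(kmer, revcomp(kmer))
            uniq += counts.get(canon, 0) == 1
            n += 1
        vals.append(uniq / n if n else 1.0)
    out = windows.copy()
    out["mappability"] = vals
    return out


def add_telomere_distance(windows: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Distance from the window midpoint to the nearer chromosome end."""
    out = windows.copy()
    mid = (out["start"] + out["end"]) / 2
    lengths = out["chrom"].map(genome.lengths())
    out["telomere_dist"] = np.minimum(mid, lengths - mid).astype(float)
    return out


def relative_coverage(windows: pd.DataFrame, depth_col: str = "depth") -> pd.DataFrame:
    out = windows.copy()
    med = float(np.median(out[depth_col]))
    if med <= 0:
        raise ValueError("genome-wide median depth is zero")
    out["relative_coverage"] = out[depth_col] / med
    return out


# --------------------------------------------------------------------------- #
# Lowess correction
# --------------------------------------------------------------------------- #

def _divide_by_trend(y: np.ndarray, x: np.ndarray, frac: float) -> np.ndarray:
    if np.ptp(x) == 0:
        return y  # constant predictor carries no trend
    fitted = lowess(y, x, frac=frac, return_sorted=False)
    fitted = np.clip(fitted, 1e-6, None)
    return y / fitted


def correct_coverage(
    windows: pd.DataFrame,
    span: float = 0.3,
    predictors: Sequence[str] = ("gc", "mappability", "telomere_dist"),
) -> pd.DataFrame:
    """Sequentially remove predictor trends from relative coverage.

    Each step fits a lowess trend of the current signal against one predictor
    and divides by it; the final signal is renormalized to median 1 and stored
    as ``corrected_relative_coverage``.  With fewer than 30 windows the trend
    is unfittable and the correction is skipped with a warning.
    """
    out = windows.copy()
    y = out["relative_coverage"].to_numpy(float)
    if len(out) < MIN_WINDOWS_FOR_CORRECTION:
        logger.warning(
            "only %d windows (<%d): coverage correction skipped",
            len(out), MIN_WINDOWS_FOR_CORRECTION,
        )
        out["corrected_relative_coverage"] = y
        return out
    for pred in predictors:
        if pred not in out.columns:
            continue
        y = _divide_by_trend(y, out[pred].to_numpy(float), span)
    med = float(np.median(y))
    if med > 0:
        y = y / med
    out["corrected_relative_coverage"] = y
    return out


# --------------------------------------------------------------------------- #
# CNV calls and consensus
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class CNVCall:
    interval: GenomicInterval
    copy_number: float
    source: str = "coverage"


def call_cnvs_threshold(
    windows: pd.DataFrame,
    ploidy: int = 1,
    source: str = "threshold",
    value_col: str = "corrected_relative_coverage",
) -> list[CNVCall]:
    """Round corrected coverage to integer copy number and merge equal runs.

    A deliberately simple segmenter so the consensus path is testable without
    external CNV callers; their per-bin tracks are consumed by
    :func:`consensus_cnv` in exactly the same shape.
    """
    calls: list[CNVCall] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cns = np.round(sub[value_col].to_numpy(float) * ploidy) / ploidy
        run_start = None
        run_cn = None
        prev_end = None
        for (_, row), cn in zip(sub.iterrows(), cns):
            if cn != run_cn:
                if run_cn is not None and run_cn != 1.0:
                    calls.append(
                        CNVCall(GenomicInterval(chrom, run_start, prev_end), run_cn, source)
                    )
                run_start, run_cn = row.start, cn
            prev_end = row.end
        if run_cn is not None and run_cn != 1.0:
            calls.append(
                CNVCall(GenomicInterval(chrom, run_start, prev_end), run_cn, source)
            )
    return calls


def consensus_cnv(tracks: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Most conservative per-bin copy number across caller tracks.

    Every track must share the same binning (columns chrom/start/end/cn).  Per
    bin the copy number closest to 1 wins; on ties, 1 wins if any program
    reports it, otherwise the smaller copy number.
    """
    if not tracks:
        raise ValueError("need at least one track")
    base = tracks[0][["chrom", "start", "end"]].reset_index(drop=True)
    mat = []
    for t in tracks:
        tt = t.reset_index(drop=True)
        if not tt[["chrom", "start", "end"]].equals(base):
            raise ValueError("tracks are not on a common binning")
        mat.append(tt["cn"].to_numpy(float))
    mat = np.vstack(mat)  # programs x bins
    dist = np.abs(mat - 1.0)
    out_cn = np.empty(mat.shape[1])
    for j in range(mat.shape[1]):
        d = dist[:, j]
        best = d.min()
        cands = sorted(set(mat[d == best, j]))
        out_cn[j] = 1.0 if 1.0 in cands else cands[0]
    out = base.copy()
    out["cn"] = out_cn
    return out


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    inter = a.intersection_length(b)
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def sv_derived_cnv_intervals(svs: Iterable[SVRecord]) -> list[CNVCall]:
    """CNV regions implied by called SVs: deletions, tandem duplications, and
    copy-insertion origins."""
    out = []
    for r in svs:
        if r.svtype == "deletion":
            out.append(CNVCall(GenomicInterval(r.chrom, r.start, r.end), 0.0, "call_svs"))
        elif r.svtype == "tandem_duplication":
            out.append(CNVCall(GenomicInterval(r.chrom, r.start, r.end), 2.0, "call_svs"))
        elif r.svtype == "insertion" and r.is_copy:
            out.append(CNVCall(GenomicInterval(r.chrom, r.start, r.end), 2.0, "call_svs"))
    return out


def remove_redundant_cnvs(
    coverage_cnvs: Sequence[CNVCall],
    sv_cnvs: Sequence[CNVCall],
    min_reciprocal_overlap: float = 0.80,
) -> list[CNVCall]:
    """Drop coverage CNVs reciprocally overlapping an SV-derived CNV by >=80%."""
    kept = []
    for c in coverage_cnvs:
        if any(
            _reciprocal_overlap(c.interval, s.interval) >= min_reciprocal_overlap
            for s in sv_cnvs
        ):
            continue
        kept.append(c)
    return kept


# --------------------------------------------------------------------------- #
# Unified VCF export
# --------------------------------------------------------------------------- #

def _overlaps_any(chrom: str, start: int, end: int,
                  repeats: Sequence[GenomicInterval] | None) -> bool:
    if not repeats:
        return False
    probe = GenomicInterval(chrom, start, max(end, start + 1))
    return any(probe.overlaps(r) for r in repeats)


def export_unified_vcf(
    svs: Mapping[str, Sequence[SVRecord]] | Sequence[SVRecord],
    cnv_calls: Sequence[CNVCall],
    path: str | Path,
    contig_lengths: dict[str, int],
    repeats: Sequence[GenomicInterval] | None = None,
    insert_sequences: Mapping[str, str] | None = None,
):
    """Write every variant as VEP-interpretable rows in one VCF.

    Decomposition: deletion -> one DEL row; tandem duplication -> one TDUP
    row; coverage CNV -> DUP or DEL row; inversion -> two BND rows (one per
    end); translocation -> one BND row per breakpoint end; insertion -> DUP
    (copy) or DEL (cut) row at the origin plus a BND row at the destination;
    non-template inserted sequences (``insert_sequences``, keyed by SV id) ->
    one insertionBND row.  Rows of one SV share a variantID; each row has a
    unique ID; a repeat-overlap flag is set when repeats are provided.
    """
    if not isinstance(svs, Mapping):
        by_type: dict[str, list[SVRecord]] = {}
        for r in svs:
            by_type.setdefault(r.svtype, []).append(r)
        svs = by_type

    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.info.add("SVTYPE", "1", "String", "DEL, DUP, TDUP, BND or insertionBND")
    header.info.add("variantID", "1", "String", "Identifier shared by rows of one SV")
    header.info.add("END", "1", "Integer", "End of the affected region")
    header.info.add("CN", "1", "Float", "Estimated copy number")
    header.info.add("BREAKEND_CHROM", "1", "String", "Partner chromosome of a BND row")
    header.info.add("BREAKEND_POS", "1", "Integer", "Partner position (1-based)")
    header.info.add("INSSEQ", "1", "String", "Non-template inserted sequence")
    header.info.add("overlaps_repeats", "0", "Flag", "Any row region overlaps a repeat")
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)

    rows = []  # (chrom, pos0, id, info)
    uid = 0

    def add_row(chrom: str, pos0: int, svtype: str, variant_id: str,
                end0: int | None = None, cn: float | None = None,
                partner: tuple[str, int] | None = None, insseq: str | None = None):
        nonlocal uid
        uid += 1
        info = {"SVTYPE": svtype, "variantID": variant_id}
        rep_end = end0 if end0 is not None else pos0 + 1
        if end0 is not None:
            info["END"] = end0  # half-open end == 1-based inclusive end
        if cn is not None:
            info["CN"] = cn
        if partner is not None:
            info["BREAKEND_CHROM"] = partner[0]
            info["BREAKEND_POS"] = to_vcf_pos(partner[1])
        if insseq:
            info["INSSEQ"] = insseq
        if _overlaps_any(chrom, pos0, rep_end, repeats):
            info["overlaps_repeats"] = True
        rows.append((chrom, pos0, f"var{uid}", info))

    for svtype, recs in svs.items():
        for rec in recs:
            vid = rec.id
            if svtype == "deletion":
                add_row(rec.chrom, rec.start, "DEL", vid, end0=rec.end, cn=0.0)
            elif svtype == "tandem_duplication":
                add_row(rec.chrom, rec.start, "TDUP", vid, end0=rec.end, cn=2.0)
            elif svtype == "inversion":
                add_row(rec.chrom, rec.start, "BND", vid, partner=(rec.chrom, rec.end))
                add_row(rec.chrom, rec.end, "BND", vid, partner=(rec.chrom, rec.start))
            elif svtype == "translocation":
                add_row(rec.chrom, rec.start, "BND", vid, partner=(rec.chrom2, rec.pos2))
                add_row(rec.chrom2, rec.pos2, "BND", vid, partner=(rec.chrom, rec.start))
            elif svtype == "insertion":
                if rec.is_copy:
                    add_row(rec.chrom, rec.start, "DUP", vid, end0=rec.end, cn=2.0)
                else:
                    add_row(rec.chrom, rec.start, "DEL", vid, end0=rec.end, cn=0.0)
                add_row(rec.chrom2, rec.pos2, "BND", vid, partner=(rec.chrom, rec.start))
            if insert_sequences and rec.id in insert_sequences:
                add_row(
                    rec.chrom, rec.start, "insertionBND", vid,
                    insseq=insert_sequences[rec.id],
                )
    for i, c in enumerate(cnv_calls):
        svtype = "DUP" if c.copy_number > 1 else "DEL"
        add_row(
            c.interval.chrom, c.interval.start, svtype, f"cnv_{i}",
            end0=c.interval.end, cn=c.copy_number,
        )

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom, pos0, rid, info in rows:
            rec = vcf.new_record(
                contig=chrom, start=pos0, alleles=("N", "<SV>"), id=rid
            )
            end0 = info.pop("END", None)
            if end0 is not None:
                rec.stop = end0  # pysam exposes the reserved END via .stop
            for k, v in info.items():
                rec.info[k] = v
            vcf.write(rec)


def parse_unified_vcf(path: str | Path) -> pd.DataFrame:
    """Read the unified VCF back into a row-per-event table."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos - 1,  # back to 0-based
                    "id": rec.id,
                    "svtype": info.get("SVTYPE"),
                    "variantID": info.get("variantID"),
                    "end": rec.stop,
                    "cn": info.get("CN"),
                    "overlaps_repeats": bool(info.get("overlaps_repeats", False)),
                }
            )
    return pd.DataFrame(rows)
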
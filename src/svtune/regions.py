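"""Inference of BEDPE region pairs for realistic SV simulations.

Two sources of regions are supported: pairs of homologous loci found by a
windowed self-comparison of the genome (seed-and-extend local alignment with
Karlin-Altschul e-values), and the neighbourhoods of previously known SV
breakends.  Either can constrain where the simulator places variants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import Genome, GenomicInterval, revcomp
from .simulate import SVRecord

logger = logging.getLogger("svtune")


@dataclass(frozen=True)
class HomologousRegionPair:
    query: GenomicInterval
    subject: GenomicInterval
    evalue: float
    identity: float


# Karlin-Altschul parameters for match +1 / mismatch -2 (declared
# approximations of the ungapped blastn defaults)
_KA_K = 0.41
_KA_LAMBDA = 1.28
_MATCH = 1
_MISMATCH = -2
_XDROP = 20


def _extend(qseq: str, sseq: str, qi: int, si: int, k: int) -> tuple[int, int, int, int, int]:
    """X-drop ungapped extension of an exact k-mer seed.

    Returns (q_start, q_end, score, aligned_len, n_matches).
    """
    score = k * _MATCH
    matches = k
    best = score
    # extend right
    bq, bs = qi + k, si + k
    cq, cs, cm = bq, bs, matches
    q_end, n_m = bq, matches
    while cq < len(qseq) and cs < len(sseq):
        score += _MATCH if qseq[cq] == sseq[cs] else _MISMATCH
        cm += qseq[cq] == sseq[cs]
        cq += 1
        cs += 1
        if score > best:
            best = score
            q_end, n_m = cq, cm
        elif best - score > _XDROP:
            break
    score = best
    matches = n_m
    # extend left
    cq, cs, cm = qi, si, matches
    q_start = qi
    best = score
    while cq > 0 and cs > 0:
        cq -= 1
        cs -= 1
        score += _MATCH if qseq[cq] == sseq[cs] else _MISMATCH
        cm += qseq[cq] == sseq[cs]
        if score > best:
            best = score
            q_start, matches = cq, cm
    aligned = q_end - q_start
    return q_start, q_end, best, aligned, matches


def _evalue(score: int, m: int, n: int) -> float:
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def find_homologous_regions(
    genome: Genome,
    window: int = 500,
    evalue_threshold: float = 1e-5,
    min_query_coverage: float = 0.5,
    seed_length: int = 11,
    max_pairs_per_window: int = 10,
) -> list[HomologousRegionPair]:
    """Pairs of homologous loci by windowed local self-alignment.

    The genome is tiled into non-overlapping windows of ``window`` bp; each
    window is aligned against the whole genome (both strands) by exact k-mer
    seeding and ungapped X-drop extension.  Hits with e-value strictly below
    ``evalue_threshold`` that cover strictly more than ``min_query_coverage``
    of the window are kept; the trivial self-hit (a window aligning to its own
    locus) is excluded.
    """
    # k-mer index of the forward genome
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, gseq in genome.items():
        s = gseq.sequence
        for i in range(0, len(s) - seed_length + 1):
            index.setdefault(s[i:i + seed_length], []).append((chrom, i))

    total = genome.total_length
    pairs: list[HomologousRegionPair] = []
    for chrom, gseq in genome.items():
        clen = gseq.length
        if clen < window:
            logger.warning("chromosome %s shorter than window; skipped", chrom)
            continue
        for wstart in range(0, clen - window + 1, window):
            wseq = gseq.sequence[wstart:wstart + window]
            win_iv = GenomicInterval(chrom, wstart, wstart + window)
            found: list[HomologousRegionPair] = []
            for strand, qseq in (("+", wseq), ("-", revcomp(wseq))):
                seen_spans: set[tuple[str, int, int]] = set()
                for qi in range(0, window - seed_length + 1, 4):
                    kmer = qseq[qi:qi + seed_length]
                    for schrom, si in index.get(kmer, ()):  # noqa: B905
                        q0, q1, score, aligned, matches = _extend(
                            qseq, genome[schrom].sequence, qi, si, seed_length
                        )
                        if aligned <= 0:
                            continue
                        s0 = si - (qi - q0)
                        s1 = s0 + aligned
                        if strand == "+":
                            subj = GenomicInterval(schrom, s0, s1)
                            q_iv = GenomicInterval(chrom, wstart + q0, wstart + q1)
                        else:
                            subj = GenomicInterval(schrom, s0, s1, strand="-")
                            q_iv = GenomicInterval(
                                chrom, wstart + window - q1, wstart + window - q0
                            )
                        if subj.chrom == chrom and subj.overlaps(q_iv):
                            continue  # self-hit
                        key = (f"{schrom}{strand}", s0 // 50, s1 // 50)
                        if key in seen_spans:
                            continue
                        ev = _evalue(score, window, total)
                        if ev >= evalue_threshold:
                            continue
                        if aligned <= min_query_coverage * window:
                            continue
                        seen_spans.add(key)
                        found.append(
                            HomologousRegionPair(
                                query=win_iv, subject=subj,
                                evalue=ev, identity=matches / aligned,
                            )
                        )
            # deduplicate near-identical subject loci, keep best e-values
            found.sort(key=lambda p: p.evalue)
            kept: list[HomologousRegionPair] = []
            for p in found:
                if any(
                    p.subject.chrom == q.subject.chrom
                    and p.subject.intersection_length(q.subject)
                    > 0.5 * p.subject.length
                    for q in kept
                ):
                    continue
                kept.append(p)
                if len(kept) >= max_pairs_per_window:
                    break
            pairs.extend(kept)
    return pairs


def pairs_from_blast_table(path: str | Path, window: int = 500,
                           evalue_threshold: float = 1e-5,
                           min_query_coverage: float = 0.5) -> list[HomologousRegionPair]:
    """Adapter: read precomputed tabular (outfmt-6 style) self-alignment hits.

    Expected columns: qseqid qstart qend sseqid sstart send pident evalue,
    with query ids of the form ``chrom:start-end`` (0-based half-open window).
    """
    cols = ["qseqid", "qstart", "qend", "sseqid", "sstart", "send", "pident", "evalue"]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    pairs = []
    for _, row in df.iterrows():
        chrom, span = str(row.qseqid).rsplit(":", 1)
        ws, we = (int(x) for x in span.split("-"))
        if row.evalue >= evalue_threshold:
            continue
        qlen = abs(int(row.qend) - int(row.qstart)) + 1
        if qlen <= min_query_coverage * (we - ws):
            continue
        s0, s1 = sorted((int(row.sstart) - 1, int(row.send)))
        subj = GenomicInterval(str(row.sseqid), s0, s1)
        query = GenomicInterval(chrom, ws, we)
        if subj.chrom == query.chrom and subj.overlaps(query):
            continue
        pairs.append(
            HomologousRegionPair(
                query=query, subject=subj,
                evalue=float(row.evalue), identity=float(row.pident) / 100.0,
            )
        )
    return pairs


def homologous_pairs_to_intervals(
    pairs: Iterable[HomologousRegionPair],
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    return [(p.query, p.subject) for p in pairs]


def find_known_sv_regions(
    svs: Sequence[SVRecord],
    chrom_lengths: dict[str, int],
    pad: int = 100,
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """+-``pad`` bp regions around the breakends of known SVs, paired per SV.

    Intervals are clipped to chromosome bounds.  SVs with more than two
    breakends (insertions) contribute one pair per junction.
    """

    def clipped(chrom: str, pos: int) -> GenomicInterval:
        lo = max(0, pos - pad)
        hi = min(chrom_lengths[chrom], pos + pad)
        if hi <= lo:  # degenerate chromosome edge
            hi = min(chrom_lengths[chrom], lo + 1)
        return GenomicInterval(chrom, lo, hi)

    out = []
    for rec in svs:
        bes = rec.breakends()
        if rec.svtype == "insertion":
            # origin junction + destination junction
            (oc, a), (_, b), (dc, d) = bes
            out.append((clipped(oc, a), clipped(oc, b)))
            out.append((clipped(oc, b), clipped(dc, d)))
        else:
            (c1, p1), (c2, p2) = bes
            out.append((clipped(c1, p1), clipped(c2, p2)))
    return out
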
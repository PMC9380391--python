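"""Matching called SVs against known SVs, and precision/recall/F-value.

Matching is type-specific.  Deletions, inversions and tandem duplications
match when they lie on the same chromosome, their altered regions overlap
reciprocally by at least the configured fraction (default 75%) and their
breakends are closer than the configured distance (default 50 bp).
Insertions additionally require the same origin and destination chromosomes,
the same copy/cut mode and nearby insertion sites; translocations require the
same chromosome pair, the same inverted state and nearby breakpoint positions.

A true positive is a called SV matching at least one known SV; one known SV
may satisfy several called SVs (no one-to-one assignment is enforced).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .simulate import SVRecord, SV_TYPES

_INTERVAL_TYPES = ("deletion", "inversion", "tandem_duplication")


@dataclass(frozen=True)
class MatchConfig:
    reciprocal_overlap: float = 0.75
    breakend_distance: int = 50
    insertion_site_distance: int = 50
    reciprocal: bool = True  # False: overlap fraction judged on the query only

    def __post_init__(self):
        if not (0 < self.reciprocal_overlap <= 1):
            raise ValueError("overlap fraction must lie in (0, 1]")
        if self.breakend_distance < 0 or self.insertion_site_distance < 0:
            raise ValueError("distances must be >= 0")


def _regions_match(
    chrom_a: str, sa: int, ea: int, chrom_b: str, sb: int, eb: int, cfg: MatchConfig
) -> bool:
    if chrom_a != chrom_b:
        return False
    if abs(sa - sb) >= cfg.breakend_distance or abs(ea - eb) >= cfg.breakend_distance:
        return False
    inter = min(ea, eb) - max(sa, sb)
    if inter <= 0:
        return False
    if inter < cfg.reciprocal_overlap * (ea - sa):
        return False
    if cfg.reciprocal and inter < cfg.reciprocal_overlap * (eb - sb):
        return False
    return True


def svs_match(a: SVRecord, b: SVRecord, cfg: MatchConfig | None = None) -> bool:
    """Type-specific conjunction of the matching conditions."""
    cfg = cfg or MatchConfig()
    if a.svtype != b.svtype:
        raise ValueError(f"cannot match SVs of different types ({a.svtype} vs {b.svtype})")
    t = a.svtype
    if t in _INTERVAL_TYPES:
        return _regions_match(a.chrom, a.start, a.end, b.chrom, b.start, b.end, cfg)
    if t == "insertion":
        if a.chrom != b.chrom or a.chrom2 != b.chrom2 or bool(a.is_copy) != bool(b.is_copy):
            return False
        if not _regions_match(a.chrom, a.start, a.end, b.chrom, b.start, b.end, cfg):
            return False
        return abs(a.pos2 - b.pos2) < cfg.insertion_site_distance
    if t == "translocation":
        # chromosome pair compared unordered
        pa = sorted([(a.chrom, a.start), (a.chrom2, a.pos2)])
        pb = sorted([(b.chrom, b.start), (b.chrom2, b.pos2)])
        if [p[0] for p in pa] != [p[0] for p in pb]:
            return False
        if bool(a.inverted) != bool(b.inverted):
            return False
        return all(
            abs(x[1] - y[1]) < cfg.breakend_distance for x, y in zip(pa, pb)
        )
    raise ValueError(f"unknown SV type {t!r}")


@dataclass(frozen=True)
class Metrics:
    """TP/FP/FN counts with pessimistic 0/0 conventions for P, R and F."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f_value(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


@dataclass
class AccuracyReport:
    """Per-SV-type and integrated accuracy of a called set against a known set."""

    per_type: dict[str, Metrics]
    integrated: Metrics

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in list(self.per_type.items()) + [("integrated", self.integrated)]:
            rows.append(
                {
                    "svtype": name, "TP": m.tp, "FP": m.fp, "FN": m.fn,
                    "precision": m.precision, "recall": m.recall, "F": m.f_value,
                }
            )
        return pd.DataFrame(rows)


def _as_typed_dict(
    svs: Mapping[str, Sequence[SVRecord]] | Iterable[SVRecord]
) -> dict[str, list[SVRecord]]:
    if isinstance(svs, Mapping):
        return {t: list(svs.get(t, [])) for t in SV_TYPES}
    out: dict[str, list[SVRecord]] = {t: [] for t in SV_TYPES}
    for r in svs:
        out[r.svtype].append(r)
    return out


def _count(called: Sequence[SVRecord], known: Sequence[SVRecord], cfg: MatchConfig) -> Metrics:
    tp = fp = 0
    known_hit = [False] * len(known)
    for c in called:
        hit = False
        for j, k in enumerate(known):
            if svs_match(c, k, cfg):
                hit = True
                known_hit[j] = True
        if hit:
            tp += 1
        else:
            fp += 1
    fn = known_hit.count(False)
    return Metrics(tp=tp, fp=fp, fn=fn)


def compare_sets(
    called: Mapping[str, Sequence[SVRecord]] | Iterable[SVRecord],
    known: Mapping[str, Sequence[SVRecord]] | Iterable[SVRecord],
    cfg: MatchConfig | None = None,
) -> AccuracyReport:
    """Count TP/FP/FN per SV type and on the merged ("integrated") sets."""
    cfg = cfg or MatchConfig()
    called_d, known_d = _as_typed_dict(called), _as_typed_dict(known)
    per_type = {t: _count(called_d[t], known_d[t], cfg) for t in SV_TYPES}
    integrated = Metrics(
        tp=sum(m.tp for m in per_type.values()),
        fp=sum(m.fp for m in per_type.values()),
        fn=sum(m.fn for m in per_type.values()),
    )
    return AccuracyReport(per_type=per_type, integrated=integrated)
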
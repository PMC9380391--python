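"""Filter-parameter optimization by F-value grid search on simulations.

The grid is a per-parameter list of candidate values (presets ``small`` /
``medium`` / ``large``); values that cannot change breakpoint filtering on the
catalog at hand — judged by toggling each value alone against the fully
unconservative baseline — are pruned before enumeration.  Enumeration is lazy
and deduplicated on the induced set of passing breakpoints, so only outcome-
distinct filter combinations are ever scored.  Per SV type, the combination
with the highest F-value wins (ties broken deterministically toward the more
permissive value in a documented parameter order); the final cross-simulation
parameter set maximizes the minimum F over every (simulation, ploidy, SV type)
instance, tie-broken by mean F and then by the fewest active filters.

The public surface is both functional (:func:`prune_grid`,
:func:`optimize_for_simulation`, :func:`select_final_parameters`,
:func:`run_optimization`) and object-based: :class:`ParameterOptimizer` is a
model built from a genome plus a simulation configuration whose ``fit()``
returns :class:`OptimizationResults`.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .accuracy import AccuracyReport, MatchConfig, Metrics, compare_sets
from .breakends import (
    Breakpoint, EmulatorNoiseModel, InsertSizeStats, emulate_caller,
    insert_stats_from_params,
)
from .filtering import (
    INF, CallResult, CoverageTable, FilterParameters, call_svs,
    expected_coverage_table, filter_breakpoints, has_long_gc_run,
)
from .io import Genome, GenomicInterval
from .simulate import ReadSimParams, SVTruthSet, SV_TYPES, simulate_svs

logger = logging.getLogger("svtune")

# parameters whose candidates act on breakend filtering, in the documented
# tie-break order (earlier parameters dominate; list order within a parameter
# runs from permissive to strict)
FILTER_PARAM_ORDER = [
    "min_Nfragments",
    "min_af",
    "min_af_EitherSmallOrLargeEvent",
    "min_QUAL",
    "wrong_FILTERtags",
    "maximum_length_inexactHomology",
    "maximum_microhomology",
    "maximum_strand_bias",
    "filter_noReadPairs",
    "filter_noSplitReads",
    "filter_overlappingRepeats",
    "filter_polyGC",
    "min_length_inversions",
    "range_filt_DEL_breakpoints",
    "dif_between_insert_and_del",
]
COVERAGE_PARAMS = ["max_rel_coverage_to_consider_del", "min_rel_coverage_to_consider_dup"]


@dataclass
class ParameterGridSpec:
    """Ordered candidate lists per parameter (permissive value first).

    Every list contains the unconservative extreme and the printed default.
    """

    candidates: dict[str, list]
    name: str = "custom"
    pruned: bool = False  # pruned grids may legitimately lose the default

    def __post_init__(self):
        if self.pruned:
            return
        unc = FilterParameters.unconservative()
        dflt = FilterParameters()
        for p, values in self.candidates.items():
            for ref, label in ((getattr(unc, p), "unconservative"),
                               (getattr(dflt, p), "default")):
                if ref not in values:
                    raise ValueError(
                        f"grid list for {p} must contain the {label} value {ref!r}"
                    )

    @property
    def n_combinations(self) -> int:
        n = 1
        for values in self.candidates.values():
            n *= len(values)
        return n

    @classmethod
    def preset(cls, name: str = "small") -> "ParameterGridSpec":
        base = {
            "min_Nfragments": [0, 5, 10, 20, 30],
            "min_af": [0.0, 0.05, 0.25, 0.5],
            "min_af_EitherSmallOrLargeEvent": [0.0, 0.25],
            "min_QUAL": [0.0, 100.0, 1000.0],
            "max_to_be_considered_small_event": [1000],
            "min_length_inversions": [0, 40],
            "maximum_length_inexactHomology": [INF, 50],
            "maximum_microhomology": [INF, 50],
            "maximum_strand_bias": [1.0, 0.99, 0.9],
            "filter_noReadPairs": [False, True],
            "filter_noSplitReads": [False, True],
            "filter_overlappingRepeats": [False, True],
            "filter_polyGC": [False, True],
            "wrong_FILTERtags": [(), ("NO_ASSEMBLY",)],
            "range_filt_DEL_breakpoints": [(-1, -1), (0, 1)],
            "dif_between_insert_and_del": [None, 5],
            "max_rel_coverage_to_consider_del": [1.0, 0.5, 0.1],
            "min_rel_coverage_to_consider_dup": [1.0, 1.4, 1.8],
        }
        if name == "small":
            return cls(candidates=base, name=name)
        if name == "medium":
            base.update(
                {
                    "min_Nfragments": [0, 2, 5, 10, 15, 20, 30],
                    "min_af": [0.0, 0.05, 0.1, 0.25, 0.5, 0.75],
                    "min_QUAL": [0.0, 50.0, 100.0, 500.0, 1000.0],
                    "maximum_length_inexactHomology": [INF, 100, 50, 10],
                    "maximum_microhomology": [INF, 100, 50, 10],
                    "maximum_strand_bias": [1.0, 0.99, 0.95, 0.9, 0.75],
                    "range_filt_DEL_breakpoints": [(-1, -1), (0, 1), (500, 1000)],
                    "dif_between_insert_and_del": [None, 5, 10],
                    "max_rel_coverage_to_consider_del": [1.0, 0.75, 0.5, 0.25, 0.1],
                    "min_rel_coverage_to_consider_dup": [1.0, 1.25, 1.4, 1.6, 1.8],
                }
            )
            return cls(candidates=base, name=name)
        if name == "large":
            spec = cls.preset("medium")
            spec.candidates.update(
                {
                    "min_Nfragments": [0, 1, 2, 3, 5, 8, 10, 15, 20, 30, 40],
                    "min_af": [0.0, 0.02, 0.05, 0.1, 0.25, 0.35, 0.5, 0.75, 0.9],
                    "max_to_be_considered_small_event": [1000, 100, 10000],
                }
            )
            spec.name = name
            return spec
        raise ValueError(f"unknown grid preset {name!r}")


# --------------------------------------------------------------------------- #
# Vectorized rule masks
# --------------------------------------------------------------------------- #

class _Catalog:
    """Flat numpy view of a breakend catalog for fast mask evaluation.

    Array layout: two breakends per breakpoint, breakend ``2*i`` and ``2*i+1``
    belonging to breakpoint ``i``.
    """

    def __init__(self, breakpoints: Sequence[Breakpoint], insert_stats: InsertSizeStats):
        self.breakpoints = list(breakpoints)
        self.insert_stats = insert_stats
        bes = [be for bp in self.breakpoints for be in bp.breakends()]
        n = len(bes)
        self.n_bp = len(self.breakpoints)
        self.fragments = np.array([be.fragments for be in bes], dtype=float)
        self.qual = np.array([be.qual for be in bes], dtype=float)
        self.vaf_small = np.array([be.vaf_small for be in bes], dtype=float)
        self.vaf_large = np.array([be.vaf_large for be in bes], dtype=float)
        self.ihom = np.array([be.inexact_homology for be in bes], dtype=float)
        self.mhom = np.array([be.microhomology for be in bes], dtype=float)
        sb = np.array([be.strand_bias for be in bes], dtype=float)
        self.sb_folded = np.maximum(sb, 1 - sb)
        self.has_rp = np.array([be.has_read_pairs for be in bes], dtype=bool)
        self.has_sr = np.array([be.has_split_reads for be in bes], dtype=bool)
        self.repeat = np.array([be.overlaps_repeat for be in bes], dtype=bool)
        self.gc_run = np.array([has_long_gc_run(be.inserted_seq) for be in bes], dtype=bool)
        self.ins_len = np.array([len(be.inserted_seq) for be in bes], dtype=float)
        self.tags = [set(be.filter_tags) for be in bes]

        intra_bp = np.array([bp.intrachromosomal for bp in self.breakpoints], dtype=bool)
        len_bp = np.array(
            [bp.length if bp.intrachromosomal else -1 for bp in self.breakpoints],
            dtype=float,
        )
        hints = np.array([bp.type_hint() for bp in self.breakpoints])
        rep = np.repeat(np.arange(self.n_bp), 2)
        self.intra = intra_bp[rep]
        self.length = len_bp[rep]
        self.inv_like = (hints == "INV-like")[rep]
        self.del_like = (hints == "DEL-like")[rep]
        self.large_vaf = ~self.intra | (self.length > insert_stats.large_event_threshold)
        self.vaf_used = np.where(self.large_vaf, self.vaf_large, self.vaf_small)

    def small_mask(self, max_small: float) -> np.ndarray:
        return self.intra & (self.length < max_small)

    def rule_mask(self, param: str, value, max_small: float) -> np.ndarray:
        """Breakend-level pass mask for one parameter value (others permissive)."""
        small = self.small_mask(max_small)
        if param == "min_Nfragments":
            return self.fragments >= value
        if param == "min_af":
            return self.vaf_used >= value
        if param == "min_af_EitherSmallOrLargeEvent":
            return ~((self.vaf_small < value) & (self.vaf_large < value))
        if param == "min_QUAL":
            return self.qual >= value
        if param == "wrong_FILTERtags":
            bad = set(value)
            return np.array([not (t & bad) for t in self.tags], dtype=bool)
        if param == "maximum_length_inexactHomology":
            return ~(~small & (self.ihom > value))
        if param == "maximum_microhomology":
            return self.mhom <= value
        if param == "maximum_strand_bias":
            return ~(small & (self.sb_folded > value))
        if param == "filter_noReadPairs":
            return ~(~small & ~self.has_rp) if value else np.ones_like(self.intra)
        if param == "filter_noSplitReads":
            return ~(small & ~self.has_sr) if value else np.ones_like(self.intra)
        if param == "filter_overlappingRepeats":
            return ~self.repeat if value else np.ones_like(self.intra)
        if param == "filter_polyGC":
            return ~self.gc_run if value else np.ones_like(self.intra)
        if param == "min_length_inversions":
            return ~(self.inv_like & (self.length < value))
        if param == "range_filt_DEL_breakpoints":
            lo, hi = value
            return ~(self.del_like & (self.length >= lo) & (self.length <= hi)
                     & (self.ihom > 5))
        if param == "dif_between_insert_and_del":
            if value is None:
                return np.ones_like(self.intra)
            return ~(small & self.del_like
                     & (self.ins_len > self.length - value))
        raise KeyError(param)

    @staticmethod
    def bp_mask(be_mask: np.ndarray) -> np.ndarray:
        """Breakpoint passes iff both of its breakends pass."""
        m = be_mask.reshape(-1, 2)
        return m[:, 0] & m[:, 1]

    def surviving(self, bp_mask: np.ndarray) -> list[Breakpoint]:
        return [bp for bp, keep in zip(self.breakpoints, bp_mask) if keep]


def prune_grid(
    spec: ParameterGridSpec,
    breakpoints: Sequence[Breakpoint],
    insert_stats: InsertSizeStats,
) -> ParameterGridSpec:
    """Drop candidate values that cannot change breakpoint filtering.

    Each value is toggled alone with every other parameter at its
    unconservative extreme; values whose passing set equals the baseline (or
    equals the set induced by an already retained, more permissive value) are
    discarded.  The unconservative extreme is always retained.  Coverage
    classification thresholds are exempt: they steer DEL/TAN confirmation, not
    breakpoint filtering.
    """
    cat = _Catalog(breakpoints, insert_stats)
    unc = FilterParameters.unconservative()
    max_small_unc = unc.max_to_be_considered_small_event
    pruned: dict[str, list] = {}
    for param, values in spec.candidates.items():
        if param in COVERAGE_PARAMS:
            pruned[param] = list(values)
            continue
        if param == "max_to_be_considered_small_event":
            # toggling the smallness cutoff alone never changes filtering
            # (every size-dependent rule is permissive in the baseline)
            pruned[param] = [getattr(unc, param) if getattr(unc, param) in values
                            else values[0]]
            continue
        seen_masks = []
        kept = []
        for v in values:
            mask = cat.bp_mask(cat.rule_mask(param, v, max_small_unc))
            if v == getattr(unc, param):
                kept.append(v)
                seen_masks.append(mask)
                continue
            if any(np.array_equal(mask, m) for m in seen_masks):
                continue
            kept.append(v)
            seen_masks.append(mask)
        pruned[param] = kept
    return ParameterGridSpec(candidates=pruned, name=f"{spec.name}(pruned)", pruned=True)


# --------------------------------------------------------------------------- #
# Scoring and per-simulation search
# --------------------------------------------------------------------------- #

def _score(
    surviving: list[Breakpoint],
    truth: SVTruthSet,
    coverage: CoverageTable,
    insert_stats: InsertSizeStats,
    cov_del: float,
    cov_dup: float,
    match_cfg: MatchConfig,
) -> AccuracyReport:
    params = replace(
        FilterParameters.unconservative(),
        max_rel_coverage_to_consider_del=cov_del,
        min_rel_coverage_to_consider_dup=cov_dup,
    )
    result = call_svs(surviving, params, coverage, insert_stats)
    return compare_sets(result.svs, truth.by_type(), match_cfg)


@dataclass
class OptimizedChoice:
    params: FilterParameters
    metrics: Metrics
    report: AccuracyReport | None = None


def _params_from_combo(combo: dict, cov_del: float, cov_dup: float) -> FilterParameters:
    return FilterParameters(
        **combo,
        max_rel_coverage_to_consider_del=cov_del,
        min_rel_coverage_to_consider_dup=cov_dup,
    )


def optimize_for_simulation(
    breakpoints: Sequence[Breakpoint],
    truth: SVTruthSet,
    coverage: CoverageTable,
    insert_stats: InsertSizeStats,
    spec: ParameterGridSpec,
    match_cfg: MatchConfig | None = None,
    max_combinations: int = 10_000_000,
) -> dict[str, OptimizedChoice]:
    """Per-SV-type argmax-F filter parameters on one simulated catalog.

    The Cartesian product over the (pruned) grid is deduplicated on the set of
    passing breakpoints, so only outcome-distinct combinations are scored; the
    representative kept for each outcome is the most permissive combination
    reaching it, which fixes the tie-break deterministically.
    """
    match_cfg = match_cfg or MatchConfig()
    if spec.n_combinations > max_combinations:
        raise ValueError(
            f"pruned grid has {spec.n_combinations} combinations "
            f"(> budget {max_combinations}); use a smaller preset"
        )
    unc = FilterParameters.unconservative()
    cat = _Catalog(breakpoints, insert_stats)
    cov_dels = spec.candidates.get(
        "max_rel_coverage_to_consider_del", [unc.max_rel_coverage_to_consider_del]
    )
    cov_dups = spec.candidates.get(
        "min_rel_coverage_to_consider_dup", [unc.min_rel_coverage_to_consider_dup]
    )
    max_smalls = spec.candidates.get(
        "max_to_be_considered_small_event", [unc.max_to_be_considered_small_event]
    )

    best: dict[str, tuple[float, FilterParameters, Metrics]] = {}
    order_rank = 0
    for max_small in max_smalls:
        # sequential dedupe over parameters: keep one (mask, combo) per
        # distinct partial passing set, most permissive combo first
        states: dict[bytes, tuple[np.ndarray, dict]] = {}
        init = np.ones(cat.n_bp, dtype=bool)
        states[init.tobytes()] = (init, {"max_to_be_considered_small_event": max_small})
        for param in FILTER_PARAM_ORDER:
            values = spec.candidates.get(param, [getattr(FilterParameters.unconservative(), param)])
            new_states: dict[bytes, tuple[np.ndarray, dict]] = {}
            for _, (mask, combo) in states.items():
                for v in values:
                    m2 = mask & cat.bp_mask(cat.rule_mask(param, v, max_small))
                    key = m2.tobytes()
                    if key not in new_states:
                        new_states[key] = (m2, {**combo, param: v})
            states = new_states
        for _, (mask, combo) in states.items():
            surviving = cat.surviving(mask)
            for cov_del in cov_dels:
                for cov_dup in cov_dups:
                    report = _score(
                        surviving, truth, coverage, insert_stats,
                        cov_del, cov_dup, match_cfg,
                    )
                    params = None
                    for svtype in SV_TYPES:
                        m = report.per_type[svtype]
                        f = m.f_value
                        if svtype not in best or f > best[svtype][0] + 1e-12:
                            if params is None:
                                params = _params_from_combo(combo, cov_del, cov_dup)
                            best[svtype] = (f, params, m)
            order_rank += 1
    logger.info("scored %d outcome-distinct filter combinations", order_rank)
    return {
        t: OptimizedChoice(params=p, metrics=m) for t, (f, p, m) in best.items()
    }


# --------------------------------------------------------------------------- #
# Final cross-simulation selection
# --------------------------------------------------------------------------- #

@dataclass
class SimulationInstance:
    """One (template genome, ploidy) catalog with its truth and coverage."""

    name: str
    ploidy: str
    breakpoints: list[Breakpoint]
    truth: SVTruthSet
    coverage: CoverageTable
    insert_stats: InsertSizeStats


def _instance_report(
    params: FilterParameters, inst: SimulationInstance, match_cfg: MatchConfig
) -> AccuracyReport:
    result = call_svs(inst.breakpoints, params, inst.coverage, inst.insert_stats)
    return compare_sets(result.svs, inst.truth.by_type(), match_cfg)


def select_final_parameters(
    candidates: Sequence[FilterParameters],
    instances: Sequence[SimulationInstance],
    match_cfg: MatchConfig | None = None,
) -> tuple[FilterParameters, pd.DataFrame]:
    """Pick the candidate that works well for every simulation, ploidy and type.

    Criterion: maximize the minimum F over all (instance, SV type) cells with
    at least one truth record, tie-broken by mean F, then by fewer active
    filters, then by candidate order.  Returns the winner plus a tabular
    report of its accuracy on every instance and SV type.
    """
    if not instances:
        raise ValueError("need at least one simulation instance")
    match_cfg = match_cfg or MatchConfig()
    # deduplicate candidates, preserving order
    uniq: list[FilterParameters] = []
    for c in candidates:
        if c not in uniq:
            uniq.append(c)
    best_key = None
    winner = None
    winner_reports = None
    for rank, cand in enumerate(uniq):
        reports = [_instance_report(cand, inst, match_cfg) for inst in instances]
        cells = []
        for inst, rep in zip(instances, reports):
            present = {r.svtype for r in inst.truth.records}
            for t in SV_TYPES:
                if t in present:
                    cells.append(rep.per_type[t].f_value)
        if not cells:
            cells = [0.0]
        key = (min(cells), float(np.mean(cells)), -cand.n_active_filters(), -rank)
        if best_key is None or key > best_key:
            best_key = key
            winner = cand
            winner_reports = reports
    rows = []
    for inst, rep in zip(instances, winner_reports):
        for t in SV_TYPES:
            m = rep.per_type[t]
            rows.append(
                {
                    "simulation": inst.name, "ploidy": inst.ploidy, "svtype": t,
                    "n_truth": sum(1 for r in inst.truth.records if r.svtype == t),
                    "TP": m.tp, "FP": m.fp, "FN": m.fn,
                    "precision": m.precision, "recall": m.recall, "F": m.f_value,
                }
            )
    return winner, pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# End-to-end optimization
# --------------------------------------------------------------------------- #

@dataclass
class SimulationConfig:
    """Study conditions for the training simulations."""

    nsimulations: int = 2
    ploidies: tuple[str, ...] = ("haploid",)
    nvars: int = 50  # per SV type, per template genome
    regions: list[tuple[GenomicInterval, GenomicInterval]] | None = None
    chromosomes: tuple[str, ...] | None = None
    read_params: ReadSimParams = field(default_factory=ReadSimParams)
    coverage_window: int = 300
    coverage_noise_sd: float = 0.05


@dataclass
class OptimizationResult:
    final_params: FilterParameters
    report: pd.DataFrame
    per_simulation: dict[tuple[str, str], dict[str, OptimizedChoice]]
    default_report: pd.DataFrame
    grid: ParameterGridSpec
    n_instances: int
    instances: list[SimulationInstance] = field(default_factory=list)


def run_optimization(
    genome: Genome,
    config: SimulationConfig | None = None,
    noise: EmulatorNoiseModel | None = None,
    grid: str | ParameterGridSpec = "small",
    seed: int = 0,
    match_cfg: MatchConfig | None = None,
) -> OptimizationResult:
    """Simulate, emulate the caller, and optimize filters end to end.

    For each of ``nsimulations`` template genomes and each ploidy, a truth set
    is planted, an annotated breakend catalog emulated, the grid pruned on
    that catalog and searched per SV type; the final parameter set is then
    selected across all instances.  Deterministic under ``seed``.
    """
    config = config or SimulationConfig()
    noise = noise if noise is not None else EmulatorNoiseModel()
    match_cfg = match_cfg or MatchConfig()
    if isinstance(grid, str):
        grid = ParameterGridSpec.preset(grid)
    if config.chromosomes:
        genome = Genome.from_sequences(
            genome[c] for c in config.chromosomes
        )
    insert_stats = insert_stats_from_params(config.read_params)
    cov_noise = 0.0 if noise.perfect else config.coverage_noise_sd

    instances: list[SimulationInstance] = []
    per_sim: dict[tuple[str, str], dict[str, OptimizedChoice]] = {}
    candidate_pool: list[FilterParameters] = []
    for i in range(config.nsimulations):
        truth = simulate_svs(
            genome, counts=config.nvars, regions=config.regions,
            seed=seed * 1009 + i,
        )
        for ploidy in config.ploidies:
            sub_seed = (seed * 1009 + i * 31 + zlib.crc32(ploidy.encode()) % 1000) % 2**31
            catalog = emulate_caller(
                truth, genome, coverage=config.read_params.coverage,
                insert_stats=insert_stats, noise=noise, ploidy=ploidy,
                seed=sub_seed,
            )
            coverage = expected_coverage_table(
                truth, genome, window_size=config.coverage_window,
                ploidy=ploidy, noise_sd=cov_noise, seed=sub_seed,
            )
            inst = SimulationInstance(
                name=f"sim{i}", ploidy=ploidy, breakpoints=catalog,
                truth=truth, coverage=coverage, insert_stats=insert_stats,
            )
            instances.append(inst)
            pruned = prune_grid(grid, catalog, insert_stats)
            choices = optimize_for_simulation(
                catalog, truth, coverage, insert_stats, pruned, match_cfg,
            )
            per_sim[(inst.name, ploidy)] = choices
            candidate_pool.extend(c.params for c in choices.values())

    candidate_pool.append(FilterParameters())  # the printed defaults
    final, report = select_final_parameters(candidate_pool, instances, match_cfg)
    _, default_report = select_final_parameters(
        [FilterParameters()], instances, match_cfg
    )
    return OptimizationResult(
        final_params=final, report=report, per_simulation=per_sim,
        default_report=default_report, grid=grid, n_instances=len(instances),
        instances=instances,
    )


# --------------------------------------------------------------------------- #
# Model / Results objects
# --------------------------------------------------------------------------- #

class ParameterOptimizer:
    """Filter-parameter optimization model for a genome and study design.

    Parameters
    ----------
    genome : Genome
        Reference genome the training simulations are planted on.
    config : SimulationConfig, optional
        Number of template genomes, ploidies, SV counts, read parameters.
    noise : EmulatorNoiseModel, optional
        Caller emulator noise model (defaults to a separable noisy model).
    grid : str or ParameterGridSpec
        Candidate grid preset name or an explicit grid.

    Examples
    --------
    >>> model = ParameterOptimizer(genome, SimulationConfig(nsimulations=2))
    >>> res = model.fit(seed=1)
    >>> res.params            # the selected FilterParameters
    >>> print(res.summary())  # accuracy per simulation, ploidy and SV type
    """

    def __init__(
        self,
        genome: Genome,
        config: SimulationConfig | None = None,
        noise: EmulatorNoiseModel | None = None,
        grid: str | ParameterGridSpec = "small",
        match_cfg: MatchConfig | None = None,
    ):
        self.genome = genome
        self.config = config or SimulationConfig()
        self.noise = noise
        self.grid = grid
        self.match_cfg = match_cfg

    def fit(self, seed: int = 0) -> "OptimizationResults":
        raw = run_optimization(
            self.genome, self.config, self.noise, self.grid, seed=seed,
            match_cfg=self.match_cfg,
        )
        return OptimizationResults(self, raw, seed=seed)


class OptimizationResults:
    """Results of a :class:`ParameterOptimizer` fit.

    Attributes
    ----------
    params : FilterParameters
        The final cross-simulation parameter set.
    report : pandas.DataFrame
        Accuracy (precision, recall, F) of ``params`` on every simulation,
        ploidy and SV type.
    default_report : pandas.DataFrame
        The same table for the un-optimized default parameters.
    """

    def __init__(self, model: ParameterOptimizer, raw: OptimizationResult, seed: int):
        self.model = model
        self.raw = raw
        self.seed = seed
        self.params = raw.final_params
        self.report = raw.report
        self.default_report = raw.default_report

    @property
    def mean_f(self) -> float:
        mask = self.report["n_truth"] > 0
        return float(self.report.loc[mask, "F"].mean())

    @property
    def mean_f_default(self) -> float:
        mask = self.default_report["n_truth"] > 0
        return float(self.default_report.loc[mask, "F"].mean())

    def save_params(self, path: str | Path):
        self.params.to_json(path)

    def summary(self) -> str:
        lines = []
        w = 72
        lines.append("=" * w)
        lines.append("Filter-parameter optimization".center(w))
        lines.append("=" * w)
        lines.append(f"Simulations: {self.raw.n_instances} instance(s); "
                     f"grid preset: {self.raw.grid.name}; seed: {self.seed}")
        lines.append(f"Mean F (optimized): {self.mean_f:.3f}    "
                     f"Mean F (default): {self.mean_f_default:.3f}")
        lines.append("-" * w)
        lines.append("Selected parameters (differences from default):")
        dflt = FilterParameters().to_dict()
        chosen = self.params.to_dict()
        diffs = {k: v for k, v in chosen.items() if dflt[k] != v}
        if not diffs:
            lines.append("  (identical to the default parameter set)")
        for k, v in diffs.items():
            lines.append(f"  {k}: {dflt[k]!r} -> {v!r}")
        lines.append("-" * w)
        lines.append("Accuracy of the selected parameters:")
        with pd.option_context("display.width", 100):
            lines.append(
                self.report[
                    ["simulation", "ploidy", "svtype", "n_truth",
                     "precision", "recall", "F"]
                ].to_string(index=False, float_format=lambda x: f"{x:.3f}")
            )
        lines.append("=" * w)
        return "\n".join(lines)
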
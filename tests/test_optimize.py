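import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from svtune.accuracy import MatchConfig, compare_sets
from svtune.breakends import (
    EmulatorNoiseModel, InsertSizeStats, emulate_caller,
)
from svtune.filtering import (
    CoverageTable, FilterParameters, call_svs, expected_coverage_table,
    filter_breakpoints,
)
from svtune.optimize import (
    COVERAGE_PARAMS, OptimizationResults, ParameterGridSpec, ParameterOptimizer,
    SimulationConfig, SimulationInstance, optimize_for_simulation, prune_grid,
    run_optimization, select_final_parameters,
)
from svtune.simulate import SVTruthSet, SV_TYPES, simulate_svs
from tests.conftest import make_breakpoint, make_genome, random_breakends

STATS = InsertSizeStats(400, 50)


def flat_cov(value=1.0, chroms=("chr1", "chr2", "chr3")):
    return CoverageTable(pd.DataFrame(
        {"chrom": list(chroms), "start": [0] * len(chroms),
         "end": [2_000_000] * len(chroms),
         "relative_coverage": [value] * len(chroms)}
    ))


class TestGridSpec:
    def test_presets_contain_default_and_unconservative(self):
        unc, dflt = FilterParameters.unconservative(), FilterParameters()
        for name in ("small", "medium", "large"):
            spec = ParameterGridSpec.preset(name)
            for p, values in spec.candidates.items():
                assert getattr(unc, p) in values
                assert getattr(dflt, p) in values

    def test_missing_default_rejected(self):
        with pytest.raises(ValueError, match="default"):
            ParameterGridSpec(candidates={"min_Nfragments": [0, 10]})

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            ParameterGridSpec.preset("gigantic")


class TestPruneGrid:
    def test_values_below_all_fragment_counts_collapse(self):
        bps = [make_breakpoint(bid=f"b{i}", pos1=i * 10_000, pos2=i * 10_000 + 5000,
                               fragments=30 + i) for i in range(20)]
        spec = ParameterGridSpec.preset("small")
        pruned = prune_grid(spec, bps, STATS)
        assert pruned.candidates["min_Nfragments"] == [0]

    def test_empty_catalog_collapses_every_filter_param(self):
        pruned = prune_grid(ParameterGridSpec.preset("small"), [], STATS)
        for p, values in pruned.candidates.items():
            if p in COVERAGE_PARAMS:
                continue  # classification thresholds are exempt from pruning
            assert len(values) == 1, p

    def test_discriminating_tag_values_are_retained(self):
        bps = []
        for i in range(20):
            tags = frozenset({"NO_ASSEMBLY"}) if i % 2 == 0 else frozenset()
            bps.append(make_breakpoint(bid=f"b{i}", pos1=i * 10_000,
                                       pos2=i * 10_000 + 5000, filter_tags=tags))
        pruned = prune_grid(ParameterGridSpec.preset("small"), bps, STATS)
        assert set(pruned.candidates["wrong_FILTERtags"]) == {(), ("NO_ASSEMBLY",)}

    def test_unconservative_value_always_retained(self):
        bps = random_breakends(100, seed=3)
        pruned = prune_grid(ParameterGridSpec.preset("small"), bps, STATS)
        unc = FilterParameters.unconservative()
        for p, values in pruned.candidates.items():
            if p in COVERAGE_PARAMS or p == "max_to_be_considered_small_event":
                continue
            assert getattr(unc, p) in values, p


def _noiseless_setup(seed=0, counts=6):
    g = make_genome([120_000] * 4, seed=seed)
    truth = simulate_svs(g, counts=counts, seed=seed + 1, min_size=300)
    cat = emulate_caller(
        truth, g, 30.0, STATS, EmulatorNoiseModel.noiseless(), seed=seed + 2
    )
    cov = expected_coverage_table(truth, g, 200)
    return g, truth, cat, cov


class TestOptimizeForSimulation:
    def test_noiseless_catalog_reaches_f1_for_every_type(self):
        g, truth, cat, cov = _noiseless_setup()
        spec = prune_grid(ParameterGridSpec.preset("small"), cat, STATS)
        choices = optimize_for_simulation(cat, truth, cov, STATS, spec)
        present = {r.svtype for r in truth.records}
        for t in present:
            assert choices[t].metrics.f_value == 1.0

    def test_budget_exceeded_raises(self):
        g, truth, cat, cov = _noiseless_setup(seed=5)
        spec = ParameterGridSpec.preset("small")
        with pytest.raises(ValueError, match="smaller preset"):
            optimize_for_simulation(cat, truth, cov, STATS, spec,
                                    max_combinations=10)

    def test_toy_grid_matches_brute_force_argmax(self):
        """On a 3x3 toy grid the dedup search equals exhaustive enumeration."""
        rng = np.random.default_rng(17)
        truth_recs = []
        bps = []
        from svtune.simulate import SVRecord

        for i in range(12):
            s = 10_000 + i * 20_000
            truth_recs.append(SVRecord(f"d{i}", "deletion", "chr1", s, s + 2000))
            bps.append(make_breakpoint(
                bid=f"t{i}", pos1=s, pos2=s + 2000,
                fragments=int(rng.integers(6, 40)),
                qual=float(rng.integers(150, 3000)),
            ))
        for i in range(8):  # false DEL-like junctions with weak support
            s = 400_000 + i * 20_000
            bps.append(make_breakpoint(
                bid=f"f{i}", pos1=s, pos2=s + 1500,
                fragments=int(rng.integers(0, 6)),
                qual=float(rng.integers(0, 120)),
            ))
        truth = SVTruthSet(truth_recs)
        cov_rows = []
        for bp in bps:
            cov_rows.append({"chrom": "chr1", "start": bp.be1.pos,
                             "end": bp.be2.pos, "relative_coverage": 0.0})
        cov = CoverageTable(pd.DataFrame(cov_rows))
        frag_values = [0, 5, 10]
        qual_values = [0.0, 100.0, 1000.0]
        spec = ParameterGridSpec(
            candidates={"min_Nfragments": frag_values, "min_QUAL": qual_values},
        )
        choices = optimize_for_simulation(bps, truth, cov, STATS, spec)

        best_f = -1.0
        for nf, q in itertools.product(frag_values, qual_values):
            params = replace(FilterParameters.unconservative(),
                             min_Nfragments=nf, min_QUAL=q)
            res = call_svs(bps, params, cov, STATS)
            f = compare_sets(res.svs, truth.by_type()).per_type["deletion"].f_value
            best_f = max(best_f, f)
        assert choices["deletion"].metrics.f_value == pytest.approx(best_f)
        assert best_f > 0.9

    def test_no_assembly_on_true_breakends_unlearns_default_tag(self):
        """When every true breakend carries NO_ASSEMBLY, requiring assembly
        support (the default) scores near zero and the optimizer drops it."""
        g = make_genome([150_000] * 3, seed=31)
        truth = simulate_svs(g, counts=8, seed=32, min_size=300)
        noise = EmulatorNoiseModel(
            detection_prob=1.0, false_rate_per_mb=5.0, jitter_sd=0.0,
            true_no_assembly_prob=1.0, false_no_assembly_prob=0.2,
        )
        cat = emulate_caller(truth, g, 30.0, STATS, noise, seed=33)
        cov = expected_coverage_table(truth, g, 200, noise_sd=0.05, seed=34)
        default_res = call_svs(cat, FilterParameters(), cov, STATS)
        default_f = compare_sets(
            default_res.svs, truth.by_type()
        ).integrated.f_value
        assert default_f < 0.1

        spec = prune_grid(ParameterGridSpec.preset("small"), cat, STATS)
        choices = optimize_for_simulation(cat, truth, cov, STATS, spec)
        for t in ("deletion", "inversion", "tandem_duplication"):
            assert "NO_ASSEMBLY" not in choices[t].params.wrong_FILTERtags
            assert choices[t].metrics.f_value > 0.8


class TestSelectFinal:
    def _instance(self, name, bps, truth, cov):
        return SimulationInstance(
            name=name, ploidy="haploid", breakpoints=bps, truth=truth,
            coverage=cov, insert_stats=STATS,
        )

    def test_max_min_criterion_prefers_balanced_candidate(self):
        """Candidate A scores (1.0, ~0.5) across two instances, candidate B
        (0.0, 1.0): the max-min rule picks A."""
        from svtune.simulate import SVRecord

        def del_bp(i, frag, start):
            return make_breakpoint(bid=f"{i}", pos1=start, pos2=start + 2000,
                                   fragments=frag)

        # instance 1: true junctions with little support, no noise
        truth1 = SVTruthSet([SVRecord(f"a{i}", "deletion", "chr1",
                                      10_000 + i * 20_000, 12_000 + i * 20_000)
                             for i in range(6)])
        bps1 = [del_bp(f"a{i}", 2, 10_000 + i * 20_000) for i in range(6)]
        # instance 2: well-supported true junctions plus weak false ones
        truth2 = SVTruthSet([SVRecord(f"b{i}", "deletion", "chr1",
                                      10_000 + i * 20_000, 12_000 + i * 20_000)
                             for i in range(6)])
        bps2 = [del_bp(f"b{i}", 30, 10_000 + i * 20_000) for i in range(6)]
        bps2 += [del_bp(f"n{i}", 2, 500_000 + i * 20_000) for i in range(6)]
        cov = flat_cov(0.0, ("chr1",))
        inst = [self._instance("s1", bps1, truth1, cov),
                self._instance("s2", bps2, truth2, cov)]
        cand_a = FilterParameters.unconservative()
        cand_b = replace(FilterParameters.unconservative(), min_Nfragments=5)
        winner, report = select_final_parameters([cand_b, cand_a], inst)
        assert winner == cand_a
        f_by_sim = report.groupby("simulation")["F"].max()
        assert f_by_sim["s1"] == 1.0

    def test_tie_broken_by_fewest_active_filters(self):
        truth = SVTruthSet([])
        inst = [self._instance("s", [], truth, flat_cov(1.0, ("chr1",)))]
        winner, _ = select_final_parameters(
            [FilterParameters(), FilterParameters.unconservative()], inst
        )
        assert winner == FilterParameters.unconservative()

    def test_single_candidate_report_covers_all_cells(self):
        g, truth, cat, cov = _noiseless_setup(seed=41)
        inst = [self._instance("s0", cat, truth, cov)]
        winner, report = select_final_parameters([FilterParameters()], inst)
        assert len(report) == len(SV_TYPES)

    def test_empty_instances_error(self):
        with pytest.raises(ValueError):
            select_final_parameters([FilterParameters()], [])


class TestRunOptimization:
    def _genome(self, seed=51):
        return make_genome([100_000] * 6, seed=seed)

    def test_report_shape_and_determinism(self):
        g = self._genome()
        cfg = SimulationConfig(nsimulations=2, ploidies=("haploid",), nvars=8)
        a = run_optimization(g, cfg, seed=3)
        b = run_optimization(g, cfg, seed=3)
        assert len(a.report) == 2 * 1 * len(SV_TYPES)
        assert a.final_params == b.final_params
        pd.testing.assert_frame_equal(a.report, b.report)

    def test_multiple_ploidies_multiply_instances(self):
        g = self._genome(seed=52)
        cfg = SimulationConfig(
            nsimulations=2, ploidies=("diploid_hetero", "diploid_homo"), nvars=5,
        )
        res = run_optimization(g, cfg, seed=4)
        assert res.n_instances == 4
        assert len(res.report) == 4 * len(SV_TYPES)

    def test_chromosome_subset_restricts_simulation(self):
        g = self._genome(seed=53)
        cfg = SimulationConfig(
            nsimulations=1, nvars=5, chromosomes=("chr1", "chr2"),
        )
        res = run_optimization(g, cfg, seed=5)
        for inst in res.instances:
            for rec in inst.truth.records:
                for chrom, _ in rec.breakends():
                    assert chrom in ("chr1", "chr2")

    def test_optimized_f_dominates_default_on_every_training_instance(self):
        """Per-simulation winners beat (or tie) the default parameter set on
        the very catalogs they were trained on — the grid contains the
        default, so the argmax must dominate it."""
        g = self._genome(seed=54)
        cfg = SimulationConfig(nsimulations=2, nvars=8)
        res = run_optimization(g, cfg, seed=6)
        for inst in res.instances:
            default_res = call_svs(
                inst.breakpoints, FilterParameters(), inst.coverage,
                inst.insert_stats,
            )
            default_rep = compare_sets(default_res.svs, inst.truth.by_type())
            choices = res.per_simulation[(inst.name, inst.ploidy)]
            present = {r.svtype for r in inst.truth.records}
            for t in present:
                assert (choices[t].metrics.f_value
                        >= default_rep.per_type[t].f_value - 1e-9)

    def test_model_results_interface(self):
        g = self._genome(seed=55)
        cfg = SimulationConfig(nsimulations=1, nvars=6)
        res = ParameterOptimizer(g, cfg).fit(seed=7)
        assert isinstance(res, OptimizationResults)
        assert isinstance(res.params, FilterParameters)
        text = res.summary()
        assert "Filter-parameter optimization" in text
        assert "Mean F" in text
        assert 0 <= res.mean_f <= 1

    def test_save_params_roundtrip(self, tmp_path):
        g = self._genome(seed=56)
        res = ParameterOptimizer(
            g, SimulationConfig(nsimulations=1, nvars=5)
        ).fit(seed=8)
        path = tmp_path / "params.json"
        res.save_params(path)
        assert FilterParameters.from_json(path) == res.params


def test_pruning_soundness_small_grid_vs_full_enumeration():
    """The argmax over the pruned grid equals the argmax over the full grid
    (the pruned values are outcome-equivalent on the catalog)."""
    g, truth, cat, cov = _noiseless_setup(seed=71, counts=5)
    # add noise so filtering matters
    noisy = emulate_caller(
        truth, g, 30.0, STATS,
        EmulatorNoiseModel(detection_prob=1.0, false_rate_per_mb=30.0,
                           jitter_sd=0.0),
        seed=72,
    )
    frag_values = [0, 5, 20]
    tag_values = [(), ("NO_ASSEMBLY",)]
    spec = ParameterGridSpec(candidates={
        "min_Nfragments": frag_values, "wrong_FILTERtags": tag_values,
    })
    pruned = prune_grid(spec, noisy, STATS)
    choices = optimize_for_simulation(noisy, truth, cov, STATS, pruned)

    best = {t: -1.0 for t in SV_TYPES}
    for nf, tags in itertools.product(frag_values, tag_values):
        params = replace(FilterParameters.unconservative(),
                         min_Nfragments=nf, wrong_FILTERtags=tags)
        res = call_svs(noisy, params, cov, STATS)
        rep = compare_sets(res.svs, truth.by_type())
        for t in SV_TYPES:
            best[t] = max(best[t], rep.per_type[t].f_value)
    present = {r.svtype for r in truth.records}
    for t in present:
        assert choices[t].metrics.f_value == pytest.approx(best[t])
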
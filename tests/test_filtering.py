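import math

import numpy as np
import pandas as pd
import pytest

from svtune.breakends import (
    LEFT, RIGHT, EmulatorNoiseModel, InsertSizeStats, emulate_caller,
)
from svtune.filtering import (
    CallResult, CoverageTable, FilterParameters, annotate_repeats,
    breakend_passes, breakpoint_passes, call_svs, classify_del_tan,
    expected_coverage_table, filter_breakpoints, has_long_gc_run,
    type_breakpoint, write_sv_tables,
)
from svtune.io import GenomicInterval
from svtune.simulate import simulate_svs
from svtune.accuracy import compare_sets
from tests.conftest import make_breakpoint, make_genome, random_breakends

STATS = InsertSizeStats(median=400, mad=50)

NOMINAL = dict(
    fragments=30, vaf_small=1.0, vaf_large=1.0, qual=1000.0,
    filter_tags=frozenset(), inexact_homology=0, microhomology=0,
    strand_bias=0.5, has_read_pairs=True, has_split_reads=True,
    inserted_seq="", overlaps_repeat=False,
)


def bp_with(pos1=10_000, pos2=110_000, orient1=RIGHT, orient2=LEFT,
            chrom2="chr1", **overrides):
    """Default: a 100 kb (large, non-small) DEL-like breakpoint."""
    ann = {**NOMINAL, **overrides}
    return make_breakpoint(
        pos1=pos1, pos2=pos2, orient1=orient1, orient2=orient2,
        chrom2=chrom2, **ann,
    )


def first_reasons(bp, params=None):
    params = params or FilterParameters()
    ok, reasons = breakend_passes(bp.be1, bp, params, STATS)
    return ok, reasons


class TestBreakendRules:
    def test_nominal_breakend_accepted_under_defaults(self):
        ok, reasons = first_reasons(bp_with())
        assert ok and reasons == []

    @pytest.mark.parametrize(
        "overrides,reason",
        [
            (dict(fragments=4), "min_Nfragments"),
            (dict(filter_tags=frozenset({"NO_ASSEMBLY"})), "wrong_FILTERtags"),
            (dict(vaf_small=0.2, vaf_large=0.2), "min_af"),
            (dict(microhomology=51), "maximum_microhomology"),
            (dict(inexact_homology=51), "maximum_length_inexactHomology"),
        ],
    )
    def test_default_rejections_on_large_event(self, overrides, reason):
        ok, reasons = first_reasons(bp_with(**overrides))
        assert not ok and reason in reasons

    @pytest.mark.parametrize(
        "overrides",
        [dict(fragments=5), dict(microhomology=50), dict(inexact_homology=50),
         dict(vaf_small=0.25, vaf_large=0.25), dict(qual=0.0)],
    )
    def test_default_boundaries_inclusive(self, overrides):
        ok, _ = first_reasons(bp_with(**overrides))
        assert ok

    def test_min_qual_inert_at_default_zero(self):
        ok, _ = first_reasons(bp_with(qual=0.0))
        assert ok
        ok, reasons = first_reasons(
            bp_with(qual=99.0),
            FilterParameters(min_QUAL=100.0),
        )
        assert not ok and "min_QUAL" in reasons

    def test_vaf_size_switch_uses_large_event_threshold(self):
        # event of 451 bp > median + MAD = 450 -> vaf_large is consulted
        bp = bp_with(pos1=1000, pos2=1451, vaf_small=0.0, vaf_large=1.0)
        ok, _ = first_reasons(bp)
        assert ok
        # event of 450 bp is not above the threshold -> vaf_small is consulted
        bp = bp_with(pos1=1000, pos2=1450, vaf_small=0.0, vaf_large=1.0)
        ok, reasons = first_reasons(bp)
        assert not ok and "min_af" in reasons

    def test_interchromosomal_uses_large_vaf(self):
        bp = bp_with(chrom2="chr2", vaf_small=0.0, vaf_large=1.0)
        ok, _ = first_reasons(bp)
        assert ok

    def test_either_vaf_requires_both_below(self):
        ok, reasons = first_reasons(bp_with(vaf_small=0.1, vaf_large=0.1))
        assert "min_af_EitherSmallOrLargeEvent" in reasons
        # one of the two VAFs at the threshold rescues the breakend from this
        # rule (the size-appropriate min_af may still fire separately)
        ok, reasons = first_reasons(bp_with(vaf_small=0.1, vaf_large=0.25))
        assert "min_af_EitherSmallOrLargeEvent" not in reasons

    def test_inexact_homology_not_applied_to_small_events(self):
        small = bp_with(pos1=1000, pos2=1500, inexact_homology=51)
        ok, _ = first_reasons(small)
        assert ok

    def test_strand_bias_only_on_small_events(self):
        small = bp_with(pos1=1000, pos2=1500, strand_bias=0.995)
        ok, reasons = first_reasons(small)
        assert not ok and "maximum_strand_bias" in reasons
        # extreme bias toward either strand is symmetric
        small = bp_with(pos1=1000, pos2=1500, strand_bias=0.004)
        assert not first_reasons(small)[0]
        large = bp_with(strand_bias=0.995)
        assert first_reasons(large)[0]

    def test_read_pair_and_split_read_applicability(self):
        params = FilterParameters(filter_noReadPairs=True, filter_noSplitReads=True)
        large = bp_with(has_read_pairs=False)
        ok, reasons = first_reasons(large, params)
        assert not ok and "filter_noReadPairs" in reasons
        small = bp_with(pos1=1000, pos2=1500, has_read_pairs=False)
        assert first_reasons(small, params)[0]
        small_nosr = bp_with(pos1=1000, pos2=1500, has_split_reads=False)
        ok, reasons = first_reasons(small_nosr, params)
        assert not ok and "filter_noSplitReads" in reasons
        large_nosr = bp_with(has_split_reads=False)
        assert first_reasons(large_nosr, params)[0]

    def test_poly_gc_run_boundary(self):
        assert not has_long_gc_run("G" * 15)
        assert has_long_gc_run("G" * 16)
        assert has_long_gc_run("C" * 16)
        assert not has_long_gc_run("GC" * 20)
        ok, reasons = first_reasons(bp_with(inserted_seq="G" * 16))
        assert not ok and "filter_polyGC" in reasons
        assert first_reasons(bp_with(inserted_seq="G" * 15))[0]
        off = FilterParameters(filter_polyGC=False)
        assert first_reasons(bp_with(inserted_seq="G" * 30), off)[0]

    def test_min_length_inversions_boundary(self):
        inv39 = bp_with(pos1=1000, pos2=1039, orient1=RIGHT, orient2=RIGHT)
        ok, reasons = first_reasons(inv39)
        assert not ok and "min_length_inversions" in reasons
        inv40 = bp_with(pos1=1000, pos2=1040, orient1=RIGHT, orient2=RIGHT)
        assert first_reasons(inv40)[0]

    def test_del_range_filter_with_inexact_homology(self):
        params = FilterParameters(range_filt_DEL_breakpoints=(500, 1000))
        mid = bp_with(pos1=1000, pos2=1700, inexact_homology=6)
        ok, reasons = first_reasons(mid, params)
        assert not ok and "range_filt_DEL_breakpoints" in reasons
        # homology of exactly 5 bp is tolerated
        assert first_reasons(bp_with(pos1=1000, pos2=1700, inexact_homology=5),
                             params)[0]
        # outside the range the rule does not fire
        assert first_reasons(bp_with(pos1=1000, pos2=1400, inexact_homology=6),
                             params)[0]

    def test_insert_vs_del_margin_small_events_only(self):
        # small DEL-like event of 20 bp with a 16 bp insert: 16 > 20 - 5
        small = bp_with(pos1=1000, pos2=1020, inserted_seq="A" * 16)
        ok, reasons = first_reasons(small)
        assert not ok and "dif_between_insert_and_del" in reasons
        ok2, _ = first_reasons(bp_with(pos1=1000, pos2=1020, inserted_seq="A" * 15))
        assert ok2

    def test_repeat_filter(self):
        params = FilterParameters(filter_overlappingRepeats=True)
        ok, reasons = first_reasons(bp_with(overlaps_repeat=True), params)
        assert not ok and "filter_overlappingRepeats" in reasons
        assert first_reasons(bp_with(overlaps_repeat=True))[0]  # off by default


class TestBreakpointLevel:
    def test_one_failing_breakend_discards_breakpoint(self):
        bp = bp_with()
        bp.be2.fragments = 2
        ok, reasons = breakpoint_passes(bp, FilterParameters(), STATS)
        assert not ok
        assert reasons[bp.be1.id] == []
        assert "min_Nfragments" in reasons[bp.be2.id]

    def test_both_fail_reports_both(self):
        bp = bp_with(fragments=1)
        ok, reasons = breakpoint_passes(bp, FilterParameters(), STATS)
        assert not ok
        assert all("min_Nfragments" in r for r in reasons.values())

    def test_both_pass_kept(self):
        ok, _ = breakpoint_passes(bp_with(), FilterParameters(), STATS)
        assert ok


# --------------------------------------------------------------------------- #
# Independent straight-line oracle of the published filter rules
# --------------------------------------------------------------------------- #

def oracle_breakend_passes(be, bp, p, stats):
    intra = bp.be1.chrom == bp.be2.chrom
    length = abs(bp.be2.pos - bp.be1.pos) if intra else None
    small = intra and length < p.max_to_be_considered_small_event
    lo_be, hi_be = bp.be1, bp.be2
    if not intra:
        hint = "inter"
    elif lo_be.orientation == hi_be.orientation:
        hint = "INV"
    elif lo_be.orientation == "right":
        hint = "DEL"
    else:
        hint = "TAN"
    if be.fragments < p.min_Nfragments:
        return False
    if be.qual < p.min_QUAL:
        return False
    if set(be.filter_tags) & set(p.wrong_FILTERtags):
        return False
    if (not intra) or length > stats.median + stats.mad:
        vaf = be.vaf_large
    else:
        vaf = be.vaf_small
    if vaf < p.min_af:
        return False
    if (be.vaf_small < p.min_af_EitherSmallOrLargeEvent
            and be.vaf_large < p.min_af_EitherSmallOrLargeEvent):
        return False
    if not small and be.inexact_homology > p.maximum_length_inexactHomology:
        return False
    if be.microhomology > p.maximum_microhomology:
        return False
    if small and max(be.strand_bias, 1 - be.strand_bias) > p.maximum_strand_bias:
        return False
    if p.filter_noReadPairs and not small and not be.has_read_pairs:
        return False
    if p.filter_noSplitReads and small and not be.has_split_reads:
        return False
    if p.filter_overlappingRepeats and be.overlaps_repeat:
        return False
    if p.filter_polyGC:
        seq = be.inserted_seq.upper()
        run, best, prev = 0, 0, ""
        for ch in seq + "$":
            if ch == prev and ch in "GC":
                run += 1
            else:
                run = 1 if ch in "GC" else 0
            best = max(best, run)
            prev = ch
        if best > 15:
            return False
    if hint == "INV" and length < p.min_length_inversions:
        return False
    if hint == "DEL":
        lo, hi = p.range_filt_DEL_breakpoints
        if lo <= length <= hi and be.inexact_homology > 5:
            return False
        if (small and p.dif_between_insert_and_del is not None
                and len(be.inserted_seq) > length - p.dif_between_insert_and_del):
            return False
    return True


def _random_param_sets(seed, n):
    rng = np.random.default_rng(seed)
    sets = [FilterParameters(), FilterParameters.unconservative()]
    for _ in range(n):
        sets.append(FilterParameters(
            min_Nfragments=int(rng.choice([0, 5, 10, 30])),
            min_af=float(rng.choice([0.0, 0.25, 0.5])),
            min_af_EitherSmallOrLargeEvent=float(rng.choice([0.0, 0.25])),
            min_QUAL=float(rng.choice([0.0, 100.0, 1000.0])),
            max_to_be_considered_small_event=int(rng.choice([100, 1000, 10000])),
            min_length_inversions=int(rng.choice([0, 40, 1000])),
            maximum_length_inexactHomology=float(rng.choice([math.inf, 50, 5])),
            maximum_microhomology=float(rng.choice([math.inf, 50, 10])),
            maximum_strand_bias=float(rng.choice([1.0, 0.99, 0.9, 0.6])),
            filter_noReadPairs=bool(rng.integers(2)),
            filter_noSplitReads=bool(rng.integers(2)),
            filter_overlappingRepeats=bool(rng.integers(2)),
            filter_polyGC=bool(rng.integers(2)),
            wrong_FILTERtags=[(), ("NO_ASSEMBLY",),
                              ("NO_ASSEMBLY", "LOW_QUAL")][rng.integers(3)],
            range_filt_DEL_breakpoints=[(-1, -1), (0, 1),
                                        (500, 1000)][rng.integers(3)],
            dif_between_insert_and_del=[None, 5, 10][rng.integers(3)],
        ))
    return sets


def test_filter_engine_agrees_with_brute_force_oracle():
    """The rule engine and an independent straight-line reimplementation agree
    on 10,000 random breakends across varied parameter sets."""
    bps = random_breakends(500, seed=42)
    n_checked = 0
    for params in _random_param_sets(1, 10):
        for bp in bps:
            for be in bp.breakends():
                got, _ = breakend_passes(be, bp, params, STATS)
                want = oracle_breakend_passes(be, bp, params, STATS)
                assert got == want, (be, params)
                n_checked += 1
    assert n_checked >= 10_000


def test_unconservative_passes_every_breakend():
    params = FilterParameters.unconservative()
    for bp in random_breakends(300, seed=7):
        ok, reasons = breakpoint_passes(bp, params, STATS)
        assert ok, reasons


@pytest.mark.parametrize(
    "tighten",
    [
        dict(min_Nfragments=20), dict(min_af=0.5), dict(min_QUAL=500.0),
        dict(maximum_microhomology=10), dict(maximum_length_inexactHomology=5),
        dict(maximum_strand_bias=0.7), dict(min_length_inversions=5000),
        dict(filter_noReadPairs=True), dict(filter_noSplitReads=True),
        dict(filter_overlappingRepeats=True), dict(filter_polyGC=True),
        dict(wrong_FILTERtags=("NO_ASSEMBLY", "LOW_QUAL")),
        dict(range_filt_DEL_breakpoints=(0, 100_000)),
        dict(dif_between_insert_and_del=10),
        dict(min_af_EitherSmallOrLargeEvent=0.6),
    ],
)
def test_tightening_any_threshold_shrinks_passing_set(tighten):
    from dataclasses import replace

    bps = random_breakends(400, seed=99)
    base = FilterParameters.unconservative()
    tight = replace(base, **tighten)
    loose_ids = {id(bp) for bp in filter_breakpoints(bps, base, STATS)}
    tight_ids = {id(bp) for bp in filter_breakpoints(bps, tight, STATS)}
    assert tight_ids <= loose_ids


class TestCoverageAndClassification:
    def _cov(self, value):
        return CoverageTable(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1_000_000],
             "relative_coverage": [value]}
        ))

    @pytest.mark.parametrize(
        "hint_orients,cov,expected",
        [
            ((RIGHT, LEFT), 0.05, "deletion"),
            ((LEFT, RIGHT), 2.0, "tandem_duplication"),
            ((RIGHT, LEFT), 0.5, "remaining"),
            ((RIGHT, LEFT), 0.1, "remaining"),   # boundary: "below" is strict
            ((LEFT, RIGHT), 1.8, "remaining"),   # boundary: "above" is strict
        ],
    )
    def test_classification_thresholds(self, hint_orients, cov, expected):
        o1, o2 = hint_orients
        bp = bp_with(orient1=o1, orient2=o2)
        dels, tans, rest = classify_del_tan([bp], self._cov(cov), FilterParameters())
        got = ("deletion" if dels else
               "tandem_duplication" if tans else "remaining")
        assert got == expected
        assert len(dels) + len(tans) + len(rest) == 1

    def test_partition_property(self):
        bps = [b for b in random_breakends(200, seed=13)
               if b.type_hint() in ("DEL-like", "TAN-like")]
        cov = CoverageTable(pd.DataFrame(
            {"chrom": [f"chr{i}" for i in (1, 2, 3)],
             "start": [0] * 3, "end": [2_000_000] * 3,
             "relative_coverage": [0.05, 1.0, 2.5]}
        ))
        dels, tans, rest = classify_del_tan(bps, cov, FilterParameters())
        assert len(dels) + len(tans) + len(rest) == len(bps)

    def test_missing_coverage_errors(self):
        bp = bp_with()  # on chr1
        cov_other = CoverageTable(pd.DataFrame(
            {"chrom": ["chrX"], "start": [0], "end": [1_000_000],
             "relative_coverage": [1.0]}
        ))
        with pytest.raises(KeyError):
            classify_del_tan([bp], cov_other, FilterParameters())


class TestCallSVs:
    def test_empty_input(self):
        cov = CoverageTable(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000],
             "relative_coverage": [1.0]}
        ))
        res = call_svs([], FilterParameters(), cov, STATS)
        assert res.all_records() == []
        assert res.unclassified == []

    def test_noiseless_end_to_end_identity(self):
        g = make_genome([120_000] * 4, seed=61)
        truth = simulate_svs(g, counts=8, seed=62, min_size=300)
        cat = emulate_caller(
            truth, g, 30.0, InsertSizeStats(400, 50),
            EmulatorNoiseModel.noiseless(), seed=63,
        )
        cov = expected_coverage_table(truth, g, 200)
        res = call_svs(cat, FilterParameters.unconservative(), cov, STATS)
        rep = compare_sets(res.svs, truth.by_type())
        assert rep.integrated.f_value == 1.0

    def test_repeats_covering_everything_discard_all(self):
        g = make_genome([100_000], seed=64)
        truth = simulate_svs(
            g, counts={"deletion": 5, "inversion": 5}, seed=65, min_size=300
        )
        cat = emulate_caller(
            truth, g, 30.0, STATS, EmulatorNoiseModel.noiseless(), seed=66
        )
        cov = expected_coverage_table(truth, g, 200)
        repeats = [GenomicInterval("chr1", 0, 100_000)]
        from dataclasses import replace

        params = replace(
            FilterParameters.unconservative(), filter_overlappingRepeats=True
        )
        res = call_svs(cat, params, cov, STATS, repeats=repeats)
        assert res.all_records() == []
        assert res.n_filtered == len(cat)

    def test_sv_tables_written(self, tmp_path):
        g = make_genome([120_000] * 3, seed=67)
        truth = simulate_svs(g, counts=4, seed=68, min_size=300)
        cat = emulate_caller(
            truth, g, 30.0, STATS, EmulatorNoiseModel.noiseless(), seed=69
        )
        cov = expected_coverage_table(truth, g, 200)
        res = call_svs(cat, FilterParameters.unconservative(), cov, STATS)
        paths = write_sv_tables(res, tmp_path)
        assert set(paths) == {
            "deletion", "inversion", "tandem_duplication", "translocation",
            "insertion", "unclassified",
        }
        for p in paths.values():
            assert p.exists()
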
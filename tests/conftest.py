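import numpy as np
import pytest

from svtune.breakends import (
    LEFT, RIGHT, BreakendRecord, Breakpoint, InsertSizeStats,
)
from svtune.io import Genome, GenomeSequence


def make_genome(lengths, seed=0, prefix="chr"):
    """Random i.i.d. genome with the given chromosome lengths."""
    rng = np.random.default_rng(seed)
    return Genome.from_sequences(
        GenomeSequence(f"{prefix}{i + 1}", "".join(rng.choice(list("ACGT"), size=L)))
        for i, L in enumerate(lengths)
    )


@pytest.fixture
def genome_factory():
    return make_genome


@pytest.fixture
def small_genome():
    return make_genome([50_000, 40_000, 30_000], seed=11)


@pytest.fixture
def insert_stats():
    return InsertSizeStats(median=400, mad=50)


def make_breakpoint(
    chrom1="chr1", pos1=10_000, orient1=RIGHT,
    chrom2="chr1", pos2=20_000, orient2=LEFT,
    bid="bp0", **annotations,
):
    """A breakpoint whose two breakends share the given annotations."""
    be1 = BreakendRecord(
        id=f"{bid}_1", chrom=chrom1, pos=pos1, orientation=orient1,
        partner_id=f"{bid}_2", **annotations,
    )
    be2 = BreakendRecord(
        id=f"{bid}_2", chrom=chrom2, pos=pos2, orientation=orient2,
        partner_id=f"{bid}_1", **annotations,
    )
    return Breakpoint(be1, be2)


@pytest.fixture
def breakpoint_factory():
    return make_breakpoint


def random_breakends(n, seed=0, n_chroms=3, chrom_len=1_000_000):
    """Annotated random breakpoints spanning the full annotation space."""
    rng = np.random.default_rng(seed)
    tag_pool = [(), ("NO_ASSEMBLY",), ("LOW_QUAL",), ("NO_ASSEMBLY", "LOW_QUAL")]
    bps = []
    for i in range(n):
        c1 = f"chr{rng.integers(1, n_chroms + 1)}"
        c2 = c1 if rng.random() < 0.8 else f"chr{rng.integers(1, n_chroms + 1)}"
        p1 = int(rng.integers(100, chrom_len))
        if c1 == c2:
            # mix of small and large events around the applicability boundaries
            length = int(rng.choice([
                rng.integers(10, 500), rng.integers(500, 2000),
                rng.integers(2000, 100_000),
            ]))
            p2 = min(p1 + length, chrom_len + 100_000)
        else:
            p2 = int(rng.integers(100, chrom_len))
        ins_len = int(rng.choice([0, rng.integers(1, 10), rng.integers(10, 30)]))
        base = "".join(rng.choice(list("ACGT"), size=ins_len))
        if rng.random() < 0.1:
            base = "G" * int(rng.integers(10, 25))
        ann = dict(
            qual=float(rng.choice([0, 50, 150, 800, 2000]) + rng.random()),
            filter_tags=frozenset(tag_pool[rng.integers(len(tag_pool))]),
            fragments=int(rng.integers(0, 60)),
            vaf_small=float(rng.random()),
            vaf_large=float(rng.random()),
            inexact_homology=int(rng.choice([0, 3, 6, 40, 60])),
            microhomology=int(rng.choice([0, 10, 49, 50, 51, 80])),
            strand_bias=float(rng.random()),
            has_read_pairs=bool(rng.random() < 0.8),
            has_split_reads=bool(rng.random() < 0.8),
            inserted_seq=base,
            overlaps_repeat=bool(rng.random() < 0.2),
        )
        ann2 = dict(ann)
        ann2["fragments"] = int(rng.integers(0, 60))
        ann2["vaf_small"] = float(rng.random())
        be1 = BreakendRecord(
            id=f"r{i}_1", chrom=c1, pos=p1,
            orientation=RIGHT if rng.random() < 0.5 else LEFT,
            partner_id=f"r{i}_2", **ann,
        )
        be2 = BreakendRecord(
            id=f"r{i}_2", chrom=c2, pos=p2,
            orientation=RIGHT if rng.random() < 0.5 else LEFT,
            partner_id=f"r{i}_1", **ann2,
        )
        bps.append(Breakpoint(be1, be2))
    return bps


@pytest.fixture
def random_breakend_factory():
    return random_breakends
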
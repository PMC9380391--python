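# Methods

This note documents the models, rules and numerical choices behind `svtune`,
in the order data flows through the package.

## Coordinates and randomness

All in-memory and tabular coordinates are 0-based half-open; only the VCF
readers/writers convert to and from 1-based positions. Every stochastic stage
draws from an RNG derived deterministically from one integer seed plus a
stage name (`svtune.io.substream`), so a fixed seed reproduces byte-identical
simulations, catalogs and optimization results.

## SV simulation

A truth set is a list of typed records: deletions, inversions and tandem
duplications carry one affected interval; interspersed insertions carry an
origin interval, a destination position and a cut/copy flag; translocations
carry one breakpoint per chromosome and an inverted flag.

Placement is rejection sampling (up to 1,000 attempts per record) under the
constraint that edited intervals keep at least 200 bp of clearance, which
keeps junction flanks locally unique and all edits conflict-free. SV lengths
are drawn uniformly from [1×10⁻⁴, 1.5×10⁻³] of the total genome length with a
50 bp floor, so variant size scales with the genome (a 12 Mb genome gets
kb-scale events); the constants are configurable. Translocations are modeled
as whole-arm balanced swaps with the breakpoint uniform in the central 80% of
each chromosome (no centromere annotation is assumed), and each chromosome
participates in at most one translocation — so a genome with *n* chromosomes
supports at most ⌊n/2⌋ of them per truth set. Insertions prefer a destination
on a different chromosome when one exists, which keeps their junction
signature unambiguous for the grouping stage.

Applying a truth set rebuilds each chromosome left-to-right from its edit
list (maintaining an original→rearranged coordinate map), then inserts
origin segments at mapped destinations, then performs the translocation arm
swaps at mapped positions. The tests verify that the total length change
equals the copy-gain minus deletion balance and that every junction's
2×50 bp flank string is realized in the rearranged sequence.

Read simulation draws fragments from a ploidy-weighted mix of the reference
and the rearranged genome: `haploid`/`diploid_homo` take every fragment from
the variant genome, `diploid_hetero` mixes 1:1, and `ref:N_var:M` mixes N:M.
Pair count is coverage × genome length / (2 × read length); fragment lengths
follow Normal(median, 1.4826 × MAD) truncated at the read length; mates are
reverse-complemented fragment ends; base errors are independent substitutions
at 0.1% (configurable, no indels — read errors are not the object of study).
Source genome, chromosome, start and insert size are encoded in read names,
which is how the distributional tests audit the simulator.

## Breakends, breakpoints and the caller emulator

A breakend is a position plus an orientation: `right` when the novel
adjacency departs to the right of the position, `left` for the converse. For
an intrachromosomal breakpoint, (right at the lower position, left at the
higher) is DEL-like, the converse TAN-like, and equal orientations INV-like;
interchromosomal junctions form their own class and have no event length.
Each SV type implies a fixed junction set: a deletion one DEL-like junction,
a tandem duplication one TAN-like, an inversion two INV-like junctions (one
right-right, one left-left), a balanced translocation two interchromosomal
junctions sharing both loci, and an insertion two junctions sharing the
destination position (plus, for cut-and-paste, a DEL-like excision junction
at the origin).

The VCF dialect stores annotations as typed INFO keys (supporting fragments,
small/large-event VAFs, inexact/microhomology lengths, strand bias,
read-pair/split-read support, repeat overlap), QUAL in the QUAL column and
flags like `NO_ASSEMBLY` in FILTER; inserted sequence lives in the bracketed
ALT. Unknown or absent keys fall back to permissive defaults, and unpaired
records are dropped with a count.

The **caller emulator** stands in for an external breakpoint caller: each
truth junction is emitted with probability `detection_prob`, positions
jittered by Normal(0, `jitter_sd`), annotations drawn from "true"
distributions (lognormal QUAL, Poisson(coverage × VAF) fragments, short
exponential homologies, Beta strand bias, occasional `NO_ASSEMBLY`); false
junctions are added at `false_rate_per_mb`, with lower QUAL, ~2 supporting
fragments, long homologies, extreme strand bias and frequent `NO_ASSEMBLY`.
A fraction of false events (`false_coordinated_prob`, default 0.2) are
emitted as *coordinated* junction pairs mimicking inversions or
translocations — caller-consistent artifacts that coverage evidence cannot
veto, which is what makes breakend-level filters worth optimizing. Two
special regimes exist: `noiseless()` (detection 1, no false events, exact
positions, perfect annotations — the identity-test limit) and
`planted_fragments(k)` (false breakends get < k fragments, true ones ≥ k,
all other annotations drawn from the *true* distributions, so fragment count
is the only separator — the recovery-test regime). The expected VAF follows
the ploidy (1.0 haploid/homozygous, 0.5 heterozygous, M/(N+M) for
`ref:N_var:M`), and an idealized coverage table is synthesized from the
truth on the same ploidy (deleted regions at 1−VAF, duplicated at 1+VAF,
Gaussian window noise sd 0.05 in noisy regimes).

What the emulator does **not** model: alignment artifacts correlated with
repeats, coverage-dependent detection probability, inter-annotation
correlations beyond the true/false dichotomy, and single breakends without a
partner. Passing tests therefore demonstrate the correctness of the
filtering/optimization machinery under a controlled, separable noise model —
not calling accuracy on real reads.

## The filter engine

Eighteen parameters, defaults in parentheses, applied per breakend; a
breakpoint is discarded if *either* breakend fails any enabled rule.
Threshold wording is literal: minima/maxima are inclusive at the printed
value, coverage comparisons are strict, the DEL length range is inclusive.

* `min_Nfragments` (5) — minimum supporting fragments.
* `min_af` (0.25) — minimum size-appropriate VAF; `vaf_large` is consulted
  when the event length exceeds insert median + MAD (interchromosomal events
  count as large), `vaf_small` otherwise.
* `min_af_EitherSmallOrLargeEvent` (0.25) — rejects only when *both* VAFs
  fall below it.
* `min_QUAL` (0) — inert at its default.
* `max_to_be_considered_small_event` (1000 bp) — not a filter itself; events
  shorter than this (intrachromosomal only) are "small", which gates the
  rules below. Interchromosomal breakpoints are never small (their event
  length is undefined).
* `min_length_inversions` (40 bp) — INV-like junctions only.
* `maximum_length_inexactHomology` (50 bp) — non-small events only.
* `maximum_microhomology` (50 bp) — all events.
* `maximum_strand_bias` (0.99) — small events only; the statistic is folded
  (max of the plus-strand fraction and its complement) so bias toward either
  strand counts.
* `filter_noReadPairs` (off) — non-small only; `filter_noSplitReads` (off) —
  small only; `filter_overlappingRepeats` (off) — needs a repeat annotation;
  `filter_polyGC` (on) — rejects inserted G or C homopolymer runs > 15 bp.
* `wrong_FILTERtags` (`{NO_ASSEMBLY}`) — any listed FILTER tag rejects.
* `range_filt_DEL_breakpoints` ([0, 1]) — DEL-like events whose length lies
  in the range *and* whose inexact homology exceeds 5 bp are rejected;
  effectively inert at the default range.
* `dif_between_insert_and_del` (5 bp) — small DEL-like events whose inserted
  sequence is longer than event length minus the margin are rejected; `None`
  disables the rule.
* `max_rel_coverage_to_consider_del` (0.1) and
  `min_rel_coverage_to_consider_dup` (1.8) — not discard rules but
  classification thresholds: DEL-like breakpoints whose spanned relative
  coverage is strictly below the first become deletions, TAN-like ones
  strictly above the second become tandem duplications, everything else goes
  to the unclassified table. The defaults are conservative choices suited to
  haploid genomes or homozygous variants; heterozygous events sit near 0.5 /
  1.5 and need relaxed thresholds — exactly the kind of fact the optimizer
  discovers.

The *unconservative* parameter set is the permissive extreme of every rule
(0 thresholds, infinite caps, booleans off, empty tag set, classification
thresholds at 1.0); it provably passes every syntactically valid breakend and
serves as the pruning baseline.

Breakpoint-to-SV summarization (the surrogate for an external graph-based
summarizer) proceeds: filters → insertion grouping (two junctions whose
destination-side positions agree within 50 bp, with the origin interval's
coverage deciding copy (≥ dup threshold) vs cut (≤ del threshold), undecided
pairs left alone; a cut insertion also consumes the nearest matching origin
excision junction within 1 kb) → translocation grouping (two interchromosomal
junctions sharing both loci within 1 kb with complementary — or, for
inverted translocations, right-right/left-left — orientations) → inversion
pairing (a right-right with a left-left junction sharing endpoints within
1 kb) → coverage confirmation of the remaining DEL-like/TAN-like junctions.
Everything left lands in the unclassified table, including lone INV-like
junctions and complex events the grouping does not model. The 50 bp
destination tolerance (rather than 1 kb) prevents accidental grouping of
unrelated nearby junctions; genuine insertion junctions disagree only by
twice the position jitter.

## Accuracy

Two SVs match per the type-specific conjunction: interval types need the same
chromosome, reciprocal overlap ≥ 75% (intersection relative to *each*
region — the reciprocal denominator is a package choice, config-exposed with
a query-only alternative) and both breakend distances strictly < 50 bp;
insertions additionally need equal origin/destination chromosomes, equal
cut/copy mode and insertion sites < 50 bp apart; translocations need the same
(unordered) chromosome pair, equal inverted state and both positions < 50 bp
apart. TP/FP/FN follow the match-at-least-one convention with no one-to-one
assignment; precision, recall and F use pessimistic 0/0 conventions
(undefined → 0), which keeps the optimizer's objective monotone. Integrated
metrics are computed on the merged sets (equivalently, summed counts, since
cross-type pairs never match).

## Parameter optimization

The grid is a per-parameter candidate list (presets: `small` ≈ 3.7×10⁵ filter
combinations × 9 coverage pairs before pruning, `medium` and `large` larger);
every list contains the printed default and the unconservative extreme.
**Pruning** evaluates each candidate with all other parameters unconservative
and discards values whose passing breakpoint set equals that of an already
retained, more permissive value (the published criterion — no change against
the unconservative baseline — is the special case of the first retained
value). Because each rule's effect on a breakend depends only on its own
parameter (given the smallness cutoff), value-equivalence under this
single-toggle test implies outcome-equivalence in every combination, so
pruning is outcome-preserving; the smallness cutoff itself is outer-looped
where a grid carries several values. The two coverage-classification
thresholds are exempt from pruning since they act after filtering.

**Search** never enumerates the raw product: combinations are deduplicated
progressively on the induced set of passing breakpoints, keeping for each
distinct outcome the most permissive representative in a documented parameter
order. Each distinct surviving set is summarized once per coverage-threshold
pair and scored against the truth; the per-SV-type argmax of F is the
per-simulation winner, with ties resolved toward the permissive
representative (deterministic across platforms). A configurable budget
(default 10⁷ raw combinations) guards against oversized custom grids.

**Final selection** pools the per-(simulation, ploidy, type) winners plus the
default set, re-scores every candidate on every instance, and picks the
candidate maximizing the minimum F over all (instance, type) cells that
contain at least one truth record — ties broken by mean F, then by fewer
active filters, then by candidate order. Max-min is a deliberately
conservative reading of "works well for all simulations"; it is the package's
choice and is isolated in `select_final_parameters` for easy substitution.
Two template genomes are the default, which is the minimum that lets the
final selection measure overfitting at all.

`ParameterOptimizer` wraps this as a model object built from a genome plus a
`SimulationConfig`; `fit(seed)` returns an `OptimizationResults` with the
selected `FilterParameters`, the per-instance accuracy report (also for the
default parameters, for comparison) and a `summary()` table. The default
pipeline derives catalogs from the emulator rather than re-consuming
simulated reads, since alignment and external calling are out of scope; read
simulation is exercised and tested independently.

## Homologous and known-SV regions

Homologous pairs come from tiling the genome into non-overlapping 500 bp
windows and locally aligning each window against the whole genome (both
strands) with exact 11-mer seeding and ungapped X-drop extension (match +1,
mismatch −2, X-drop 20). Significance uses Karlin–Altschul e-values with
K = 0.41 and λ = 1.28 — declared approximations of the ungapped blastn
defaults; the affine-gap parameters (open 5, extend 2) are reserved for a
gapped extension stage not currently implemented, which makes the detector
conservative for diverged homologies (tests plant exact duplications). Hits
need e-value < 10⁻⁵ and must cover > 50% of the window; hits whose aligned
span overlaps the query window's own locus are excluded (slightly broader
than excluding only the exact self-hit, and config-free). A precomputed
tabular (outfmt-6-style) alignment can be supplied instead of the built-in
aligner. Known-SV regions are simply the ±100 bp neighbourhoods of every
junction of the provided SV tables, clipped to chromosome bounds and paired
per junction; both region flavours feed the simulator's `regions` argument.

## CNV support

Coverage correction regresses relative coverage on GC content, then
mappability, then distance to the nearer chromosome end (the telomere proxy),
dividing by each lowess trend (span 0.3, multiplicative model — both
unspecified upstream, both config-exposed) and renormalizing to median 1.
Below 30 windows the trend is statistically unfittable and correction is
skipped with a warning. Constant predictors are no-ops, so ranking within
predictor-homogeneous strata is preserved. Mappability defaults to an exact
k-mer (k = read length) uniqueness fraction per window — a faithful
stand-alone proxy; an externally computed track can be supplied instead.

Consensus across per-bin CNV tracks takes, per bin, the copy number closest
to 1 (ties: 1 if any track says 1, else the smaller value) and requires an
identical binning. External CNV callers are not re-implemented; a simple
round-and-merge segmenter on corrected coverage makes the consensus path
testable stand-alone. Coverage CNVs reciprocally overlapping an SV-derived
CNV (deletion, tandem duplication, copy-insertion origin) by ≥ 80% are
removed as redundant. The unified VCF decomposes every variant into
DEL/DUP/TDUP/BND/insertionBND rows sharing a `variantID`, with unique row
IDs and a repeat-overlap INFO flag when a repeat annotation is given; the
round trip back to grouped events is tested.

## Problem sizes

The test suite and the acceptance script run on synthetic genomes of 0.4–0.7
Mb across 4–6 chromosomes with 5–15 SVs per type and the `small` grid preset
— sizes chosen so every property (noiseless identity, 20-seed planted-rule
recovery, pruning soundness, oracle equivalences on 10⁴ random breakends)
completes in seconds while still exercising all five SV types, both ploidy
regimes and several hundred breakpoints per catalog.

## Known limitations

* Translocation capacity is bounded by chromosome count; multi-way or
  segmental translocations and complex nested events are not simulated and
  are routed to the unclassified table when called.
* The emulator's annotation distributions are independent across breakends;
  real callers produce correlated artifacts.
* The self-aligner is ungapped; diverged (indel-containing) homologies below
  ~95% identity over a window may be missed.
* The max-min final-selection rule and the reciprocal-overlap denominator are
  documented package choices among several defensible conventions; both are
  config-exposed.
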
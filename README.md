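# svtune

Sample-adaptive structural-variant (SV) calling, at desk scale.

Short-read SV callers are usually shipped with filtering defaults tuned on
human data, and those defaults transfer poorly to other genomes, ploidies,
coverages and read geometries. `svtune` implements the computational core of a
sample-adaptive calling framework: it simulates SVs and paired-end reads on
*your* reference genome, pushes the resulting breakend calls through a
tunable rule engine (the full set of gridss-style breakend filters plus
coverage-based confirmation of deletion-like and tandem-duplication-like
breakpoints), and searches a parameter grid for the filter combination that
maximizes the F-value (harmonic mean of precision and recall) against the
known simulated truth. The selected parameters — and an honest report of the
accuracy they achieve on the training simulations — are the output.

Everything runs on synthetic data end to end: a built-in caller emulator
generates annotated breakend catalogs from a truth set plus a noise model, so
the optimizer, the filter engine and the scoring rules are all testable
without any external aligner or breakpoint caller.

## What is in the box

| module | contents |
| --- | --- |
| `svtune.io` | FASTA/BED/BEDPE/TSV readers and writers, 0-based half-open coordinates, seeded RNG substreams |
| `svtune.simulate` | SV truth-set simulation (deletions, inversions, tandem duplications, balanced translocations, cut/copy insertions), template-genome derivation, wgsim-like paired-end read simulation with ploidy mixing (`haploid`, `diploid_homo`, `diploid_hetero`, `ref:N_var:M`), read downsampling |
| `svtune.breakends` | Breakend/breakpoint model, VCF 4.2 BND parsing and writing, insert-size statistics (median + MAD), the caller emulator |
| `svtune.filtering` | The 18 breakend filter parameters with their printed defaults, orientation-based breakpoint typing (DEL-like / TAN-like / INV-like / interchromosomal), coverage-based DEL/TAN confirmation, grouping of junction pairs into inversions, translocations and insertions |
| `svtune.accuracy` | Type-specific SV matching (75% reciprocal overlap, breakends < 50 bp), precision / recall / F-value per type and integrated |
| `svtune.optimize` | Grid presets, outcome-preserving pruning, per-simulation argmax-F search, cross-simulation max-min-F selection; `ParameterOptimizer` / `OptimizationResults` model objects |
| `svtune.regions` | Homologous-region pairs by windowed self-alignment (500 bp windows, Karlin–Altschul e-values), ±100 bp regions around known SV breakends — both emitted as BEDPE for region-constrained simulations |
| `svtune.cnv` | Relative-coverage correction by sequential lowess on GC / mappability / telomere distance, conservative consensus across CNV tracks, 80% reciprocal-overlap redundancy removal, unified VEP-compatible VCF export |

## Worked example

Optimize filter parameters for a 600 kb six-chromosome genome, training on
two template simulations with twelve SVs per type:

```python
import numpy as np
from svtune import ParameterOptimizer, SimulationConfig
from svtune.io import Genome, GenomeSequence

rng = np.random.default_rng(0)
genome = Genome.from_sequences(
    GenomeSequence(f"chr{i+1}", "".join(rng.choice(list("ACGT"), size=100_000)))
    for i in range(6)
)
model = ParameterOptimizer(genome, SimulationConfig(nsimulations=2, nvars=12))
res = model.fit(seed=1)
print(res.summary())
```

This prints:

```
========================================================================
                     Filter-parameter optimization
========================================================================
Simulations: 2 instance(s); grid preset: small; seed: 1
Mean F (optimized): 0.872    Mean F (default): 0.434
------------------------------------------------------------------------
Selected parameters (differences from default):
  min_Nfragments: 5 -> 0
  min_af: 0.25 -> 0.0
  min_af_EitherSmallOrLargeEvent: 0.25 -> 0.0
  min_length_inversions: 40 -> 0
  maximum_length_inexactHomology: 50 -> 'inf'
  maximum_microhomology: 50 -> 'inf'
  maximum_strand_bias: 0.99 -> 1.0
  filter_polyGC: True -> False
  wrong_FILTERtags: ['NO_ASSEMBLY'] -> []
  range_filt_DEL_breakpoints: [0, 1] -> [-1, -1]
  dif_between_insert_and_del: 5 -> None
  max_rel_coverage_to_consider_del: 0.1 -> 1.0
  min_rel_coverage_to_consider_dup: 1.8 -> 1.4
------------------------------------------------------------------------
Accuracy of the selected parameters:
simulation  ploidy             svtype  n_truth  precision  recall     F
      sim0 haploid           deletion       12      1.000   1.000 1.000
      sim0 haploid          inversion       12      1.000   0.917 0.957
      sim0 haploid tandem_duplication       12      1.000   0.917 0.957
      sim0 haploid      translocation        3      0.400   0.667 0.500
      sim0 haploid          insertion       12      0.900   0.750 0.818
      sim1 haploid           deletion       12      1.000   1.000 1.000
      sim1 haploid          inversion       12      1.000   0.917 0.957
      sim1 haploid tandem_duplication       12      1.000   0.833 0.909
      sim1 haploid      translocation        3      0.667   0.667 0.667
      sim1 haploid          insertion       12      1.000   0.917 0.957
========================================================================
```

Reading this: under the emulator's default noise model, the conservative
default filters (which require de novo assembly support and haploid-grade
coverage thresholds) reach a mean F-value of 0.434 on the training
simulations; the selected parameters relax exactly the rules that were
discarding true breakends here and roughly double it to 0.872, mostly by
improving recall. The per-row table is the accuracy report a user would
consult to judge how trustworthy calls on a real sample of this genome,
coverage and read geometry would be. `res.params` is a `FilterParameters`
object; `res.save_params("best.json")` writes it in the JSON form that
`svtune call --params` consumes.

The same run from a shell:

```bash
svtune optimize --genome genome.fasta --nsim 2 --nvars 12 --seed 1 \
    --out-params best.json --out-report report.tsv
svtune call --vcf breakends.vcf --params best.json --coverage windows.tsv
svtune score --called calls/deletions.tab --known truth/deletions.tab
```

## Scope notes

`svtune` deliberately re-implements only the bespoke computational layer of
the calling framework. Read alignment, the external breakpoint caller, the
graph-based breakpoint-to-SV summarizer and external CNV segmenters are out
of scope: their roles are played by the caller emulator, the orientation-based
typer/grouper, and per-bin CNV tracks consumed as input, respectively. See
`docs/methods.md` for the model, its assumptions and known limitations.
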
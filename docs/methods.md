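# Methods

This note documents the models and procedures implemented in centrochip,
the parameters that matter, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The enrichment statistic

The core quantity is a per-window depth-normalised ChIP/input ratio.
Let `c_w` and `i_w` be the number of mapped reads overlapping window `w`
in the ChIP and input libraries, and `C`, `I` the mapped totals. Then

    ratio_w = (c_w / C) / (i_w / I).

Windows are consecutive, nonoverlapping, 150 bp wide; the final window of
each chromosome is partial and retained with its true extent. A read
counts in every window its `[start, start + 49)` interval overlaps by at
least one base (so a boundary-spanning read counts twice; total window
counts can exceed, never undercount, the mapped-read total). An
alternative assign-by-read-start mode exists but is off by default.
Windows with `i_w < 10` raw input reads are masked and excluded from all
downstream statistics — a tiny denominator makes the ratio noise, not
signal. The mask applies to raw input counts, before normalisation.

Totals are mapped-read totals (reads surviving QC but failing to map do
not enter the denominator). Clean-read totals would differ by well under
1% at the simulator's error rates; the choice is recorded here because
either reading is defensible.

Interpretation note: under enrichment the statistic's background sits
*below* 1, because the ChIP library spends a fixed read budget and
concentrates it on the enriched regions, depleting everything else
relative to input. The background is therefore always estimated
empirically — the arithmetic mean of unmasked ratios over a configurable
non-centromeric reference interval (the demo uses a 100 kb arm interval
on the last chromosome) — and never assumed to be 1.

**Peaks.** No quantitative peak definition came with the procedure being
reproduced, so the package defines one: a peak is a merged run of
unmasked windows with `ratio >= fold_threshold * background`
(`fold_threshold` default 3.0), where runs separated by at most
`merge_gap` windows (default 1) are joined. Per chromosome, the call
with the largest mean ratio is flagged as the centromere candidate. Both
knobs are config/CLI options. No significance testing is attached to
peaks — the statistic of interest is the ratio itself, and the synthetic
truth makes calibration directly checkable.

## Mapping model

Reads are placed ungapped on both strands, allowing up to
`max_mismatches` substitutions (default 2 for 49 bp reads). Only the
best stratum — every placement at the minimum achievable mismatch count —
is reported; a 0-mismatch hit suppresses 1–2-mismatch hits. A read with
k tied best placements is assigned to one of them uniformly at random
(multiplicity k is recorded, SAM tag `XH`). This random assignment is the
mechanism under study: it spreads repeat-derived reads evenly over
near-identical copies, which is what makes a homogeneous repeat array
show enrichment at all, and equally what donates signal to any
near-identical copy elsewhere.

Completeness is guaranteed by a pigeonhole seed index: the read is cut
into `max_mismatches + 1` contiguous partitions (17/16/16 bp for the
default), and any placement within the mismatch budget must match at
least one partition exactly. Exact lookups of each partition on each
strand enumerate a candidate superset; candidates are verified by
vectorised Hamming counting, deduplicated, and reduced to the best
stratum. N bases count as mismatches against everything (in read or
genome), which keeps QC-surviving reads (≤ 2 Ns at 49 bp) mappable.
Coordinates are 0-based, leftmost-on-forward-strand, regardless of read
strand. A brute-force full-scan oracle ships with the package
(`mapping.brute_force_best_hits`) and the test suite asserts exact
stratum equality against it; the two paths share no code beyond the base
encoding.

Gapped alignment, mapping quality and paired-end logic are out of scope:
the simulator produces substitution errors only, so ungapped Hamming
placement is exact for the data the package generates.

## Synthetic genome

Chromosome arms are i.i.d. per-base sequence at a configurable GC
fraction (default 0.46). Real arms contain genes and degenerate
retroelements, but the enrichment statistic only requires mappable,
non-repetitive context; anything repeat-like can be represented
explicitly as a planted duplicate. Each chromosome carries one
centromeric tandem array: `copy_count` copies of a master unit
(default 113 × 177 bp ≈ 20 kb), each copy independently mutated at
`per_copy_divergence` substitutions per base (default 0.02, giving
~96% pairwise copy identity — deliberately inside the regime where 49 bp
reads cannot always separate copies). The master unit is drawn with an
*exact* A+T base count at the requested AT fraction (default 0.70,
AT-rich as centromeric units are): the whole array inherits the unit's
composition, so per-base sampling noise in a 177 bp unit would otherwise
dominate the array-level AT fraction.

Divergence is substitution-only throughout; percent identity therefore
reduces to Hamming identity. How the published 96%/93% repeat-similarity
figures were computed (alignment method, gap treatment) is not stated
anywhere, so this package adopts substitution-only identity and flags it;
an alignment-based path exists in `ambiguity.unit_similarity` for
unequal-length input.

Planted duplicates copy a source interval (typically centromeric) to an
arm position, mutated to a *target* identity by an exact substitution
count — a target is a specification, unlike divergence which is a
process, hence the different sampling. The default fixtures use 97%
identity for an indistinguishable pair (above the 96% bound) and 90% for
a distinguishable one (below the 93% bound).

The minichromosome contig (default 42,529 bp) is a tandem array of a
177 bp unit laid out palindromically: the halves read outward from the
inversion point (default the midpoint) as reverse complements, truncated
at the shorter side. The invariant is assertable by direct string
comparison and is property-tested over random sizes and inversion
points.

Coordinates are 0-based half-open internally and in BED; FASTA output is
line-wrapped at 70 columns and byte-identical for identical spec + seed.

## Read simulation and QC

Fragment start positions are drawn with probability proportional to a
per-base fold-occupancy profile (baseline 1, configurable folds per truth
feature; the demo uses 10-fold on centromeres, 3-fold on the
minichromosome). Fragment lengths are truncated normal (mean 200 bp,
sd 50, floored at the read length, clipped at chromosome ends) — no
sonication profile was available to fit, and only fragment-scale
locality matters at 150 bp windows. One single-end 49 bp read is taken
from the 5' end of a uniformly chosen strand; substitution errors occur
independently per base at `error_rate` (default 0.005, typical of the
platform generation being emulated), and the quality string encodes the
Phred score implied by that rate (capped Q40). The simulator does not
model PCR duplicates, GC bias or paired ends.

Artifact injection degrades disjoint read subsets to exercise the QC
rules: an adapter read-through prefix (read stays 49 bp), N injections
(⌊0.05·49⌋+1 = 3 Ns, the smallest count tripping the 5% rule), or
quality downgrades (⌊0.20·49⌋+1 = 10 bases to Q2, tripping the 20%
rule).

QC removes, in order, with first-match attribution: (1) reads whose
prefix is the (configurable) adapter — removal, not trimming, matching
the cleaning behaviour being reproduced; (2) reads with N fraction
strictly above 5% of read length; (3) reads with strictly more than 20%
of bases below quality 10. The inequalities are strict: 2 Ns (4.1%) and
9 sub-Q10 bases (18.4%) survive at 49 bp, and Q10 exactly is not "below
10". The rule *order* was unspecified in the source procedure; the fixed
order above is this package's choice and the per-rule counts in
`QCReport` depend on it. Quality encoding is Phred+33 throughout.
Whether the N rule means ">5% of length" or ">5 Ns" was ambiguous; the
fraction-of-length reading is implemented as written.

## Repeat-ambiguity diagnostics

`cross_map_rate(A, B)` enumerates every 49-mer of feature A (all of
them when A ≤ 5 kb, otherwise a seeded sample of 10,000) and reports the
fraction whose best-stratum placements include a position in B. For an
exact copy the rate is 1 by construction; as a copy diverges, a k-mer
cross-maps only where its window is locally identical, so the rate decays
roughly like (identity)^49. The packaged identity sweep diverges *one*
duplicate cumulatively (substitution positions drawn once, applied
incrementally), under which the rate is non-increasing by construction;
regenerating independent duplicates per step would make the tail of the
sweep noisy rather than monotone.

Peak annotation: a peak overlapping a truth centromere is labelled
`centromeric`; a peak on the minichromosome contig is labelled
`repeat_contig` (enrichment there is a separate question from arm
artifacts); any other peak is scanned, window by window, for its best
ungapped identity against any truth centromere (both strands), and
labelled `likely_artifact` at ≥ 96% identity, `independent` otherwise.
The window scale (150 bp) is used because that is the scale at which
cross-mapping manufactures peaks. The published similarity statements
refer ambiguously to repeat units or whole arrays; both granularities are
exposed (`unit_similarity` on units, the annotation scan on arbitrary
intervals).

## AP-MS subcomplex inference

Evidence rows (bait, detected protein, peptide count) are filtered at a
minimum of two peptides, pivoted to a boolean bait × protein matrix
(duplicate rows aggregated with a warning), and clustered: baits a and b
are joined when a's purification detects b *and* b's detects a, and
subcomplexes are the connected components of that reciprocal graph.

The published assignments were expert judgment over a supplementary
table; the reciprocal-component formalisation is this package's
reconstruction, not the original procedure, and is documented as such.
Two refinements make it behave sensibly:

- **Support peeling.** Member support = fraction of a component's bait
  purifications detecting that member. While any multi-member component
  has a member below `support_threshold` (default 0.75), the
  lowest-support member (ties alphabetical) is peeled off; peeled baits
  are re-clustered among themselves. A single sporadic false-positive
  detection can forge one reciprocal edge and weld two real subcomplexes
  together; inside such a chimera most members are seen by only a
  minority of baits, so peeling restores the blocks. Noise-free matrices
  are unaffected (all supports are 1).
- **Prey attachment.** A protein never used as bait joins the component
  detecting it in the largest fraction of bait purifications, if that
  fraction reaches the threshold; otherwise it stays a singleton.

An optional frequency filter can drop contaminant-like preys detected in
more than 80% of all purifications — a stand-in for the informal
"apparently specific" criterion, which was never defined quantitatively.
Output is deterministic and invariant to row/column permutation.

## Seeding and determinism

One global seed governs a pipeline run; each stage derives its generator
from `SeedSequence([seed, crc32(stage_name)])`, so stages are independent
and individually re-runnable, and two runs with identical config + seed
produce byte-identical outputs (asserted in the acceptance suite).

## Standard problem sizes

The demo genome is 4 × 400 kb chromosomes plus the 42,529 bp
minichromosome; benchmark experiments use 20× coverage per library for
ratio calibration, 5× for demo-genome recovery, and 10× for the
single-chromosome duplicate screen (400 kb, 2 kb duplicate). These sizes
keep a complete run in seconds-to-minutes on one CPU while leaving every
window with an expected input count comfortably above the mask threshold
(~20 reads/window at 5×). They emulate megabase chromosomes at reduced
length only — nothing in the statistic depends on chromosome length
beyond window counts.

## What the synthetic benchmark does and does not show

The generator reproduces the features that drive the analysis: AT-rich
tandem centromeric arrays with realistic within-array identity,
palindromic minichromosome repeats, near-identical arm copies, 49 bp
single-end reads with substitution errors and QC-able artifacts. It does
not contain genes, transcription-coupled coverage structure, GC bias,
PCR duplicates, indels, or chromatin-dependent fragmentation. Passing
tests therefore demonstrate that the *pipeline logic* is correct and the
statistic calibrated under its stated model — they do not certify
performance on real libraries, where background is structured and the
input itself is biased. The false-positive mechanism, however, is a
sequence-level phenomenon and transfers directly: any ≥ 96%-identical
copy of bound sequence longer than a read will attract signal under
random multi-mapper assignment, on real data exactly as here.

## Known limitations

- Substitution-only sequence model end to end (no indels anywhere).
- Adapter handling is whole-read removal by exact prefix match, not
  trimming or fuzzy matching.
- Best-stratum-only mapping is fixed behaviour; sampling among all
  ≤ 2-mismatch hits (rather than best-stratum ties) is not implemented,
  though the stratum choice is isolated in one routine.
- The enrichment model fits one ChIP library against one input; no
  replicate handling or between-protein comparison.
- Peak calling is threshold-based by design; it inherits the
  arbitrariness of the 3× default, which is why the threshold is a
  parameter and truth-overlap flags accompany every call.
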
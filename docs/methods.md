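# Methods

This note documents the models and procedures implemented in `telmap`,
the assumptions behind them, the tunable parameters and their defaults,
what the synthetic-study generator does and does not emulate, and the
design decisions taken where the problem left genuine latitude.

## Coordinates and interval width

All coordinates are 1-based and intervals fully closed, matching
genome-browser convention for the organism's reference assembly;
chromosome labels are normalized by stripping any `chr` prefix. BED
output converts to 0-based half-open at the writing boundary only.
Interval width is reported as `upper − lower` (not `+ 1`): under this
convention the worked-example intervals round to the familiar 15, 77,
316 and 79 kb figures. Width in kb rounds half away from zero.

## Side calls and interval combination

A transposon insertion yields a side call from its marker-classed
recombinants. Marker geometry — which marker class retains the
low-coordinate side of the mutant chromosome — is genetic background
and is supplied as configuration (`low_side_marker`, default `st`),
never inferred from data. A marker class is informative only when all
its recombinants agree; internal disagreement, or conflict between
classes, yields `Ambiguous`, which is reported with counts but excluded
from interval combination (strict consistency; no majority voting).
A single flat low-side recombinant is a valid `Right` call even with no
high-side recombinants — absence of the phenotype on the retained side
is informative on its own.

`combine_sides` takes the maximum coordinate over `Right` calls as the
lower bound and the minimum over `Left` calls as the upper bound.
Range-valued insertion coordinates contribute their conservative end
(range high for `Right`, range low for `Left`) so the interval can
never exclude the true locus. The packaged mapping table repairs one
obvious digit-grouping typo in a printed range (`196,44,026` read as
`19,644,026`); the repair is noted here rather than silently assumed.
Correctness is checked against a brute-force oracle: the set of
coordinates consistent with every call must equal the open interval
between the returned bounds.

## Variant normalization

Indel calls from different callers describe the same haplotype with
different `(pos, ref, alt)` tuples. Every set operation keys variants
by their normalized identity: shared suffix trimmed (extending left
through the reference when an allele would empty, i.e. left-shifting
through repeat context), then shared prefix trimmed keeping one anchor
base. The procedure is idempotent and haplotype-preserving; the test
suite proves equivalence with a brute-force haplotype-reconstruction
oracle on repeat-rich references, and cross-checks against
`bcftools norm` as an independent implementation. Matching is exact on
the normalized key; a relaxed position-window match was considered and
deliberately not made the default, since exact-after-normalization is
the reproducible core of cross-caller comparison.

## Exclusion filters

Filters are monotone (each stage's output is a subset of its input)
and composable, and every input variant ends in exactly one provenance
bin (`in_control`, `outside_interval`, `in_panel:<line>`,
`other_chromosome`, or `survived`). Two boundary conventions are
deliberately conservative:

* a deletion straddling the interval edge is kept if any affected base
  is inside (a manual scan of the region would see it);
* panel lines flagged as copy-number outliers never contribute to
  exclusion — a line that may itself carry the causative allele cannot
  vouch for a variant's innocence.

SNP and indel exclusion may use different panel subsets (configured per
class), reflecting panels with dense SNP genotypes for many lines but
indel calls for only a few.

## Large-indel discovery

Read-level callers are reliable only for indels of a few bp. Larger
events are recovered the way a manual inspection of a contig alignment
finds them: a global pairwise alignment of an assembly contig to the
reference region (affine gap penalties: match +1, mismatch −2, gap open
−6, gap extend −0.5, chosen so an isolated ≥5 bp gap is preferred over
scattered mismatches; all config-exposed), scanned for gap runs of at
least `min_len` (default 5) bp. Each qualifying run becomes one
anchored, normalized variant; runs touching an alignment end are
treated as contig overhangs, not variants; equal-length double-gaps are
substitutions, not indels. Alignments below 20% identity raise an
error rather than emit calls. The implementation is quadratic and
intended for kb-scale windows, not chromosome arms.

The companion presence test (`indel_presence_in_window`) asks whether a
locally assembled panel window carries a candidate indel by exact
containment of a diagnostic core (±20 bp around the edit, within ±200
bp haplotypes): alternate core only → present, reference core only →
absent, both or neither → undetermined. Undetermined windows are left
to the caller; they never silently count as exclusions.

## qPCR model

Replicate Ct values are aggregated by arithmetic mean (no within-
triplicate outlier rejection); replicate SDs propagate in quadrature.
ΔCt = mean target Ct − mean reference-gene Ct; relative copy number is
the standard 2^−ΔΔCt against a designated calibrator sample. Elongation
is called from a (generation, ΔCt) trajectory as fold change
2^(ΔCt₀ − ΔCt_last) ≥ `fold_threshold` (default 2.0 — one full qPCR
cycle of drift), optionally requiring a negative regression slope of
ΔCt on generation; both knobs are exposed because the qualitative
judgment "showed elongation" has no canonical numeric criterion.
Amplification efficiency is assumed ideal (exactly 2 per cycle);
efficiency calibration curves are out of scope.

The panel screen fits a log-normal by moments on log10 values (sample
SD) and flags lines beyond `k` = 3 fitted SDs (high tail by default).
The log scale is used because panel copy numbers are well described as
log-normal. The fit includes all values — a one-pass screen; an
iterative re-fit mode exists but is off by default. A one-pass k-SD
screen tolerates only a few percent contamination before the outliers
inflate the fitted spread enough to hide themselves: at 3 outliers of
5 log-SD in 162 lines the planted lines sit near z ≈ 4 and are always
flagged, while e.g. 2 in 12 would sit near z ≈ 1.9 and never be. The
scaled-down test configuration therefore keeps the outlier fraction
near the full-scale value (1 in 30).

In-silico PCR uses exact primer matching (no mismatches): forward
primer on the given strand, reverse complement of the reverse primer
downstream, every pairing reported up to a 5 kb product cap, product
length = span from first forward-primer base to last reverse-primer
base inclusive.

## Synthetic-study generator

The generator emulates the statistical structure the analysis assumes,
at the scale of the motivating study. Defaults: a 79 kb segment of
chromosome arm 3R (origin 19,325,278) at GC 0.42; 626 background SNPs
and 115 background indels (lengths 1–12 bp, placed collision-free with
re-draws, max 1000 attempts) plus one causative variant — by default a
3 bp deletion of a `TGT` motif written into the reference inside intron
8 of a synthetic ten-exon gene model, at position 19,396,067; a control
strain sharing each background variant with probability 0.47 (matching
the shared fraction observed after control subtraction at this scale);
a 162-line panel carrying each background variant with probability
0.25, with three planted copy-number outliers at +5 log-SD on a
log10-normal(0, 0.15) distribution — leaving 159 phenotypically normal
lines for exclusion. Recombinant stocks are generated per insertion and
marker class (3 per class by default; real experiments of this design
recover between one and six per insertion): a stock that retains the
causative side drifts −0.25 ΔCt per generation (≈8-fold copy gain over
12 generations), others stay flat, with Gaussian replicate noise
(SD 0.15 Ct) around base Cts of 20 (target) and 15 (reference gene),
assayed at generations 0, 6, 9 and 12. Drift and noise magnitudes are
free parameters: the source experiments published trajectories only as
plots.

Pure Bernoulli carriage leaves a background variant uncovered by the
panel with probability (1−p)^N, so a *guaranteed coverage* mode
(default on) force-assigns each otherwise-uncovered background variant
to one random **phenotype-normal** panel line. Outlier lines are
excluded from this guarantee deliberately: they are removed by the
phenotype filter downstream, so a variant whose only carrier is an
outlier line would escape exclusion and break the deterministic
end-to-end recovery property the mode exists to provide. The causative
variant is never placed in the control or any panel line.

Randomness derives from one integer seed; every layer (reference,
mutant, control, each panel line, coverage, copy numbers, each
recombinant) draws from its own spawned substream, so enlarging the
panel does not perturb the mutant layer. Identical configurations give
byte-identical fixtures.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: linkage and population structure in the
panel (carriage is independent per line and variant), sequencing and
variant-calling error (all call sets are exact), caller-specific
representation quirks beyond what normalization handles (exercised
separately by re-representation tests), mapping artifacts near repeats,
recombination-rate variation, and any phenotype model beyond the linear
ΔCt drift. Real panels may also carry private variants absent from the
mutant strain; these are irrelevant to exclusion and are not generated.

## Pipeline

`run_pipeline` executes: panel screen → phenotype filter → elongation
calls → side calls → interval combination (with optional round
selection) → normalization → control subtraction → interval
restriction → class-aware panel exclusion → annotation → report
(JSON + provenance TSV + BED interval), with sha256 digests of every
input recorded in the run log. Any stage failure aborts with the stage
name and leaves a `FAILED` marker next to any partial outputs. The
pipeline draws no random numbers; reruns on identical inputs produce
identical reports.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on a 5 kb miniature study (50 background
variants, 30-line panel) and randomized small instances; the
many-seed recovery properties use 50 seeds on reduced configurations.
The acceptance script runs the mapping-table worked example, twenty
independently seeded full-size panel screens, and one full-scale
(79 kb / 741 background variants / 162-line panel) study end to end —
about a second in total. These sizes are the package's own choice of
desk-scale defaults; all are configurable upward.

## Known limitations

* Amplicon sizing against the two published qPCR template records
  requires fetching them from GenBank; the in-silico PCR operation is
  fully tested against constructed templates and a brute-force scan,
  but the published product sizes (195 bp and 152 bp) can only be
  verified where those records are available.
* `discover_large_indels` merges nothing: two gap runs separated by a
  matched block are two variants, even if a different alignment would
  fuse them. Adversarial repeat contexts longer than the gap-open
  advantage can shift gap placement; normalization absorbs pure
  left-right ambiguity but not genuinely different alignments.
* The printed coordinate of the motivating study's causative deletion
  appears in two variants in different places in that study's own
  text (19,366,069-71 vs 19,396,067-69); the generator's default uses
  the latter, which is the one consistent with the final mapped
  interval. The discrepancy is recorded, not resolved.
* The elongation caller reproduces only the qualitative judgment; no
  significance statistic is attached to a trajectory.
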
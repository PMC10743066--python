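# Methods

## The assay and its encoding

Each grain is genotyped with an ordered panel of allele-specific PCR markers
whose read-out is binary: a product of the expected size is present or
absent. Marker 1 amplifies an endogenous soybean gene and gates the assay —
a marker-1-negative sample is not soybean (or the reaction failed) and is
rejected with a dedicated error rather than scored 0. Marker 1 scores 1 and
marker *k* scores 2^(k−1), so the judgment value of a grain is a base-2
encoding of its amplification profile. The mapping is bijective on odd
integers in [1, 2^m − 1] for an *m*-marker panel; decoding is the binary
expansion and is never stored, always derived. The packaged panel has 11
markers in six multiplex sets (A–F); co-amplified markers must differ in
amplicon size to be separable on a gel, checked with a configurable margin
(default 20 bp — the smallest gap actually present in the panel is 26 bp, in
set B, and no published criterion exists, so the default sits just below it).

## Discrimination tables and classification

The classifier is pure set membership against origin-labeled reference
collections, packaged here as fixtures: 53 distinct domestic values from 630
grains and 70 distinct foreign values from 466 grains. Four values (671,
1183, 1215, 1695) occur on both sides; grains at those values are
*undetermined* by the genetic assay. A value may be registered as
morphology-resolved (default: none; 1215 is the documented case, where seed
shape separates the varieties): classification then requires a per-sample
morphology call, because the resolving evidence is external to the assay.
Grains whose value appears in neither collection are reported as
`unknown_value` and excluded from confusion tallies — the reference
collections define the universe and contain no such case.

Confusion semantics: FD counts *domestic* grains not recovered as domestic
(stuck at overlaps) and FF the foreign analogue. Both follow from treating
undetermined grains as failures on their own true side; this is the only
reading under which TD+FD and TF+FF equal the collection sizes and the
published rates follow. Percentages are rounded half-up to one decimal for
display; raw ratios are used internally.

Panel reduction projects every value onto a reduced marker set by
subtracting the dropped markers' scores where present, merging collided
entries (counts summed, notes concatenated, ascending value order). Counts
are conserved and the overlap set can only grow, which is what the tests
assert; the reduced-panel rates the pipeline computes from the packaged
tables (79.4 / 88.2 / 83.1 for markers 1–10) are reported as computed, not
calibrated to any external figure.

## Lot sampling

A lot verdict aggregates per-grain verdicts: all informative grains one
origin → that origin; both present → mixed; none informative →
undetermined. Detection power for an admixed lot uses independent draws,
1 − (1 − p)^n, inverted in closed form for the minimum grain count; 24
grains reach 95% power at p ≈ 0.1175. Independent draws are a deliberate
approximation — lots (200 g, thousands of grains) dwarf the 24-grain draw —
but a finite-lot hypergeometric variant is available via `lot_size` for
small lots. The admixture fraction behind "95% reliability" is exposed as a
parameter, not asserted, since no canonical value exists.

## Variation-block segmentation

Marker discovery tiles each chromosome into non-overlapping 100 kb windows
(the characteristic dVB scale; tiling rather than sliding keeps blocks
deterministic and mergeable), computes SNPs/kb per window, classes windows
against a density threshold, and merges adjacent same-class runs into
blocks that exactly tile the chromosome. VCF positions are 1-based;
internal intervals are 0-based half-open, so a variant at position *p*
belongs to the window containing *p* − 1 (tested at the boundary). Only
biallelic records are used; multiallelics are skipped with a logged count.
The density cutoff has no canonical value and is a user parameter; an
optional data-driven mode exploits the dVB/sVB bimodality with an exact 1-D
two-means split of log(density + ε) (ε = half a variant per window so empty
windows participate), returning the midpoint of the two cluster means.
InDel candidates are the variants inside dVBs whose allele-length difference
lies in [5, 50] bp by default — long enough for a robust allele-specific
product difference, short enough to amplify cleanly.

## Synthetic data

The generator emulates the study's design, not soybean biology: variety
fingerprints are independent Bernoulli(0.5) draws per marker (the
maximal-entropy choice; per-marker probabilities are configurable),
populations copy a fingerprint and flip markers 2..n with a dropout rate
(present→absent) and false-amplification rate (absent→present, both default
0.01 — a low-noise PCR assay), marker 1 never flips, and lots draw grains
from origin pools with a mixture fraction (default 0.2) for admixed lots.
Defaults mirror the reference collection's shape: 53 domestic and 70
foreign fingerprints (the observed distinct-value counts), ~10 grains per
variety, 24-grain lots. `force_separable` draws the two origins' judgment
values disjointly so that a noiseless population is perfectly classifiable —
the end-to-end control experiment. One config seed feeds fixed per-stage
RNG streams (varieties/noise/lots/vcf), so extending one stage never shifts
another's draws.

Simulated chromosomes place SNPs as a homogeneous Poisson process at a
per-class density (defaults in the examples: 5.0/kb dense vs 0.5/kb sparse,
a 10× contrast), plant a fixed number of qualifying InDels per dense block
and 1 bp decoy InDels in sparse gaps, and record ground truth. Chromosomes
of 2–3 Mb with three planted blocks are used throughout the tests and the
acceptance run — large enough for stable window densities, small enough to
run in seconds.

What passing synthetic tests do **not** show: real populations have linked
markers, uneven allele frequencies, pedigree structure and shared values
between origins (the packaged tables show exactly four), so perfect
recovery under `force_separable` is a correctness check of the machinery,
not a performance claim about field samples. Real performance is what the
packaged reference tables yield.

## Numerical and degenerate-input choices

- Rounding: half-up (`decimal`) at one decimal everywhere a percentage is
  reported; tests compare at that precision.
- Zero denominators in any rate raise `UndefinedMetricError` rather than
  returning NaN.
- The overlap value-fraction denominator is the *union* of distinct values
  across origins (119 in the packaged tables), counting shared values once.
- Empty profile lists build an empty table; empty lots are an error.
- `min_grains` guards its closed form with a one-step scan against float
  edge cases exactly at the confidence boundary.

## Known limitations

- Marker attrition (how discovery candidates are whittled down by wet-lab
  specificity failures) is not modeled; discovery stops at the candidate
  list.
- Variety identification is out of scope: the note field carries variety
  names but classification is origin-level only.
- The morphology resolution mechanism models one documented case (value
  1215); it accepts any value but encodes no image analysis.
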
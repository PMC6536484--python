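# Methods

## Coordinate conventions

All coordinates are 0-based half-open (`[start, end)`), BED-native; GFF3 is
converted on read (start − 1) and on write (start + 1).  The gap between
two intervals is `start(next) − end(prev)`, the bases strictly between
them; a gap of exactly the merge threshold merges.  Strand is carried on
genes and features but ignored by the interval algebra — only the
TSS-profile layout consults it.

## Smoothing

The chromatin-state classifier emits fixed-width fragments (200 bp at model
resolution) labelled with one of four states or `gap`.  `smooth()` scans
the non-gap fragments left to right and merges consecutive same-state
fragments whose separation is at most `max_gap` (default 400 bp), whether
that separation is empty space or explicit gap calls.  A fragment of a
different state always breaks the run.  Each output domain records how many
bridged bases it absorbed (`absorbed_gap_bp`), so composition can be
computed either way: measuring a region against *fragments* counts absorbed
bases as gap; measuring against *domains* attributes them to the merged
state.  Both views are reported by the pipeline; neither is asserted to be
the one used for any published percentage.

## Segmentation into bands and interbands

On the smoothed domains of one chromosome:

1. **Interband candidates** are maximal aquamarine runs.  A run may extend
   across a block of non-aquamarine domains when the block is contiguous
   (no unassigned space inside), shorter than `inclusion_max` (default
   5,000 bp) and aquamarine-flanked; bridged domains are recorded as
   inclusions of the interband.  A run qualifies as an interband when its
   total aquamarine length is at least `interband_min_len` (default
   4,000 bp).
2. **Bands** are everything between consecutive interbands (and before the
   first / after the last), spanning from their first to their last member
   domain.  Aquamarine domains inside a band — necessarily below the
   interband threshold — become inclusions of the band.
3. A band is **black** when its members carry at least `ruby_min` (default
   5,000 bp) of ruby, else **gray**.

Unassigned gaps between a band's member domains lie inside the band's span;
gaps adjacent to an interband remain unassigned.  Consequently every
state-labelled base belongs to exactly one structure, structures are
disjoint, and bands/interbands strictly alternate.

Parameter rationale: ~4 kb separates the observed populations of
band-internal aquamarine inclusions (≤ 3.8 kb) from described interbands
(≈ 4–12 kb); ~5 kb is the smallest fragment resolvable as a band by
electron microscopy, used both for the inclusion bound and the black-band
ruby criterion.  These populations genuinely overlap in real material
(interband inclusions up to 7.2 kb have been described), so
`inclusion_max ≥ interband_min_len` is allowed but triggers a warning, and
both parameters are user-settable.  Cytological judgment calls that no
threshold reproduces are supported as explicit per-structure class
overrides (`apply_overrides`), after which adjacent bands are coalesced to
preserve alternation.  Cytological names enter through an anchor table
(coordinate → name join); unanchored structures keep automatic `B###`/
`I###` names.

## Feature statistics

* **Density** — points per kilobase of a merged region set; zero-length
  sets yield null with a warning.
* **Overlap percent** — covered bases of a region set under the merged
  feature intervals, as a percentage of set length.
* **TSS profile** — bins of `bin` bp (default 200), `n_bins` (default 5)
  on each side of every in-scope gene's 5′ start; s-bins extend away from
  the body, g-bins into it, mirrored on the − strand.  In-scope means the
  5′ start lies in the scope set (typically the interbands).  Counts are
  divided by the gene's transcript number and summed over genes; because
  genes are binned independently, a feature between two head-to-head
  starts is credited to both genes' s-bins, each under its own
  normalisation — the most literal symmetric reading of "taking gene
  arrangement into account", flagged as an interpretation.  Interval
  features are assigned by midpoint (switchable to any-overlap) to avoid
  double counting across adjacent bins.
* **Enrichment** — per (feature, state), the coverage proportions of the
  target chromosome's state domains versus those of all other chromosomes,
  compared with the two-sided unpaired rank-sum test at α = 0.001 with no
  multiple-testing correction.  The unit of observation is the smoothed
  domain (a per-200-bp-fragment mode exists behind `unit="fragment"`); the
  per-domain choice is the natural unpaired sample when medians of
  "proportions occupied" are compared, and is the package's documented
  reading.  Rows with fewer than two observations on either side are
  emitted as `ns` with an `insufficient_sample` flag.
* **Signal medians** — per region, the peak is the maximum bedGraph step
  value overlapping it (0 when none); per named set the median of peaks is
  reported.  For structure *classes* the pipeline evaluates the member
  domains of all structures in the class with a length-weighted median, so
  the value describes the typical base rather than the typical structure:
  a black band whose ruby core is a minority of its length then reports a
  near-zero value even though the band's own maximum is high — matching
  the behaviour this statistic is meant to capture.  "Peak" is not defined
  more finely than this; the per-domain maximum is our documented choice.
* **Expression breadth** — genes are grouped by the class of the structure
  containing their 5′ start; group medians/means and pairwise two-sided
  rank-sum p values are reported.  Genes lacking a breadth value are
  excluded and counted.

## The rank-sum test

Both branches are two-sided and unpaired.  With both groups ≤ 10
observations the p value is computed by exact enumeration of all
C(n, n_A) group assignments of the pooled midranks — valid under ties,
and verified in the tests against an independent U-statistic
pair-counting oracle to 1e−12.  Larger samples use the tie-corrected
normal approximation with continuity correction (scipy's asymptotic
Mann–Whitney U).  Verdicts compare medians; when the test rejects but the
medians tie, the mean-rank direction breaks the tie.

## Synthetic genome

The generator emulates the statistical organisation the analysis assumes,
on a 1.25-Mb target arm plus a 10-Mb rest-of-genome chromosome built with
the same machinery but no target-specific biases.  The default plan places
11 black and 16 gray bands (and hence 26 interbands) in the canonical
order of the modelled arm.  Structure sizes are drawn from scaled Beta
distributions over the published ranges (black 35.8–89 kb, gray
6.6–56.8 kb, interbands 4–12.3 kb) with means matching the published
averages (61.0 kb, 22.9 kb, ~6.6 kb); a plain uniform draw over the ranges
is available (`size_distribution="uniform"`) but is not the default
because its expected total (the gray midpoint alone is 31.7 kb versus the
observed 22.9 kb mean) exceeds the arm length.  The default arm length is
1.25 Mb rather than the nominal 1.2 Mb for the same arithmetic reason: 27
bands averaging 38.4 kb plus 26 interbands cannot fit in 1.2 Mb.  When a
draw still overruns the budget, sizes are rescaled and grid-shaved,
never letting interbands drop below their 4-kb range minimum.

Within structures: black bands are a ruby core (37% of length) with
malachite neighbours and lazurite edges; gray bands are lazurite (54%)
with malachite; interbands are aquamarine with short (≤ 400 bp) model-gap
punches that smoothing re-absorbs.  Larger unassigned gap runs are placed
strictly inside bands and at some structure boundaries, reproducing the
high gap fraction of the modelled chromosome (~20% of the arm).
Inclusions are planted per the observed census — 21 aquamarine fragments
(0.4–2.6 kb) in 8 black + 5 gray host bands, 7 lazurite (2.8–4.8 kb) and
2 malachite (1.6–1.8 kb) fragments in interbands.  Two constraints keep
the planted truth identifiable: interband inclusions stay below the 5-kb
bridging bound (observed lazurite inclusions reach 7.2 kb, but an
inclusion at or above the bound would, by the segmentation's own rules,
split its host — the same threshold conflict the parameters expose), and
band inclusions keep ≥ 5 kb of band material between themselves, each
other and the band edges, because closer placements are *legitimately*
segmented differently (bridged into the neighbouring interband or merged
into one apparent structure).  Passing recovery tests therefore shows the
segmenter inverts the generator wherever the planted structure is
identifiable at all — not that real chromosomes contain no ambiguous
configurations.

Genes start in every interband (head-to-head divergent pairs with
probability 0.5), six interbands carry a fully contained gene, and sixteen
genes start inside band aquamarine inclusions; transcript counts are drawn
from {1..4} with weights (0.5, 0.25, 0.15, 0.1) and expression breadth from
clipped normals with means 18/9/3 tissues for interband/gray/black-start
genes.  Features: 107 insertion-site points (70% within ±400 bp of
interband gene starts), 250 DHS-like points (85% within 200 bp upstream),
250 ORC2-like intervals (centres ~N(0, 180 bp) truncated at ±400),
55 TE remnants (0.4–1.4 kb, band states only, ~50 kb total), HP1a/POF-like
coverage drawn per domain from Beta distributions with mean 0.25/0.25/
0.20/0.05 per state ×2 on target aquamarine+lazurite, and a repressive
step signal ~N(2.5, 0.3) on ruby versus N(0, 0.3) elsewhere.

All randomness flows from one seed through fixed per-component substreams
(genome, genes, then one stream per feature label), so adding a feature
label never perturbs earlier draws, and identical configs produce
byte-identical files.

What the generator does **not** emulate: sequence content, read-level
noise, mappability, ChIP background structure, inter-replicate
variability, or the real genome's irregular domain-size mixture.  Passing
tests therefore demonstrate correctness of the measurement chain under the
stated statistical structure, not performance on real modENCODE/FlyBase
data, which the package reads through the same interfaces but which are
outside the test scope.

## Numerical choices and degenerate inputs

* Exact/asymptotic switch at n ≤ 10 per group; exact branch enumerates at
  most C(20, 10) = 184,756 assignments.
* Weighted median: smallest value whose cumulative weight reaches half the
  total.
* A chromosome with no aquamarine at all segments into a single band with
  a warning; an empty region yields an empty composition profile with a
  warning; empty feature sets propagate as zero densities/overlaps and an
  "empty" enrichment section rather than errors.
* Floating-point numbers in reports are serialised to 6 significant
  digits; TSVs keep full precision.

## Problem sizes in the test suite

Oracle-equivalence tests run on ≤ 100-kb instances against base-resolution
boolean arrays.  Seed-sweep tests (planted-bias recovery, null
calibration) use 50 seeds of the default genome; the acceptance script
uses 15 recovery seeds and 20 null seeds.  These sizes give the rates
reported by `scripts/acceptance.py` their granularity (1/15 ≈ 6.7
percentage points) and were chosen as the package's own defaults.

## Known limitations

* The segmentation thresholds are sharp cut-offs; real cytological calls
  blend size, density and context, and the published threshold populations
  overlap (see above).  Exact reproduction of any particular manual map is
  out of scope.
* The head-to-head double-crediting rule and the per-domain enrichment
  unit are documented interpretations of under-specified procedures; both
  have switchable alternatives.
* `apply_overrides` reclassifies and coalesces but does not re-split
  structures.
* No multiple-testing correction is applied by default, mirroring the
  fixed-α design this package implements; the enrichment table carries raw
  p values so any correction can be applied downstream.
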
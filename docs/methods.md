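# Methods

This note documents the models, conventions and numerical choices behind
`polyloop`, and what the synthetic-data generators do and do not emulate.

## Coordinate conventions and interval algebra

All coordinates are 0-based, half-open (BED convention); a shared endpoint
is not an overlap. Zero-length intervals are rejected at parse time.
Strand is ignored throughout — none of the implemented analyses are
stranded. Interval queries are backed by one interval tree per chromosome,
so results are independent of input order; the test suite checks every
query operation against nested-loop enumeration oracles.

Loop anchor distance supports two conventions: **midpoint** (absolute
difference of floor midpoints; the default everywhere a distance is
reported) and **inner_edge** (gap between facing anchor edges, floored at
zero for abutting anchors). Published loop sets rarely state which
convention their distance axes use, so the choice is an explicit, logged
parameter rather than a constant.

"TADs crossed" by a loop counts TADs *fully contained* in the open
interior between the anchors' inner edges. Partially overlapping TADs are
excluded: containment is the only reading that is reproducible across TAD
callers with fuzzy boundaries, and it is flagged in output metadata.

"Top percentile" summaries take the `ceil(p·n)` loops with the largest
value of the ranking variable (distance and TAD count ranked
independently), with `p = 0.01` by default; medians of even-length samples
use the midpoint rule.

## Wilcoxon rank-sum test

`compare_distributions` computes the two-sided Mann–Whitney U. For pooled
sample sizes `n1 + n2 ≤ 20` the p-value comes from full enumeration of
rank assignments (a permutation test on midranks, exact under ties;
C(20,10) ≈ 1.8×10⁵ assignments). Larger samples use the normal
approximation with the standard tie correction and a continuity
correction of ½; when every pooled value is tied the test returns p = 1.
Two-sided exact p doubles the smaller tail, capped at 1. The suite
verifies exactness against an independent pairwise-comparison oracle for
all `n1 + n2 ≤ 10` and calibrates the type-I error at n = 50 vs 50 over
1,000 null simulations.

## Nucleation classification

Loops spanning more than `min_distance` (default 1 Mb, strict inequality)
are labelled `both`/`one`/`neither` by half-open overlap of their anchor
intervals with the nucleation-point set. Reported aggregates are the
fraction with at least one nucleation anchor and, conditional on that,
the fraction with exactly one — the two numbers such studies quote.

## Aggregate profiles and loess curves

`aggregate_profile` integrates a bedGraph-like track over fixed bins in a
window (default 10 kb, 50-bp bins → 200 bins) centred on each centre's
midpoint, then divides by covered bp × (library depth/10⁶), giving
normalized library depth per bp per centre. The track is reduced to a
cumulative-mass function, so the result is invariant to fragmentation of
equal-value runs, and windows truncated at chromosome ends contribute
only their covered bases (the per-bin divisor tracks covered bp).
Library depth defaults to the track's total mass. When an anchor holds
several peaks, each peak contributes one centre and normalization is per
centre. The 50-bp bin width is a resolution choice, not a biological one.

The overlap-vs-distance trend uses an internal loess: degree-1 local
regression with tricube weights over the nearest `ceil(span·n)` points
(span 0.6 by default), evaluated on a 50-point grid in log10 distance,
clamped to [0, 1]. Implementing it internally keeps the fit bit-for-bit
reproducible; at span 1 on exactly linear data it reproduces the
least-squares line (verified to 1e-6). The 95% band is a percentile
bootstrap over loops (200 resamples, seeded) — the generic choice when a
figure's CI method is unstated. Fewer than 10 points returns raw points
without a fit. The per-loop indicator (≥1 overlapping anchor) is the
default y; a per-anchor mode assigns each anchor the minimum distance
among its loops.

## Virtual 4C and loop matching

Contact matrices are stored as the upper triangle of symmetric binned
counts with a bin table and the total filtered read-pair count. Virtual
4C sums matrix rows over the viewpoint's bins (cis only) and scales by
10⁶ / total pairs; smoothing is an optional centred running mean over an
odd number of bins. Viewpoint self-interaction bins are reported but
flagged, and callers typically exclude a ±5-bin zone when looking for
distal maxima. Profile mass equals the scaled row sum exactly
(conservation is asserted to 1e-9).

Loop matching declares two loops concordant when left anchors overlap
after symmetric extension by `slack_bp` (default one bin, 10 kb) *and*
right anchors do likewise; assignment is greedy one-to-one in ascending
combined midpoint offset with deterministic tie-breaks, making shared
counts symmetric and fractions well-defined. Conservation between a
native and a mapped (lifted-over upstream) loop set is the matched
fraction of the native set; mismatched chromosome naming styles ("chr1"
vs "1") are rejected with a hint rather than silently yielding zero.

## ORCA distances

A cell informs a barcode pair only when both barcodes are localized
(pairwise-complete; no imputation). Contact means distance strictly
below the threshold (default 150 nm), and contact frequency is reported
over informative cells, with the excluded-cell count alongside so the
raw-denominator variant can be formed. Distances are nm throughout and
invariant under rigid motions to 1e-9 (tested with random rotations).
Genotype comparisons reuse the Wilcoxon machinery above.

## Differential-site stratification

Significance is strict on both sides (|log2FC| > cut AND adjusted
p < cut); missing adjusted p (upstream independent filtering) means
non-significant. The fold-change cut is a parameter so analyses using 1.0
(H3K27me3 Cut&Tag, RNA) and 0.5 (EZH2 occupancy) share one code path.
Sites overlapping the engineered deletion by any bp are flagged excluded;
cis means the deletion's chromosome; the compartment label of a site (or
the deletion) is that of the segment containing its midpoint, with a
warning when a deletion spans a boundary. The stratified summary
cross-tabulates status by EZH2 occupancy × same-compartment, genome-wide
and cis-only, and adds a two-sided Fisher exact test
(point-probability method) on the (down vs not) × (EZH2 vs not) table —
a quantitative convenience for a relationship such studies present
graphically. Rather than imposing an arbitrary "local" vs "distant" cut,
outputs retain per-site coordinates so distance to the deletion can be
computed downstream.

## Synthetic data: what it emulates

The generators reproduce the statistical structure the analyses assume,
with mouse-scale defaults; all randomness flows through a seeded PCG64
generator, so fixed seeds give bit-identical outputs across platforms.

- **Genome**: 19 autosomes with mouse-like lengths (~2.4 Gb), large
  enough that tens-of-megabase loops fit without truncating the tail.
- **Loops**: anchors are 10-kb intervals centred on their midpoints, so
  realized midpoint distances equal the drawn distances exactly and
  summaries can be checked against ground truth to the base pair.
  H3K27ac distances are log-normal (median 200 kb, σ = 0.9 in log space).
  H3K27me3 distances mix a log-normal body (median 500 kb, σ = 1.0) with
  a Pareto tail (scale 1 Mb, shape 1.8, weight 0.10); these constants were
  chosen analytically so the class's 99.5th percentile sits near 8 Mb,
  about four-fold the H3K27ac value, echoing the reported contrast
  between Polycomb and enhancer loops. Anchors avoid each other
  (rejection sampling) so overlap-based classification is unconfounded.
- **Nucleation**: per H3K27me3 loop, both anchors carry a nucleation
  point with probability 0.391 and exactly one with probability 0.229 —
  i.e. 62% carry at least one, and 37% of those have it at one anchor
  only, matching the reported fractions for loops over 1 Mb. Nucleation
  points are 1-kb intervals at anchor midpoints; the EZH2 peak set is a
  superset whose anchor-occupancy probability rises with loop distance.
- **Contact maps**: expected counts decay as (1+|i−j|)^−1, multiplied by
  a dot-enrichment factor (8×) at loop-anchor bin pairs, scaled to a
  target depth and Poisson-sampled; the realized total is the recorded
  filtered read-pair count. The demo uses a 5-Mb chromosome at 10-kb
  bins; with this decay an 8× dot stays the profile maximum outside a
  ±5-bin viewpoint zone only within ~55 bins of the viewpoint, so the
  planted partner sits 20 bins away.
- **Signal tracks**: piecewise-constant background plus triangular bumps
  whose run values are the triangle at run midpoints with the apex on a
  run boundary, making peak integrals exact (background·w + height·w/2).
- **ORCA traces**: a Gaussian random walk over ordered barcodes (step sd
  400 nm per axis by default); planted contacts resample the second
  barcode uniformly inside the contact ball, so they satisfy the strict
  threshold by construction; barcodes drop out independently. The demo
  imaging experiment uses 2,190 WT and 520 anchor-deleted cells with
  planted contact probabilities 0.40 and 0.05. Background proximity of
  non-contact pairs adds a small upward bias (~1% at the defaults) that
  recovery tests account for.
- **Differential tables**: sites lacking EZH2 occupancy in the deletion's
  compartment get log2FC = −effect ± N(0, 0.25) and adjusted
  p = 10^−U(3,6); everything else is null (N(0, 0.25), uniform p).

Not modelled: read-level noise, ChIP pulldown efficiency, correlated
imaging dropout, matrix balancing artefacts, replicate structure, or any
sequence content. Passing recovery tests therefore demonstrates that the
statistics are implemented correctly and are calibrated under their
assumed sampling models — not that those models capture every property
of real HiChIP, Cut&Tag or imaging data.

## Problem sizes and determinism

The shipped demo runs 2,000 loops per class, 2,469 TADs, a 500-bin
contact map, 2,710 imaged cells and 300 differential sites — sizes at
which every recovery bound (3 binomial SDs) is tight while the whole
pipeline completes in seconds. The pipeline derives one sub-seed per
stage from the run seed; identical configuration and seed give
byte-identical `summary.json` files. All thresholds and defaults are
echoed into the run manifest, and every silently applied default is
logged at INFO.
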
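# Methods

## Study design and model

The pipeline targets the monozygotic-twin cohort design for DNA
fingerprint comparison: three couples of twins, two individuals per
couple (`a`/`b`), four independent PCR + electrophoresis replicates per
individual, two dye channels analysed independently.  The modelling
assumption is that twins share a genome, so their fingerprints differ
only by experimental error; between-couple differences that exceed the
within-couple variability are candidate polymorphisms.  Everything below
is per dye channel.

## Preprocessing

**Calibration.** Instrument datapoints are mapped to bp by
piecewise-linear interpolation between the size-standard knots
(`numpy.interp`).  The vendor's exact sizing curve is unknown; linear
interpolation is the simplest monotone choice, and a property test
guarantees monotonicity for any valid standard.  Records outside the
standard's range are flagged and excluded.

**Size range.** Analysis is restricted to 50–1000 bp (defaults
`min_bp`/`max_bp`): longer fragments separate poorly, and the assay's
primer products start around 50 bp.

**Local amplitude cut-off.** A peak survives if its height is at least
`cutoff_fraction` (default 0.10) of the tallest peak within a window of
`window_bp` (default 250 bp) centred on it.  The reference maximum is
local because amplification efficiency drifts with fragment length on a
~300 bp scale; it is computed on the *pre-cut-off* track, which makes the
retained set invariant under rescaling all heights and independent of
the removal order.  A tiled-window variant is available
(`cutoff_mode="tiled"`); sliding is the default because it has no tile
boundary artefacts.

**Replicate union.** Peaks from all replicates are pooled, sorted, and
swept left to right; a peak joins the open cluster if it is within
`union_tolerance_bp` (default 5 bp) of the cluster's most recent member
and its replicate is not yet represented, otherwise it opens a new
cluster.  Each cluster yields one union peak at the mean member position
(logical OR: support by a single replicate suffices), with the replicate
count kept as a diagnostic.  Nearest-member linkage, rather than
distance-to-seed, is used because with position jitter of sd 2.5 bp the
four calls of one locus span more than 5 bp end-to-end in roughly 12% of
loci; linkage cuts the spurious split rate to ~4% and keeps the union
position sd at ≈ 1.19 bp (the tests measure this).  A consequence of
mean-anchored clustering is that adding a replicate can occasionally
*merge* two previous clusters; the union therefore guarantees the weaker
monotonicity that every previous union peak stays within the tolerance
of some current one, which is what the property test asserts.

## Signal reconstruction

Each union peak becomes a Gaussian with unit amplitude and σ = 1 bp
("mean square value equal to 1 bp" is read as σ² = 1 bp²; the alternative
unit-L2-norm reading would only rescale amplitudes uniformly).  Signals
span 0–1024 bp at 32 samples/bp (2¹⁵ samples), rendering the 1 bp peak
smoothly on a dyadic grid.  Peak centres are *not* snapped to the grid —
union positions are replicate means and generically off-grid.  Gaussians
are truncated at 6σ (neglected tail < 10⁻⁸ of the area) and summed where
they overlap.  The sampled area of one isolated peak, 32·√(2π) ≈ 80.21,
is the *peak-area unit* used by the discriminant; on this grid it matches
the continuum value to better than 10⁻⁶ relative.

Measured heights and areas are deliberately discarded at this stage: only
positions (and the area/height ratio) are reproducible across replicates,
so amplitude information would inject noise, not signal.

## Haar–Walsh wavelet packet transform

The full packet table is computed with the orthonormal Haar filters
(pairwise sums and differences over √2).  Row *j* consists of 2ʲ
frequency blocks in natural (filter-cascade) order, each holding
2^(M−j) translations; the basis vector of coefficient (j, b, t) is a
Walsh ±1 pattern on a dyadic support of 2ʲ samples, scaled 2^(−j/2).
The orthonormal convention makes Parseval exact (tested to 10⁻⁹
relative) and every row exactly invertible (10⁻¹⁰).  An explicit
Walsh-pattern constructor, built from the synthesis recursion rather
than the analysis cascade, serves as an independent oracle: every
coefficient equals the inner product with its explicit basis vector, and
PyWavelets' Haar packets provide a second, external cross-check in the
test suite.  Block order never affects supports or scores.

## Twin-contrast discriminant

For reference couple *r*, coefficient (j, i) scores

    K = [ min_{k≠r; x,y∈{a,b}} |c_rx − c_ky|  −  |c_ra − c_rb| ] / A(j, i)

and is selected when K ≥ δ (default δ = 1/3).  All eight cross pairs
(2 reference twins × 2 other couples × 2 twins) enter the min.  K is
invariant under swapping twins within any couple and permuting the two
non-reference couples, and vanishes identically for identical cohorts.

**Normalisation.** A(j, i) expresses the contrast in peak-area units:
unit-norm coefficients are rescaled by √2ʲ into signed areas, then
divided by the signal area inside the coefficient's support — the
cohort-mean signal integrated over the support, floored at one peak-area
unit.  Consequences, all pinned by tests:

* a single standard peak fully present in the reference couple and
  absent elsewhere scores K = 1 exactly at any depth containing it;
* a single peak at couple-distinct positions within one support (the
  positive/negative/near-zero coefficient geometry) scores K ≈ 0.95;
* in a support holding n peaks, selection demands a pattern difference
  of δ·n peak-areas — a fraction δ of the *total* signal area under the
  support — which suppresses the aggregate position-jitter noise that
  otherwise floods coarse scales over dense multi-locus stretches.

Under this normalisation and zero within-couple difference, the smallest
integer single-peak shift that fires the criterion is 1 bp (a 1 bp
displacement across a packet sign boundary already moves ≈ 0.68
peak-areas of signed area).  In replicate data the within-couple term is
nonzero, so in practice a shift must exceed the within-couple positional
variability (~1–2 bp) by about 2 bp to be selected — the practical
detection floor quoted for this design.

**Depth band.** Selection considers depths 6–11 (supports 2–64 bp),
matching the scale range of biologically plausible regions; both ends
are configurable.

**Refinement.** Selected supports are dyadic, hence nested or disjoint.
`refine_to_smallest_scale` keeps, per maximal nested chain, the most
localised support still passing δ (ties: larger K, then lower block) —
the "optimal classification at the smallest scale" view used when
inspecting a single reference couple.

**Global regions.** Selection runs once per reference couple.  Each
run's selected supports, dilated by the 5 bp alignment tolerance (two
classifying intervals closer than the position measurement accuracy
refer to the same locus), are merged into that couple's classifying
coverage; maximal stretches covered by *all three* runs become global
regions.  Within each region every couple reports its most localised
passing support and that coefficient's K.  The three per-couple
intervals may be nested, overlapping or even disjoint — neighbouring
sub-intervals of one variable stretch can be what separates different
couples — and one wide region may span several variable loci.  An
optional stricter mode (`min_chain_depths > 1`) additionally requires
each counted support to sit in a nested selected chain across several
depths; it trades sensitivity for specificity and is off by default.

## Synthetic cohorts

The generator emulates the twin experiment so the whole pipeline runs
without external data.  True loci are fixed by the configuration; the
simulation seed drives only the noise, so seeds replay the same cohort
under new experimental error.

* **Cohort size:** ~50 loci per dye channel (the assay resolves on the
  order of a hundred fragments across its two channels), uniform over
  60–985 bp with a minimum spacing of 8 bp.  Spacing below the ±5 bp
  jitter range would make neighbouring loci physically unresolvable by a
  5 bp-tolerance union, so tighter packing tests the union's failure
  mode, not the discriminant.
* **Planted polymorphisms:** 6 loci per channel with pairwise-distinct
  couple states, by default pure length shifts of 0/8/16 bp
  (short-repeat length variation spanning a few repeat units; a shift
  must exceed the within-couple variability by ~2 bp to be detectable,
  so 8 bp sits safely above the floor).  A `mixed_fraction` switches
  some to shift-plus-absence states; these carry an intrinsic
  per-reference detection ceiling (the presence contrast saturates at
  one peak-area at the single coefficient that must separate both other
  couples) and are not planted by default.  Polymorphic loci get 26 bp
  of clearance so the variant span plus jitter stays inside one locus's
  territory.
* **Noise defaults:** position jitter sd 2.5 bp truncated at ±5 bp
  (consistent with the 5 bp alignment tolerance and a < 2 bp mean
  position error after averaging); 5% peak dropout per replicate;
  spurious peaks at 0.2 per 100 bp per replicate with heights 2–6% of a
  typical peak (low enough that the amplitude cut-off removes them);
  lognormal height variation (sd 0.5 in log-space).
* **Scoring:** `truth_match` counts a planted three-way polymorphism as
  recovered when a global region (± 5 bp slack) contains one of its
  per-couple positions; regions matching no such locus are false
  positives.

What passing tests on these cohorts show — and what they do not: the
generator reproduces the *position-level* error structure of the assay
(jitter, dropout, spurious calls, amplitude drift) but not peak-shape
asymmetry, stutter, dye cross-talk, or amplification kinetics; real
fingerprints may also be locally denser than the resolvability floor, in
which case the union, not the discriminant, limits what is detectable.
On the default conditions the pipeline recovers ≈ 95% of planted
three-way polymorphisms with ≈ 0.1 false global regions per channel
(the acceptance suite asserts ≥ 90% and ≤ 1).

## Numerical choices and degenerate inputs

* Dyadic signal length is fixed at 2¹⁵; no padding logic exists.
* Ties in smallest-scale representatives break by larger K, then lower
  frequency block, then lower translation — fully deterministic.
* δ = 0 is rejected (it would select every coefficient), as are empty
  peak tables, non-monotone size standards, mixed-sample unions and
  incomplete cohorts.
* All randomness flows through `numpy.random.Generator` seeds; the CLI
  separates the locus-layout seed from the noise seed.
* Problem sizes in the test and acceptance suites (50-locus channels,
  10,000-locus union simulations, length-256 oracle checks) were chosen
  to make each check statistically meaningful while keeping the whole
  suite under a minute of compute; the planted-recovery check uses three
  independent cohort layouts.

## Known limitations

* The support-area normalisation is a calibrated reconstruction pinned
  to the printed single-peak anchors (K ≈ 1 for a full peak difference);
  its exact original functional form is not recoverable from the source
  material.
* The global-region overlap rule (tolerance-dilated three-way coverage)
  is one of several defensible readings of "distinguishing all couples
  simultaneously"; alternatives (strict smallest-scale overlap) proved
  far less robust to replicate noise and cannot reproduce per-couple
  interval layouts with disjoint sub-intervals.
* No false-positive rate or statistical power is claimed for real data;
  the recovery figures above are properties of the synthetic conditions.
* Presence/absence polymorphisms that must separate all three couples
  are intrinsically harder for criterion-style minimum contrasts (see
  above); sensitivity targets for them would need either more replicates
  or a relaxed two-of-three notion of globality.
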
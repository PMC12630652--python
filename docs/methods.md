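# Methods

This note documents the models and procedures implemented in `cafomap`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the package's known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

A detection-driven aerial survey of large livestock facilities (CAFOs)
produces building-level annotations: polygons with uncalibrated detector
confidence scores, linked where possible to land parcels. The scientific
products are (a) a *facility*-level dataset — buildings operated together
as one animal feeding operation, with geography, permits, animal types and
lifetime bounds — and (b) a defensible statement of how complete the
dataset is, i.e. what fraction of all true facilities it captured.

## Survey frame

The region is cut into square tiles of `tile_size_m` (default 1,000 m,
roughly the footprint of a high-resolution aerial image) with half-open
extents `[x0, x0+s) × [y0, y0+s)`, so the grid is a partition and no
boundary point is counted twice. Urban polygons are intersected with each
tile; tiles more than 70% masked are dropped from the frame (urban
structures dominate false detections and are surveyed separately, if at
all). Tiles straddling county boundaries are duplicated, one entry per
county with the geometry clipped to that county, so county-level
stratification is exact: the per-county clipped areas sum to the tile
area.

The human-review set is the closure of two seed conditions — tiles
containing a known permit coordinate, and tiles with a detection at
confidence ≥ 0.5 (inclusive) — under 8-neighbor adjacency of tiles
confirmed positive, iterated to fixpoint. Both choices are deliberate:
"adjacent" is read as edge-or-corner contact (the conservative superset),
and the expansion iterates because a facility chain discovered in a later
round merits the same treatment as one discovered in the first. The
closure is monotone in its inputs and terminates (bounded by the tile
count). Remaining tiles are stratified into detection category
(`low_confidence` if any detection is present below threshold,
`no_detection` otherwise) × county cluster.

## Facility clustering

Two buildings are related when any of four rules holds:

1. same parcel (no distance limit — implemented exactly as stated, and
   noted as a deliberate reading; a parcel is single ownership by
   definition);
2. within 400 m and similar parcel-owner names;
3. within 200 m and ownership data missing on either side;
4. within 50 m and at least one is a *lone* building.

Distances are minimum planar distances between axis-aligned bounding
boxes. "Lone" status is computed from rules 1–3 only, in a single second
pass, which avoids a circular definition of rule 4. Facilities are
connected components; ids are assigned by each component's minimum
building id, making output independent of input order.

Owner-name similarity normalizes (casefold, strip punctuation, collapse
whitespace), drops trailing legal-entity tokens (`LLC`, `Inc`, single
letters left by initialisms), and takes a length-normalized Levenshtein
similarity with default threshold 0.85. The threshold is exposed in
`ClusterThresholds` and in the CLI for sensitivity analysis; facility
counts are monotone in the distance thresholds (tested).

Facility attributes: centroid of the union of footprints; envelope
bounding box; footprint area as the sum of building areas; county, census
tract and block group by plurality of building centroids, with ties broken
by a seeded uniform choice among the tied units (reproducible across runs
and input orderings). Facilities containing buildings with no parcel match
are flagged as having incomplete parcel information.

## Permit matching

Permits carry two candidate locations: the registered point and a
geocoded address point (geocoding itself is out of scope; the address
point is an input column). A **best** match requires *both* points,
individually, to lie on one of the facility's parcels or within 200 m of
its building-footprint union, and vetoes any permit whose two points are
both within 200 m of a *different* facility. The veto is distance-only,
exactly as specified; distances are to the buildings, not the centroid,
because the dataset's value is that its geography reflects where animals
actually are. Permits missing either point can never best-match — a
deliberate consequence of the conjunction. In the corner case where a
permit qualifies for several facilities through the parcel clause and the
veto does not fire, the nearest facility wins, ties to the smaller id.

**Expanded** matches take any permit with either point within 1,000 m,
many-to-many. Note expanded is not formally a superset of best: a permit
matched only through the parcel clause farther than 1 km would be in best
but not expanded; the GeoJSON validator warns on such records. Matching
ignores the regulatory program's active/inactive flag (inactive programs
can have grandfathered operating facilities).

## Completeness estimation

Positive tiles are rare in the unreviewed strata (many strata observe
zero), so normal-approximation intervals are inappropriate. Per category,
the proportion interval combines per-stratum exact Clopper–Pearson bounds
(via upper-tail F quantiles; the degenerate cases x=0 and x=n use the
exact limits 0 and 1) with weights `w_i = N_i / Σ N_j` and the
equal-variance adjustment factor

    R = sqrt(Σ w_i²/n_i) / Σ (w_i/√n_i)

which rescales the conservative sum of per-stratum intervals to the
stratified standard error. The two categories are estimated separately —
the equal-variance assumption behind R is only plausible within a
category — and their unobserved-image estimates are summed (no covariance
term; conservative). Weights use stratum totals N_i; an override argument
allows unlabeled-count weighting for sensitivity analysis. All rounding of
image and facility counts is half-away-from-zero, fixed for determinism.

Image counts convert to facilities through the images-per-facility ratio
r = (distinct labeled positive images) / (facilities on them), which
deliberately counts image sharing: ten facilities on the same two images
give r = 0.2. Completeness is 100 × observed / total, reported as an
integer percent; the CI lower bound divides by the upper-bound total, and
the CI upper end equals the point estimate (the unobserved count is
bounded below by zero).

### Rare-event behavior of the interval (important limitation)

With L comparable strata, R ≈ 1/√L, and the lower bound
`LB = p̂ − (p̂ − LB0)R ≈ (1 − R)·p̂` tracks the point estimate closely.
For very rare events (expected positive counts of a few), the sampled
count frequently exceeds ~1.25× its expectation, and then LB excludes the
true proportion: measured two-sided coverage in a 26-stratum design is
far below nominal at p = 10⁻⁴–10⁻³ and about nominal at p = 10⁻²
(`tests/test_acceptance.py` computes these, and the shortfall is not an
implementation artifact — the single-stratum case is exact to 10⁻¹⁰, and
a variance-weighted R behaves similarly). The interval's operative
rare-event guarantee is one-sided: the upper bound covers essentially
always (tested ≥ 97.5% at all three rates), and the completeness CI uses
exactly that side. Users should treat LB of the proportion interval as
descriptive, not as a calibrated bound, when positives are very rare.

## Lifetime bounds and annotation

Observations are year-granular presence/absence/no-image records.
Construction upper bound = Dec 31 of the first present year (the facility
is known to exist by then); construction lower bound = Jan 1 of the
latest absent year before it (absent if never observed absent).
Destruction lower bound = Dec 31 of the last present year *when a later
absent year exists*, destruction upper bound = Jan 1 of the earliest such
absent year; both are null for facilities present through the end of the
record. The destruction-lower convention (Dec 31 rather than Jan 1) makes
the known-active interval `[construction_upper, destruction_lower]`
maximal and internally consistent; the serialized day for that bound is
genuinely ambiguous at year granularity and this choice is documented
rather than hidden.

Animal typing: a facility whose best permits exist and are all
cattle-program permits is typed `{cattle}` from the register; otherwise a
human label is required, `dairy` always implies `cattle`, and
inconclusive evidence yields `{unknown}`. The three-stage confirmation
(initial labeling, typing, dating) acts as a filter: a facility enters
the final set only if no stage flags it. Cohen's kappa is implemented
directly (the degenerate p_e = 1 case is defined as 1.0 under perfect
agreement) and cross-checked against scikit-learn in tests.

## Synthetic landscape generator

The generator emulates the statistical structure the pipeline assumes:
facilities as compact clusters (disk radius 80 m) of 2–8 disjoint
rectangular buildings with a common owner, centers rejection-sampled at a
minimum separation (default 2,500 m — above every clustering threshold);
a parcel grid (800 m) with owner names from a pool, with optional
spelling-noise perturbations that exercise the string-similarity rule; a
permit register with one permit per facility at rate 0.9 plus orphan
permits at rate 0.1, and pathology rates defaulting to the magnitudes
seen in real state registers (≈11% missing coordinates, ≈18% duplicated
addresses, ≈25% missing/zero animal counts); detection confidences drawn
above 0.5 for detected facilities and below for missed ones, with a
default facility miss rate of 0.01 — a conservative emulation of a
survey whose review stage captures over 99.7% of positive images. All
randomness derives from one master seed through named child streams, so
each component is reproducible independently of call order; infeasible
packing raises an explicit error rather than silently truncating.

What it does **not** emulate: imagery and visual appearance, detector
behavior beyond a per-building confidence score, realistic spatial
clustering of facilities by region (the county bands are uniform strips —
the spatial distribution of real facilities is not characterized well
enough to calibrate), geocoding error structure, or permit-register
duplication beyond shared addresses. Passing tests on this generator
therefore validate the pipeline's logic and its statistical estimators
under known ground truth; they do not certify performance on real
imagery-derived data.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately compact problems: landscapes of
8–12 facilities on 12–16 km regions, 26-stratum Monte-Carlo designs with
n_i ∈ [200, 2,000] over 2,000 replicates, and 200 replicated noisy
pipelines for completeness-interval coverage. Distances and areas are
exact shapely operations in planar meters; WGS84 conversion happens only
at the I/O boundary via a local equirectangular projection (exactly
invertible; adequate below ~100 km extents). CSV floats are serialized in
shortest round-trippable form and parsed with round-trip precision.
F-distribution quantiles use the upper tail (`1 − α/2`), the convention
under which the single-stratum interval is exactly Clopper–Pearson.
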
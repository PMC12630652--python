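# cafomap

Tools for building a facility-level census of concentrated animal feeding
operations (CAFOs) from satellite-derived building annotations, and for
quantifying how complete such a census is.

Administrative permit registers for large livestock facilities are
notoriously unreliable: permits with no coordinates, duplicated addresses,
absent animal counts, and locations that point at offices rather than
barns. A detection-driven aerial survey fixes the geography but raises two
new problems this package addresses:

1. **Aggregation** — turning thousands of annotated animal-housing
   buildings into *facilities* (the regulated unit), and linking those
   facilities to noisy permit records;
2. **Completeness** — estimating how many facilities the survey missed,
   from a stratified sample of image tiles the detector flagged weakly or
   not at all.

It is a library first (importable API plus `examples/`), with a thin
`cafomap` CLI for running the pipeline stage by stage.

## What it implements

- **Synthetic landscape generator** (`cafomap.synthetic`) — a planar study
  region with parcels, facilities, buildings, a permit register with
  configurable real-world pathologies, a tile frame with county bands, and
  full ground truth, so every stage can be validated exactly.
- **Survey frame** (`cafomap.tiling`) — ~1 km² half-open tiles, urban
  masking with a 70% mask-fraction cutoff, county-boundary tile
  duplication, review-set selection (permit seeds + detections with
  confidence ≥ 0.5 + the 8-neighbor adjacency closure of confirmed
  positives), and stratification of the rest by detection category ×
  county cluster.
- **Facility clustering** (`cafomap.clustering`) — two buildings belong to
  the same facility when (1) they share a parcel, (2) they are within
  400 m with similar parcel-owner names, (3) within 200 m with ownership
  data missing on either side, or (4) within 50 m of a "lone" building;
  facilities are connected components of this relation. Attributes
  (centroid, bounding box, footprint area, county/tract by plurality of
  building centroids with seeded tie-breaks) are derived per facility.
- **Permit matching** (`cafomap.permits`) — unambiguous *best* matches
  (both permit points on-parcel or within 200 m of exactly one facility)
  and inclusive *expanded* matches (either point within 1 km, many-to-many),
  plus per-county reconciliation tables.
- **Completeness estimation** (`cafomap.completeness`) — stratified
  exact-binomial confidence intervals for rare positive-tile proportions.
  For strata with weights $w_i$, sample sizes $n_i$ and positive counts
  $x_i$:

  $$\hat p = \sum_i w_i \frac{x_i}{n_i},\qquad
    R = \frac{\left(\sum_i w_i^2/n_i\right)^{1/2}}{\sum_i w_i/\sqrt{n_i}},$$

  $$LB = \hat p - (\hat p - LB_0)\,R,\qquad UB = \hat p + (UB_0 - \hat p)\,R,$$

  where $LB_0$ and $UB_0$ are weighted sums of per-stratum Clopper–Pearson
  limits (expressed through upper-tail $F$ quantiles). With a single
  stratum $R = 1$ and the interval is exactly Clopper–Pearson. Proportion
  bounds scale by unlabeled-tile counts to unobserved-image counts, divide
  by the observed images-per-facility ratio, and give a completeness
  percentage with its CI.
- **Annotation model** (`cafomap.annotation`) — construction/destruction
  date bounds from yearly presence/absence imagery observations, lifetime
  profile classification, animal-type resolution (cattle-permit shortcut,
  human labels otherwise, dairy ⊆ cattle), and Cohen's kappa for
  inter-rater reliability.
- **I/O** (`cafomap.io`) — the flat `facilities.csv` schema, the rich
  `facilities.geojson` (RFC 7946 MultiPolygon features with nested parcel
  and permit lists), permit/building/parcel/strata CSVs, and the planar ↔
  WGS84 boundary conversion.

## Worked example

`python examples/completeness_estimate.py` estimates completeness for a
compact five-stratum survey (500 observed facilities, 1.44 positive images
per facility):

```
no_detection   : p_hat=2.08e-04  95% CI [8.73e-05, 1.74e-03]  (R=0.596)
low_confidence : p_hat=2.18e-03  95% CI [7.63e-04, 7.13e-03]  (R=0.716)
unobserved images   : 27 (ub 167)
total facilities    : 519 (ub 616)
completeness        : 96%  95% CI [81, 96]
```

Reading the output: each detection category gets its own stratified
interval for the proportion of unlabeled tiles that contain a facility;
the point estimates imply ~27 unseen positive tiles (at most 167 at 95%
confidence), i.e. ~19 (at most 116) unseen facilities, so the 500 observed
facilities are an estimated 96% of the true population — and at least 81%.

The other examples generate a landscape and recover its ground-truth
clustering (`generate_and_cluster.py`), exercise permit linkage under
register pathologies (`permit_matching.py`), and bracket facility
lifetimes (`lifetime_bounds.py`).

The CLI chains the same stages through files:

```
cafomap generate --out ws
cafomap cluster  --workspace ws
cafomap match    --workspace ws
cafomap estimate --workspace ws
cafomap export   --workspace ws     # facilities.csv + facilities.geojson
cafomap validate --workspace ws
```

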
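# Methods

`dcniche` quantifies how activated (CCR7+) dendritic cells organize
around tumor vasculature and how long they engage regulatory T cells.
It operates downstream of segmentation and cell typing: its inputs are
typed, point-located cell tables, segmented marker polygons, and object
tracks. This note records the models, conventions and parameter
choices, and what the synthetic validation does and does not show.

## Geometry and units

All static analyses are 2-D in physical micrometres; only tracks carry
a z coordinate. Segmented objects are shapely polygons. The
border-to-border distance between two surfaces is the minimum Euclidean
distance between their boundaries, 0 when they touch or overlap.
Overlap ratios are intersection area over the area of the query
surface, computed against the union of the covering set so multiply
covered area is never double counted. Spatial graphs are Delaunay
triangulations of cell centroids with Euclidean edge lengths; edges
above the 99th percentile of the length distribution (linear
interpolation percentile; strict `>` removal) are pruned to suppress
long-range artifacts at tissue boundaries. "Cell layers" are graph
hops on that pruned graph; a k-layer neighborhood excludes the index
cell itself. Exactly coincident points are de-duplicated before
triangulation and mapped back to all ids; fewer than three (or
collinear) points degrade to the complete graph.

## DC cluster detection

Primary (section-based) rule: detections smaller than 5 μm² are
discarded (boundary kept: ≥ 5 retained); Delaunay edges longer than
22.5 μm are cut; connected components are merged transitively whenever
any two of their detections lie closer than 20 μm border-to-border
(strict `<`); groups whose total area falls below 500 μm² are dropped.
The merge step was a curated manual step in the imaging workflow this
mirrors; here it is a deterministic transitive closure, so results are
order-independent and reproducible. Singleton components are eligible
clusters if they clear the area floor; inputs with fewer than two
detections yield no clusters.

Secondary (volumetric) rule for 3-D centroids: link points within
20 μm, require at least 5 members, and split components wider than
100 μm by repeatedly deleting the longest internal link (lexicographic
tie-break) until every component complies; fragments that fall below 5
members are dropped. The splitting rule replaces a manual curation
step and is deterministic by construction.

## Vessel typing and niche association

CD31+ surfaces are typed by LYVE-1 overlap: ratio < 0.01% → blood
vessel (BV), otherwise lymphatic (LV); the boundary case resolves to
LV ("below" is strict). Ccl19 coverage of a vessel is any strictly
positive overlap with Ccl19+ surfaces; covered and non-covered BV areas
are reported normalized to total BV area.

A DC farther than the association cutoff from every vessel is
non-vessel-associated; otherwise it takes the class of the nearer
vessel. The cutoff comparison is inclusive (more than 20 μm away
excludes). An exact distance tie within the cutoff is assigned to BV:
ties are measure-zero on continuous data, and the rare dual cases were
resolved visually in the source workflow, which must become a fixed
rule here. Dialects are configuration presets, not code paths: mouse
sections use 20 μm border-to-border; human FAST cycling imaging uses
50 μm border-to-border; human multispectral imaging uses 100 μm
centroid-to-centroid. Clusters are associated when at least 50% of
their member area lies within the cutoff of a vessel class; dual
qualification resolves to the class with the larger proximal area. A
cluster is inside a CCL21+ region when any member centroid lies in or
on a region polygon (centroid-to-border distance 0). A vessel is
"cluster-associated" when the summed area of DCs within 20 μm reaches
500 μm².

## Neighborhood statistics

`nh_sum` builds the cell × neighborhood-type count matrix within k
cell layers (default 5) via boolean sparse-matrix powers; the `all`
column is the neighborhood size.

`permutation_enrichment` tests whether a target type is enriched
around a selected cell set. Per-cell density is target count over
neighborhood size; cells with empty neighborhoods contribute 0 (they
carry real information about isolation; configurable). The observed
statistic averages per-cell densities (mean-of-ratios; a pooled
ratio-of-means variant is available) and is normalized by the baseline
target fraction among non-selected cells — the same universe the null
shuffles, so the score is 1 in expectation under exchangeability. The
null permutes only non-selected labels, keeping the graph and the
selected cells fixed, and p uses the add-one estimator
(1 + #{null ≥ obs})/(1 + n_perm) so it is never 0; with 1,000
permutations the smallest attainable p is 1/1001.

`pairwise_enrichment` is the asymmetric source→target z-score matrix
against a full label-permutation null; with same-label edges excluded
("without intra-cluster edges"), a type's own-neighbor count is
suppressed in both the observed and null statistics. The external
closed-form implementation this parallels is not reproduced
bit-for-bit; whether "intra-cluster" means "same label" follows that
tool's convention and is flagged as an interpretation, not asserted.

`group_composition` sums neighborhood counts per cell group,
normalizes by the `all` column with pseudocount 0.001, and reports the
ratio of normalized frequencies between each group and all remaining
cells; one target type's ratios can optionally be renormalized across
groups to display within-type differences.

## Proximity profiles

Nearest-distance tables operate on squared distances with a final
square root; a cell is never its own nearest target. Absent target
types are reported as undefined, not silently infinite. The profile
statistics follow the quoted rules of the figures they mirror: a DC
"has a nearby Treg" when the nearest Treg is strictly closer than
50 μm; a DC–CD8 niche is a DC with a CD8 cell within the ≤ 5 μm static
interaction threshold, and it is Treg-proximal when a Treg lies
strictly within 100 μm; the vessel-site distribution of DC–Treg
contacts restricts to DCs with a Treg within ≤ 5 μm and reports their
BV/LV/none label fractions.

## Track dynamics

Objects are spheres (centroid + equivalent radius); the surface
distance at a frame is max(0, centroid distance − r₁ − r₂), so radius
0 degrades to centroid distance. A contact episode is a maximal run of
consecutive co-observed frames with surface distance strictly below
5 μm. A run of n frames counts n sampling intervals: duration =
n × mean local frame interval, reported in minutes (the convention is
configurable; the source did not state frames-vs-intervals). Gaps in
observation break episodes by default; an optional gap-bridging
tolerance exists and is off. Cumulative interactions use the < 20 μm
centroid rule; both the per-frame Treg count and the cumulative number
of distinct interaction episodes are emitted, episodes as the
headline, since the source does not state which it counts. Track speed
is total path length over total elapsed time.

## Signature scoring

The per-cell score is mean signature expression minus the mean of a
pooled control set drawn per signature gene from genes of comparable
dataset-mean expression (rank-binned; 25 bins, 50 controls per gene —
the cited scoring convention's defaults, pinned here and
configurable). Scores are location-invariant by construction.
Classification is strict: score > cutoff → positive. The printed
cutoffs of the two dialects this package mirrors are 0.5 and 1.5; an
automatic valley finder (KDE minimum between the two largest modes) is
provided for datasets without a printed cutoff and falls back to the
median with a warning when the distribution is not bimodal.

## Synthetic generators

The generators plant every structure the pipeline measures, so each
stage is validated against construction-guaranteed truth:

* **Scenes.** Vessels are capsules (segment + radius, closed-form
  border distances) kept mutually separated by more than twice the
  association cutoff, so planted labels are unambiguous. Defaults:
  1000×1000 μm field, 4 BVs + 2 LVs of radius 5–12 μm and length
  30–80 μm, DC disks of radius 4 μm, association cutoff 20 μm.
  A configured fraction of DCs is planted with surface gap uniform in
  (0.5, cutoff − DC radius − 0.5) of an anchor BV, dispersed along the
  vessel wall with 10 μm Gaussian spread; background cells are
  rejection-sampled beyond cutoff + 2 μm of every vessel. Ccl19 shells
  are annuli straddling covered-BV boundaries.
* **Tracks.** DC and Treg homes sit on rows 1000 μm apart with 150 μm
  pitch; objects perform bounded random walks (1.5 μm/frame SD, ±15 μm
  box), so outside planted episodes every pair's surface distance
  exceeds the 5 μm threshold by tens of μm. During an episode the Treg
  is carried with its DC at a 2 μm surface gap. Frames are 90 s apart,
  matching the intravital acquisition cadence the module emulates.
  Same-pair overlapping episodes merge with a warning; one Treg cannot
  hold simultaneous episodes with two DCs (rejected), since a single
  object cannot be in contact with two separated partners.
* **Expression.** Per-gene baseline means uniform on [0, 3], Gaussian
  noise SD 0.5, a planted positive fraction shifted by 3.0 on the
  signature genes — a 6-noise-SD separation producing the bimodal score
  structure the classifier consumes.

What passing on synthetic data does **not** show: the generators are
distributional, not mechanistic. There is no chemotaxis, no irregular
vessel morphology, no segmentation error, no label noise, no optical
artifacts, and planted classes are geometrically unambiguous by
construction. Real-tissue performance therefore depends on upstream
segmentation and typing quality in ways these tests cannot certify;
what they do certify is that every rule is implemented exactly as
stated and that the statistical machinery is calibrated.

## Numerical choices and degenerate inputs

Zero-area polygons are rejected everywhere. Disk/capsule polygons use
64-segment approximations. Boundary conventions follow the quoted
wording of each rule and are noted above (≥ 5 μm² keep, ≤ 22.5 μm
edge keep, < 20 μm merge, < 0.01% BV, > 0% Ccl19 coverage, ≥ 500 μm²
load, strict `>` cutoff classification, strict `<` dynamic
thresholds). Empty inputs return empty, explicitly-flagged results
(NaN with a warning) rather than raising, except where the contract is
unsatisfiable (no signature genes present, unknown seeds, unknown
workflow parameters). All stochastic stages take a single seed and
derive every stream from it; reruns with the same config and seed are
byte-identical.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` run the oracles at
the sizes the package's own design targets: 50 random scenes of up to
300 detections against the brute-force clustering pipeline, 200 point
sets of up to 50 points against the O(n⁴) empty-circumcircle test,
500 calibration replicates of the 1,000-permutation test on 200-cell
maps, 3 × 20 scenes of 1,000 DCs for association recovery, 500 planted
contact episodes, 50 graphs of up to 500 nodes for the neighborhood
matrix, and 5,000 cells for the score classifier.

## Known limitations

* The analytical null of the external pairwise-enrichment tool is not
  reproduced; the permutation analogue is the contract here.
* Vessel subtype (venous/arterial/capillary) is consumed as an input
  column; no marker-image computation is attempted.
* The 2-D rules are not applied to 3-D surfaces; volumetric data only
  flows through the centroid-based cluster rule and the track module.
* Episode durations are quantized by the frame interval; planted
  medians are recovered only to within one interval.
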
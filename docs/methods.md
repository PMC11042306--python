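# Methods

## Scope and data model

`colonnade` operates on tabular connectome exports: a synapse table (one row
per pre- or postsynaptic site, with 3D position in nanometres, region label,
partner site and — for presynapses — a probability vector over seven
transmitters), a neuron table (type, side instance, group, status) and a
directed connection table (pre, post, weight = paired pre/post site count).
Autapses are excluded and, per neuron, the number of postsynaptic records
must equal the summed input connection weight; the reader validates both.
Region boundaries are represented as surfaces answering ray-intersection and
signed-side queries; the shipped implementation uses horizontal planes
(top z = z₀, bottom z = z₁), which is all the pin construction needs.

Serialization is plain CSV with fixed decimal formatting (positions 3
decimals, probabilities 6), so write → read → write is byte-identical and
fixtures are diffable. Row order never affects results: all stages sort or
aggregate before computing.

## Column centerlines (pins)

A pin is an ordered list of `N_samp` points from a region's top surface to
its bottom, fitted to the synapse cloud of one hexagonal coordinate:

1. gather the 3D synapse positions of the coordinate's neurons;
2. PCA; the first axis is oriented top→bottom via its boundary intersections;
3. drop points whose lateral distance from the axis is ≥ `f_lat·σ_lat`,
   where `σ_lat` is the root-mean-square lateral distance;
4. normalize the axial coordinate t to [−1, 1] between the surfaces;
5. anchor the endpoints: separate sub-PCAs over the t<0.1 / t>0.2 subsets
   (falling back to the `N_PC` extreme points) intersected with the
   surfaces; in single-PCA mode the main axis is intersected instead, with
   an optional median-extrapolated top for regions whose top surface is
   ridged;
6. rank points by t and smooth with a centered moving average of
   2·`N_avg`+1 points (truncated at the ends);
7. take the shortest sublist from top to bottom anchor with consecutive gaps
   ≤ `d_max` = ‖top−bottom‖/`N_tang` (breadth-first search over indices;
   among equally short paths the lexicographically first, so the result is
   deterministic);
8. interpolate each coordinate with a monotone cubic (PCHIP) over cumulative
   chord length and resample at `N_samp` uniform parameter values.

Parameter defaults per region: medulla `f_lat`=2, `N_PC`=800, `N_avg`=260,
`N_tang`=7, `N_samp`=121; lobula `f_lat`=1.5, `N_avg`=37, `N_tang`=2,
`N_samp`=76 (median-extrapolated top over the 37 smallest t, configurable);
lobula plate `f_lat`=1, `N_avg`=56, `N_tang`=2, `N_samp`=51, PCA on
per-neuron mean positions because the region is thin. In the criteria-
enforcing mode (lobula/lobula plate) a pin fails — returning a typed no-pin
value, not an exception — when fewer than `N_avg` points survive step 3 or
when either endpoint is farther than `d_max` from the mean of the 5% most
extreme points. We pair the top endpoint with the smallest-t extreme and the
bottom with the largest; the opposite pairing would compare an endpoint with
the far end of the column and always fail at `N_tang`=2.

Failed or missing coordinates are repaired iteratively: regularization
replaces each pin by its first point plus the coordinate-wise median of the
first-point-anchored offsets of pins within hex distance 2; fill-in takes the
coordinate-wise median of the 4 axis neighbors (±1 along one axial
coordinate) or, failing that, of the 2 neighbors along a single axis.
Iteration stops when nothing is filled in. Refinement runs by default only
in the criteria-enforcing mode: with medulla parameters every column
normally yields a pin, and the neighbor median would flatten real
per-column geometry.

Interpretation choices that the procedure text leaves open, recorded here as
this package's choices: "uniform sampling" is uniform in cumulative
chord-length parameter (the only parameterization that makes depth bins
comparable across pins); the moving-average window is 2·`N_avg`+1 centered
and truncated; ties in the t-ranking break by synapse id; the lateral
outlier rule drops the *far* points (points with lateral distance ≥
`f_lat·σ_lat` belong to other columns).

Synapses are assigned to the pin holding their globally nearest pin point
(k-d tree; exact distance ties go to the lexicographically smaller
(p, q, index)), and depth is that point's order normalized to [0, 1].

## Layers

Per-type depth distributions are mean per-depth-bin synapse counts across
the type's cells, pre and post separately, with depth subsampled by a factor
of 2 (61 bins for 121-point pins). Subsampling decimates to even depth
indices by default; summation of adjacent bins is available behind a flag.
Smoothing is the order-1, window-5 Savitzky–Golay filter — equivalently a
centered 5-point mean — with symmetric end reflection, which conserves total
mass exactly.

Boundaries come from peak cutoffs: `syn_thre` is the largest value t such
that the mass of bins with value > t is at least `frac_peaks` of the total
(scanned over the sorted unique values; any t between two consecutive unique
values yields the same crossings, so the scan is exhaustive). A peak's lower
cutoff is the first bin above threshold, its upper cutoff the next crossing
below, and every cutoff is at least 3 bins from the previous one — peaks
closer than that merge. Defaults: `frac_peaks` 0.85 (medulla), 0.80
(lobula), 0.75 (lobula plate). A boundary spec may average several markers'
thresholds (used where marker peaks leave depth gaps, e.g. the lobula
plate's four input bands). Layers are the half-open intervals [bᵢ, bᵢ₊₁)
with depth 1 in the last layer; whether per-pin boundary warping should
replace the global depth thresholds is unknowable from depth data alone, so
thresholds are global.

## Coordinate assignment and cross-region matching

Paired-connection voting: for cells of types named in a pair list, each
synapse whose partner belongs to the paired type votes for its nearest
column axis; the cell takes the modal coordinate. Exact vote ties and
disagreements between per-pair modes are flagged for review, never silently
resolved (the source workflow resolved them by manual inspection, which is
out of scope).

Cross-region extension: the anchor×candidate connection matrix is
row-normalized (zero rows excluded and reported) and a maximum-weight
matching is computed with `scipy.optimize.linear_sum_assignment`. Among
equal-weight optima the lexicographically smallest pairing by anchor id is
selected by fixing, for each anchor in order, the smallest candidate that
preserves the optimal total (verified by re-solving the remainder);
rectangular matrices leave the surplus side unmatched. Matched pairs are
rejected when the distance between the anchor's mean presynapse position
onto the candidate's type and the candidate's mean postsynapse position
exceeds 8 µm (the inter-column gap scale at the matching depth). Groups of
at least `min_types` = 3 matched roles per anchor are flagged complete and
seed downstream column construction.

## Connectivity typing

Features are summed connection weights to every named type-instance, split
by direction, within the scope regions; partners typed `*_unclear`
contribute nothing and `fragment` cells merge into their parent type.
Clustering is hierarchical with Ward linkage on L2-normalized rows and a
flat cut at k clusters. This is the Euclidean formulation of
cosine-distance/Ward clustering — the normalization is what matters, and
Ward's objective is only well-defined in Euclidean space — and the
per-row-scaling invariance is covered by a test.

Completeness and homogeneity are the standard conditional-entropy scores
(scikit-learn implementation; the tests check it against a direct entropy
computation). Confusion matrices order types lexicographically and clusters
by a greedy picking rule (per type, take clusters by descending count until
every remaining cluster holds ≤5% of the type), and categorize every
non-zero cell from the fraction of the type in the cluster and of the
cluster in the type at 80%/10% thresholds into one-to-one, many-to-one,
one-to-many, mixed, or outlier. Top-k distinguishability ranks a type's
partner connections by weight (ties by label) and reports the fraction of
types whose top-k set is unique; k defaults to 5.

Group classification implements only the quantitative rules — OLIN/OLCN at
>98% of both input and output connections inside the optic lobe (single vs
multiple regions), VPN/VCN at >10% of inputs/outputs inside it — and
returns the rules that fired; cells passing both 10% rules are left in
"other" rather than adjudicated, since the source workflow decided such
marginal cases on qualitative evidence.

Mosaic views project per-cell synapse centers of mass onto the first two
principal axes of a fixed reference synapse set per region (default: all of
the region's synapses, overridable), so candidate-type splits are compared
in one standard view.

## Morphology features

Per neuron and region: presynapse counts, postsynapse counts,
presynapse-innervated column counts and postsynapse-innervated column counts
per subsampled depth bin, concatenated (4 × 61 = 244 features for medulla
sampling). The synapse blocks are multiplied by one factor per direction,
`N_size/N_syn` (total innervated-column count over total synapse count,
computed on the subsampled blocks), which equalizes scales without changing
ratios between depth bins; column blocks stay raw. Clustering uses Ward
linkage under the Euclidean metric and the same scoring machinery.

## Trimming and coverage

Per neuron, columns are ranked by synapse count and the cumulative fraction
by rank computed; the across-neuron median curve (ragged tails padded with
1.0, point (0,0) prepended) is fed to an internal kneedle detector for
concave increasing curves: min–max normalize both axes, form d = y − x, and
accept a local maximum of d as the knee if d falls below
d_max − S/(n−1) before the next local maximum (S = 1). If there is no knee
or the median value at the knee is below 0.775, the trim rank falls back to
the first rank reaching 0.995 (or the last rank). Each neuron then retains
the columns whose count is at least the count of its rank-`rank*` column —
ties at the threshold survive beyond the rank. Kneedle is implemented
in-package (no dependency) so the brute-force oracle test pins its exact
discrete behavior.

Coverage statistics per type and region: cell size = median trimmed column
count; coverage factor = mean number of cells contributing trimmed synapses
per occupied column (occupied = by the type); columnar completeness =
untrimmed occupied fraction of the region's columns; convex area = hull area
of the untrimmed coordinates in column units (axial → Cartesian at unit
pitch, divided by the √3/2 per-column footprint), falling back to the
column count, flagged, for degenerate sets.

## Transmitter consensus

Per-presynapse calls are probability argmaxes (exact ties go to the
lexicographically first transmitter name and are flagged). A neuron's
consensus is the modal call, accepted with ≥50 presynapses and modal
fraction ≥0.5 (boundary inclusive), otherwise "unclear"; types pool all
their cells' presynapses with a 100-presynapse threshold, so a type call can
succeed where every cell fails. Confidence is defined here as the modal-call
fraction (the upstream method's exact confidence formula lives in an
external reference; the scorer is pluggable, with mean modal probability as
the alternative). Type-level dopamine/octopamine/serotonin calls without
independent experimental support are overridden to "unclear" — those classes
are underrepresented in classifier training sets. Fanout is the per-cell
ratio of summed output connection weight to presynapse count, averaged over
cells. Co-transmission is representable as an optional secondary call above
a configurable fraction floor, off by default.

## Inter-region flow

A neuron's contribution to source→target connectivity is its output count
in the target times its input fraction in the source, so contributions to a
fixed target sum to the neuron's downstream count there. The input fraction
uses the listed source regions as denominator by default ("all regions" is
a flag); neurons with no upstream connections in scope contribute nothing
and are reported. Group matrices are sums over neurons; entries are ranked
ascending and binned by cumulative share with default edges
50/75/87.5/93.75/100% (the binary subdivision of the upper half), with ties
broken by position. Labels are invariant to global scaling.

## Synthetic data

The generator plants: a hexagonal lattice patch (radius r, 3r(r+1)+1
columns, 5 µm pitch) of quadratic-Bézier centerlines through a 30 µm deep
region — one global bend direction with small per-column wobble, amplitude
1.5 µm, as in coherently curved neuropil; columnar cell types with
truncated-Gaussian depth profiles whose bands jointly span the depth (so
clouds reach both surfaces, as layered arbors do); block-structured
connectivity, Poisson-distributed per same-column cell pair (neighbor
columns at a configurable overlap factor), each unit of weight instantiating
one pre and one post synapse at profile-drawn depths with 200 nm lateral
jitter and a 5% stray rate into neighboring columns; and per-presynapse
Dirichlet transmitter vectors (concentration 50) with planted dominant
probability 0.75. All randomness flows from one seeded generator; identical
seeds give byte-identical datasets. The ground truth (pins, home columns,
per-synapse columns, types, transmitters) scores every stage.

What the generator does **not** emulate: reconstruction errors and
fragments, non-columnar arbor shapes, inter-region projections within one
dataset, co-transmission, and the full inventory's type diversity. Passing
planted-recovery tests therefore demonstrates algorithmic correctness under
the stated statistical structure, not performance on real reconstruction
noise.

## Problem sizes and numerical choices

Tests and the acceptance experiments run at lattice radius 2–5 (19–91
columns, ~3·10³–8·10⁴ synapse records) with pin parameters scaled to the
per-column point counts (`N_avg`=8, `N_PC`=50): the published `N_avg`=260
presupposes thousands of synapses per column, and a moving-average window
wider than the cloud collapses the centerline. The algorithms are identical
at both scales. Matching tie resolution uses a 1e-9 tolerance on normalized
weights; PCHIP interpolation requires strictly increasing chord length, so
consecutive duplicate points are dropped; hull degeneracies are caught and
fall back to column counts.

## Known limitations

Layer membership is computed from pin depth only (no voxel ROIs or
alpha-shape meshes); manual curation steps of the source workflow (conflict
resolution by inspection, qualitative group adjudication) are flagged, not
reproduced; the neuPrint adapter is an extension point; and statistics at
full-connectome scale (hundreds of types, 10⁵ cells) are untested here,
though nothing in the implementation is quadratic in the dataset beyond the
pairwise steps already noted.
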
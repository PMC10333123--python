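# Methods

This note records the models, conventions and numerical choices behind
the toolkit, including every place where the design was genuinely open.

## Annotation model

An annotation package is a sequence of integer-labelled instance masks
(per-frame TIFF, 0 = background, 2D or 3D) plus a track table with one
record `label begin end parent` per line. Compilation produces a lineage
graph whose nodes are the `(frame, label)` occurrences found in the pixel
data. Track-link edges join consecutive frames of one label and never
skip frames; parent edges join a mother's last observed node to a
daughter's first and may skip frames (a detection gap between mother and
daughter is legal). Strict compilation requires every table span to be
fully covered by pixels and every pixel label to appear in the table;
lenient compilation — used for sparse segmentation references and for
segmentation-only fused outputs — records uncovered frames as coverage
gaps instead. File dialect: `mask%03d.tif` + `res_track.txt` for results,
`man_track%03d.tif` + `man_track.txt` for detection/tracking markers,
`man_seg%03d.tif` for segmentation references; 4-digit frame numbers are
auto-detected. Output labels are 16-bit unsigned; writing a larger label
is an error rather than a silent wrap.

## Matching

A reference instance is assigned to the computed instance that covers a
*strict* majority of its pixels. Exactly 50 % is a non-match: this keeps
the assignment provably unique (two computed instances cannot each hold
more than half of the same region) and fixes the behaviour at the
boundary. The same test drives detection/tracking matching (against
markers), SEG (against reference masks), and segment collection during
fusion — one semantics everywhere. A computed node holding k ≥ 2
reference nodes requires k − 1 split operations; this accounting is a
design choice, not an externally fixed rule.

## Edit costs and their weights

Default weights: split 5, false negative 10, false positive 1, edge
delete 1, edge add 1.5, edge change 1. They follow the convention of
established tracking-evaluation software in this field; all ledger
identities in the test-suite are weight-parametric, so correctness does
not depend on these numbers. Edge correspondence is restricted to vertex
pairs matched 1:1. Every computed edge incident to a false-positive or
merged vertex counts as a deletion; a reference edge whose counterpart
exists but differs in kind (track-link vs parent) counts as one semantic
change, not a delete + add pair. The `min(cost, empty_cost)` clamp is
applied per video, where the normalisation is defined; per-video scores
are averaged, never pooled, when aggregating.

## Biological measures

CT uses strict span equality: a computed track that outlives the
reference cell does not count as a complete reconstruction (looser
readings inflate CT). TF averages only over *detected* tracks (at least
one matched node). Division time is the frame of the mother's last node;
reference and computed divisions are paired greedily, nearest in time
first, ties broken toward the earlier computed event, one-to-one, and
only between mothers whose tracks share at least one matched node.
BC(i) = 2·paired/(n_ref + n_comp), defined as 1 when neither side
divides; it is reported for i ∈ {0, 1, 2, 3} by default. A complete cell
cycle is a track that is born in a division and itself ends in one; its
length is its frame count, and CCA is one minus the Kolmogorov–Smirnov
distance between the two length distributions. When either side has no
complete cycle, CCA is *not applicable* and is reported as such, never
as 0.

## Fusion

Original silver-truth algorithm, per detection marker (ascending id): the
candidate segments covering a strict majority of the marker are
collected; if fewer than ⌈⅔·K⌉ of the K selected methods contribute,
nothing is emitted. Pixels voted by strictly more than two-thirds of the
collected segments are kept (integer fraction arithmetic — no float
threshold wobble); the largest 4-connected component is inserted. On
collision, every involved segment — previously inserted and new alike —
is judged by its PoIP, the intersection as a percentage of the segment's
size at insertion time: above 10 % the segment is removed entirely,
otherwise only its intersection pixels are cleared. Contested pixels
therefore never survive, which is what guarantees disjoint outputs.

Modified algorithm: the voting fraction is optimised per video by
scanning all achievable fractions m/n (n ≤ K) in ascending order and
keeping the first maximiser of SEG against the gold segmentation
reference — deterministic, and the scan always contains 2/3, so the
optimised variant can never score below the fixed one on the same
machinery. When fewer segments are collected than ⌈threshold·K⌉, the
best-performing method's segment is taken instead (ranking = selection
order). Collisions are resolved by watershed on the negated Euclidean
distance transform of the union of the involved segments, seeded per
segment by its own pixels minus the contested ones when its PoIP ≤ 20 %,
or by its detection marker otherwise; ties on plateaus are broken by the
deterministic ascending processing order.

Gold-truth merging collects, per marker, each annotator's
majority-overlapping instance, keeps pixels present in at least two of
them, and takes the largest connected component; a marker annotated by
fewer than two annotators yields no gold mask. If two merged masks
collide (possible only with extreme jitter), the earlier marker keeps
the contested pixels.

Method selection for fusion keeps candidates whose SEG and DET exceed
half the human mean on both the training and test splits, ranked by the
mean of those four scores, at most 16; fewer than five qualifying
methods raises a warning because silver truth is historically skipped in
that regime.

## Dataset properties

Per frame: SNR = (μ_fg − μ_bg)/σ_bg; CR = μ_fg/μ_bg; Het_i = mean over
instances of σ_instance/(μ_fg − μ_bg); Het_b = std/mean of per-instance
mean intensities; Res = mean instance size; Sha = mean circularity
4πA/P² (Crofton perimeter, clipped at 1 to absorb rasterisation bias) or
3D sphericity with a voxel-face surface estimate; Spa = mean
nearest-neighbour centroid distance over mean equivalent diameter.
Across frames: Cha = mean |μ_cell(t+1) − μ_cell(t)|/(μ_fg − μ_bg) and
Ove = mean IoU over consecutive same-track mask pairs; Mit = number of
nodes with ≥ 2 parent edges, also reported as a rate per track-frame
because both conventions appear in published tables. Foreground
statistics pool all instance pixels; the background is the complement of
a 2-pixel dilation of the foreground so that boundary halos contaminate
neither μ_bg nor σ_bg. These normalisations are fixed here explicitly —
published summaries do not print them — so values are comparable within
this toolkit but not necessarily to other implementations. The
colour-scale helper reproduces the usual reporting rule: clamp values
beyond 1.5× the interquartile range from the quartiles, then map
linearly to [0, 1].

## Synthetic scenes

Cells are rasterised ellipses (2D) or ellipsoids (3D) with flat interior
intensity `fg_mean` on background `bg_mean`, plus i.i.d. Gaussian noise
of s.d. `noise_sd` — so SNR = (fg_mean − bg_mean)/noise_sd and
CR = fg_mean/bg_mean analytically. Defaults (128² frames, 6 cells, radii
6–10 px, fg 100, bg 10, noise 5, step 2 px/frame, division probability
0.02 per cell per frame, 20 frames) give a mid-difficulty fluorescence-
like scene: SNR 18 is clean enough that all measures are exercised away
from their floors, and the step size yields consecutive-frame overlaps
near 0.7, typical of well-sampled live imaging. Each frame every cell
takes a fixed-length step in a random direction; contested pixels go to
the cell whose normalised ellipse coordinate is smallest, keeping masks
disjoint without processing-order bias. A dividing mother is replaced by
two daughters at 0.75 scale placed symmetrically about her centre. Cells
leaving the field of view are truncated and their tracks ended.
Detection markers are per-instance erosions of the masks (2 px,
falling back to the mask if erosion would empty it). All draws come from
one seeded stream consumed in a fixed order, so packages are
bit-reproducible across platforms.

What the generator does *not* emulate: textured or graded cell
interiors, blur and shading artefacts, touching-cell boundaries,
apoptosis, debris, and photobleaching trends. Passing tests therefore
demonstrate the correctness of the evaluation machinery on controlled
input, not robustness of any segmentation method on real microscopy.

### Ledgered corruption

`corrupt_submission` injects a requested number of errors, each consuming
one or two whole tracks no other injection touches, and returns the
realised ledger *in units of graph edit operations*, including the edge
operations an injection implies:

- false negative: the last node of a childless track is deleted
  (1 FN + 1 reference link to restore);
- merge: a neighbour track is absorbed into another in their common
  final frame (1 split + 2 links to restore + 1 computed link to delete);
- cut link: the last node of a track is detached into a fresh label
  (1 link to restore);
- semantics change: the final link of a track is reported as a division
  (1 edge-kind change);
- spurious blob: a disk is placed in free background (1 FP); a spurious
  *link* is realised as a 2-frame background track (2 FP + 1 computed
  link to delete);
- boundary jitter: one node's mask is dilated into the background —
  changes SEG but, because the mask still covers its marker, never DET.

Because the sites are disjoint, the weighted ledger sum equals the AOGM
cost exactly; this identity is asserted across random requests and
weight sets and is the backbone of the measure tests. Requests that
cannot be placed (not enough eligible tracks, no free background) raise
an explicit infeasibility error rather than degrading silently.

## Analytics

Correlation banding uses left-closed magnitude intervals: [0, 0.2) very
weak, [0.2, 0.4) weak, [0.4, 0.6) moderate, [0.6, 0.8) strong, [0.8, 1]
very strong, mirrored for negative coefficients. Published usage is not
perfectly self-consistent near 0.6 (a coefficient of 0.608 is sometimes
described as moderate); this toolkit applies the interval table and
documents the discrepancy rather than special-casing it. The human band
is mean ± 1 s.d. of the three annotators' scores, boundary inclusive.
Leaderboard ties break alphabetically; top-3 points are 3/2/1 per
top-1/2/3 occurrence, summed across datasets. Group-comparison tests
(Kruskal–Wallis, Dunn, Mann–Whitney) are deliberately left to standard
statistics libraries and are not reimplemented here.

## Problem sizes and tolerances

The test-suite and the acceptance script run on scenes between 64² × 2
and 160² × 16 frames with 4–6 initial cells — large enough that every
code path (divisions, exits, collisions, sparse references) occurs, small
enough that the whole suite runs in seconds. Parameter-recovery
assertions use ±5 % tolerance: at these sizes the Monte-Carlo error of
the intensity statistics and the rasterisation error of disk overlaps
both sit well under that bound (measured relative errors are typically
below 1 %). Exact identities — ledger sums, determinism, disjointness,
the no-false-positive property of fused outputs — are asserted exactly,
with no tolerance.

## Known limitations

- Edge-cost accounting around merged/false-positive vertices follows the
  explicit convention above; other implementations may attribute the same
  errors to different operation categories (the normalised scores agree
  on non-pathological inputs, the breakdowns need not).
- The split accounting (k − 1 operations for a k-fold merge) and the
  two-thirds collection threshold being relative to the number of
  *selected* methods (not the number submitting in that frame) are
  documented choices where the published descriptions are silent.
- PoIP is measured against a segment's size at insertion time; repeated
  collisions are each judged against that original size.
- 3D support is implemented throughout (ellipsoid scenes, voxel-face
  sphericity) but the test-suite exercises 2D far more densely.
- CCA compares cycle-length distributions, not per-cell correspondence;
  two wrong results with coincidentally equal length distributions score
  CCA = 1 by design.
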
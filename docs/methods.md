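# Methods

This note documents the models behind celltrax, the parameters that
matter, the synthetic data the package is validated on, and the design
choices made where the problem left room.

## Recognition

Spot detection uses the scale-normalized, negated Laplacian of Gaussian,
`R = -σ² ∇²(G_σ * I)`, so bright blobs give positive peaks and a response
threshold transfers across scales: a Gaussian blob of amplitude `A` and
size `s` under a filter of scale `σ` peaks at `2Aσ²s²/(σ²+s²)²` (so a
matched filter, `σ = s`, responds at `A/2`). Two numerical details:

* scipy's truncated LoG kernel does not sum exactly to zero; the kernel's
  DC gain (measured by filtering a constant) times the Gaussian-smoothed
  image is subtracted, so constant images map to exactly zero response;
* candidate maxima are suppressed greedily, strongest first, with ties
  broken by (row, col) lexicographic order — detection is deterministic
  across runs and platforms.

Region formation is a marker-controlled watershed of the inverted
smoothed intensity, seeded with one marker per spot and restricted to a
foreground mask (Otsu of the smoothed frame by default, or a fixed
threshold). The raw watershed support is then trimmed per object to its
full-width-at-half-maximum contour: pixels above
`background + 0.5 × (peak − background)`, with the background estimated
as the median intensity outside the foreground. A single global
threshold systematically over-extends dim objects (Otsu settles well
below half-maximum on sparse-foreground fluorescence frames, roughly
doubling region area); the per-object relative cut delineates each
object at its own scale, which is how nuclei are conventionally outlined
in fluorescence work. Set `region_level=None` for the raw watershed.

Key parameters (`DetectionParams`): `sigma` (px, default 3.5 — match to
object radius/√2), `threshold` (response units, default 10 — about a
quarter of the matched-filter response of the dimmest expected object),
`min_distance` (px, default 5), `smoothing_sigma` (px, default 1),
`region_level` (relative, default 0.5).

The built-in recognizer assumes bright blobs on a dark background (the
fluorescence case). Anything else should enter through the detector
plugin registry — a plugin maps one frame to a ROI list, and imported
label images (e.g. from a deep-learning segmenter) are bridged by the
`masks` plugin. Plugin output is validated against the ROI invariants
and violations are reported against the plugin by name.

## Linking

Stage 1 solves, per adjacent frame pair, a linear assignment problem on
the standard augmented matrix: link cost `d²(1 + Σ w_k |Δf_k|/max|f_k|)`
(squared centroid distance, optionally inflated by relative feature
differences; no feature terms by default), entries beyond `max_link_dist`
(default 15 px) forbidden, and birth/death alternatives priced at
`alt_cost_factor` (default 1.05) times the worst accepted link. The
solver is `scipy.optimize.linear_sum_assignment` with forbidden entries
mapped to a finite sentinel and verified after the fact; optimality is
cross-checked against exhaustive permutation search in the test suite.

Stage 2 runs one more assignment over segment endpoints:

* gap closing: end → start with frame offset `2 … max_gap_frames+1`
  (default bridges up to 2 skipped frames), cost `d² × offset`; closed
  gaps keep no interpolated nodes;
* division: a segment start attaching to a *non-terminal* node of
  another segment exactly one frame earlier, within `max_split_dist`
  (default 15 px), cost `d²`. The mother segment is cut after that node;
  its continuation and the attached segment become the two daughters.

Merging (cell fusion) is not modelled; divisions are capped at two
daughters by validation (configurable). Where several assignments tie,
any minimum-cost solution is accepted — tests assert on cost, not on
pair identity.

## Sequential tracking

A bootstrap particle filter with `n_particles` (default 300) candidate
positions: Gaussian random-walk proposal (`motion_sigma`, default 5
px/frame — generous for nuclei drifting ≲2 px/frame), appearance weight
`w ∝ exp(β · sim)` with `β = 10` and `sim` the normalized
cross-correlation of the initial template with the patch at the particle
(zero-variance patches score 0 by definition, avoiding NaN on flat
background; an SSD variant is available), systematic resampling when the
effective sample size drops below half the cloud, and the weighted mean
as the per-frame estimate. The template is fixed by default (drift-safe);
an exponential-moving-average update is optional. Backward tracking is
the same recursion run over a descending frame range. Everything is
driven by one seeded generator, so fixed seeds give bit-identical tracks.

`resume_from` implements the cancel–correct–resume loop: truncate the
track at the corrected frame, re-take the template at the corrected
position, continue to the original end.

## Editing

Edits are value-producing (the input lineage is never mutated) and every
operation either returns a lineage that passes validation or raises.
Deleting an interior node splits the track rather than bridging the
hole — identity across a gap is never invented silently; re-joining is
an explicit `link`. Cutting re-points the children of the cut track to
the tail piece (the piece containing the old last frame), which is the
only re-pointing that preserves mother-before-daughter ordering.
Deleting a parent orphans its children by default (cascade optional).
Edit scripts apply atomically: the first failing command aborts with its
index and no state change.

## Evaluation

Matching per frame follows the strict-majority rule: ground-truth object
G matches result object R iff `|G∩R| > ½|G|` (exact halves do not
match); the rule makes the match unique per G, while one R may absorb
several G. SEG is the mean Jaccard over all GT objects in all frames,
zero for unmatched objects (one global mean, not a mean of per-frame
means).

DET/TRA are acyclic-oriented-graph-matching scores. Nodes are
objects-in-frames; edges are track links (consecutive track nodes,
including across closed gaps) and parent links (mother's last node →
daughter's first). Operation counts: a result node matched by k > 1 GT
nodes contributes k−1 node splits (NS, weight 5); unmatched GT nodes are
false negatives (FN, 10); unmatched result nodes false positives (FP,
1). Result edges whose endpoints are both uniquely matched induce
comparable edges: induced pairs absent from the GT graph are redundant
deletions (ED, 1), GT edges never induced are additions (EA, 1.5), and
induced edges of the wrong kind (link vs parent) are semantics changes
(EC, 1). Edges with split or spurious endpoints count as ED. Then
`TRA = 1 − min(AOGM, AOGM₀)/AOGM₀` with `AOGM₀ = 10·|nodes| +
1.5·|edges|` of the GT graph, and DET likewise from node operations
only. Parent edges are compared as-is (no one-frame tolerance). The test
suite carries an independent straight-line re-computation of all three
scores and checks parity on hand-built scenarios covering broken links,
missed/spurious cells, merges, missed divisions and wrong edge kinds.

Both graphs are keyed by mask labels equal to track ids (the
track-table convention); `relabel_masks_to_tracks` restores that
invariant after edits that renumber tracks.

## Synthetic movies

The generator emulates fluorescence nuclear imagery: isotropic Gaussian
blobs (σ 3–4 px, amplitude 80–120 over a background of 10) on a
256×256 field, Brownian diffusion (0.5 px/frame) plus a common drift
(0.3, 0.2 px/frame) with reflecting boundaries, Gaussian read noise
(σ 2; Poisson shot noise optional). Ground-truth masks are each cell's
own 50 %-of-peak contour rasterized before noise, with contested pixels
going to the brighter cell — the truth is therefore exact and
independent of the noise realization. A dividing cell spends two frames
"swelling", rendered as a dumbbell of two lobes whose separation grows
with `swell_factor`, then splits into daughters `division_separation`
(12 px) apart, recorded as mother→daughter edges. Divisions are
scheduled so daughters are observable for at least two frames. The RNG
draw order is fixed and documented in `generate_movie` so independent
consumers can replay the stream (the test suite does).

The default regime — 15 cells, 30 frames, two scheduled divisions,
minimum seeding separation 28 px, seed 42 — is the well-separated
condition under which link-type tracking is expected to be exact; the
end-to-end tests assert DET = TRA = 1.0 and SEG ≥ 0.7 there (SEG < 1 is
expected from the ±1 px rasterization band). Two knobs recreate the
classic failure modes:

* `contact_fraction` seeds cell pairs travelling `contact_distance`
  (6 px ≈ 1.7 σ) apart with shared diffusion; detection merges each pair
  into one object, producing node splits and broken links;
* `swell_factor` ≥ ~1.4 widens the pre-division dumbbell past the
  blob-resolution limit (lobe separation `3σ(swell_factor−1)` per swell
  frame), so the still-single mother is over-segmented and the linker
  hallucinates an early division.

What the generator does *not* emulate: phase-contrast or bright-field
appearance, intensity fluctuations over time, cell shape irregularity,
apoptosis, fusion, out-of-focus blur and field inhomogeneity. Passing
tests therefore demonstrate the correctness of the machinery on
blob-like fluorescence-type data, not performance on arbitrary
modalities — for those, an external recognizer via the plugin path is
the intended route.

`inject_errors` corrupts a result deterministically (merge, split, drop
link, drop object, false division) with a log, for testing that the
metrics and the repair tooling respond as documented.

## The repair loop

The documented correction recipes combine the three tracking modes:

* contact pairs: re-track each member with the particle filter from a
  user-supplied seed position (`motion_sigma` 2 px/frame for slow
  nuclei), then split every merged region by assigning its pixels to the
  nearer tracked position. A marker-controlled watershed is *not* used
  here: two blobs merged tightly enough to defeat detection share a
  single intensity peak, so there is no valley for a watershed line and
  one marker would win almost the whole region;
* over-segmented divisions: replace the fragments with their union via a
  replayable edit script;
* finally, re-run link-type tracking over the full edited ROI set.

On the error regime (two contact pairs, `swell_factor` 1.5) this loop
takes the tracking accuracy from below 1 back to 1.0 at the injected
sites; the acceptance script reports both numbers.

## Problem sizes and runtime choices

All simulations are sized to run comfortably on one CPU core: 256×256 ×
30-frame movies with 15–19 cells for end-to-end checks, 20 repetitions ×
30 frames for the particle-filter benchmark, and 200 random assignment
problems (augmented matrices up to 6×6) for the exhaustive LAP
optimality check. These sizes were chosen so the full suite finishes in
well under a minute of compute per scenario while still exercising every
code path (divisions, gaps, contact, over-segmentation).

## Known limitations

* 2D only; z-stacks are out of scope.
* Detection runs on one designated channel; features are computed on all.
* The stage-2 LAP handles gap closing and binary division, not fusion or
  multi-hypothesis whole-movie optimization.
* Sequential tracking propagates a box, not a region shape.
* SEG requires region masks; spot-only results can only be scored with
  DET/TRA (rasterized bounding boxes would bias Jaccard).
* CTC-format labels are 16-bit: at most 65535 tracks per result.
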
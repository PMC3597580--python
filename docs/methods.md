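# Methods

This note documents the models, algorithms and numerical choices behind
`cecalign`: what is computed, under which assumptions, with which defaults,
and what the synthetic test substrate does and does not establish about
real clinical images.

## Problem setting

A specular microscope images the corneal endothelial mosaic of the central
cornea; a fixation light makes repeated images of the same eye overlap
approximately, but each acquisition is shifted, rotated and slightly scaled
by head repositioning. Aligning two frames so that corresponding cells
coincide turns the mosaic itself into evidence: if every cell of the first
visit is found unchanged in the second, no cell in that patch was lost.
The discriminative signal is the natural variation of cell sizes and
positions (polymegathism) — two unrelated mosaics of similar density will
not coincide cell-for-cell under any small affine map.

## Centroid extraction

Pipeline (all steps deterministic): Gaussian illumination flattening
(divide by a blur at `background_sigma`, rescale by the global mean, clip
to the bit-depth range) → Gaussian smoothing (`smoothing_sigma`) → marker
generation → marker-controlled watershed on the inverted image → area and
border filtering → unweighted region centroids, sorted by (y, x).

Markers are the Otsu-bright connected components that contain at least one
regional maximum surviving h-maxima suppression (`h_depth`). The
h-criterion rejects shallow noise peaks; merging maxima within one bright
component keeps a single marker per cell even when a flat-topped interior
carries several pixel-level maxima or when flattening halos turn an
isolated cell's plateau into a ring. Dark pixels below the Otsu threshold
form an explicit background catchment so isolated cells do not flood the
frame.

Defaults (`SegmentationParams`): `background_sigma` 50 px,
`smoothing_sigma` 2 px, `h_depth` 10 gray levels, cell area 40–2000 px²,
`border_margin` 2 px. They were fixed once against the synthetic renderer
at its default scale (≈250 cells in 480×480 px) and live in the params
object, not in code paths. Cells whose bounding box approaches the frame
border are dropped deliberately: their truncated shape biases the
centroid. Centroids closer than 2 px are deduplicated (greedy, keep the
first in (y, x) order).

Coordinates are 0-based pixels, x = column, y = row, origin top-left;
centroids are continuous (sub-pixel). CSV interchange uses an `x,y` header
plus a `# frame <width> <height>` comment.

## Registration

Given moving set *M* and fixed set *F* (≥ 3 points each), the estimated
map is T(x) = A x + t from moving to fixed coordinates.

**Start candidates.** Both sets are rasterized into occupancy grids with
bin = 0.5 × mean nearest-neighbour spacing of *F*; points are splatted
bilinearly and the grid blurred (σ = 0.5 bin) so the correlation peak
survives sub-bin offsets. The full FFT cross-correlation scores every
integer-bin translation; the top `n_candidate_translations` (default 20)
peaks are kept, ties broken by smaller translation magnitude, then (dy, dx)
lexicographic order. Because a translation-only start cannot bridge larger
head tilt, the search is repeated over deterministic rotation probes
(default 0, ±3°, ±6°, ±9° about the moving frame centre); each start is the
probe rotation composed with a candidate translation.

**Inner loop (affine ICP).** Repeat up to `max_inner_iterations` (50):
pair mutually nearest centroids of T(M) and F within the pairing cap
(0.6 × mean NN spacing of F); refit T by ordinary least squares of each
fixed coordinate on (1, x_moving, y_moving) over the paired points (a
degenerate or singular fit terminates the start). Convergence: stop after
`convergence_patience` (3) iterations without improvement, where
improvement is judged lexicographically on (coincidence pairs, wide-cap
pairs, −coincidence RMS).

**Scoring and verdict.** Alignment quality is the number of *coinciding*
centroids: mutual-NN pairs within the score cap, 0.2 × mean NN spacing of
F. Two caps are deliberate: at equal densities the wide ICP cap pairs
nearly everything between any two sets, so it can steer the fit but cannot
discriminate; coincidence within a fifth of a cell spacing essentially
only happens between images of the same mosaic. The best start's result
becomes **match** if coincidence pairs ≥ `match_min_pairs` (30) and the
matched fraction (pairs / min(|M|, |F|)) ≥ `match_min_fraction` (0.5) and
the transform passes the plausibility screen; **implausible** if only the
screen fails; otherwise **no_match**. Restarts stop early once a candidate
reaches a matched fraction of `early_stop_fraction` (0.8) — a pure speed
optimisation that never changes which result wins otherwise.

**Plausibility screen.** The linear part is factored uniquely as
A = R(θ) · Shear(m) · diag(s_x, s_y) (the rotation that zeroes the lower
off-diagonal of RᵀA; recomposition reproduces A to machine precision).
Defaults: s ∈ (0.8, 1.25), |m| ≤ 0.15, |θ| ≤ 15°. Same-day, same-device
acquisitions differ by small head movements only; the limits are generous
on purpose — they exist to catch the grossly distorted fits that arise
when a small set (≈73 cells) is contorted onto a subset of a larger
unrelated set, not to arbitrate borderline alignments. A low-count flag
(either input < 100 centroids) accompanies every result, since below
roughly that count a match loses evidential value.

The whole procedure is deterministic: candidate enumeration, tie-breaking
and pairing involve no random draws (the config seed exists for forward
compatibility with candidate subsampling).

## Synthetic data

The generator replaces unavailable clinical material and defines the
conditions under which the pipeline is validated.

**Mosaic.** A hexagonal lattice at the pitch implied by `n_cells` in the
frame, given a seed-dependent global orientation (uniform over the 60°
hex symmetry) and phase — real mosaics have no preferred axis, and two
eyes never share one; without this, two "unrelated" mosaics would share
lattice phase and coincide heavily by construction. The `n_cells` sites
nearest the frame centre are jittered uniformly by `jitter_fraction`
(default 0.3) × pitch per coordinate; the Voronoi tessellation (bounded by
mirror sites across the frame edges) is clipped to the frame, so cell
areas sum exactly to the frame area. Polymegathism is thus controlled by
one knob; no claim of clinical morphometry is made.

**Rendering.** Nearest-seed labelling, dark borders (level 60) on bright
interiors (190), additive Gaussian noise, optional multiplicative radial
vignette, 8-bit output.

**Pairs.** fixed = mosaic centroids; moving = inverse ground-truth
transform applied to them, cropped to the (equal-size) moving frame. If
the frame crop keeps more than `overlap_fraction` × |fixed| points, a
deterministic band crop (smallest x first) trims to the target; if it
keeps less than target − 5 percentage points, the requested overlap is
unreachable and an error is raised. Degradations are then applied in
order: Gaussian centroid jitter, Bernoulli dropout, uniform spurious
points. Unrelated pairs are two mosaics with distinct seeds.

What passing on this substrate does **not** show: robustness to real
optical blur, local mosaic remodelling after cell loss, video-print
digitization artifacts, or non-affine distortion; the generator's cells
are convex Voronoi polygons, which real cells are only approximately.

## Detection power

The cornea is modelled as a hemisphere of white-to-white diameter w
(11 mm) with uniform density ρ (2000 cells/mm²): N = 2π(w/2)²ρ ≈ 380,000
cells (a flat disc, exposed as an option, gives half that). Diffuse damage
of fraction p marks D = round(pN) cells. Sampling n cells without
replacement, detection — at least one damaged cell inside the aligned
patch, which is sufficient because a single damaged cell breaks the
cell-by-cell identity — has probability

    P = 1 − C(N−D, n) / C(N, n).

The Monte-Carlo estimator draws the per-replicate damaged-cell count from
numpy's hypergeometric sampler (the exact law of an explicit
without-replacement draw, at a fraction of the cost) over `reps` (1000)
seeded replicates and reports the detection fraction with its binomial
standard error next to the closed form. The threshold search walks a
damage grid (default 0.1%) and returns the smallest value whose
closed-form probability reaches the target (0.95), or None when none does.

For contrast, `cohort_ttest_total_n` sizes a two-sample two-sided t-test
for a mean density loss δ = 20 cells/mm² (1% of a 2000 baseline) at
σ = 200 cells/mm², α = 0.05, power 0.95 — statsmodels' noncentral-t
solver, with an integer walk to the smallest per-group n that actually
achieves the power and a normal-approximation fallback where the
noncentral-t evaluation overflows. The two-sample reading is used because
the comparison of interest is between an exposed and an unexposed cohort;
it yields ≈ 5,200 patients in total.

## Numerical choices and limitations

* Affine fits use `numpy.linalg.lstsq`; rank < 3 of the design matrix
  (fewer than 3 pairs, or collinear pairs) raises a degenerate-fit error.
* Transforms are screened for singularity at a relative determinant
  tolerance of 1e-12; decomposition/recomposition round-trips to ~1e-15.
* Image warping inverse-maps with bilinear interpolation (nearest
  available for bit-exact checks); out-of-frame pixels get a sentinel
  value and a False entry in the output mask. Stripe composites and
  flicker animations never resample — every output pixel comes verbatim
  from one input.
* FFT correlation scores are rounded to 1e-6 before ranking so ties break
  identically across platforms.
* Registration accuracy targets hold under the validated envelope
  (≈250-cell frames, jitter ≤ 0.5 px, dropout ≤ 15%, overlap ≥ 40%,
  |rotation| ≤ 10°, scale 0.95–1.05); outside it, rotation beyond the
  probe range or overlap below ~30% degrades to no_match rather than to a
  wrong match, which is the intended failure direction.
* Monte-Carlo suite sizes (1000 power replicates; 27 sensitivity and 50
  specificity pairs) are the package's validation defaults; all are
  seed-reproducible.
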
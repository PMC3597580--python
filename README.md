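# cecalign

Cell-by-cell alignment of repeated specular microscopy (SM) images of the
corneal endothelium.

Corneal endothelial cells (CECs) do not regenerate: their preservation is a
key safety parameter in anterior-segment trials, yet density estimates are
too noisy to certify stability in an individual eye. If, instead, two SM
images of the same eye can be aligned so that corresponding cells coincide,
the unchanged mosaic itself is proof that no cell in the imaged patch was
lost. The obstacle is that repeated acquisitions shift, rotate and scale
slightly with head position, and SM frames offer no obvious landmarks.

`cecalign` registers the two frames using the cells themselves as
landmarks. It is aimed at reading-center and image-analysis work: a Python
library first, with a thin `cec-align` command-line wrapper.

## Method

Cell centroids are extracted from each grayscale frame by illumination
flattening, smoothing, and marker-controlled watershed segmentation. The
moving centroid set *M* is then aligned onto the fixed set *F* by
estimating a planar affine map

    T(x) = A x + t,        A ∈ R^{2×2},  t ∈ R^2,

with two nested loops. The outer loop restarts from candidate starts
(cross-correlation peaks of rasterized occupancy grids, over a small set of
rotation probes). The inner loop is iterative-closest-point with an affine
model: pair mutually nearest centroids within a distance cap, refit A and t
by ordinary least squares of the fixed coordinates on the moving
coordinates, and repeat until the matched-pair count stops improving. The
best alignment is scored by the number of centroids that *coincide* (within
a tight fraction of the cell spacing) and turned into a verdict:

* **match** — enough cells coincide under a physically plausible transform;
  the frames show the same cells, cell for cell;
* **implausible** — a high-scoring fit whose scale/shear/rotation
  decomposition is outside same-session acquisition geometry (the
  overfitting mode seen when a sparse set is contorted onto a subset of a
  larger unrelated set);
* **no_match** — no alignment reaches the thresholds; the frames do not
  share a mosaic.

A low-count flag warns when either frame supplies fewer than ~100
centroids, the regime where a match stops being reliable evidence.

The package also quantifies why cell-by-cell comparison is worth the
effort. Modelling the endothelium as a hemisphere of 11 mm white-to-white
diameter at 2000 cells/mm² (≈ 380,000 cells), the probability of catching
diffuse damage of fraction *p* in an aligned patch of *n* cells is
hypergeometric, P = 1 − C(N−D, n)/C(N, n) with D = pN: a single 300-cell
patch detects 1% diffuse loss with 95% probability, while a density-based
two-sample t-test (σ = 200 cells/mm²) needs thousands of patients for the
same claim.

Because no clinical SM images ship with the package, a synthetic generator
produces jittered-hexagonal Voronoi mosaics, SM-like renderings, and
registered pairs with known ground-truth transforms for testing and
benchmarking.

## Worked example

`examples/01_simulate_and_register.py` simulates a second visit of a
250-cell mosaic (25 px shift, 3° rotation, 2% magnification, 0.5 px
centroid jitter, 10% dropout, 60% overlap) and recovers the transform from
the centroid sets alone:

```
fixed set: 250 centroids, moving set: 136
verdict: match
matched pairs: 136 (fraction 1.00), residual RMS 0.72 px
recovered translation (+32.94, -32.05) px  [truth (+33.35, -32.28)]
recovered rotation +3.010 deg  [truth +3.000]
recovered scale (1.0210, 1.0192)  [truth 1.0200]
```

Every moving centroid found its counterpart; translation is recovered to
half a pixel, rotation to a hundredth of a degree. The other examples cover
centroid extraction from rendered images (`02`), the visual verification
outputs — warped overlay, stripe composite, alternation-flicker GIF,
centroid superposition plot (`03`) — and the detection-power statistics
(`04`), which print:

```
endothelial cells (hemisphere, 11 mm, 2000/mm^2): 380,133 ~ 380,000
P(detect 1% damage | 300-cell patch): 95.4% (MC, SE 0.7%; closed form 95.1%)
smallest damage detectable with 95% probability, 300 cells: 1.0%
smallest damage detectable with 95% probability, 600 cells: 0.5%
patients needed to rule out the same 1% loss by density t-test: 5,200
```

## Command line

```sh
cec-align simulate --cells 250 --seed 1 --out-prefix sim/
cec-align register sim/moving.csv sim/fixed.csv --out result.json
cec-align centroids image.png --out points.csv
cec-align power detect --sample 300 --damage 0.01
```

`register` accepts images (PNG/TIFF) or centroid CSVs and exits 0 on match,
3 on no-match, 4 on implausible.

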
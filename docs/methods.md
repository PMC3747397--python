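# Methods

This note documents the models, conventions, parameters and design choices
behind `specseg`, and what the synthetic benchmark does and does not show.

## Problem setting

Specular reflections on moist tissue appear in three phenotypes with
different detectability. Large reflections near the endoscope have very
high, usually clipped intensities and a slow radial decay; any reasonable
threshold finds their core. Small reflections on curved surfaces farther
away have a step-shaped border; the bright ones still clear a threshold,
but the weak ones sit inside the intensity range that bright ordinary
tissue also occupies, so a global threshold can only trade missed weak
reflections against false positives on tissue. The hybrid detector breaks
that trade-off by using a structural cue — the step edge forms a closed
contour, which smooth tissue shading does not.

## Conventions

- Pixel grid: (row, col), 0-based, row 0 at top; images are H×W×3 uint8,
  masks H×W boolean (stored as 0/255 PNG).
- Luminance: BT.601 weights (0.299, 0.587, 0.114) — the classic YUV
  definition. All intensity statistics (component means, ring means,
  Type-3 constraints) use it.
- Strict inequalities everywhere a comparison defines a set membership
  (thresholds, cone membership, Type-3 constraints).
- Connectivity: 8-connectivity for components of thresholded masks and for
  lobe growth (blob-like bright regions; avoids splitting thin diagonal
  glints). The complement of the edge map is labeled with 4-connectivity —
  the dual of 8-connected edge curves — so a flood fill cannot leak
  diagonally through a one-pixel contour.
- Histogram binning: half-up rounding (`floor(v + 0.5)`), 256 bins.
- Histogram smoothing: unit-sum Gaussian kernel truncated at ±⌈3σ⌉ bins,
  edge-including mirror padding. This boundary conserves total mass
  exactly for any normalized kernel; the edge-excluding variant does not.

## Detector parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `gray.t_gray` | fixed luminance threshold | 230 | intensity |
| `peak.t_min` | lowest admissible specular-peak threshold | 100 | intensity |
| `peak.sigma` | histogram smoothing width | 2 | bins |
| `cone.x0` | cone tip along the gray axis | 100·√3 | axial units (intensity·√3) |
| `cone.a` | cone slope | 0.3 | dimensionless |
| `lobe.c` | growth threshold factor (`Y > c·μ`) | 0.7 | dimensionless |
| `hybrid.canny_low/high` | hysteresis thresholds | 0.1 / 0.25 | fraction of max gradient |
| `hybrid.canny_sigma` | Canny smoothing | 1.0 | px |
| `hybrid.closing_radius` | closing element radius | 1 | px |
| `hybrid.t_av` | min mean luminance of a Type-3 region | 140 | intensity |
| `hybrid.t_diff` | min drop from region to perimeter ring | 30 | intensity |
| `hybrid.t_cc_min/max` | Type-3 size band (strict) | 5 / 2000 | px |

Defaults are starting points, not claims of optimality: the supported way
to set parameters is `optimize_parameters` (exhaustive grid search
maximizing mean Jaccard on a labeled corpus), and the benchmark always
optimizes each detector before comparing. Ties in the grid search go to
the lexicographically smallest parameter tuple, which makes the argmax
deterministic.

### Notes on individual choices

- **Peak-threshold candidate set.** The raw descent-end rule would always
  select the final descent into the histogram's empty tail and produce an
  empty segmentation; candidates are therefore required to have positive
  histogram mass above them. Returning "none" (empty mask) when no
  candidate clears `t_min` is deliberate robustness for reflection-free
  images.
- **Cone geometry.** Membership compares the pixel's orthogonal distance
  to the gray axis with `a·(axial − x0)`, where `axial = (R+G+B)/√3`.
  `x0` is therefore in axial units: a gray pixel of value v sits at axial
  coordinate v·√3. Note that a perfectly gray uniform image above the tip
  is, by construction, entirely inside the cone.
- **Canny thresholds as fractions of the max gradient.** Absolute gradient
  thresholds do not transfer across scenes with different contrast. The
  reference magnitude is the Sobel magnitude of the Gaussian-smoothed
  luminance — the same operator the Canny implementation applies
  internally. Consequence: any non-constant image has at least one edge
  pixel; the relevant degenerate condition for the hybrid is "no *closed*
  contour", under which it reduces exactly to cone thresholding plus lobe
  growing. The default high threshold (0.25) is set to sit above the rim
  gradient of a large smooth Type-1 blob and below the step-edge gradient
  of small reflections, so each phenotype is routed down its intended
  process line.
- **Closing element.** Chessboard-metric disk (square of side 2r+1). A
  Euclidean radius-1 disk (4-connected cross) provably cannot bridge a
  one-pixel gap in a straight one-pixel contour — dilation fills the gap
  pixel, erosion removes it again — so the square is the smallest element
  for which radius 1 means "close small gaps".
- **Contour ownership.** Edge pixels adjacent to an enclosed region are
  assigned to that region's mask: the rim of a step-edged reflection is
  visually glare, and this keeps Type-2 masks contiguous with their
  thresholded cores.
- **Perimeter ring.** The Type-3 intensity-drop constraint is measured on
  the one-pixel ring *beyond* the contour, not on the contour itself, so
  it compares glare to tissue rather than glare to its own anti-aliased
  rim. Components whose ring is empty (pathological geometry) cannot be
  scored and are excluded with a log message.
- **Type-1 lobe growing.** Only Type-1 components are lobe-grown; Types 2
  and 3 are bounded by their contour, which is the more precise boundary.
- **Seed pixels are always kept** in lobe growth even if their own
  luminance fails the `c·μ` test (possible because cores may come from the
  transformed image while growth uses raw luminance); the final
  segmentation is defined as a union with the core.
- **Empty-vs-empty Jaccard is 1.0** (perfect agreement), so images without
  reflections are not dropped from the per-image distribution.
- **Reflection matching** is one-pixel overlap — the most permissive rule,
  under which tiny Type-3 detections register; PPV counts predicted
  components touching no ground truth. Quantiles use linear interpolation.
  Average sensitivity is the unweighted mean over types present; the
  reflection-count-weighted mean is also reported.

## Synthetic scenes

`generate_scene` renders what the detectors are built around, not
photorealism:

- **Tissue background**: a spatially correlated Gaussian field (correlation
  length 6 px) mapped to liver-like channel ranges (R 90–160, G 40–90,
  B 35–80 at the default brightness level) — smooth, low-texture, clearly
  saturated (mean HSV saturation ≈ 0.45).
- **Sheen patches** (3 per scene, unlabeled): wide Gaussian blends toward a
  bright desaturated gray, peaking around luminance 150 with low
  saturation. They emulate bright tissue and are the reason thresholds
  cannot reach the weak reflections for free: a detector that admits the
  Type-3 intensity/saturation region also admits sheen area several times
  larger, which the Jaccard-driven optimization punishes. Their profile is
  smooth, so they produce no closed Canny contour.
- **Type 1** (2 per scene): blend-to-white profiles `w = min(1, 1.15·exp(−r²/2s²))`,
  s ∈ [10, 13] px — a clipped plateau in the center, slow radial decay,
  strongly desaturated. Ground truth is cut where the profile falls below
  10% of its amplitude (a Gaussian tail has no natural boundary; the
  fraction is config). The decay scale keeps the rim gradient below the
  Canny high threshold so Type 1 does not form closed contours.
- **Type 2** (3 per scene): near-white disks, radius 3–6 px, peak intensity
  235–255, ≤1 px anti-aliasing — step edges that Canny reliably closes.
- **Type 3** (4 per scene): weak disks, radius 3–6 px, placed on ordinary
  (non-sheen) tissue and set to a luminance *offset* of 35–60 above their
  local surround. The offset parameterization keeps the step visible to
  the edge detector wherever the disk lands while the absolute level stays
  inside the sheen's range — which is exactly the separability structure
  the benchmark is about: any single threshold catching all Type 2 misses
  every Type 3.
- Additive Gaussian pixel noise (σ = 2) before quantization; one seeded
  generator per scene, no global random state; reflections are placed
  without overlap and away from the border (bounded rejection sampling;
  a crowded spec raises `PlacementError`).

What passing the benchmark does **not** show: robustness to real
endoscopic phenomena — texture, vessels, smoke, fluid, motion blur, lens
distortion, white-balance error (the cone model assumes none), or
reflections with broken/weak contours. On clinical data the hybrid's
contour line will miss some weak reflections (open contours) and admit
some false ones; the synthetic corpus makes the contrast between the
detector families crisp rather than estimating clinical accuracy.

## Benchmark protocol and problem sizes

The default benchmark uses 20 scenes of 180×180 px (40 Type-1, 60 Type-2,
80 Type-3 reflections in total), small per-method grids (12–27 points)
over the parameters that matter (threshold level and lobe factor; for the
hybrid, cone position and the Type-3 acceptance thresholds), and runs in
well under a minute on one CPU. These sizes were chosen so the full
pipeline — rendering, optimization, evaluation — is cheap to rerun
end-to-end while each per-type sensitivity still rests on dozens of
reflections.

## Known limitations

- The peak-thresholding valley rule can reject the only valley when it
  lies below `t_min` (empty mask on images whose background and glare are
  both dark); this is the documented fail-safe behavior, not an error.
- Relative Canny thresholds make edge detection contrast-adaptive but mean
  that a single bright step anywhere in the frame sets the reference for
  the whole image.
- The Type-3 filter scores candidates independently; overlapping or
  touching contours are not merged or arbitrated beyond connected-component
  structure.
- Sensitivity uses one-pixel overlap; it does not reward boundary
  precision (that is what the Jaccard columns are for).
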
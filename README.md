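# specseg

Segmentation of specular reflections (glare) in laparoscopic images.

Moist tissue under endoscopic illumination produces mirror-like highlights
wherever the surface normal bisects the light and viewing directions. These
white or light-colored spots corrupt every downstream step — tissue
segmentation, classification, registration — so masking them out is a
standard preprocessing stage. The catch is that a single global threshold
cannot do it well: the brightest parts of ordinary tissue overlap with weak
reflections in color space, so any threshold that catches the weak glare
also floods bright tissue with false positives.

`specseg` implements three classical threshold-based detectors and a hybrid
detector that combines thresholding with closed edge contours to recover
exactly those weak reflections, plus the evaluation metrics and a synthetic
scene generator with per-reflection ground truth so the whole pipeline can
be exercised and benchmarked without clinical data.

## Methods

All detectors return boolean masks on the image grid and segment the bright
specular **core** first; adaptive region growing then expands each core
into its surrounding **specular lobe** (the halo where specular reflection
is still strong but diffuse reflection increases).

**Gray-level thresholding** — `Y(x) > t_gray` on BT.601 luminance
`Y = 0.299 R + 0.587 G + 0.114 B`. The baseline.

**Specular-peak thresholding** — the saturation-suppressed transform
`I_t(x) = (1 − S(x)) I(x)` (S = HSV saturation) pulls saturated tissue
toward black while leaving desaturated glare nearly untouched, widening the
gap between tissue and reflections in the luminance histogram. The
histogram of `Y(I_t)` is smoothed with a Gaussian kernel (σ bins) to merge
peaks from reflections at different intensity levels, and the threshold
`t_spec` is placed at the deepest valley below the brightest remaining peak
(the largest descent-end with positive mass above it, restricted to
`t_spec > t_min`). No valley means no reflections: the mask is empty rather
than the brightest tissue being segmented.

**Cone thresholding** — a cone around the gray axis `r = g = b` of RGB
space. A pixel `I(x)` is specular when its orthogonal distance to the axis
is strictly below `a · (⟨n, I(x)⟩/|n| − x0)` with `n = (1,1,1)ᵀ`: `x0` is
the cone tip along the axis, `a` its slope. Assumes a good white balance.

**Specular lobe growing** — for each connected core component with mean
luminance `μ`, every 8-connected pixel with `Y(x) > c·μ` is added; the
per-component threshold adapts growth to the local reflection intensity.

**Hybrid closed-contour detector** — three process lines, combined by
union. A Canny edge map of the luminance channel (hysteresis thresholds as
fractions of the maximum gradient; morphological closing bridges small
gaps) is flood-filled from the image border; regions the fill cannot reach
are *enclosed by contours*. Cone-thresholded reflections inside an enclosed
region are **Type 2** (small, bright, step-edged) and are segmented by
their contour, which is more precise than the threshold. Thresholded
reflections with no closed contour are **Type 1** (large, clipped-center,
slow radial decay) and get lobe growing. Enclosed regions the threshold
missed entirely are **Type 3** candidates — small weak reflections — and
are accepted when mean luminance exceeds `t_av`, the drop from the region
to the one-pixel ring beyond its contour exceeds `t_diff`, and the size
lies strictly between `t_cc_min` and `t_cc_max`.

**Evaluation** — pixel overlap by Jaccard index `tp/(tp+fp+fn)` (mean, Q1,
Q3 over images); object-level sensitivity per reflection type (a reflection
is detected when the prediction touches it) and positive prediction value
`PPV = tp/(tp+fp)` over detected reflections. Parameters are set by
exhaustive grid search maximizing mean Jaccard on a labeled corpus.

## Worked example

Run the full benchmark — render a 20-scene synthetic corpus (each scene:
2 Type-1, 3 Type-2, 4 Type-3 reflections on liver-like tissue with bright
sheen patches), grid-optimize every detector, evaluate each at its optimum:

```bash
specseg bench --seed 7 --out report.csv
```

which prints (identically reproducible from the seed):

```text
algorithm  f_jaccard    q1    q3  sens_t1  sens_t2  sens_t3  sens_avg  ppv
     gray       0.52  0.46  0.55      1.0     1.00     0.00      0.67  1.0
     peak       0.56  0.53  0.62      1.0     0.08     0.00      0.36  1.0
     cone       0.51  0.45  0.56      1.0     1.00     0.00      0.67  1.0
   hybrid       0.53  0.47  0.56      1.0     1.00     0.96      0.99  1.0
```

Reading the table: every method finds all large clipped Type-1 reflections
(`sens_t1 = 1`), and the bright step-edged Type 2s are caught by the
threshold methods too — but the weak Type 3s are invisible to every
single-threshold detector at its Jaccard-optimal setting (`sens_t3 = 0`),
because any threshold low enough to reach them floods the bright tissue
sheen with false positives. The hybrid detector recovers them through
their closed contours (`sens_t3 = 0.96`), lifting average sensitivity from
0.67 to 0.99 at equal PPV. The peak method's low Type-2 sensitivity is the
multi-peak failure mode: its single histogram threshold locks onto the
brightest (clipped) peak, above the Type-2 intensity level.

Individual steps are available as subcommands:

```bash
specseg simulate --n 20 --seed 7 --out corpus/
specseg segment  --method hybrid --in corpus/ --out masks/ --per-type
specseg optimize --method cone --corpus-dir corpus/ --grid grid.json --out opt.json
specseg evaluate --pred-dir masks/ --truth-dir corpus/ --out report.csv
```

or from Python:

```python
from specseg import SceneSpec, generate_scene, hybrid_segment, ConeParams

scene = generate_scene(SceneSpec(seed=3))
result = hybrid_segment(scene.image, cone=ConeParams(x0=260, a=0.3))
result.type3.sum()   # pixels of weak reflections recovered via contours
```

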
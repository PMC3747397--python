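"""Synthetic laparoscopic scenes with ground-truth specular reflections.

Renders liver-like frames that reproduce the phenomenology the detectors
are built around, so the whole pipeline is exercisable without clinical
data:

* a smooth, low-texture reddish tissue background (spatially correlated
  noise field mapped to liver-like channel ranges);
* smooth desaturated bright *sheen* patches — bright tissue with no step
  edge and no ground-truth label. These overlap weak reflections in color
  space, which is precisely why single-threshold detectors cannot recover
  Type 3 reflections without paying in false positives;
* **Type 1**: large reflections with a clipped white center and a slow
  radial intensity decay (endoscope close to the organ);
* **Type 2**: small bright disks with a step-shaped border;
* **Type 3**: small weak disks with a step-shaped border, brighter than
  their immediate surround but inside the intensity range that bright
  tissue also reaches.

Scenes are deterministic given the spec's seed; reflections are placed
without mutual overlap and away from the image border.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

from specseg.image_io import ReflectionLabel

#: Liver-like channel ranges (at background_level == 85), dark to bright.
_CHANNEL_LO = np.array([90.0, 40.0, 35.0])
_CHANNEL_HI = np.array([160.0, 90.0, 80.0])
_REFERENCE_LEVEL = 85.0
#: Bright desaturated gray the sheen blends toward.
_SHEEN_COLOR = np.array([168.0, 162.0, 156.0])


class PlacementError(RuntimeError):
    """Raised when reflections cannot be placed without overlap."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``type1_radius_range`` is the Gaussian decay scale ``s`` of the Type-1
    profile in pixels (the ground-truth footprint extends to ~2.15 s, where
    the profile falls below 10% of its amplitude). ``type23_radius_range``
    is the disk radius of the small step-edged reflections.
    ``type2_intensity`` is the peak luminance of Type-2 disks;
    ``type3_intensity`` is the luminance *offset of a Type-3 disk above its
    local background*, so the weak reflections stay visible as a step
    wherever they land while remaining inside the intensity range bright
    tissue reaches elsewhere in the frame.
    """

    width: int = 180
    height: int = 180
    n_type1: int = 2
    n_type2: int = 3
    n_type3: int = 4
    background_level: float = 85.0
    background_smoothness: float = 6.0
    noise_sd: float = 2.0
    type1_radius_range: tuple[float, float] = (10.0, 13.0)
    type23_radius_range: tuple[float, float] = (3.0, 6.0)
    type2_intensity: tuple[float, float] = (235.0, 255.0)
    type3_intensity: tuple[float, float] = (35.0, 60.0)
    seed: int = 0
    # bright-tissue sheen (unlabeled): count, Gaussian scale, peak blend weight
    n_sheen: int = 3
    sheen_radius_range: tuple[float, float] = (14.0, 22.0)
    sheen_strength: tuple[float, float] = (0.7, 0.9)
    #: fraction of the Type-1 profile amplitude that cuts its truth mask
    type1_truth_frac: float = 0.1
    #: Type-3 disks are only placed where the local background luminance is
    #: at most this value (weak reflections sit on ordinary tissue, not on
    #: the brightest sheen)
    type3_max_local_luminance: float = 100.0

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("scene must be at least 32x32")
        if min(self.n_type1, self.n_type2, self.n_type3) < 0:
            raise ValueError("reflection counts must be non-negative")
        if not 0 < self.type1_truth_frac < 1:
            raise ValueError("type1_truth_frac must lie in (0, 1)")
        # the weak type must stay strictly below the bright type
        if self.type3_intensity[1] >= self.type2_intensity[0]:
            raise ValueError("type3_intensity range must lie below type2_intensity")
        for name in ("type1_radius_range", "type23_radius_range",
                     "type2_intensity", "type3_intensity", "sheen_radius_range",
                     "sheen_strength"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be an increasing positive range")


@dataclass(frozen=True)
class SyntheticScene:
    """Rendered image plus its ground truth."""

    image: np.ndarray
    labels: list[ReflectionLabel] = field(default_factory=list)
    spec: SceneSpec = field(default_factory=SceneSpec)


def _luma(rgb: np.ndarray) -> np.ndarray:
    return rgb @ np.array([0.299, 0.587, 0.114])


def _background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth tissue-colored field, (H, W, 3) float."""
    fld = ndi.gaussian_filter(
        rng.standard_normal((spec.height, spec.width)), spec.background_smoothness,
        mode="reflect",
    )
    lo, hi = fld.min(), fld.max()
    b = (fld - lo) / (hi - lo) if hi > lo else np.zeros_like(fld)
    scale = spec.background_level / _REFERENCE_LEVEL
    return (_CHANNEL_LO + b[..., None] * (_CHANNEL_HI - _CHANNEL_LO)) * scale


def _add_sheen(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> None:
    """Blend smooth bright desaturated patches into the tissue, in place."""
    h, w = img.shape[:2]
    rr, cc = np.mgrid[0:h, 0:w]
    scale = spec.background_level / _REFERENCE_LEVEL
    target = _SHEEN_COLOR * scale
    for _ in range(spec.n_sheen):
        s = rng.uniform(*spec.sheen_radius_range)
        w_max = rng.uniform(*spec.sheen_strength)
        cy = rng.uniform(s, h - s)
        cx = rng.uniform(s, w - s)
        r2 = (rr - cy) ** 2 + (cc - cx) ** 2
        weight = w_max * np.exp(-r2 / (2.0 * s * s))
        img += weight[..., None] * (target - img)


def _disk_alpha(shape: tuple[int, int], cy: float, cx: float, radius: float) -> np.ndarray:
    """Disk coverage with at most one pixel of anti-aliasing at the rim."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
    return np.clip(radius + 0.5 - d, 0.0, 1.0)


def _place(
    rng: np.random.Generator,
    shape: tuple[int, int],
    extent: float,
    occupied: list[tuple[float, float, float]],
    *,
    ok_at: "callable | None" = None,
    margin: float = 3.0,
    max_tries: int = 300,
) -> tuple[float, float]:
    """Draw a center so a footprint of radius ``extent`` overlaps nothing."""
    h, w = shape
    lo = extent + margin
    if h - lo <= lo or w - lo <= lo:
        raise PlacementError("reflection does not fit inside the image")
    for _ in range(max_tries):
        cy = rng.uniform(lo, h - lo)
        cx = rng.uniform(lo, w - lo)
        if any(
            np.hypot(cy - oy, cx - ox) < extent + oe + margin
            for oy, ox, oe in occupied
        ):
            continue
        if ok_at is not None and not ok_at(cy, cx):
            continue
        occupied.append((cy, cx, extent))
        return cy, cx
    raise PlacementError(
        f"could not place a reflection of extent {extent:.1f}px after {max_tries} tries"
    )


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one scene with ground-truth labels; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    img = _background(spec, rng)
    _add_sheen(spec=spec, rng=rng, img=img)
    shape = (spec.height, spec.width)
    rr, cc = np.mgrid[0 : spec.height, 0 : spec.width]
    base_lum = _luma(img)

    labels: list[ReflectionLabel] = []
    occupied: list[tuple[float, float, float]] = []
    next_id = 1
    truth_cut = np.sqrt(2.0 * np.log(1.0 / spec.type1_truth_frac))

    # Type 1: clipped-center blobs with slow radial decay. The blend weight
    # toward white exceeds 1 near the center and is clipped, producing the
    # saturated plateau; the 10%-amplitude cut defines the truth footprint.
    for _ in range(spec.n_type1):
        s = rng.uniform(*spec.type1_radius_range)
        extent = truth_cut * s
        cy, cx = _place(rng, shape, extent, occupied)
        r2 = (rr - cy) ** 2 + (cc - cx) ** 2
        profile = 1.15 * np.exp(-r2 / (2.0 * s * s))
        weight = np.clip(profile, 0.0, 1.0)
        img += weight[..., None] * (255.0 - img)
        mask = profile > spec.type1_truth_frac * 1.15
        labels.append(ReflectionLabel(id=next_id, type_tag=1, mask=mask))
        next_id += 1

    # Type 2: small bright near-white disks with a hard edge.
    for _ in range(spec.n_type2):
        radius = rng.uniform(*spec.type23_radius_range)
        cy, cx = _place(rng, shape, radius + 1.0, occupied)
        v = rng.uniform(*spec.type2_intensity)
        color = np.array([v, 0.97 * v, 0.94 * v])
        alpha = _disk_alpha(shape, cy, cx, radius)
        img += alpha[..., None] * (np.clip(color, 0, 255) - img)
        d = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
        labels.append(ReflectionLabel(id=next_id, type_tag=2, mask=d <= radius))
        next_id += 1

    # Type 3: small weak disks, a fixed luminance step above their local
    # surround, placed on ordinary (non-sheen) tissue.
    lum_smooth = ndi.uniform_filter(base_lum, 7, mode="nearest")

    for _ in range(spec.n_type3):
        radius = rng.uniform(*spec.type23_radius_range)

        def _on_dark_tissue(cy: float, cx: float) -> bool:
            return (
                lum_smooth[int(round(cy)), int(round(cx))]
                <= spec.type3_max_local_luminance
            )

        cy, cx = _place(rng, shape, radius + 1.0, occupied, ok_at=_on_dark_tissue)
        offset = rng.uniform(*spec.type3_intensity)
        v = lum_smooth[int(round(cy)), int(round(cx))] + offset
        color = np.clip(v * np.array([1.10, 1.0, 0.90]), 0, 255)
        alpha = _disk_alpha(shape, cy, cx, radius)
        img += alpha[..., None] * (color - img)
        d = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
        labels.append(ReflectionLabel(id=next_id, type_tag=3, mask=d <= radius))
        next_id += 1

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SyntheticScene(image=image, labels=labels, spec=spec)


def generate_corpus(
    spec_template: SceneSpec, n_images: int, seed: int
) -> tuple[list[SyntheticScene], dict]:
    """Render ``n_images`` scenes with per-image seeds derived from ``seed``.

    Returns the scenes plus a manifest recording per-image seeds and label
    counts; two corpora built from the same template and seed are
    identical.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    seed_rng = np.random.default_rng(seed)
    child_seeds = seed_rng.integers(0, 2**31 - 1, size=n_images)
    scenes = []
    entries = []
    for i, s in enumerate(child_seeds):
        scene_spec = dataclasses.replace(spec_template, seed=int(s))
        scene = generate_scene(scene_spec)
        scenes.append(scene)
        counts = {t: sum(1 for lab in scene.labels if lab.type_tag == t) for t in (1, 2, 3)}
        entries.append(
            {
                "index": i,
                "seed": int(s),
                "counts": {str(t): c for t, c in counts.items()},
                "n_reflections": len(scene.labels),
            }
        )
    manifest = {
        "corpus_seed": int(seed),
        "n_images": int(n_images),
        "total_reflections": int(sum(e["n_reflections"] for e in entries)),
        "images": entries,
    }
    return scenes, manifest


def write_corpus(
    scenes: list[SyntheticScene], manifest: dict, out_dir: str | Path
) -> None:
    """Write a corpus to disk: images, truth masks, label sidecars, manifest."""
    from specseg.image_io import write_image, write_labels

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for i, scene in enumerate(scenes):
        stem = f"scene_{i:03d}"
        write_image(out / f"{stem}.png", scene.image)
        write_labels(
            out / f"{stem}_labels.json",
            scene.labels,
            masks_dir=out,
            stem=stem + "_mask",
        )
        files.append({"image": f"{stem}.png", "labels": f"{stem}_labels.json"})
    manifest = dict(manifest)
    manifest["files"] = files
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
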
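"""Threshold-based detectors of the central specular part.

Three detectors segment the bright specular core of a reflection:

* **Gray-level thresholding** — a fixed global threshold on luminance, the
  classical baseline.
* **Specular-peak thresholding** — a saturation-suppressed transform
  ``I_t = (1 - S) I`` pulls desaturated glare away from saturated tissue in
  the luminance histogram; the threshold is then placed at the valley below
  the brightest remaining peak of the Gaussian-smoothed histogram.
* **Cone thresholding** — a cone around the gray axis ``r = g = b`` of RGB
  space: a pixel is specular when its orthogonal distance to the axis is
  below a linearly widening bound ``a * (axial - x0)``. Assumes a good
  white balance, so glare sits near the axis.

All detectors return boolean masks on the shared (row, col) grid and use
strict inequalities throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from specseg.image_io import validate_color_image

_SQRT3 = float(np.sqrt(3.0))

#: BT.601 luma weights — the classic YUV definition.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PeakParams:
    """Specular-peak thresholding parameters.

    ``t_min`` rejects implausibly dark thresholds (below it, the brightest
    tissue would be segmented when no reflection is present); ``sigma`` is
    the Gaussian smoothing width in histogram bins that merges nearby peaks
    caused by reflections at different intensity levels.
    """

    t_min: int = 100
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.t_min < 255:
            raise ValueError(f"t_min must lie in [0, 255), got {self.t_min}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class ConeParams:
    """Gray-axis cone parameters.

    ``x0`` is the cone tip position along the gray axis in axial-coordinate
    units (intensity times sqrt(3): a gray pixel of value v projects to
    axial coordinate v*sqrt(3)); ``a`` is the dimensionless slope of the
    cone's opening.
    """

    x0: float = 100.0 * _SQRT3
    a: float = 0.3

    def __post_init__(self) -> None:
        if self.x0 < 0:
            raise ValueError(f"x0 must be non-negative, got {self.x0}")
        if self.a <= 0:
            raise ValueError(f"cone slope a must be positive, got {self.a}")


@dataclass(frozen=True)
class GrayThresholdParams:
    """Fixed luminance threshold for the gray-level baseline."""

    t_gray: int = 230

    def __post_init__(self) -> None:
        if not 0 <= self.t_gray <= 255:
            raise ValueError(f"t_gray must lie in [0, 255], got {self.t_gray}")


def saturation_channel(img: np.ndarray) -> np.ndarray:
    """HSV saturation per pixel, in [0, 1].

    ``S = (max - min) / max`` over the RGB channels, and 0 where
    ``max = 0`` (black has no defined hue or saturation).
    """
    img = validate_color_image(img).astype(np.float64)
    mx = img.max(axis=2)
    mn = img.min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    return sat


def suppress_saturation(img: np.ndarray) -> np.ndarray:
    """Saturation-suppressed transform ``I_t = (1 - S) I``.

    Scales each pixel's RGB vector by one minus its HSV saturation, so
    colors far from the gray axis are pulled toward black while desaturated
    glare is left almost untouched. Output is real-valued in [0, 255].
    """
    img = validate_color_image(img).astype(np.float64)
    return (1.0 - saturation_channel(img))[..., None] * img


def luminance(img: np.ndarray) -> np.ndarray:
    """BT.601 luma ``Y = 0.299 R + 0.587 G + 0.114 B`` (real-valued)."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 image, got shape {img.shape}")
    return img @ LUMA_WEIGHTS


def compute_histogram(gray: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of a gray image.

    Real-valued intensities are assigned to bins by half-up rounding
    (``floor(v + 0.5)``), clipped to [0, 255]. The counts sum to the pixel
    count.
    """
    gray = np.asarray(gray, dtype=np.float64)
    bins = np.clip(np.floor(gray + 0.5).astype(np.int64), 0, 255)
    return np.bincount(bins.ravel(), minlength=256).astype(np.float64)


def smooth_histogram(h: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve a histogram with a unit-sum Gaussian kernel.

    The kernel is truncated at ±ceil(3*sigma) bins and the histogram is
    mirror-padded (edge-including reflection), which conserves total mass
    exactly for any normalized kernel.
    """
    h = np.asarray(h, dtype=np.float64)
    if h.shape != (256,):
        raise ValueError(f"histogram must have 256 bins, got shape {h.shape}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    radius = int(np.ceil(3.0 * sigma))
    offsets = np.arange(-radius, radius + 1, dtype=np.float64)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(h, radius, mode="symmetric")
    return np.convolve(padded, kernel, mode="valid")


def select_specular_peak_threshold(h_smooth: np.ndarray, params: PeakParams) -> int | None:
    """Place the threshold at the valley below the brightest histogram peak.

    The descent indicator ``h~(t) = 1`` iff ``h(t) - h(t+1) > 0`` is scanned
    for descent-to-non-descent transitions (valley bottoms). A candidate
    valley must have positive histogram mass above it — without that clause
    the final descent into the empty tail would always win and the
    segmentation would always be empty. The largest candidate strictly
    above ``t_min`` is returned; ``None`` signals that no specular peak is
    present (a valid outcome on reflection-free images, not an error).
    """
    h = np.asarray(h_smooth, dtype=np.float64)
    if h.shape != (256,):
        raise ValueError(f"histogram must have 256 bins, got shape {h.shape}")
    descent = (h[:-1] - h[1:]) > 0  # h~(t) for t = 0..254
    # mass strictly above t: sum of h[t+1:]
    tail = np.cumsum(h[::-1])[::-1]  # tail[t] = sum h[t:]
    best: int | None = None
    for t in range(254):  # t+1 must be a valid index of `descent`
        if descent[t] and not descent[t + 1] and tail[t + 1] > 0 and t > params.t_min:
            best = t if best is None else max(best, t)
    return best


def specular_peak_segment(img: np.ndarray, params: PeakParams = PeakParams()) -> np.ndarray:
    """Segment the specular core by specular-peak thresholding.

    Pipeline: saturation suppression, BT.601 luminance, 256-bin histogram,
    Gaussian smoothing, valley selection, then a strict ``>`` threshold on
    the transformed luminance. When no threshold is found the mask is empty.
    """
    gray = luminance(suppress_saturation(img))
    h = smooth_histogram(compute_histogram(gray), params.sigma)
    t_spec = select_specular_peak_threshold(h, params)
    if t_spec is None:
        return np.zeros(gray.shape, dtype=bool)
    return gray > t_spec


def cone_segment(img: np.ndarray, params: ConeParams = ConeParams()) -> np.ndarray:
    """Segment pixels inside the gray-axis cone.

    A pixel I belongs to the cone when its orthogonal distance to the axis
    r=g=b is strictly below ``a * (axial - x0)``, where ``axial`` is the
    scalar projection ``(R+G+B)/sqrt(3)``. Pixels with axial projection at
    or below the tip ``x0`` can never be members.
    """
    img = validate_color_image(img).astype(np.float64)
    axial = img.sum(axis=2) / _SQRT3
    centered = img - img.mean(axis=2, keepdims=True)
    dist = np.sqrt((centered**2).sum(axis=2))
    return dist < params.a * (axial - params.x0)


def gray_level_segment(
    img: np.ndarray, params: GrayThresholdParams = GrayThresholdParams()
) -> np.ndarray:
    """Fixed global threshold on BT.601 luminance (strict ``>``)."""
    return luminance(validate_color_image(img)) > params.t_gray
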
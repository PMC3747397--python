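"""Adaptive region growing of the specular lobe.

Thresholding captures only the bright central part of a reflection. Around
it lies the specular lobe — the halo where specular reflection is still
strong but diffuse reflection increases. Each thresholded connected
component is grown outward into every 8-connected pixel whose raw-image
luminance exceeds ``c * mu``, where ``mu`` is the component's mean
luminance; the per-component threshold adapts the growth to the local
reflection intensity instead of using one global value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as _sk_label

from specseg.thresholding import luminance


@dataclass(frozen=True)
class Component:
    """One connected pixel set of a binary mask.

    ``coords`` is an (N, 2) integer array of (row, col) pixel coordinates;
    ``mean_intensity`` is filled lazily where a gray image is available.
    """

    label: int
    coords: np.ndarray
    mean_intensity: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.intp)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] == 0:
            raise ValueError("coords must be a non-empty (N, 2) array")
        object.__setattr__(self, "coords", coords)

    @property
    def size(self) -> int:
        return int(self.coords.shape[0])

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[self.coords[:, 0], self.coords[:, 1]] = True
        return mask


@dataclass(frozen=True)
class LobeParams:
    """Scaling factor for adaptive growth.

    ``c`` multiplies the component's mean luminance to form the acceptance
    threshold. Values in (0, 1) grow outward; values above 1 admit nothing
    beyond the seed (useful to disable growth), and above 1.5 they are
    rejected as meaningless for clipped cores.
    """

    c: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.c <= 1.5:
            raise ValueError(f"c must lie in (0, 1.5], got {self.c}")


def connected_components(mask: np.ndarray) -> list[Component]:
    """Maximal 8-connected components of a boolean mask.

    Components are labeled 1..N deterministically, ordered by the raster
    position of each component's first (topmost, then leftmost) pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if not mask.any():
        return []
    labeled = _sk_label(mask, connectivity=2)
    n = labeled.max()
    coords_by_label: dict[int, list] = {}
    order: list[int] = []
    flat = labeled.ravel()
    first_idx = {}
    for lab in range(1, n + 1):
        idx = np.flatnonzero(flat == lab)
        coords_by_label[lab] = np.column_stack(np.unravel_index(idx, mask.shape))
        first_idx[lab] = idx[0]
    order = sorted(range(1, n + 1), key=lambda lab: first_idx[lab])
    return [
        Component(label=i + 1, coords=coords_by_label[lab])
        for i, lab in enumerate(order)
    ]


def component_mean(comp: Component, gray: np.ndarray) -> float:
    """Arithmetic mean of ``gray`` over the component's pixels."""
    gray = np.asarray(gray, dtype=np.float64)
    rows, cols = comp.coords[:, 0], comp.coords[:, 1]
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() >= gray.shape[0]
        or cols.max() >= gray.shape[1]
    ):
        raise IndexError("component coordinates fall outside the image")
    return float(gray[rows, cols].mean())


def grow_lobe(
    seed: Component, gray: np.ndarray, params: LobeParams = LobeParams()
) -> np.ndarray:
    """Grow one component into its specular lobe.

    Pixels with ``gray > c * mu`` (mu = seed mean over ``gray``) are
    traversable; the result is the set of traversable pixels 8-connected to
    the seed, plus the seed pixels themselves, which are always kept even
    when their own luminance fails the test (the final segmentation is
    defined as a union with the thresholded core).
    """
    gray = np.asarray(gray, dtype=np.float64)
    mu = component_mean(seed, gray)
    accept = gray > params.c * mu
    accept[seed.coords[:, 0], seed.coords[:, 1]] = True
    labeled = _sk_label(accept, connectivity=2)
    seed_labels = np.unique(labeled[seed.coords[:, 0], seed.coords[:, 1]])
    seed_labels = seed_labels[seed_labels > 0]
    return np.isin(labeled, seed_labels)


def segment_with_lobes(
    img: np.ndarray, core_mask: np.ndarray, params: LobeParams = LobeParams()
) -> np.ndarray:
    """Union of the thresholded core with every component's grown lobe.

    Growth runs on the raw image's BT.601 luminance (not the
    saturation-suppressed transform), with each core component seeding its
    own adaptively thresholded expansion; overlapping lobes simply merge.
    """
    core_mask = np.asarray(core_mask, dtype=bool)
    out = core_mask.copy()
    if not core_mask.any():
        return out
    gray = luminance(img)
    for comp in connected_components(core_mask):
        out |= grow_lobe(comp, gray, params)
    return out
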
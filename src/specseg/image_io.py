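"""Image, mask, label-sidecar and report I/O.

Pixel-grid convention shared by every module: arrays are indexed
``(row, col)``, 0-based, row 0 at the top. Color images are ``(H, W, 3)``
uint8 in [0, 255]; binary masks are ``(H, W)`` boolean and are stored on
disk as 0/255 single-channel PNG. Ground-truth reflection type labels
travel in a JSON sidecar next to the mask files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: Fixed column order of Table-1-shaped reports.
REPORT_COLUMNS = [
    "algorithm",
    "f_jaccard",
    "q1",
    "q3",
    "sens_t1",
    "sens_t2",
    "sens_t3",
    "sens_avg",
    "ppv",
]


class ImageFormatError(ValueError):
    """Raised when a decoded file does not match the expected layout."""


@dataclass(frozen=True)
class ReflectionLabel:
    """One ground-truth specular reflection.

    Parameters
    ----------
    id : int
        Identifier, unique within an image.
    type_tag : int
        Reflection phenotype: 1 (large, clipped center, slow radial decay),
        2 (small, bright, step-edged) or 3 (small, low-intensity,
        step-edged).
    mask : ndarray of bool
        Footprint of the reflection on the image grid; non-empty.
    """

    id: int
    type_tag: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.type_tag not in (1, 2, 3):
            raise ValueError(f"type_tag must be 1, 2 or 3, got {self.type_tag}")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or not mask.any():
            raise ValueError("label mask must be a non-empty 2-D boolean array")
        object.__setattr__(self, "mask", mask)


def validate_color_image(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a valid H×W×3 image with values in [0, 255]."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ImageFormatError(
            f"expected an H×W×3 color image, got shape {img.shape}"
        )
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ImageFormatError("image must have at least one pixel")
    if img.min() < 0 or img.max() > 255:
        raise ImageFormatError("channel values must lie in [0, 255]")
    return img


def read_image(path: str | Path) -> np.ndarray:
    """Read a 3-channel PNG/TIFF into an ``(H, W, 3)`` uint8 array.

    16-bit inputs are rescaled linearly to [0, 255]. Grayscale or
    alpha-carrying files are rejected: every detector in this package is
    defined on RGB input.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise IOError(f"cannot decode image file {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[2] != 3:
        n_ch = 1 if arr.ndim == 2 else arr.shape[2]
        raise ImageFormatError(
            f"{path}: expected 3 channels, got {n_ch}"
        )
    if arr.dtype == np.uint16:
        arr = np.round(arr.astype(np.float64) / 257.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.round(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    return arr


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a color image as 8-bit PNG/TIFF (format chosen by suffix)."""
    img = validate_color_image(img)
    iio.imwrite(Path(path), np.asarray(np.round(img), dtype=np.uint8))


def read_mask(path: str | Path, reference_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a single-channel 0/255 PNG as a boolean mask.

    Values are thresholded at 128 for tolerance against slightly lossy
    round-trips. If ``reference_shape`` is given, the mask dimensions must
    match it.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[..., 0]
        else:
            raise ImageFormatError(
                f"{path}: mask must be single-channel, got {arr.shape[2]} channels"
            )
    mask = np.asarray(arr) >= 128
    if reference_shape is not None and mask.shape != tuple(reference_shape):
        raise ValueError(
            f"{path}: mask shape {mask.shape} does not match reference {tuple(reference_shape)}"
        )
    return mask


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 single-channel PNG."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def _rle_encode(mask: np.ndarray) -> list[list[int]]:
    flat = np.asarray(mask, dtype=bool).ravel()
    # runs of True: [start, length] pairs over the flattened row-major array
    padded = np.concatenate([[False], flat, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [[int(s), int(e - s)] for s, e in zip(starts, ends)]


def _rle_decode(runs: Sequence[Sequence[int]], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(shape[0]) * int(shape[1]), dtype=bool)
    for start, length in runs:
        flat[start : start + length] = True
    return flat.reshape(shape)


def write_labels(
    path: str | Path,
    labels: Iterable[ReflectionLabel],
    *,
    masks_dir: str | Path | None = None,
    stem: str = "label",
) -> None:
    """Write a JSON sidecar describing ground-truth reflections.

    With ``masks_dir`` set, each footprint is written as a 0/255 PNG and the
    sidecar references the file; otherwise footprints are inlined as
    row-major run-length encodings.
    """
    labels = list(labels)
    records = []
    for lab in labels:
        rec: dict = {
            "id": int(lab.id),
            "type": int(lab.type_tag),
            "shape": list(lab.mask.shape),
        }
        if masks_dir is not None:
            mask_file = f"{stem}_{lab.id:03d}.png"
            write_mask(Path(masks_dir) / mask_file, lab.mask)
            rec["mask_file"] = mask_file
        else:
            rec["rle"] = _rle_encode(lab.mask)
        records.append(rec)
    ids = [r["id"] for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("label ids must be unique within an image")
    Path(path).write_text(json.dumps({"labels": records}, indent=1))


def read_labels(path: str | Path, *, masks_dir: str | Path | None = None) -> list[ReflectionLabel]:
    """Read a label sidecar written by :func:`write_labels`."""
    path = Path(path)
    data = json.loads(path.read_text())
    base = Path(masks_dir) if masks_dir is not None else path.parent
    labels = []
    for rec in data["labels"]:
        shape = tuple(rec["shape"])
        if "mask_file" in rec:
            mask = read_mask(base / rec["mask_file"], reference_shape=shape)
        else:
            mask = _rle_decode(rec["rle"], shape)
        labels.append(ReflectionLabel(id=rec["id"], type_tag=rec["type"], mask=mask))
    return labels


def write_report(
    rows: Sequence[Mapping] | pd.DataFrame, path: str | Path
) -> pd.DataFrame:
    """Serialize a Table-1-shaped comparison report as CSV plus JSON.

    ``path`` names the CSV file; a sibling ``.json`` with the same stem is
    written alongside it. Columns follow :data:`REPORT_COLUMNS`; missing
    metrics are left empty (e.g. PPV on a run with no detections).
    """
    df = pd.DataFrame(rows)
    if len(df) and "algorithm" not in df.columns:
        raise ValueError("report rows must contain an 'algorithm' field")
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series(dtype=float if col != "algorithm" else object)
    df = df[REPORT_COLUMNS]
    path = Path(path)
    df.to_csv(path, index=False)
    df.to_json(path.with_suffix(".json"), orient="records", indent=1)
    return df


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a CSV report written by :func:`write_report`."""
    return pd.read_csv(Path(path))
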
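"""Independent brute-force reference implementations.

Every function here recomputes an operation pixel by pixel (or bin by bin)
with explicit Python loops and no shared code with the package, so the
vectorized implementations can be checked against them.
"""

import math
from collections import deque

import numpy as np


def saturation_pixel(r, g, b):
    mx = max(r, g, b)
    mn = min(r, g, b)
    return 0.0 if mx == 0 else (mx - mn) / mx


def peak_segment_bruteforce(img, t_min, sigma):
    """Per-pixel recomputation of the specular-peak pipeline."""
    h_img, w_img = img.shape[:2]
    gray = [[0.0] * w_img for _ in range(h_img)]
    hist = [0.0] * 256
    for i in range(h_img):
        for j in range(w_img):
            r, g, b = (float(v) for v in img[i, j])
            s = saturation_pixel(r, g, b)
            y = 0.299 * (1 - s) * r + 0.587 * (1 - s) * g + 0.114 * (1 - s) * b
            gray[i][j] = y
            bin_ = int(math.floor(y + 0.5))
            hist[min(max(bin_, 0), 255)] += 1
    smoothed = smooth_histogram_bruteforce(hist, sigma)
    t_spec = select_threshold_bruteforce(smoothed, t_min)
    mask = np.zeros((h_img, w_img), dtype=bool)
    if t_spec is None:
        return mask
    for i in range(h_img):
        for j in range(w_img):
            mask[i, j] = gray[i][j] > t_spec
    return mask


def smooth_histogram_bruteforce(hist, sigma):
    """Explicit kernel-sum loop with whole-sample mirror boundary."""
    radius = int(math.ceil(3 * sigma))
    kernel = [math.exp(-0.5 * (d / sigma) ** 2) for d in range(-radius, radius + 1)]
    ksum = sum(kernel)
    kernel = [k / ksum for k in kernel]

    def mirrored(idx):
        while idx < 0 or idx > 255:
            if idx < 0:
                idx = -idx - 1
            else:
                idx = 511 - idx
        return idx

    out = [0.0] * 256
    for t in range(256):
        acc = 0.0
        for k, d in enumerate(range(-radius, radius + 1)):
            acc += kernel[k] * hist[mirrored(t + d)]
        out[t] = acc
    return out


def select_threshold_bruteforce(hist, t_min):
    """Exhaustive scan for the valley below the brightest peak.

    Descent indicator per bin, candidate = descent-to-non-descent
    transition with positive mass strictly above, maximum candidate above
    t_min.
    """
    htil = [1 if hist[t] - hist[t + 1] > 0 else 0 for t in range(255)]
    best = None
    for t in range(254):
        if htil[t] == 1 and htil[t + 1] == 0:
            mass_above = sum(hist[t + 1 :])
            if mass_above > 0 and t > t_min:
                best = t if best is None else max(best, t)
    return best


def cone_member_bruteforce(r, g, b, x0, a):
    """Independent vector-algebra evaluation of gray-axis cone membership."""
    norm_n = math.sqrt(3.0)
    axial = (r + g + b) / norm_n
    # orthogonal projection of (r,g,b) onto the axis direction
    mean = (r + g + b) / 3.0
    dist = math.sqrt((r - mean) ** 2 + (g - mean) ** 2 + (b - mean) ** 2)
    return dist < a * (axial - x0)


def cone_segment_bruteforce(img, x0, a):
    h_img, w_img = img.shape[:2]
    mask = np.zeros((h_img, w_img), dtype=bool)
    for i in range(h_img):
        for j in range(w_img):
            r, g, b = (float(v) for v in img[i, j])
            mask[i, j] = cone_member_bruteforce(r, g, b, x0, a)
    return mask


def grow_bruteforce(seed_coords, gray, c, mu):
    """Breadth-first 8-connected expansion from the seed pixels."""
    h_img, w_img = gray.shape
    accept = gray > c * mu
    visited = np.zeros((h_img, w_img), dtype=bool)
    queue = deque()
    for i, j in seed_coords:
        visited[i, j] = True
        queue.append((i, j))
    while queue:
        i, j = queue.popleft()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if (
                    0 <= ni < h_img
                    and 0 <= nj < w_img
                    and not visited[ni, nj]
                    and accept[ni, nj]
                ):
                    visited[ni, nj] = True
                    queue.append((ni, nj))
    return visited


def enclosed_bruteforce(edges):
    """Border-seeded 4-connected flood fill of the edge-map complement.

    Returns a list of frozensets of (row, col), the enclosed regions.
    """
    h_img, w_img = edges.shape
    reached = np.zeros((h_img, w_img), dtype=bool)
    queue = deque()
    for i in range(h_img):
        for j in (0, w_img - 1):
            if not edges[i, j] and not reached[i, j]:
                reached[i, j] = True
                queue.append((i, j))
    for j in range(w_img):
        for i in (0, h_img - 1):
            if not edges[i, j] and not reached[i, j]:
                reached[i, j] = True
                queue.append((i, j))
    while queue:
        i, j = queue.popleft()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if (
                0 <= ni < h_img
                and 0 <= nj < w_img
                and not edges[ni, nj]
                and not reached[ni, nj]
            ):
                reached[ni, nj] = True
                queue.append((ni, nj))
    remaining = ~edges & ~reached
    regions = []
    seen = np.zeros_like(remaining)
    for i in range(h_img):
        for j in range(w_img):
            if remaining[i, j] and not seen[i, j]:
                region = []
                queue = deque([(i, j)])
                seen[i, j] = True
                while queue:
                    ci, cj = queue.popleft()
                    region.append((ci, cj))
                    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        ni, nj = ci + di, cj + dj
                        if (
                            0 <= ni < h_img
                            and 0 <= nj < w_img
                            and remaining[ni, nj]
                            and not seen[ni, nj]
                        ):
                            seen[ni, nj] = True
                            queue.append((ni, nj))
                regions.append(frozenset(region))
    return regions
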
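"""Fluorescent spot calling on preprocessed images.

Spots are strict local maxima (26-connected in 3D) passing a brightness
threshold (default 3600) and a minimum Pearson correlation between the
local patch and the point spread function (default 0.25).  smFISH
channels get an extra relative-background filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["detect_spots", "threshold_smfish"]

DEFAULT_MIN_BRIGHTNESS = 3600.0
DEFAULT_MIN_PSF_CORR = 0.25

SPOT_COLUMNS = ["z", "y", "x", "brightness", "psf_correlation"]


def _psf_correlation(image: np.ndarray, z: int, y: int, x: int, psf: np.ndarray) -> float:
    """Pearson correlation of the psf-sized patch at (z,y,x) with the PSF.

    The window is the PSF bounding box centered on the candidate; at image
    edges only the valid overlap region enters the correlation.
    """
    py, px = psf.shape
    ry, rx = py // 2, px // 2
    ny, nx = image.shape[1], image.shape[2]
    y0, y1 = y - ry, y + ry + 1
    x0, x1 = x - rx, x + rx + 1
    cy0, cy1 = max(0, -y0), py - max(0, y1 - ny)
    cx0, cx1 = max(0, -x0), px - max(0, x1 - nx)
    patch = image[z, max(0, y0):min(ny, y1), max(0, x0):min(nx, x1)]
    kern = psf[cy0:cy1, cx0:cx1]
    a = patch.ravel().astype(float)
    b = kern.ravel().astype(float)
    if a.size < 3:
        return 0.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom < 1e-12:
        return 0.0
    return float(np.dot(a, b) / denom)


def detect_spots(
    image: np.ndarray,
    psf: np.ndarray,
    min_brightness: float = DEFAULT_MIN_BRIGHTNESS,
    min_psf_corr: float = DEFAULT_MIN_PSF_CORR,
) -> pd.DataFrame:
    """Local-maxima spot table for one preprocessed bit image.

    A pixel qualifies iff it is >= all its 26-connected neighbors (plateau
    ties resolved to the lexicographically smallest (z, y, x) member of
    the plateau), its value is >= ``min_brightness``, and the PSF
    correlation of its local patch is >= ``min_psf_corr``.  Brightness is
    the pixel value at the maximum.
    """
    image = np.asarray(image, dtype=float)
    squeeze_2d = image.ndim == 2
    if squeeze_2d:
        image = image[None]
    footprint = np.ones((3, 3, 3), dtype=bool)
    is_max = image == ndimage.maximum_filter(image, footprint=footprint)
    is_max &= image >= min_brightness
    rows = []
    if is_max.any():
        # collapse connected plateaus of candidate maxima to one pixel
        labels, n_lab = ndimage.label(is_max, structure=footprint)
        for coords in ndimage.value_indices(labels).items():
            lab, idx = coords
            if lab == 0:
                continue
            pts = np.column_stack(idx)
            z, y, x = pts[np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))[0]]
            corr = _psf_correlation(image, z, y, x, np.asarray(psf, dtype=float))
            if corr >= min_psf_corr:
                rows.append((int(z), int(y), int(x), float(image[z, y, x]), corr))
    table = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    if squeeze_2d and len(table):
        table["z"] = 0
    return table


def threshold_smfish(
    spots: pd.DataFrame,
    image: np.ndarray,
    background_radius: int = 10,
    min_ratio: float = 3.0,
) -> pd.DataFrame:
    """Keep spots bright relative to their local median background.

    The background is the median of the (2r+1)-box around the spot in its
    z-plane, floored at a small positive value so zero background keeps
    every spot.
    """
    if background_radius <= 0:
        raise ValueError("background_radius must be positive")
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[None]
    keep = []
    floor = max(1e-6, 1e-6 * image.max())
    for _, row in spots.iterrows():
        z, y, x = int(row["z"]), int(row["y"]), int(row["x"])
        r = background_radius
        patch = image[z, max(0, y - r):y + r + 1, max(0, x - r):x + r + 1]
        bg = max(float(np.median(patch)), floor)
        keep.append(row["brightness"] / bg >= min_ratio)
    return spots[np.asarray(keep, dtype=bool)].reset_index(drop=True)
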
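"""Image pre-processing: flat-field, Wiener deconvolution, high-pass, drift.

The chain applied before decoding is: flat-field correction (divide by a
per-color per-pixel median illumination image), Wiener deconvolution with
the microscope PSF, then a subtractive-Gaussian high-pass (sigma 30 px)
clamped at zero.  Drift between imaging rounds is estimated at integer
pixel resolution (including z) by phase correlation of anchor point
clouds detected in a DAPI-like channel, and is applied to coordinates
downstream, never by resampling images.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import restoration
from skimage.registration import phase_cross_correlation

from .stack import ImageStack

__all__ = [
    "compute_flatfield",
    "apply_flatfield",
    "wiener_deconvolve",
    "highpass",
    "detect_anchor_points",
    "estimate_drift",
    "preprocess_stack",
]

FLATFIELD_FLOOR_FRACTION = 0.01  # clamp floor as a fraction of the global median
HIGHPASS_SIGMA = 30.0


def compute_flatfield(first_round_images: list[np.ndarray]) -> np.ndarray:
    """Per-pixel median brightness across first-round fields of view.

    One flat-field is computed per color channel; pass the first-round
    images of one color.  The result is clamped below at 1% of its global
    median so later division cannot blow up in dark corners.
    """
    if len(first_round_images) == 0:
        raise ValueError("need at least one field of view")
    stack = np.stack([np.asarray(im, dtype=float) for im in first_round_images])
    field = np.median(stack, axis=0)
    floor = FLATFIELD_FLOOR_FRACTION * max(np.median(field), 1e-12)
    return np.maximum(field, max(floor, 1e-12))


def apply_flatfield(image: np.ndarray, flatfield: np.ndarray) -> np.ndarray:
    """Inversely scale an image by the flat-field.

    The field is normalized to unit mean first so corrected images keep
    their photometric scale (the printed brightness thresholds stay
    meaningful); 2D fields broadcast over the z axis of 3D images.
    """
    image = np.asarray(image, dtype=float)
    flatfield = np.asarray(flatfield, dtype=float)
    if flatfield.shape != image.shape[-flatfield.ndim:]:
        raise ValueError(
            f"flat-field shape {flatfield.shape} does not match image {image.shape}"
        )
    return image / (flatfield / flatfield.mean())


def wiener_deconvolve(
    image: np.ndarray, psf: np.ndarray, noise_parameter: float = 0.05
) -> np.ndarray:
    """Wiener deconvolution with a custom PSF (2D, applied per z-plane).

    ``noise_parameter`` is the regularization (noise-to-signal) balance.
    Output is clamped at zero: negative ringing carries no brightness
    meaning downstream.
    """
    psf = np.asarray(psf, dtype=float)
    if not np.isclose(psf.sum(), 1.0, atol=1e-6):
        raise ValueError("psf must be normalized to unit sum")
    image = np.asarray(image, dtype=float)
    if psf.shape[-1] > image.shape[-1] or psf.shape[-2] > image.shape[-2]:
        raise ValueError("psf larger than image")
    if image.ndim == 3:
        return np.stack([wiener_deconvolve(pl, psf, noise_parameter) for pl in image])
    scale = max(image.max(), 1e-12)
    out = restoration.wiener(image / scale, psf, balance=noise_parameter, clip=False)
    return np.clip(out * scale, 0, None)


def highpass(image: np.ndarray, sigma: float = HIGHPASS_SIGMA) -> np.ndarray:
    """Subtractive-Gaussian high-pass, clamped at zero.

    ``out = image - gaussian_blur(image, sigma)`` removes slowly varying
    background (DC exactly); the clamp affects only negative values.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        blurred = np.stack([ndimage.gaussian_filter(pl, sigma) for pl in image])
    else:
        blurred = ndimage.gaussian_filter(image, sigma)
    return np.clip(image - blurred, 0, None)


def detect_anchor_points(volume: np.ndarray, min_intensity: float | None = None) -> np.ndarray:
    """Local maxima of a DAPI-like volume, as an (n, 3) array of (z, y, x)."""
    volume = np.asarray(volume, dtype=float)
    if min_intensity is None:
        min_intensity = 0.1 * volume.max()
    footprint = np.ones((3,) * volume.ndim, dtype=bool)
    is_max = (
        (volume == ndimage.maximum_filter(volume, footprint=footprint))
        & (volume >= min_intensity)
        & (volume > 0)
    )
    return np.argwhere(is_max)


def estimate_drift(
    anchor_reference: np.ndarray,
    anchor_moving: np.ndarray,
    *,
    min_intensity: float | None = None,
) -> tuple[int, int, int]:
    """Integer (dz, dy, dx) shift of the moving anchors vs the reference.

    Anchor extrema are detected in both volumes, rendered as sparse
    indicator volumes, and registered by FFT phase correlation.  The
    returned offset is the shift *of the moving volume*: shifting the
    reference by it reproduces the moving volume.
    """
    ref_pts = detect_anchor_points(anchor_reference, min_intensity)
    mov_pts = detect_anchor_points(anchor_moving, min_intensity)
    if len(ref_pts) == 0 or len(mov_pts) == 0:
        raise ValueError("no anchor points detected")
    shape = anchor_reference.shape
    ref_ind = np.zeros(shape, dtype=float)
    mov_ind = np.zeros(shape, dtype=float)
    ref_ind[tuple(ref_pts.T)] = 1.0
    mov_ind[tuple(mov_pts.T)] = 1.0
    shift, _, _ = phase_cross_correlation(
        mov_ind, ref_ind, upsample_factor=1, normalization=None
    )
    return tuple(int(round(s)) for s in shift)


def preprocess_stack(
    stack: ImageStack,
    psf: np.ndarray | None = None,
    *,
    flatfields: dict[int, np.ndarray] | None = None,
    noise_parameter: float = 0.05,
    highpass_sigma: float = HIGHPASS_SIGMA,
    deconvolve: bool = True,
) -> ImageStack:
    """Full pre-processing chain over every bit image.

    Order: flat-field (per color) -> Wiener deconvolution -> high-pass.
    If an anchor channel is present, per-round drift is estimated against
    round 0 and stored on the returned stack (replacing any prior
    estimate); images themselves are never shifted.
    """
    out = stack.copy()
    for b in range(out.n_bits):
        img = out.data[b]
        if flatfields is not None:
            ff = flatfields.get(out.color_of(b))
            if ff is not None:
                img = apply_flatfield(img, ff)
        if deconvolve and psf is not None:
            img = wiener_deconvolve(img, psf, noise_parameter)
        img = highpass(img, highpass_sigma)
        out.data[b] = img
    if stack.anchors is not None and stack.anchors.shape[0] > 1:
        drift = np.zeros((out.n_bits, 3), dtype=int)
        for r in range(stack.anchors.shape[0]):
            if r == 0:
                d = (0, 0, 0)
            else:
                d = estimate_drift(stack.anchors[0], stack.anchors[r])
            for b in range(out.n_bits):
                if out.round_of(b) == r:
                    drift[b] = d
        out.drift = drift
    return out
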
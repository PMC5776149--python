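"""Glare convolution: scene luminance -> retinal contrast.

The retinal-contrast raster ``R`` is the linear convolution of the scene
luminance ``L`` with the unit-sum glare kernel, using replicate (edge-extend)
boundary padding so that border pixels see plausible neighbors instead of
zeros. The kernel sums to one, so the operation only redistributes light:
a constant raster is a fixed point, and the darkest pixel can only get
brighter.

The FFT path (scipy.signal.fftconvolve on the padded array) is an
optimization; correctness is defined by direct spatial convolution, with
which it agrees to double-precision round-off.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator, TransformerMixin

from .gsf import Geometry, GlareParameters, build_kernel, validate_kernel

__all__ = ["compute_retinal_contrast", "GlareConvolver"]

logger = logging.getLogger(__name__)


def compute_retinal_contrast(scene: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve scene luminance with a unit-sum glare kernel.

    Parameters
    ----------
    scene : ndarray (h, w)
        Linear relative scene luminance, strictly positive.
    kernel : ndarray (2r+1, 2r+1)
        Unit-sum, strictly positive glare kernel (see :func:`build_kernel`).
        Any odd side >= 3 is accepted; sides smaller than the full
        ``2*max(w,h)+1`` support truncate far-field glare and trigger a
        warning.

    Returns
    -------
    ndarray (h, w) of float64
        Linear retinal contrast. FFT round-off can push values a hair below
        the scene minimum; such pixels are clamped to the scene minimum and
        counted in the log.
    """
    scene = np.asarray(scene, dtype=np.float64)
    if scene.ndim != 2:
        raise ValueError(f"scene must be 2-D, got shape {scene.shape}")
    if not np.all(scene > 0):
        raise ValueError("scene luminance must be strictly positive")
    validate_kernel(kernel)
    h, w = scene.shape
    full_side = 2 * max(w, h) + 1
    if kernel.shape[0] < full_side:
        warnings.warn(
            f"kernel side {kernel.shape[0]} is smaller than the full support "
            f"{full_side} for a {w}x{h} raster; far glare will be truncated",
            stacklevel=2,
        )

    pad = kernel.shape[0] // 2
    padded = np.pad(scene, pad, mode="edge")
    out = fftconvolve(padded, kernel, mode="same")[pad:pad + h, pad:pad + w]

    floor = scene.min()
    clamped = out < floor
    n_clamped = int(clamped.sum())
    if n_clamped:
        out[clamped] = floor
        logger.info("clamped %d pixels below the input floor (FFT round-off)", n_clamped)
    logger.info(
        "convolution sums: input %.6e output %.6e (ratio %.6f), min %.3e -> %.3e, max %.3e -> %.3e",
        scene.sum(), out.sum(), out.sum() / scene.sum(),
        scene.min(), out.min(), scene.max(), out.max(),
    )
    return out


class GlareConvolver(BaseEstimator, TransformerMixin):
    """Transformer applying CIE-observer intraocular glare to luminance rasters.

    ``fit`` builds the glare kernel for the raster geometry; ``transform``
    convolves. X is a single 2-D luminance raster (the "samples" are the
    pixel grid, not sklearn's usual row-per-sample matrix).

    Parameters
    ----------
    age : float, default 25
        Observer age in years.
    pigment : float, default 0.5
        Iris pigmentation factor, 0 (dark eyes) to 1.2 (blue eyes).
    degrees_per_pixel : float
        Angular pixel pitch of the raster.
    kernel_radius : int or None
        Kernel half-side in pixels; defaults to max(width, height).

    Attributes
    ----------
    kernel_ : ndarray
        Unit-sum glare kernel built by ``fit``.
    geometry_ : Geometry
        Geometry the kernel was built for.
    """

    def __init__(self, age=25.0, pigment=0.5,
                 degrees_per_pixel=15.5 / 600.0, kernel_radius=None):
        self.age = age
        self.pigment = pigment
        self.degrees_per_pixel = degrees_per_pixel
        self.kernel_radius = kernel_radius

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError(f"X must be a 2-D luminance raster, got shape {X.shape}")
        h, w = X.shape
        self.geometry_ = Geometry(width_px=w, height_px=h,
                                  degrees_per_pixel=self.degrees_per_pixel)
        params = GlareParameters(age_years=self.age, pigment=self.pigment)
        self.kernel_ = build_kernel(self.geometry_, params, radius_px=self.kernel_radius)
        return self

    def transform(self, X):
        if not hasattr(self, "kernel_"):
            raise RuntimeError("GlareConvolver is not fitted; call fit(X) first")
        return compute_retinal_contrast(np.asarray(X, dtype=np.float64), self.kernel_)
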
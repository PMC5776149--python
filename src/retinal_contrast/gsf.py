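"""CIE Standard Glare Observer: glare spread function and convolution kernel.

The glare spread function (GSF) of the CIE standard observer gives the
equivalent veiling luminance produced on the retina per unit glare
illuminance at the eye (cd·m⁻² per lux, i.e. sr⁻¹) as a function of the
visual angle ``theta`` between the glaring and the receiving point. It
depends on the observer's age ``A`` (the ocular media scatter more with
age) and an iris/fundus pigmentation factor ``p`` (0 for very dark eyes,
0.5 brown, 1.0 blue-green, up to 1.2 for blue eyes).

The 2-D convolution kernel is the GSF sampled on a flat pixel grid
(Euclidean pixel distance times the angular pixel pitch) and normalized to
unit sum, so that convolution redistributes light without introducing any
DC gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GlareParameters",
    "Geometry",
    "DEFAULT_DEGREES_PER_PIXEL",
    "evaluate_gsf",
    "build_kernel",
    "validate_kernel",
    "kernel_profile",
]

#: Angular pixel pitch of the reference target geometry: a 15.5 deg tall,
#: 600 px tall field of view (~1.55 arcmin per pixel).
DEFAULT_DEGREES_PER_PIXEL = 15.5 / 600.0


@dataclass(frozen=True)
class GlareParameters:
    """Observer parameters of the CIE glare observer.

    Parameters
    ----------
    age_years : float
        Observer age in years; must be positive.
    pigment : float
        Iris/fundus pigmentation factor in [0, 1.2].
    """

    age_years: float = 25.0
    pigment: float = 0.5

    def __post_init__(self):
        if not np.isfinite(self.age_years) or self.age_years <= 0:
            raise ValueError(f"age_years must be a positive finite number, got {self.age_years!r}")
        if not np.isfinite(self.pigment) or not (0.0 <= self.pigment <= 1.2):
            raise ValueError(f"pigment must lie in [0, 1.2], got {self.pigment!r}")


@dataclass(frozen=True)
class Geometry:
    """Raster geometry: pixel dimensions and angular pixel pitch."""

    width_px: int
    height_px: int
    degrees_per_pixel: float = DEFAULT_DEGREES_PER_PIXEL

    def __post_init__(self):
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("width_px and height_px must be >= 1")
        if not np.isfinite(self.degrees_per_pixel) or self.degrees_per_pixel <= 0:
            raise ValueError("degrees_per_pixel must be positive")
        for n, axis in ((self.width_px, "width"), (self.height_px, "height")):
            if n * self.degrees_per_pixel > 200.0:
                raise ValueError(
                    f"field of view along {axis} is {n * self.degrees_per_pixel:.1f} deg; "
                    "the glare formula is specified for angles up to 100 deg "
                    "(200 deg total field)"
                )

    @property
    def diagonal_deg(self) -> float:
        return float(np.hypot(self.width_px, self.height_px) * self.degrees_per_pixel)


def evaluate_gsf(theta_deg, params: GlareParameters = GlareParameters()):
    """Evaluate the CIE glare spread function at visual angle ``theta_deg``.

    Parameters
    ----------
    theta_deg : float or array_like
        Visual angle(s) in degrees, >= 0. The standard covers 0.01-100 deg;
        the formula is finite at 0 (every denominator is >= 1) and is
        extrapolated smoothly beyond 100 deg.
    params : GlareParameters
        Observer age and pigmentation.

    Returns
    -------
    float or ndarray
        Equivalent veiling luminance per glare illuminance (cd/m2 per lux).
    """
    theta = np.asarray(theta_deg, dtype=np.float64)
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta_deg must be finite")
    if np.any(theta < 0):
        raise ValueError("theta_deg must be non-negative")

    a4 = (params.age_years / 70.0) ** 4
    p = params.pigment
    t2 = theta * theta

    near = 9.2e6 / (1.0 + t2 / 0.046**2) ** 1.5 + 1.5e5 / (1.0 + t2 / 0.045**2) ** 1.5
    wide_lorentz = 1.0 + t2 / 0.1**2
    wide = 400.0 / wide_lorentz + 3.0e-8 * t2
    pig = 1300.0 / wide_lorentz**1.5 + 0.8 / np.sqrt(wide_lorentz)

    value = (1.0 - 0.08 * a4) * near + (1.0 + 1.6 * a4) * (wide + p * pig) + 2.5e-3 * p
    if np.ndim(theta_deg) == 0:
        return float(value)
    return value


def build_kernel(
    geometry: Geometry,
    params: GlareParameters = GlareParameters(),
    radius_px: int | None = None,
) -> np.ndarray:
    """Build the unit-sum glare convolution kernel for a raster geometry.

    The kernel is square with side ``2*r + 1`` where ``r = max(width, height)``
    unless overridden, so every pixel of the raster contributes glare to every
    other. Entry at integer offset (i, j) from the center is the GSF evaluated
    at the flat-plane angle ``degrees_per_pixel * hypot(i, j)``; the whole
    kernel is then divided by its sum, so it adds up to exactly one.

    Returns
    -------
    ndarray of float64, shape (2r+1, 2r+1)
        Strictly positive weights summing to 1.
    """
    if radius_px is None:
        radius_px = max(geometry.width_px, geometry.height_px)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    corner = geometry.diagonal_deg
    if corner > 100.0:
        warnings.warn(
            f"corner-to-corner angle {corner:.1f} deg exceeds the 100 deg domain of the "
            "CIE glare formula; kernel values beyond 100 deg are extrapolated",
            stacklevel=2,
        )
    offsets = np.arange(-radius_px, radius_px + 1, dtype=np.float64)
    theta = geometry.degrees_per_pixel * np.hypot(offsets[:, None], offsets[None, :])
    kernel = evaluate_gsf(theta, params)
    kernel /= kernel.sum()
    return kernel


def validate_kernel(kernel: np.ndarray, rtol: float = 1e-9) -> None:
    """Check that ``kernel`` is a valid glare kernel (square, odd, positive, unit sum)."""
    kernel = np.asarray(kernel)
    if kernel.ndim != 2 or kernel.shape[0] != kernel.shape[1]:
        raise ValueError(f"kernel must be square, got shape {kernel.shape}")
    if kernel.shape[0] % 2 == 0:
        raise ValueError(f"kernel side must be odd, got {kernel.shape[0]}")
    if not np.all(kernel > 0):
        raise ValueError("kernel values must be strictly positive")
    s = kernel.sum()
    if abs(s - 1.0) > rtol:
        raise ValueError(f"kernel must sum to 1 (got {s!r})")


def kernel_profile(
    params: GlareParameters = GlareParameters(),
    theta_min: float = 0.01,
    theta_max: float = 100.0,
    n: int = 512,
):
    """Radial log-log profile of the GSF, as (theta_deg, gsf_value) columns.

    Convenience for exporting the standard's 0.01-100 deg curve for
    inspection/plotting; returns a pandas DataFrame.
    """
    import pandas as pd

    theta = np.logspace(np.log10(theta_min), np.log10(theta_max), n)
    return pd.DataFrame({"theta_deg": theta, "gsf_value": evaluate_gsf(theta, params)})
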
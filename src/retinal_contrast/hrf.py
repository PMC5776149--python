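"""Scene-dependent Human Response Function (HRF).

Apparent lightness of a patch in an HDR display is a linear function of the
log of its retinal contrast, but the slope of that line depends on the
spatial content of the scene. The model is

    lightness = (26.7 + s) * log10(R) + 93

on a 0-100 lightness scale, where ``R`` is relative retinal contrast
(R = 1 at the scene maximum) and ``s`` is an additive scene-content factor:
s = 0 for a black surround (lightness spans 3.5 decades of retinal
contrast), s = 20 for a half-white/half-black mosaic, s = 30 for a white
surround (the same white-to-black swing compressed into 1.6 decades).

``fit_hrf`` recovers slope, intercept and the Pearson correlation from
observed (lightness, log10 R) pairs by ordinary least squares, and
``estimate_s`` reads off the scene factor as slope - 26.7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "BASE_SLOPE",
    "BASE_INTERCEPT",
    "HrfModel",
    "HrfFit",
    "predict_lightness",
    "fit_hrf",
    "estimate_s",
    "HrfRegressor",
    "square_log_contrast",
    "fit_from_observations",
]

BASE_SLOPE = 26.7
BASE_INTERCEPT = 93.0


@dataclass(frozen=True)
class HrfModel:
    """Lightness model ``L = (base_slope + s) * log10(R) + intercept``."""

    s: float = 0.0
    base_slope: float = BASE_SLOPE
    intercept: float = BASE_INTERCEPT

    def __post_init__(self):
        if self.base_slope + self.s <= 0:
            raise ValueError("total slope base_slope + s must be positive")

    @property
    def slope(self) -> float:
        return self.base_slope + self.s


@dataclass(frozen=True)
class HrfFit:
    """Least-squares HRF fit: slope, intercept and Pearson correlation."""

    slope: float
    intercept: float
    correlation: float


def predict_lightness(log_retinal_contrast, model: HrfModel = HrfModel()):
    """Predicted apparent lightness (0-100 scale) at ``log10`` retinal contrast."""
    logr = np.asarray(log_retinal_contrast, dtype=np.float64)
    out = model.slope * logr + model.intercept
    return float(out) if np.ndim(log_retinal_contrast) == 0 else out


def fit_hrf(lightness, log_retinal_contrast) -> HrfFit:
    """Ordinary least-squares HRF: lightness regressed on log10 retinal contrast."""
    y = np.asarray(lightness, dtype=np.float64)
    x = np.asarray(log_retinal_contrast, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("lightness and log_retinal_contrast must be equal-length 1-D series")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("observations must be finite")
    if np.ptp(x) == 0:
        raise ValueError("log retinal contrast is constant; slope is undefined")
    res = stats.linregress(x, y)
    return HrfFit(slope=float(res.slope), intercept=float(res.intercept),
                  correlation=float(res.rvalue))


def estimate_s(fit: HrfFit, base_slope: float = BASE_SLOPE) -> float:
    """Scene-content factor implied by a fitted slope: ``s = slope - 26.7``."""
    return fit.slope - base_slope


class HrfRegressor(BaseEstimator, RegressorMixin):
    """sklearn-style linear lightness-vs-log-retinal-contrast regressor.

    X is ``(n, 1)`` log10 retinal contrast, y is apparent lightness (0-100).

    Attributes
    ----------
    slope_, intercept_, correlation_ : float
        OLS line and Pearson correlation.
    s_ : float
        Scene-content factor ``slope_ - base_slope``.
    """

    def __init__(self, base_slope=BASE_SLOPE):
        self.base_slope = base_slope

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be (n_samples, 1) log10 retinal contrast")
        res = fit_hrf(y, X[:, 0])
        self.slope_ = res.slope
        self.intercept_ = res.intercept
        self.correlation_ = res.correlation
        self.s_ = estimate_s(res, self.base_slope)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "slope_"):
            raise RuntimeError("HrfRegressor is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        return self.slope_ * X[:, 0] + self.intercept_


def square_log_contrast(retinal: np.ndarray, layout: dict, erode_px: int = 1) -> pd.DataFrame:
    """Per-test-square mean log10 retinal contrast, relative to the raster maximum.

    Each square is sampled over its interior, eroded ``erode_px`` from every
    edge so the glare gradient at the patch boundary does not contaminate
    the mean; the mean is taken on linear values, then logged.
    """
    retinal = np.asarray(retinal, dtype=np.float64)
    vmax = retinal.max()
    rows = []
    for sq in layout["test_squares"]:
        e = min(erode_px, (sq["size"] - 1) // 2)
        patch = retinal[sq["y"] + e:sq["y"] + sq["size"] - e,
                        sq["x"] + e:sq["x"] + sq["size"] - e]
        rows.append({"square_id": sq["id"], "pair": sq["pair"],
                     "log10_retinal_contrast": float(np.log10(patch.mean() / vmax))})
    return pd.DataFrame(rows)


def fit_from_observations(retinal: np.ndarray, layout: dict, observations: pd.DataFrame) -> dict:
    """Join observer lightness matches to test squares and fit the HRF.

    ``observations`` needs columns ``square_id`` and ``lightness``. Returns a
    dict with slope, intercept, correlation and the implied scene factor s.
    """
    if not {"square_id", "lightness"} <= set(observations.columns):
        raise ValueError("observations must have columns square_id,lightness")
    contrast = square_log_contrast(retinal, layout)
    merged = observations.merge(contrast, on="square_id", how="inner")
    if len(merged) < 3:
        raise ValueError("fewer than 3 observations matched the layout's test squares")
    fit = fit_hrf(merged["lightness"], merged["log10_retinal_contrast"])
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "correlation": fit.correlation,
        "s_hat": estimate_s(fit),
        "n": int(len(merged)),
    }
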
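"""Gray-level dynamics limitation and quantization of a region of interest.

Before any texture statistic is computed, in-mask intensities are windowed to
``[mu - 3*sigma, mu + 3*sigma]`` (mu, sigma = in-mask mean and population SD)
and linearly mapped to integer gray levels ``1..Ng``.  The windowing removes
the dependence of texture features on global brightness and contrast: the
quantized levels are exactly invariant under ``v -> a*v + b`` (a > 0), because
mu and sigma transform covariantly.

Ng defaults to 64 (6-bit), the granularity the co-occurrence and run-length
feature definitions presuppose; all families in this package consume the same
quantized raster.  Out-of-window intensities are clipped, not discarded, so
the ROI geometry (and hence run and neighborhood structure) is preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import GrayImage, ROIMask

__all__ = ["NormalizationParams", "QuantizedROI", "compute_window", "quantize", "quantize_roi"]

DEFAULT_NG = 64


@dataclass
class NormalizationParams:
    """In-mask intensity statistics and the derived quantization window."""

    mu: float
    sigma: float
    window: tuple[float, float]
    ng: int = DEFAULT_NG

    def __post_init__(self) -> None:
        if self.ng < 2:
            raise ValueError("Ng must be at least 2")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    @property
    def degenerate(self) -> bool:
        """True when the ROI is constant and the window has zero width."""
        return self.window[1] <= self.window[0]


@dataclass
class QuantizedROI:
    """Integer gray levels 1..Ng inside the mask, 0 outside."""

    levels: np.ndarray
    ng: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.mask = np.asarray(self.mask) != 0
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.ng):
            raise ValueError("in-mask levels must lie in 1..Ng")
        if np.any(self.levels[~self.mask] != 0):
            raise ValueError("out-of-mask levels must be 0")

    @property
    def in_mask_levels(self) -> np.ndarray:
        """1-D array of the in-mask gray levels."""
        return self.levels[self.mask]


def compute_window(
    image: GrayImage, mask: ROIMask, *, ng: int = DEFAULT_NG, n_sigma: float = 3.0
) -> NormalizationParams:
    """Mean, population SD and the mu +/- 3 sigma window of in-mask intensities."""
    mask.require_nonempty()
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image shape")
    values = image.pixels[mask.pixels]
    mu = float(values.mean())
    sigma = float(values.std())  # population SD (divisor n)
    return NormalizationParams(mu=mu, sigma=sigma, window=(mu - n_sigma * sigma, mu + n_sigma * sigma), ng=ng)


def quantize(image: GrayImage, mask: ROIMask, params: NormalizationParams) -> QuantizedROI:
    """Clip in-mask intensities to the window and map to levels 1..Ng.

    ``level = floor((v - lower) / (upper - lower) * Ng) + 1`` with the upper
    edge mapping to Ng.  A zero-width window (constant ROI) maps everything to
    level 1 and emits a degeneracy warning.
    """
    lower, upper = params.window
    ng = params.ng
    levels = np.zeros(image.shape, dtype=np.int64)
    m = mask.pixels
    if params.degenerate:
        warnings.warn("degenerate (constant) ROI: all levels set to 1", stacklevel=2)
        levels[m] = 1
        return QuantizedROI(levels, ng, m)
    v = np.clip(image.pixels[m], lower, upper)
    lv = np.floor((v - lower) / (upper - lower) * ng).astype(np.int64) + 1
    np.clip(lv, 1, ng, out=lv)  # v == upper maps to Ng
    levels[m] = lv
    return QuantizedROI(levels, ng, m)


def quantize_roi(
    image: GrayImage,
    mask: ROIMask,
    *,
    ng: int = DEFAULT_NG,
    mode: str = "mu3sigma",
) -> QuantizedROI:
    """Window and quantize in one step.

    mode: ``mu3sigma`` (default) windows to mu +/- 3 sigma; ``minmax`` uses the
    in-mask min/max; ``none`` quantizes the full observed range (identical to
    minmax for finite rasters, kept as an explicit switch).
    """
    if mode == "mu3sigma":
        params = compute_window(image, mask, ng=ng)
    elif mode in ("minmax", "none"):
        mask.require_nonempty()
        values = image.pixels[mask.pixels]
        mu = float(values.mean())
        sigma = float(values.std())
        params = NormalizationParams(mu=mu, sigma=sigma, window=(float(values.min()), float(values.max())), ng=ng)
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    return quantize(image, mask, params)
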
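"""Sparse-vegetation masking from the seasonal maximum of NIR reflectance.

Pixels whose growing-season maximum NIR top-of-atmosphere reflectance stays
below a threshold (default 0.3) are masked as non-vegetation — alkaline
land, built-up areas, water — and excluded before classification.  The
threshold can also be derived from reference vegetation pixels as
mean - standard deviation of their seasonal NIR maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .composites import FeatureCube


@dataclass
class MaskConfig:
    """Vegetation-mask threshold; pixels with max NIR >= threshold are kept."""

    threshold: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")


def seasonal_max(cube: FeatureCube, band: str = "NIR") -> np.ndarray:
    """Per-pixel maximum of the band over all composites (NaN if never seen)."""
    cols = cube.band_feature_indices(band)
    if not cols:
        raise ValueError(f"cube has no {band} features")
    vals = np.where(cube.missing[:, cols], np.nan, cube.values[:, cols])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
        out = np.nanmax(vals, axis=1)
    return out


def derive_threshold(vegetation_max_nir: np.ndarray) -> float:
    """Threshold = mean - sd of seasonal max-NIR over reference vegetation."""
    vals = np.asarray(vegetation_max_nir, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 vegetation reference values")
    return float(vals.mean() - vals.std(ddof=0))


def apply_mask(max_values: np.ndarray, config: MaskConfig | None = None) -> np.ndarray:
    """Boolean vegetation mask: True where max NIR >= threshold.

    A pixel with no NIR observation at all (NaN) counts as non-vegetation.
    """
    config = config or MaskConfig()
    vals = np.asarray(max_values, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(vals), vals >= config.threshold, False)


def vegetation_mask(cube: FeatureCube, config: MaskConfig | None = None) -> np.ndarray:
    """Convenience: seasonal NIR max then threshold, per pixel."""
    return apply_mask(seasonal_max(cube), config)
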
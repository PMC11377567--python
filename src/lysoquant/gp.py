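"""Laurdan generalized polarization (GP) membrane-fluidity maps.

GP is the normalized two-band emission ratio of the solvatochromic probe
Laurdan::

    GP = (I_blue - G * I_red) / (I_blue + G * I_red)

with I_blue the 400-460 nm band, I_red the 470-530 nm band, and G an
instrument calibration factor derived from a reference measurement of
Laurdan in DMSO with known GP (0.0357).  Higher GP means a more ordered,
less fluid membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, NoSignalError
from .io import Image2D, polygon_mask

__all__ = ["GPMap", "derive_g_factor", "gp_map", "roi_mean_gp"]


@dataclass
class GPMap:
    """Per-pixel GP values (NaN where intensity is below the floor)."""

    values: np.ndarray
    g_factor: float
    background_blue: float
    background_red: float
    intensity_floor: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def derive_g_factor(i_blue_ref: float, i_red_ref: float, gp_ref: float) -> float:
    """Solve the GP equation for the calibration factor G.

    Given reference channel intensities of Laurdan in DMSO and its known
    GP, ``G = (i_blue / i_red) * (1 - gp_ref) / (1 + gp_ref)``.
    """
    if i_blue_ref <= 0 or i_red_ref <= 0:
        raise DomainError("reference intensities must be positive")
    if not -1 < gp_ref < 1:
        raise DomainError("gp_ref must lie strictly inside (-1, 1)")
    return float((i_blue_ref / i_red_ref) * (1 - gp_ref) / (1 + gp_ref))


def gp_map(
    i_blue: Image2D,
    i_red: Image2D,
    g_factor: float,
    background: tuple[float, float] | None = None,
    intensity_floor: float | None = None,
) -> GPMap:
    """Compute a per-pixel GP map from the two Laurdan emission channels.

    Per-channel backgrounds are subtracted (clipping at 0) before applying
    the GP equation.  When ``background`` is None the 1st-percentile
    intensity of each channel is used; when ``intensity_floor`` is None it
    defaults to twice the summed background, suppressing GP noise blow-up
    where the denominator approaches zero.  Pixels whose summed intensity
    falls below the floor are undefined (NaN).
    """
    if i_blue.pixels.shape != i_red.pixels.shape:
        raise DomainError("channel images differ in shape")
    if g_factor <= 0:
        raise DomainError("G factor must be positive")
    if background is None:
        background = (
            float(np.percentile(i_blue.pixels, 1)),
            float(np.percentile(i_red.pixels, 1)),
        )
    bg_b, bg_r = background
    if intensity_floor is None:
        intensity_floor = 2.0 * (bg_b + bg_r)
    blue = np.clip(i_blue.pixels - bg_b, 0, None)
    red = np.clip(i_red.pixels - bg_r, 0, None)
    total = blue + red
    denom = blue + g_factor * red
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (blue - g_factor * red) / denom
    values[(total < intensity_floor) | (denom <= 0)] = np.nan
    if not np.isfinite(values).any():
        warnings.warn("GP map has no defined pixels", stacklevel=2)
    return GPMap(values, float(g_factor), bg_b, bg_r, float(intensity_floor))


def roi_mean_gp(gpm: GPMap, roi: np.ndarray) -> float:
    """Mean of defined GP pixels inside a polygon ROI or boolean mask.

    ROIs are typically drawn at the plasma membrane; the mean is the
    arithmetic pixel mean of the GP map, not the GP of mean intensities.
    """
    roi = np.asarray(roi)
    if roi.dtype == bool:
        mask = roi
        if mask.shape != gpm.values.shape:
            raise DomainError("ROI mask shape does not match the map")
    else:
        mask = polygon_mask(roi, gpm.values.shape)
    vals = gpm.values[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise NoSignalError("no defined GP pixels inside the ROI")
    return float(vals.mean())
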
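"""Pixel-based and object-based colocalization statistics.

Implements Pearson's correlation and Manders' thresholded coefficients
(M1: fraction of channel-A intensity in B-positive pixels; M2 the converse)
over a cell mask, plus an object-based triple-overlap fraction: the share of
reference vesicles (e.g. LAMP1) that carry a punctum of each of two partner
markers (e.g. Cx43 and Gal3) within a matching radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .errors import DomainError, NoSignalError
from .io import CellGeometry, Image2D, polygon_mask
from .puncta import PunctaSet

__all__ = ["ColocResult", "pearson", "manders", "triple_overlap", "coloc_pair"]


@dataclass
class ColocResult:
    pearson_r: float
    manders_m1: float
    manders_m2: float
    threshold_a: float
    threshold_b: float
    n_pixels: int


def _resolve_mask(mask, shape) -> np.ndarray:
    if isinstance(mask, CellGeometry):
        return polygon_mask(mask.cell_polygon, shape)
    m = np.asarray(mask, dtype=bool)
    if m.shape != shape:
        raise DomainError("mask shape does not match image shape")
    return m


def _pixels(a: Image2D, b: Image2D, mask) -> tuple[np.ndarray, np.ndarray]:
    if a.pixels.shape != b.pixels.shape:
        raise DomainError("images differ in shape")
    m = _resolve_mask(mask, a.pixels.shape)
    if m.sum() < 2:
        raise DomainError("mask must contain at least 2 pixels")
    return a.pixels[m], b.pixels[m]


def pearson(a: Image2D, b: Image2D, mask) -> float:
    """Sample Pearson correlation of paired pixel intensities within a mask."""
    va, vb = _pixels(a, b, mask)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise DomainError("correlation undefined: zero variance in a channel")
    va = va - va.mean()
    vb = vb - vb.mean()
    return float(va @ vb / np.sqrt((va @ va) * (vb @ vb)))


def manders(
    a: Image2D, b: Image2D, mask, thr_a: float, thr_b: float
) -> tuple[float, float]:
    """Manders' thresholded coefficients (M1, M2).

    M1 sums channel-A intensity over pixels where B exceeds ``thr_b``,
    normalised by the total A intensity over A-positive pixels (A > ``thr_a``);
    M2 is the symmetric quantity for channel B.
    """
    if thr_a < 0 or thr_b < 0:
        raise DomainError("thresholds must be >= 0")
    va, vb = _pixels(a, b, mask)
    a_pos = va > thr_a
    b_pos = vb > thr_b
    denom1 = va[a_pos].sum()
    denom2 = vb[b_pos].sum()
    if denom1 <= 0:
        raise NoSignalError("no signal above threshold in channel A")
    if denom2 <= 0:
        raise NoSignalError("no signal above threshold in channel B")
    m1 = va[a_pos & b_pos].sum() / denom1
    m2 = vb[a_pos & b_pos].sum() / denom2
    return float(m1), float(m2)


def _subtract_background(img: Image2D, mask: np.ndarray, thr: float) -> Image2D:
    below = img.pixels[mask][img.pixels[mask] <= thr]
    bg = float(np.median(below)) if below.size else 0.0
    return Image2D(np.clip(img.pixels - bg, 0, None), img.pixel_size, img.channel_name)


def coloc_pair(a: Image2D, b: Image2D, mask) -> ColocResult:
    """Pearson r and Manders M1/M2 with per-channel Otsu thresholds.

    Per-cell background (median of sub-threshold in-mask pixels) is
    subtracted from each channel before the coefficients.
    """
    m = _resolve_mask(mask, a.pixels.shape)
    thr_a0 = float(threshold_otsu(a.pixels[m])) if np.ptp(a.pixels[m]) else 0.0
    thr_b0 = float(threshold_otsu(b.pixels[m])) if np.ptp(b.pixels[m]) else 0.0
    a_s = _subtract_background(a, m, thr_a0)
    b_s = _subtract_background(b, m, thr_b0)
    thr_a = float(threshold_otsu(a_s.pixels[m])) if np.ptp(a_s.pixels[m]) else 0.0
    thr_b = float(threshold_otsu(b_s.pixels[m])) if np.ptp(b_s.pixels[m]) else 0.0
    r = pearson(a_s, b_s, m)
    m1, m2 = manders(a_s, b_s, m, thr_a, thr_b)
    return ColocResult(r, m1, m2, thr_a, thr_b, int(m.sum()))


def _greedy_match(ref: np.ndarray, partner: np.ndarray, radius: float) -> np.ndarray:
    """One-to-one nearest-first matching; returns a boolean matched flag per ref point."""
    matched = np.zeros(len(ref), dtype=bool)
    if len(partner) == 0 or len(ref) == 0:
        return matched
    tree = cKDTree(partner)
    pairs = []
    for i, p in enumerate(ref):
        for j in tree.query_ball_point(p, radius):
            d = float(np.hypot(*(p - partner[j])))
            pairs.append((d, i, j))
    pairs.sort()
    used_ref: set[int] = set()
    used_par: set[int] = set()
    for d, i, j in pairs:
        if i in used_ref or j in used_par:
            continue
        used_ref.add(i)
        used_par.add(j)
        matched[i] = True
    return matched


def triple_overlap(
    reference: PunctaSet,
    partner1: PunctaSet,
    partner2: PunctaSet,
    match_radius: float,
) -> float:
    """Fraction of reference puncta with a one-to-one match in both partner sets.

    Matching is greedy nearest-first within ``match_radius`` pixels, one
    partner punctum per reference punctum.
    """
    if match_radius <= 0:
        raise DomainError("match_radius must be > 0")
    if len(reference) == 0:
        raise DomainError("triple overlap undefined for an empty reference set")
    ref = reference.centroids
    m1 = _greedy_match(ref, partner1.centroids, match_radius)
    m2 = _greedy_match(ref, partner2.centroids, match_radius)
    return float(np.mean(m1 & m2))
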
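"""Competition outcomes from two-channel rasters, footprints, doubling times.

The relative strain density ("% challenger remaining") is the challenger's
share of total fluorescence or biomass: integrated above-threshold intensity
per channel after a rolling-ball-style morphological background subtraction
and an automatic (Otsu) threshold. Intensity weighting (rather than pixel
counting) is the default because relative strain *density* weights brighter,
denser regions; pixel-count mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label


class EmptyBiofilmError(ValueError):
    """Both channels/fields carry no signal."""


class NoGrowthError(ValueError):
    """Growth-curve fit found no exponential increase."""


@dataclass
class ChannelPair:
    challenger: np.ndarray
    partner: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        self.challenger = np.asarray(self.challenger, dtype=float)
        self.partner = np.asarray(self.partner, dtype=float)
        if self.challenger.shape != self.partner.shape:
            raise ValueError("channel shapes differ")
        for c in (self.challenger, self.partner):
            if not np.isfinite(c).all() or (c < 0).any():
                raise ValueError("intensities must be finite and >= 0")


@dataclass
class GrowthSeries:
    times: np.ndarray       # minutes
    od600: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times.shape != self.od600.shape or self.times.ndim != 1:
            raise ValueError("times and od600 must be matching 1-D arrays")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if (self.od600 <= 0).any():
            raise ValueError("od600 values must be > 0")


def relative_density_from_fields(B1: np.ndarray,
                                 B2: np.ndarray) -> tuple[float, float]:
    """f_i = sum(B_i) / sum(B1 + B2)."""
    B1, B2 = np.asarray(B1, float), np.asarray(B2, float)
    if (B1 < 0).any() or (B2 < 0).any():
        raise ValueError("fields must be nonnegative")
    s1, s2 = float(B1.sum()), float(B2.sum())
    if s1 + s2 == 0:
        raise EmptyBiofilmError("empty biofilm")
    return s1 / (s1 + s2), s2 / (s1 + s2)


def _subtract_background(img: np.ndarray, radius: int) -> np.ndarray:
    """Rolling-ball-style background removal: grey opening with a flat
    (2r+1)-square structuring element, applied separably."""
    size = 2 * radius + 1
    er = ndimage.grey_erosion(img, size=(1, size))
    er = ndimage.grey_erosion(er, size=(size, 1))
    bg = ndimage.grey_dilation(er, size=(1, size))
    bg = ndimage.grey_dilation(bg, size=(size, 1))
    return np.clip(img - bg, 0.0, None)


def _channel_signal(img: np.ndarray, background_radius: int | None,
                    threshold_method: str, mode: str) -> float:
    img = np.asarray(img, dtype=float)
    if background_radius:
        img = _subtract_background(img, background_radius)
    if img.max() <= 0 or img.max() == img.min():
        return 0.0
    if threshold_method != "otsu":
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    thr = threshold_otsu(img)
    mask = img > thr
    if not mask.any():
        return 0.0
    return float(img[mask].sum()) if mode == "intensity" else float(mask.sum())


def quantify_relative_density(images: ChannelPair,
                              background_radius: int | None = 50,
                              threshold_method: str = "otsu",
                              mode: str = "intensity") -> float:
    """% challenger remaining, in [0, 100]."""
    s_ch = _channel_signal(images.challenger, background_radius,
                           threshold_method, mode)
    s_pa = _channel_signal(images.partner, background_radius,
                           threshold_method, mode)
    if s_ch + s_pa == 0:
        raise EmptyBiofilmError("empty biofilm: no pixel above threshold")
    return 100.0 * s_ch / (s_ch + s_pa)


def biofilm_footprint(image: np.ndarray, threshold_method: str = "otsu",
                      pixel_size: float = 1.0) -> float:
    """Area of the largest above-threshold connected component (satellite
    colonies are ignored)."""
    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        if img.max() > 0:           # uniformly saturated frame
            return img.size * pixel_size ** 2
        warnings.warn("blank image: footprint is 0", stacklevel=2)
        return 0.0
    if threshold_method != "otsu":
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    mask = img > threshold_otsu(img)
    if not mask.any():
        warnings.warn("no pixel above threshold: footprint is 0", stacklevel=2)
        return 0.0
    lab, n = label(mask, return_num=True)
    largest = max(np.bincount(lab.ravel())[1:])
    return float(largest) * pixel_size ** 2


def fit_doubling_time(series: GrowthSeries,
                      window: tuple[float, float] | None = None,
                      min_points: int = 3,
                      r2_min: float = 0.99) -> float:
    """Doubling time (min) from a log2-linear least-squares fit over the
    exponential window.

    With window=None the exponential phase is found automatically: among all
    contiguous runs of >= ``min_points`` points with positive slope and R^2
    above ``r2_min``, the longest run whose R^2 ties the best observed R^2
    (within 1e-6). Maximising fit quality before length keeps lag or plateau
    boundary points out of the window: a hockey-stick window can hold R^2
    above 0.99 while biasing the slope, but it can never tie the pure
    exponential run's R^2 of ~1. Raises NoGrowthError when no window shows
    growth.
    """
    t, y = series.times, np.log2(series.od600)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        if sel.sum() < min_points:
            raise ValueError("window holds fewer than 3 points")
        res = stats.linregress(t[sel], y[sel])
        if res.slope <= 0:
            raise NoGrowthError("no growth detected")
        return 1.0 / res.slope

    n = len(t)
    candidates = []   # (r2, length, slope)
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            res = stats.linregress(t[i:j], y[i:j])
            if res.slope <= 0:
                continue
            r2 = res.rvalue ** 2
            if r2 > r2_min:
                candidates.append((r2, j - i, res.slope))
    if not candidates:
        raise NoGrowthError("no growth detected")
    r2_best = max(c[0] for c in candidates)
    tier = [c for c in candidates if c[0] >= r2_best - 1e-6]
    _, _, slope = max(tier, key=lambda c: (c[1], c[0]))
    return 1.0 / slope
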
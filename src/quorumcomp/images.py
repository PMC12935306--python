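"""Synthetic two-channel fluorescence images with recorded ground truth.

Renders a pair of density fields (e.g. simulator output) into a two-channel
16-bit image the way a fluorescence stereoscope would see a mixed colony:
an affine intensity map per channel, optional cross-channel bleed-through,
and additive Gaussian noise, clipped to the dtype range. The true relative
density of the challenger field is recorded so image-based quantification
can be validated against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class RenderedImage:
    """channels[0] = challenger, channels[1] = partner (both uint16)."""

    channels: np.ndarray
    truth_percent_challenger: float
    noise_sd: float
    bleed: float
    seed: int


def render_fluorescence_image(field1: np.ndarray, field2: np.ndarray,
                              noise_sd: float = 0.0, bleed: float = 0.0,
                              seed: int = 0,
                              fill_fraction: float = 0.8) -> RenderedImage:
    """Render two nonnegative fields into a two-channel uint16 image.

    noise_sd is the Gaussian noise standard deviation as a fraction of the
    dtype dynamic range; bleed in [0, 1) mixes a fraction of the other
    field into each channel before noise. Ground truth is the challenger
    (field1) share of total field mass, in percent.
    """
    f1 = np.asarray(field1, dtype=float)
    f2 = np.asarray(field2, dtype=float)
    if f1.shape != f2.shape:
        raise ValueError("field shapes differ")
    if (f1 < 0).any() or (f2 < 0).any():
        raise ValueError("fields must be nonnegative")
    if not 0.0 <= bleed < 1.0:
        raise ValueError("bleed must be in [0, 1)")

    full = np.iinfo(np.uint16).max
    peak = max(f1.max(), f2.max())
    gain = fill_fraction * full / peak if peak > 0 else 0.0

    rng = np.random.default_rng(seed)
    chans = []
    for a, b in ((f1, f2), (f2, f1)):
        img = gain * (a + bleed * b)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd * full, size=img.shape)
        chans.append(np.clip(np.rint(img), 0, full).astype(np.uint16))

    s1, s2 = float(f1.sum()), float(f2.sum())
    truth = 100.0 * (s1 / (s1 + s2)) if s1 + s2 > 0 else math.nan
    return RenderedImage(np.stack(chans), truth, noise_sd, bleed, seed)


def sector_fields(shape: tuple[int, int], n_sectors: int, seed: int,
                  colony_radius_frac: float = 0.38,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Colony-like density fields: a domed disc split into angular sectors
    randomly assigned to the two strains, emulating the frozen sector
    geometry of a mature mixed colony biofilm."""
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.sqrt((xx - nx / 2) ** 2 + (yy - ny / 2) ** 2)
    theta = np.arctan2(yy - ny / 2, xx - nx / 2)
    R = colony_radius_frac * min(nx, ny)
    disc = r < R
    bounds = np.sort(rng.uniform(-np.pi, np.pi, n_sectors))
    owner = np.zeros(shape, dtype=int)
    labels = rng.integers(0, 2, n_sectors)
    for i in range(n_sectors):
        lo, hi = bounds[i], bounds[(i + 1) % n_sectors]
        sel = ((theta >= lo) & (theta < hi) if hi > lo
               else (theta >= lo) | (theta < hi))
        owner[sel] = labels[i]
    dome = np.clip(1.0 - (r / R) ** 4, 0.0, 1.0)
    return (np.where(disc & (owner == 0), dome, 0.0),
            np.where(disc & (owner == 1), dome, 0.0))


def gaussian_blob_fields(shape: tuple[int, int], n_blobs: int, seed: int,
                         sigma_range: tuple[float, float] = (6.0, 14.0),
                         amplitude_range: tuple[float, float] = (0.4, 1.0),
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Two smooth nonnegative test fields built from random Gaussian blobs
    (a stand-in for colony sectors when no simulation snapshot is at hand)."""
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    fields = []
    for _ in range(2):
        f = np.zeros(shape)
        for _ in range(n_blobs):
            cx = rng.uniform(0.2 * nx, 0.8 * nx)
            cy = rng.uniform(0.2 * ny, 0.8 * ny)
            s = rng.uniform(*sigma_range)
            a = rng.uniform(*amplitude_range)
            f += a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s ** 2))
        fields.append(f)
    return fields[0], fields[1]
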
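"""Handcrafted features for candidate patches.

Four feature families describe a candidate region: first-order gray-level
statistics (mean, standard deviation, skewness, kurtosis), a local binary
pattern (LBP) texture histogram, a histogram-of-oriented-gradients (HOG)
shape descriptor, and per-channel color histograms. Mitotic figures tend to
be dark, bluish and irregularly textured, so these families carry most of
the signal that separates them from look-alike nuclei.

Conventions fixed here and used everywhere:

* grayscale = ITU-R 601 luma (0.299 R + 0.587 G + 0.114 B);
* moments are population moments; kurtosis is uncorrected (normal -> 3);
* LBP neighbors are enumerated clockwise starting at the top-left
  neighbor, bit i contributing ``2**i``, with the sign function taking
  value 1 at zero difference;
* HOG uses the canonical 64 x 128 (1:2) geometry, 8 x 8 cells, 9 unsigned
  orientation bins with hard assignment, 2 x 2-cell blocks sliding by one
  cell, each 36-vector L2-normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .errors import InvalidGeometryError

__all__ = [
    "FirstOrderStats",
    "FeatureBundle",
    "rgb_to_gray",
    "first_order_stats",
    "lbp_histogram",
    "hog_descriptor",
    "color_histogram",
    "compute_features",
]

GRAY_WEIGHTS = (0.299, 0.587, 0.114)  # ITU-R 601

# clockwise ring of (dy, dx) offsets starting at the top-left neighbor
_LBP_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)

HOG_SIZE = (128, 64)  # (height, width): the 1:2 canonical geometry
HOG_CELL = 8
HOG_BINS = 9
HOG_BLOCK = 2


@dataclass(frozen=True)
class FirstOrderStats:
    """Population moments of a gray patch.

    ``degenerate`` is set when the patch is constant (zero variance), in
    which case skewness and kurtosis are reported as 0 by convention.
    """

    mean: float
    std: float
    skewness: float
    kurtosis: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.std, self.skewness, self.kurtosis])


@dataclass(frozen=True)
class FeatureBundle:
    """The four feature families computed on one candidate patch."""

    stats: FirstOrderStats
    lbp_hist: np.ndarray  # 256 bins, sums to 1
    hog: np.ndarray  # 3780 values at the default geometry
    color_hist: np.ndarray  # 3 * bins_per_channel, each channel sums to 1

    def family(self, name: str) -> np.ndarray:
        """Feature vector of one family by name (stats/lbp/hog/color)."""
        if name == "stats":
            return self.stats.as_array()
        if name == "lbp":
            return self.lbp_hist
        if name == "hog":
            return self.hog
        if name == "color":
            return self.color_hist
        raise KeyError(name)

    def flattened(self) -> np.ndarray:
        return np.concatenate(
            [self.stats.as_array(), self.lbp_hist, self.hog, self.color_hist]
        )


def rgb_to_gray(patch: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma of an RGB raster (float output, same scale)."""
    patch = np.asarray(patch, dtype=float)
    if patch.ndim == 2:
        return patch
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise InvalidGeometryError(f"expected RGB raster, got shape {patch.shape}")
    r, g, b = GRAY_WEIGHTS
    return patch[..., 0] * r + patch[..., 1] * g + patch[..., 2] * b


def first_order_stats(patch: np.ndarray) -> FirstOrderStats:
    """Mean, population std, skewness and (uncorrected) kurtosis of a gray patch.

    Skewness is the normalized third central moment ``E[(x-mu)^3]/sigma^3``
    and kurtosis the normalized fourth, so a normal distribution has
    kurtosis 3. A constant patch has undefined shape moments; they are
    reported as 0 with the ``degenerate`` flag set.
    """
    x = np.asarray(patch, dtype=float).ravel()
    if x.size == 0:
        raise InvalidGeometryError("empty patch")
    mu = float(x.mean())
    centered = x - mu
    var = float(np.mean(centered**2))
    std = float(np.sqrt(var))
    if std == 0.0:
        return FirstOrderStats(mean=mu, std=0.0, skewness=0.0, kurtosis=0.0, degenerate=True)
    skew = float(np.mean(centered**3)) / std**3
    kurt = float(np.mean(centered**4)) / std**4
    return FirstOrderStats(mean=mu, std=std, skewness=skew, kurtosis=kurt)


def lbp_codes(patch: np.ndarray) -> np.ndarray:
    """8-bit LBP code of every interior pixel (radius 1, 8 neighbors).

    Each neighbor at gray level ``g_i`` contributes bit ``2**i`` when
    ``g_i - g_c >= 0``; bits run clockwise from the top-left neighbor.
    A constant patch therefore codes every pixel as 255.
    """
    g = np.asarray(patch, dtype=float)
    if g.ndim != 2:
        raise InvalidGeometryError("LBP expects a grayscale raster")
    if g.shape[0] < 3 or g.shape[1] < 3:
        raise InvalidGeometryError(f"patch {g.shape} too small for radius-1 LBP")
    center = g[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    h, w = g.shape
    for i, (dy, dx) in enumerate(_LBP_OFFSETS):
        neighbor = g[1 + dy : h - 1 + dy, 1 + dx : w - 1 + dx]
        codes |= (neighbor >= center).astype(np.int64) << i
    return codes


def lbp_histogram(patch: np.ndarray, radius: int = 1, neighbors: int = 8) -> np.ndarray:
    """Normalized 256-bin histogram of LBP codes over interior pixels.

    Only the radius-1, 8-neighbor configuration is implemented; the
    parameters exist to make the configuration explicit at call sites.
    """
    if radius != 1 or neighbors != 8:
        raise NotImplementedError("only radius=1, neighbors=8 LBP is supported")
    codes = lbp_codes(patch)
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    return hist / hist.sum()


def _gradients(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # [-1, 0, 1] kernel interior, one-sided differences at the borders
    gx = np.empty_like(a)
    gx[:, 1:-1] = a[:, 2:] - a[:, :-2]
    gx[:, 0] = a[:, 1] - a[:, 0]
    gx[:, -1] = a[:, -1] - a[:, -2]
    gy = np.empty_like(a)
    gy[1:-1, :] = a[2:, :] - a[:-2, :]
    gy[0, :] = a[1, :] - a[0, :]
    gy[-1, :] = a[-1, :] - a[-2, :]
    return gx, gy


def hog_descriptor(patch: np.ndarray) -> np.ndarray:
    """HOG shape descriptor of a gray patch at the canonical 64 x 128 geometry.

    The patch is resized to 64 x 128 (width x height), per-pixel gradient
    magnitude is voted into 9 unsigned orientation bins (hard assignment,
    0-180 degrees) per 8 x 8 cell, and 2 x 2-cell blocks sliding by one
    cell are each L2-normalized (all-zero blocks left zero) and
    concatenated: (64/8 - 1) * (128/8 - 1) * 36 = 3780 values.
    """
    g = np.asarray(patch, dtype=float)
    if g.size == 0:
        raise InvalidGeometryError("empty patch")
    if g.ndim == 3:
        g = rgb_to_gray(g)
    if g.shape != HOG_SIZE:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = resize(g, HOG_SIZE, order=1, preserve_range=True, anti_aliasing=False)
    gx, gy = _gradients(g)
    mag = np.hypot(gx, gy)
    ang = np.degrees(np.arctan2(gy, gx)) % 180.0
    bins = np.minimum((ang / (180.0 / HOG_BINS)).astype(int), HOG_BINS - 1)

    n_rows, n_cols = HOG_SIZE[0] // HOG_CELL, HOG_SIZE[1] // HOG_CELL
    cell_hist = np.zeros((n_rows, n_cols, HOG_BINS))
    for cr in range(n_rows):
        for cc in range(n_cols):
            sl = np.s_[cr * HOG_CELL : (cr + 1) * HOG_CELL, cc * HOG_CELL : (cc + 1) * HOG_CELL]
            cell_hist[cr, cc] = np.bincount(
                bins[sl].ravel(), weights=mag[sl].ravel(), minlength=HOG_BINS
            )

    blocks = []
    for br in range(n_rows - HOG_BLOCK + 1):
        for bc in range(n_cols - HOG_BLOCK + 1):
            v = cell_hist[br : br + HOG_BLOCK, bc : bc + HOG_BLOCK].ravel()
            norm = np.linalg.norm(v)
            blocks.append(v / norm if norm > 0 else v)
    return np.concatenate(blocks)


def color_histogram(patch: np.ndarray, bins_per_channel: int = 16) -> np.ndarray:
    """Concatenated per-channel color histograms of an 8-bit RGB patch.

    Each channel is binned into ``bins_per_channel`` equal-width bins over
    [0, 255] and normalized to sum 1; the result is R || G || B.
    """
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise InvalidGeometryError(f"expected RGB raster, got shape {patch.shape}")
    hists = []
    for c in range(3):
        h, _ = np.histogram(patch[..., c], bins=bins_per_channel, range=(0, 256))
        hists.append(h.astype(float) / h.sum())
    return np.concatenate(hists)


def compute_features(rgb_patch: np.ndarray, color_bins: int = 16) -> FeatureBundle:
    """All four feature families of one RGB candidate patch."""
    gray = rgb_to_gray(rgb_patch)
    return FeatureBundle(
        stats=first_order_stats(gray),
        lbp_hist=lbp_histogram(gray),
        hog=hog_descriptor(gray),
        color_hist=color_histogram(rgb_patch, bins_per_channel=color_bins),
    )
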
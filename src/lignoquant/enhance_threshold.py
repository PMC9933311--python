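"""Local contrast enhancement and histogram auto-thresholding.

The measurement procedure normalizes uneven illumination ("wavy" sections)
with CLAHE and then binarizes with one of four classic histogram criteria:

* ``huang``    -- Huang & Wang fuzzy-membership entropy (wall mask, spruce)
* ``moments``  -- Tsai moment-preserving threshold (wall mask, beechwood)
* ``li``       -- Li minimum cross-entropy (lumen mask, spruce)
* ``minimum``  -- Prewitt & Mendelsohn iterated-smoothing valley (lumen
  mask, beechwood)

All four operate on a 256-bin :class:`~lignoquant.imagestack_io.IntensityHistogram`
and return an integer grey level.  "dark" in the method names means
dark-background polarity: wall (bright) pixels are those strictly above the
level, lumen (dark) pixels those at or below it.  Criterion minimizers break
ties toward the lower level so results are platform-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.exposure import equalize_adapthist

from .imagestack_io import GreyImage, IntensityHistogram, round_half_up

__all__ = [
    "ClaheParams",
    "ThresholdResult",
    "BimodalityError",
    "clahe",
    "average_projection",
    "threshold_huang",
    "threshold_li",
    "threshold_moments",
    "threshold_minimum",
    "threshold_by_name",
    "apply_threshold",
    "THRESHOLD_METHODS",
]


class BimodalityError(RuntimeError):
    """The 'minimum' method could not reach a two-peak histogram."""


@dataclass
class ClaheParams:
    """CLAHE settings: contextual tile edge (px), histogram bins, clip slope.

    Defaults follow the de-facto conventions of the plugin ecosystem this
    procedure originated in (127 px tiles, 256 bins, max slope 3.0).
    """

    block_size: int = 127
    histogram_bins: int = 256
    max_slope: float = 3.0

    def __post_init__(self) -> None:
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError(f"block_size must be odd and >= 3, got {self.block_size}")
        if not 2 <= self.histogram_bins <= 256:
            raise ValueError(f"histogram_bins must be in [2, 256], got {self.histogram_bins}")
        if not np.isfinite(self.max_slope) or self.max_slope <= 1:
            raise ValueError(f"max_slope must be finite and > 1, got {self.max_slope}")


@dataclass
class ThresholdResult:
    level: int
    method: str
    dark_background: bool = True
    degenerate: bool = False


def clahe(image: GreyImage, params: ClaheParams | None = None) -> GreyImage:
    """Contrast-limited adaptive histogram equalization of an 8-bit frame.

    Tile-wise clipped-histogram equalization with bilinear interpolation
    between tile mappings (scikit-image backend).  The plugin-style
    ``max_slope`` clip limit is mapped onto the backend's normalized limit as
    ``max_slope / histogram_bins`` (both clip the tile histogram at
    ``max_slope`` times the uniform bin occupancy).  A constant image is
    returned unchanged: there is no contrast to amplify.
    """
    params = params or ClaheParams()
    if params.block_size >= min(image.shape):
        raise ValueError(
            f"block_size {params.block_size} must be smaller than the image's "
            f"smaller dimension {min(image.shape)}"
        )
    px = image.pixels
    if px.min() == px.max():
        return GreyImage(px.copy(), image.pixel_size_um)
    out = equalize_adapthist(
        px,
        kernel_size=params.block_size,
        clip_limit=params.max_slope / params.histogram_bins,
        nbins=params.histogram_bins,
    )
    out8 = np.clip(round_half_up(out * 255.0), 0, 255).astype(np.uint8)
    return GreyImage(out8, image.pixel_size_um)


def average_projection(stack) -> GreyImage:
    """Per-pixel arithmetic mean over the stack's frames, rounded half-up."""
    mean = stack.as_array().astype(np.float64).mean(axis=0)
    return GreyImage(
        np.clip(round_half_up(mean), 0, 255).astype(np.uint8), stack.pixel_size_um
    )


# -- threshold criteria ------------------------------------------------------


def _degenerate_or_range(hist: IntensityHistogram, method: str):
    if hist.total <= 0:
        raise ValueError("cannot threshold an empty histogram")
    first, last = hist.occupied_range()
    if first == last:
        return ThresholdResult(first, method, degenerate=True), None
    return None, (first, last)


def threshold_huang(hist: IntensityHistogram) -> ThresholdResult:
    """Huang-Wang threshold: minimize total fuzzy-membership entropy.

    For a candidate level t, pixels are given a membership to their class
    (mean of the dark side for g <= t, mean of the bright side above) of
    u = 1 / (1 + |g - mu_class| / C) with C the occupied grey range, and the
    Shannon entropy of u, summed over the histogram, is minimized.  All
    candidates in [first, last) are evaluated; ties go to the lower level.
    """
    deg, rng = _degenerate_or_range(hist, "huang")
    if deg:
        return deg
    first, last = rng
    g = np.arange(256, dtype=np.float64)
    c = hist.counts.astype(np.float64)
    w = np.cumsum(c)
    s = np.cumsum(g * c)
    ts = np.arange(first, last)
    mu0 = s[ts] / w[ts]
    mu1 = (s[-1] - s[ts]) / (w[-1] - w[ts])
    span = float(last - first)
    low = g[None, :] <= ts[:, None]
    mu = np.where(low, mu0[:, None], mu1[:, None])
    u = 1.0 / (1.0 + np.abs(g[None, :] - mu) / span)
    # u is in (0, 1]; both entropy terms vanish at their endpoints
    ent = np.zeros_like(u)
    inner = (u > 0) & (u < 1)
    ui = u[inner]
    ent[inner] = -(ui * np.log(ui) + (1.0 - ui) * np.log(1.0 - ui))
    score = (ent * c[None, :]).sum(axis=1)
    return ThresholdResult(int(ts[int(np.argmin(score))]), "huang")


def li_cross_entropy(hist: IntensityHistogram, level: int) -> float:
    """Li's cross-entropy objective for a split at ``level`` (lower class
    g <= level).  Grey levels are shifted by +1 internally so histograms
    with mass at 0 are well defined.  Smaller is better."""
    c = hist.counts.astype(np.float64)
    x = np.arange(256, dtype=np.float64) + 1.0
    a = c * x
    lo = slice(0, level + 1)
    hi = slice(level + 1, 256)
    n_lo, n_hi = c[lo].sum(), c[hi].sum()
    if n_lo == 0 or n_hi == 0:
        return np.inf
    m1 = a[lo].sum() / n_lo
    m2 = a[hi].sum() / n_hi
    return -(a[lo].sum() * np.log(m1) + a[hi].sum() * np.log(m2))


def threshold_li(hist: IntensityHistogram) -> ThresholdResult:
    """Minimum-cross-entropy (Li) threshold.

    Returns the exact integer minimizer of :func:`li_cross_entropy` over the
    occupied range (cumulative-sum evaluation of all 255 candidate splits).
    The classic Li-Tam fixed-point iteration converges to this minimizer on
    well-behaved histograms; evaluating the criterion exhaustively costs the
    same O(256) work and is reproducible across platforms by construction.
    """
    deg, rng = _degenerate_or_range(hist, "li")
    if deg:
        return deg
    first, last = rng
    c = hist.counts.astype(np.float64)
    x = np.arange(256, dtype=np.float64) + 1.0
    a = c * x
    cum_c = np.cumsum(c)
    cum_a = np.cumsum(a)
    ts = np.arange(first, last)
    m1 = cum_a[ts] / cum_c[ts]
    m2 = (cum_a[-1] - cum_a[ts]) / (cum_c[-1] - cum_c[ts])
    eta = -(cum_a[ts] * np.log(m1) + (cum_a[-1] - cum_a[ts]) * np.log(m2))
    return ThresholdResult(int(ts[int(np.argmin(eta))]), "li")


def threshold_moments(hist: IntensityHistogram) -> ThresholdResult:
    """Tsai moment-preserving threshold.

    Chooses the binarization whose two representative levels preserve the
    first three grey-level moments of the histogram, then returns the
    smallest level at which the cumulative fraction reaches the
    moment-preserving dark fraction p0.
    """
    deg, rng = _degenerate_or_range(hist, "moments")
    if deg:
        return deg
    g = np.arange(256, dtype=np.float64)
    p = hist.counts.astype(np.float64) / hist.total
    m1 = float((g * p).sum())
    m2 = float((g**2 * p).sum())
    m3 = float((g**3 * p).sum())
    cd = m2 - m1 * m1
    # cd > 0 whenever two distinct levels are occupied
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)
    cumulative = np.cumsum(p)
    level = int(np.searchsorted(cumulative, p0, side="left"))
    return ThresholdResult(min(level, 255), "moments")


def smooth_histogram(values: np.ndarray) -> np.ndarray:
    """One pass of the 3-bin mean filter used by the 'minimum' method.

    Interior bins take the mean of their 3-neighbourhood; the out-of-range
    third at each edge stays in the edge bin (new h0 = (2 h0 + h1)/3 and
    symmetrically), so total mass is conserved exactly at every iteration.
    """
    h = np.asarray(values, dtype=np.float64)
    out = np.empty_like(h)
    out[1:-1] = (h[:-2] + h[1:-1] + h[2:]) / 3.0
    out[0] = (2.0 * h[0] + h[1]) / 3.0
    out[-1] = (h[-2] + 2.0 * h[-1]) / 3.0
    return out


def _count_peaks(h: np.ndarray) -> list[tuple[int, int]]:
    """Local maxima of ``h`` as (start, end) index runs, plateau-aware."""
    # collapse equal-value runs, then compare each run to its neighbours
    runs: list[tuple[int, int, float]] = []
    i = 0
    n = len(h)
    while i < n:
        j = i
        while j + 1 < n and h[j + 1] == h[i]:
            j += 1
        runs.append((i, j, h[i]))
        i = j + 1
    peaks = []
    for k, (a, b, v) in enumerate(runs):
        left = runs[k - 1][2] if k > 0 else -np.inf
        right = runs[k + 1][2] if k + 1 < len(runs) else -np.inf
        if v > left and v > right:
            peaks.append((a, b))
    return peaks


def threshold_minimum(hist: IntensityHistogram, max_iter: int = 10000) -> ThresholdResult:
    """Valley threshold: smooth the histogram with a 3-bin mean filter until
    exactly two local maxima remain, then return the minimum between them
    (lowest level on ties).

    Raises :class:`BimodalityError` if the histogram is (or becomes)
    unimodal, or if two peaks are not reached within ``max_iter`` smoothing
    passes.
    """
    deg, _ = _degenerate_or_range(hist, "minimum")
    if deg:
        return deg
    h = hist.counts.astype(np.float64)
    for it in range(max_iter + 1):
        peaks = _count_peaks(h)
        if len(peaks) == 2:
            lo = peaks[0][1] + 1
            hi = peaks[1][0]
            valley = h[lo:hi]
            if valley.size == 0:  # adjacent plateaus cannot happen, but guard
                level = peaks[0][1]
            else:
                level = lo + int(np.argmin(valley))
            return ThresholdResult(int(level), "minimum")
        if len(peaks) < 2:
            raise BimodalityError(
                f"histogram is unimodal after {it} smoothing iterations; "
                "the 'minimum' method needs a bimodal histogram"
            )
        h = smooth_histogram(h)
    raise BimodalityError(
        f"histogram did not become bimodal within max_iter={max_iter} smoothing iterations"
    )


THRESHOLD_METHODS = {
    "huang": threshold_huang,
    "li": threshold_li,
    "moments": threshold_moments,
    "minimum": threshold_minimum,
}


def threshold_by_name(hist: IntensityHistogram, method: str) -> ThresholdResult:
    try:
        fn = THRESHOLD_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown threshold method {method!r}; choose from {sorted(THRESHOLD_METHODS)}"
        ) from None
    return fn(hist)


def apply_threshold(
    image: GreyImage,
    result: ThresholdResult,
    select: Literal["above", "at_or_below"],
) -> np.ndarray:
    """Binarize: ``above`` keeps pixels > level (bright walls on a dark
    background), ``at_or_below`` keeps pixels <= level (dark lumens).  The
    two polarities partition the image exactly."""
    if not 0 <= result.level <= 255:
        raise ValueError(f"threshold level {result.level} outside [0, 255]")
    if select == "above":
        return image.pixels > result.level
    if select == "at_or_below":
        return image.pixels <= result.level
    raise ValueError(f"select must be 'above' or 'at_or_below', got {select!r}")
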
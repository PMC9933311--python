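"""Cell-wall mask construction and mean wall fluorescence along the stack.

The wall selection is built once per stack — CLAHE on every frame, average
intensity projection, histogram auto-threshold ("dark" polarity, pixels
above the level are wall) — and then applied to every frame of the
*unmodified* stack, so contrast enhancement shapes the mask but never the
measured intensities.  The result is one mean grey value per exposure time:
the fluorescence curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enhance_threshold import (
    ClaheParams,
    apply_threshold,
    average_projection,
    clahe,
    threshold_by_name,
)
from .imagestack_io import ExposureStack, compute_histogram

__all__ = [
    "FluorescenceCurve",
    "enhanced_projection",
    "wall_mask",
    "measure_wall_intensity",
    "intensity_at",
]

# a frame counts as saturated when this fraction of wall pixels sits at 255
SATURATION_FRACTION = 0.01


@dataclass
class FluorescenceCurve:
    """Mean wall grey per exposure, with the mask bookkeeping needed to
    interpret it (pixel count, wall area fraction, per-frame saturation)."""

    exposure_ms: list[float]
    mean_grey: list[float]
    n_pixels: int
    wall_fraction: float
    saturated: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.exposure_ms) != len(self.mean_grey):
            raise ValueError("exposure_ms and mean_grey must have equal length")
        if not self.saturated:
            self.saturated = [False] * len(self.exposure_ms)

    def to_frame(self) -> pd.DataFrame:
        """CSV twin of the 'Table of results for fluorescence intensity';
        means are reported to two decimals."""
        return pd.DataFrame(
            {
                "exposure_ms": self.exposure_ms,
                "mean_grey": [round(v, 2) for v in self.mean_grey],
                "n_pixels": self.n_pixels,
                "wall_fraction": self.wall_fraction,
                "saturated_flag": self.saturated,
            }
        )


def enhanced_projection(
    stack: ExposureStack,
    clahe_params: ClaheParams | None = None,
    enhance: str = "per_frame",
):
    """The enhanced grey-level average image both thresholds operate on.

    ``enhance='per_frame'`` (default) equalizes every frame before
    projecting — each dim frame is stretched to the full 8-bit range first,
    so averaging the series preserves sub-level precision even for weakly
    fluorescent (severely pretreated) sections.  ``'projection'`` projects
    the raw frames first and equalizes once (config-switchable; the two
    differ only in noise/quantization behaviour).
    """
    params = clahe_params or ClaheParams()
    if enhance == "per_frame":
        enhanced = ExposureStack([clahe(f, params) for f in stack.frames], stack.exposure_ms)
        return average_projection(enhanced)
    if enhance == "projection":
        return clahe(average_projection(stack), params)
    raise ValueError(f"enhance must be 'per_frame' or 'projection', got {enhance!r}")


def wall_mask(
    stack: ExposureStack,
    method: str = "huang",
    clahe_params: ClaheParams | None = None,
    enhance: str = "per_frame",
):
    """Detect cell walls: CLAHE -> average projection -> auto-threshold.

    Returns ``(mask, ThresholdResult)``; a degenerate (single-level)
    histogram is flagged on the result rather than raised so batch runs
    survive blank fields of view.
    """
    projection = enhanced_projection(stack, clahe_params, enhance)
    result = threshold_by_name(compute_histogram(projection), method)
    return apply_threshold(projection, result, "above"), result


def measure_wall_intensity(stack: ExposureStack, mask: np.ndarray) -> FluorescenceCurve:
    """Mean grey over the mask on each *original* frame, ordered by exposure."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape:
        raise ValueError(f"mask shape {mask.shape} != frame shape {stack.shape}")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("wall mask is empty")
    means, saturated = [], []
    for frame in stack.frames:
        vals = frame.pixels[mask]
        means.append(float(vals.mean()))
        saturated.append(bool((vals == 255).mean() >= SATURATION_FRACTION))
    return FluorescenceCurve(
        exposure_ms=list(stack.exposure_ms),
        mean_grey=means,
        n_pixels=n,
        wall_fraction=n / mask.size,
        saturated=saturated,
    )


def intensity_at(curve: FluorescenceCurve, exposure_ms: float) -> float:
    """Mean wall grey at an exposure present in the curve (no interpolation)."""
    for e, v in zip(curve.exposure_ms, curve.mean_grey):
        if e == float(exposure_ms):
            return v
    raise KeyError(
        f"no measurement at {exposure_ms} ms; available exposures: {curve.exposure_ms}"
    )
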
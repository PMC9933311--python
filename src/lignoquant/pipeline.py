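"""Orchestration: species presets, the two measurement branches, condition
summaries and the summary statistics of the study design.

``run_section`` executes the full procedure on one exposure stack:

* wall branch — CLAHE each frame, average-project, auto-threshold
  (``huang`` for spruce, ``moments`` for beechwood, dark polarity), then
  measure mean wall grey per exposure on the unmodified stack;
* lumen branch — CLAHE the frame at the reference exposure (2000 ms by
  default; configurable to the projection instead), threshold the lowest
  intensities (``li`` for spruce, ``minimum`` for beechwood), and measure
  every surviving particle's area/perimeter/circularity with the species
  size bound (20 px spruce, 500 px beechwood).

All analysis is deterministic; randomness lives only in the synthetic
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import __version__
from .enhance_threshold import ClaheParams, apply_threshold, clahe, threshold_by_name
from .fluorometry import (
    FluorescenceCurve,
    enhanced_projection,
    intensity_at,
    measure_wall_intensity,
)
from .imagestack_io import ExposureStack, compute_histogram
from .morphometry import ParticleFilter, ParticleRecord, majority_smooth, measure_lumens

__all__ = [
    "SpeciesProfile",
    "SPECIES_PROFILES",
    "SectionResult",
    "ConditionSummary",
    "run_section",
    "summarize_condition",
    "pearson_r",
    "holm_sidak_adjust",
]


@dataclass
class SpeciesProfile:
    """Named bundle of threshold methods and the particle size bound."""

    name: str
    wall_threshold: str
    lumen_threshold: str
    min_area_px: int
    clahe: ClaheParams = field(default_factory=ClaheParams)
    exclude_edge_particles: bool = True
    fill_holes: bool = True
    smooth_mask: bool = True  # 3x3 majority vote on the lumen mask

    def particle_filter(self) -> ParticleFilter:
        return ParticleFilter(self.min_area_px, self.exclude_edge_particles)


SPECIES_PROFILES = {
    "spruce": SpeciesProfile("spruce", "huang", "li", 20),
    "beechwood": SpeciesProfile("beechwood", "moments", "minimum", 500),
}


@dataclass
class SectionResult:
    particles: list[ParticleRecord]
    curve: FluorescenceCurve | None
    manifest: dict
    status: dict


@dataclass
class ConditionSummary:
    """Pooled mean +/- SD per morphological parameter and per-section wall
    grey at the reference exposure (SD across sections; None when only one
    section was analysed)."""

    label: str
    n_sections: int
    n_particles: int
    perimeter_um_mean: float
    perimeter_um_sd: float
    area_um2_mean: float
    area_um2_sd: float
    circularity_mean: float
    circularity_sd: float
    wall_grey_mean: float
    wall_grey_sd: float | None
    reference_exposure_ms: float

    def to_dict(self) -> dict:
        return asdict(self)


def run_section(
    stack: ExposureStack,
    profile: SpeciesProfile,
    reference_exposure_ms: float = 2000.0,
    lumen_source: str = "projection",
    wall_enhance: str = "per_frame",
) -> SectionResult:
    """Run both measurement branches on one stack.

    Both thresholds operate on one enhanced grey-level average image (CLAHE
    on each frame, then the average intensity projection): the wall mask
    keeps pixels above its level, the lumen mask pixels at or below its
    level.  ``lumen_source='reference_frame'`` switches the lumen branch to
    the CLAHE frame at ``reference_exposure_ms`` instead.  A branch that
    fails (e.g. a degenerate histogram on a blank field of view) is
    reported in ``status`` while the other branch's results are kept.
    """
    status: dict = {"wall": "ok", "lumen": "ok"}
    manifest = {
        "package": "lignoquant",
        "version": __version__,
        "profile": {
            "name": profile.name,
            "wall_threshold": profile.wall_threshold,
            "lumen_threshold": profile.lumen_threshold,
            "min_area_px": profile.min_area_px,
            "clahe": asdict(profile.clahe),
            "exclude_edge_particles": profile.exclude_edge_particles,
            "fill_holes": profile.fill_holes,
            "smooth_mask": profile.smooth_mask,
        },
        "reference_exposure_ms": reference_exposure_ms,
        "lumen_source": lumen_source,
        "wall_enhance": wall_enhance,
        "n_frames": len(stack),
        "exposure_ms": list(stack.exposure_ms),
        "pixel_size_um": stack.pixel_size_um,
        "image_size": [stack.shape[1], stack.shape[0]],
    }

    projection = None
    curve = None
    try:
        projection = enhanced_projection(stack, profile.clahe, wall_enhance)
        wall_thr = threshold_by_name(compute_histogram(projection), profile.wall_threshold)
        manifest["wall_threshold_level"] = wall_thr.level
        manifest["wall_threshold_degenerate"] = wall_thr.degenerate
        mask = apply_threshold(projection, wall_thr, "above")
        curve = measure_wall_intensity(stack, mask)
    except Exception as exc:
        status["wall"] = f"failed: {exc}"

    particles: list[ParticleRecord] = []
    try:
        if lumen_source == "reference_frame":
            enhanced = clahe(stack.frame_at(reference_exposure_ms), profile.clahe)
        elif lumen_source == "projection":
            enhanced = (
                projection
                if projection is not None
                else enhanced_projection(stack, profile.clahe, wall_enhance)
            )
        else:
            raise ValueError(
                f"lumen_source must be 'reference_frame' or 'projection', got {lumen_source!r}"
            )
        lumen_thr = threshold_by_name(compute_histogram(enhanced), profile.lumen_threshold)
        manifest["lumen_threshold_level"] = lumen_thr.level
        manifest["lumen_threshold_degenerate"] = lumen_thr.degenerate
        lumen_mask = apply_threshold(enhanced, lumen_thr, "at_or_below")
        if profile.smooth_mask:
            lumen_mask = majority_smooth(lumen_mask)
        particles = measure_lumens(
            lumen_mask,
            profile.particle_filter(),
            stack.pixel_size_um,
            fill_holes=profile.fill_holes,
        )
    except Exception as exc:
        status["lumen"] = f"failed: {exc}"

    return SectionResult(particles=particles, curve=curve, manifest=manifest, status=status)


def summarize_condition(
    records_by_section: list[list[ParticleRecord]],
    curves: list[FluorescenceCurve],
    reference_exposure_ms: float = 2000.0,
    label: str = "",
) -> ConditionSummary:
    """Pool particles across sections for morphology (single mean +/- SD per
    parameter over all lumens) and average the per-section wall grey at the
    reference exposure across sections."""
    if len(records_by_section) < 1:
        raise ValueError("need at least one section")
    pooled = [p for sec in records_by_section for p in sec]
    if not pooled:
        raise ValueError("no particles to summarize")

    def mean_sd(vals):
        arr = np.asarray(vals, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    per_m, per_s = mean_sd([p.perimeter_um for p in pooled])
    area_m, area_s = mean_sd([p.area_um2 for p in pooled])
    circ_m, circ_s = mean_sd([p.circularity for p in pooled])

    section_greys = [intensity_at(c, reference_exposure_ms) for c in curves]
    if not section_greys:
        raise ValueError("need at least one fluorescence curve")
    grey_mean = float(np.mean(section_greys))
    grey_sd = float(np.std(section_greys, ddof=1)) if len(section_greys) > 1 else None

    return ConditionSummary(
        label=label,
        n_sections=len(records_by_section),
        n_particles=len(pooled),
        perimeter_um_mean=per_m,
        perimeter_um_sd=per_s,
        area_um2_mean=area_m,
        area_um2_sd=area_s,
        circularity_mean=circ_m,
        circularity_sd=circ_s,
        wall_grey_mean=grey_mean,
        wall_grey_sd=grey_sd,
        reference_exposure_ms=reference_exposure_ms,
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation between two equal-length samples (n >= 3,
    both with non-zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in x or y")
    return float(stats.pearsonr(x, y).statistic)


def holm_sidak_adjust(p_values) -> list[float]:
    """Step-down Sidak adjustment of a family of p-values.

    Sort ascending; the i-th smallest (i = 1..k) becomes
    1 - (1 - p_(i))^(k - i + 1); enforce monotone non-decreasing along the
    sorted order, cap at 1, and return in the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (k - np.arange(k))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(k)
    out[order] = adj_sorted
    return [float(v) for v in out]
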
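"""Particle (cell-lumen) labelling and calibrated morphometry.

A binarized lumen mask is decomposed into 8-connected particles, interior
holes are filled (noise speckles inside a lumen must not punch holes in it),
particles below the species size bound or touching the image border are
dropped, and each survivor is measured: area (pixel count x calibration^2),
perimeter (corner-corrected crack-boundary length, below), and circularity
4*pi*A/P^2 clamped to 1.

Perimeter convention
--------------------
The raw crack boundary (the polyline between foreground and background pixel
edges) of a digitized shape is exact for axis-aligned rectangles but
overestimates smooth contours by up to 4/pi.  We therefore subtract a fixed
penalty c per 90-degree direction change of the crack boundary,

    P = L_crack - c * n_corners,     c = (1 - (pi/4 - sqrt2/2)/(1 - sqrt2/2)) / 2

where c ~ 0.36635 is the unique value that makes the estimator unbiased for
smooth boundaries under a uniform distribution of orientations.  A 20 x 20 px
square measures 78.53 (true 80, -1.8%); digitized disks of radius >= 10 px
measure within ~1% of 2*pi*r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ParticleRecord",
    "ParticleFilter",
    "CORNER_PENALTY",
    "majority_smooth",
    "label_particles",
    "crack_perimeter",
    "measure_particle",
    "filter_particles",
    "measure_lumens",
    "records_to_frame",
]

# unbiased-for-isotropic-smooth-boundaries corner penalty (see module docstring)
CORNER_PENALTY = (1.0 - (np.pi / 4.0 - np.sqrt(2.0) / 2.0) / (1.0 - np.sqrt(2.0) / 2.0)) / 2.0

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class ParticleRecord:
    """One lumen: label, raw and calibrated geometry, shape descriptor."""

    label: int
    area_px: int
    area_um2: float
    perimeter_um: float
    circularity: float
    centroid: tuple[float, float]  # (x, y) pixel coordinates
    touches_edge: bool


@dataclass
class ParticleFilter:
    """Species size bound (px) and border-exclusion flag."""

    min_area_px: int = 1
    exclude_edge_particles: bool = True

    def __post_init__(self) -> None:
        if self.min_area_px < 1:
            raise ValueError(f"min_area_px must be >= 1, got {self.min_area_px}")


def majority_smooth(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """3x3 majority vote (binary median) over the mask.

    Sensor noise at the segmentation boundary shows up as single-pixel
    raggedness that inflates any perimeter estimate while leaving area
    almost unchanged; a majority vote regularizes the boundary with
    sub-0.2 px systematic bias for particles of >= 20 px diameter.
    """
    m = np.asarray(mask, dtype=bool)
    for _ in range(iterations):
        m = ndimage.uniform_filter(m.astype(np.float32), 3) > 0.5
    return m


def label_particles(mask: np.ndarray, fill_holes: bool = True) -> tuple[np.ndarray, int]:
    """8-connected components of the foreground, labelled 1..n in raster-scan
    order of each component's first pixel.  With ``fill_holes`` (default),
    background enclosed by foreground is filled before labelling."""
    mask = np.asarray(mask, dtype=bool)
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    return labels, int(n)


def crack_perimeter(region: np.ndarray) -> float:
    """Corner-corrected crack-boundary perimeter of a binary region, px units.

    Counts exposed pixel edges (4-adjacency, zero-padded) and the 90-degree
    corners of the crack polyline via 2x2 pixel configurations: one corner
    for a lone foreground / lone background quarter, two for a diagonal
    (checkerboard) configuration.
    """
    a = np.pad(np.asarray(region, dtype=bool), 1).astype(np.int8)
    edges = int(np.abs(np.diff(a, axis=0)).sum() + np.abs(np.diff(a, axis=1)).sum())
    q = a[:-1, :-1] + a[:-1, 1:] + a[1:, :-1] + a[1:, 1:]
    n_corners = int((q == 1).sum() + (q == 3).sum())
    diag = (q == 2) & (a[:-1, :-1] == a[1:, 1:]) & (a[:-1, 1:] == a[1:, :-1])
    n_corners += 2 * int(diag.sum())
    return float(edges - CORNER_PENALTY * n_corners)


def measure_particle(
    region: np.ndarray,
    pixel_size_um: float,
    label: int = 1,
    origin: tuple[int, int] = (0, 0),
    touches_edge: bool = False,
) -> ParticleRecord:
    """Measure one connected region given as a (local) boolean array.

    ``origin`` is the (row, col) offset of the local array inside the full
    image, so centroids come out in image coordinates.
    """
    region = np.asarray(region, dtype=bool)
    area_px = int(region.sum())
    if area_px == 0:
        raise ValueError("cannot measure an empty region")
    rows, cols = np.nonzero(region)
    cy = float(rows.mean()) + origin[0]
    cx = float(cols.mean()) + origin[1]
    perim_px = crack_perimeter(region)
    area_um2 = area_px * pixel_size_um**2
    perimeter_um = perim_px * pixel_size_um
    circ = 4.0 * np.pi * area_px / perim_px**2 if perim_px > 0 else 1.0
    return ParticleRecord(
        label=int(label),
        area_px=area_px,
        area_um2=float(area_um2),
        perimeter_um=float(perimeter_um),
        circularity=float(min(circ, 1.0)),
        centroid=(cx, cy),
        touches_edge=bool(touches_edge),
    )


def filter_particles(
    particles: list[ParticleRecord], filt: ParticleFilter
) -> list[ParticleRecord]:
    """Drop particles below the size bound and, optionally, border-touching
    ones.  Idempotent."""
    out = [p for p in particles if p.area_px >= filt.min_area_px]
    if filt.exclude_edge_particles:
        out = [p for p in out if not p.touches_edge]
    return out


def measure_lumens(
    mask: np.ndarray,
    filt: ParticleFilter,
    pixel_size_um: float,
    fill_holes: bool = True,
) -> list[ParticleRecord]:
    """Label -> measure -> filter; records sorted by label, deterministic."""
    labels, n = label_particles(mask, fill_holes=fill_holes)
    h, w = labels.shape
    records = []
    for lab, sl in enumerate(ndimage.find_objects(labels, n), start=1):
        if sl is None:
            continue
        region = labels[sl] == lab
        touches = (
            sl[0].start == 0 or sl[1].start == 0 or sl[0].stop == h or sl[1].stop == w
        )
        records.append(
            measure_particle(
                region,
                pixel_size_um,
                label=lab,
                origin=(sl[0].start, sl[1].start),
                touches_edge=touches,
            )
        )
    return filter_particles(records, filt)


def records_to_frame(records: list[ParticleRecord]) -> pd.DataFrame:
    """Per-particle results table (the machine twin of the tool's
    'Table of results for morphological parameters')."""
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "area_px": r.area_px,
                "area_um2": r.area_um2,
                "perimeter_um": r.perimeter_um,
                "circularity": r.circularity,
                "centroid_x": r.centroid[0],
                "centroid_y": r.centroid[1],
                "touches_edge": r.touches_edge,
            }
            for r in records
        ],
        columns=[
            "label",
            "area_px",
            "area_um2",
            "perimeter_um",
            "circularity",
            "centroid_x",
            "centroid_y",
            "touches_edge",
        ],
    )
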
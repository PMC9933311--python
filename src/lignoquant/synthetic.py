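"""Synthetic wood-section generator with per-lumen ground truth.

Emulates transverse sections of softwood and hardwood under UV
autofluorescence: bright lignified cell walls on dark lumens, a
quasi-periodic tracheid honeycomb (``spruce`` mode) or large vessels among
small fibre lumens (``beechwood`` mode), severity-dependent shrinkage and
deformation, a smooth multiplicative illumination field (the "wavy section"
artefact), wall fluorescence growing linearly with exposure up to 8-bit
clipping, and additive sensor noise.  Every lumen's true geometry (area from
8x supersampled rasterization, perimeter as polygon arc length) and the
stack's true wall intensity per exposure are emitted alongside the images,
so each pipeline stage can be validated without any real micrograph.

Ground truth is defined on the pre-noise, pre-illumination geometry: the
measurement error of the analysis pipeline is then attributable and bounded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from matplotlib.path import Path as MplPath
from scipy import ndimage
from scipy.spatial import cKDTree

from .imagestack_io import ExposureStack, GreyImage, round_half_up

__all__ = [
    "SectionSpec",
    "GroundTruthTable",
    "SectionGenerationError",
    "CalibrationError",
    "build_layout",
    "generate_section",
    "calibrate_to_target",
    "raster_area_px",
    "effective_wall_gain",
]


class SectionGenerationError(RuntimeError):
    """Requested section cannot be laid out (too many cells for the frame)."""


class CalibrationError(RuntimeError):
    """Target morphology/fluorescence outside the generator's feasible range."""


DEFAULT_EXPOSURES = tuple(float(e) for e in range(100, 3001, 100))

# Species shape defaults.  'shape_knob' in [0, 1] moves each species from its
# pristine geometry (rounded rectangular tracheids / near-circular vessels)
# toward collapsed low-circularity lumens; it is the single axis the
# calibrator searches.  Severity acts on top of it.
SPRUCE_SHAPE = {
    "width_um": 18.0,          # tracheid lumen width before scaling
    "shape_knob": 0.30,
    "size_cv": 0.25,           # lognormal CV of lumen area
    "aspect_jitter": 0.08,
    "rotation_jitter_deg": 3.0,
    "center_jitter": 0.04,     # fraction of the lattice pitch
    "size_scale": 1.0,
    "min_wall_px": 2.5,
}
BEECH_SHAPE = {
    "equiv_diameter_um": 41.0,  # vessel lumen equivalent diameter before scaling
    "shape_knob": 0.40,
    "size_cv": 0.25,
    "aspect_jitter": 0.06,
    "center_jitter": 0.02,
    "size_scale": 1.0,
    "min_wall_px": 2.5,
    "fibers_per_vessel": 3.0,   # small sub-threshold fibre lumens between vessels
    "fiber_radius_px": (3.5, 7.5),
}


@dataclass
class SectionSpec:
    """Full recipe for one synthetic section; bit-reproducible from ``seed``."""

    species_mode: str
    image_size: tuple[int, int] = (1024, 1024)  # (width, height) px
    pixel_size_um: float = 0.8
    n_cells: int = 400
    severity: float = 0.0
    wall_gain: float = 0.0125            # grey levels per ms of exposure
    noise_sd: float = 3.0
    illumination_amplitude: float = 0.2
    seed: int = 0
    exposure_ms: tuple = DEFAULT_EXPOSURES
    lumen_floor: float = 2.0             # residual grey inside lumens
    edge_blur_px: float = 0.7
    lumen_shape_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species_mode not in ("spruce", "beechwood"):
            raise ValueError(
                f"species_mode must be 'spruce' or 'beechwood', got {self.species_mode!r}"
            )
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must lie in [0, 1], got {self.severity}")
        if self.wall_gain <= 0:
            raise ValueError("wall_gain must be > 0")
        base = dict(SPRUCE_SHAPE if self.species_mode == "spruce" else BEECH_SHAPE)
        base.update(self.lumen_shape_params)
        for k, v in base.items():
            if k in ("shape_knob", "center_jitter"):
                continue
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"shape parameter {k} must be positive, got {v}")
        self.lumen_shape_params = base
        self.image_size = (int(self.image_size[0]), int(self.image_size[1]))
        self.exposure_ms = tuple(float(e) for e in self.exposure_ms)

    # -- serialization (exact re-generation from a config file) --
    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        d["exposure_ms"] = list(self.exposure_ms)
        p = dict(d["lumen_shape_params"])
        if "fiber_radius_px" in p:
            p["fiber_radius_px"] = list(p["fiber_radius_px"])
        d["lumen_shape_params"] = p
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SectionSpec":
        d = dict(d)
        p = dict(d.get("lumen_shape_params", {}))
        if "fiber_radius_px" in p:
            p["fiber_radius_px"] = tuple(p["fiber_radius_px"])
        d["lumen_shape_params"] = p
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SectionSpec":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass
class GroundTruthTable:
    """True per-lumen geometry and true wall intensity of one section."""

    lumens: pd.DataFrame        # id, kind, true_area_um2, true_perimeter_um, ...
    wall_curve: pd.DataFrame    # exposure_ms, true_mean_grey
    wall_mask: np.ndarray       # bool, wall-material coverage >= 0.5 at 1x

    def cells_of_interest(self) -> pd.DataFrame:
        """Tracheids/vessels (excludes beechwood fibre lumens)."""
        return self.lumens[self.lumens.kind != "fiber"]

    def true_wall_grey_at(self, exposure_ms: float) -> float:
        row = self.wall_curve[self.wall_curve.exposure_ms == float(exposure_ms)]
        if row.empty:
            raise KeyError(f"no exposure {exposure_ms} in ground truth")
        return float(row.true_mean_grey.iloc[0])


# -- polygon helpers ---------------------------------------------------------


def _polyline_length(coords: np.ndarray) -> float:
    d = np.diff(np.vstack([coords, coords[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _shoelace_area(coords: np.ndarray) -> float:
    x, y = coords[:, 0], coords[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _resample(coords: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed polygon to ~uniform vertex spacing along its arc."""
    closed = np.vstack([coords, coords[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / spacing)), 16)
    t = np.linspace(0.0, total, n, endpoint=False)
    return np.column_stack([np.interp(t, s, closed[:, 0]), np.interp(t, s, closed[:, 1])])


def _rounded_rect(w: float, h: float, r: float) -> np.ndarray:
    """Axis-aligned w x h rectangle with corner radius r, centred at origin."""
    r = min(r, 0.49 * min(w, h))
    cx, cy = w / 2.0 - r, h / 2.0 - r
    arcs = []
    for qx, qy, a0 in ((cx, cy, 0.0), (-cx, cy, 90.0), (-cx, -cy, 180.0), (cx, -cy, 270.0)):
        ang = np.deg2rad(np.linspace(a0, a0 + 90.0, 12))
        arcs.append(np.column_stack([qx + r * np.cos(ang), qy + r * np.sin(ang)]))
    return np.vstack(arcs)


def _ellipse(a: float, b: float) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * np.pi, 72, endpoint=False)
    return np.column_stack([a * np.cos(ang), b * np.sin(ang)])


def _perturb_radial(coords: np.ndarray, harmonics) -> np.ndarray:
    """r(theta) *= 1 + sum_k a_k cos(k theta + phi_k) about the centroid."""
    c = coords.mean(axis=0)
    rel = coords - c
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    factor = np.ones(len(coords))
    for k, amp, phase in harmonics:
        factor += amp * np.cos(k * theta + phase)
    return c + rel * np.maximum(factor, 0.05)[:, None]


def _rotate(coords: np.ndarray, deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    return coords @ rot.T


def raster_area_px(coords: np.ndarray, factor: int = 8) -> float:
    """Polygon area (1x px^2) by supersampled pixel-centre counting.

    Sub-pixel centres at (i + (j + 0.5)/factor) on the 1x grid are tested
    for containment — the convention of the ground-truth tables.
    """
    x0, y0 = np.floor(coords.min(axis=0)).astype(int) - 1
    x1, y1 = np.ceil(coords.max(axis=0)).astype(int) + 1
    xs = x0 + (np.arange((x1 - x0) * factor) + 0.5) / factor
    ys = y0 + (np.arange((y1 - y0) * factor) + 0.5) / factor
    xx, yy = np.meshgrid(xs, ys)
    inside = MplPath(coords).contains_points(np.column_stack([xx.ravel(), yy.ravel()]))
    return float(inside.sum()) / factor**2


# -- knob mappings and lattices ----------------------------------------------


def _spruce_knob(u: float) -> dict:
    return {
        "aspect": 1.25 + 0.50 * u,
        "corner_frac": 0.30 * (1.0 - u),
        "amp": 0.02 + 0.25 * u,
        "k_choices": (3, 4),
    }


def _beech_knob(u: float) -> dict:
    # circularity loss is carried mostly by multi-lobed boundary harmonics
    # (collapsed-vessel look) rather than elongation: for a given circularity
    # this costs the least radial excursion, i.e. packs densest.
    return {
        "aspect": 1.08 + 0.12 * u,
        "amp": 0.03 + 0.40 * u,
        "k_choices": (4, 5),
    }


def _spruce_sites(spec: SectionSpec, aspect: float):
    """Rectangular lattice of cell centres with per-cell half-extent limits."""
    w_img, h_img = spec.image_size
    p = spec.lumen_shape_params
    n = spec.n_cells
    pitch = np.sqrt(w_img * h_img / (n * aspect))
    nx = max(int(round(w_img / pitch)), 1)
    ny = max(int(round(h_img / (pitch * aspect))), 1)
    while nx * ny < n:
        if w_img / (nx + 1) >= 6.0:
            nx += 1
        elif h_img / (ny + 1) >= 6.0:
            ny += 1
        else:
            raise SectionGenerationError(
                f"cannot place {n} tracheids in a {w_img}x{h_img} px frame"
            )
    px, py = w_img / nx, h_img / ny
    jit = p["center_jitter"]
    centers = [
        ((i + 0.5) * px, (j + 0.5) * py) for j in range(ny) for i in range(nx)
    ]
    half_w = (0.5 - jit) * px - p["min_wall_px"] / 2.0
    half_h = (0.5 - jit) * py - p["min_wall_px"] / 2.0
    if half_w < 2.0 or half_h < 2.0:
        raise SectionGenerationError(
            f"cannot place {n} tracheids in a {w_img}x{h_img} px frame"
        )
    return np.asarray(centers), {"half_w": half_w, "half_h": half_h, "pitch": (px, py)}


def _beech_sites(spec: SectionSpec):
    """Hexagonal lattice (alternating row offsets, no wrap-around).

    Searches nearby (nx, ny) grid shapes and keeps the one whose
    nearest-neighbour distance (hence per-vessel radius budget) is largest
    while still providing ``n_cells`` sites.
    """
    w_img, h_img = spec.image_size
    p = spec.lumen_shape_params
    n = spec.n_cells
    d = np.sqrt(2.0 * w_img * h_img / (np.sqrt(3.0) * n))
    jit = p["center_jitter"]

    def capacity(nx, ny):
        return sum((nx if j % 2 == 0 else nx - 1) for j in range(ny))

    best = None
    nx0 = max(int(round(w_img / d)), 1)
    for nx in range(max(nx0 - 2, 1), nx0 + 5):
        px = w_img / nx
        ny0 = max(int(round(h_img / (px * np.sqrt(3.0) / 2.0))), 1)
        for ny in range(max(ny0 - 2, 1), ny0 + 5):
            if capacity(nx, ny) < n:
                continue
            py = h_img / ny
            diag = np.hypot(px / 2.0, py)
            mind = min(px, diag)
            if best is None or mind > best[0]:
                best = (mind, nx, ny)
    if best is None:
        raise SectionGenerationError(
            f"cannot place {n} vessels in a {w_img}x{h_img} px frame"
        )
    mind, nx, ny = best
    px, py = w_img / nx, h_img / ny
    centers = []
    for j in range(ny):
        cols = nx if j % 2 == 0 else nx - 1
        off = 0.5 if j % 2 == 0 else 1.0
        for i in range(cols):
            centers.append(((i + off) * px, (j + 0.5) * py))
    allowed = (mind * (1.0 - 2.0 * jit) - p["min_wall_px"]) / 2.0
    if allowed < 3.0:
        raise SectionGenerationError(
            f"cannot place {n} vessels in a {w_img}x{h_img} px frame"
        )
    return np.asarray(centers), {"allowed_r": allowed, "pitch": (px, py)}


def _severity_extra(severity: float, amp_jit: float) -> float:
    """Additional deformation-harmonic amplitude contributed by severity."""
    return 0.22 * severity * float(np.clip(amp_jit, 0.3, 1.7))


def build_layout(spec: SectionSpec, include_fibers: bool = True) -> dict:
    """Deterministically lay out all lumen polygons for a spec.

    Returns ``{"cells": [...], "fibers": [...]}``, each entry carrying
    ``coords`` (N x 2, image x/y in px) and ``kind``.  Severity is applied
    *after* each lumen is fitted to its lattice cell, as a per-cell radial
    shrink plus extra boundary harmonics, so at a fixed seed every cell's
    true area and circularity are strictly decreasing in severity.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.lumen_shape_params
    w_img, h_img = spec.image_size
    u = float(p["shape_knob"])
    if not 0.0 <= u <= 1.0:
        raise ValueError("shape_knob must lie in [0, 1]")
    knob = _spruce_knob(u) if spec.species_mode == "spruce" else _beech_knob(u)

    if spec.species_mode == "spruce":
        centers, lim = _spruce_sites(spec, knob["aspect"])
    else:
        centers, lim = _beech_sites(spec)

    n = spec.n_cells
    order = rng.permutation(len(centers))[:n]
    sigma = np.sqrt(np.log(1.0 + p["size_cv"] ** 2))
    # one block of per-cell randomness, independent of knob/scale/severity
    size_mult = np.exp(rng.normal(0.0, sigma, n))          # area multiplier
    aspect_jit = np.abs(1.0 + rng.normal(0.0, p["aspect_jitter"], n))
    rot = (
        rng.normal(0.0, p["rotation_jitter_deg"], n)
        if spec.species_mode == "spruce"
        else rng.uniform(0.0, 180.0, n)
    )
    jitter = rng.uniform(-p["center_jitter"], p["center_jitter"], (n, 2))
    k_main = rng.choice(knob["k_choices"], n)
    phases = rng.uniform(0.0, 2.0 * np.pi, (n, 3))
    amp_jit = np.clip(1.0 + rng.normal(0.0, 0.15, n), 0.3, 1.7)
    sev_u = rng.uniform(0.0, 1.0, n)

    px = spec.pixel_size_um
    pitch = lim["pitch"]
    cells = []
    for i in range(n):
        cx, cy = centers[order[i]]
        cx += jitter[i, 0] * pitch[0]
        cy += jitter[i, 1] * pitch[1]
        lin = np.sqrt(size_mult[i]) * p["size_scale"]
        amp0 = knob["amp"] * amp_jit[i]
        if spec.species_mode == "spruce":
            w0 = p["width_um"] / px * lin
            h0 = w0 * knob["aspect"] * aspect_jit[i]
            base = _rounded_rect(w0, h0, knob["corner_frac"] * w0 / 2.0)
        else:
            r_eq = p["equiv_diameter_um"] / px / 2.0 * lin
            a_sp = knob["aspect"] * aspect_jit[i]
            base = _ellipse(r_eq * np.sqrt(a_sp), r_eq / np.sqrt(a_sp))
        coords = _resample(base, 1.2)
        coords = _perturb_radial(
            coords,
            [(int(k_main[i]), 0.85 * amp0, phases[i, 0]),
             (max(int(k_main[i]) - 1, 2), 0.25 * amp0, phases[i, 1])],
        )
        coords = _rotate(coords, rot[i])
        # fit inside the lattice cell, preserving shape (uniform scale only)
        if spec.species_mode == "spruce":
            ext = np.abs(coords).max(axis=0)
            s = min(1.0, lim["half_w"] / max(ext[0], 1e-9), lim["half_h"] / max(ext[1], 1e-9))
        else:
            maxr = np.hypot(coords[:, 0], coords[:, 1]).max()
            s = min(1.0, lim["allowed_r"] / max(maxr, 1e-9))
        coords = coords * s
        # severity: per-cell shrink + extra low-frequency deformation
        if spec.severity > 0:
            shrink = 1.0 - 0.30 * spec.severity * (0.8 + 0.4 * sev_u[i])
            coords = _perturb_radial(
                coords,
                [(int(k_main[i]), _severity_extra(spec.severity, amp_jit[i]), phases[i, 2])],
            )
            coords = coords * shrink
        cells.append(
            {
                "coords": coords + np.array([cx, cy]),
                "kind": "tracheid" if spec.species_mode == "spruce" else "vessel",
            }
        )

    fibers = []
    if spec.species_mode == "beechwood" and include_fibers:
        n_fib = int(round(p["fibers_per_vessel"] * n))
        r_lo, r_hi = p["fiber_radius_px"]
        v_centers = np.array([c["coords"].mean(axis=0) for c in cells])
        v_radii = np.array(
            [np.hypot(*(c["coords"] - c["coords"].mean(axis=0)).T).max() for c in cells]
        )
        tree = cKDTree(v_centers)
        placed: list[np.ndarray] = []
        placed_r: list[float] = []
        attempts = 0
        while len(fibers) < n_fib and attempts < 40 * n_fib:
            attempts += 1
            r = rng.uniform(r_lo, r_hi)
            pos = rng.uniform([r + 2.0, r + 2.0], [w_img - r - 2.0, h_img - r - 2.0])
            near = tree.query_ball_point(pos, r + v_radii.max() + p["min_wall_px"])
            if any(
                np.hypot(*(pos - v_centers[j])) < v_radii[j] + r + p["min_wall_px"]
                for j in near
            ):
                continue
            if any(
                np.hypot(*(pos - q)) < pr + r + p["min_wall_px"]
                for q, pr in zip(placed, placed_r)
            ):
                continue
            ecc = rng.uniform(1.0, 1.6)
            coords = _rotate(
                _ellipse(r * np.sqrt(ecc), r / np.sqrt(ecc)), rng.uniform(0.0, 180.0)
            )
            fibers.append({"coords": coords + pos, "kind": "fiber"})
            placed.append(pos)
            placed_r.append(r)

    return {"cells": cells, "fibers": fibers}


def _layout_truth(
    layout: dict, pixel_size_um: float, raster: bool, factor: int = 8
) -> pd.DataFrame:
    rows = []
    for i, lum in enumerate(layout["cells"] + layout["fibers"], start=1):
        coords = lum["coords"]
        per_px = _polyline_length(coords)
        area_px = raster_area_px(coords, factor) if raster else _shoelace_area(coords)
        circ = min(1.0, 4.0 * np.pi * area_px / per_px**2) if per_px > 0 else 1.0
        c = coords.mean(axis=0)
        rows.append(
            {
                "id": i,
                "kind": lum["kind"],
                "true_area_um2": area_px * pixel_size_um**2,
                "true_perimeter_um": per_px * pixel_size_um,
                "true_circularity": circ,
                "centroid_x": c[0],
                "centroid_y": c[1],
                "n_vertices": len(coords),
            }
        )
    return pd.DataFrame(rows)


# -- rendering ---------------------------------------------------------------


def _paint_polygons(layout: dict, shape_wh: tuple[int, int], factor: int = 4) -> np.ndarray:
    """Lumen coverage in [0, 1] at 1x, from a factor-x supersampled raster."""
    w, h = shape_wh
    canvas = np.zeros((h * factor, w * factor), dtype=bool)
    for lum in layout["cells"] + layout["fibers"]:
        coords = lum["coords"]
        x0 = max(int(np.floor(coords[:, 0].min())) - 1, 0)
        y0 = max(int(np.floor(coords[:, 1].min())) - 1, 0)
        x1 = min(int(np.ceil(coords[:, 0].max())) + 1, w)
        y1 = min(int(np.ceil(coords[:, 1].max())) + 1, h)
        if x1 <= x0 or y1 <= y0:
            continue
        xs = x0 + (np.arange((x1 - x0) * factor) + 0.5) / factor
        ys = y0 + (np.arange((y1 - y0) * factor) + 0.5) / factor
        xx, yy = np.meshgrid(xs, ys)
        inside = (
            MplPath(coords)
            .contains_points(np.column_stack([xx.ravel(), yy.ravel()]))
            .reshape(yy.shape)
        )
        canvas[y0 * factor : y1 * factor, x0 * factor : x1 * factor] |= inside
    return canvas.reshape(h, factor, w, factor).mean(axis=(1, 3))


def _illumination_field(shape_hw: tuple[int, int], amplitude: float, rng) -> np.ndarray:
    """Smooth multiplicative field 1 +/- amplitude (period >> CLAHE tiles)."""
    h, w = shape_hw
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    f = np.zeros((h, w))
    weights = []
    for _ in range(3):
        period = rng.uniform(0.6, 1.4) * max(h, w)
        angle = rng.uniform(0.0, np.pi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wgt = rng.uniform(0.5, 1.0)
        kx, ky = np.cos(angle) / period, np.sin(angle) / period
        f += wgt * np.cos(2.0 * np.pi * (kx * xx + ky * yy) + phase)
        weights.append(wgt)
    f /= sum(weights)  # |f| <= 1
    return 1.0 + amplitude * f


def effective_wall_gain(spec: SectionSpec) -> float:
    """Wall fluorescence gain after severity-dependent loss (grey/ms)."""
    return spec.wall_gain * (1.0 - 0.6 * spec.severity)


def generate_section(spec: SectionSpec) -> tuple[ExposureStack, GroundTruthTable]:
    """Render the exposure stack and its ground-truth table."""
    layout = build_layout(spec)
    truth = _layout_truth(layout, spec.pixel_size_um, raster=True)

    w, h = spec.image_size
    cov = _paint_polygons(layout, (w, h))
    wall_mask = cov < 0.5
    wallness = ndimage.gaussian_filter(1.0 - cov, sigma=spec.edge_blur_px)
    # intensity truth lives on core wall pixels, clear of partial-coverage edges
    core = ndimage.binary_erosion(wall_mask, iterations=2)
    if not core.any():
        core = wall_mask

    rng = np.random.default_rng([spec.seed, 1])
    illum = _illumination_field((h, w), spec.illumination_amplitude, rng)
    gain = effective_wall_gain(spec)

    frames, truth_means = [], []
    for e in spec.exposure_ms:
        wall_val = min(255.0, gain * e)
        clean = np.clip(
            spec.lumen_floor + (wall_val - spec.lumen_floor) * wallness, 0.0, 255.0
        )
        truth_means.append(float(clean[core].mean()))
        noisy = clean * illum + rng.normal(0.0, spec.noise_sd, (h, w))
        frames.append(
            GreyImage(
                np.clip(round_half_up(noisy), 0, 255).astype(np.uint8),
                spec.pixel_size_um,
            )
        )

    stack = ExposureStack(frames, list(spec.exposure_ms))
    curve = pd.DataFrame(
        {"exposure_ms": list(spec.exposure_ms), "true_mean_grey": truth_means}
    )
    return stack, GroundTruthTable(lumens=truth, wall_curve=curve, wall_mask=wall_mask)


# -- calibration -------------------------------------------------------------


def _quick_truth_means(spec: SectionSpec) -> tuple[float, float]:
    """(mean area um^2, mean circularity) over cells of interest, from exact
    polygon formulas (shoelace) — the calibrator's fast inner loop.  Fibre
    lumens are skipped: they are not calibration targets and their placement
    draws come after all cell draws, so skipping them changes nothing else."""
    layout = build_layout(spec, include_fibers=False)
    df = _layout_truth(layout, spec.pixel_size_um, raster=False)
    df = df[df.kind != "fiber"]
    return float(df.true_area_um2.mean()), float(df.true_circularity.mean())


def calibrate_to_target(
    species_mode: str,
    target_mean_area_um2: float,
    target_mean_circularity: float,
    target_wall_grey_at_2000ms: float,
    n_cells: int,
    seed: int,
    image_size: tuple[int, int] = (1024, 1024),
    pixel_size_um: float = 0.8,
    **spec_overrides,
) -> SectionSpec:
    """Find a :class:`SectionSpec` whose ground-truth means hit the targets.

    Bisects the species' shape knob for the circularity target, rescales all
    linear dimensions for the area target (circularity is scale-invariant),
    and sets the wall gain analytically (gain = target grey / 2000 ms).
    Ground-truth means of the returned spec match the targets within 2% for
    n_cells >= 300; infeasible targets raise :class:`CalibrationError`.
    """
    if target_mean_area_um2 <= 0 or target_wall_grey_at_2000ms <= 0:
        raise CalibrationError("targets must be positive")
    if not 0.0 < target_mean_circularity <= 1.0:
        raise CalibrationError("circularity target must lie in (0, 1]")
    if target_wall_grey_at_2000ms > 255.0:
        raise CalibrationError("wall grey target exceeds the 8-bit range")

    shape_overrides = dict(spec_overrides.pop("lumen_shape_params", {}))

    def make(knob: float, scale: float) -> SectionSpec:
        params = dict(shape_overrides)
        params["shape_knob"] = knob
        params["size_scale"] = scale
        return SectionSpec(
            species_mode=species_mode,
            image_size=image_size,
            pixel_size_um=pixel_size_um,
            n_cells=n_cells,
            wall_gain=target_wall_grey_at_2000ms / 2000.0,
            seed=seed,
            lumen_shape_params=params,
            **spec_overrides,
        )

    scale, knob = 1.0, 0.5
    target_c = target_mean_circularity
    for _ in range(4):
        area_hi, c_hi = _quick_truth_means(make(0.0, scale))
        _, c_lo = _quick_truth_means(make(1.0, scale))
        if target_c > c_hi:
            if target_c - c_hi <= 0.02 * target_c:
                knob = 0.0  # e.g. 'perfect circles': closest feasible geometry
            else:
                raise CalibrationError(
                    f"circularity {target_c} above the feasible range "
                    f"[{c_lo:.3f}, {c_hi:.3f}] for {species_mode} geometry"
                )
        elif target_c < c_lo:
            raise CalibrationError(
                f"circularity {target_c} below the feasible range "
                f"[{c_lo:.3f}, {c_hi:.3f}] for {species_mode} geometry"
            )
        else:
            lo, hi = 0.0, 1.0
            for _ in range(22):
                knob = 0.5 * (lo + hi)
                _, c_mid = _quick_truth_means(make(knob, scale))
                if c_mid > target_c:
                    lo = knob
                else:
                    hi = knob
            knob = 0.5 * (lo + hi)
        area, _ = _quick_truth_means(make(knob, scale))
        scale *= float(np.sqrt(target_mean_area_um2 / area))

    spec = make(knob, scale)
    area, circ = _quick_truth_means(spec)
    if abs(area - target_mean_area_um2) > 0.02 * target_mean_area_um2:
        raise CalibrationError(
            f"area target {target_mean_area_um2} um^2 not reachable "
            f"(achieved {area:.1f}; frame too crowded for the requested cells?)"
        )
    if abs(circ - target_c) > max(0.02 * target_c, 0.02):
        raise CalibrationError(
            f"circularity target {target_c} not reachable (achieved {circ:.3f})"
        )
    return spec
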
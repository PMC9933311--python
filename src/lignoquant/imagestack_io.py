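"""Calibrated image containers and TIFF stack I/O.

A wood section is imaged once per exposure time, giving an ordered stack of
8-bit grey frames that share one spatial calibration.  This module defines the
two containers the rest of the package operates on (:class:`GreyImage`,
:class:`ExposureStack`), the 256-bin intensity histogram used by the
auto-threshold algorithms, and lossless multi-page TIFF round-tripping with
the exposure list and pixel size stored in the file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

__all__ = [
    "GreyImage",
    "ExposureStack",
    "IntensityHistogram",
    "StackIOError",
    "round_half_up",
    "to_grey8",
    "compute_histogram",
    "read_stack",
    "write_stack",
    "exposures_from_filenames",
]


class StackIOError(ValueError):
    """Raised for malformed stacks, mismatched frames, or unreadable files."""


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round with ties going up (0.5 -> 1), the single integerization rule
    used throughout the package (numpy's default rounds ties to even)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass
class GreyImage:
    """A single 2-D 8-bit intensity field with its spatial calibration.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W)
        Grey levels in [0, 255].
    pixel_size_um : float
        Edge length of one pixel in micrometres (> 0).
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise StackIOError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if np.any(self.pixels < 0) or np.any(self.pixels > 255):
                raise StackIOError("grey levels must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        self.pixel_size_um = float(self.pixel_size_um)
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise StackIOError(f"pixel_size_um must be finite and > 0, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ExposureStack:
    """Ordered frames of one section acquired at strictly increasing exposures."""

    frames: list[GreyImage]
    exposure_ms: list[float]

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise StackIOError("a stack needs at least one frame")
        if len(self.frames) != len(self.exposure_ms):
            raise StackIOError(
                f"{len(self.frames)} frames but {len(self.exposure_ms)} exposure times"
            )
        self.exposure_ms = [float(e) for e in self.exposure_ms]
        if any(b <= a for a, b in zip(self.exposure_ms, self.exposure_ms[1:])):
            raise StackIOError(f"exposures must be strictly increasing: {self.exposure_ms}")
        shape0 = self.frames[0].shape
        px0 = self.frames[0].pixel_size_um
        for i, f in enumerate(self.frames):
            if f.shape != shape0:
                raise StackIOError(f"frame {i} has shape {f.shape}, expected {shape0}")
            if f.pixel_size_um != px0:
                raise StackIOError("all frames must share one pixel size")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def pixel_size_um(self) -> float:
        return self.frames[0].pixel_size_um

    def frame_at(self, exposure_ms: float) -> GreyImage:
        """Frame acquired at exactly ``exposure_ms`` (no interpolation)."""
        for f, e in zip(self.frames, self.exposure_ms):
            if e == float(exposure_ms):
                return f
        raise KeyError(
            f"no frame at {exposure_ms} ms; available exposures: {self.exposure_ms}"
        )

    def as_array(self) -> np.ndarray:
        """(n_frames, H, W) uint8 view of the stack."""
        return np.stack([f.pixels for f in self.frames])


@dataclass
class IntensityHistogram:
    """256-bin grey-level histogram; the common currency of the thresholds."""

    counts: np.ndarray
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (256,):
            raise ValueError(f"histogram must have exactly 256 bins, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")
        self.total = int(self.counts.sum())

    def occupied_range(self) -> tuple[int, int]:
        """(first, last) occupied grey levels; requires total > 0."""
        nz = np.nonzero(self.counts)[0]
        if nz.size == 0:
            raise ValueError("empty histogram has no occupied range")
        return int(nz[0]), int(nz[-1])


def to_grey8(image: np.ndarray, weights: Sequence[float] | None = None) -> np.ndarray:
    """Convert an (H, W, 3) 8-bit RGB image to 8-bit grey.

    Default is the unweighted channel mean (rounded half-up); pass
    ``weights`` (e.g. ITU-R 601 luminance ``(0.299, 0.587, 0.114)``) for a
    weighted conversion.  Returns a (H, W) uint8 array.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise StackIOError(f"expected an (H, W, 3) image, got shape {image.shape}")
    if np.any(image < 0) or np.any(image > 255):
        raise StackIOError("channel values must lie in [0, 255]")
    if weights is None:
        w = np.full(3, 1.0 / 3.0)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (3,) or np.any(w < 0) or w.sum() <= 0:
            raise StackIOError("weights must be three non-negative numbers")
        w = w / w.sum()
    grey = round_half_up(image.astype(np.float64) @ w)
    return np.clip(grey, 0, 255).astype(np.uint8)


def compute_histogram(image: GreyImage, mask: np.ndarray | None = None) -> IntensityHistogram:
    """Histogram of the image (or of the masked region).

    Raises if a mask is given that selects zero pixels or mismatches the
    image dimensions.
    """
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape:
            raise StackIOError(f"mask shape {mask.shape} != image shape {image.shape}")
        values = image.pixels[mask]
        if values.size == 0:
            raise StackIOError("mask selects zero pixels")
    else:
        values = image.pixels.ravel()
    counts = np.bincount(values, minlength=256)
    return IntensityHistogram(counts)


# -- TIFF round-trip ---------------------------------------------------------

_DESC_RE = re.compile(r"^lignoquant:pixel_size_um=(?P<px>[^;]+);exposure_ms=(?P<exp>.*)$")


def _description(stack: ExposureStack) -> str:
    exp = ",".join(repr(e) for e in stack.exposure_ms)
    return f"lignoquant:pixel_size_um={stack.pixel_size_um!r};exposure_ms={exp}"


def write_stack(stack: ExposureStack, path: str | Path) -> None:
    """Write a multi-page 8-bit grey TIFF, one page per frame in exposure
    order.  Pixel size goes into the TIFF resolution tags (pixels/cm) and,
    authoritatively, into an ImageDescription key=value block together with
    the exposure list, so ``read_stack`` reproduces the stack bit-exactly."""
    ppcm = 1.0e4 / stack.pixel_size_um
    tifffile.imwrite(
        str(path),
        stack.as_array(),
        photometric="minisblack",
        resolution=(ppcm, ppcm),
        resolutionunit="CENTIMETER",
        description=_description(stack),
    )


def _load_frame(path: str | Path) -> np.ndarray:
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # decoding or filesystem failure
        raise StackIOError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] == 3:
        arr = to_grey8(arr)
    if arr.ndim != 2:
        raise StackIOError(f"{path!r}: expected a 2-D or RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise StackIOError(f"{path!r}: expected 8-bit data, got dtype {arr.dtype}")
    return arr


def read_stack(
    paths: str | Path | Iterable[str | Path],
    exposures_ms: Sequence[float] | None = None,
    pixel_size_um: float | None = None,
) -> ExposureStack:
    """Assemble an :class:`ExposureStack` from image files.

    ``paths`` is either one multi-page TIFF (as written by
    :func:`write_stack`, whose metadata then supplies any calibration not
    given explicitly) or a list of single-frame files, one per exposure.
    Frames are returned sorted by ascending exposure regardless of input
    order; RGB frames are converted with :func:`to_grey8`.
    """
    if isinstance(paths, (str, Path)):
        return _read_multipage(Path(paths), exposures_ms, pixel_size_um)
    paths = [Path(p) for p in paths]
    if len(paths) < 1:
        raise StackIOError("need at least one path")
    if exposures_ms is None or len(list(exposures_ms)) != len(paths):
        n = None if exposures_ms is None else len(list(exposures_ms))
        raise StackIOError(f"{len(paths)} paths but {n} exposure times")
    if pixel_size_um is None:
        raise StackIOError("pixel_size_um is required when reading per-file frames")
    frames = [_load_frame(p) for p in paths]
    shape0 = frames[0].shape
    for p, f in zip(paths, frames):
        if f.shape != shape0:
            raise StackIOError(f"{p!r}: frame shape {f.shape} != {shape0} of {paths[0]!r}")
    order = np.argsort(np.asarray(list(exposures_ms), dtype=float), kind="stable")
    exp_sorted = [float(list(exposures_ms)[i]) for i in order]
    frames_sorted = [GreyImage(frames[i], pixel_size_um) for i in order]
    return ExposureStack(frames_sorted, exp_sorted)


def _read_multipage(
    path: Path,
    exposures_ms: Sequence[float] | None,
    pixel_size_um: float | None,
) -> ExposureStack:
    try:
        with tifffile.TiffFile(str(path)) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description or ""
    except Exception as exc:
        raise StackIOError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    m = _DESC_RE.match(desc)
    if m:
        meta_px = float(m.group("px"))
        meta_exp = [float(x) for x in m.group("exp").split(",") if x]
    else:
        meta_px, meta_exp = None, None
    px = pixel_size_um if pixel_size_um is not None else meta_px
    exp = list(exposures_ms) if exposures_ms is not None else meta_exp
    if px is None or exp is None:
        raise StackIOError(
            f"{path!r} carries no lignoquant metadata; pass exposures_ms and pixel_size_um"
        )
    if len(exp) != arr.shape[0]:
        raise StackIOError(f"{path!r}: {arr.shape[0]} pages but {len(exp)} exposure times")
    order = np.argsort(np.asarray(exp, dtype=float), kind="stable")
    frames = [GreyImage(arr[i], px) for i in order]
    return ExposureStack(frames, [float(exp[i]) for i in order])


def exposures_from_filenames(paths: Iterable[str | Path]) -> list[float]:
    """Convenience: pull exposure times (ms) out of names like ``x_1200ms.tif``.

    Exposure metadata should normally travel explicitly; this helper only
    serves ad-hoc directories of per-exposure files.
    """
    out = []
    for p in paths:
        m = re.search(r"(\d+(?:\.\d+)?)\s*ms", Path(p).name)
        if not m:
            raise StackIOError(f"no '<number>ms' token in filename {Path(p).name!r}")
        out.append(float(m.group(1)))
    return out
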
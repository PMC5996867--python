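"""Containers and file I/O for multiband stacks and score maps.

A :class:`MultispectralStack` is the co-registered reflectance cube coming
off the (cross-polarized) multispectral camera; a :class:`ScoreMap` is the
common currency of the planning pipeline: an H×W array in [0, 1] tagged with
the role it plays in the suture map ``J = V * T * B``.

Stacks are stored as multi-page TIFF (one page per band, ascending
wavelength, float32) with a JSON sidecar carrying the wavelengths and the
pixel pitch; score maps as single-page TIFF plus sidecar.  Coordinates are
(row, col), 0-based; rectangles are half-open ``(r0, r1, c0, c1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

SCORE_ROLES = ("vessel_V", "thickness_T", "bite_depth_B", "suture_J")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


@dataclass
class MultispectralStack:
    """Co-registered H×W×B reflectance cube with wavelength metadata.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, B)
        Reflectance values in [0, 1].
    wavelengths_nm : sequence of float
        Band center wavelengths, strictly increasing, one per band.
    pixel_pitch_mm : float
        Physical size of one pixel in mm.
    """

    pixels: np.ndarray
    wavelengths_nm: tuple[float, ...]
    pixel_pitch_mm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        self.wavelengths_nm = tuple(float(w) for w in self.wavelengths_nm)
        if self.pixels.ndim != 3:
            raise ValueError("stack must be H x W x B")
        if self.pixels.shape[2] != len(self.wavelengths_nm):
            raise ValueError(
                f"{self.pixels.shape[2]} bands but "
                f"{len(self.wavelengths_nm)} wavelengths"
            )
        if len(self.wavelengths_nm) < 2:
            raise ValueError("need at least 2 bands")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixel values")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("reflectance must lie in [0, 1]")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def band(self, wavelength_nm: float) -> np.ndarray:
        """Return the single-band image closest to ``wavelength_nm``."""
        idx = int(np.argmin(np.abs(np.asarray(self.wavelengths_nm) - wavelength_nm)))
        return self.pixels[:, :, idx]


@dataclass
class ScoreMap:
    """H×W map in [0, 1] with a pipeline role tag (V, T, B or J)."""

    values: np.ndarray
    role: str
    pixel_pitch_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("score map must be 2-D")
        if self.role not in SCORE_ROLES:
            raise ValueError(f"role must be one of {SCORE_ROLES}, got {self.role!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite score values")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("score values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def write_stack(stack: MultispectralStack, path: str | Path) -> Path:
    """Write a stack as multi-page float32 TIFF plus JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(stack.pixels.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps(
            {
                "wavelengths_nm": list(stack.wavelengths_nm),
                "pixel_pitch_mm": stack.pixel_pitch_mm,
            },
            indent=1,
        )
    )
    return path


def read_stack(path: str | Path) -> MultispectralStack:
    """Read a multi-page TIFF stack written by :func:`write_stack`.

    Raises
    ------
    ValueError
        If the page count disagrees with the sidecar wavelengths or the
        pages are not co-registered (differing shapes).
    """
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"pages are not co-registered: shapes {sorted(shapes)}")
    if len(pages) != len(meta["wavelengths_nm"]):
        raise ValueError(
            f"sidecar lists {len(meta['wavelengths_nm'])} wavelengths "
            f"but file has {len(pages)} pages"
        )
    pixels = np.moveaxis(np.stack(pages), 0, 2)
    return MultispectralStack(pixels, meta["wavelengths_nm"], meta["pixel_pitch_mm"])


def write_score_map(smap: ScoreMap, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, smap.values.astype(np.float32))
    _sidecar(path).write_text(
        json.dumps({"role": smap.role, "pixel_pitch_mm": smap.pixel_pitch_mm})
    )
    return path


def read_score_map(path: str | Path) -> ScoreMap:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return ScoreMap(tifffile.imread(path), meta["role"], meta["pixel_pitch_mm"])


def crop_roi(
    stack: MultispectralStack, rect: tuple[int, int, int, int]
) -> MultispectralStack:
    """Crop to the half-open rectangle ``(r0, r1, c0, c1)``.

    Mirrors the acquisition workflow where the raw frame is cropped to the
    tissue region of interest before analysis.
    """
    r0, r1, c0, c1 = (int(v) for v in rect)
    h, w, _ = stack.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"rectangle {rect} invalid for image {h}x{w}")
    return MultispectralStack(
        stack.pixels[r0:r1, c0:c1, :], stack.wavelengths_nm, stack.pixel_pitch_mm
    )


def _draw_points(rgb: np.ndarray, points: Iterable, color, radius: int) -> None:
    h, w, _ = rgb.shape
    rr, cc = np.mgrid[0:h, 0:w]
    for p in points:
        pos = getattr(p, "position", p)
        r, c = int(round(pos[0])), int(round(pos[1]))
        disk = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
        rgb[disk] = color


def render_overlay(
    base: np.ndarray,
    overlay=None,
    *,
    color: Sequence[float] = (1.0, 0.0, 0.0),
    alpha: float = 0.6,
    cmap: str = "viridis",
    marker_radius: int = 3,
) -> np.ndarray:
    """Render an RGB visualization of ``overlay`` on a grayscale base band.

    ``overlay`` may be None (plain grayscale replication), a boolean mask
    (solid color at opacity ``alpha``), a float map or :class:`ScoreMap`
    (matplotlib colormap, per-pixel opacity ``alpha * value``), or an
    iterable of points / SuturePoints (solid markers).
    """
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import colormaps

    base = np.asarray(base, dtype=np.float64)
    if base.ndim != 2:
        raise ValueError("base band must be 2-D")
    lo, hi = base.min(), base.max()
    gray = (base - lo) / (hi - lo) if hi > lo else base.copy()
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    color = np.asarray(color, dtype=np.float64)

    if overlay is None:
        return rgb
    if isinstance(overlay, ScoreMap):
        overlay = overlay.values
    if isinstance(overlay, np.ndarray):
        if overlay.shape != base.shape:
            raise ValueError("overlay shape does not match base")
        if overlay.dtype == bool:
            a = float(alpha) * overlay[:, :, None]
            rgb = (1 - a) * rgb + a * color[None, None, :]
        else:
            colored = colormaps[cmap](np.clip(overlay, 0, 1))[:, :, :3]
            a = float(alpha) * np.clip(overlay, 0, 1)[:, :, None]
            rgb = (1 - a) * rgb + a * colored
    else:
        _draw_points(rgb, overlay, color, marker_radius)
    return np.clip(rgb, 0, 1)


def write_overlay_png(rgb: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, (np.clip(rgb, 0, 1) * 255).astype(np.uint8))
    return path
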
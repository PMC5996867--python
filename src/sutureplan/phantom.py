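"""Synthetic multispectral intestine phantom with complete ground truth.

No imaging data ships with this package, so every downstream stage is
exercised on a seeded phantom that emulates what a cross-polarized
three-band (470/600/770 nm) reflectance acquisition of ex vivo small bowel
looks like to the analysis:

* four tissue regions with distinct spectra — background, inner lumen
  (mucosa/submucosa, exposed where the bowel is incised), outer lumen
  (serosa, in a thick and a thin variant), and mesentery;
* dark blood vessels whose contrast is strongest at 470 nm (superficial
  absorption by hemoglobin) and weakest at 770 nm;
* a cut edge — the incision line between inner-lumen-exposed and
  non-incised tissue — along which sutures are to be planned;
* additive Gaussian sensor noise.

The default cut edge is gently sinusoidal rather than straight: real cut
lines are never geometrically perfect, and the curvature also gives the
bite-depth ridge genuine local structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .io import MultispectralStack

CLASS_NAMES = ("background", "inner_lumen", "outer_lumen", "mesentery")

#: Default per-class reflectance at (470, 600, 770) nm.  Chosen so that the
#: spectral angles between classes are distinct and both the spectral-angle
#: and discriminant classifiers are exercised non-trivially.
DEFAULT_SPECTRA: dict[str, tuple[float, float, float]] = {
    "background": (0.02, 0.02, 0.02),
    "inner_lumen": (0.45, 0.55, 0.60),
    "outer_lumen_thick": (0.55, 0.60, 0.70),
    "outer_lumen_thin": (0.40, 0.50, 0.65),
    "mesentery": (0.60, 0.40, 0.35),
}


def _default_cut_edge(height: int) -> list[tuple[float, float]]:
    rows = np.arange(40, min(216, height - 40 if height < 256 else 216))
    cols = 112.0 + 6.0 * np.sin(2 * np.pi * (rows - 40) / 96.0)
    return [(float(r), float(c)) for r, c in zip(rows, cols)]


def _default_vessels() -> list[list[tuple[float, float]]]:
    return [
        [(150.0, 126.0), (154.0, 236.0)],  # crosses the bite band
        [(58.0, 190.0), (212.0, 203.0)],  # distal serosal vessel
    ]


@dataclass
class PhantomSpec:
    """Geometry, spectra and noise model of the synthetic phantom.

    All coordinates are (row, col) pixels.  ``vessel_contrast_per_band``
    multiplies the underlying tissue reflectance at vessel pixels and must
    be non-decreasing with wavelength (vessels darkest at 470 nm).
    """

    height_px: int = 256
    width_px: int = 256
    wavelengths_nm: tuple[float, ...] = (470.0, 600.0, 770.0)
    pixel_pitch_mm: float = 0.05
    tissue_rect: tuple[int, int, int, int] = (40, 216, 16, 240)
    mesentery_region: tuple[tuple[float, float], ...] = (
        (16, 32),
        (16, 224),
        (40, 224),
        (40, 32),
    )
    cut_edge_polyline: list[tuple[float, float]] = field(
        default_factory=lambda: _default_cut_edge(256)
    )
    thick_rule: str = "right_of_cut"
    thin_serosa_min_col: int = 220
    vessel_centerlines: list[list[tuple[float, float]]] = field(
        default_factory=_default_vessels
    )
    vessel_radius_px: float = 3.0
    class_spectra: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRA)
    )
    vessel_contrast_per_band: tuple[float, ...] = (0.3, 0.6, 0.85)
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        nb = len(self.wavelengths_nm)
        if len(self.vessel_contrast_per_band) != nb:
            raise ValueError("one vessel contrast factor per band required")
        if np.any(np.diff(self.vessel_contrast_per_band) < 0):
            raise ValueError(
                "vessel contrast must be non-decreasing with wavelength "
                "(vessels darkest at the shortest band)"
            )
        if not all(0 < f <= 1 for f in self.vessel_contrast_per_band):
            raise ValueError("vessel contrast factors must lie in (0, 1]")
        for label, spec in self.class_spectra.items():
            if len(spec) != nb:
                raise ValueError(f"spectrum of {label!r} must have {nb} bands")
            if min(spec) < 0 or max(spec) > 1:
                raise ValueError(f"spectrum of {label!r} outside [0, 1]")
        if self.thick_rule != "right_of_cut":
            raise ValueError(f"unknown thick_rule {self.thick_rule!r}")
        for poly in [self.cut_edge_polyline, *self.vessel_centerlines]:
            self._check_bounds(poly)
        self._check_bounds(self.mesentery_region)

    def _check_bounds(self, pts: Sequence[tuple[float, float]]) -> None:
        for r, c in pts:
            if not (0 <= r < self.height_px and 0 <= c < self.width_px):
                raise ValueError(
                    f"geometry point ({r}, {c}) outside "
                    f"{self.height_px}x{self.width_px} image"
                )


@dataclass
class GroundTruth:
    """Planted truth accompanying a phantom stack.

    ``class_map`` uses integer labels indexing :data:`CLASS_NAMES`; the
    cut-edge mask is the 2-px band along the inner/outer lumen boundary.
    ``thick_mask`` marks the non-incised, double-layered serosa that is
    mechanically suitable for suturing.
    """

    vessel_mask: np.ndarray
    thick_mask: np.ndarray
    class_map: np.ndarray
    cut_edge_mask: np.ndarray
    spectrum_id: np.ndarray  # index into the ordered class_spectra keys
    spectrum_labels: tuple[str, ...]


def _rasterize_polyline(
    polyline: Sequence[tuple[float, float]], shape: tuple[int, int]
) -> np.ndarray:
    """Mark pixels under a densely sampled polyline."""
    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(polyline, dtype=float)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        n = max(2, int(np.hypot(r1 - r0, c1 - c0) * 4))
        rr = np.round(np.linspace(r0, r1, n)).astype(int)
        cc = np.round(np.linspace(c0, c1, n)).astype(int)
        mask[rr, cc] = True
    if len(pts) == 1:
        mask[int(round(pts[0, 0])), int(round(pts[0, 1]))] = True
    return mask


def _tube_mask(
    polylines: Sequence[Sequence[tuple[float, float]]],
    radius: float,
    shape: tuple[int, int],
) -> np.ndarray:
    center = np.zeros(shape, dtype=bool)
    for poly in polylines:
        center |= _rasterize_polyline(poly, shape)
    if not center.any():
        return center
    dist = ndimage.distance_transform_edt(~center)
    return dist <= radius


def generate_phantom(spec: PhantomSpec) -> tuple[MultispectralStack, GroundTruth]:
    """Generate the seeded phantom stack and its ground truth.

    The stack is piecewise constant over the planted regions (each pixel
    carries its region's spectrum), vessels multiply the underlying
    reflectance by the per-band contrast factor, and zero-mean Gaussian
    noise of sd ``noise_sd`` is added and clipped to [0, 1].  Identical
    spec and seed reproduce the stack bit-for-bit.
    """
    h, w = spec.height_px, spec.width_px
    nb = len(spec.wavelengths_nm)
    r0, r1, c0, c1 = spec.tissue_rect

    rr, cc = np.mgrid[0:h, 0:w]
    tissue = (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)

    mes = np.zeros((h, w), dtype=bool)
    poly = np.asarray(spec.mesentery_region, dtype=float)
    pr, pc = draw_polygon(poly[:, 0], poly[:, 1], shape=(h, w))
    mes[pr, pc] = True
    mes &= ~tissue

    edge_pts = np.asarray(spec.cut_edge_polyline, dtype=float)
    order = np.argsort(edge_pts[:, 0])
    edge_col = np.interp(np.arange(h), edge_pts[order, 0], edge_pts[order, 1])
    inner = tissue & (cc < edge_col[:, None])
    outer = tissue & ~inner
    outer_thin = outer & (cc >= spec.thin_serosa_min_col)
    outer_thick = outer & ~outer_thin

    class_map = np.zeros((h, w), dtype=np.int64)
    class_map[inner] = CLASS_NAMES.index("inner_lumen")
    class_map[outer] = CLASS_NAMES.index("outer_lumen")
    class_map[mes] = CLASS_NAMES.index("mesentery")

    # Cut edge: 2-px band on the inner/outer boundary (3x3 dilations).
    st = np.ones((3, 3), dtype=bool)
    cut_edge = (
        ndimage.binary_dilation(inner, st)
        & ndimage.binary_dilation(outer, st)
        & (inner | outer)
    )

    vessel_mask = _tube_mask(
        spec.vessel_centerlines, spec.vessel_radius_px, (h, w)
    ) & (class_map > 0)

    spectrum_labels = tuple(spec.class_spectra.keys())
    spectra = np.asarray([spec.class_spectra[k] for k in spectrum_labels])

    def sid(label: str) -> int:
        return spectrum_labels.index(label)

    spectrum_id = np.full((h, w), sid("background"), dtype=np.int64)
    spectrum_id[inner] = sid("inner_lumen")
    spectrum_id[outer_thick] = sid("outer_lumen_thick")
    spectrum_id[outer_thin] = sid("outer_lumen_thin")
    spectrum_id[mes] = sid("mesentery")

    pixels = spectra[spectrum_id].astype(np.float64)  # H x W x B
    contrast = np.asarray(spec.vessel_contrast_per_band)
    pixels[vessel_mask] = pixels[vessel_mask] * contrast[None, :]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)

    stack = MultispectralStack(pixels, spec.wavelengths_nm, spec.pixel_pitch_mm)
    gt = GroundTruth(
        vessel_mask=vessel_mask,
        thick_mask=outer_thick,
        class_map=class_map,
        cut_edge_mask=cut_edge,
        spectrum_id=spectrum_id,
        spectrum_labels=spectrum_labels,
    )
    return stack, gt
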
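"""Hessian-eigenvalue (Frangi) vessel filtering and the vessel map V.

Blood vessels appear as dark tubular structures on the 470 nm band of the
cross-polarized stack.  The filter smooths the band at each scale s,
forms the scale-normalized Hessian (s^2 times explicit 3-point second
differences on an edge-padded image), orders its eigenvalues by magnitude
|l1| <= |l2|, and scores tubularity with the standard two-term response

    v = exp(-Rb^2 / (2 beta^2)) * (1 - exp(-S^2 / (2 c^2))),

where Rb = l1/l2 penalizes blobs and S = sqrt(l1^2 + l2^2) (the Frobenius
norm of the Hessian) suppresses flat background; the response is zero where
the curvature polarity disagrees (dark ridges require l2 > 0).  The final
vesselness is the per-pixel maximum over scales.

The vessel-possibility map V negates a binarized vesselness (vessels = 0,
everything else = 1), Gaussian-smooths it to grade the pixels next to a
vessel, and re-imposes exact zeros inside the segmented vessels so that a
confident vessel can never be recommended for a suture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import ScoreMap


@dataclass
class FrangiParams:
    """Internal parameters of the vesselness filter.

    ``c="auto"`` uses the standard heuristic of half the maximum Hessian
    Frobenius norm over the image, per scale.  ``polarity`` selects dark
    vessels on bright tissue (the 470 nm situation) or the reverse.
    """

    scales_px: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    beta: float = 0.5
    c: float | str = "auto"
    polarity: str = "dark"

    def __post_init__(self) -> None:
        if len(self.scales_px) == 0:
            raise ValueError("at least one scale required")
        if any(s <= 0 for s in self.scales_px):
            raise ValueError("scales must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")
        if not (self.c == "auto" or (isinstance(self.c, (int, float)) and self.c > 0)):
            raise ValueError("c must be 'auto' or a positive number")


@dataclass
class VesselMapParams:
    """Binarization and smoothing that turn vesselness into the V map."""

    binarize_threshold: float | str = 0.5  # fraction of the map maximum, or "otsu"
    smooth_sigma_mm: float = 0.3

    def __post_init__(self) -> None:
        if self.binarize_threshold != "otsu":
            t = float(self.binarize_threshold)
            if not 0 < t < 1:
                raise ValueError("binarize_threshold must be in (0, 1) or 'otsu'")
        if self.smooth_sigma_mm <= 0:
            raise ValueError("smooth_sigma_mm must be positive")


def _hessian_components(band: np.ndarray, scale_px: float):
    """Scale-normalized Hessian via Gaussian smoothing + second differences."""
    smoothed = ndimage.gaussian_filter(band.astype(np.float64), scale_px, mode="nearest")
    f = np.pad(smoothed, 1, mode="edge")
    hrr = f[2:, 1:-1] - 2 * f[1:-1, 1:-1] + f[:-2, 1:-1]
    hcc = f[1:-1, 2:] - 2 * f[1:-1, 1:-1] + f[1:-1, :-2]
    hrc = (f[2:, 2:] - f[2:, :-2] - f[:-2, 2:] + f[:-2, :-2]) / 4.0
    s2 = scale_px**2
    return s2 * hrr, s2 * hrc, s2 * hcc


def hessian_eigenvalues(
    band: np.ndarray, scale_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel eigenvalues of the scale-normalized Hessian.

    Returns ``(l1, l2)`` ordered by magnitude, ``|l1| <= |l2|`` everywhere.
    """
    band = np.asarray(band, dtype=np.float64)
    if band.ndim != 2:
        raise ValueError("band must be 2-D")
    if not np.all(np.isfinite(band)):
        raise ValueError("non-finite pixels in band")
    if scale_px <= 0:
        raise ValueError("scale must be positive")
    hrr, hrc, hcc = _hessian_components(band, scale_px)
    half_trace = (hrr + hcc) / 2.0
    disc = np.sqrt(((hrr - hcc) / 2.0) ** 2 + hrc**2)
    e_lo, e_hi = half_trace - disc, half_trace + disc
    swap = np.abs(e_lo) > np.abs(e_hi)
    l1 = np.where(swap, e_hi, e_lo)
    l2 = np.where(swap, e_lo, e_hi)
    return l1, l2


def frangi_vesselness(band: np.ndarray, params: FrangiParams) -> np.ndarray:
    """Multiscale Frangi tubularity response in [0, 1]."""
    best = np.zeros_like(np.asarray(band, dtype=np.float64))
    for s in params.scales_px:
        l1, l2 = hessian_eigenvalues(band, s)
        structure = np.sqrt(l1**2 + l2**2)
        if params.c == "auto":
            c = structure.max() / 2.0
        else:
            c = float(params.c)
        if c == 0:  # flat image at this scale
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(l2 != 0, (l1 / np.where(l2 == 0, 1.0, l2)) ** 2, 0.0)
        resp = np.exp(-rb2 / (2 * params.beta**2)) * (
            1.0 - np.exp(-(structure**2) / (2 * c**2))
        )
        wrong_polarity = (l2 <= 0) if params.polarity == "dark" else (l2 >= 0)
        resp = np.where(wrong_polarity, 0.0, resp)
        best = np.maximum(best, resp)
    return np.clip(best, 0.0, 1.0)


def binarize_vesselness(vesselness: np.ndarray, params: VesselMapParams) -> np.ndarray:
    """Threshold the vesselness response into a confident-vessel mask."""
    v = np.asarray(vesselness, dtype=np.float64)
    vmax = v.max()
    if vmax == 0:
        return np.zeros_like(v, dtype=bool)
    if params.binarize_threshold == "otsu":
        thr = threshold_otsu(v)
    else:
        thr = float(params.binarize_threshold) * vmax
    return v >= thr


def vessel_map(
    vesselness: np.ndarray,
    params: VesselMapParams,
    pixel_pitch_mm: float,
    vessel_mask: np.ndarray | None = None,
) -> ScoreMap:
    """Build the vessel-possibility map V (role ``vessel_V``).

    Confident vessel pixels are exactly 0, tissue far from any vessel is 1,
    and the Gaussian-smoothed transition grades the pixels in between so
    that suture scores fall off near vessels.  ``vessel_mask`` can be
    supplied to bypass the internal binarization.
    """
    if vessel_mask is None:
        vessel_mask = binarize_vesselness(vesselness, params)
    v0 = 1.0 - vessel_mask.astype(np.float64)
    sigma_px = params.smooth_sigma_mm / pixel_pitch_mm
    v = ndimage.gaussian_filter(v0, sigma_px, mode="nearest")
    v = np.minimum(v, v0)  # keep exact zeros inside vessels
    return ScoreMap(np.clip(v, 0.0, 1.0), "vessel_V", pixel_pitch_mm)
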
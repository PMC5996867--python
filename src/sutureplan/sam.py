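"""Spectral angle mapper (SAM) thickness differentiation and the T map.

SAM classifies each pixel by the angle between its spectrum and a small
library of reference endmembers — here the double-layered (non-incised,
thick) and single-layered (incised, thin) tissue spectra.  The angle is
invariant to positive scaling of either vector, i.e. to overall
illumination, which is exactly why it suits reflectance imagery.

The thickness map T assigns 1 to confidently thick (suturable) tissue and
0 to thin tissue, with a 2-D Gaussian smoothing grading the transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import MultispectralStack, ScoreMap

UNCLASSIFIED = -1


def spectral_angle(x: np.ndarray, r: np.ndarray) -> float:
    """Angle in radians between two spectra, in [0, pi].

    arccos of the normalized inner product; raises on zero-norm input.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    r = np.asarray(r, dtype=np.float64).ravel()
    if x.shape != r.shape:
        raise ValueError("spectra must have equal length")
    nx, nr = np.linalg.norm(x), np.linalg.norm(r)
    if nx == 0 or nr == 0:
        raise ValueError("zero-norm spectrum")
    cosang = np.clip(np.dot(x, r) / (nx * nr), -1.0, 1.0)
    return float(np.arccos(cosang))


@dataclass
class SpectralLibrary:
    """Labeled endmember spectra plus the maximum acceptable angle."""

    endmembers: list[tuple[str, np.ndarray]]
    angle_threshold_rad: float = 0.10

    def __post_init__(self) -> None:
        if not self.endmembers:
            raise ValueError("library needs at least one endmember")
        labels = [lab for lab, _ in self.endmembers]
        if len(set(labels)) != len(labels):
            raise ValueError("endmember labels must be unique")
        lengths = {len(np.ravel(s)) for _, s in self.endmembers}
        if len(lengths) != 1:
            raise ValueError("all endmember spectra must have the same length")
        for lab, s in self.endmembers:
            if np.linalg.norm(s) == 0:
                raise ValueError(f"endmember {lab!r} has zero norm")
        if self.angle_threshold_rad <= 0:
            raise ValueError("angle_threshold_rad must be positive")
        self.endmembers = [
            (lab, np.asarray(s, dtype=np.float64).ravel()) for lab, s in self.endmembers
        ]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.endmembers)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def build_reference(
    stack: MultispectralStack, regions: list[tuple[int, int, int, int]]
) -> np.ndarray:
    """Mean spectrum over one or more disjoint pixel regions.

    Regions are half-open rectangles (r0, r1, c0, c1); they must be
    non-empty, in bounds, and pairwise non-overlapping (the reference is
    an average of distinct tissue patches of similar thickness).
    """
    if not regions:
        raise ValueError("at least one region required")
    h, w, _ = stack.shape
    cover = np.zeros((h, w), dtype=np.int64)
    pixels = []
    for rect in regions:
        r0, r1, c0, c1 = (int(v) for v in rect)
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"region {rect} empty or out of bounds for {h}x{w}")
        cover[r0:r1, c0:c1] += 1
        pixels.append(
            stack.pixels[r0:r1, c0:c1, :].reshape(-1, stack.shape[2]).astype(np.float64)
        )
    if cover.max() > 1:
        raise ValueError("regions overlap; references require disjoint regions")
    return np.concatenate(pixels, axis=0).mean(axis=0)


def sam_classify(
    stack: MultispectralStack, library: SpectralLibrary
) -> tuple[np.ndarray, np.ndarray]:
    """Label every pixel with its minimum-angle endmember.

    Returns ``(labels, angles)``: ``labels`` is an H×W int map indexing
    ``library.endmembers`` with :data:`UNCLASSIFIED` (-1) where the best
    angle exceeds the library threshold or the pixel spectrum is zero;
    ``angles`` holds the per-pixel best angle in radians.
    """
    h, w, nb = stack.shape
    refs = np.stack([s for _, s in library.endmembers])  # K x B
    if refs.shape[1] != nb:
        raise ValueError("endmember length does not match band count")
    flat = stack.pixels.reshape(-1, nb).astype(np.float64)
    norms = np.linalg.norm(flat, axis=1)
    ref_norms = np.linalg.norm(refs, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    cos = (flat @ refs.T) / (safe[:, None] * ref_norms[None, :])
    ang = np.arccos(np.clip(cos, -1.0, 1.0))  # N x K
    best = np.argmin(ang, axis=1)
    best_ang = ang[np.arange(ang.shape[0]), best]
    labels = best.astype(np.int64)
    labels[(best_ang > library.angle_threshold_rad) | (norms == 0)] = UNCLASSIFIED
    return labels.reshape(h, w), best_ang.reshape(h, w)


def thickness_map(
    sam_labels: np.ndarray,
    thick_label: int,
    smooth_sigma_mm: float,
    pixel_pitch_mm: float,
    exclude_mask: np.ndarray | None = None,
) -> ScoreMap:
    """Build the thickness map T (role ``thickness_T``).

    Thick pixels get 1, everything else 0, then a 2-D Gaussian smoothing
    grades the thin/thick transition.  ``exclude_mask`` removes pixels that
    are not suturable bowel wall regardless of their spectrum (mesentery,
    segmented vessels); they contribute 0 before smoothing.
    """
    if smooth_sigma_mm <= 0 or pixel_pitch_mm <= 0:
        raise ValueError("sigma and pixel pitch must be positive")
    binary = (np.asarray(sam_labels) == thick_label).astype(np.float64)
    if exclude_mask is not None:
        binary[np.asarray(exclude_mask, dtype=bool)] = 0.0
    sigma_px = smooth_sigma_mm / pixel_pitch_mm
    t = ndimage.gaussian_filter(binary, sigma_px, mode="nearest")
    return ScoreMap(np.clip(t, 0.0, 1.0), "thickness_T", pixel_pitch_mm)


def read_library(path, angle_threshold_rad: float = 0.10) -> SpectralLibrary:
    """Read an endmember library from plain text: ``label v1 v2 ... vB``."""
    endmembers = []
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        endmembers.append((parts[0], np.asarray([float(v) for v in parts[1:]])))
    return SpectralLibrary(endmembers, angle_threshold_rad)


def write_library(library: SpectralLibrary, path) -> None:
    with open(path, "w") as fh:
        for lab, s in library.endmembers:
            fh.write(lab + " " + " ".join(f"{v:.6g}" for v in s) + "\n")
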
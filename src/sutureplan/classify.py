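"""Supervised discriminant tissue classification, cut-edge extraction and
the bite-depth map B.

The composite three-band image is classified into four regions —
background, inner lumen (mucosa/submucosa), outer lumen (serosa) and
mesentery — with a Gaussian maximum-likelihood (quadratic) discriminant
trained on user-designated rectangles.  The cut edge, where sutures belong,
is the boundary between inner and outer lumen, extracted by intersecting
dilations of the two class masks.  The bite-depth map rewards serosal
pixels whose distance d from the cut edge matches the surgical rule of
thumb of 1.5 tissue thicknesses:

    B = exp(-(d - 1.5 tau)^2 / (2 sigma^2)),  sigma = (1.5 tau - delta) / 3,

zeroed closer than the clearance delta and outside the serosa.  The 3-sigma
choice puts 99.7% of the response mass between delta and 1.5 tau + (1.5 tau
- delta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .io import MultispectralStack, ScoreMap
from .phantom import CLASS_NAMES


@dataclass
class TrainingField:
    """A labeled training rectangle (half-open, pixel coordinates)."""

    class_label: str
    region: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_NAMES:
            raise ValueError(
                f"label {self.class_label!r} not in {CLASS_NAMES}"
            )


@dataclass
class ClassMap:
    """H×W integer label image over the four tissue classes."""

    labels: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.class_names.index(name)


@dataclass
class DiscriminantModel:
    """Per-class Gaussian statistics for the quadratic discriminant."""

    class_names: tuple[str, ...]
    means: np.ndarray  # K x B
    covariances: np.ndarray  # K x B x B
    _inv: np.ndarray = field(repr=False, default=None)
    _logdet: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self._inv = np.stack([np.linalg.inv(c) for c in self.covariances])
        sign, logdet = np.linalg.slogdet(self.covariances)
        if np.any(sign <= 0):
            raise ValueError("covariance not positive definite")
        self._logdet = logdet


@dataclass
class BiteDepthParams:
    """Tissue thickness tau, clearance delta, and the derived sigma (mm).

    delta must be at least 0.5 mm (suture-size clearance floor) and small
    enough that sigma = (1.5 tau - delta)/3 stays positive.
    """

    tau_mm: float
    delta_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.tau_mm <= 0:
            raise ValueError("tau_mm must be positive")
        if self.delta_mm < 0.5:
            raise ValueError("delta_mm must be at least 0.5 mm")
        if self.sigma_mm <= 0:
            raise ValueError(
                f"sigma = (1.5*tau - delta)/3 = {self.sigma_mm:.3f} mm <= 0; "
                "delta must be smaller than 1.5*tau"
            )

    @property
    def sigma_mm(self) -> float:
        return (1.5 * self.tau_mm - self.delta_mm) / 3.0


_LOADING_EPS = 1e-6
_LOADING_FLOOR = 1e-12


def train_discriminant(
    stack: MultispectralStack, fields: list[TrainingField]
) -> DiscriminantModel:
    """Estimate per-class means and (regularized) covariances.

    Every class needs at least band-count + 1 training pixels so the
    covariance is estimable; diagonal loading of 1e-6 times the mean
    variance (with a tiny absolute floor for noise-free data) keeps the
    matrices positive definite.
    """
    nb = stack.shape[2]
    pixels_by_class: dict[str, list[np.ndarray]] = {}
    for f in fields:
        r0, r1, c0, c1 = (int(v) for v in f.region)
        h, w, _ = stack.shape
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"training region {f.region} out of bounds")
        pixels_by_class.setdefault(f.class_label, []).append(
            stack.pixels[r0:r1, c0:c1, :].reshape(-1, nb).astype(np.float64)
        )
    means, covs, names = [], [], []
    for name in CLASS_NAMES:
        if name not in pixels_by_class:
            continue
        x = np.concatenate(pixels_by_class[name], axis=0)
        if x.shape[0] < nb + 1:
            raise ValueError(
                f"class {name!r} has {x.shape[0]} training pixels; "
                f"need at least {nb + 1} for a {nb}-band covariance"
            )
        mu = x.mean(axis=0)
        cov = np.cov(x, rowvar=False)
        lam = max(_LOADING_EPS * float(np.trace(cov)) / nb, _LOADING_FLOOR)
        cov = cov + lam * np.eye(nb)
        names.append(name)
        means.append(mu)
        covs.append(cov)
    return DiscriminantModel(tuple(names), np.stack(means), np.stack(covs))


def classify_pixels(stack: MultispectralStack, model: DiscriminantModel) -> ClassMap:
    """Assign each pixel the class maximizing the Gaussian log-likelihood.

    Equal priors; ties break to the lowest class index (deterministic).
    """
    h, w, nb = stack.shape
    if model.means.shape[1] != nb:
        raise ValueError("model band count does not match stack")
    flat = stack.pixels.reshape(-1, nb).astype(np.float64)
    scores = np.empty((flat.shape[0], len(model.class_names)))
    for k in range(len(model.class_names)):
        d = flat - model.means[k]
        maha = np.einsum("ij,jk,ik->i", d, model._inv[k], d)
        scores[:, k] = -0.5 * (maha + model._logdet[k])
    best = np.argmax(scores, axis=1)  # argmax returns the first (lowest) on ties
    # map model class order back onto the canonical CLASS_NAMES indices
    canon = np.asarray([CLASS_NAMES.index(n) for n in model.class_names])
    return ClassMap(canon[best].reshape(h, w))


def extract_cut_edge(class_map: ClassMap, dilation_radius_px: int = 2) -> np.ndarray:
    """Cut-edge mask: dilated inner-lumen AND dilated outer-lumen.

    Non-empty exactly where the two lumen layers come within twice the
    dilation radius of each other, i.e. along the incision line.
    """
    inner = class_map.mask("inner_lumen")
    outer = class_map.mask("outer_lumen")
    if not inner.any() or not outer.any():
        missing = "inner_lumen" if not inner.any() else "outer_lumen"
        raise ValueError(f"class map contains no {missing} pixels; cannot locate cut edge")
    if dilation_radius_px < 0:
        raise ValueError("dilation radius must be non-negative")
    st = disk(dilation_radius_px).astype(bool)
    return ndimage.binary_dilation(inner, st) & ndimage.binary_dilation(outer, st)


def bite_depth_map(
    edge_mask: np.ndarray,
    class_map: ClassMap,
    params: BiteDepthParams,
    pixel_pitch_mm: float,
) -> ScoreMap:
    """Build the bite-depth map B (role ``bite_depth_B``).

    With d the Euclidean distance (mm) to the nearest cut-edge pixel,
    serosal pixels score ``exp(-(d - 1.5 tau)^2 / (2 sigma^2))``; pixels
    closer than delta, and all non-serosa pixels, score 0.
    """
    edge_mask = np.asarray(edge_mask, dtype=bool)
    if not edge_mask.any():
        raise ValueError("empty cut-edge mask")
    d_mm = ndimage.distance_transform_edt(~edge_mask) * pixel_pitch_mm
    target = 1.5 * params.tau_mm
    b = np.exp(-((d_mm - target) ** 2) / (2 * params.sigma_mm**2))
    b[d_mm < params.delta_mm] = 0.0
    b[~class_map.mask("outer_lumen")] = 0.0
    return ScoreMap(np.clip(b, 0.0, 1.0), "bite_depth_B", pixel_pitch_mm)
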
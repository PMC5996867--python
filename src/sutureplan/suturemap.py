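"""Suture-map fusion, local-maximum extraction and equidistant refinement.

The three submaps are fused by elementwise multiplication,

    J(u, v) = V(u, v) * T(u, v) * B(u, v),

so that J is 0 wherever any factor forbids a suture (on a vessel, on thin
tissue, too close to or too far from the cut edge) and close to 1 only
where all three agree.  Candidate placements are the strict 8-neighbor
local maxima of J above a threshold; the final recommendations are an
equidistant subset along the cut edge at the surgical spacing of 1.5
tissue thicknesses, selected greedily from the best-scoring candidate
outward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .io import ScoreMap


@dataclass
class SuturePoint:
    """A recommended (or candidate) placement: position, J score, and the
    signed arc position along the cut edge in mm (None until projected)."""

    position: tuple[int, int]
    score: float
    arc_position_mm: float | None = None


@dataclass
class SuturePlan:
    """Ordered suture recommendations with spacing diagnostics."""

    points: list[SuturePoint]
    spacing_target_mm: float
    spacing_tolerance_frac: float

    def spacings_mm(self) -> np.ndarray:
        arcs = np.asarray([p.arc_position_mm for p in self.points], dtype=float)
        return np.diff(arcs)


def fuse(v: ScoreMap, t: ScoreMap, b: ScoreMap) -> ScoreMap:
    """Elementwise product of the three submaps (role ``suture_J``)."""
    if not (v.shape == t.shape == b.shape):
        raise ValueError("submaps must share shape")
    if not (v.pixel_pitch_mm == t.pixel_pitch_mm == b.pixel_pitch_mm):
        raise ValueError("submaps must share pixel pitch")
    j = v.values * t.values * b.values
    return ScoreMap(j, "suture_J", v.pixel_pitch_mm)


_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def local_maxima(j: ScoreMap | np.ndarray, threshold: float = 0.5) -> list[SuturePoint]:
    """Strict 8-neighbor local maxima of J with value >= threshold.

    Pixels below the threshold are eliminated first; a surviving pixel is a
    candidate iff it is strictly larger than all existing 8-neighbors
    (border pixels are compared against their in-image neighbors only).
    Plateaus therefore yield no candidate.  Candidates are returned sorted
    by descending score, then row, then column.
    """
    values = j.values if isinstance(j, ScoreMap) else np.asarray(j, dtype=np.float64)
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    h, w = values.shape
    padded = np.full((h + 2, w + 2), -np.inf)
    padded[1:-1, 1:-1] = values
    is_max = values >= threshold
    for dr, dc in _SHIFTS:
        is_max &= values > padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
    rows, cols = np.nonzero(is_max)
    pts = [SuturePoint((int(r), int(c)), float(values[r, c])) for r, c in zip(rows, cols)]
    pts.sort(key=lambda p: (-p.score, p.position))
    return pts


def edge_arc_coordinates(
    edge_mask: np.ndarray, pixel_pitch_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length parameterization of the cut edge.

    The edge band is skeletonized to a 1-px curve; the returned path is
    the longest geodesic through the skeleton (ordered pixel coordinates,
    N x 2) together with the cumulative arc length in mm at each pixel.
    """
    skel = skeletonize(np.asarray(edge_mask, dtype=bool))
    coords = np.argwhere(skel)
    if coords.shape[0] == 0:
        raise ValueError("edge mask skeletonizes to nothing")
    if coords.shape[0] == 1:
        return coords.astype(float), np.zeros(1)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(np.sqrt(2) + 1e-9, output_type="ndarray")
    wts = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    n = coords.shape[0]
    graph = coo_matrix(
        (np.r_[wts, wts], (np.r_[pairs[:, 0], pairs[:, 1]], np.r_[pairs[:, 1], pairs[:, 0]])),
        shape=(n, n),
    ).tocsr()
    # restrict to the largest connected component
    ncomp, comp = connected_components(graph, directed=False)
    main = np.argmax(np.bincount(comp))
    start = int(np.nonzero(comp == main)[0][0])
    d0 = dijkstra(graph, directed=False, indices=start)
    a = int(np.nanargmax(np.where(np.isfinite(d0), d0, -1)))
    d1, pred = dijkstra(graph, directed=False, indices=a, return_predecessors=True)
    b = int(np.nanargmax(np.where(np.isfinite(d1), d1, -1)))
    path = [b]
    while path[-1] != a:
        path.append(int(pred[path[-1]]))
    path_coords = coords[path[::-1]]
    steps = np.linalg.norm(np.diff(path_coords, axis=0), axis=1)
    arc_mm = np.concatenate([[0.0], np.cumsum(steps)]) * pixel_pitch_mm
    return path_coords.astype(float), arc_mm


def _project_to_arc(
    candidates: list[SuturePoint], path_coords: np.ndarray, arc_mm: np.ndarray
) -> list[SuturePoint]:
    tree = cKDTree(path_coords)
    out = []
    for p in candidates:
        _, idx = tree.query(np.asarray(p.position, dtype=float))
        out.append(SuturePoint(p.position, p.score, float(arc_mm[idx])))
    return out


def refine_equidistant(
    candidates: list[SuturePoint],
    edge_mask: np.ndarray,
    *,
    spacing_target_mm: float,
    spacing_tolerance_frac: float = 0.25,
    pixel_pitch_mm: float = 1.0,
) -> SuturePlan:
    """Greedy equidistant subset of the candidates along the cut edge.

    Candidates are projected to the nearest skeleton pixel of the cut edge
    and parameterized by arc length.  The plan seeds at the highest-scoring
    candidate (ties: smaller arc position, then row/col) and extends in
    both directions, each step accepting the highest-scoring candidate
    whose arc gap to the last accepted point lies within
    ``spacing_target_mm * (1 ± tolerance)``, stopping when none qualifies.
    An empty candidate list yields an empty plan; if no pair is feasible
    the plan holds the single best candidate.
    """
    plan_args = dict(
        spacing_target_mm=spacing_target_mm,
        spacing_tolerance_frac=spacing_tolerance_frac,
    )
    if not candidates:
        return SuturePlan([], **plan_args)
    path_coords, arc_mm = edge_arc_coordinates(edge_mask, pixel_pitch_mm)
    cands = _project_to_arc(candidates, path_coords, arc_mm)

    def pref(p: SuturePoint):
        return (-p.score, p.arc_position_mm, p.position)

    lo = spacing_target_mm * (1 - spacing_tolerance_frac)
    hi = spacing_target_mm * (1 + spacing_tolerance_frac)
    seed = min(cands, key=pref)
    accepted = [seed]
    remaining = [p for p in cands if p is not seed]
    for direction in (+1, -1):
        last = seed
        while True:
            eligible = [
                p
                for p in remaining
                if lo <= direction * (p.arc_position_mm - last.arc_position_mm) <= hi
            ]
            if not eligible:
                break
            nxt = min(eligible, key=pref)
            accepted.append(nxt)
            remaining.remove(nxt)
            last = nxt
    accepted.sort(key=lambda p: (p.arc_position_mm, p.position))
    return SuturePlan(accepted, **plan_args)
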
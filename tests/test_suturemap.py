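"""Fusion algebra, strict 8-neighbor maxima, equidistant refinement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sutureplan import (
    ScoreMap,
    SuturePoint,
    fuse,
    local_maxima,
    refine_equidistant,
)

PITCH = 0.05


def _smap(values, role):
    return ScoreMap(values, role, PITCH)


def _random_triple(rng, shape=(16, 16)):
    v = _smap(rng.random(shape), "vessel_V")
    t = _smap(rng.random(shape), "thickness_T")
    b = _smap(rng.random(shape), "bite_depth_B")
    return v, t, b


def test_fusion_identity_and_absorbing_zero(rng):
    ones = np.ones((8, 8))
    j = fuse(_smap(ones, "vessel_V"), _smap(ones, "thickness_T"), _smap(ones, "bite_depth_B"))
    assert np.all(j.values == 1.0) and j.role == "suture_J"
    v, t, b = _random_triple(rng, (8, 8))
    b.values[3, 4] = 0.0
    assert fuse(v, t, b).values[3, 4] == 0.0
    v.values[2, 2] = t.values[2, 2] = b.values[2, 2] = 0.5
    assert fuse(v, t, b).values[2, 2] == pytest.approx(0.125, abs=1e-12)


def test_fusion_algebra_on_random_maps(rng):
    for _ in range(100):
        v, t, b = _random_triple(rng)
        zeros = rng.random((16, 16)) < 0.05
        v.values[zeros] = 0.0
        j = fuse(v, t, b)
        np.testing.assert_array_equal(j.values, v.values * t.values * b.values)
        assert np.all(j.values <= np.minimum(np.minimum(v.values, t.values), b.values))
        assert np.all(j.values[zeros] == 0.0)


@settings(max_examples=50, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_fusion_commutative_and_associative(seed):
    rng = np.random.default_rng(seed)
    v, t, b = _random_triple(rng, (8, 8))
    j1 = fuse(v, t, b).values
    j2 = fuse(
        _smap(b.values, "vessel_V"), _smap(v.values, "thickness_T"), _smap(t.values, "bite_depth_B")
    ).values
    np.testing.assert_allclose(j1, j2, atol=1e-15)


def test_fusion_shape_mismatch_rejected(rng):
    v, t, b = _random_triple(rng)
    bad = _smap(np.ones((8, 8)), "bite_depth_B")
    with pytest.raises(ValueError):
        fuse(v, t, bad)


def _maxima_oracle(values, threshold):
    h, w = values.shape
    out = set()
    for r in range(h):
        for c in range(w):
            if values[r, c] < threshold:
                continue
            ok = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and values[r, c] <= values[rr, cc]:
                        ok = False
            if ok:
                out.add((r, c))
    return out


def test_constant_map_has_no_strict_maxima():
    assert local_maxima(np.full((10, 10), 0.8), 0.5) == []


def test_single_peak_found():
    values = np.full((9, 9), 0.1)
    values[4, 5] = 0.9
    pts = local_maxima(values, 0.5)
    assert [p.position for p in pts] == [(4, 5)]
    assert pts[0].score == pytest.approx(0.9)


def test_below_threshold_peaks_eliminated():
    values = np.full((9, 9), 0.1)
    values[2, 2] = 0.4  # genuine peak but under threshold
    values[6, 6] = 0.6
    assert [p.position for p in local_maxima(values, 0.5)] == [(6, 6)]


def test_local_maxima_equal_brute_force_on_random_maps():
    for seed in range(50):
        rng = np.random.default_rng(seed)
        values = rng.random((32, 32))
        got = {p.position for p in local_maxima(values, 0.5)}
        assert got == _maxima_oracle(values, 0.5)


def _straight_edge_mask(length_px=120, row=10, w=130):
    mask = np.zeros((21, w), dtype=bool)
    mask[row, 0:length_px] = True
    return mask


def test_refine_single_candidate_returned():
    edge = _straight_edge_mask()
    plan = refine_equidistant(
        [SuturePoint((12, 40), 0.8)],
        edge,
        spacing_target_mm=1.5,
        pixel_pitch_mm=PITCH,
    )
    assert len(plan.points) == 1
    assert plan.points[0].position == (12, 40)
    assert plan.points[0].arc_position_mm is not None


def test_refine_empty_candidates_empty_plan():
    plan = refine_equidistant(
        [], _straight_edge_mask(), spacing_target_mm=1.5, pixel_pitch_mm=PITCH
    )
    assert plan.points == []


def test_refine_exactly_spaced_candidates_all_kept():
    """Candidates 1.5 mm apart along the edge (tau = 1 mm) all survive."""
    edge = _straight_edge_mask()
    cands = [SuturePoint((12, c), 0.8) for c in (10, 40, 70, 100)]  # 1.5 mm gaps
    plan = refine_equidistant(
        cands,
        edge,
        spacing_target_mm=1.5,
        spacing_tolerance_frac=0.25,
        pixel_pitch_mm=PITCH,
    )
    assert len(plan.points) == 4
    np.testing.assert_allclose(plan.spacings_mm(), 1.5, atol=1e-9)


def _greedy_oracle(arcs, scores, target, tol):
    """Independently coded greedy rule on (arc, score) pairs."""
    lo, hi = target * (1 - tol), target * (1 + tol)
    idx = sorted(range(len(arcs)), key=lambda i: (-scores[i], arcs[i]))
    seed = idx[0]
    accepted = {seed}
    for direction in (+1, -1):
        last = seed
        while True:
            elig = [
                i
                for i in range(len(arcs))
                if i not in accepted and lo <= direction * (arcs[i] - arcs[last]) <= hi
            ]
            if not elig:
                break
            nxt = min(elig, key=lambda i: (-scores[i], arcs[i]))
            accepted.add(nxt)
            last = nxt
    return sorted(accepted, key=lambda i: arcs[i])


def test_refine_matches_greedy_oracle_and_feasibility():
    edge = _straight_edge_mask()
    target, tol = 1.5, 0.25
    lo, hi = target * (1 - tol), target * (1 + tol)
    for seed in range(10):
        rng = np.random.default_rng(seed)
        cols = np.sort(rng.choice(np.arange(5, 115), size=8, replace=False))
        scores = 0.5 + 0.5 * rng.random(8)
        cands = [SuturePoint((12, int(c)), float(s)) for c, s in zip(cols, scores)]
        plan = refine_equidistant(
            cands,
            edge,
            spacing_target_mm=target,
            spacing_tolerance_frac=tol,
            pixel_pitch_mm=PITCH,
        )
        arcs = cols * PITCH
        want = _greedy_oracle(list(arcs), list(scores), target, tol)
        got_cols = sorted(p.position[1] for p in plan.points)
        assert got_cols == sorted(int(cols[i]) for i in want)
        # the greedy selection must be one of the exhaustively enumerated
        # feasible subsets (all consecutive gaps within tolerance)
        feasible = []
        for k in range(1, 9):
            for sub in itertools.combinations(range(8), k):
                gaps = np.diff(arcs[list(sub)])
                if np.all((gaps >= lo) & (gaps <= hi)):
                    feasible.append(set(sub))
        assert set(want) in feasible
        if len(plan.points) > 1:
            gaps = plan.spacings_mm()
            assert np.all((gaps >= lo - 1e-9) & (gaps <= hi + 1e-9))


def test_refine_is_deterministic_under_score_ties():
    edge = _straight_edge_mask()
    cands = [SuturePoint((12, c), 0.7) for c in (10, 40, 70)]
    plans = [
        refine_equidistant(
            list(cands), edge, spacing_target_mm=1.5, pixel_pitch_mm=PITCH
        )
        for _ in range(2)
    ]
    assert [p.position for p in plans[0].points] == [
        p.position for p in plans[1].points
    ]
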
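import numpy as np
import pytest

from specseg.contour_hybrid import (
    ContourParams,
    Type3Constraints,
    classify_type3,
    close_gaps,
    component_perimeter_ring,
    detect_edges,
    enclosed_components,
    hybrid_segment,
)
from specseg.lobe import Component, LobeParams, segment_with_lobes
from specseg.thresholding import ConeParams, cone_segment
from oracles import enclosed_bruteforce


def ring_mask(shape, top, left, height, width):
    """Rectangular one-pixel contour."""
    m = np.zeros(shape, dtype=bool)
    m[top, left : left + width] = True
    m[top + height - 1, left : left + width] = True
    m[top : top + height, left] = True
    m[top : top + height, left + width - 1] = True
    return m


def test_detect_edges_uniform_and_square():
    uniform = np.full((20, 20, 3), 90, dtype=np.uint8)
    assert not detect_edges(uniform).any()
    img = np.full((30, 30, 3), 40, dtype=np.uint8)
    img[10:20, 10:20] = 220
    edges = detect_edges(img)
    # edges form a closed ring around the square: its interior is enclosed
    closed = close_gaps(edges, 1)
    comps = enclosed_components(closed)
    assert len(comps) == 1
    inner = comps[0]
    assert inner.size > 0
    rows, cols = inner.coords[:, 0], inner.coords[:, 1]
    assert rows.min() >= 10 and rows.max() < 20 and cols.min() >= 10 and cols.max() < 20


def test_detect_edges_parameter_validation():
    with pytest.raises(ValueError):
        ContourParams(canny_low=0.3, canny_high=0.2)


def test_close_gaps_is_extensive_and_bridges_one_pixel_gap():
    shape = (15, 15)
    ring = ring_mask(shape, 3, 3, 8, 8)
    closed = close_gaps(ring, 1)
    assert np.all(closed >= ring)
    gapped = ring.copy()
    gapped[3, 6] = False  # open the top edge by one pixel
    assert len(enclosed_components(gapped)) == 0  # fill leaks through the gap
    bridged = close_gaps(gapped, 1)
    assert len(enclosed_components(bridged)) == 1
    assert not close_gaps(np.zeros(shape, dtype=bool), 1).any()


def test_enclosed_components_fixtures_match_flood_fill_oracle():
    shape = (20, 20)
    closed = ring_mask(shape, 4, 4, 10, 10)
    nested = closed | ring_mask(shape, 7, 7, 4, 4)
    open_ring = closed.copy()
    open_ring[4, 8:11] = False  # 3-pixel gap, wider than any closing applied
    # a ring against the border still encloses its interior ...
    border_ring = ring_mask(shape, 0, 0, 6, 6)
    # ... but a U-shape open to the border encloses nothing
    u_shape = ring_mask(shape, 0, 10, 6, 6)
    u_shape[0, 10:16] = False
    cases = ((closed, 1), (nested, 2), (open_ring, 0), (border_ring, 1), (u_shape, 0))
    for edges, n_expected in cases:
        comps = enclosed_components(edges)
        oracle = enclosed_bruteforce(edges)
        assert len(comps) == n_expected == len(oracle)
        got = {frozenset(map(tuple, c.coords)) for c in comps}
        assert got == set(oracle)


def test_perimeter_ring_basic_cases():
    edges = np.zeros((7, 7), dtype=bool)
    center = Component(label=1, coords=np.array([(3, 3)]))
    ring = component_perimeter_ring(center, edges)
    assert {tuple(c) for c in ring} == {
        (i, j) for i in (2, 3, 4) for j in (2, 3, 4) if (i, j) != (3, 3)
    }
    # component filling rows/cols 1..3 of a 5x5 image: ring = 16 border pixels
    big = Component(
        label=1, coords=np.array([(i, j) for i in (1, 2, 3) for j in (1, 2, 3)])
    )
    ring = component_perimeter_ring(big, np.zeros((5, 5), dtype=bool))
    assert ring.shape[0] == 16
    # touching the border: clipped, no out-of-bounds coordinates
    corner = Component(label=1, coords=np.array([(0, 0)]))
    ring = component_perimeter_ring(corner, np.zeros((5, 5), dtype=bool))
    assert {tuple(c) for c in ring} == {(0, 1), (1, 0), (1, 1)}


def test_perimeter_ring_skips_adjacent_contour():
    # with an edge ring around the component, the perimeter ring lies beyond it
    edges = ring_mask((9, 9), 2, 2, 5, 5)
    comp = Component(
        label=1, coords=np.array([(i, j) for i in (3, 4, 5) for j in (3, 4, 5)])
    )
    ring = component_perimeter_ring(comp, edges)
    rows, cols = ring[:, 0], ring[:, 1]
    assert len(ring) > 0
    # strictly outside the 2..6 contour box
    assert np.all((rows < 2) | (rows > 6) | (cols < 2) | (cols > 6))


def make_toy_candidates():
    """Isolated uniform rectangles with known mean, ring mean and size."""
    gray = np.full((40, 240), 50.0)
    specs = []  # (mean, ring_value, height, width)
    cases = [
        (200, 80, 5, 6), (150, 80, 4, 4), (140, 80, 4, 4), (100, 20, 3, 3),
        (220, 180, 4, 5), (180, 150, 2, 3), (255, 0, 1, 6), (130, 100, 5, 5),
        (90, 10, 2, 2), (160, 129, 3, 4), (141, 80, 3, 2), (200, 80, 2, 2),
        (200, 80, 6, 7), (250, 240, 4, 4), (120, 119, 3, 3), (170, 60, 1, 5),
        (200, 170, 5, 4), (110, 40, 4, 6), (135, 90, 2, 5), (245, 100, 3, 5),
    ]
    comps = []
    col = 2
    for i, (mean, ringv, h, w) in enumerate(cases):
        top, left = 10, col
        gray[top - 2 : top + h + 2, left - 2 : left + w + 2] = ringv
        gray[top : top + h, left : left + w] = mean
        coords = np.array([(r, c) for r in range(top, top + h) for c in range(left, left + w)])
        comps.append(Component(label=i + 1, coords=coords))
        specs.append((mean, ringv, h * w))
        col += w + 5
    return gray, comps, specs


@pytest.mark.parametrize(
    "constraints",
    [
        Type3Constraints(t_av=150, t_diff=50, t_cc_min=10, t_cc_max=500),
        Type3Constraints(t_av=100, t_diff=20, t_cc_min=5, t_cc_max=30),
        Type3Constraints(t_av=199, t_diff=119, t_cc_min=4, t_cc_max=31),
        Type3Constraints(t_av=140, t_diff=1, t_cc_min=1, t_cc_max=2000),
        Type3Constraints(t_av=1, t_diff=150, t_cc_min=2, t_cc_max=16),
    ],
)
def test_classify_type3_matches_analytic_subset(constraints):
    gray, comps, specs = make_toy_candidates()
    edges = np.zeros(gray.shape, dtype=bool)
    kept = classify_type3(comps, gray, edges, constraints)
    expected = {
        i + 1
        for i, (mean, ringv, size) in enumerate(specs)
        if mean > constraints.t_av
        and mean - ringv > constraints.t_diff
        and size > constraints.t_cc_min
        and size < constraints.t_cc_max
    }
    assert {c.label for c in kept} == expected


def test_classify_type3_strict_boundaries():
    gray, comps, specs = make_toy_candidates()
    edges = np.zeros(gray.shape, dtype=bool)
    # component 0: mean 200, ring 80, size 30
    baseline = Type3Constraints(t_av=150, t_diff=50, t_cc_min=10, t_cc_max=500)
    assert comps[0] in classify_type3([comps[0]], gray, edges, baseline)
    for tight in (
        Type3Constraints(t_av=200, t_diff=50, t_cc_min=10, t_cc_max=500),
        Type3Constraints(t_av=150, t_diff=120, t_cc_min=10, t_cc_max=500),
        Type3Constraints(t_av=150, t_diff=50, t_cc_min=30, t_cc_max=500),
        Type3Constraints(t_av=150, t_diff=50, t_cc_min=10, t_cc_max=30),
    ):
        assert classify_type3([comps[0]], gray, edges, tight) == []


def test_classify_type3_rejects_low_mean_regardless():
    gray, comps, specs = make_toy_candidates()
    low = [c for c, (m, r, s) in zip(comps, specs) if m == 100][0]
    assert classify_type3(
        [low], gray, np.zeros(gray.shape, dtype=bool),
        Type3Constraints(t_av=150, t_diff=1, t_cc_min=1, t_cc_max=2000),
    ) == []


def test_hybrid_uniform_image_is_empty():
    # uniform tissue color: saturated, far from the gray axis
    uniform = np.zeros((32, 32, 3), dtype=np.uint8)
    uniform[:] = (130, 70, 60)
    res = hybrid_segment(uniform)
    assert not res.union.any()
    assert not (res.type1.any() or res.type2.any() or res.type3.any())


def test_hybrid_bright_square_is_type2_with_contour_boundary():
    img = np.full((30, 30, 3), 40, dtype=np.uint8)
    img[10:20, 10:20] = 230
    cone = ConeParams(x0=150.0, a=0.4)
    assert cone_segment(img, cone)[12:18, 12:18].all()
    res = hybrid_segment(img, cone=cone)
    assert res.type2.any() and not res.type1.any() and not res.type3.any()
    # mask is the enclosed interior plus its contour: inside the square
    rows, cols = np.nonzero(res.type2)
    assert rows.min() >= 9 and rows.max() <= 20


def test_hybrid_degenerates_to_cone_plus_lobe_without_edges(rng):
    # very smooth image: no gradient exceeds the hysteresis thresholds
    img = np.full((24, 24, 3), 60, dtype=np.uint8)
    res = hybrid_segment(img)
    core = cone_segment(img, ConeParams())
    assert np.array_equal(res.union, segment_with_lobes(img, core, LobeParams()))
    # open contour: a half-plane step produces an edge line touching the
    # border, which encloses nothing, so the hybrid degenerates as well
    img2 = np.zeros((40, 40, 3), dtype=np.uint8)
    img2[:, :20] = (130, 70, 60)  # tissue
    img2[:, 20:] = (210, 210, 210)  # bright gray half-plane
    cone = ConeParams(x0=200.0, a=0.5)
    res2 = hybrid_segment(img2, cone=cone)
    from specseg.contour_hybrid import detect_edges, enclosed_components as _enc

    assert detect_edges(img2).any()  # edges exist ...
    assert _enc(close_gaps(detect_edges(img2), 1)) == []  # ... but enclose nothing
    expected = segment_with_lobes(img2, cone_segment(img2, cone), LobeParams())
    assert res2.type1.any()
    assert np.array_equal(res2.union, expected)


def test_hybrid_segments_all_three_types_on_synthetic_scene(small_scene):
    res = hybrid_segment(
        small_scene.image,
        cone=ConeParams(x0=260.0, a=0.3),
        constraints=Type3Constraints(t_av=100.0, t_diff=20.0),
    )
    by_type = {1: [], 2: [], 3: []}
    for lab in small_scene.labels:
        by_type[lab.type_tag].append(lab)
    for t, mask in ((1, res.type1), (2, res.type2), (3, res.type3)):
        assert mask.any(), f"type {t} mask is empty"
        for lab in by_type[t]:
            assert (mask & lab.mask).any(), f"type {t} reflection missed"
    assert np.array_equal(res.union, res.type1 | res.type2 | res.type3)


def test_hybrid_type3_components_never_intersect_threshold_mask(small_scene):
    cone = ConeParams(x0=260.0, a=0.3)
    res = hybrid_segment(
        small_scene.image, cone=cone,
        constraints=Type3Constraints(t_av=100.0, t_diff=20.0),
    )
    s_thresh = cone_segment(small_scene.image, cone)
    for comp in res.components_by_type[3]:
        assert not s_thresh[comp.coords[:, 0], comp.coords[:, 1]].any()
    # type-2 and type-3 component sets are disjoint
    t2 = {frozenset(map(tuple, c.coords)) for c in res.components_by_type[2]}
    t3 = {frozenset(map(tuple, c.coords)) for c in res.components_by_type[3]}
    assert not (t2 & t3)


def test_hybrid_union_monotone_under_relaxed_type3_constraints(small_scene):
    cone = ConeParams(x0=260.0, a=0.3)
    strict = hybrid_segment(
        small_scene.image, cone=cone,
        constraints=Type3Constraints(t_av=130.0, t_diff=40.0, t_cc_min=8, t_cc_max=500),
    )
    relaxed = hybrid_segment(
        small_scene.image, cone=cone,
        constraints=Type3Constraints(t_av=90.0, t_diff=15.0, t_cc_min=3, t_cc_max=3000),
    )
    assert np.all(strict.union <= relaxed.union)
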
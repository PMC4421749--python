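"""Turning-angle curvature statistic: analytic oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from filacoord.curvature import (
    SegmentTooShortError,
    aggregate,
    network_curvature,
    resample_path,
    segment_curvature,
)

PX = 16.0 / 60.0


def circle_path(radius_um, px=PX, n_mult=4, closed=True):
    r_px = radius_um / px
    n = int(round(2 * np.pi * r_px)) * n_mult
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([r_px * np.cos(th), r_px * np.sin(th)])
    if closed:
        pts = np.vstack([pts, pts[:1]])
    return pts


def test_resample_preserves_straight_path():
    line = np.column_stack([np.zeros(50), np.arange(50.0)])
    rs = resample_path(line, step_px=1.0)
    assert np.allclose(rs, line)


def test_resample_preserves_polyline_length():
    # gently curved path, as traced filaments are at the 1-px scale
    x = np.linspace(0, 100, 120)
    pts = np.column_stack([10 * np.sin(x / 20), x])
    orig = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    rs = resample_path(pts, step_px=1.0)
    new = np.linalg.norm(np.diff(rs, axis=0), axis=1).sum()
    assert abs(new - orig) <= 1.0


def test_resample_refines_coarse_circle_arc_length():
    """Chord-length error of a coarsely sampled circle drops below 0.5%
    after 1-px resampling of a dense polygon."""
    r_px = 5.0 / PX
    coarse = circle_path(5.0, n_mult=1)
    rs = resample_path(coarse, step_px=1.0)
    length = np.linalg.norm(np.diff(rs, axis=0), axis=1).sum()
    assert length == pytest.approx(2 * np.pi * r_px, rel=0.005)


def test_degenerate_path_raises():
    with pytest.raises(ValueError):
        resample_path(np.array([[3.0, 3.0]]))


def test_straight_line_curvature_is_exactly_zero():
    line = np.column_stack([np.arange(100.0), np.zeros(100)])
    s = segment_curvature(resample_path(line), spacing_px=10,
                          pixel_size_um=PX)
    assert s.curvature == 0.0
    assert s.length_um == pytest.approx(99 * PX)


@pytest.mark.parametrize("radius_um", [2.0, 5.0, 10.0])
def test_circle_oracle_recovers_analytic_curvature(radius_um):
    """Equal-arc chords on a circle of radius R give (180/pi)/R deg/um."""
    pts = resample_path(circle_path(radius_um), step_px=1.0)
    s = segment_curvature(pts, spacing_px=10, pixel_size_um=PX)
    assert s.curvature == pytest.approx((180 / np.pi) / radius_um, rel=0.02)


def test_too_short_path_is_rejected_with_reason():
    short = np.column_stack([np.arange(15.0), np.zeros(15)])
    with pytest.raises(SegmentTooShortError):
        segment_curvature(short, spacing_px=10, pixel_size_um=PX)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.floats(0, 2 * np.pi), st.floats(-50, 50), st.floats(-50, 50))
def test_curvature_rigid_motion_invariance(theta, dx, dy):
    rng = np.random.default_rng(7)
    pts = np.cumsum(rng.normal(0, 1, size=(80, 2)), axis=0) * 2
    pts = resample_path(pts, 1.0)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    moved = pts @ rot.T + np.array([dx, dy])
    s0 = segment_curvature(pts, 10, PX)
    s1 = segment_curvature(moved, 10, PX)
    assert s1.curvature == pytest.approx(s0.curvature, rel=1e-9, abs=1e-9)


def test_unit_scaling_halves_curvature_when_pixel_doubles():
    rng = np.random.default_rng(11)
    pts = resample_path(np.cumsum(rng.normal(size=(60, 2)), axis=0) * 2, 1.0)
    s1 = segment_curvature(pts, 10, PX)
    s2 = segment_curvature(pts, 10, 2 * PX)
    assert s2.length_um == pytest.approx(2 * s1.length_um)
    assert s2.curvature == pytest.approx(s1.curvature / 2)


def test_aggregate_median_is_self_consistent():
    rng = np.random.default_rng(13)
    samples = []
    for i in range(25):
        pts = resample_path(np.cumsum(rng.normal(size=(60, 2)), axis=0) * 2,
                            1.0)
        samples.append(segment_curvature(pts, 10, PX, segment_id=i))
    res = aggregate(samples, condition="x")
    assert res.median == np.median([s.curvature for s in samples])
    assert res.percentiles[25] <= res.median <= res.percentiles[75]


def test_network_curvature_on_blank_masks_is_empty():
    res = network_curvature([np.zeros((64, 64), bool)], pixel_size_um=PX)
    assert res.samples == []
    assert np.isnan(res.median)


def test_network_curvature_processes_all_long_segments():
    """Straight drawn filaments: every segment yields exactly one sample."""
    masks = []
    for k in range(3):
        m = np.zeros((128, 128), bool)
        for i in range(4):
            m[20 + 25 * i, 10:110] = True
        masks.append(m)
    res = network_curvature(masks, pixel_size_um=PX, smooth_sigma_px=0.0)
    assert len(res.samples) == 12
    assert res.n_rejected == 0
    assert res.median == pytest.approx(0.0, abs=1e-9)


def test_curly_vs_straight_networks_reproduce_bundler_contrast():
    """Low-persistence (fascin-like) networks score orders of magnitude more
    curvature than straightened (tau-like) ones, as the per-condition medians."""
    from filacoord.config import SceneConfig
    from filacoord.synthgen import simulate_scene

    medians = {}
    for lp, label in [(1.0, "curly"), (1e5, "straight")]:
        cfg = SceneConfig(field_size_um=80, n_microtubules=0, n_actin=25,
                          actin_persistence_um=lp, duration_s=400,
                          nucleation_margin_um=15, seed=17)
        gt = simulate_scene(cfg)
        res = network_curvature([gt.actin_masks[-1]], pixel_size_um=PX,
                                min_length_px=25)
        medians[label] = res.median
    assert medians["curly"] > 5 * medians["straight"]
    assert medians["curly"] > 1.0  # fascin-like scale, deg/um
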
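"""Generator ground truth: seeded determinism, worm-like-chain statistics,
zippering, growth bookkeeping, and the biochemistry dataset simulators."""

import numpy as np
import pytest

from filacoord.config import NoiseModel, SceneConfig
from filacoord.synthgen import (
    CHANNEL_ACTIN,
    render_movie,
    simulate_binding,
    simulate_bundling,
    simulate_scene,
)

PX = 16.0 / 60.0


def test_empty_scene_gives_blank_masks():
    cfg = SceneConfig(field_size_um=20, n_microtubules=0, n_actin=0,
                      duration_s=20, seed=0)
    gt = simulate_scene(cfg)
    assert gt.paths == []
    assert not gt.mt_masks.any()
    assert not gt.actin_masks.any()


def test_zero_duration_scene_is_single_frame():
    cfg = SceneConfig(field_size_um=20, duration_s=0.0, n_microtubules=2,
                      n_actin=2, seed=1)
    gt = simulate_scene(cfg)
    assert gt.n_frames == 1


def test_field_too_small_raises():
    cfg = SceneConfig(field_size_um=8.0, nucleation_margin_um=5.0,
                      n_microtubules=1, n_actin=0)
    with pytest.raises(ValueError, match="field too small"):
        simulate_scene(cfg)


def test_seeded_determinism_bit_identical():
    cfg = SceneConfig(field_size_um=30, duration_s=150, n_microtubules=4,
                      n_actin=6, zip_probability=0.5, seed=9)
    g1, g2 = simulate_scene(cfg), simulate_scene(cfg)
    for p1, p2 in zip(g1.paths, g2.paths):
        assert np.array_equal(p1.vertices, p2.vertices)
        assert np.array_equal(p1.zipped, p2.zipped)
    assert np.array_equal(g1.mt_masks, g2.mt_masks)
    assert np.array_equal(g1.actin_masks, g2.actin_masks)
    s1 = render_movie(g1)
    s2 = render_movie(g2)
    assert np.array_equal(s1[0].data, s2[0].data)
    assert np.array_equal(s1[1].data, s2[1].data)


def test_arc_length_tracks_growth_rate_within_one_step():
    cfg = SceneConfig(field_size_um=80, duration_s=300, n_microtubules=3,
                      n_actin=4, nucleation_margin_um=20, seed=11)
    gt = simulate_scene(cfg)
    ds = cfg.pixel_size_um
    for frame in (0, gt.n_frames // 2, gt.n_frames - 1):
        t = frame * cfg.frame_interval_s
        for p in gt.paths:
            if p.stopped:
                continue
            target = p.growth_rate_um_min / 60.0 * max(t - p.birth_time_s, 0)
            assert abs(p.length_um(ds, frame) - target) <= ds + 1e-9


@pytest.mark.parametrize("lp", [10.0, 100.0])
def test_wlc_step_angle_variance_matches_ds_over_lp(lp):
    """Per-step turning-angle variance of generated paths equals ds/Lp."""
    cfg = SceneConfig(field_size_um=120, n_microtubules=0, n_actin=100,
                      actin_persistence_um=lp, duration_s=300,
                      nucleation_margin_um=25, seed=42)
    gt = simulate_scene(cfg)
    angs = []
    for p in gt.channel_paths(CHANNEL_ACTIN):
        d = np.diff(p.vertices, axis=0)
        th = np.arctan2(d[:, 1], d[:, 0])
        dth = np.diff(th)
        angs.append((dth + np.pi) % (2 * np.pi) - np.pi)
    var = np.concatenate(angs).var()
    expected = cfg.pixel_size_um / lp
    assert var == pytest.approx(expected, rel=0.10)


def test_curvature_statistic_decreases_with_persistence_length():
    from filacoord.curvature import resample_path, segment_curvature

    medians = {}
    for lp in (10.0, 100.0, 1e6):
        cfg = SceneConfig(field_size_um=120, n_microtubules=0, n_actin=60,
                          actin_persistence_um=lp, duration_s=300,
                          nucleation_margin_um=25, seed=7)
        gt = simulate_scene(cfg)
        curvs = [
            segment_curvature(resample_path(p.vertices / PX, 1.0), 10,
                              PX).curvature
            for p in gt.channel_paths(CHANNEL_ACTIN)
        ]
        medians[lp] = np.median(curvs)
    assert medians[10.0] > medians[100.0] > medians[1e6]
    # straightness limit: stiff filaments measure as straight
    assert medians[1e6] < 0.1


def test_dense_microtubule_zippering_captures_most_actin_arc():
    cfg = SceneConfig(field_size_um=60, n_microtubules=120, n_actin=10,
                      zip_probability=1.0, capture_radius_um=1.0,
                      actin_persistence_um=10, duration_s=700,
                      actin_birth_time_s=500, nucleation_margin_um=8, seed=5)
    gt = simulate_scene(cfg)
    assert gt.zipped_arc_fraction() >= 0.8
    # zip events recorded on the paths themselves
    assert any(p.zip_events for p in gt.channel_paths(CHANNEL_ACTIN))


def test_zip_off_channels_are_statistically_independent():
    """Chance-level control: overlap equals actin coverage on label masks."""
    from filacoord.coalign import overlap_fraction

    pcts, covs = [], []
    for seed in range(30):
        cfg = SceneConfig(field_size_um=40, n_microtubules=10, n_actin=12,
                          zip_probability=0.0, duration_s=300,
                          nucleation_margin_um=3, seed=300 + seed)
        gt = simulate_scene(cfg)
        p = overlap_fraction(gt.mt_masks[-1], gt.actin_masks[-1])
        if not np.isnan(p):
            pcts.append(p)
            covs.append(100.0 * gt.actin_masks[-1].mean())
    pcts = np.asarray(pcts)
    tol = 3.0 * pcts.std(ddof=1) / np.sqrt(len(pcts))
    assert abs(pcts.mean() - np.mean(covs)) <= tol


def test_render_blank_scene_is_noise_only_background():
    cfg = SceneConfig(field_size_um=30, n_microtubules=0, n_actin=0,
                      duration_s=10, seed=1)
    mt, actin = render_movie(simulate_scene(cfg))
    nm = cfg.noise_model
    se = np.sqrt(nm.background + nm.read_noise_sd**2) / np.sqrt(mt.data.size)
    assert abs(mt.data.mean() - nm.background) < 2 * se
    assert abs(actin.data.mean() - nm.background) < 2 * se


def test_render_single_filament_segmentation_recovers_labels(single_mt_movie):
    from filacoord.imgseg import segment_channel

    cfg, gt, mt_stack = single_mt_movie
    mask = segment_channel(mt_stack.data[-1], pixel_size_um=cfg.pixel_size_um)
    label = gt.mt_masks[-1]
    recall = (mask.pixels & label).sum() / label.sum()
    assert recall >= 0.95


def test_undersampled_psf_warns():
    cfg = SceneConfig(field_size_um=20, duration_s=10, n_microtubules=1,
                      n_actin=0, psf_sigma_um=0.05, nucleation_margin_um=5,
                      seed=3)
    gt = simulate_scene(cfg)
    with pytest.warns(UserWarning, match="undersampled"):
        render_movie(gt)


# -- biochemistry simulators -------------------------------------------------

def test_binding_half_saturation_identity():
    kd_nM = 250.0
    c = np.array([0.05, 0.1, kd_nM / 1000.0, 1.0])
    (ds,) = simulate_binding(kd_nM, 80.0, c, noise_sd_pct=0.0,
                             n_replicates=1, seed=0)
    assert ds.fraction_bound_pct[2] == pytest.approx(40.0)


def test_binding_rejects_all_zero_concentrations():
    with pytest.raises(ValueError, match="unidentifiable|increasing"):
        simulate_binding(100.0, 100.0, np.zeros(4), 0.0, 1, 0)


def test_bundling_half_saturation_and_zero_dose():
    ds = simulate_bundling(0.5, 90.0, np.array([0.0, 0.5, 4.0]),
                           noise_sd_pct=0.0, seed=0)
    assert ds.pellet_fraction_pct[0] == 0.0
    assert ds.pellet_fraction_pct[1] == pytest.approx(45.0)


def test_bundling_monotone_in_expectation():
    c = np.array([0.0, 0.2, 0.5, 1.0, 2.0, 4.0])
    mean = np.mean(
        [simulate_bundling(0.5, 90.0, c, 8.0, seed=s).pellet_fraction_pct
         for s in range(100)], axis=0)
    assert np.all(np.diff(mean) > -0.5)
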
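"""Scene simulator: determinism, containment, placement distributions."""

import numpy as np
import pytest

from nbprox.scene_sim import (
    Nucleus,
    PlacementError,
    SceneConfig,
    generate_scene,
    generate_truth,
    place_foci,
    render,
    truth_to_label_map,
)


def test_identical_config_and_seed_is_bit_identical(noisefree_cfg):
    cfg = noisefree_cfg.with_(shot_noise=True, background_level=5.0, read_noise_sd=1.0)
    s1, t1 = generate_scene(cfg, seed=3)
    s2, t2 = generate_scene(cfg, seed=3)
    assert np.array_equal(s1.data, s2.data)
    assert np.array_equal(t1.true_nearest_distances(), t2.true_nearest_distances())


def test_empty_scene_is_background_only():
    cfg = SceneConfig(
        field_shape=(8, 32, 32), n_nuclei=0,
        shot_noise=False, background_level=0.0, read_noise_sd=0.0,
    )
    stack, truth = generate_scene(cfg, seed=0)
    assert truth.nuclei == [] and truth.bodies == [] and truth.foci == []
    assert np.all(stack.data == 0)


def test_all_objects_inside_rasterized_nucleus_mask():
    cfg = SceneConfig(
        field_shape=(24, 192, 192),
        n_nuclei=3,
        nucleus_radii_um=((1.2, 1.6), (2.4, 3.2)),
        n_bodies_per_nucleus=3,
        n_foci_per_nucleus=2,
    )
    truth = generate_truth(cfg, seed=5)
    labels = truth_to_label_map(truth, cfg).labels
    voxel = np.asarray(cfg.voxel_size)
    for obj in truth.bodies + truth.foci:
        idx = tuple(np.floor(obj.position_um / voxel).astype(int))
        assert labels[idx] == obj.nucleus_id


def test_true_nearest_distance_matches_brute_force():
    cfg = SceneConfig(
        field_shape=(24, 192, 192), n_nuclei=2,
        nucleus_radii_um=((1.2, 1.6), (2.4, 3.2)),
        n_bodies_per_nucleus=4, n_foci_per_nucleus=3,
    )
    truth = generate_truth(cfg, seed=9)
    for focus in truth.foci:
        same = [b for b in truth.bodies if b.nucleus_id == focus.nucleus_id]
        brute = min(np.linalg.norm(focus.position_um - b.position_um) for b in same)
        assert focus.nearest_distance_um == pytest.approx(brute, abs=1e-12)


def test_degenerate_tether_places_focus_on_body():
    cfg = SceneConfig(
        n_nuclei=1, n_bodies_per_nucleus=1, n_foci_per_nucleus=1,
        placement_mode="tethered", tether_mean_um=0.0, tether_sd_um=0.0,
        min_separation_um=0.0,
    )
    truth = generate_truth(cfg, seed=2)
    assert truth.foci[0].nearest_distance_um == pytest.approx(0.0, abs=1e-12)


def test_zero_sd_tether_gives_exact_programmed_distance():
    cfg = SceneConfig(
        n_nuclei=1, n_bodies_per_nucleus=1, n_foci_per_nucleus=1,
        placement_mode="tethered", tether_mean_um=1.0, tether_sd_um=0.0,
        min_separation_um=0.0,
    )
    truth = generate_truth(cfg, seed=4)
    assert truth.foci[0].nearest_distance_um == pytest.approx(1.0, abs=1e-9)


def test_csr_radius_cdf_matches_uniform_in_ball(rng):
    # uniform in a ball of radius R: P(r <= x) = (x/R)^3
    R = 5.0
    nucleus = Nucleus(id=1, center_um=np.zeros(3), semi_axes_um=np.full(3, R))
    pts = place_foci(nucleus, np.empty((0, 3)), "csr", rng, n=10_000)
    r = np.sort(np.linalg.norm(pts, axis=1))
    ecdf = np.arange(1, r.size + 1) / r.size
    ks = np.max(np.abs(ecdf - (r / R) ** 3))
    assert ks < 0.02


def test_tethered_distances_match_truncated_normal_mean(rng):
    mean, sd = 1.4, 0.3
    nucleus = Nucleus(id=1, center_um=np.zeros(3), semi_axes_um=np.full(3, 10.0))
    body = np.zeros((1, 3))
    pts = place_foci(
        nucleus, body, "tethered", rng, n=10_000,
        tether_mean_um=mean, tether_sd_um=sd,
    )
    r = np.linalg.norm(pts, axis=1)
    # truncation at zero is negligible at mean/sd ~ 4.7, so the
    # truncated-normal mean is the plain mean to float precision
    assert abs(r.mean() - mean) < 3 * sd / np.sqrt(r.size)


def test_tethered_requires_a_body(rng):
    nucleus = Nucleus(id=1, center_um=np.zeros(3), semi_axes_um=np.full(3, 5.0))
    with pytest.raises(ValueError, match="at least one body"):
        place_foci(nucleus, np.empty((0, 3)), "tethered", rng, n=1)


def test_crowded_field_raises_placement_error():
    cfg = SceneConfig(
        field_shape=(16, 64, 64),  # 4 x 6.4 x 6.4 um: no room for 4 nuclei
        n_nuclei=4,
        nucleus_radii_um=((1.2, 1.4), (2.4, 2.8)),
    )
    with pytest.raises(PlacementError, match="crowded|fit"):
        generate_truth(cfg, seed=0)


def test_render_peak_at_true_position(noisefree_cfg):
    cfg = noisefree_cfg.with_(n_foci_per_nucleus=1, n_bodies_per_nucleus=1)
    stack, truth = generate_scene(cfg, seed=8)
    peak = np.unravel_index(np.argmax(stack.channel("foci")), stack.spatial_shape)
    true_vox = np.floor(
        truth.foci[0].position_um / np.asarray(cfg.voxel_size)
    ).astype(int)
    assert np.all(np.abs(np.asarray(peak) - true_vox) <= 1)


def test_zero_photon_scale_renders_empty_spot_channels(noisefree_cfg):
    cfg = noisefree_cfg.with_(photon_scale=0.0)
    stack, _ = generate_scene(cfg, seed=6)
    assert np.all(stack.channel("foci") == 0)
    assert np.all(stack.channel("bodies") == 0)


def test_config_validation_rejects_bad_parameters():
    with pytest.raises(ValueError):
        SceneConfig(voxel_size=(0.25, 0.0, 0.1))
    with pytest.raises(ValueError):
        SceneConfig(placement_mode="sideways")
    with pytest.raises(ValueError):
        SceneConfig(placement_mode="tethered", tether_mean_um=50.0)
    with pytest.raises(ValueError):
        SceneConfig(nucleus_radii_um=((2.0, 1.0), (4.0, 5.0)))
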
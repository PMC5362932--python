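"""Segmentation and detection against simulator ground truth."""

import numpy as np
import pytest

from nbprox.image_ops import (
    ImageStack,
    NucleusLabelMap,
    detect_foci,
    segment_nuclei,
    weighted_centroid,
)
from nbprox.scene_sim import generate_scene
from nbprox.studies import match_points


# ---------------------------------------------------------------------------
# weighted_centroid

@pytest.mark.parametrize(
    "indices,weights,voxel,expected",
    [
        # single voxel: centre convention (index + 0.5) * voxel_size
        ([(2, 3, 4)], [1.0], (0.25, 0.10, 0.10), (0.625, 0.35, 0.45)),
        # two equal voxels: symmetry midpoint
        ([(0, 0, 0), (0, 0, 2)], [1.0, 1.0], (1, 1, 1), (0.5, 0.5, 1.5)),
    ],
)
def test_weighted_centroid_voxel_centre_convention(indices, weights, voxel, expected):
    out = weighted_centroid(np.array(indices), np.array(weights), voxel)
    assert out == pytest.approx(expected, abs=1e-12)


def test_weighted_centroid_matches_explicit_loop(rng):
    block = rng.uniform(0.1, 1.0, size=(3, 3, 3))
    voxel = (0.25, 0.10, 0.10)
    idx = np.argwhere(block >= 0)
    out = weighted_centroid(idx, block[tuple(idx.T)], voxel)
    expected = np.zeros(3)
    total = 0.0
    for i in range(3):
        for j in range(3):
            for k in range(3):
                pos = (np.array([i, j, k]) + 0.5) * np.asarray(voxel)
                expected += block[i, j, k] * pos
                total += block[i, j, k]
    assert out == pytest.approx(expected / total, rel=1e-9)


def test_weighted_centroid_rejects_zero_intensity():
    with pytest.raises(ValueError, match="positive"):
        weighted_centroid(np.array([[0, 0, 0]]), np.array([0.0]), (1, 1, 1))


# ---------------------------------------------------------------------------
# segment_nuclei

def test_all_zero_channel_yields_no_nuclei():
    stack = ImageStack(np.zeros((1, 8, 16, 16)), (0.25, 0.1, 0.1), ("dna",))
    assert segment_nuclei(stack, "dna").n_labels == 0


def test_two_disjoint_nuclei_found_with_accurate_centroids():
    cfg_kwargs = dict(
        field_shape=(24, 192, 192),
        n_nuclei=2,
        nucleus_radii_um=((1.2, 1.6), (2.4, 3.2)),
        n_bodies_per_nucleus=1,
        n_foci_per_nucleus=1,
        shot_noise=False,
        background_level=0.0,
        read_noise_sd=0.0,
    )
    from nbprox.scene_sim import SceneConfig

    cfg = SceneConfig(**cfg_kwargs)
    stack, truth = generate_scene(cfg, seed=21)
    nuclei = segment_nuclei(stack, "dna", min_volume_voxels=64)
    assert nuclei.n_labels == 2
    centroids = np.vstack(list(nuclei.centroids_um().values()))
    true_centres = np.vstack([n.center_um for n in truth.nuclei])
    errs = match_points(centroids, true_centres)
    voxel_diag = np.linalg.norm(cfg.voxel_size)
    assert np.all(errs < voxel_diag)


def test_sphere_volume_within_ten_percent():
    # solid sphere of radius 10 voxels on zero background
    r = 10
    z, y, x = np.ogrid[-15:16, -15:16, -15:16]
    sphere = (z**2 + y**2 + x**2 <= r**2).astype(float) * 100.0
    stack = ImageStack(sphere[None], (1, 1, 1), ("dna",))
    nuclei = segment_nuclei(stack, "dna", min_volume_voxels=10)
    volume = list(nuclei.voxel_counts().values())[0]
    assert volume == pytest.approx(4 / 3 * np.pi * r**3, rel=0.10)


def test_labels_ordered_by_descending_volume():
    vol = np.zeros((4, 32, 32))
    vol[1, 2:6, 2:6] = 50.0     # 16 voxels
    vol[1, 12:28, 12:28] = 50.0  # 256 voxels
    stack = ImageStack(vol[None], (1, 1, 1), ("dna",))
    nuclei = segment_nuclei(stack, "dna", min_volume_voxels=4)
    counts = nuclei.voxel_counts()
    assert counts[1] > counts[2]


# ---------------------------------------------------------------------------
# detect_foci

def _sphere_labels(shape, centre, radius, voxel=(1.0, 1.0, 1.0)):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g + 0.5) - c) ** 2 for g, c in zip(grids, centre))
    return NucleusLabelMap((d2 <= radius**2).astype(np.int32), voxel)


def test_blob_outside_nuclei_is_discarded():
    labels = _sphere_labels((16, 32, 32), (8, 8, 8), 6)
    vol = np.zeros((16, 32, 32))
    vol[8, 24:26, 24:26] = 100.0  # bright blob far outside the nucleus
    stack = ImageStack(np.stack([vol, vol]), (1, 1, 1), ("dna", "spots"))
    out = detect_foci(stack, "spots", labels, threshold_method="absolute",
                      threshold_value=10.0, min_voxels=2)
    assert len(out) == 0


def test_min_voxels_filter_removes_small_components():
    labels = _sphere_labels((16, 32, 32), (8, 16, 16), 10)
    vol = np.zeros((16, 32, 32))
    vol[8, 16, 16:18] = 100.0  # 2-voxel blob inside the nucleus
    stack = ImageStack(np.stack([vol, vol]), (1, 1, 1), ("dna", "spots"))
    kwargs = dict(threshold_method="absolute", threshold_value=10.0)
    assert len(detect_foci(stack, "spots", labels, min_voxels=3, **kwargs)) == 0
    assert len(detect_foci(stack, "spots", labels, min_voxels=2, **kwargs)) == 1


def test_detection_invariant_to_global_intensity_scaling(noisefree_cfg):
    cfg = noisefree_cfg.with_(shot_noise=True, background_level=10.0, read_noise_sd=2.0)
    stack, _ = generate_scene(cfg, seed=13)
    nuclei = segment_nuclei(stack, "dna", min_volume_voxels=64)
    base = detect_foci(stack, "foci", nuclei)
    scaled_stack = ImageStack(stack.data * 7.3, stack.voxel_size, stack.channel_names)
    nuclei2 = segment_nuclei(scaled_stack, "dna", min_volume_voxels=64)
    scaled = detect_foci(scaled_stack, "foci", nuclei2)
    assert len(base) == len(scaled)
    assert base.positions() == pytest.approx(scaled.positions(), abs=1e-9)


def test_noise_free_blob_centroid_matches_truth(noisefree_scene, noisefree_cfg):
    stack, truth = noisefree_scene
    nuclei = segment_nuclei(stack, "dna", min_volume_voxels=64)
    foci = detect_foci(stack, "foci", nuclei, min_voxels=2)
    assert len(foci) == len(truth.foci)
    errs = match_points(
        foci.positions(), np.vstack([o.position_um for o in truth.foci])
    )
    assert errs.max() < np.linalg.norm(noisefree_cfg.voxel_size) / 2


def test_every_focus_assigned_to_existing_nucleus(noisefree_scene):
    stack, _ = noisefree_scene
    nuclei = segment_nuclei(stack, "dna", min_volume_voxels=64)
    foci = detect_foci(stack, "foci", nuclei, min_voxels=2)
    valid = set(int(k) for k in nuclei.label_ids)
    assert all(f.nucleus_id in valid for f in foci.foci)


def test_single_plane_stack_uses_2d_connectivity():
    # two diagonal-touching spots: 8-connectivity joins them in 2D mode
    vol = np.zeros((1, 16, 16))
    vol[0, 4:8, 4:8] = 100.0
    labels = _sphere_labels((1, 16, 16), (0.5, 8, 8), 7.5)
    vol[0, 5, 5] = 100.0
    spots = np.zeros((1, 16, 16))
    spots[0, 6, 6] = 50.0
    spots[0, 7, 7] = 50.0  # touches only diagonally
    stack = ImageStack(np.stack([vol, spots]), (1, 1, 1), ("dna", "spots"))
    out = detect_foci(stack, "spots", labels, threshold_method="absolute",
                      threshold_value=10.0, min_voxels=1)
    assert len(out) == 1  # one 8-connected component, not two


def test_shape_mismatch_raises():
    labels = _sphere_labels((8, 16, 16), (4, 8, 8), 3)
    stack = ImageStack(np.zeros((1, 8, 16, 8)), (1, 1, 1), ("spots",))
    with pytest.raises(ValueError, match="shape"):
        detect_foci(stack, "spots", labels)
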
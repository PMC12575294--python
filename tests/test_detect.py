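"""Detection core: thresholding, AND-masking, block flood fill, dedup,
size filter, and their invariants against an independent labeling oracle."""

import numpy as np
import pytest
from scipy import ndimage

import mfquant as m
from mfquant.detect import (
    DetectionParams,
    and_mask,
    dedup_clusters,
    detect_clusters,
    filter_small,
    threshold_channel,
)

from conftest import random_mask


def oracle_label(mask: np.ndarray, connectivity: int = 4):
    """Independent connected-component labeling (scipy.ndimage)."""
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    lab, n = ndimage.label(mask, structure=structure)
    areas = np.bincount(lab.ravel())[1:]
    return lab, n, sorted(areas.tolist())


def cluster_signature(table):
    """Order-independent signature: sorted (canonical pixel, area)."""
    return sorted((c.canonical_pixel, c.area_px) for c in table.clusters)


# --- thresholding ----------------------------------------------------------


@pytest.mark.parametrize(
    "value,threshold,expected",
    [
        (515, 515, False),  # strictly-above rule: equality is excluded
        (0, 0, False),
        (516, 515, True),
        (351, 350, True),
    ],
)
def test_threshold_is_strict(value, threshold, expected):
    img = np.full((8, 8), value, dtype=np.uint16)
    mask = threshold_channel(img, threshold)
    assert mask.all() == expected and mask.any() == expected


def test_threshold_monotone_in_threshold():
    img = (np.random.default_rng(0).random((64, 64)) * 1000).astype(np.uint16)
    counts = [threshold_channel(img, t).sum() for t in (100, 300, 500, 700)]
    assert counts == sorted(counts, reverse=True)


def test_and_mask_properties():
    rng = np.random.default_rng(1)
    a = rng.random((32, 32)) < 0.5
    b = rng.random((32, 32)) < 0.5
    assert np.array_equal(and_mask(a, a), a)  # idempotent
    assert not and_mask(a, np.zeros_like(a)).any()
    assert not and_mask(a, ~a).any()  # disjoint
    with pytest.raises(m.ParameterError):
        and_mask(a, np.zeros((16, 16), dtype=bool))


# --- flood fill vs oracle --------------------------------------------------


def test_solid_rectangle_single_cluster():
    mask = np.zeros((100, 100), dtype=bool)
    mask[40:60, 45:55] = True  # 20 x 10 rectangle
    table = dedup_clusters(detect_clusters(mask, DetectionParams()))
    assert len(table) == 1
    assert table.clusters[0].area_px == 200
    assert table.clusters[0].canonical_pixel == (40, 45)
    assert table.clusters[0].centroid == pytest.approx((49.5, 49.5))


@pytest.mark.parametrize("connectivity", [4, 8])
@pytest.mark.parametrize("seed", range(8))
def test_stride1_matches_oracle(seed, connectivity):
    """At stride 1, block flood fill equals exhaustive labeling."""
    density = 0.005 + 0.045 * seed / 7
    mask = random_mask(seed, density=density)
    params = DetectionParams(
        seed_stride=1, block_size=100, connectivity=connectivity
    )
    table = dedup_clusters(detect_clusters(mask, params))
    _, n, areas = oracle_label(mask, connectivity)
    assert len(table) == n
    assert sorted(table.areas_px.tolist()) == areas
    # conservation with stride 1: every true pixel is assigned exactly once
    assert table.total_area_px == int(mask.sum())
    assert table.n_unassigned_px == 0


def test_stride1_pixel_sets_match_oracle():
    mask = random_mask(3, shape=(256, 256), density=0.02)
    table = dedup_clusters(
        detect_clusters(mask, DetectionParams(seed_stride=1, block_size=100))
    )
    lab, n, _ = oracle_label(mask)
    for c in table.clusters:
        labels = lab[c.pixels[:, 0], c.pixels[:, 1]]
        assert np.all(labels == labels[0]) and labels[0] > 0
        assert (lab == labels[0]).sum() == c.area_px


@pytest.mark.parametrize("block_size", [100, 250, 500])
def test_block_size_invariance(block_size):
    mask = random_mask(11, shape=(700, 900), density=0.01)
    ref = dedup_clusters(
        detect_clusters(mask, DetectionParams(seed_stride=1, block_size=130))
    )
    table = dedup_clusters(
        detect_clusters(
            mask, DetectionParams(seed_stride=1, block_size=block_size)
        )
    )
    assert cluster_signature(table) == cluster_signature(ref)


def test_block_traversal_order_invariance():
    mask = random_mask(5, shape=(600, 600), density=0.02)
    params = DetectionParams(seed_stride=1, block_size=200)
    fwd = dedup_clusters(detect_clusters(mask, params))
    n_blocks = 9
    rev = dedup_clusters(
        detect_clusters(mask, params, block_order=range(n_blocks - 1, -1, -1))
    )
    perm = np.random.default_rng(0).permutation(n_blocks)
    shuf = dedup_clusters(detect_clusters(mask, params, block_order=perm))
    assert cluster_signature(fwd) == cluster_signature(rev) == cluster_signature(shuf)


def test_cross_block_cluster_deduped_once():
    """A blob straddling the block boundary is found from both blocks and
    reported once, with both source blocks recorded."""
    mask = np.zeros((100, 1000), dtype=bool)
    mask[10:40, 480:520] = True  # straddles the column-500 boundary
    params = DetectionParams(seed_stride=1, block_size=500)
    raw = detect_clusters(mask, params)
    assert len(raw) == 2  # one discovery per seeding block
    table = dedup_clusters(raw)
    assert len(table) == 1
    assert table.clusters[0].source_blocks == {0, 1}
    assert table.clusters[0].area_px == 30 * 40


def test_stride_soundness_any_seeded_cluster_found_once():
    """With default stride 4, clusters holding a seed candidate are found
    exactly once; unassigned pixels are reported for audit."""
    mask = np.zeros((64, 64), dtype=bool)
    mask[10:30, 10:30] = True  # 400 px, certainly contains stride-4 seeds
    table = dedup_clusters(detect_clusters(mask, DetectionParams(block_size=64)))
    assert len(table) == 1 and table.clusters[0].area_px == 400
    assert table.n_unassigned_px == 0


def test_empty_mask_empty_table():
    table = detect_clusters(np.zeros((50, 50), dtype=bool), DetectionParams())
    assert len(table) == 0 and table.n_unassigned_px == 0


# --- filtering -------------------------------------------------------------


def test_filter_small_boundary():
    """150-px minimum keeps clusters at exactly 150 px (strictly smaller
    removed)."""
    mask = np.zeros((60, 600), dtype=bool)
    mask[10:20, 10:25] = True  # 150 px  (10 x 15)
    mask[30:40, 100:115] = True
    mask[30:40, 200:215] = True
    mask[45:52, 300:321] = True  # 147 px (7 x 21)
    mask[2:9, 400:423] = True  # 161 px (7 x 23)
    table = dedup_clusters(detect_clusters(mask, DetectionParams(seed_stride=1)))
    areas = sorted(table.areas_px.tolist())
    assert areas == [147, 150, 150, 150, 161]
    kept = filter_small(table, 150)
    assert sorted(kept.areas_px.tolist()) == [150, 150, 150, 161]
    assert len(filter_small(table, 1)) == len(table)


def test_filter_empty_table():
    table = detect_clusters(np.zeros((20, 20), dtype=bool), DetectionParams())
    assert len(filter_small(table, 150)) == 0


# --- full pipeline ---------------------------------------------------------


def test_ground_truth_consistency_zero_noise(clean_scene, clean_image):
    """Zero noise: detected clusters equal the scene's true clusters."""
    table = m.run_detection(clean_image)
    assert len(table) == clean_scene.n_true_clusters
    # detected areas match the scene's ideal thresholded footprints
    assert sorted(table.areas_px.tolist()) == sorted(
        c.footprint_px for c in clean_scene.clusters
    )


def test_distractors_only_yield_no_clusters():
    scene = m.make_scene(
        (400, 400),
        n_somata=0,
        distractors_per_channel=25,
        soma_radius_px=40,
        noise=m.NoiseSpec(gaussian_sd=0.0, baseline=0.0),
        seed=3,
    )
    img = m.render(scene)
    post = threshold_channel(img.channel(m.CHAN_POST), 515)
    pre = threshold_channel(img.channel(m.CHAN_PRE), 350)
    assert post.any() and pre.any()  # distractors do light up singly
    assert not and_mask(post, pre).any()  # but never colocalize
    assert len(m.run_detection(img)) == 0


def test_run_detection_frozen_regression(small_scene, small_image):
    """Frozen count and total area for the standard seeded fixture."""
    table = m.run_detection(small_image, image_id="fixture42")
    assert len(table) == 12
    assert table.total_area_px == 3097
    assert len(table) == small_scene.n_true_clusters


def test_run_detection_missing_channel_rejected(small_image):
    img = m.Micrograph(
        pixels=small_image.pixels[:1],
        channel_names=("postsynaptic",),
        pixel_scale=small_image.pixel_scale,
    )
    with pytest.raises(m.ChannelError):
        m.run_detection(img)


def test_roi_restricts_detection(clean_image, clean_scene):
    roi = np.zeros(clean_image.shape, dtype=bool)
    roi[:, :300] = True
    table = m.run_detection(clean_image, roi=roi)
    full = m.run_detection(clean_image)
    assert 0 < len(table) <= len(full)
    assert all(c.pixels[:, 1].max() < 300 + 1 for c in table.clusters)


def test_and_mask_pixel_count_monotone_in_thresholds(small_image):
    post = small_image.channel(m.CHAN_POST)
    pre = small_image.channel(m.CHAN_PRE)
    counts = [
        and_mask(
            threshold_channel(post, tp), threshold_channel(pre, 350)
        ).sum()
        for tp in (400, 515, 700, 1200)
    ]
    assert counts == sorted(counts, reverse=True)


def test_detection_params_validation():
    with pytest.raises(m.ParameterError):
        DetectionParams(threshold_post=-1)
    with pytest.raises(m.ParameterError):
        DetectionParams(min_cluster_px=0)
    with pytest.raises(m.ParameterError):
        DetectionParams(connectivity=6)
    with pytest.raises(m.ParameterError):
        DetectionParams(seed_stride=0)
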
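"""Phantom generator: geometry, intensity statistics and determinism."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops

import sinocad as sc
from sinocad.phantom import count_intensity_modes


def test_determinism_volume_and_truth():
    cfg = sc.PhantomConfig(seed=11)
    v1, t1 = sc.generate_phantom(cfg)
    v2, t2 = sc.generate_phantom(sc.PhantomConfig(seed=11))
    assert np.array_equal(v1.intensities, v2.intensities)
    assert np.array_equal(t1.lung_mask, t2.lung_mask)
    assert all(np.array_equal(a, b) for a, b in zip(t1.nodule_masks, t2.nodule_masks))


def test_degenerate_config_empty_structures():
    cfg = sc.PhantomConfig(n_nodules=0, n_juxtapleural=0, vessel_count=0,
                           n_high_parenchyma=0, noise_std=0.0, seed=2)
    vol, truth = sc.generate_phantom(cfg)
    assert truth.nodule_masks == []
    assert not truth.vessel_mask.any()
    # lung interior is then a single low-intensity Gaussian
    inside = vol.intensities[truth.lung_mask]
    assert abs(inside.mean() - cfg.class_means[0]) < 3 * cfg.class_stds[0] / np.sqrt(len(inside))
    assert abs(inside.std() - cfg.class_stds[0]) < 0.1 * cfg.class_stds[0]


def test_per_class_sample_means_match_configuration():
    cfg = sc.PhantomConfig(n_nodules=5, n_juxtapleural=1, noise_std=0.0,
                           class_means=(-850.0, -50.0, 50.0, 30.0),
                           class_stds=(40.0, 40.0, 30.0, 30.0), seed=5)
    vol, truth = sc.generate_phantom(cfg)
    nodules = np.zeros_like(truth.lung_mask)
    for m in truth.nodule_masks:
        nodules |= m
    parenchyma = truth.lung_mask & ~(nodules | truth.vessel_mask
                                     | truth.high_parenchyma_mask)
    for mask, mean, std in [
        (parenchyma, cfg.class_means[0], cfg.class_stds[0]),
        (truth.high_parenchyma_mask, cfg.class_means[1], cfg.class_stds[1]),
        (truth.vessel_mask, cfg.class_means[2], cfg.class_stds[2]),
        (nodules, cfg.class_means[3], cfg.class_stds[3]),
    ]:
        vals = vol.intensities[mask]
        assert len(vals) > 10
        assert abs(vals.mean() - mean) < 3 * std / np.sqrt(len(vals))


def test_mask_shape_and_nodule_connectivity():
    vol, truth = sc.generate_phantom(sc.PhantomConfig(seed=9))
    assert truth.lung_mask.shape == vol.shape
    for m in truth.nodule_masks:
        assert m.shape == vol.shape
        assert m.sum() >= 3
        _, n = ndimage.label(m, structure=np.ones((3, 3, 3)))
        assert n == 1
        assert (m & truth.lung_mask).any()   # inside or touching the lung


def test_juxtapleural_nodules_touch_lung_boundary():
    _, truth = sc.generate_phantom(sc.PhantomConfig(n_nodules=3, n_juxtapleural=2, seed=4))
    boundary = truth.lung_mask & ~ndimage.binary_erosion(truth.lung_mask)
    labelled = [(m, lab) for m, lab in zip(truth.nodule_masks, truth.nodule_labels)]
    juxta = [m for m, lab in labelled if lab == "juxtapleural"]
    assert len(juxta) == 2
    for m in juxta:
        assert (m & boundary).any()


def test_four_intensity_modes_when_classes_are_well_separated():
    cfg = sc.PhantomConfig(n_nodules=5, vessel_count=8, noise_std=0.0,
                           class_means=(-900.0, -300.0, 300.0, 900.0),
                           class_stds=(30.0, 30.0, 30.0, 30.0), seed=6)
    vol, truth = sc.generate_phantom(cfg)
    body = sc.extract_body_envelope(vol)
    assert count_intensity_modes(vol.intensities[body]) == 4


@pytest.mark.parametrize("bad", [
    dict(n_juxtapleural=3, n_nodules=2),
    dict(volume_shape=(16, 16, 16), nodule_radius_range=(4.0, 8.0)),
    dict(class_means=(0.0, -50.0, 50.0, 30.0)),       # low class not minimal
    dict(nodule_radius_range=(5.0, 3.0)),
    dict(noise_std=-1.0),
])
def test_invalid_configs_rejected(bad):
    with pytest.raises(ValueError):
        sc.PhantomConfig(**bad).validate()


# ---------------------------------------------------------------------------
# patch datasets
# ---------------------------------------------------------------------------

def test_patch_dataset_counts_shapes_labels():
    patches = sc.generate_patch_dataset(10, 10, patch_size=40, seed=1)
    assert len(patches) == 20
    assert all(p.pixels.shape == (40, 40) for p in patches)
    assert sum(p.label for p in patches) == 10
    assert len({p.roi_id for p in patches}) == 20


def test_patch_dataset_deterministic_per_seed():
    a = sc.generate_patch_dataset(5, 5, seed=3)
    b = sc.generate_patch_dataset(5, 5, seed=3)
    c = sc.generate_patch_dataset(5, 5, seed=4)
    assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))
    assert any(not np.array_equal(x.pixels, y.pixels) for x, y in zip(a, c))


def test_patches_centered_and_normalized(small_patch_set):
    for p in small_patch_set:
        com = ndimage.center_of_mass(p.pixels)
        c = (p.size - 1) / 2
        assert abs(com[0] - c) <= 1.0 and abs(com[1] - c) <= 1.0
        assert p.pixels.min() == 0.0 and p.pixels.max() == pytest.approx(1.0)
        # background-masked: a substantial zero background remains
        assert (p.pixels == 0).mean() > 0.2


def _mean_elongation(patches):
    ratios = []
    for p in patches:
        lab = cc_label(p.pixels > 0.3)
        props = max(regionprops(lab), key=lambda r: r.area)
        minor = max(props.axis_minor_length, 1e-3)
        ratios.append(props.axis_major_length / minor)
    return float(np.mean(ratios))


def test_negatives_more_elongated_than_positives():
    patches = sc.generate_patch_dataset(100, 100, seed=21)
    pos = [p for p in patches if p.label == 1]
    neg = [p for p in patches if p.label == 0]
    assert _mean_elongation(neg) > _mean_elongation(pos)


def test_size_texture_coding_couples_label_to_size_and_texture():
    patches = sc.generate_patch_dataset(60, 60, seed=9, coding="size_texture")
    areas = {0: [], 1: []}
    for p in patches:
        areas[p.label].append((p.pixels > 0.25).sum())
        com = ndimage.center_of_mass(p.pixels)
        assert abs(com[0] - 19.5) <= 1.0 and abs(com[1] - 19.5) <= 1.0
    # positives are uniformly large; negatives mix large and small objects,
    # so the positive mean area exceeds the negative mean but the negative
    # area distribution overlaps the positive one (size alone insufficient)
    assert np.mean(areas[1]) > np.mean(areas[0])
    assert np.max(areas[0]) > np.min(areas[1])


@pytest.mark.parametrize("kwargs", [
    dict(n_pos=0, n_neg=5), dict(n_pos=5, n_neg=0),
    dict(n_pos=5, n_neg=5, patch_size=4),
    dict(n_pos=5, n_neg=5, difficulty=1.5),
    dict(n_pos=5, n_neg=5, coding="other"),
])
def test_patch_dataset_invalid_args(kwargs):
    with pytest.raises(ValueError):
        sc.generate_patch_dataset(**kwargs)
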
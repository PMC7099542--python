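"""Stage 1 of the CADe pipeline: lung segmentation and candidate detection.

Hierarchical VQ scheme: a high-level two-class VQ separates the lung from
the rest of the chest body (followed by hole filling and morphological
closing, which recovers juxtapleural nodules carved out of the
low-intensity region), then a low-level four-class VQ inside the lung
separates low/high-intensity parenchyma, vessels and initial nodule
candidates (INCs).  The INC class is chosen as the highest-intensity
class whose connected components are compact; elongated components are
attributed to vessels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball
from skimage.transform import resize as sk_resize

from .core import CTVolume, CandidateRecord, ROIPatch, minmax_normalize
from .vq import OnlineVQ, extract_feature_vectors, kl_reduce


@dataclass
class SegmentationConfig:
    """Tunables of the lung-extraction stage."""

    variance_threshold: float = 0.95
    closing_radius: int = 3
    min_lung_volume: int = 500          # voxels; below this "no lung found"
    max_components: int = 2             # left + right lung
    min_contrast: float = 3.0           # class separation in pooled-std units


@dataclass
class DetectionConfig:
    """Tunables of the INC-detection stage."""

    variance_threshold: float = 0.95
    n_classes: int = 4                  # maximum tissue class number
    min_size: int = 3                   # voxels
    max_size: int = 4000
    max_candidates: int = 100
    elongation_threshold: float = 3.0   # compact vs vessel-like components
    min_contrast: float = 2.0           # class mean above background, in bg-std units
    patch_size: int = 40


def _largest_components(mask: np.ndarray, k: int, min_size: int) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:k] + 1
    keep = [int(i) for i in keep if sizes[i - 1] >= min_size]
    return np.isin(lab, keep)


def _vq_labels(volume: CTVolume, region: np.ndarray, n_classes: int,
               variance_threshold: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Run features -> KL -> VQ inside a region.

    Returns per-voxel class labels (full-volume int grid, -1 outside the
    region) with classes relabelled in ascending mean *raw intensity* of
    their member voxels, so "class 0" is always the lowest-intensity
    tissue regardless of the sign conventions of the KL rotation.
    """
    feats = extract_feature_vectors(volume, region)
    reduced, _ = kl_reduce(feats, variance_threshold)
    vq = OnlineVQ(n_classes=n_classes, random_state=seed).fit(reduced.vectors)
    raw = volume.intensities[region]
    means = np.array([
        raw[vq.labels_ == k].mean() if np.any(vq.labels_ == k) else np.inf
        for k in range(n_classes)
    ])
    remap = np.argsort(np.argsort(means, kind="stable"), kind="stable")
    labels = np.full(volume.shape, -1, dtype=np.int8)
    labels[region] = remap[vq.labels_]
    return labels, means[np.argsort(means, kind="stable")]


def extract_body_envelope(volume: CTVolume) -> np.ndarray:
    """Largest above-background connected component, holes filled."""
    thr = threshold_otsu(volume.intensities)
    body = _largest_components(volume.intensities > thr, 1, 1)
    if not body.any():
        raise ValueError("no body region found above background")
    return ndimage.binary_fill_holes(body)


def segment_lung(volume: CTVolume, seed: int = 0,
                 config: SegmentationConfig | None = None) -> np.ndarray:
    """Extract the lung mask by two-class VQ inside the body envelope.

    Pipeline: body envelope -> 7-neighbour features -> KL reduction ->
    2-class online VQ -> low-intensity class -> 3-D hole filling ->
    morphological closing (recovers juxtapleural indentations) -> the two
    largest components.
    """
    cfg = config or SegmentationConfig()
    body = extract_body_envelope(volume)
    labels, _ = _vq_labels(volume, body, 2, cfg.variance_threshold, seed)
    lo = volume.intensities[labels == 0]
    hi = volume.intensities[labels == 1]
    if len(lo) == 0 or len(hi) == 0:
        raise ValueError("no lung found: degenerate two-class segmentation")
    pooled = np.sqrt((lo.std() ** 2 + hi.std() ** 2) / 2.0)
    if hi.mean() - lo.mean() < cfg.min_contrast * max(pooled, 1e-9):
        raise ValueError(
            "no lung found: no low-intensity class distinct from the body")
    lung = labels == 0
    lung = ndimage.binary_fill_holes(lung)
    if cfg.closing_radius > 0:
        lung = ndimage.binary_closing(
            lung, structure=ball(cfg.closing_radius),
            iterations=1, border_value=0)
        lung = ndimage.binary_fill_holes(lung)
    lung &= body
    lung = _largest_components(lung, cfg.max_components, cfg.min_lung_volume)
    if not lung.any():
        raise ValueError("no lung found: no low-intensity component above minimum volume")
    return lung


def _component_elongation(coords: np.ndarray) -> float:
    """Major/minor axis ratio of a voxel cloud via coordinate PCA."""
    if len(coords) < 4:
        return 1.0
    c = coords - coords.mean(axis=0)
    ev = np.linalg.eigvalsh(np.cov(c.T))
    ev = np.clip(ev, 1e-3, None)
    return float(np.sqrt(ev[-1] / ev[0]))


def detect_incs(volume: CTVolume, lung_mask: np.ndarray, seed: int = 0,
                config: DetectionConfig | None = None) -> list[CandidateRecord]:
    """Detect initial nodule candidates inside the lung mask.

    Four-class VQ inside the lung; among classes whose connected
    components are compact (median elongation below threshold) the one
    with the highest mean intensity is taken as the INC class.  Its
    26-connected components are size-filtered and returned as candidate
    records, each with a centred, mask-isolated, resized axial patch.
    """
    cfg = config or DetectionConfig()
    lung_mask = np.asarray(lung_mask, bool)
    if not lung_mask.any():
        raise ValueError("empty lung mask")
    labels, class_means = _vq_labels(volume, lung_mask, cfg.n_classes,
                                     cfg.variance_threshold, seed)

    # Class 0 is the parenchyma background; candidates are the compact
    # components of the brighter classes.  Each class mask is opened with a
    # small cross element first, which severs thin pleural rim sheets and
    # sub-voxel vessel bridges that would otherwise merge a nodule into one
    # large elongated component; remaining elongated components are
    # attributed to vessels and dropped.
    struct = np.ones((3, 3, 3), dtype=int)
    cross = ndimage.generate_binary_structure(3, 1)
    bg = volume.intensities[labels == 0]
    bg_mean, bg_std = bg.mean(), max(bg.std(), 1e-9)
    compact: list[tuple[int, np.ndarray]] = []
    for k in range(1, cfg.n_classes):
        vals = volume.intensities[labels == k]
        if len(vals) == 0 or vals.mean() - bg_mean < cfg.min_contrast * bg_std:
            continue        # indistinct from parenchyma background: not a source
        opened = ndimage.binary_opening(labels == k, structure=cross)
        lab, n = ndimage.label(opened, structure=struct)
        for i in range(1, n + 1):
            comp = lab == i
            size = int(comp.sum())
            if not (cfg.min_size <= size <= cfg.max_size):
                continue
            if _component_elongation(np.argwhere(comp)) < cfg.elongation_threshold:
                compact.append((size, comp))
    if not compact:
        return []
    compact.sort(key=lambda t: -t[0])
    records: list[CandidateRecord] = []
    for rank, (size, mask) in enumerate(compact[: cfg.max_candidates]):
        coords = np.argwhere(mask)
        z0, y0, x0 = coords.min(axis=0)
        z1, y1, x1 = coords.max(axis=0) + 1
        centroid = tuple(coords.mean(axis=0))
        zc = int(round(centroid[0]))
        patch = extract_roi_patch(volume.intensities[zc], mask[zc],
                                  patch_size=cfg.patch_size)
        patch.roi_id = f"inc{rank:04d}"
        records.append(CandidateRecord(
            mask=mask, bounding_box=(int(z0), int(z1), int(y0), int(y1), int(x0), int(x1)),
            patch=patch, centroid=centroid))
    return records


def extract_roi_patch(image: np.ndarray, candidate_mask: np.ndarray,
                      patch_size: int = 40, margin: int = 2,
                      normalize: bool = True) -> ROIPatch:
    """Centre, isolate and resize one candidate to a square patch.

    The candidate is shifted so its mask centroid sits at the patch
    centre, everything outside the mask is zeroed, the mask bounding box
    (plus a small margin) is cropped into a square canvas and bilinearly
    resized to ``patch_size``; intensities are min-max normalised.
    """
    image = np.asarray(image, dtype=np.float64)
    candidate_mask = np.asarray(candidate_mask, bool)
    if candidate_mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    if not candidate_mask.any():
        raise ValueError("empty candidate mask")

    isolated = np.where(candidate_mask, image, 0.0)
    coords = np.argwhere(candidate_mask)
    y0, x0 = coords.min(axis=0)
    y1, x1 = coords.max(axis=0) + 1
    com = ndimage.center_of_mass(candidate_mask)

    half = max(y1 - y0, x1 - x0) / 2 + margin
    side = int(np.ceil(2 * half))
    side += side % 2
    c = (side - 1) / 2.0
    # sample the source on a canvas whose centre is the mask centroid
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    canvas = ndimage.map_coordinates(
        isolated, [yy - c + com[0], xx - c + com[1]], order=1, mode="constant")
    mcanvas = ndimage.map_coordinates(
        candidate_mask.astype(np.float64), [yy - c + com[0], xx - c + com[1]],
        order=1, mode="constant")

    out = sk_resize(canvas, (patch_size, patch_size), order=1,
                    anti_aliasing=side > 2 * patch_size, mode="constant")
    mout = sk_resize(mcanvas, (patch_size, patch_size), order=1,
                     anti_aliasing=side > 2 * patch_size, mode="constant")
    out[mout < 0.25] = 0.0
    out = np.clip(out, 0.0, None)
    if normalize:
        out = minmax_normalize(out)
    return ROIPatch(out, roi_id="roi", label=None, normalized=normalize)
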
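"""Synthetic chest phantoms and labelled ROI patch sets.

The volume generator emulates the intensity structure the candidate
detector assumes: a soft-tissue body envelope containing two low-intensity
lungs, with four Gaussian intensity populations inside the body
(low-intensity parenchyma, high-intensity parenchyma, vessels, nodule
candidates).  Geometry is deliberately minimal — lungs are two ellipsoids
in an elliptic-cylinder body, vessels are random-walk tubes, nodules are
randomly oriented spheroids of which a configurable number are
juxtapleural (touching the pleural boundary).

The patch generator supplies labelled 40x40 ROI patches directly, without
running volume detection: positives are compact nodule-like blobs of
varied size and eccentricity, negatives are elongated vessel-like or
curved-tube structures (the dominant false-positive source in the
candidate stage).  A single ``difficulty`` knob controls how much the two
shape/texture distributions overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .core import CTVolume, ROIPatch, minmax_normalize

AIR_HU = -1000.0


@dataclass
class PhantomConfig:
    """Geometry and intensity parameters of a synthetic chest volume.

    ``class_means``/``class_stds`` parameterize the four tissue
    populations, ordered (low-intensity parenchyma, high-intensity
    parenchyma, vessels, nodules); the first mean must be the minimum.
    """

    volume_shape: tuple[int, int, int] = (48, 64, 64)
    n_nodules: int = 4
    n_juxtapleural: int = 1
    nodule_radius_range: tuple[float, float] = (2.5, 4.5)
    vessel_count: int = 6
    n_high_parenchyma: int = 2          # dense parenchyma blobs inside the lungs
    class_means: tuple[float, float, float, float] = (-850.0, -50.0, 50.0, 30.0)
    class_stds: tuple[float, float, float, float] = (40.0, 40.0, 30.0, 30.0)
    noise_std: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.volume_shape) != 3 or any(s < 16 for s in self.volume_shape):
            raise ValueError("volume_shape must be 3 integers, each >= 16")
        if self.n_nodules < 0 or self.n_juxtapleural < 0:
            raise ValueError("nodule counts must be non-negative")
        if self.n_juxtapleural > self.n_nodules:
            raise ValueError("n_juxtapleural cannot exceed n_nodules")
        rmin, rmax = self.nodule_radius_range
        if not (1.0 <= rmin <= rmax):
            raise ValueError("nodule_radius_range must satisfy 1 <= min <= max")
        if self.class_means[0] != min(self.class_means):
            raise ValueError("class_means[0] (low-intensity parenchyma) must be the minimum")
        if any(s <= 0 for s in self.class_stds):
            raise ValueError("class_stds must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")
        # the largest requested nodule must fit inside a lung
        if 2 * rmax + 2 > min(self.volume_shape) / 2:
            raise ValueError(
                f"volume {self.volume_shape} too small to host nodules of radius {rmax}")


@dataclass
class PhantomTruth:
    """Ground-truth geometry of a generated phantom."""

    lung_mask: np.ndarray
    nodule_masks: list[np.ndarray]
    vessel_mask: np.ndarray
    nodule_centers: list[tuple[float, float, float]]
    nodule_labels: list[str] = field(default_factory=list)  # "internal" | "juxtapleural"
    high_parenchyma_mask: np.ndarray | None = None


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation matrix from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _spheroid_mask(shape: tuple[int, int, int], center: np.ndarray,
                   semi_axes: np.ndarray, rot: np.ndarray) -> np.ndarray:
    rmax = float(semi_axes.max()) + 1.5
    lo = np.maximum(np.floor(center - rmax).astype(int), 0)
    hi = np.minimum(np.ceil(center + rmax).astype(int) + 1, shape)
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    pts = np.stack([zz - center[0], yy - center[1], xx - center[2]], axis=-1)
    local = pts @ rot            # rotate into the spheroid frame
    q = np.sum((local / semi_axes) ** 2, axis=-1)
    mask = np.zeros(shape, dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = q <= 1.0
    return mask


def _ball_offsets(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    keep = zz * zz + yy * yy + xx * xx <= radius * radius
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)


def _paint_tube(mask: np.ndarray, points: np.ndarray, radius: float) -> None:
    offs = _ball_offsets(radius)
    shape = np.array(mask.shape)
    for p in points:
        vox = np.round(p[None, :] + offs).astype(int)
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        v = vox[ok]
        mask[v[:, 0], v[:, 1], v[:, 2]] = True


def generate_phantom(config: PhantomConfig) -> tuple[CTVolume, PhantomTruth]:
    """Generate a synthetic chest CT volume and its ground truth.

    Deterministic for a fixed ``config.seed``.  The returned truth lung
    mask is the union of the lung ellipsoids and all nodules (juxtapleural
    nodules indent the low-intensity region but belong to the lung for
    evaluation purposes, mirroring how morphological closing restores
    them).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.volume_shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(np.float64)
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2

    body = ((yy - cy) / (0.42 * ny)) ** 2 + ((xx - cx) / (0.45 * nx)) ** 2 <= 1.0

    lungs = np.zeros_like(body)
    for side in (-1.0, 1.0):
        lx = cx + side * 0.22 * nx
        lungs |= (((zz - cz) / (0.40 * nz)) ** 2
                  + ((yy - cy) / (0.28 * ny)) ** 2
                  + ((xx - lx) / (0.16 * nx)) ** 2) <= 1.0
    lungs &= body

    dist_in = ndimage.distance_transform_edt(lungs)

    # -- nodules: randomly oriented spheroids, some touching the pleura --
    rmin, rmax = config.nodule_radius_range
    nodule_masks: list[np.ndarray] = []
    centers: list[np.ndarray] = []
    labels: list[str] = []
    nodule_union = np.zeros_like(lungs)
    for i in range(config.n_nodules):
        juxta = i < config.n_juxtapleural
        placed = False
        for _ in range(300):
            if juxta:
                # juxtapleural nodules sit on the wall and bulge into the
                # lung: centre them at a depth below their radius so the
                # spheroid still crosses the pleural boundary, and keep
                # them in the lower half of the size range so the closing
                # step can realistically recover the indentation
                a = rng.uniform(rmin, min(rmax, rmin + 0.5 * (rmax - rmin)))
                cand = np.argwhere((dist_in > 0.60 * a) & (dist_in < 0.90 * a))
            else:
                a = rng.uniform(rmin, rmax)
                cand = np.argwhere(dist_in > a + 1.0)
            if len(cand) == 0:
                continue
            center = cand[rng.integers(len(cand))].astype(np.float64)
            if all(np.linalg.norm(center - c) > 2 * rmax + 2 for c in centers):
                semi = np.array([a, a * rng.uniform(0.7, 1.0), a * rng.uniform(0.7, 1.0)])
                mask = _spheroid_mask((nz, ny, nx), center, semi, _random_rotation(rng))
                mask &= body
                if juxta:
                    # must actually touch the pleural boundary and keep a core inside
                    if not (np.any(mask & ~lungs) and np.any(mask & lungs)):
                        continue
                if mask.sum() < 3:
                    continue
                nodule_masks.append(mask)
                centers.append(center)
                labels.append("juxtapleural" if juxta else "internal")
                nodule_union |= mask
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not place nodule {i}; volume too crowded")

    # -- vessels: random-walk tubes inside the lungs --
    # walks terminate when they come close to a nodule so that the truth
    # stays unambiguous (a vessel fused through a nodule has no clean label)
    vessel_mask = np.zeros_like(lungs)
    near_nodule = ndimage.binary_dilation(nodule_union, iterations=3)
    interior = np.argwhere((dist_in > 2.0) & ~near_nodule)
    for _ in range(config.vessel_count):
        if len(interior) == 0:
            break
        pos = interior[rng.integers(len(interior))].astype(np.float64)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts = []
        for _ in range(int(rng.integers(25, 60))):
            pts.append(pos.copy())
            d += 0.25 * rng.normal(size=3)
            d /= np.linalg.norm(d)
            pos = pos + d
            if not (0 <= pos[0] < nz and 0 <= pos[1] < ny and 0 <= pos[2] < nx):
                break
            if near_nodule[int(pos[0]), int(pos[1]), int(pos[2])]:
                break
        _paint_tube(vessel_mask, np.array(pts), rng.uniform(0.9, 1.5))
    vessel_mask &= lungs
    vessel_mask &= ~nodule_union

    # -- high-intensity parenchyma blobs inside the lungs --
    hp_mask = np.zeros_like(lungs)
    for _ in range(config.n_high_parenchyma):
        cand = np.argwhere(dist_in > 4.0)
        if len(cand) == 0:
            break
        c = cand[rng.integers(len(cand))].astype(np.float64)
        semi = rng.uniform(2.0, 3.5, size=3)
        hp_mask |= _spheroid_mask((nz, ny, nx), c, semi, _random_rotation(rng))
    hp_mask &= lungs
    hp_mask &= ~(vessel_mask | nodule_union)

    # -- class map and intensity draw --
    class_map = np.full((nz, ny, nx), -1, dtype=np.int8)      # -1 = air
    class_map[body] = 1                                        # wall: high-intensity tissue
    class_map[lungs] = 0                                       # low-intensity parenchyma
    class_map[hp_mask] = 1
    class_map[vessel_mask] = 2
    class_map[nodule_union] = 3

    vol = rng.normal(AIR_HU, 20.0, size=(nz, ny, nx))
    for k in range(4):
        sel = class_map == k
        vol[sel] = rng.normal(config.class_means[k], config.class_stds[k], size=int(sel.sum()))
    if config.noise_std > 0:
        vol += rng.normal(0.0, config.noise_std, size=vol.shape)

    truth = PhantomTruth(
        lung_mask=lungs | nodule_union,
        nodule_masks=nodule_masks,
        vessel_mask=vessel_mask,
        nodule_centers=[tuple(c) for c in centers],
        nodule_labels=labels,
        high_parenchyma_mask=class_map == 1,   # chest wall plus dense lung blobs
    )
    return CTVolume(vol), truth


def count_intensity_modes(values: np.ndarray, bins: int = 120, sigma: float = 2.0,
                          min_prominence: float = 0.05) -> int:
    """Count local maxima of a smoothed log-scale intensity histogram.

    Used to verify that a generated body contains the expected number of
    tissue intensity populations when the class means are well separated;
    log counts keep small populations (vessels, nodules) detectable next
    to the dominant parenchyma and wall peaks.
    """
    hist, _ = np.histogram(values, bins=bins)
    smooth = ndimage.gaussian_filter1d(np.log1p(hist.astype(np.float64)), sigma)
    peaks, _ = find_peaks(smooth, prominence=min_prominence * smooth.max())
    return int(len(peaks))


# ---------------------------------------------------------------------------
# labelled ROI patch sets
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma)
    s = f.std()
    return f / s if s > 0 else f


def _rotated_coords(size: int, theta: float) -> tuple[np.ndarray, np.ndarray]:
    c = (size - 1) / 2
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    u = (xx - c) * math.cos(theta) + (yy - c) * math.sin(theta)
    v = -(xx - c) * math.sin(theta) + (yy - c) * math.cos(theta)
    return u, v


def _soft_edge(q: np.ndarray, width: float = 0.08) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((q - 1.0) / width))


def _positive_patch(rng: np.random.Generator, size: int, difficulty: float) -> np.ndarray:
    a = rng.uniform(0.12, 0.30) * size
    ratio = rng.uniform(1.0, 1.0 + 1.4 * difficulty)
    b = a / ratio
    u, v = _rotated_coords(size, rng.uniform(0, math.pi))
    q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    img = _soft_edge(q)
    # coarse, gentle texture: nodules read as smooth in the image domain
    tex = 1.0 + (0.08 + 0.15 * difficulty) * _smooth_noise(rng, size, sigma=3.0)
    return np.clip(img * tex, 0.0, None)


def _negative_patch(rng: np.random.Generator, size: int, difficulty: float) -> np.ndarray:
    u, v = _rotated_coords(size, rng.uniform(0, math.pi))
    if rng.random() < 0.5:
        # elongated vessel-segment ellipse
        ratio = rng.uniform(max(1.05, 1.9 - 0.85 * difficulty), 3.5)
        a = rng.uniform(0.20, 0.42) * size
        b = a / ratio
        q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        img = _soft_edge(q)
    else:
        # bent tube: thin structure with a quadratic centreline offset
        half_len = rng.uniform(0.25, 0.42) * size
        w = rng.uniform(1.6, 3.2)
        bend = rng.uniform(-0.25, 0.25) / max(half_len, 1.0)
        dv = v - bend * u ** 2
        inside = np.abs(u) <= half_len
        q = np.sqrt((dv / w) ** 2 + np.maximum(np.abs(u) - half_len, 0.0) ** 2)
        img = _soft_edge(q, width=0.15) * (inside | (q < 2.0))
    # fine speckle: vessel/parenchyma fragments read as granular
    tex = 1.0 + (0.15 + 0.25 * difficulty) * _smooth_noise(rng, size, sigma=1.0)
    # keep support inside the inscribed disk so projections see the whole object
    c = (size - 1) / 2
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    disk = (yy - c) ** 2 + (xx - c) ** 2 <= (0.45 * size) ** 2
    return np.clip(img * tex, 0.0, None) * disk


def _blob(rng: np.random.Generator, size: int, a: float, ratio_max: float) -> np.ndarray:
    ratio = rng.uniform(1.0, ratio_max)
    u, v = _rotated_coords(size, rng.uniform(0, math.pi))
    q = np.sqrt((u / a) ** 2 + (ratio * v / a) ** 2)
    return _soft_edge(q)


def _size_texture_patch(rng: np.random.Generator, size: int, difficulty: float,
                        positive: bool) -> np.ndarray:
    """Size/texture-coded patch: positives are large AND smooth.

    Negatives draw uniformly from the other three (size, texture)
    combinations, so neither cue alone separates the classes.  Pixel
    noise added later obscures object boundaries in the image domain;
    projections integrate over ~size pixels and recover the support
    (hence object size) much more cleanly.
    """
    if positive:
        large, smooth = True, True
    else:
        large, smooth = ((True, False), (False, True), (False, False))[rng.integers(3)]
    a = rng.uniform(0.24, 0.34) * size if large else rng.uniform(0.10, 0.16) * size
    img = _blob(rng, size, a, ratio_max=1.6)
    if smooth:
        tex = 1.0 + 0.10 * _smooth_noise(rng, size, sigma=3.0)
    else:
        tex = 1.0 + 0.45 * _smooth_noise(rng, size, sigma=0.8)
    return np.clip(img * tex, 0.0, None)


def _finalize(img: np.ndarray, rng: np.random.Generator, difficulty: float,
              noise_std: float | None = None) -> np.ndarray:
    size = img.shape[0]
    support = img > 0.02
    if support.sum() == 0:          # degenerate draw; keep a tiny central dot
        support[size // 2, size // 2] = True
        img[size // 2, size // 2] = 1.0
    if noise_std is None:
        noise_std = 0.05 + 0.30 * difficulty
    img = img + support * rng.normal(0.0, noise_std, size=img.shape)
    img = np.clip(img, 0.0, None) * support
    # re-centre the mass centroid onto the patch centre
    com = ndimage.center_of_mass(img)
    c = (size - 1) / 2
    img = ndimage.shift(img, (c - com[0], c - com[1]), order=1, mode="constant")
    img = np.clip(img, 0.0, None)
    return minmax_normalize(img)


def generate_patch_dataset(n_pos: int, n_neg: int, patch_size: int = 40,
                           seed: int = 0, difficulty: float = 0.6,
                           coding: str = "shape") -> list[ROIPatch]:
    """Generate a labelled set of centred, background-masked ROI patches.

    With the default ``coding="shape"``, positives are compact blobs with
    varied radius and eccentricity (their projections carry shape and
    size information) and negatives are elongated or curved vessel-like
    structures with finer speckle texture.  With ``coding="size_texture"``
    the label depends jointly on object size and texture (positives are
    large AND smooth; negatives are every other combination), the setting
    used by the experiment harness: under pixel noise the projection
    domain reads off object size far more reliably than the image domain.
    ``difficulty`` in [0, 1] widens distribution overlap and raises pixel
    noise (0 gives a cleanly separable set).
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    if patch_size < 8:
        raise ValueError("patch_size must be at least 8")
    if not (0.0 <= difficulty <= 1.0):
        raise ValueError("difficulty must lie in [0, 1]")
    if coding not in ("shape", "size_texture"):
        raise ValueError("coding must be 'shape' or 'size_texture'")
    rng = np.random.default_rng(seed)
    sized = coding == "size_texture"
    noise = (0.10 + 0.20 * difficulty) if sized else None
    patches: list[ROIPatch] = []
    for i in range(n_pos):
        raw = (_size_texture_patch(rng, patch_size, difficulty, True) if sized
               else _positive_patch(rng, patch_size, difficulty))
        img = _finalize(raw, rng, difficulty, noise_std=noise)
        patches.append(ROIPatch(img, roi_id=f"pos{i:05d}", label=1, normalized=True))
    for i in range(n_neg):
        raw = (_size_texture_patch(rng, patch_size, difficulty, False) if sized
               else _negative_patch(rng, patch_size, difficulty))
        img = _finalize(raw, rng, difficulty, noise_std=noise)
        patches.append(ROIPatch(img, roi_id=f"neg{i:05d}", label=0, normalized=True))
    return patches
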
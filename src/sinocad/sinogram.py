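"""Radon projection of ROI patches and multi-channel sinogram conversion.

A parallel-beam Radon transform maps each square patch f(x, y) to a
``bins x views`` sinogram: entry (b, v) approximates the line integral of
f along the line x cos(phi_v) + y sin(phi_v) = s_b, with coordinates
centred on the patch centre.  Views cover [0, pi) uniformly; the detector
has ``n_bins`` bins spanning the patch width, and no circular mask is
applied (lines through the patch corners contribute wherever they fall).

Wide sinograms are converted to multi-channel stacks either by cutting
contiguous blocks of views (direct-cut) or by strided "sparse-view"
subsets (interleave-cut), e.g. 40 x 640 -> 40 x 40 x 16.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

from .core import ROIPatch, minmax_normalize


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam geometry: detector bins, views and sampling step."""

    n_bins: int = 40
    n_views: int = 640
    angle_span: float = math.pi
    bin_span: float | None = None     # detector extent in pixels; None -> patch width
    sample_step: float = 0.5          # integration step along each line, pixels

    def __post_init__(self) -> None:
        if self.n_bins < 2 or self.n_views < 1:
            raise ValueError("need n_bins >= 2 and n_views >= 1")
        if not (0 < self.angle_span <= 2 * math.pi):
            raise ValueError("angle_span must lie in (0, 2*pi]")
        if self.sample_step <= 0:
            raise ValueError("sample_step must be positive")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_views) * (self.angle_span / self.n_views)

    def bin_centers(self, patch_size: int) -> np.ndarray:
        span = self.bin_span if self.bin_span is not None else float(patch_size)
        width = span / self.n_bins
        return (np.arange(self.n_bins) + 0.5 - self.n_bins / 2) * width


@dataclass
class Sinogram:
    """A bins x views projection with its geometry."""

    values: np.ndarray
    geometry: ProjectionGeometry
    source_patch: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.geometry.n_bins, self.geometry.n_views):
            raise ValueError("sinogram shape must be (n_bins, n_views)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")


@dataclass
class ChannelStack:
    """bins x views-per-channel x channels tensor with its view partition."""

    values: np.ndarray
    scheme: str                       # "direct" | "interleave"
    step: int
    view_map: list[np.ndarray] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


def _projection_matrix(patch_size: int, geometry: ProjectionGeometry) -> sparse.csr_matrix:
    """Sparse operator mapping a flattened patch to a flattened sinogram.

    Rows index (view, bin); each row accumulates bilinear interpolation
    weights of the sample points along the corresponding line, scaled by
    the integration step.  Samples falling outside the patch contribute
    nothing (zero padding).
    """
    P = int(patch_size)
    c = (P - 1) / 2.0
    s = geometry.bin_centers(P)                              # (B,)
    phi = geometry.angles                                    # (V,)
    t_max = 0.5 * P * math.sqrt(2.0) + 1.0
    t = np.arange(-t_max, t_max + geometry.sample_step, geometry.sample_step)

    cos, sin = np.cos(phi)[:, None, None], np.sin(phi)[:, None, None]
    sg = s[None, :, None]
    tg = t[None, None, :]
    x = sg * cos - tg * sin                                  # (V, B, T)
    y = sg * sin + tg * cos
    rows_f = (c + y).ravel()
    cols_f = (c + x).ravel()

    B, V, T = geometry.n_bins, geometry.n_views, len(t)
    row_idx = np.repeat(np.arange(V * B), T)

    iy0 = np.floor(rows_f).astype(np.int64)
    ix0 = np.floor(cols_f).astype(np.int64)
    fy = rows_f - iy0
    fx = cols_f - ix0

    entries_r, entries_c, entries_w = [], [], []
    for dy, dx, w in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                      (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
        yy, xx = iy0 + dy, ix0 + dx
        ok = (yy >= 0) & (yy < P) & (xx >= 0) & (xx < P) & (w > 0)
        entries_r.append(row_idx[ok])
        entries_c.append(yy[ok] * P + xx[ok])
        entries_w.append(w[ok])
    A = sparse.coo_matrix(
        (np.concatenate(entries_w) * geometry.sample_step,
         (np.concatenate(entries_r), np.concatenate(entries_c))),
        shape=(V * B, P * P))
    return A.tocsr()


_MATRIX_CACHE: dict[tuple, sparse.csr_matrix] = {}


def _cached_matrix(patch_size: int, geometry: ProjectionGeometry) -> sparse.csr_matrix:
    key = (patch_size, geometry.n_bins, geometry.n_views, geometry.angle_span,
           geometry.bin_span, geometry.sample_step)
    if key not in _MATRIX_CACHE:
        _MATRIX_CACHE[key] = _projection_matrix(patch_size, geometry)
    return _MATRIX_CACHE[key]


def radon_project(patch: ROIPatch | np.ndarray,
                  geometry: ProjectionGeometry | None = None) -> Sinogram:
    """Project one square patch into the sinogram domain."""
    geometry = geometry or ProjectionGeometry()
    pixels = patch.pixels if isinstance(patch, ROIPatch) else np.asarray(patch, float)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError("patch must be square")
    A = _cached_matrix(pixels.shape[0], geometry)
    values = (A @ pixels.ravel()).reshape(geometry.n_views, geometry.n_bins).T
    name = patch.roi_id if isinstance(patch, ROIPatch) else ""
    return Sinogram(values, geometry, source_patch=name)


class RadonTransform(BaseEstimator, TransformerMixin):
    """Stateless batch transformer: (n, P, P) patches -> (n, bins, views).

    ``normalize=True`` applies the same per-item min-max scaling used for
    image patches before classification.
    """

    def __init__(self, n_bins: int = 40, n_views: int = 640,
                 angle_span: float = math.pi, sample_step: float = 0.5,
                 normalize: bool = False):
        self.n_bins = n_bins
        self.n_views = n_views
        self.angle_span = angle_span
        self.sample_step = sample_step
        self.normalize = normalize

    @property
    def geometry(self) -> ProjectionGeometry:
        return ProjectionGeometry(n_bins=self.n_bins, n_views=self.n_views,
                                  angle_span=self.angle_span,
                                  sample_step=self.sample_step)

    def fit(self, X, y=None) -> "RadonTransform":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("X must be (n, P, P) square patches")
        n, P = X.shape[0], X.shape[1]
        A = _cached_matrix(P, self.geometry)
        flat = (A @ X.reshape(n, -1).T).T            # (n, V*B)
        out = flat.reshape(n, self.n_views, self.n_bins).transpose(0, 2, 1)
        if self.normalize:
            out = np.stack([minmax_normalize(s) for s in out])
        return out


# ---------------------------------------------------------------------------
# multi-channel conversion
# ---------------------------------------------------------------------------

def _check_divisible(n_views: int, n_channels: int) -> int:
    if n_channels < 1:
        raise ValueError("n_channels must be positive")
    if n_views % n_channels != 0:
        raise ValueError(
            f"view count {n_views} must be divisible by channel count {n_channels}")
    return n_views // n_channels


def direct_cut(sino: Sinogram | np.ndarray, n_channels: int) -> ChannelStack:
    """Cut a sinogram into contiguous equal-sized view blocks.

    Channel c holds views [c*V/C, (c+1)*V/C); concatenating the channels
    along the view axis reconstructs the sinogram exactly.
    """
    values = sino.values if isinstance(sino, Sinogram) else np.asarray(sino)
    vpc = _check_divisible(values.shape[1], n_channels)
    view_map = [np.arange(c * vpc, (c + 1) * vpc) for c in range(n_channels)]
    stack = np.stack([values[:, m] for m in view_map], axis=2)
    return ChannelStack(stack, scheme="direct", step=1, view_map=view_map)


def interleave_cut(sino: Sinogram | np.ndarray, n_channels: int,
                   step: int = 1) -> ChannelStack:
    """Cut a sinogram into strided sparse-view channels.

    Channel c holds views ``(c + j * C * step) mod V`` for j = 0..V/C-1;
    with the default step each channel is the classic sparse-view comb
    {c, c+C, c+2C, ...} spanning the full angular range.  The assignment
    is a partition iff gcd(step, V/C) == 1, which is checked up front
    (the step-3 configuration on 640 views / 16 channels satisfies it).
    """
    values = sino.values if isinstance(sino, Sinogram) else np.asarray(sino)
    V = values.shape[1]
    vpc = _check_divisible(V, n_channels)
    if step < 1:
        raise ValueError("step must be positive")
    if math.gcd(step, vpc) != 1:
        raise ValueError(
            f"step {step} shares a factor with views-per-channel {vpc}; "
            "the strided assignment would not partition the views")
    j = np.arange(vpc)
    view_map = [(c + j * n_channels * step) % V for c in range(n_channels)]
    stack = np.stack([values[:, m] for m in view_map], axis=2)
    return ChannelStack(stack, scheme="interleave", step=step, view_map=view_map)


def reassemble(stack: ChannelStack) -> np.ndarray:
    """Invert a cut: scatter every channel's views back to their positions."""
    vpc, C = stack.values.shape[1], stack.values.shape[2]
    out = np.empty((stack.values.shape[0], vpc * C), dtype=stack.values.dtype)
    for c, m in enumerate(stack.view_map):
        out[:, m] = stack.values[:, :, c]
    return out


class SinogramChannelizer(BaseEstimator, TransformerMixin):
    """Batch transformer: (n, bins, views) -> (n, bins, views/C, C)."""

    def __init__(self, n_channels: int = 16, scheme: str = "interleave", step: int = 1):
        self.n_channels = n_channels
        self.scheme = scheme
        self.step = step

    def fit(self, X, y=None) -> "SinogramChannelizer":
        if self.scheme not in ("direct", "interleave"):
            raise ValueError("scheme must be 'direct' or 'interleave'")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self.fit(X)
        cut = direct_cut if self.scheme == "direct" else interleave_cut
        kwargs = {} if self.scheme == "direct" else {"step": self.step}
        return np.stack([cut(x, self.n_channels, **kwargs).values for x in X])
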
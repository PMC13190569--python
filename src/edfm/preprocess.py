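"""Input preprocessing: z-score normalization, series smoothing and
windowing, point-cloud denoising and downsampling, image standardization
and plant-level dataset splitting.

Normalization statistics are fitted on the training partition only (the
caller is responsible for passing training data to :func:`fit_zscore`);
sigma is the population standard deviation so the transformed training
set has variance exactly 1. Data splits are assigned per plant, never
per record, to prevent leakage between partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DegenerateChannelError, InvalidArgumentError

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationStats",
    "SplitAssignment",
    "fit_zscore",
    "apply_zscore",
    "invert_zscore",
    "smooth_series",
    "sliding_windows",
    "sor_filter",
    "voxel_downsample",
    "downsample_to_count",
    "standardize_image",
    "split_plants",
    "align_streams",
    "load_point_cloud",
]

IMAGE_SIZE = 224


@dataclass
class NormalizationStats:
    """Per-channel mean and population standard deviation."""

    mu: np.ndarray
    sigma: np.ndarray
    channels: tuple[str, ...] | None = None


def fit_zscore(train: np.ndarray, channels: tuple[str, ...] | None = None) -> NormalizationStats:
    """Fit z-score statistics per channel (columns) of the training data.

    Raises :class:`DegenerateChannelError` naming the first constant
    channel, since a zero sigma makes the transform undefined.
    """
    x = np.atleast_2d(np.asarray(train, dtype=float))
    if x.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 training values per channel")
    mu = x.mean(axis=0)
    sigma = x.std(axis=0)  # population sd
    bad = np.flatnonzero(sigma <= 0)
    if bad.size:
        name = channels[bad[0]] if channels else f"column {bad[0]}"
        raise DegenerateChannelError(f"channel {name} is constant; cannot z-score")
    return NormalizationStats(mu=mu, sigma=sigma, channels=channels)


def apply_zscore(x: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Elementwise (x - mu) / sigma."""
    arr = np.asarray(x, dtype=float)
    if arr.shape[-1] != stats.mu.shape[0]:
        raise InvalidArgumentError(
            f"channel mismatch: data has {arr.shape[-1]}, stats have {stats.mu.shape[0]}"
        )
    return (arr - stats.mu) / stats.sigma


def invert_zscore(z: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Inverse transform z * sigma + mu."""
    arr = np.asarray(z, dtype=float)
    if arr.shape[-1] != stats.mu.shape[0]:
        raise InvalidArgumentError("channel mismatch")
    return arr * stats.sigma + stats.mu


def smooth_series(x: np.ndarray, width: int = 7, kernel: str = "mean") -> np.ndarray:
    """Trailing moving-window smoothing (mean or median) along axis 0.

    The first ``width - 1`` entries average over the partial trailing
    window, so the output has the input's length.
    """
    if width < 1:
        raise InvalidArgumentError("width must be >= 1")
    if kernel not in ("mean", "median"):
        raise InvalidArgumentError("kernel must be 'mean' or 'median'")
    s = pd.DataFrame(np.atleast_2d(np.asarray(x, dtype=float).T).T)
    roll = s.rolling(window=width, min_periods=1)
    out = (roll.mean() if kernel == "mean" else roll.median()).to_numpy()
    return out.reshape(np.asarray(x, dtype=float).shape)


def sliding_windows(series: np.ndarray, width: int, stride: int = 1) -> list[np.ndarray]:
    """Contiguous, ordered windows of ``width`` records every ``stride``.

    Returns floor((n - width)/stride) + 1 windows for n >= width, and an
    empty list (with a logged warning) otherwise.
    """
    if width < 1 or stride < 1:
        raise InvalidArgumentError("width and stride must be >= 1")
    arr = np.asarray(series)
    n = arr.shape[0]
    if n < width:
        logger.warning("series length %d < window width %d: no windows", n, width)
        return []
    return [arr[i : i + width] for i in range(0, n - width + 1, stride)]


def sor_filter(
    points: np.ndarray, k_neighbors: int = 16, std_ratio: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Statistical outlier removal.

    For each point the mean distance to its k nearest neighbours is
    computed; points whose mean distance exceeds
    mean(d) + std_ratio * sd(d) (population sd over all points) are
    removed. Returns the filtered cloud and the removed indices.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidArgumentError("points must be (N, 3)")
    n = len(pts)
    if n <= k_neighbors:
        raise InvalidArgumentError(f"need more than k_neighbors={k_neighbors} points, got {n}")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=k_neighbors + 1)  # first neighbour is the point itself
    mean_d = dists[:, 1:].mean(axis=1)
    threshold = mean_d.mean() + std_ratio * mean_d.std()
    removed = np.flatnonzero(mean_d > threshold)
    keep = np.flatnonzero(mean_d <= threshold)
    return pts[keep], removed


def voxel_downsample(points: np.ndarray, voxel_size: float) -> np.ndarray:
    """One centroid per occupied voxel; the grid origin is the per-axis minimum.

    Voxel index of point p is floor((p - origin)/voxel_size); output
    points are ordered by voxel index, so the result is deterministic.
    """
    if voxel_size <= 0:
        raise InvalidArgumentError("voxel_size must be positive")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidArgumentError("points must be (N, 3)")
    if len(pts) == 0:
        return pts.copy()
    origin = pts.min(axis=0)
    idx = np.floor((pts - origin) / voxel_size).astype(np.int64)
    _, inverse, counts = np.unique(idx, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((len(counts), 3))
    np.add.at(sums, inverse, pts)
    return sums / counts[:, None]


def downsample_to_count(
    points: np.ndarray, target: int, tolerance: float = 0.05, max_iter: int = 40
) -> np.ndarray:
    """Binary-search the voxel size until the output count is within
    ``tolerance`` of ``target`` (or ``max_iter`` halvings elapse);
    returns the best cloud seen. Clouds already at or below the target
    are returned unchanged with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) <= target:
        logger.warning("cloud has %d <= target %d points; returning unchanged", len(pts), target)
        return pts.copy()
    extent = pts.max(axis=0) - pts.min(axis=0)
    lo = 1e-9
    hi = float(np.linalg.norm(extent)) + 1e-9
    best, best_err = pts.copy(), abs(len(pts) - target)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        out = voxel_downsample(pts, mid)
        err = abs(len(out) - target)
        if err < best_err:
            best, best_err = out, err
        if abs(len(out) - target) <= tolerance * target:
            return out
        if len(out) > target:
            lo = mid  # need larger voxels -> fewer points
        else:
            hi = mid
    return best


def standardize_image(image: np.ndarray) -> np.ndarray:
    """Center-crop to the largest square, bilinear-resize to 224x224,
    scale to [0, 1].

    Integer rasters are divided by 255; float inputs are assumed to be
    already on [0, 1] (making the operation idempotent on standardized
    rasters up to interpolation tolerance).
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise InvalidArgumentError("image must be a nonempty H x W x 3 raster")
    h, w = img.shape[:2]
    side = min(h, w)
    top = (h - side) // 2
    left = (w - side) // 2
    crop = img[top : top + side, left : left + side].astype(float)
    if np.issubdtype(img.dtype, np.integer):
        crop = crop / 255.0
    if crop.shape[:2] != (IMAGE_SIZE, IMAGE_SIZE):
        from skimage.transform import resize

        crop = resize(
            crop, (IMAGE_SIZE, IMAGE_SIZE), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    return np.clip(crop, 0.0, 1.0)


@dataclass
class SplitAssignment:
    """Plant-level train/validation/test assignment."""

    assignment: dict[str, str]
    seed: int

    def ids(self, partition: str) -> list[str]:
        return [p for p, lab in self.assignment.items() if lab == partition]


def split_plants(
    plant_ids: list[str],
    ratio: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Shuffle plants with the seed and split 6:2:2 (largest-remainder rounding).

    All records of a plant share its partition, which prevents leakage
    between training and evaluation data.
    """
    ids = list(plant_ids)
    if len(set(ids)) != len(ids):
        raise InvalidArgumentError("duplicate plant ids")
    if len(ids) < 5:
        raise InvalidArgumentError("need at least 5 plants to split")
    if abs(sum(ratio) - 1.0) > 1e-9:
        raise InvalidArgumentError("ratio fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    raw = [f * n for f in ratio]
    sizes = [int(np.floor(r)) for r in raw]
    remainders = [r - s for r, s in zip(raw, sizes)]
    for _ in range(n - sum(sizes)):
        j = int(np.argmax(remainders))
        sizes[j] += 1
        remainders[j] = -1.0
    labels = ["train"] * sizes[0] + ["validation"] * sizes[1] + ["test"] * sizes[2]
    return SplitAssignment(dict(zip(shuffled, labels)), seed)


def align_streams(
    left: pd.DataFrame,
    right: pd.DataFrame,
    on: str = "timestamp",
    tolerance_s: float = 0.1,
) -> pd.DataFrame:
    """Join two sensor streams on nearest timestamp.

    Models the acquisition system's synchronization contract: the join
    is rejected if any matched pair differs by more than ``tolerance_s``
    seconds.
    """
    lf = left.sort_values(on).reset_index(drop=True)
    rf = right.sort_values(on).reset_index(drop=True)
    merged = pd.merge_asof(
        lf, rf, on=on, direction="nearest", suffixes=("", "_right")
    )
    idx = rf[on].searchsorted(lf[on])
    idx_lo = np.clip(idx - 1, 0, len(rf) - 1)
    idx_hi = np.clip(idx, 0, len(rf) - 1)
    resid = np.minimum(
        np.abs((lf[on].values - rf[on].values[idx_lo]).astype("timedelta64[ns]").astype(float)),
        np.abs((rf[on].values[idx_hi] - lf[on].values).astype("timedelta64[ns]").astype(float)),
    ) / 1e9
    if np.any(resid > tolerance_s):
        worst = float(resid.max())
        raise InvalidArgumentError(
            f"stream alignment residual {worst:.3f}s exceeds tolerance {tolerance_s}s"
        )
    return merged


def load_point_cloud(path: str) -> np.ndarray:
    """Read a PLY/OBJ point cloud or mesh into an (N, 3) array via trimesh."""
    import trimesh

    obj = trimesh.load(path)
    if hasattr(obj, "vertices"):
        return np.asarray(obj.vertices, dtype=float)
    raise InvalidArgumentError(f"no point data found in {path}")
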
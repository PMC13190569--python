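"""Per-modality feature encoders.

The environmental encoder is a from-scratch 1-D convolutional LSTM with
peephole connections, unrolled over a normalized multi-day weather
window. The point-cloud and image encoders are deterministic
hand-crafted geometric/spectral descriptors exposing the same
vector-out interface as learned backbones; a plug-in registry lets
users substitute trained encoders without touching the fusion layer.

All encoders are pure functions of their inputs: the same input always
yields a bit-identical output, and descriptor lengths are fixed by
configuration, never by input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import InvalidArgumentError
from .preprocess import IMAGE_SIZE

__all__ = [
    "ConvLSTMParams",
    "ConvLSTMState",
    "FeatureBundle",
    "convlstm_cell",
    "encode_environment",
    "encode_point_cloud",
    "encode_image",
    "farthest_point_sample",
    "POINT_DESCRIPTOR_LENGTH",
    "IMAGE_DESCRIPTOR_LENGTH",
    "ENCODER_REGISTRY",
    "register_encoder",
    "fit_ridge_readout",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _xavier(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, shape)


@dataclass
class ConvLSTMParams:
    """Kernels, peepholes and biases of a 1-D peephole ConvLSTM cell.

    Input-to-state kernels have shape (hidden, in_channels, k);
    state-to-state kernels (hidden, hidden, k). Peephole weights are
    per-hidden-channel Hadamard factors broadcast over the spatial axis,
    so one parameter set serves any spatial length.
    """

    w_xi: np.ndarray
    w_xf: np.ndarray
    w_xc: np.ndarray
    w_xo: np.ndarray
    w_hi: np.ndarray
    w_hf: np.ndarray
    w_hc: np.ndarray
    w_ho: np.ndarray
    w_ci: np.ndarray
    w_cf: np.ndarray
    w_co: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise InvalidArgumentError("kernel_size must be odd")
        for name in ("w_xi", "w_xf", "w_xc", "w_xo", "w_hi", "w_hf", "w_hc", "w_ho"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise InvalidArgumentError(f"{name} contains non-finite values")

    @property
    def hidden_channels(self) -> int:
        return self.w_xi.shape[0]

    @property
    def in_channels(self) -> int:
        return self.w_xi.shape[1]

    @property
    def kernel_size(self) -> int:
        return self.w_xi.shape[2]

    @classmethod
    def initialize(
        cls,
        in_channels: int = 1,
        hidden_channels: int = 64,
        kernel_size: int = 3,
        seed: int = 0,
    ) -> "ConvLSTMParams":
        """Xavier-uniform initialization from a seed; biases start at zero."""
        if hidden_channels < 1 or kernel_size % 2 != 1:
            raise InvalidArgumentError("hidden_channels >= 1 and odd kernel_size required")
        rng = np.random.default_rng(seed)
        h, c, k = hidden_channels, in_channels, kernel_size

        def wx() -> np.ndarray:
            return _xavier(rng, (h, c, k), c * k, h * k)

        def wh() -> np.ndarray:
            return _xavier(rng, (h, h, k), h * k, h * k)

        def peep() -> np.ndarray:
            return _xavier(rng, (h,), h, h)

        return cls(
            w_xi=wx(), w_xf=wx(), w_xc=wx(), w_xo=wx(),
            w_hi=wh(), w_hf=wh(), w_hc=wh(), w_ho=wh(),
            w_ci=peep(), w_cf=peep(), w_co=peep(),
            b_i=np.zeros(h), b_f=np.zeros(h), b_c=np.zeros(h), b_o=np.zeros(h),
        )


@dataclass
class ConvLSTMState:
    """Hidden and cell state, each (hidden_channels, spatial_length)."""

    h: np.ndarray
    c: np.ndarray

    @classmethod
    def zeros(cls, hidden_channels: int, length: int) -> "ConvLSTMState":
        return cls(np.zeros((hidden_channels, length)), np.zeros((hidden_channels, length)))


def _conv1d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded 1-D cross-correlation: x (c_in, L) * w (c_out, c_in, k)."""
    k = w.shape[2]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (c_in, L, k)
    return np.einsum("oik,ilk->ol", w, windows)


def convlstm_cell(x: np.ndarray, state: ConvLSTMState, params: ConvLSTMParams) -> ConvLSTMState:
    """One ConvLSTM step with peephole gates.

    i = sigmoid(Wxi*X + Whi*H + Wci o C + bi)
    f = sigmoid(Wxf*X + Whf*H + Wcf o C + bf)
    C' = f o C + i o tanh(Wxc*X + Whc*H + bc)
    o = sigmoid(Wxo*X + Who*H + Wco o C' + bo)
    H' = o o tanh(C')

    ``*`` is same-padded convolution, ``o`` the Hadamard product.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] != params.in_channels:
        raise InvalidArgumentError(
            f"input must be ({params.in_channels}, L), got {x.shape}"
        )
    if state.h.shape != (params.hidden_channels, x.shape[1]):
        raise InvalidArgumentError("state shape does not match input/params")
    h_prev, c_prev = state.h, state.c
    b = lambda v: v[:, None]
    i = _sigmoid(_conv1d_same(x, params.w_xi) + _conv1d_same(h_prev, params.w_hi)
                 + b(params.w_ci) * c_prev + b(params.b_i))
    f = _sigmoid(_conv1d_same(x, params.w_xf) + _conv1d_same(h_prev, params.w_hf)
                 + b(params.w_cf) * c_prev + b(params.b_f))
    c_new = f * c_prev + i * np.tanh(
        _conv1d_same(x, params.w_xc) + _conv1d_same(h_prev, params.w_hc) + b(params.b_c)
    )
    o = _sigmoid(_conv1d_same(x, params.w_xo) + _conv1d_same(h_prev, params.w_ho)
                 + b(params.w_co) * c_new + b(params.b_o))
    return ConvLSTMState(h=o * np.tanh(c_new), c=c_new)


def encode_environment(
    window: np.ndarray, params: ConvLSTMParams, expected_width: int = 7
) -> np.ndarray:
    """Encode a normalized weather window into h_env.

    ``window`` is (T, d): T days by d channels. Each day enters the cell
    as a single-channel signal of spatial length d (the convolution
    mixes neighbouring channels); the cell is unrolled from a zero state
    and h_env is the spatial average of the final hidden state, length
    ``hidden_channels``.
    """
    win = np.atleast_2d(np.asarray(window, dtype=float))
    if win.shape[0] != expected_width:
        raise InvalidArgumentError(
            f"window length {win.shape[0]} != configured width {expected_width}"
        )
    if params.in_channels != 1:
        raise InvalidArgumentError("environment encoder expects single-channel params")
    state = ConvLSTMState.zeros(params.hidden_channels, win.shape[1])
    for t in range(win.shape[0]):
        state = convlstm_cell(win[t][None, :], state, params)
    return state.h.mean(axis=1)


# --------------------------------------------------------------------------
# Point-cloud descriptor
# --------------------------------------------------------------------------

POINT_SAMPLE = 1024
POINT_DESCRIPTOR_LENGTH = 5 + 3 + 3 + 10 + 1


def farthest_point_sample(points: np.ndarray, n_samples: int) -> np.ndarray:
    """Deterministic farthest-point sampling, seeded at the lowest-z point."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n <= n_samples:
        return pts.copy()
    chosen = np.empty(n_samples, dtype=np.int64)
    chosen[0] = int(np.argmin(pts[:, 2]))
    dist = np.linalg.norm(pts - pts[chosen[0]], axis=1)
    for i in range(1, n_samples):
        chosen[i] = int(np.argmax(dist))
        dist = np.minimum(dist, np.linalg.norm(pts - pts[chosen[i]], axis=1))
    return pts[chosen]


def encode_point_cloud(points: np.ndarray) -> np.ndarray:
    """Fixed-length geometric descriptor h_point of a plant point cloud.

    After deterministic farthest-point resampling to 1024 points:
    height percentiles (5/25/50/75/95), bounding-box extents, covariance
    eigenvalue shape ratios (linearity, planarity, sphericity), a 10-bin
    vertical density histogram, and the convex-hull-to-bounding-box
    volume ratio.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 8:
        raise InvalidArgumentError("need an (N, 3) cloud with N >= 8")
    pts = farthest_point_sample(pts, POINT_SAMPLE)
    z = pts[:, 2]
    percentiles = np.percentile(z, [5, 25, 50, 75, 95])
    extents = pts.max(axis=0) - pts.min(axis=0)
    cov = np.cov(pts.T)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    l1 = max(eig[0], 1e-300)
    linearity = (eig[0] - eig[1]) / l1
    planarity = (eig[1] - eig[2]) / l1
    sphericity = max(eig[2], 0.0) / l1
    span = z.max() - z.min()
    if span > 0:
        hist, _ = np.histogram(z, bins=10, range=(z.min(), z.max()))
        hist = hist / len(z)
    else:
        hist = np.zeros(10)
        hist[0] = 1.0
    bbox_vol = float(np.prod(extents))
    if bbox_vol > 0:
        try:
            hull_ratio = ConvexHull(pts).volume / bbox_vol
        except QhullError:
            hull_ratio = 0.0
    else:
        hull_ratio = 0.0
    return np.concatenate(
        [percentiles, extents, [linearity, planarity, sphericity], hist, [hull_ratio]]
    )


# --------------------------------------------------------------------------
# Image descriptor
# --------------------------------------------------------------------------

IMAGE_DESCRIPTOR_LENGTH = 3 * 8 + 2 + 1 + 1 + 5
EXG_COVER_THRESHOLD = 0.1


def encode_image(image: np.ndarray) -> np.ndarray:
    """Fixed-length spectral/texture descriptor h_rgb of a standardized raster.

    Per-channel 8-bin histograms, excess-green index (2G - R - B)
    mean/sd, green-cover fraction (ExG above 0.1), Sobel
    gradient-energy texture of the luminance, and the green-cover
    fraction in 5 concentric rings from the image centre.
    """
    img = np.asarray(image, dtype=float)
    if img.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
        raise InvalidArgumentError(f"expected standardized {IMAGE_SIZE}x{IMAGE_SIZE}x3 raster")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise InvalidArgumentError("standardized raster must have values in [0, 1]")
    hists = [
        np.histogram(img[..., c], bins=8, range=(0.0, 1.0))[0] / img[..., c].size
        for c in range(3)
    ]
    exg = 2 * img[..., 1] - img[..., 0] - img[..., 2]
    cover_mask = exg > EXG_COVER_THRESHOLD
    cover = float(cover_mask.mean())
    from skimage.filters import sobel

    gray = img.mean(axis=2)
    grad_energy = float(np.mean(sobel(gray) ** 2))
    yy, xx = np.mgrid[0:IMAGE_SIZE, 0:IMAGE_SIZE]
    center = (IMAGE_SIZE - 1) / 2.0
    r = np.hypot(yy - center, xx - center)
    r_max = r.max()
    rings = []
    for i in range(5):
        ring = (r >= i * r_max / 5) & (r < (i + 1) * r_max / 5 + (1 if i == 4 else 0))
        rings.append(float(cover_mask[ring].mean()) if ring.any() else 0.0)
    return np.concatenate(
        [*hists, [float(exg.mean()), float(exg.std()), cover, grad_energy], rings]
    )


# --------------------------------------------------------------------------
# Bundle, registry and readout
# --------------------------------------------------------------------------


@dataclass
class FeatureBundle:
    """Per-modality feature vectors consumed by the fusion layer."""

    h_env: np.ndarray
    h_point: np.ndarray
    h_rgb: np.ndarray

    def __post_init__(self) -> None:
        for name in ("h_env", "h_point", "h_rgb"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1 or not np.all(np.isfinite(v)):
                raise InvalidArgumentError(f"{name} must be a finite 1-D vector")
            setattr(self, name, v)

    @property
    def dims(self) -> dict[str, int]:
        return {"env": len(self.h_env), "point": len(self.h_point), "rgb": len(self.h_rgb)}


ENCODER_REGISTRY: dict[str, object] = {}


def register_encoder(name: str):
    """Register a named encoder callable for the plug-in contract."""

    def deco(fn):
        ENCODER_REGISTRY[name] = fn
        return fn

    return deco


ENCODER_REGISTRY["env_convlstm"] = encode_environment
ENCODER_REGISTRY["point_descriptor"] = encode_point_cloud
ENCODER_REGISTRY["rgb_descriptor"] = encode_image


def fit_ridge_readout(
    features: np.ndarray, targets: np.ndarray, alpha: float = 1e-3
) -> tuple[np.ndarray, float]:
    """Closed-form ridge regression readout (weights, intercept).

    A minimal gradient-free trainer mapping fused features to a scalar
    trait, used in the parameter-recovery demonstrations.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    w = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(X.shape[1]), Xc.T @ yc)
    return w, float(ym - xm @ w)
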
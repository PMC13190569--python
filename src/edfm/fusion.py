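"""Gated attention fusion of the three modality feature vectors.

Each modality is first linearly projected to a common dimension D (the
source descriptors have different lengths). The canonical scoring is
the two-stage tanh + softmax gate: s_i = tanh(w_i . h_i + b_i) followed
by alpha = softmax(s), giving weights on the 2-simplex; an alternative
"concatenated" mode scores each modality by a linear functional of the
concatenated raw feature vector. The fused representation is the convex
combination h_fusion = sum_i alpha_i h_i(projected).

Per-stage mean weight trajectories expose which modality dominates each
growth stage, the mechanism's interpretability surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax

from .encoders import FeatureBundle
from .errors import InvalidArgumentError

__all__ = [
    "MODALITIES",
    "GateParams",
    "AttentionWeights",
    "FusedFeature",
    "score_modality",
    "attention_weights",
    "fuse",
    "weight_trajectory",
]

MODALITIES = ("env", "rgb", "point")


@dataclass
class GateParams:
    """Projection and scoring parameters of the gated attention network.

    ``projections[m]`` is the (D, d_m) matrix taking modality m to the
    common dimension D; ``score_w[m]``/``score_b[m]`` parameterize the
    per-modality tanh score; ``concat_w[m]`` the alternative
    concatenated-score functional (kept as distinct parameters).
    """

    projections: dict[str, np.ndarray]
    score_w: dict[str, np.ndarray]
    score_b: dict[str, float]
    concat_w: dict[str, np.ndarray] = field(default_factory=dict)
    scoring_mode: str = "per_modality"  # or "concatenated"

    def __post_init__(self) -> None:
        if self.scoring_mode not in ("per_modality", "concatenated"):
            raise InvalidArgumentError(f"unknown scoring_mode {self.scoring_mode!r}")
        dims = {m: p.shape[0] for m, p in self.projections.items()}
        if len(set(dims.values())) != 1:
            raise InvalidArgumentError("all projections must share the output dimension D")

    @property
    def dim(self) -> int:
        return next(iter(self.projections.values())).shape[0]

    @classmethod
    def initialize(
        cls,
        dims: dict[str, int],
        d: int = 32,
        seed: int = 0,
        scoring_mode: str = "per_modality",
    ) -> "GateParams":
        """Xavier-uniform initialization from a config seed."""
        rng = np.random.default_rng(seed)

        def xavier(shape, fan_in, fan_out):
            bound = math.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-bound, bound, shape)

        if set(dims) != set(MODALITIES):
            raise InvalidArgumentError(f"dims must cover modalities {MODALITIES}")
        proj = {m: xavier((d, dims[m]), dims[m], d) for m in MODALITIES}
        sw = {m: xavier((d,), d, 1) for m in MODALITIES}
        sb = {m: 0.0 for m in MODALITIES}
        d_total = sum(dims.values())
        cw = {m: xavier((d_total,), d_total, 1) for m in MODALITIES}
        return cls(proj, sw, sb, cw, scoring_mode)


@dataclass
class AttentionWeights:
    """Per-modality softmax weights (alpha_env, alpha_rgb, alpha_point)."""

    alpha: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.alpha.values())
        if any(a < 0 for a in self.alpha.values()) or abs(total - 1.0) > 1e-12:
            raise InvalidArgumentError("attention weights must be nonnegative and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha[m] for m in MODALITIES])


@dataclass
class FusedFeature:
    h_fusion: np.ndarray
    weights: AttentionWeights


def score_modality(h: np.ndarray, params: GateParams, modality: str) -> float:
    """Bounded importance score s = tanh(w . P h + b) in (-1, 1)."""
    if modality not in params.projections:
        raise InvalidArgumentError(f"unknown modality {modality!r}")
    p = params.projections[modality]
    h = np.asarray(h, dtype=float)
    if h.shape != (p.shape[1],):
        raise InvalidArgumentError(
            f"{modality} vector has length {h.shape}, projection expects {p.shape[1]}"
        )
    return float(np.tanh(params.score_w[modality] @ (p @ h) + params.score_b[modality]))


def attention_weights(scores: dict[str, float] | np.ndarray) -> AttentionWeights:
    """Softmax normalization of the modality scores (shift-invariant)."""
    if isinstance(scores, dict):
        keys = tuple(scores)
        vals = np.array([scores[k] for k in keys], dtype=float)
    else:
        keys = MODALITIES
        vals = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise InvalidArgumentError("scores must be finite")
    alpha = softmax(vals)
    return AttentionWeights({k: float(a) for k, a in zip(keys, alpha)})


def fuse(
    bundle: FeatureBundle,
    params: GateParams,
    masked: bool = False,
    mask: dict[str, bool] | None = None,
) -> FusedFeature:
    """Project, score, weight and combine the three modalities.

    With ``masked=True`` and a mask marking absent modalities, the
    softmax renormalizes over the present ones (missing-data days);
    otherwise all three modalities are required.
    """
    vectors = {"env": bundle.h_env, "rgb": bundle.h_rgb, "point": bundle.h_point}
    present = [m for m in MODALITIES if mask is None or mask.get(m, True)]
    if len(present) < len(MODALITIES) and not masked:
        missing = set(MODALITIES) - set(present)
        raise InvalidArgumentError(f"missing modalities {sorted(missing)} (masked mode is off)")
    if not present:
        raise InvalidArgumentError("at least one modality must be present")
    projected = {m: params.projections[m] @ np.asarray(vectors[m], float) for m in present}
    if params.scoring_mode == "per_modality":
        scores = {m: score_modality(vectors[m], params, m) for m in present}
    else:
        concat = np.concatenate([np.asarray(vectors[m], float) for m in MODALITIES])
        scores = {m: float(params.concat_w[m] @ concat) for m in present}
    weights = attention_weights(scores)
    h_fusion = sum(weights.alpha[m] * projected[m] for m in present)
    if len(present) < len(MODALITIES):
        full = {m: weights.alpha.get(m, 0.0) for m in MODALITIES}
        weights = AttentionWeights(full)
    return FusedFeature(np.asarray(h_fusion), weights)


def weight_trajectory(
    daily_weights: list[AttentionWeights],
    stage_labels: list[str],
    stage_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-growth-stage arithmetic mean of the daily attention weights.

    Returns one row per stage with columns alpha_point, alpha_rgb,
    alpha_env; every row sums to 1 (averaging preserves the simplex).
    """
    if len(daily_weights) != len(stage_labels):
        raise InvalidArgumentError("one stage label per day of weights required")
    if not daily_weights:
        raise InvalidArgumentError("need at least one day of weights")
    df = pd.DataFrame(
        {
            "stage": stage_labels,
            "alpha_point": [w.alpha["point"] for w in daily_weights],
            "alpha_rgb": [w.alpha["rgb"] for w in daily_weights],
            "alpha_env": [w.alpha["env"] for w in daily_weights],
        }
    )
    table = df.groupby("stage", sort=False).mean()
    if stage_order is not None:
        table = table.reindex([s for s in stage_order if s in table.index])
    return table
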
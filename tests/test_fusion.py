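"""Gated attention scoring, softmax weights, fusion and trajectories."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from edfm.encoders import FeatureBundle
from edfm.errors import InvalidArgumentError
from edfm.fusion import (
    MODALITIES,
    AttentionWeights,
    GateParams,
    attention_weights,
    fuse,
    score_modality,
    weight_trajectory,
)

DIMS = {"env": 6, "rgb": 5, "point": 4}


def _params(seed=0, mode="per_modality"):
    return GateParams.initialize(DIMS, d=3, seed=seed, scoring_mode=mode)


def _bundle(seed=0):
    rng = np.random.default_rng(seed)
    return FeatureBundle(
        h_env=rng.normal(size=DIMS["env"]),
        h_rgb=rng.normal(size=DIMS["rgb"]),
        h_point=rng.normal(size=DIMS["point"]),
    )


class TestScoreModality:
    def test_zero_parameters_score_zero(self):
        p = _params()
        p.score_w["env"][:] = 0.0
        p.score_b["env"] = 0.0
        assert score_modality(np.ones(DIMS["env"]), p, "env") == 0.0

    def test_tanh_of_half(self):
        p = _params()
        p.projections["env"] = np.eye(1, DIMS["env"], 0) * 0  # project to zero
        p.projections["env"] = np.zeros((3, DIMS["env"]))
        p.score_b["env"] = 0.5
        assert score_modality(np.ones(DIMS["env"]), p, "env") == pytest.approx(
            0.4621, abs=1e-4
        )

    @given(st.integers(0, 10_000))
    def test_bounded_open_interval(self, seed):
        rng = np.random.default_rng(seed)
        p = _params(seed % 17)
        s = score_modality(rng.normal(size=DIMS["env"]), p, "env")
        assert -1.0 < s < 1.0
        # extreme inputs saturate to the bound in floating point, never beyond
        s_big = score_modality(rng.normal(size=DIMS["env"]) * 1e6, p, "env")
        assert -1.0 <= s_big <= 1.0

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            score_modality(np.ones(3), _params(), "env")


class TestAttentionWeights:
    def test_equal_scores_uniform(self):
        w = attention_weights(np.array([0.3, 0.3, 0.3]))
        assert np.allclose(w.as_array(), 1 / 3)

    def test_printed_softmax_values(self):
        w = attention_weights(np.array([1.0, 0.0, -1.0]))
        assert np.allclose(w.as_array(), [0.6652, 0.2447, 0.0900], atol=1e-4)

    @given(st.lists(st.floats(-30, 30), min_size=3, max_size=3), st.floats(-20, 20))
    def test_shift_invariance_and_simplex(self, scores, c):
        s = np.array(scores)
        w1 = attention_weights(s).as_array()
        w2 = attention_weights(s + c).as_array()
        assert np.allclose(w1, w2, atol=1e-12)
        assert abs(w1.sum() - 1.0) < 1e-12
        assert np.all(w1 >= 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            attention_weights(np.array([np.inf, 0.0, 0.0]))


class TestFuse:
    def test_forced_single_modality(self):
        p = _params()
        for m in MODALITIES:
            p.score_w[m][:] = 0.0
        p.score_b["env"] = 0.999999
        for m in ("rgb", "point"):
            p.score_b[m] = -0.999999
        out = fuse(_bundle(), p)
        assert out.weights.alpha["env"] == max(out.weights.alpha.values())

    def test_single_present_modality_reproduces_projection(self):
        # with the other modalities masked out, alpha_env = 1 and the
        # fused vector is exactly the projected environment feature
        p = _params()
        b = _bundle()
        out = fuse(b, p, masked=True, mask={"rgb": False, "point": False})
        assert out.weights.alpha["env"] == pytest.approx(1.0)
        assert np.allclose(out.h_fusion, p.projections["env"] @ b.h_env)

    def test_weighted_sum_of_basis_vectors(self):
        # projections mapping each modality to a separate basis vector
        p = _params()
        d = 3
        p.projections["env"] = np.zeros((d, DIMS["env"]))
        p.projections["rgb"] = np.zeros((d, DIMS["rgb"]))
        p.projections["point"] = np.zeros((d, DIMS["point"]))
        bundle = FeatureBundle(
            h_env=np.ones(DIMS["env"]), h_rgb=np.ones(DIMS["rgb"]),
            h_point=np.ones(DIMS["point"]),
        )
        p.projections["env"][0, 0] = 1.0
        p.projections["rgb"][1, 0] = 1.0
        p.projections["point"][2, 0] = 1.0
        out = fuse(bundle, p)
        a = out.weights.alpha
        assert np.allclose(out.h_fusion, [a["env"], a["rgb"], a["point"]])

    def test_equal_weights_mean(self):
        p = _params()
        for m in MODALITIES:
            p.score_w[m][:] = 0.0
            p.score_b[m] = 0.0
        b = _bundle(3)
        out = fuse(b, p)
        proj = [p.projections[m] @ getattr(b, f"h_{m}") for m in MODALITIES]
        assert np.allclose(out.h_fusion, np.mean(proj, axis=0))

    def test_convex_combination_norm_bound(self):
        p = _params(4)
        b = _bundle(4)
        out = fuse(b, p)
        norms = [np.linalg.norm(p.projections[m] @ getattr(b, f"h_{m}")) for m in MODALITIES]
        assert np.linalg.norm(out.h_fusion) <= max(norms) + 1e-12

    def test_missing_modality_requires_masked_mode(self):
        p = _params()
        b = _bundle()
        with pytest.raises(InvalidArgumentError):
            fuse(b, p, masked=False, mask={"rgb": False})
        out = fuse(b, p, masked=True, mask={"rgb": False})
        assert out.weights.alpha["rgb"] == 0.0
        assert sum(out.weights.alpha.values()) == pytest.approx(1.0)

    def test_concatenated_mode_blocksparse_equivalence(self):
        """Concatenated scoring with block-sparse weights equals per-modality
        linear scoring (the documented equivalence when tanh is bypassed)."""
        p = _params(mode="concatenated")
        rng = np.random.default_rng(8)
        b = _bundle(8)
        order = MODALITIES  # concatenation order env, rgb, point
        offsets = np.cumsum([0] + [DIMS[m] for m in order])
        linear_scores = {}
        for i, m in enumerate(order):
            w_m = rng.normal(size=DIMS[m])
            full = np.zeros(offsets[-1])
            full[offsets[i] : offsets[i + 1]] = w_m  # selects only h_m
            p.concat_w[m] = full
            linear_scores[m] = float(w_m @ getattr(b, f"h_{m}"))
        out = fuse(b, p)
        expected = attention_weights(linear_scores)
        assert np.allclose(out.weights.as_array(), expected.as_array(), atol=1e-12)


class TestWeightTrajectory:
    def _w(self, a, b, c):
        return AttentionWeights({"env": a, "rgb": b, "point": c})

    def test_constant_weights_every_stage(self):
        w = self._w(0.2, 0.3, 0.5)
        table = weight_trajectory([w] * 6, ["veg"] * 3 + ["rep"] * 3)
        assert np.allclose(table.loc["veg"], [0.5, 0.3, 0.2])
        assert np.allclose(table.loc["rep"], [0.5, 0.3, 0.2])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        ws = []
        for _ in range(9):
            a = rng.dirichlet([1, 1, 1])
            ws.append(self._w(*a))
        table = weight_trajectory(ws, ["a", "b", "c"] * 3)
        assert np.allclose(table.sum(axis=1), 1.0)

    def test_two_day_mean(self):
        ws = [self._w(1.0, 0.0, 0.0), self._w(0.0, 1.0, 0.0)]
        table = weight_trajectory(ws, ["s", "s"])
        assert np.allclose(table.loc["s"], [0.0, 0.5, 0.5])  # point, rgb, env

    def test_label_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            weight_trajectory([self._w(1, 0, 0)], ["a", "b"])
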
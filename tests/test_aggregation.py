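"""Attention-weighted frame aggregation: hand examples, oracle, properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcedn.aggregation import (AggregationConfig, FrameSequence, LearnablePhi,
                               aggregate_video, aggregate_window, phi_map,
                               weight_frame)
from tcedn.nn import Tensor
from tcedn.synthetic import make_fixture


# ------------------------------------------------------------------- oracle
def oracle_weight_frame(Xj, Xi, d):
    """Pixel-by-pixel loop evaluation of the attention weighting."""
    C, H, W = Xi.shape
    prod = np.zeros_like(Xi)
    for c in range(C):
        for h in range(H):
            for w in range(W):
                prod[c, h, w] = Xj[c, h, w] * Xi[c, h, w] / d
    m = np.max(np.abs(prod))
    out = np.zeros_like(Xi)
    for c in range(C):
        for h in range(H):
            for w in range(W):
                wmap = prod[c, h, w] / m if m > 0 else 0.0
                out[c, h, w] = wmap * Xi[c, h, w]
    return out


def oracle_aggregate(frames, cfg):
    d = cfg.scale_for(frames.shape[1:])
    if cfg.window_mode == "sliding":
        refs = range(1, frames.shape[0] - 1)
        triples = [(i - 1, i, i + 1) for i in refs]
    else:
        triples = [(3 * k, 3 * k + 1, 3 * k + 2)
                   for k in range(frames.shape[0] // 3)]
    out = []
    for p, i, n in triples:
        out.append(cfg.alpha * oracle_weight_frame(frames[p], frames[i], d)
                   + cfg.gamma * frames[i]
                   + cfg.beta * oracle_weight_frame(frames[n], frames[i], d))
    return np.stack(out)


# ------------------------------------------------------------------ phi map
def test_phi_identity_and_learnable_init():
    frame = np.random.default_rng(0).uniform(size=(2, 3, 3))
    cfg = AggregationConfig()
    np.testing.assert_array_equal(phi_map(frame, cfg), frame)
    cfg_l = AggregationConfig(phi_mode="learnable-pointwise")
    phi = LearnablePhi(2)
    np.testing.assert_allclose(phi_map(frame, cfg_l, phi), frame, rtol=1e-6)
    phi.scale.data[:] = 2.0
    np.testing.assert_allclose(phi_map(frame, cfg_l, phi), 2 * frame, rtol=1e-6)


def test_phi_rejects_non_finite():
    with pytest.raises(ValueError):
        phi_map(np.array([[[np.nan]]]), AggregationConfig())


# ------------------------------------------------------------- weight frame
def test_weight_frame_constant_positive_maps_to_reference():
    Xi = np.full((1, 2, 2), 0.7)
    out = weight_frame(Xi.copy(), Xi, AggregationConfig(d=5.0))
    np.testing.assert_allclose(out, Xi, rtol=1e-12)


def test_weight_frame_hand_example():
    # 1x1x2 frames, d=1: product [2,4] -> weights [0.5,1] -> output [1,2]
    Xj = np.array([1.0, 2.0]).reshape(1, 1, 2)
    Xi = np.array([2.0, 2.0]).reshape(1, 1, 2)
    out = weight_frame(Xj, Xi, AggregationConfig(d=1.0))
    np.testing.assert_allclose(out.ravel(), [1.0, 2.0], rtol=1e-12)


def test_weight_frame_zero_neighbour_annihilates():
    Xi = np.random.default_rng(1).uniform(size=(2, 3, 3))
    out = weight_frame(np.zeros_like(Xi), Xi)
    np.testing.assert_array_equal(out, np.zeros_like(Xi))


def test_weight_frame_shape_mismatch():
    with pytest.raises(ValueError):
        weight_frame(np.zeros((1, 2, 2)), np.zeros((1, 3, 3)))


# --------------------------------------------------------- window aggregate
def test_degenerate_weights_return_reference():
    rng = np.random.default_rng(2)
    a, b, c = rng.uniform(size=(3, 1, 2, 2))
    cfg = AggregationConfig(alpha=0.0, beta=0.0, gamma=1.0)
    np.testing.assert_allclose(aggregate_window(a, b, c, cfg), b, rtol=1e-12)


def test_constant_window_returns_reference():
    f = np.full((1, 2, 2), 0.4)
    cfg = AggregationConfig(alpha=0.05, beta=0.05, gamma=0.9)
    np.testing.assert_allclose(aggregate_window(f, f, f, cfg), f, rtol=1e-12)


def test_aggregate_window_matches_oracle():
    rng = np.random.default_rng(3)
    frames = rng.uniform(size=(3, 1, 2, 2))
    cfg = AggregationConfig()
    got = aggregate_window(frames[0], frames[1], frames[2], cfg)
    d = cfg.scale_for(frames.shape[1:])
    want = (cfg.alpha * oracle_weight_frame(frames[0], frames[1], d)
            + cfg.gamma * frames[1]
            + cfg.beta * oracle_weight_frame(frames[2], frames[1], d))
    np.testing.assert_allclose(got, want, rtol=1e-10)


def test_invalid_weight_sum_rejected():
    with pytest.raises(ValueError):
        AggregationConfig(alpha=0.3, beta=0.3, gamma=0.3)


# ------------------------------------------------------------- whole clips
@pytest.mark.parametrize("T,mode,expected", [
    (66, "sliding", 64),     # 66 sampled frames -> 64 aggregated
    (48, "nonoverlap", 16),  # 48 sampled frames -> 16 aggregated
    (3, "nonoverlap", 1),
    (3, "sliding", 1),
])
def test_window_count_identities(T, mode, expected):
    frames = np.random.default_rng(4).uniform(size=(T, 1, 2, 3))
    cfg = AggregationConfig(window_mode=mode)
    out = aggregate_video(frames, cfg, target_T=expected)
    assert out.shape == (expected, 1, 2, 3)


def test_single_triple_equals_window():
    frames = np.random.default_rng(5).uniform(size=(3, 2, 2, 2))
    cfg = AggregationConfig(window_mode="nonoverlap")
    clip = aggregate_video(frames, cfg)
    win = aggregate_window(frames[0], frames[1], frames[2], cfg)
    np.testing.assert_allclose(clip[0], win, rtol=1e-10)


def test_inconsistent_target_raises():
    frames = np.zeros((9, 1, 2, 2))
    with pytest.raises(ValueError):
        aggregate_video(frames, AggregationConfig(window_mode="sliding"),
                        target_T=3)
    with pytest.raises(ValueError):
        aggregate_video(np.zeros((8, 1, 2, 2)),
                        AggregationConfig(window_mode="nonoverlap"))


@pytest.mark.parametrize("mode", ["sliding", "nonoverlap"])
@pytest.mark.parametrize("T", [3, 6, 9])
def test_aggregate_video_matches_nested_loop_oracle(mode, T):
    rng = np.random.default_rng(T * 11)
    frames = rng.uniform(size=(T, 2, 4, 4))
    cfg = AggregationConfig(window_mode=mode)
    got = aggregate_video(frames, cfg)
    want = oracle_aggregate(frames, cfg)
    np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-9)


def test_identity_anchor_alpha_beta_zero():
    frames = make_fixture("two_by_two_random", seed=9).frames
    cfg = AggregationConfig(alpha=0.0, beta=0.0, gamma=1.0,
                            window_mode="sliding")
    out = aggregate_video(frames, cfg)
    np.testing.assert_allclose(out, frames[1:-1], rtol=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_boundedness_property(seed):
    """Inputs in [0,1] with max-abs normalization keep outputs in [-1, 1]."""
    rng = np.random.default_rng(seed)
    frames = rng.uniform(size=(6, 1, 3, 3))
    out = aggregate_video(frames, AggregationConfig(window_mode="nonoverlap"))
    assert np.all(out >= -1.0 - 1e-9) and np.all(out <= 1.0 + 1e-9)


def test_tensor_path_matches_numpy_path():
    frames = np.random.default_rng(12).uniform(size=(6, 1, 3, 3))
    cfg = AggregationConfig(window_mode="nonoverlap")
    out_np = aggregate_video(frames, cfg)
    out_t = aggregate_video(Tensor(frames), cfg)
    np.testing.assert_allclose(out_t.data, out_np, rtol=1e-12)


def test_frame_sequence_round_trip():
    seq = FrameSequence(np.random.default_rng(0).uniform(size=(6, 1, 3, 3)))
    out = aggregate_video(seq, AggregationConfig(window_mode="nonoverlap"))
    assert isinstance(out, FrameSequence)
    assert out.frame_count == 2 and out.frame_shape == (1, 3, 3)
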
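"""Model/Results facade, ablation harness, robustness table, and clip I/O."""

import numpy as np
import pandas as pd
import pytest

from tcedn.aggregation import FrameSequence
from tcedn.backbone import BackboneConfig
from tcedn.config import scaled_config
from tcedn.io import load_clip, load_manifest_dataset, save_clip, write_dataset
from tcedn.model import TCEDNModel
from tcedn.perturb import PerturbationSpec
from tcedn.synthetic import SyntheticSpec, generate_dataset
from tcedn.training import (TABLE2_VARIANTS, Preprocessor, TrainConfig,
                            ablation_run, robustness_suite)


def tiny_config():
    cfg = scaled_config()
    cfg.input.frame_height = 12
    cfg.input.frame_width = 33
    cfg.input.frames_per_clip = 12
    cfg.backbone = BackboneConfig(
        in_channels=1, stage_channels=(2, 4), blocks_per_stage=1,
        convlstm_hidden=4, head_channels=(4,), temporal_stride_stages=(1,))
    cfg.train = TrainConfig(learning_rate=1e-3, max_epochs=2, seed=0)
    return cfg


@pytest.fixture(scope="module")
def tiny_fit():
    cfg = tiny_config()
    model = TCEDNModel.from_synthetic(n=12, seed=3, config=cfg)
    return model, model.fit()


def test_fit_results_surface(tiny_fit):
    model, res = tiny_fit
    assert len(res.history) == 2
    assert {"epoch", "lr", "train_mae", "train_rmse"} <= set(res.history.columns)
    preds = res.predict()
    assert preds.shape == (12,) and np.isfinite(preds).all()
    rep = res.evaluate("test")
    assert rep.rmse >= rep.mae >= 0
    text = res.summary()
    assert "trainable parameters" in text and "GFLOPs" in text
    assert res.n_parameters == res.net.num_parameters()


def test_results_robustness_table(tiny_fit):
    _, res = tiny_fit
    specs = [PerturbationSpec("identity"),
             PerturbationSpec("gaussian_noise", sigma=0.3, seed=1)]
    table = res.robustness("test", specs=specs)
    assert list(table["kind"]) == ["identity", "gaussian_noise"]
    assert (table["n_clips"] == (res.model.splits == "test").sum()).all()
    base = res.evaluate("test")
    row = table[table["kind"] == "identity"].iloc[0]
    assert row["mae"] == pytest.approx(base.mae)
    assert row["rmse"] == pytest.approx(base.rmse)


def test_plots_return_axes(tiny_fit):
    import matplotlib
    matplotlib.use("Agg")
    _, res = tiny_fit
    assert res.plot_history() is not None
    assert res.plot_error_distribution("test") is not None


def test_mismatched_channels_rejected():
    cfg = tiny_config()
    clips = [np.zeros((12, 3, 12, 33))]
    with pytest.raises(ValueError):
        TCEDNModel(clips, [5.0], config=cfg)


# ------------------------------------------------------------- preprocessor
def test_preprocessor_modes_shapes():
    clip = np.random.default_rng(0).uniform(size=(12, 2, 6, 9))
    for mode, c, t in [("awam", 2, 4), ("splice", 6, 4),
                       ("decimate", 2, 4), ("raw", 2, 12)]:
        pre = Preprocessor(mode)
        from tcedn.aggregation import AggregationConfig
        pre.agg_cfg = AggregationConfig(window_mode="nonoverlap")
        out = pre(clip)
        assert out.shape == (c, t, 6, 9), mode
        assert pre.channels_out(2) == c and pre.frames_out(12) == t


def test_splice_concatenates_triples_channelwise():
    clip = np.arange(12 * 2 * 2).reshape(12, 1, 2, 2).astype(float)
    out = Preprocessor("splice")(clip)          # (3, 4, 2, 2)
    np.testing.assert_array_equal(out[0, 0], clip[0, 0])
    np.testing.assert_array_equal(out[1, 0], clip[1, 0])
    np.testing.assert_array_equal(out[2, 0], clip[2, 0])


# ----------------------------------------------------------------- ablation
def test_ablation_variants_run_and_differ():
    cfg = tiny_config()
    spec = SyntheticSpec(frame_shape=(12, 33), frames_per_clip=12)
    clips, manifest = generate_dataset(10, spec, seed=1)
    raw = [c.sequence for c in clips]
    out = ablation_run(raw, manifest["bdi_score"], manifest["split"],
                       cfg.backbone, cfg.train,
                       variants=("full", "3dcnn+lstm", "splice+3dcnn+convlstm"))
    assert set(out) == {"full", "3dcnn+lstm", "splice+3dcnn+convlstm"}
    for name, r in out.items():
        assert np.isfinite(r["report"].mae)
        assert len(r["history"]) == cfg.train.max_epochs
    # variant nets genuinely differ in wiring
    assert out["3dcnn+lstm"]["net"].recurrent.spatial == (1, 1)
    assert out["splice+3dcnn+convlstm"]["net"].cfg.in_channels == 3


def test_contradictory_ablation_flags_rejected():
    cfg = tiny_config()
    with pytest.raises(ValueError):
        ablation_run([np.zeros((12, 1, 12, 33))], [1.0], ["train"],
                     cfg.backbone, cfg.train,
                     variants=({"use_awam": True, "use_splice_baseline": True},))


def test_variant_grid_covers_flag_semantics():
    full = TABLE2_VARIANTS["full"]
    assert full["use_awam"] and full["use_stdwm"] and full["use_convlstm"]
    baseline = TABLE2_VARIANTS["3dcnn+lstm"]
    assert not baseline["use_convlstm"]


# ----------------------------------------------------------------------- io
def test_clip_round_trip_npz_and_png(tmp_path):
    frames = np.random.default_rng(0).uniform(size=(4, 1, 6, 9))
    p = save_clip(tmp_path / "clip_a", frames, fmt="npz")
    np.testing.assert_allclose(load_clip(p), frames, atol=1e-6)
    d = save_clip(tmp_path / "clip_b", frames, fmt="png")
    np.testing.assert_allclose(load_clip(d), frames, atol=1 / 255)


def test_dataset_write_and_manifest_load(tmp_path):
    spec = SyntheticSpec(frame_shape=(12, 33), frames_per_clip=6)
    clips, manifest = generate_dataset(5, spec, seed=0)
    mpath = write_dataset(tmp_path / "ds", clips, manifest)
    loaded_clips, labels, splits = load_manifest_dataset(mpath)
    assert len(loaded_clips) == 5
    np.testing.assert_allclose(labels, manifest["bdi_score"], rtol=1e-6)
    np.testing.assert_allclose(loaded_clips[2].frames,
                               clips[2].sequence.frames, atol=1e-6)
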
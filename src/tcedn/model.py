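"""Model / Results facade over the severity-regression pipeline.

``TCEDNModel`` binds a labelled clip collection to an experiment
configuration; ``fit()`` runs the seeded training protocol and returns a
``TCEDNResults`` carrying the trained network, the epoch history, metrics on
any split, robustness tables, complexity accounting and plots:

    >>> model = TCEDNModel.from_synthetic(n=96, seed=7)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.evaluate("test").mae
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .aggregation import FrameSequence
from .backbone import build_network
from .complexity import count_flops, count_params
from .config import ExperimentConfig, scaled_config
from .io import load_manifest_dataset
from .metrics import MetricsReport, compute_report
from .synthetic import SyntheticSpec, generate_dataset
from .training import (Preprocessor, TrainConfig, evaluate_network,
                       robustness_suite, train)

__all__ = ["TCEDNModel", "TCEDNResults"]


class TCEDNModel:
    """A severity-regression model bound to data and a configuration.

    Parameters
    ----------
    clips : sequence of FrameSequence (or (T, C, H, W) arrays)
    labels : BDI-II-scale scores in [0, 63]
    splits : per-clip 'train' / 'val' / 'test' tags; defaults to all 'train'
    config : ExperimentConfig; defaults to the shipped scaled configuration
    use_stdwm, use_convlstm : module ablation switches
    """

    def __init__(self, clips, labels, splits=None,
                 config: ExperimentConfig | None = None,
                 use_stdwm: bool = True, use_convlstm: bool = True):
        if len(clips) != len(labels):
            raise ValueError("clips and labels differ in length")
        self.config = config or scaled_config()
        self.clips = [c if isinstance(c, FrameSequence) else FrameSequence(c)
                      for c in clips]
        self.labels = np.asarray(labels, dtype=float)
        self.splits = (np.asarray(splits, dtype=object) if splits is not None
                       else np.full(len(clips), "train", dtype=object))
        self.use_stdwm = use_stdwm
        self.use_convlstm = use_convlstm
        self.preprocessor = Preprocessor("awam", self.config.aggregation)
        raw_c = self.clips[0].frames.shape[1]
        if raw_c != self.config.input.channels:
            raise ValueError(
                f"clips have {raw_c} channels but the configuration expects "
                f"{self.config.input.channels}")

    # ------------------------------------------------------------ constructors
    @classmethod
    def from_synthetic(cls, n: int = 96, spec: SyntheticSpec | None = None,
                       seed: int = 0, config: ExperimentConfig | None = None,
                       **kwargs) -> "TCEDNModel":
        """Build a model over a freshly generated synthetic corpus."""
        config = config or scaled_config()
        if spec is None:
            spec = SyntheticSpec(
                frame_shape=(config.input.frame_height, config.input.frame_width),
                frames_per_clip=config.input.frames_per_clip, seed=seed)
        clips, manifest = generate_dataset(n, spec, seed=seed)
        return cls([c.sequence for c in clips],
                   manifest["bdi_score"].to_numpy(),
                   manifest["split"].to_numpy(), config=config, **kwargs)

    @classmethod
    def from_manifest(cls, manifest_csv, root=None,
                      config: ExperimentConfig | None = None,
                      **kwargs) -> "TCEDNModel":
        clips, labels, splits = load_manifest_dataset(manifest_csv, root)
        return cls(clips, labels, splits, config=config, **kwargs)

    # ----------------------------------------------------------------- fitting
    def _arrays(self):
        x = self.preprocessor.batch(self.clips)
        return x, self.labels

    def fit(self, seed: int | None = None, max_epochs: int | None = None,
            verbose: bool = False) -> "TCEDNResults":
        """Run the seeded training protocol and return a results object."""
        cfg = self.config.train
        if seed is not None or max_epochs is not None:
            cfg = replace(cfg,
                          seed=cfg.seed if seed is None else seed,
                          max_epochs=cfg.max_epochs if max_epochs is None
                          else max_epochs)
        x, y = self._arrays()
        tr = self.splits == "train"
        va = self.splits == "val"
        bcfg = replace(self.config.backbone, seed=cfg.seed)
        net = build_network(bcfg, x.shape[1:], use_stdwm=self.use_stdwm,
                            use_convlstm=self.use_convlstm)
        history, best = train(net, x[tr], y[tr], cfg,
                              val_x=x[va] if va.any() else None,
                              val_y=y[va] if va.any() else None,
                              verbose=verbose)
        final_state = net.state_dict()
        net.load_state_dict(best["state"])
        return TCEDNResults(self, net, history, best_epoch=best["epoch"],
                            train_config=cfg, x=x, final_state=final_state)


class TCEDNResults:
    """Fitted-model results: trained parameters, history, diagnostics."""

    def __init__(self, model: TCEDNModel, net, history: pd.DataFrame,
                 best_epoch: int, train_config: TrainConfig,
                 x: np.ndarray, final_state: dict):
        self.model = model
        self.net = net
        self.history = history
        self.best_epoch = best_epoch
        self.train_config = train_config
        self.final_state = final_state
        self._x = x

    # ------------------------------------------------------------- predictions
    def predict(self, clips=None) -> np.ndarray:
        """Severity predictions for raw clips (default: the bound dataset)."""
        if clips is None:
            x = self._x
        else:
            clips = [c if isinstance(c, FrameSequence) else FrameSequence(c)
                     for c in clips]
            x = self.model.preprocessor.batch(clips)
        from .training import _predict_batches
        return _predict_batches(self.net, x, self.train_config.batch_size)

    def evaluate(self, split: str = "test") -> MetricsReport:
        mask = self.model.splits == split
        if not mask.any():
            raise ValueError(f"no clips in split {split!r}")
        return evaluate_network(self.net, self._x[mask], self.model.labels[mask])

    def robustness(self, split: str = "test", specs=None) -> pd.DataFrame:
        mask = self.model.splits == split
        clips = [c for c, m in zip(self.model.clips, mask) if m]
        return robustness_suite(self.net, clips, self.model.labels[mask],
                                self.model.preprocessor, specs=specs)

    # -------------------------------------------------------------- accounting
    def complexity(self):
        cfg = self.model.config
        return count_flops(self.net.cfg, self.net.input_shape,
                           raw_T=cfg.input.frames_per_clip,
                           window_mode=cfg.aggregation.window_mode,
                           use_stdwm=self.model.use_stdwm,
                           use_convlstm=self.model.use_convlstm)

    @property
    def n_parameters(self) -> int:
        return self.net.num_parameters()

    # ----------------------------------------------------------------- summary
    def summary(self) -> str:
        m = self.model
        comp = self.complexity()
        counts = {s: int((m.splits == s).sum()) for s in ("train", "val", "test")}
        lines = [
            "TCEDN severity regression results",
            "=" * 44,
            f"clips (train/val/test)   {counts['train']}/{counts['val']}/{counts['test']}",
            f"input (C, T, H, W)       {self.net.input_shape}",
            f"trainable parameters     {self.n_parameters:,d} ({comp.params_m:.3f} M)",
            f"forward cost             {comp.gflops:.3f} GFLOPs (MAC convention)",
            f"epochs run               {len(self.history)}",
            f"best validation epoch    {self.best_epoch}",
            f"final learning rate      {self.history['lr'].iloc[-1]:.3g}",
            f"final train MAE / RMSE   {self.history['train_mae'].iloc[-1]:.3f} / "
            f"{self.history['train_rmse'].iloc[-1]:.3f}",
        ]
        if "val_mae" in self.history:
            lines.append(
                f"best val MAE / RMSE      "
                f"{self.history['val_mae'].iloc[self.best_epoch]:.3f} / "
                f"{self.history['val_rmse'].iloc[self.best_epoch]:.3f}")
        return "\n".join(lines)

    # ------------------------------------------------------------------- plots
    def plot_history(self, ax=None):
        """Training / validation error curves over epochs."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_rmse"],
                label="train RMSE")
        ax.plot(self.history["epoch"], self.history["train_mae"],
                label="train MAE", ls="--")
        if "val_rmse" in self.history:
            ax.plot(self.history["epoch"], self.history["val_rmse"],
                    label="val RMSE")
            ax.plot(self.history["epoch"], self.history["val_mae"],
                    label="val MAE", ls="--")
        ax.set_xlabel("epoch")
        ax.set_ylabel("error (BDI-II units)")
        ax.legend()
        return ax

    def plot_error_distribution(self, split: str = "test", ax=None):
        """Sorted absolute-error curve of per-clip test errors."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        report = self.evaluate(split)
        ax.plot(report.sorted_error_curve(), marker="o")
        ax.set_xlabel("clip (sorted by error)")
        ax.set_ylabel("absolute error")
        return ax
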
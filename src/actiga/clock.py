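"""The gestational-age clock: an Inception-block convolutional regressor.

`GestationalAgeClock` is the model object (built from a patient-split
`CohortDataset` or raw arrays); `fit()` trains it with the composite loss

    L_m = lambda2 * (1/m) * sum (y - yhat)^2 + lambda1 * sum |y - yhat|

under Adam with reduce-on-plateau learning-rate scheduling (patience 10,
engaged after a minimum number of epochs) and the configured augmentation
scheme, and returns a `ClockResults` carrying the best-on-validation
parameters, the training history, per-split prediction records and a
`summary()` table. The 128-d embedding is the global-average-pooled
representation preceding the nonlinear prediction head.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, UndefinedMetricError
from .augment import AugmentationScheme, AugmentationParams, apply_operators, draw_augmentation, tta_predict
from .io import CohortDataset, WEEK_EPOCHS, downsample_signal
from .nn import Adam, InceptionRegressor, ReduceLROnPlateau


@dataclass
class ClockConfig:
    """Architecture and optimisation settings for the clock."""

    n_blocks: int = 9
    embed_dim: int = 128
    bottleneck_dim: int = 32
    kernel_sizes: tuple = (9, 19, 39)
    lambda1: float = 1e-6
    lambda2: float = 0.001
    learning_rate: float = 1e-3
    patience_epochs: int = 10
    min_epochs: int = 200
    max_epochs: int = 500
    early_stop_patience: Optional[int] = None
    batch_size: int = 64
    seed: int = 0
    input_length: int = WEEK_EPOCHS
    in_channels: int = 2
    weight_decay_as_lambda2: bool = False

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ConfigError("lambda1 and lambda2 must be >= 0")
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ConfigError("kernel sizes must be odd")
        if max(self.kernel_sizes) > self.input_length:
            raise ConfigError("kernel size exceeds the input length")
        if self.batch_size < 1 or self.min_epochs < 0 or self.max_epochs < 1:
            raise ConfigError("batch_size and epoch counts must be positive")


def clock_loss(y: np.ndarray, yhat: np.ndarray, lambda1: float = 1e-6, lambda2: float = 0.001) -> float:
    """Composite loss: lambda2 * MSE + lambda1 * sum of absolute residuals."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("y and yhat must be equal-length, non-empty vectors")
    r = y - yhat
    return float(lambda2 * np.mean(r**2) + lambda1 * np.sum(np.abs(r)))


def _loss_grad(y: np.ndarray, yhat: np.ndarray, lambda1: float, lambda2: float) -> np.ndarray:
    """d loss / d yhat."""
    r = yhat - y
    return lambda2 * 2.0 * r / y.size + lambda1 * np.sign(r)


def evaluate_records(records: pd.DataFrame) -> dict:
    """MAE (weeks) and Spearman rho between predicted and actual GA."""
    err = records["signed_error"].to_numpy(dtype=float)
    mae = float(np.mean(np.abs(err)))
    yhat = records["predicted_ga"].to_numpy(dtype=float)
    y = records["actual_ga"].to_numpy(dtype=float)
    if len(y) < 3 or np.ptp(yhat) == 0 or np.ptp(y) == 0:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(yhat, y).statistic)
    return {"mae": mae, "spearman_rho": rho, "n": int(len(y))}


class GestationalAgeClock:
    """Convolutional GA regressor over 2-channel weekly actigraphy.

    Parameters
    ----------
    dataset : CohortDataset
        Preprocessed samples with a per-patient train/val/test assignment.
    config : ClockConfig
    scheme : AugmentationScheme or None
        Training-time augmentation; None disables it.
    downsample : int
        Optional bin-mean downsampling factor applied to every signal
        (e.g. 7 turns the 10,080-epoch week into 1,440 bins) for
        desk-scale configurations.
    """

    def __init__(
        self,
        dataset: Optional[CohortDataset] = None,
        config: Optional[ClockConfig] = None,
        scheme: Optional[AugmentationScheme] = None,
        downsample: int = 1,
    ):
        self.config = config or ClockConfig()
        self.config.validate()
        self.scheme = scheme
        self.downsample = int(downsample)
        self.dataset = dataset
        self.net = InceptionRegressor(
            in_channels=self.config.in_channels,
            n_blocks=self.config.n_blocks,
            bottleneck=self.config.bottleneck_dim,
            embed_dim=self.config.embed_dim,
            kernel_sizes=self.config.kernel_sizes,
            seed=self.config.seed,
        )
        if dataset is not None:
            self._arrays = {
                split: self._stack(dataset.subset(split)) for split in ("train", "val", "test")
            }

    @classmethod
    def from_dataset(cls, dataset: CohortDataset, config=None, scheme=None, downsample: int = 1):
        return cls(dataset=dataset, config=config, scheme=scheme, downsample=downsample)

    # ------------------------------------------------------------------
    def _prepare_signal(self, signal: np.ndarray) -> np.ndarray:
        x = np.asarray(signal, dtype=np.float32)
        if self.downsample > 1:
            x = downsample_signal(x, self.downsample).astype(np.float32)
        if x.shape[-1] != self.config.input_length:
            raise ValueError(
                f"signal length {x.shape[-1]} != configured input_length {self.config.input_length}"
            )
        return x

    def _stack(self, samples):
        if not samples:
            return None
        X = np.stack([self._prepare_signal(s.signal) for s in samples])
        y = np.array([s.ga_weeks for s in samples], dtype=np.float32)
        ids = [s.sample_id for s in samples]
        return X, y, ids

    def predict_array(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass on a (B, C, L) batch."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        preds = []
        for start in range(0, len(X), 256):
            preds.append(self.net.forward(X[start : start + 256]))
        return np.concatenate(preds).astype(float)

    def embed_array(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        embs = []
        for start in range(0, len(X), 256):
            embs.append(self.net.forward(X[start : start + 256], want_embedding=True)[1])
        return np.concatenate(embs)

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """Gradient of the scalar prediction w.r.t. each input (for attribution)."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        self.net.forward(X)
        self.net.zero_grad()
        return self.net.backward(np.ones(len(X), dtype=np.float32))

    # ------------------------------------------------------------------
    def fit(self, verbose: bool = False) -> "ClockResults":
        """Train on the dataset's train split, monitor the val split."""
        cfg = self.config
        if self.dataset is None:
            raise ValueError("fit() requires a dataset")
        train = self._arrays["train"]
        val = self._arrays["val"]
        if train is None:
            raise ValueError("empty train split")
        if val is None:
            raise ValueError("empty validation split")
        Xtr, ytr, _ = train
        Xval, yval, _ = val

        # data-dependent init: start the output at the train-mean GA so early
        # optimisation spends its steps on deviations, not on the offset
        self.net.fc2.b.value[0] = np.float32(ytr.mean())

        opt = Adam(
            self.net.params,
            lr=cfg.learning_rate,
            weight_decay=cfg.lambda2 if cfg.weight_decay_as_lambda2 else 0.0,
        )
        sched = ReduceLROnPlateau(opt, patience=cfg.patience_epochs)
        rng = np.random.default_rng(cfg.seed + 1)
        params = self.scheme.params if self.scheme else AugmentationParams()

        history = {"epoch": [], "train_loss": [], "val_loss": [], "lr": [], "augmentations": []}
        best_val = np.inf
        best_state = self.net.state()
        bad = 0
        n = len(Xtr)
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_ops = []
            losses = []
            for bi, start in enumerate(range(0, n, cfg.batch_size)):
                idx = order[start : start + cfg.batch_size]
                xb = Xtr[idx]
                if self.scheme is not None:
                    ops = draw_augmentation(self.scheme, epoch, bi)
                    epoch_ops.append(ops)
                    xb = np.stack(
                        [apply_operators(x, ops, params, rng) for x in xb]
                    ).astype(np.float32)
                yb = ytr[idx]
                pred = self.net.forward(xb)
                losses.append(clock_loss(yb, pred, cfg.lambda1, cfg.lambda2))
                self.net.zero_grad()
                self.net.backward(_loss_grad(yb, pred, cfg.lambda1, cfg.lambda2).astype(np.float32))
                opt.step()

            val_pred = self.predict_array(Xval)
            val_loss = clock_loss(yval, val_pred, cfg.lambda1, cfg.lambda2)
            history["epoch"].append(epoch)
            history["train_loss"].append(float(np.mean(losses)))
            history["val_loss"].append(float(val_loss))
            history["lr"].append(float(opt.lr))
            history["augmentations"].append(epoch_ops)
            if verbose and epoch % 10 == 0:
                print(f"epoch {epoch:4d} train {np.mean(losses):.5f} val {val_loss:.5f} lr {opt.lr:.2e}")

            if val_loss < best_val:
                best_val = val_loss
                best_state = self.net.state()
                bad = 0
            else:
                bad += 1
            if epoch + 1 >= cfg.min_epochs:
                sched.step(val_loss)
                if cfg.early_stop_patience is not None and bad >= cfg.early_stop_patience:
                    break

        self.net.load_state(best_state)
        return ClockResults(model=self, history=pd.DataFrame(
            {k: history[k] for k in ("epoch", "train_loss", "val_loss", "lr")}
        ), augmentation_log=history["augmentations"], best_val_loss=float(best_val))


@dataclass
class ClockResults:
    """Fitted-clock results: best parameters, history and evaluation helpers."""

    model: GestationalAgeClock
    history: pd.DataFrame
    augmentation_log: list
    best_val_loss: float

    def predict(self, split: str = "test", tta: Optional[AugmentationScheme] = None) -> pd.DataFrame:
        """Prediction records (sample_id, predicted_ga, actual_ga, signed_error)."""
        arrays = self.model._arrays.get(split)
        if arrays is None:
            raise ValueError(f"no samples in split {split!r}")
        X, y, ids = arrays
        if tta is not None:
            preds = np.array(
                [
                    tta_predict(
                        lambda s: self.model.predict_array(s[None])[0],
                        x,
                        operators=tta.operators,
                        params=tta.params,
                        seed=tta.seed,
                    )
                    for x in X
                ]
            )
        else:
            preds = self.model.predict_array(X)
        return pd.DataFrame(
            {
                "sample_id": ids,
                "predicted_ga": preds,
                "actual_ga": y.astype(float),
                "signed_error": preds - y,
            }
        )

    def predict_all(self, tta=None) -> pd.DataFrame:
        frames = []
        for split in ("train", "val", "test"):
            if self.model._arrays.get(split) is not None:
                f = self.predict(split, tta=tta)
                f["split"] = split
                frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def embeddings(self, split: str = "test") -> tuple:
        X, _, ids = self.model._arrays[split]
        return self.model.embed_array(X), ids

    def evaluate(self, split: str = "test", tta=None) -> dict:
        return evaluate_records(self.predict(split, tta=tta))

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Gestational-age clock  (Inception-block 1-D conv regressor)",
            "=" * 60,
            f"blocks: {cfg.n_blocks}   embedding: {self.model.net.embed_dim}-d   "
            f"kernels: {cfg.kernel_sizes}",
            f"parameters: {self.model.net.n_parameters():,}",
            f"loss: lambda2*MSE + lambda1*sum|r|  (lambda1={cfg.lambda1}, lambda2={cfg.lambda2})",
            f"epochs run: {len(self.history)}   best val loss: {self.best_val_loss:.6f}",
        ]
        for split in ("train", "val", "test"):
            if self.model._arrays.get(split) is not None:
                ev = self.evaluate(split)
                rho = "nan" if np.isnan(ev["spearman_rho"]) else f"{ev['spearman_rho']:.3f}"
                lines.append(
                    f"{split:>5}: n={ev['n']:<4d} MAE={ev['mae']:.2f} weeks  Spearman rho={rho}"
                )
        return "\n".join(lines)
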
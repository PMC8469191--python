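"""Scikit-learn style estimator wrapping the MA-UDCAE network.

:class:`MAUDCAERegressor` is the fit/predict surface of the package: ``X`` is
a ``(n_windows, in_len)`` array of scaled ECG windows and ``y`` a
``(n_windows, out_channels, in_len)`` array of scaled pressure windows.
Training minimizes mean absolute error with Adam, tracks per-epoch training
and validation loss, and keeps the weights of the epoch with the best
validation loss (the checkpoint system); ties break toward the earliest
epoch.  Everything is deterministic given ``random_state``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .architecture import ModelConfig, build


class MAUDCAERegressor(RegressorMixin, BaseEstimator):
    """ECG-window to pressure-waveform regressor.

    Parameters mirror :class:`~hemowave.architecture.ModelConfig` plus the
    training setup.  Fitted attributes (trailing underscore):

    - ``network_``: the built :class:`~hemowave.architecture.MAUDCAE`
    - ``history_``: dict with per-epoch ``train_loss``, ``val_loss`` and,
      when an ``eval_set`` is supplied, ``eval_loss``
    - ``best_epoch_``: 0-based epoch index of the selected checkpoint
    - ``n_features_in_``: window length seen at fit time
    """

    def __init__(
        self,
        in_len: int = 256,
        out_channels: int = 3,
        levels: int = 3,
        base_filters: int = 8,
        kernel_size: int = 3,
        dilation_rates: tuple[int, ...] = (1, 2, 4),
        skip_connections: tuple[str, ...] | None = None,
        head_convs: int = 2,
        filter_cap: int = 64,
        epochs: int = 20,
        batch_size: int = 16,
        learning_rate: float = 2e-3,
        validation_fraction: float = 0.15,
        random_state: int = 0,
    ):
        self.in_len = in_len
        self.out_channels = out_channels
        self.levels = levels
        self.base_filters = base_filters
        self.kernel_size = kernel_size
        self.dilation_rates = dilation_rates
        self.skip_connections = skip_connections
        self.head_convs = head_convs
        self.filter_cap = filter_cap
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def model_config(self) -> ModelConfig:
        return ModelConfig(
            in_len=self.in_len,
            in_channels=1,
            out_channels=self.out_channels,
            levels=self.levels,
            base_filters=self.base_filters,
            kernel_size=self.kernel_size,
            dilation_rates=tuple(self.dilation_rates),
            skip_connections=self.skip_connections,
            head_convs=self.head_convs,
            filter_cap=self.filter_cap,
        )

    @staticmethod
    def _check_X(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[:, None, :]  # (n, 1, L)
        if X.ndim != 3:
            raise ValueError(f"X must be (n, in_len) or (n, 1, in_len), got {X.shape}")
        return X

    def _check_y(self, y: np.ndarray, n: int) -> np.ndarray:
        y = np.asarray(y, dtype=np.float32)
        if y.ndim == 2 and self.out_channels == 1:
            y = y[:, None, :]
        if y.ndim != 3 or y.shape[0] != n or y.shape[1] != self.out_channels:
            raise ValueError(
                f"y must be (n, {self.out_channels}, in_len), got {y.shape}"
            )
        return y

    def _eval_loss(self, net, X: np.ndarray, y: np.ndarray, batch: int = 256) -> float:
        total, count = 0.0, 0
        for i in range(0, len(X), batch):
            pred = net.forward(X[i : i + batch]).data
            total += float(np.abs(pred - y[i : i + batch]).sum())
            count += pred.size
        return total / count

    # ------------------------------------------------------------------
    def fit(self, X, y, validation_data=None, eval_set=None):
        """Train with MAE loss and best-validation checkpointing.

        ``validation_data``: optional ``(X_val, y_val)``; otherwise the last
        ``validation_fraction`` of a seeded shuffle of (X, y) is held out.
        ``eval_set``: optional extra ``(X, y)`` whose loss is tracked each
        epoch (used by the ablation study for test curves) without ever
        influencing training or checkpoint selection.
        """
        X = self._check_X(X)
        y = self._check_y(y, len(X))
        if X.shape[2] != self.in_len:
            raise ValueError(f"window length {X.shape[2]} != in_len {self.in_len}")
        rng = np.random.default_rng(self.random_state)

        if validation_data is not None:
            Xt, yt = X, y
            Xv = self._check_X(validation_data[0])
            yv = self._check_y(validation_data[1], len(Xv))
        else:
            order = rng.permutation(len(X))
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            if n_val >= len(X):
                raise ValueError("not enough windows to hold out a validation set")
            Xt, yt = X[order[:-n_val]], y[order[:-n_val]]
            Xv, yv = X[order[-n_val:]], y[order[-n_val:]]
        if len(Xt) == 0 or len(Xv) == 0:
            raise ValueError("empty training or validation set")

        net = build(self.model_config(), rng)
        opt = nn.Adam(net.parameters, lr=self.learning_rate)
        history = {"train_loss": [], "val_loss": []}
        if eval_set is not None:
            history["eval_loss"] = []
        best_val, best_weights, best_epoch = np.inf, net.get_weights(), -1

        for epoch in range(self.epochs):
            perm = rng.permutation(len(Xt))
            batch_losses = []
            for i in range(0, len(Xt), self.batch_size):
                idx = perm[i : i + self.batch_size]
                opt.zero_grad()
                loss = nn.mae_loss(net.forward(Xt[idx]), yt[idx])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "check input scaling and learning rate"
                    )
                loss.backward()
                opt.step()
                batch_losses.append(float(loss.data))
            history["train_loss"].append(float(np.mean(batch_losses)))
            val_loss = self._eval_loss(net, Xv, yv)
            history["val_loss"].append(val_loss)
            if eval_set is not None:
                Xe = self._check_X(eval_set[0])
                ye = self._check_y(eval_set[1], len(Xe))
                history["eval_loss"].append(self._eval_loss(net, Xe, ye))
            if val_loss < best_val:  # strict: ties keep the earliest epoch
                best_val, best_epoch = val_loss, epoch
                best_weights = net.get_weights()

        net.set_weights(best_weights)
        self.network_ = net
        self.history_ = {k: np.asarray(v) for k, v in history.items()}
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = best_val
        self.n_features_in_ = self.in_len
        return self

    def predict(self, X) -> np.ndarray:
        """Predict scaled pressure windows, shape (n, out_channels, in_len)."""
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted")
        X = self._check_X(X)
        if X.shape[2] != self.in_len:
            raise ValueError(f"window length {X.shape[2]} != in_len {self.in_len}")
        return self.network_.predict(X).astype(np.float64)

    def validation_loss(self, X_val, y_val) -> float:
        """Recompute MAE of the checkpointed network on a validation set."""
        Xv = self._check_X(X_val)
        yv = self._check_y(y_val, len(Xv))
        return self._eval_loss(self.network_, Xv, yv)
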
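"""Inner-loop k-fold cross-validation around the MA-UDCAE estimator.

The protocol keeps one random test split fixed (default 20%) and rotates
train/validation folds over the remaining pool: every pool window validates
exactly once, every fold's network is evaluated on the same fixed test set,
and fold assignment depends only on the seed, not on input order.  Scalers
are fit on the training pool only; predictions are reported back in mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimator import MAUDCAERegressor
from .records import ChannelScaler
from .windows import PairedWindow, fit_scalers


@dataclass(frozen=True)
class TrainConfig:
    """Training setup; loss is mean absolute error with best-validation
    checkpointing (ties break toward the earliest epoch)."""

    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 2e-3
    loss: str = "mae"
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss != "mae" or self.optimizer != "adam":
            raise ValueError("supported setup: loss='mae', optimizer='adam'")


@dataclass(frozen=True)
class FoldPlan:
    """k (train, validation) id splits over the pool plus the fixed test ids."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    test_ids: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return len(self.folds)


def make_folds(pool_ids, k: int, seed: int = 0, test_ids=()) -> FoldPlan:
    """Shuffled k-fold partition of ``pool_ids``.

    Validation sets partition the pool with sizes differing by at most one;
    the shuffle is governed by ``seed`` alone (ids are sorted first, so the
    caller's ordering is irrelevant).
    """
    pool = sorted(set(pool_ids))
    if len(pool) != len(list(pool_ids)):
        raise ValueError("pool ids must be unique")
    if k < 1 or k > len(pool):
        raise ValueError(f"k={k} incompatible with pool of {len(pool)} ids")
    if set(test_ids) & set(pool):
        raise ValueError("test ids overlap the training pool")
    rng = np.random.default_rng(seed)
    order = [pool[i] for i in rng.permutation(len(pool))]
    val_chunks = np.array_split(np.arange(len(order)), k)
    folds = []
    for chunk in val_chunks:
        val = tuple(order[i] for i in chunk)
        train = tuple(i for i in order if i not in set(val))
        folds.append((train, val))
    return FoldPlan(folds=tuple(folds), test_ids=tuple(test_ids))


def split_test(window_ids, test_fraction: float = 0.2, seed: int = 0):
    """Fixed random test split: returns (pool_ids, test_ids)."""
    ids = sorted(set(window_ids))
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_test = int(round(test_fraction * len(ids)))
    return order[n_test:], order[:n_test]


# ----------------------------------------------------------------------
def windows_to_arrays(
    windows: list[PairedWindow],
    scalers: dict[str, ChannelScaler],
    target_channels: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into network arrays: scaled ECG X (n, L) and targets
    y (n, C, L) in scaled units, channel order as given."""
    X = np.stack([scalers["ECG"].transform(w.input) for w in windows])
    y = np.stack(
        [[scalers[c].transform(w.targets[c]) for c in target_channels] for w in windows]
    )
    return X, y


def train(
    estimator: MAUDCAERegressor,
    fold: tuple[tuple[str, ...], tuple[str, ...]],
    windows: list[PairedWindow],
    scalers: dict[str, ChannelScaler],
    target_channels: list[str],
    eval_set=None,
) -> MAUDCAERegressor:
    """Fit one fold: resolves the fold's train/validation ids to windows and
    trains with explicit validation data.  Returns the fitted estimator
    (its ``history_`` carries the loss trajectory)."""
    by_id = {w.window_id: w for w in windows}
    train_ids, val_ids = fold
    missing = [i for i in (*train_ids, *val_ids) if i not in by_id]
    if missing:
        raise KeyError(f"fold references unknown window ids, e.g. {missing[:3]}")
    if not train_ids or not val_ids:
        raise ValueError("fold has an empty train or validation set")
    Xt, yt = windows_to_arrays([by_id[i] for i in train_ids], scalers, target_channels)
    Xv, yv = windows_to_arrays([by_id[i] for i in val_ids], scalers, target_channels)
    return estimator.fit(Xt, yt, validation_data=(Xv, yv), eval_set=eval_set)


def predict(
    estimator: MAUDCAERegressor,
    windows: list[PairedWindow],
    scalers: dict[str, ChannelScaler],
    target_channels: list[str],
) -> dict[str, np.ndarray]:
    """Predict pressure waveforms in mmHg: channel name -> (n_windows, L)."""
    X = np.stack([scalers["ECG"].transform(w.input) for w in windows])
    raw = estimator.predict(X)  # (n, C, L), scaled units
    return {
        c: scalers[c].inverse_transform(raw[:, j, :]) for j, c in enumerate(target_channels)
    }


@dataclass
class CVResult:
    """Per-fold fitted estimators and their predictions on the fixed test set."""

    plan: FoldPlan
    estimators: list[MAUDCAERegressor]
    fold_predictions: list[dict[str, np.ndarray]]  # mmHg, per fold
    test_windows: list[PairedWindow] = field(repr=False, default_factory=list)
    target_channels: list[str] = field(default_factory=list)
    scalers: dict[str, ChannelScaler] = field(default_factory=dict)


def run_cv(
    windows: list[PairedWindow],
    estimator: MAUDCAERegressor,
    k: int = 5,
    test_fraction: float = 0.2,
    seed: int = 0,
    target_channels: list[str] | None = None,
) -> CVResult:
    """Fixed-test inner-loop cross-validation.

    Splits windows into a fixed test set and a pool, k-folds the pool, fits a
    clone of ``estimator`` per fold (seeded per fold) and predicts the same
    test set with each.  Scalers are fit on the pool only.
    """
    from sklearn.base import clone

    if target_channels is None:
        target_channels = sorted(windows[0].targets)
    by_id = {w.window_id: w for w in windows}
    pool_ids, test_ids = split_test(by_id, test_fraction, seed)
    plan = make_folds(pool_ids, k, seed, test_ids=test_ids)
    scalers = fit_scalers([by_id[i] for i in pool_ids])
    test_windows = [by_id[i] for i in test_ids]
    estimators, predictions = [], []
    for fold_idx, fold in enumerate(plan.folds):
        est = clone(estimator)
        est.set_params(random_state=estimator.random_state + fold_idx)
        if k == 1:
            # degenerate single fold: no rotation is possible, so train on
            # the whole pool with the estimator's internal validation split
            Xp, yp = windows_to_arrays(
                [by_id[i] for i in pool_ids], scalers, target_channels)
            est.fit(Xp, yp)
        else:
            est = train(est, fold, windows, scalers, target_channels)
        estimators.append(est)
        predictions.append(predict(est, test_windows, scalers, target_channels))
    return CVResult(
        plan=plan,
        estimators=estimators,
        fold_predictions=predictions,
        test_windows=test_windows,
        target_channels=target_channels,
        scalers=scalers,
    )


def mean_baseline_predictions(
    train_windows: list[PairedWindow],
    test_windows: list[PairedWindow],
    target_channels: list[str],
) -> dict[str, np.ndarray]:
    """Predict-the-training-mean baseline: each channel's constant mean value
    over all training samples, repeated over every test window."""
    n = test_windows[0].n_samples
    out = {}
    for c in target_channels:
        m = float(np.mean([w.targets[c].mean() for w in train_windows]))
        out[c] = np.full((len(test_windows), n), m)
    return out
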
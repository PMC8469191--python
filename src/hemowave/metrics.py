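"""Fiducial extraction and the evaluation suite: R, RMSE, MAE, fold
aggregation and Bland-Altman agreement.

Fiducials follow the raw window rule used throughout: systolic = window
maximum, diastolic = window minimum (ABP, PAP), mean = arithmetic mean of
the 2-s window (CVP, ICP) — no peak detection or smoothing, which preserves
the method's known noise sensitivity.  All pressures are in mmHg.

R is Pearson's linear correlation

    R = sum_i (x_i - xbar)(y_i - ybar) / sqrt(sum_i (x_i - xbar)^2 sum_i (y_i - ybar)^2)

with x the reference and y the prediction; MAE = mean |x_i - y_i| and
RMSE = sqrt(mean (x_i - y_i)^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: How each channel's clinically reported values are extracted from a window.
FIDUCIAL_MODES: dict[str, str] = {"ABP": "maxmin", "PAP": "maxmin", "CVP": "mean", "ICP": "mean"}

#: Human-readable fiducial names per channel.
FIDUCIAL_NAMES: dict[str, tuple[str, ...]] = {
    "ABP": ("SBP", "DBP"),
    "PAP": ("systolic PAP", "diastolic PAP"),
    "CVP": ("mean CVP",),
    "ICP": ("mean ICP",),
}


@dataclass(frozen=True)
class FiducialSet:
    """Per-window fiducials of one channel; unused slots are None."""

    systolic: float | None = None
    diastolic: float | None = None
    mean: float | None = None


def extract_fiducials(waveform: np.ndarray, mode: str) -> FiducialSet:
    """Extract fiducials from one window by the raw max/min/mean rule."""
    waveform = np.asarray(waveform, dtype=np.float64)
    if waveform.size == 0:
        raise ValueError("cannot extract fiducials from an empty window")
    if mode == "maxmin":
        return FiducialSet(systolic=float(waveform.max()), diastolic=float(waveform.min()))
    if mode == "mean":
        return FiducialSet(mean=float(waveform.mean()))
    raise ValueError(f"unknown fiducial mode {mode!r}")


def _paired(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} paired samples, got {x.size}")
    return x, y


def pearson_r(x, y) -> float:
    """Pearson's linear correlation of reference x and prediction y."""
    x, y = _paired(x, y, 2)
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx**2).sum() * (dy**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined: an input has zero variance")
    return float((dx * dy).sum() / denom)


def mae(x, y) -> float:
    """Mean absolute error, in the input units (mmHg for pressures)."""
    x, y = _paired(x, y, 1)
    return float(np.mean(np.abs(x - y)))


def rmse(x, y) -> float:
    """Root mean squared error, in the input units."""
    x, y = _paired(x, y, 1)
    return float(np.sqrt(np.mean((x - y) ** 2)))


@dataclass(frozen=True)
class MetricReport:
    """R / RMSE / MAE of one evaluation over n paired samples."""

    r: float
    rmse: float
    mae: float
    n: int

    def as_dict(self) -> dict:
        return {"R": self.r, "RMSE": self.rmse, "MAE": self.mae, "n": self.n}


def metric_report(reference, prediction) -> MetricReport:
    x, y = _paired(reference, prediction, 2)
    return MetricReport(r=pearson_r(x, y), rmse=rmse(x, y), mae=mae(x, y), n=x.size)


def evaluate_waveforms(ref_windows, pred_windows) -> MetricReport:
    """Waveform-level metrics pooling all samples of all windows.

    ``ref_windows`` / ``pred_windows`` are aligned sequences of 1D arrays;
    every sample of every window enters one pooled pair of vectors.
    """
    ref_windows, pred_windows = list(ref_windows), list(pred_windows)
    if len(ref_windows) != len(pred_windows):
        raise ValueError("reference and prediction window counts differ")
    for a, b in zip(ref_windows, pred_windows):
        if np.shape(a) != np.shape(b):
            raise ValueError("misaligned window shapes")
    return metric_report(np.concatenate(ref_windows), np.concatenate(pred_windows))


def evaluate_fiducials(ref_values, pred_values) -> MetricReport:
    """Fiducial-level metrics: one scalar per window on each side."""
    return metric_report(ref_values, pred_values)


@dataclass(frozen=True)
class FoldAggregate:
    """Mean and sample (n-1) standard deviation of each metric across folds."""

    mean: dict[str, float]
    std: dict[str, float]
    n_folds: int


def aggregate_folds(reports: list[MetricReport]) -> FoldAggregate:
    """Aggregate per-fold reports into Mean/STD rows.

    Uses the sample (ddof=1) standard deviation — with the published 5-fold
    SBP correlations it reproduces the printed STD at 3 decimals, which the
    population convention does not.  A single fold yields STD 0.
    """
    if not reports:
        raise ValueError("need at least one fold report")
    out_mean, out_std = {}, {}
    for key in ("R", "RMSE", "MAE"):
        vals = np.array([r.as_dict()[key] for r in reports], dtype=np.float64)
        out_mean[key] = float(vals.mean())
        out_std[key] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return FoldAggregate(mean=out_mean, std=out_std, n_folds=len(reports))


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Bias and 1.96-SD limits of agreement, plus the (average, difference)
    point cloud for plotting.  Differences are ``prediction - reference`` by
    default; the direction used is recorded in the summary."""

    bias: float
    loa_lower: float
    loa_upper: float
    sd: float
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)
    direction: str = "prediction-reference"
    n: int = 0


def bland_altman(reference, prediction, direction: str = "prediction-reference") -> BlandAltmanSummary:
    """Bland-Altman agreement of paired fiducial values.

    ``direction`` is either ``"prediction-reference"`` (default) or
    ``"reference-prediction"``.  Limits are bias +- 1.96 x sample SD of the
    differences.
    """
    x, y = _paired(reference, prediction, 2)
    if direction == "prediction-reference":
        diffs = y - x
    elif direction == "reference-prediction":
        diffs = x - y
    else:
        raise ValueError(f"unknown difference direction {direction!r}")
    means = (x + y) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanSummary(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        sd=sd,
        means=means,
        diffs=diffs,
        direction=direction,
        n=x.size,
    )


def bland_altman_plot(summary: BlandAltmanSummary, ax=None, title: str = ""):
    """Render the classic agreement plot (matplotlib imported lazily)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(summary.means, summary.diffs, s=6, alpha=0.5)
    ax.axhline(summary.bias, color="red", label=f"bias {summary.bias:.2f}")
    for y in (summary.loa_lower, summary.loa_upper):
        ax.axhline(y, color="k", linestyle="-.")
    ax.set_xlabel("pair average (mmHg)")
    ax.set_ylabel(f"difference, {summary.direction} (mmHg)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    return ax
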
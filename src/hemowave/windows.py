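"""Cutting aligned 2-second windows and rule-based quality screening.

Windows tile each record from sample 0 in consecutive non-overlapping blocks
(half-open ``[start, start + n)``); any window touching an excluded sample is
dropped, and a trailing partial window is discarded.  Quality screening
replaces the original manual visual filtering with three explicit rules:
non-finite samples, flat-lined channels, and out-of-physiological-range
pressures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ChannelError, ConfigurationError
from .records import ChannelScaler, SignalRecord

#: Default physiological plausibility gates per channel (inclusive bounds).
DEFAULT_RANGE_GATES: dict[str, tuple[float, float]] = {
    "ECG": (-10.0, 10.0),   # mV
    "ABP": (10.0, 300.0),   # mmHg
    "CVP": (-10.0, 50.0),
    "PAP": (-5.0, 120.0),
    "ICP": (-10.0, 100.0),
}


@dataclass
class PairedWindow:
    """One aligned (ECG input, pressure targets) sample of n = window_s * fs points."""

    window_id: str
    record_id: str
    start_index: int
    fs: float
    input: np.ndarray
    targets: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.input = np.asarray(self.input, dtype=np.float64)
        self.targets = {k: np.asarray(v, dtype=np.float64) for k, v in self.targets.items()}
        n = len(self.input)
        for name, vec in self.targets.items():
            if len(vec) != n:
                raise ValueError(f"target {name} length {len(vec)} != input length {n}")

    @property
    def n_samples(self) -> int:
        return len(self.input)


def segment_record(
    record: SignalRecord,
    window_seconds: float = 2.0,
    required_channels: list[str] | None = None,
    input_channel: str = "ECG",
) -> list[PairedWindow]:
    """Cut consecutive non-overlapping windows starting at sample 0.

    ``required_channels`` lists every channel a window must carry (input and
    targets); it defaults to all channels of the record.  Windows that
    intersect the record's exclusion mask are dropped.
    """
    if required_channels is None:
        required_channels = record.channel_names
    missing = [c for c in required_channels if c not in record.channels]
    if missing:
        raise ChannelError(f"record {record.record_id} lacks channels {missing}")
    if input_channel not in required_channels:
        raise ChannelError(f"input channel {input_channel!r} not in required channels")
    n_float = window_seconds * record.fs
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 or n <= 0:
        raise ConfigurationError(
            f"window of {window_seconds} s at {record.fs} Hz is not an integer "
            f"number of samples ({n_float})"
        )
    target_names = [c for c in required_channels if c != input_channel]
    windows: list[PairedWindow] = []
    for k in range(record.n_samples // n):
        start = k * n
        if record.exclusion_mask[start : start + n].any():
            continue
        windows.append(
            PairedWindow(
                window_id=f"{record.record_id}:{start}",
                record_id=record.record_id,
                start_index=start,
                fs=record.fs,
                input=record.channels[input_channel][start : start + n],
                targets={c: record.channels[c][start : start + n] for c in target_names},
            )
        )
    return windows


@dataclass(frozen=True)
class ScreenRules:
    """Thresholds for the rule-based quality screen.

    flat_variance
        A channel whose sample variance falls below this is considered
        flat-lined (units: squared channel units).
    range_gates
        Per-channel (low, high) plausibility bounds; samples outside reject
        the window.
    """

    flat_variance: float = 1e-6
    range_gates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGE_GATES)
    )


@dataclass(frozen=True)
class ScreenDecision:
    keep: bool
    reason: str | None = None

    def __bool__(self) -> bool:  # allows `if quality_screen(w):`
        return self.keep


def quality_screen(window: PairedWindow, rules: ScreenRules | None = None) -> ScreenDecision:
    """Keep/reject decision with a reason code naming the rule and channel.

    Rules fire in a fixed order (non-finite, flat-line, range) over channels
    in a fixed order (input first, then targets sorted by name), so the
    decision is deterministic and independent of dict ordering.
    """
    rules = rules or ScreenRules()
    named = [("ECG" if "ECG" not in window.targets else "input", window.input)]
    named += sorted(window.targets.items())
    for name, sig in named:
        if not np.isfinite(sig).all():
            return ScreenDecision(False, f"non-finite: {name}")
    for name, sig in named:
        if float(np.var(sig)) < rules.flat_variance:
            return ScreenDecision(False, f"flat-line: {name}")
    for name, sig in named:
        gate = rules.range_gates.get(name)
        if gate is not None and ((sig < gate[0]).any() or (sig > gate[1]).any()):
            return ScreenDecision(False, f"out-of-range: {name}")
    return ScreenDecision(True, None)


def screen_windows(
    windows: list[PairedWindow], rules: ScreenRules | None = None
) -> tuple[list[PairedWindow], list[tuple[str, str]]]:
    """Split windows into kept and (window_id, reason) rejects."""
    kept, rejected = [], []
    for w in windows:
        d = quality_screen(w, rules)
        if d.keep:
            kept.append(w)
        else:
            rejected.append((w.window_id, d.reason))
    return kept, rejected


def fit_scalers(windows: list[PairedWindow]) -> dict[str, ChannelScaler]:
    """Fit per-channel min-max scalers over a training pool of windows.

    The ECG input contributes under the name ``"ECG"``.  Deterministic given
    the window list; raises ``ValueError`` on an empty list.
    """
    if not windows:
        raise ValueError("cannot fit scalers on an empty window list")
    pools: dict[str, list[np.ndarray]] = {"ECG": []}
    for w in windows:
        pools["ECG"].append(w.input)
        for name, vec in w.targets.items():
            pools.setdefault(name, []).append(vec)
    return {name: ChannelScaler.fit(np.concatenate(vecs)) for name, vecs in pools.items()}
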
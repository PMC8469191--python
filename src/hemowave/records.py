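"""Multi-channel waveform records and their on-disk text format.

A :class:`SignalRecord` holds uniformly sampled physiological channels (ECG in
mV, pressures in mmHg) plus a per-sample exclusion mask used to reproduce
curated segment removal.  Records are stored as a tab-separated sample matrix
(``<name>.tsv``, one column per channel) next to a JSON sidecar
(``<name>.json``) carrying the sampling frequency, channel order, units and
excluded intervals — the same metadata a WFDB header records, in plain text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._exceptions import ChannelError, FormatError

#: Channel names the pipeline understands, with their physical units.
KNOWN_CHANNELS = {"ECG": "mV", "ABP": "mmHg", "CVP": "mmHg", "PAP": "mmHg", "ICP": "mmHg"}


@dataclass
class SignalRecord:
    """A uniformly sampled multi-channel waveform record.

    Parameters
    ----------
    record_id : str
        Identifier, used to derive window ids.
    fs : float
        Sampling frequency in Hz, constant across channels.
    channels : dict[str, numpy.ndarray]
        Ordered map channel name -> 1D sample series.  All series share one
        length.  ECG is in mV, pressure channels in mmHg.
    exclusion_mask : numpy.ndarray or None
        Boolean per-sample mask; ``True`` marks samples excluded from
        windowing (the rule-based stand-in for manual curation).
    """

    record_id: str
    fs: float
    channels: dict[str, np.ndarray]
    exclusion_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.channels:
            raise ValueError("record needs at least one channel")
        for name in self.channels:
            if name not in KNOWN_CHANNELS:
                raise ChannelError(f"unknown channel name {name!r}")
        lengths = {name: len(sig) for name, sig in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        self.channels = {k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()}
        if self.exclusion_mask is None:
            self.exclusion_mask = np.zeros(self.n_samples, dtype=bool)
        else:
            self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
            if len(self.exclusion_mask) != self.n_samples:
                raise ValueError("exclusion mask length differs from channels")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def exclude_interval(self, start: int, stop: int) -> None:
        """Mark samples in the half-open range ``[start, stop)`` as excluded."""
        self.exclusion_mask[start:stop] = True


def _mask_to_intervals(mask: np.ndarray) -> list[list[int]]:
    """Run-length encode a boolean mask into half-open [start, stop) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(np.int8)))
    return [[int(a), int(b)] for a, b in zip(idx[::2], idx[1::2])]


def _intervals_to_mask(intervals, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for a, b in intervals:
        mask[a:b] = True
    return mask


def write_record(record: SignalRecord, path: str | Path) -> Path:
    """Write a record as ``<path>.tsv`` + ``<path>.json``; returns the sidecar path.

    Samples are written with 6 decimal digits, enough for mV/mmHg precision.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    data = np.column_stack([record.channels[name] for name in record.channel_names])
    np.savetxt(base.with_suffix(".tsv"), data, fmt="%.6f", delimiter="\t")
    header = {
        "record_id": record.record_id,
        "fs": record.fs,
        "n_samples": record.n_samples,
        "channels": record.channel_names,
        "units": [KNOWN_CHANNELS[c] for c in record.channel_names],
        "excluded_intervals": _mask_to_intervals(record.exclusion_mask),
        "meta": record.meta,
    }
    base.with_suffix(".json").write_text(json.dumps(header, indent=1, sort_keys=True))
    return base.with_suffix(".json")


def read_record(path: str | Path) -> SignalRecord:
    """Read a record written by :func:`write_record`.

    ``path`` may be the base name or either of the two component files.
    Raises :class:`FormatError` when header and signal matrix disagree.
    """
    base = Path(path)
    if base.suffix in {".json", ".tsv"}:
        base = base.with_suffix("")
    sidecar = base.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing header sidecar {sidecar}")
    try:
        header = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:  # pragma: no cover - malformed by hand
        raise FormatError(f"malformed header {sidecar}: {exc}") from exc
    for key in ("record_id", "fs", "channels", "n_samples"):
        if key not in header:
            raise FormatError(f"header {sidecar} missing key {key!r}")
    data = np.loadtxt(base.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    names = header["channels"]
    if data.shape[1] != len(names):
        raise FormatError(
            f"header declares {len(names)} channels but signal matrix has "
            f"{data.shape[1]} columns"
        )
    if data.shape[0] != header["n_samples"]:
        raise FormatError("header n_samples differs from signal matrix rows")
    mask = _intervals_to_mask(header.get("excluded_intervals", []), data.shape[0])
    return SignalRecord(
        record_id=header["record_id"],
        fs=float(header["fs"]),
        channels={name: data[:, j] for j, name in enumerate(names)},
        exclusion_mask=mask,
        meta=header.get("meta", {}),
    )


@dataclass(frozen=True)
class ChannelScaler:
    """Affine map between physical units and network units.

    ``transform(x) = (x - offset) * gain`` with ``gain > 0``; fitting uses
    min-max over the training pool so training data land in [0, 1].  A
    constant channel degenerates to unit gain with the constant as offset
    (mapping it to 0), keeping the inverse exact.
    """

    offset: float
    gain: float

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("scaler gain must be positive")

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x) - self.offset) * self.gain

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) / self.gain + self.offset

    @classmethod
    def fit(cls, x: np.ndarray) -> "ChannelScaler":
        x = np.asarray(x, dtype=np.float64)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo <= 0:
            return cls(offset=lo, gain=1.0)
        return cls(offset=lo, gain=1.0 / (hi - lo))
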
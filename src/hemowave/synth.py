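"""Synthetic beat-coupled ECG + pressure records.

The generator produces per-subject records in which a Gaussian-bump lead-II
ECG and delayed template pressure waveforms (ABP, PAP pulse templates;
CVP a/c/v-wave and ICP P1/P2/P3 templates) are driven by one shared beat
train.  Subject-level pressure targets are deterministically encoded in the
ECG morphology — QRS amplitude tracks systolic ABP, S-wave depth tracks
systolic PAP, P-wave amplitude tracks mean CVP, T-wave amplitude tracks mean
ICP, Q depth tracks diastolic ABP — mirroring the ECG/hemodynamics
correlations reported for hypertensive and raised-ICP patients.  This makes
the single-lead ECG -> pressure mapping well-posed, which is what the
downstream network is asked to learn.

Fiducials of the noise-free targets are analytic by construction: each
ABP/PAP beat attains exactly the systolic target at the top of its upstroke
and the diastolic target at end-diastole, and the CVP/ICP beat templates are
zero-mean per beat so the series mean equals the mean target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import SignalRecord

CARDIO_CHANNELS = ("ECG", "ABP", "CVP", "PAP")
CEREBRAL_CHANNELS = ("ECG", "ICP")

#: Default sampling rates: 2-s windows must hold an integer, power-of-two-
#: divisible number of samples (256 at 128 Hz for the 4-level cardiovascular
#: network, 100 at 50 Hz for the 2-level cerebral network).
DEFAULT_FS_CARDIO = 128.0
DEFAULT_FS_CEREBRAL = 50.0


@dataclass(frozen=True)
class SubjectRanges:
    """Uniform sampling ranges (lo, hi) for subject parameters."""

    heart_rate_mean: tuple[float, float] = (55.0, 95.0)  # bpm
    rr_jitter_sd: tuple[float, float] = (0.01, 0.03)     # s
    sbp_target: tuple[float, float] = (95.0, 175.0)      # mmHg
    dbp_target: tuple[float, float] = (55.0, 95.0)
    pap_sys_target: tuple[float, float] = (18.0, 45.0)
    pap_dia_target: tuple[float, float] = (6.0, 18.0)
    cvp_mean_target: tuple[float, float] = (4.0, 12.0)
    icp_mean_target: tuple[float, float] = (8.0, 25.0)
    pulse_transit_delay: tuple[float, float] = (0.14, 0.22)  # s
    respiratory_rate: tuple[float, float] = (10.0, 18.0)     # breaths/min

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.__dict__.items():
            if hi < lo:
                raise ValueError(f"inverted range for {name}: ({lo}, {hi})")


@dataclass
class SubjectParams:
    """Ground-truth generative parameters for one synthetic subject."""

    heart_rate_mean: float
    rr_jitter_sd: float
    sbp_target: float
    dbp_target: float
    pap_sys_target: float
    pap_dia_target: float
    cvp_mean_target: float
    icp_mean_target: float
    pulse_transit_delay: float
    respiratory_rate: float
    resp_depth_abp: float = 0.02        # fractional pulse-amplitude modulation
    resp_depth_additive: float = 0.5    # mmHg, CVP/ICP sinusoid
    noise_sd: dict = field(
        default_factory=lambda: {"ECG": 0.01, "ABP": 0.4, "CVP": 0.15, "PAP": 0.25, "ICP": 0.15}
    )
    arrhythmia: str = "none"            # none | irregular_rr | premature_beats
    arrhythmia_probability: float = 0.0
    invert_premature_r: bool = False

    def __post_init__(self) -> None:
        if self.sbp_target <= self.dbp_target:
            raise ValueError("sbp_target must exceed dbp_target")
        if self.pap_sys_target <= self.pap_dia_target:
            raise ValueError("pap_sys_target must exceed pap_dia_target")
        if self.pulse_transit_delay < 0:
            raise ValueError("pulse_transit_delay must be non-negative")
        if self.arrhythmia not in {"none", "irregular_rr", "premature_beats"}:
            raise ValueError(f"unknown arrhythmia mode {self.arrhythmia!r}")

    def noise_free(self) -> "SubjectParams":
        """Copy with all noise and respiratory components switched off."""
        return replace(
            self,
            resp_depth_abp=0.0,
            resp_depth_additive=0.0,
            noise_sd={k: 0.0 for k in self.noise_sd},
        )


def _unit(value: float, rng_pair: tuple[float, float]) -> float:
    """Position of value inside its sampling range, in [0, 1]."""
    lo, hi = rng_pair
    return 0.5 if hi == lo else (value - lo) / (hi - lo)


def ecg_morphology(params: SubjectParams, ranges: SubjectRanges | None = None) -> dict[str, tuple[float, float, float]]:
    """Per-wave (time offset s, amplitude mV, width s) of the 5-bump ECG beat.

    Amplitudes are deterministic functions of the subject's pressure targets
    (the morphology coupling described in the module docstring).
    """
    r = ranges or SubjectRanges()
    z_sbp = _unit(params.sbp_target, r.sbp_target)
    z_dbp = _unit(params.dbp_target, r.dbp_target)
    z_pap = _unit(params.pap_sys_target, r.pap_sys_target)
    z_papd = _unit(params.pap_dia_target, r.pap_dia_target)
    z_cvp = _unit(params.cvp_mean_target, r.cvp_mean_target)
    z_icp = _unit(params.icp_mean_target, r.icp_mean_target)
    return {
        "P": (-0.20, 0.06 + 0.18 * z_cvp, 0.020 + 0.012 * z_papd),
        "Q": (-0.04, -(0.04 + 0.10 * z_dbp), 0.010),
        "R": (0.00, 0.60 + 0.90 * z_sbp, 0.014),
        "S": (0.04, -(0.08 + 0.25 * z_pap), 0.011),
        "T": (0.22, 0.12 + 0.45 * z_icp, 0.045),
    }


def sample_subject(
    seed: int | np.random.Generator,
    ranges: SubjectRanges | None = None,
    arrhythmia: str = "none",
    arrhythmia_probability: float = 0.15,
) -> SubjectParams:
    """Draw one subject uniformly from ``ranges`` (deterministic given seed).

    Ordering constraints (SBP > DBP, systolic PAP > diastolic PAP) are
    enforced by conditioning the diastolic draw below its systolic partner.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = ranges or SubjectRanges()

    def draw(pair):
        return float(rng.uniform(pair[0], pair[1]))

    sbp = draw(r.sbp_target)
    dbp = draw((r.dbp_target[0], min(r.dbp_target[1], sbp - 20.0)))
    pap_s = draw(r.pap_sys_target)
    pap_d = draw((r.pap_dia_target[0], min(r.pap_dia_target[1], pap_s - 5.0)))
    # pulse transit time shortens deterministically with arterial pressure
    # (stiffer, more pressurised arteries conduct the pulse faster) — this is
    # the relationship PTT-based cuffless BP estimation rests on, and it keeps
    # the ECG -> pressure phase relationship identifiable
    d_lo, d_hi = r.pulse_transit_delay
    delay = d_hi - (d_hi - d_lo) * _unit(sbp, r.sbp_target)
    return SubjectParams(
        heart_rate_mean=draw(r.heart_rate_mean),
        rr_jitter_sd=draw(r.rr_jitter_sd),
        sbp_target=sbp,
        dbp_target=dbp,
        pap_sys_target=pap_s,
        pap_dia_target=pap_d,
        cvp_mean_target=draw(r.cvp_mean_target),
        icp_mean_target=draw(r.icp_mean_target),
        pulse_transit_delay=delay,
        respiratory_rate=draw(r.respiratory_rate),
        arrhythmia=arrhythmia,
        arrhythmia_probability=arrhythmia_probability if arrhythmia == "premature_beats" else 0.0,
    )


@dataclass
class BeatTrain:
    """R-wave onset times (s) with per-beat type tags."""

    onsets: np.ndarray
    types: list[str]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.float64)
        if len(self.onsets) != len(self.types):
            raise ValueError("onsets and types differ in length")
        if len(self.onsets) > 1 and not (np.diff(self.onsets) > 0).all():
            raise ValueError("beat onsets must be strictly increasing")

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.onsets)


def make_beat_train(
    params: SubjectParams, duration_s: float, seed: int | np.random.Generator = 0
) -> BeatTrain:
    """Generate beat onsets over ``duration_s`` seconds.

    Normal mode jitters RR intervals with sd ``rr_jitter_sd``; irregular_rr
    multiplies that jitter sixfold; premature_beats inserts, with the
    configured probability, an early beat at 55% of the base interval tagged
    ``premature`` followed by a compensatory pause completing 2x the base RR.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rr_mean = 60.0 / params.heart_rate_mean
    sd = params.rr_jitter_sd * (6.0 if params.arrhythmia == "irregular_rr" else 1.0)
    t = 0.3  # first beat after a short lead-in so its R-wave is fully rendered
    onsets, types = [], []
    while t < duration_s:
        rr = max(0.3, float(rng.normal(rr_mean, sd)))
        if (
            params.arrhythmia == "premature_beats"
            and rng.uniform() < params.arrhythmia_probability
            and t + rr < duration_s
        ):
            onsets.append(t)
            types.append("normal")
            onsets.append(t + 0.55 * rr)
            types.append("premature")
            t += 2.0 * rr  # compensatory pause
            continue
        onsets.append(t)
        types.append("normal")
        t += rr
    return BeatTrain(np.array(onsets), types)


def _gauss_bumps(t: np.ndarray, centers, amps, widths) -> np.ndarray:
    """Sum of Gaussian bumps evaluated on time grid t (vectorized per bump)."""
    out = np.zeros_like(t)
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    for c, a, w in zip(centers, amps, widths):
        lo = max(0, int((c - 5 * w) / dt))
        hi = min(len(t), int((c + 5 * w) / dt) + 1)
        if hi > lo:
            seg = t[lo:hi]
            out[lo:hi] += a * np.exp(-0.5 * ((seg - c) / w) ** 2)
    return out


def render_ecg(
    beats: BeatTrain,
    params: SubjectParams,
    fs: float,
    duration_s: float,
    seed: int | np.random.Generator = 0,
    ranges: SubjectRanges | None = None,
) -> np.ndarray:
    """Render the lead-II-like ECG (mV) for a beat train.

    Each beat is a P-Q-R-S-T sum of Gaussian bumps whose amplitudes encode
    the subject's pressure targets; premature beats get a doubled-width,
    optionally inverted R bump with suppressed P wave.  Gaussian noise of sd
    ``noise_sd['ECG']`` is added last.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    morph = ecg_morphology(params, ranges)
    centers, amps, widths = [], [], []
    for onset, btype in zip(beats.onsets, beats.types):
        for wave, (off, amp, width) in morph.items():
            if btype == "premature":
                if wave == "P":
                    continue  # ectopic beats lack a preceding P wave
                if wave == "R":
                    width *= 2.0
                    amp = -0.7 * amp if params.invert_premature_r else 0.8 * amp
            centers.append(onset + off)
            amps.append(amp)
            widths.append(width)
    ecg = _gauss_bumps(t, centers, amps, widths)
    sd = params.noise_sd.get("ECG", 0.0)
    if sd > 0:
        ecg = ecg + rng.normal(0.0, sd, size=n)
    return ecg


def _pulse_shape(u: np.ndarray, rise_frac: float = 0.18, tau_frac: float = 0.40) -> np.ndarray:
    """Normalized arterial pulse: 0 -> 1 half-cosine upstroke, then an
    exponential diastolic decay rescaled to end exactly at 0.

    max = 1 at u = rise_frac, min = 0 at u = 1 (analytic fiducials).
    """
    s = np.empty_like(u)
    rising = u < rise_frac
    s[rising] = 0.5 * (1.0 - np.cos(np.pi * u[rising] / rise_frac))
    decay = np.exp(-(u[~rising] - rise_frac) / tau_frac)
    e_end = np.exp(-(1.0 - rise_frac) / tau_frac)
    s[~rising] = (decay - e_end) / (1.0 - e_end)
    return s


#: Venous / intracranial per-beat templates: (phase in beat, signed relative
#: amplitude, width as fraction of RR).  Alternating signs keep the running
#: integral small so window means stay close to the mean target.
_CVP_WAVES = [(0.10, 1.0, 0.05), (0.22, -0.8, 0.05), (0.34, 0.55, 0.045),
              (0.48, -0.45, 0.05), (0.66, 0.9, 0.06), (0.84, -0.75, 0.06)]
_ICP_WAVES = [(0.12, 1.0, 0.06), (0.30, 0.8, 0.06), (0.48, 0.6, 0.06),
              (0.72, -1.1, 0.09), (0.90, -0.35, 0.06)]
_WAVE_AMPLITUDE = {"CVP": 0.45, "ICP": 0.8}  # mmHg scale of the beat pattern


def render_pressure(
    beats: BeatTrain,
    params: SubjectParams,
    channel: str,
    fs: float,
    duration_s: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Render one pressure channel (mmHg), beat-synchronous and delayed by
    the pulse transit time.

    ABP/PAP: per-beat pulse template scaled so each beat's maximum equals the
    systolic target and its minimum the diastolic target (premature beats get
    a reduced-stroke pulse).  CVP/ICP: zero-mean multi-peak beat template
    around the mean target plus a respiratory sinusoid.  Noise is added last.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    d = params.pulse_transit_delay
    onsets = beats.onsets + d
    rr_mean = 60.0 / params.heart_rate_mean
    resp = np.sin(2.0 * np.pi * params.respiratory_rate / 60.0 * t)

    if channel in ("ABP", "PAP"):
        sys_t, dia_t = (
            (params.sbp_target, params.dbp_target)
            if channel == "ABP"
            else (params.pap_sys_target, params.pap_dia_target)
        )
        p = np.full(n, dia_t, dtype=np.float64)
        bounds = np.concatenate((onsets, [max(duration_s, onsets[-1] + rr_mean) + rr_mean]))
        for k in range(len(onsets)):
            lo = int(np.ceil(bounds[k] * fs))
            hi = min(n, int(np.ceil(bounds[k + 1] * fs)))
            if hi <= lo:
                continue
            u = (t[lo:hi] - bounds[k]) / (bounds[k + 1] - bounds[k])
            amp = sys_t - dia_t
            if beats.types[k] == "premature":
                amp *= 0.55  # reduced stroke volume of an ectopic beat
            if params.resp_depth_abp > 0:
                amp = amp * (1.0 + params.resp_depth_abp * resp[lo:hi])
            p[lo:hi] = dia_t + amp * _pulse_shape(np.clip(u, 0.0, 1.0))
    elif channel in ("CVP", "ICP"):
        mean_t = params.cvp_mean_target if channel == "CVP" else params.icp_mean_target
        waves = _CVP_WAVES if channel == "CVP" else _ICP_WAVES
        scale = _WAVE_AMPLITUDE[channel]
        centers, amps, widths = [], [], []
        per_beat_means = []
        bounds = np.concatenate((onsets, [onsets[-1] + rr_mean]))
        for k in range(len(onsets)):
            rr = bounds[k + 1] - bounds[k]
            integral = 0.0
            for phase, rel_amp, rel_w in waves:
                a = scale * rel_amp * (0.7 if beats.types[k] == "premature" else 1.0)
                w = rel_w * rr
                centers.append(bounds[k] + phase * rr)
                amps.append(a)
                widths.append(w)
                integral += a * w * np.sqrt(2.0 * np.pi)
            per_beat_means.append((k, rr, integral))
        p = _gauss_bumps(t, centers, amps, widths)
        # remove each beat's residual mean so the series mean is the target
        for k, rr, integral in per_beat_means:
            lo = int(np.ceil(bounds[k] * fs))
            hi = min(n, int(np.ceil(bounds[k + 1] * fs)))
            if hi > lo:
                p[lo:hi] -= integral / rr
        p += mean_t
        if params.resp_depth_additive > 0:
            p = p + params.resp_depth_additive * resp
    else:
        raise ValueError(f"unknown pressure channel {channel!r}")

    sd = params.noise_sd.get(channel, 0.0)
    if sd > 0:
        p = p + rng.normal(0.0, sd, size=n)
    return p


def generate_subject_record(
    record_id: str,
    params: SubjectParams,
    duration_s: float,
    fs: float,
    channels: tuple[str, ...],
    seed: int | np.random.Generator = 0,
    ranges: SubjectRanges | None = None,
) -> SignalRecord:
    """Render one subject's multi-channel record from a single beat train."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beat_rng, *chan_rngs = rng.spawn(len(channels) + 1)
    beats = make_beat_train(params, duration_s, beat_rng)
    signals: dict[str, np.ndarray] = {}
    for name, crng in zip(channels, chan_rngs):
        if name == "ECG":
            signals[name] = render_ecg(beats, params, fs, duration_s, crng, ranges)
        else:
            signals[name] = render_pressure(beats, params, name, fs, duration_s, crng)
    return SignalRecord(
        record_id=record_id,
        fs=fs,
        channels=signals,
        meta={"subject_params": {k: v for k, v in params.__dict__.items() if k != "noise_sd"}},
    )


def generate_corpus(
    n_subjects: int,
    seconds_per_subject: float = 60.0,
    fs: float = DEFAULT_FS_CARDIO,
    channels: tuple[str, ...] = CARDIO_CHANNELS,
    seed: int = 0,
    ranges: SubjectRanges | None = None,
    arrhythmia: str = "none",
    arrhythmia_probability: float = 0.15,
    noise_free: bool = False,
) -> tuple[list[SignalRecord], list[SubjectParams]]:
    """Generate one record per synthetic subject (deterministic given seed)."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    root = np.random.default_rng(seed)
    records, all_params = [], []
    for i, srng in enumerate(root.spawn(n_subjects)):
        prng, rrng = srng.spawn(2)
        params = sample_subject(prng, ranges, arrhythmia, arrhythmia_probability)
        if noise_free:
            params = params.noise_free()
        rec = generate_subject_record(
            f"synth-{seed}-{i:03d}", params, seconds_per_subject, fs, tuple(channels), rrng, ranges
        )
        records.append(rec)
        all_params.append(params)
    return records, all_params
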
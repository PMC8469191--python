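"""Generator properties: determinism, beat statistics, analytic fiducials,
ECG/pressure coupling and arrhythmia modes."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from hemowave import (
    SubjectRanges,
    generate_corpus,
    make_beat_train,
    render_ecg,
    render_pressure,
    sample_subject,
)
from hemowave.synth import ecg_morphology
from hemowave.windows import screen_windows, segment_record


def test_sample_subject_deterministic():
    a, b = sample_subject(42), sample_subject(42)
    assert a == b


def test_sample_subject_respects_orderings():
    rng = np.random.default_rng(0)
    for _ in range(10_000):
        p = sample_subject(rng)
        assert p.sbp_target > p.dbp_target
        assert p.pap_sys_target > p.pap_dia_target


def test_degenerate_range_collapses():
    r = SubjectRanges(sbp_target=(120.0, 120.0))
    assert sample_subject(5, r).sbp_target == 120.0


def test_inverted_range_rejected():
    with pytest.raises(ValueError, match="inverted"):
        SubjectRanges(sbp_target=(180.0, 90.0))


def _steady(hr=60.0, **kw):
    p = sample_subject(0)
    p.heart_rate_mean = hr
    p.rr_jitter_sd = 0.0
    for k, v in kw.items():
        setattr(p, k, v)
    return p


def test_beat_train_regular_spacing():
    beats = make_beat_train(_steady(60.0), 10.0, seed=1)
    assert len(beats.onsets) == 10
    np.testing.assert_allclose(beats.rr_intervals, 1.0, atol=1e-9)
    assert all(t == "normal" for t in beats.types)


def test_beat_train_mean_interval():
    p = _steady(75.0)
    p.rr_jitter_sd = 0.05
    beats = make_beat_train(p, 600.0, seed=3)
    rr = beats.rr_intervals
    se = rr.std(ddof=1) / np.sqrt(len(rr))
    assert abs(rr.mean() - 0.8) < 2 * se + 1e-6


def test_premature_probability_zero_means_no_tags():
    p = _steady(60.0, arrhythmia="premature_beats", arrhythmia_probability=0.0)
    beats = make_beat_train(p, 60.0, seed=2)
    assert "premature" not in beats.types


def test_premature_beats_arrive_early():
    p = _steady(60.0, arrhythmia="premature_beats", arrhythmia_probability=0.3)
    beats = make_beat_train(p, 120.0, seed=2)
    prem = [i for i, t in enumerate(beats.types) if t == "premature"]
    assert prem, "expected some premature beats at probability 0.3"
    rr = beats.rr_intervals
    for i in prem:
        assert rr[i - 1] < 0.8 * np.median(rr)  # shortened preceding interval


def test_irregular_rr_raises_interval_cv():
    normal = make_beat_train(_steady(70.0, rr_jitter_sd=0.02), 300.0, seed=4)
    p_irr = _steady(70.0, rr_jitter_sd=0.02, arrhythmia="irregular_rr")
    irregular = make_beat_train(p_irr, 300.0, seed=4)

    def cv(b):
        return b.rr_intervals.std() / b.rr_intervals.mean()

    assert cv(normal) <= 0.05
    assert cv(irregular) > 2 * cv(normal)


def test_render_ecg_zero_beats_is_noise():
    from hemowave.synth import BeatTrain

    p = _steady()
    p.noise_sd = {k: 0.0 for k in p.noise_sd}
    ecg = render_ecg(BeatTrain(np.array([]), []), p, 128.0, 4.0)
    assert ecg.shape == (512,)
    np.testing.assert_array_equal(ecg, 0.0)


def test_render_ecg_r_peak_position():
    p = _steady().noise_free()
    beats = make_beat_train(p, 5.0, seed=0)
    fs = 128.0
    ecg = render_ecg(beats, p, fs, 5.0)
    # R is the dominant positive bump: argmax near first onset
    first = beats.onsets[0]
    assert abs(np.argmax(ecg[: int(fs)]) - first * fs) <= 1


def test_ecg_morphology_monotone_in_sbp():
    """Higher systolic pressure yields a taller R wave (the coupling the
    network exploits)."""
    lo, hi = _steady(sbp_target=100.0), _steady(sbp_target=170.0)
    assert ecg_morphology(hi)["R"][1] > ecg_morphology(lo)["R"][1]


@pytest.mark.parametrize("channel,attr", [("ABP", "sbp_target"), ("PAP", "pap_sys_target")])
def test_pressure_beat_maxima_hit_systolic_target(channel, attr):
    p = _steady(72.0).noise_free()
    beats = make_beat_train(p, 30.0, seed=0)
    fs = 128.0
    wave = render_pressure(beats, p, channel, fs, 30.0)
    target = getattr(p, attr)
    onsets = ((beats.onsets + p.pulse_transit_delay) * fs).astype(int)
    for a, b in zip(onsets[:-1], onsets[1:]):
        assert abs(wave[a:b].max() - target) / target < 0.01


def test_icp_series_mean_matches_target():
    p = _steady(65.0).noise_free()
    beats = make_beat_train(p, 60.0, seed=1)
    wave = render_pressure(beats, p, "ICP", 50.0, 60.0)
    assert abs(wave.mean() - p.icp_mean_target) / p.icp_mean_target < 0.01


def test_unknown_pressure_channel_raises():
    p = _steady()
    beats = make_beat_train(p, 5.0, seed=0)
    with pytest.raises(ValueError, match="unknown"):
        render_pressure(beats, p, "PPG", 128.0, 5.0)


def test_transit_delay_visible_in_cross_correlation():
    """The ECG-to-ABP lag recovered by cross-correlating the R-peak impulse
    train with the ABP upstroke velocity equals the configured delay."""
    p = _steady(60.0).noise_free()
    fs = 128.0
    beats = make_beat_train(p, 40.0, seed=0)
    ecg_impulses = np.zeros(int(40.0 * fs))
    ecg_impulses[(beats.onsets * fs).astype(int)] = 1.0
    abp = render_pressure(beats, p, "ABP", fs, 40.0)
    upstroke = np.clip(np.diff(abp, prepend=abp[0]), 0, None)
    xc = sp_signal.correlate(upstroke, ecg_impulses, mode="full")
    lags = sp_signal.correlation_lags(len(upstroke), len(ecg_impulses), mode="full")
    window = (lags >= 0) & (lags <= int(0.5 * fs))
    lag = lags[window][np.argmax(xc[window])]
    # the upstroke velocity peaks mid-rise; allow half the rise time
    rise_samples = 0.18 * (60.0 / p.heart_rate_mean) * fs
    assert abs(lag - p.pulse_transit_delay * fs) <= rise_samples / 2 + 1


def test_corpus_bit_identical_for_same_seed():
    a, _ = generate_corpus(3, 20.0, 125.0, ("ECG", "ABP", "CVP", "PAP"), seed=7)
    b, _ = generate_corpus(3, 20.0, 125.0, ("ECG", "ABP", "CVP", "PAP"), seed=7)
    for ra, rb in zip(a, b):
        assert ra.record_id == rb.record_id
        for name in ra.channel_names:
            np.testing.assert_array_equal(ra.channels[name], rb.channels[name])


def test_corpus_windows_all_pass_screening():
    records, _ = generate_corpus(4, 30.0, 128.0, ("ECG", "ABP", "CVP", "PAP"), seed=9)
    for rec in records:
        kept, rejected = screen_windows(segment_record(rec, 2.0))
        assert rejected == []
        assert len(kept) == 15


def test_corpus_shapes():
    records, params = generate_corpus(1, 10.0, 50.0, ("ECG", "ICP"), seed=0)
    assert len(records) == 1
    assert records[0].channel_names == ["ECG", "ICP"]
    assert records[0].n_samples == 500
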
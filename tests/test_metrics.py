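"""Evaluation suite: correlation/error formulas against brute-force oracles,
fiducial extraction, fold aggregation and Bland-Altman agreement."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from hemowave import (
    MetricReport,
    aggregate_folds,
    bland_altman,
    evaluate_waveforms,
    extract_fiducials,
    mae,
    pearson_r,
    rmse,
)


def brute_force_r(x, y):
    """Direct evaluation of the correlation sums, scalar loop."""
    n = len(x)
    xb = sum(x) / n
    yb = sum(y) / n
    num = sum((x[i] - xb) * (y[i] - yb) for i in range(n))
    den = math.sqrt(sum((x[i] - xb) ** 2 for i in range(n))
                    * sum((y[i] - yb) ** 2 for i in range(n)))
    return num / den


def test_pearson_identity_and_antisymmetry():
    x = np.array([1.0, 2.0, 3.0, 5.0])
    assert pearson_r(x, x) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)


def test_pearson_matches_brute_force_and_scipy():
    x = [1.0, 2.0, 3.0, 4.0]
    y = [2.0, 4.0, 5.0, 4.0]
    r = pearson_r(x, y)
    assert r == pytest.approx(brute_force_r(x, y), rel=1e-12)
    assert r == pytest.approx(stats.pearsonr(x, y).statistic, rel=1e-12)


def test_pearson_zero_variance_raises():
    with pytest.raises(ValueError, match="zero variance"):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_error_metric_examples():
    x = np.array([0.0, 0.0])
    y = np.array([3.0, -3.0])
    assert mae(x, y) == pytest.approx(3.0)
    assert rmse(x, y) == pytest.approx(3.0)
    assert mae(y, y) == 0.0 and rmse(y, y) == 0.0


def test_length_mismatch_raises():
    with pytest.raises(ValueError, match="mismatch"):
        mae([1.0, 2.0], [1.0])


@given(arrays(np.float64, st.integers(2, 60),
              elements=st.floats(-100, 100, allow_nan=False)),
       st.integers(0, 2**31 - 1))
def test_rmse_dominates_mae(x, seed):
    y = x + np.random.default_rng(seed).normal(0, 5.0, size=len(x))
    assert rmse(x, y) >= mae(x, y) - 1e-12


@given(st.integers(0, 2**31 - 1), st.floats(0.1, 10), st.floats(-50, 50))
def test_pearson_affine_invariance(seed, a, b):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    r = pearson_r(x, y)
    assert pearson_r(x, a * y + b) == pytest.approx(r, abs=1e-9)
    assert pearson_r(x, -a * y + b) == pytest.approx(-r, abs=1e-9)


def test_extract_fiducials_examples():
    f = extract_fiducials(np.array([80.0, 120.0, 80.0, 60.0]), "maxmin")
    assert f.systolic == 120.0 and f.diastolic == 60.0
    assert extract_fiducials(np.full(7, 4.2), "mean").mean == pytest.approx(4.2)
    with pytest.raises(ValueError):
        extract_fiducials(np.array([]), "mean")
    with pytest.raises(ValueError, match="mode"):
        extract_fiducials(np.ones(3), "median")


def test_fiducial_invariants(rng):
    w = rng.normal(100, 20, size=256)
    f = extract_fiducials(w, "maxmin")
    m = extract_fiducials(w, "mean")
    assert f.systolic >= f.diastolic
    assert f.diastolic <= m.mean <= f.systolic


def test_evaluate_waveforms_pools_samples():
    ref = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])]
    pred = [np.array([1.0, 2.0, 2.0]), np.array([5.0, 5.0, 6.0])]
    rep = evaluate_waveforms(ref, pred)
    assert rep.n == 6
    manual = np.abs(np.concatenate(ref) - np.concatenate(pred)).mean()
    assert rep.mae == pytest.approx(manual)


def test_evaluate_waveforms_permutation_invariant(rng):
    ref = [rng.normal(size=50) for _ in range(6)]
    pred = [r + rng.normal(0, 0.1, size=50) for r in ref]
    a = evaluate_waveforms(ref, pred)
    order = rng.permutation(6)
    b = evaluate_waveforms([ref[i] for i in order], [pred[i] for i in order])
    assert a.n == b.n
    for key in ("r", "mae", "rmse"):  # equal up to summation rounding
        assert getattr(a, key) == pytest.approx(getattr(b, key), rel=1e-12)


def test_perfect_prediction_metrics():
    ref = [np.linspace(60, 120, 100) for _ in range(3)]
    rep = evaluate_waveforms(ref, ref)
    assert rep.r == pytest.approx(1.0)
    assert rep.mae == 0.0 and rep.rmse == 0.0


def test_aggregate_published_fold_correlations():
    """Five per-fold systolic correlations aggregate to mean 0.894 with the
    printed sample STD 0.004."""
    folds = [0.890, 0.894, 0.892, 0.895, 0.900]
    reports = [MetricReport(r=v, rmse=0.0, mae=0.0, n=10) for v in folds]
    agg = aggregate_folds(reports)
    assert round(agg.mean["R"], 3) == 0.894
    assert round(agg.std["R"], 3) == 0.004


def test_aggregate_identical_reports_zero_std():
    reports = [MetricReport(r=0.9, rmse=2.0, mae=1.0, n=5)] * 5
    agg = aggregate_folds(reports)
    assert agg.std == {"R": 0.0, "RMSE": 0.0, "MAE": 0.0}
    single = aggregate_folds(reports[:1])
    assert single.mean["R"] == 0.9 and single.std["R"] == 0.0


def test_aggregate_matches_direct_computation(rng):
    vals = rng.uniform(0, 10, size=(5, 3))
    reports = [MetricReport(r=v[0], rmse=v[1], mae=v[2], n=3) for v in vals]
    agg = aggregate_folds(reports)
    np.testing.assert_allclose(
        [agg.mean["R"], agg.mean["RMSE"], agg.mean["MAE"]], vals.mean(axis=0))
    np.testing.assert_allclose(
        [agg.std["R"], agg.std["RMSE"], agg.std["MAE"]], vals.std(axis=0, ddof=1))


def test_bland_altman_exact_cases():
    ref = np.array([100.0, 110.0, 120.0])
    same = bland_altman(ref, ref)
    assert same.bias == 0.0 and same.loa_lower == 0.0 and same.loa_upper == 0.0
    shifted = bland_altman(ref, ref + 5.0)
    assert shifted.bias == pytest.approx(5.0)
    assert shifted.sd == 0.0
    assert shifted.loa_lower == shifted.loa_upper == pytest.approx(5.0)


def test_bland_altman_formula_oracle(rng):
    ref = rng.normal(100, 15, size=200)
    pred = ref + rng.normal(-2, 4, size=200)
    ba = bland_altman(ref, pred)
    d = pred - ref
    assert ba.bias == pytest.approx(d.mean(), rel=1e-12)
    assert ba.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), rel=1e-12)
    assert ba.loa_lower == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), rel=1e-12)
    np.testing.assert_allclose(ba.means, (ref + pred) / 2)


def test_bland_altman_direction_switch(rng):
    ref = rng.normal(size=50)
    pred = ref + 1.0
    assert bland_altman(ref, pred).bias == pytest.approx(1.0)
    rev = bland_altman(ref, pred, direction="reference-prediction")
    assert rev.bias == pytest.approx(-1.0)
    assert rev.direction == "reference-prediction"


def test_bland_altman_limits_cover_95_percent():
    rng = np.random.default_rng(99)
    ref = rng.normal(100, 10, size=20_000)
    pred = ref + rng.normal(1.0, 3.0, size=20_000)
    ba = bland_altman(ref, pred)
    inside = np.mean((ba.diffs >= ba.loa_lower) & (ba.diffs <= ba.loa_upper))
    assert 0.945 < inside < 0.955
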
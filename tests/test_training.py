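"""Cross-validation protocol, checkpointing and the estimator surface."""

import numpy as np
import pytest
from sklearn.base import clone

from hemowave import MAUDCAERegressor, make_folds
from hemowave.pipeline import build_windows, default_config
from hemowave.training import (
    TrainConfig,
    predict as predict_windows,
    run_cv,
    split_test,
    train as train_fold,
    windows_to_arrays,
)
from hemowave.windows import fit_scalers


# ---------------------------------------------------------------- folds
def test_make_folds_partitions_exactly():
    ids = [f"w{i}" for i in range(10)]
    plan = make_folds(ids, 5, seed=3)
    vals = [set(v) for _, v in plan.folds]
    assert all(len(v) == 2 for v in vals)
    assert set().union(*vals) == set(ids)
    for i in range(5):
        for j in range(i + 1, 5):
            assert not vals[i] & vals[j]
    for train_ids, val_ids in plan.folds:
        assert set(train_ids) | set(val_ids) == set(ids)
        assert not set(train_ids) & set(val_ids)


def test_make_folds_uneven_sizes():
    plan = make_folds([f"w{i}" for i in range(11)], 5, seed=0)
    sizes = sorted(len(v) for _, v in plan.folds)
    assert sizes == [2, 2, 2, 2, 3]


def test_make_folds_deterministic_and_order_independent():
    ids = [f"w{i}" for i in range(20)]
    a = make_folds(ids, 4, seed=7)
    b = make_folds(list(reversed(ids)), 4, seed=7)
    assert a == b
    assert a != make_folds(ids, 4, seed=8)


def test_make_folds_errors():
    with pytest.raises(ValueError):
        make_folds(["a", "b"], 3, seed=0)
    with pytest.raises(ValueError, match="overlap"):
        make_folds(["a", "b", "c"], 2, seed=0, test_ids=("a",))


def test_split_test_disjoint_and_seeded():
    ids = [f"w{i}" for i in range(50)]
    pool, test = split_test(ids, 0.2, seed=4)
    assert len(test) == 10
    assert not set(pool) & set(test)
    assert set(pool) | set(test) == set(ids)
    assert (pool, test) == split_test(ids, 0.2, seed=4)


def test_train_config_invariants():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(loss="mse")


# ---------------------------------------------------------- tiny corpus
@pytest.fixture(scope="module")
def tiny_setup():
    cfg = default_config("cerebral")
    cfg["seed"] = 5
    cfg["synth"].update({"n_subjects": 4, "seconds_per_subject": 30.0})
    _, _, kept, _ = build_windows(cfg)
    by_id = {w.window_id: w for w in kept}
    pool_ids, test_ids = split_test(by_id, 0.2, 5)
    scalers = fit_scalers([by_id[i] for i in pool_ids])
    return kept, by_id, pool_ids, test_ids, scalers


def _tiny_estimator(**kw):
    defaults = dict(in_len=100, out_channels=1, levels=2, base_filters=4,
                    epochs=2, random_state=0)
    defaults.update(kw)
    return MAUDCAERegressor(**defaults)


def test_single_epoch_history(tiny_setup):
    kept, by_id, pool_ids, _, scalers = tiny_setup
    plan = make_folds(pool_ids, 2, seed=1)
    est = train_fold(_tiny_estimator(epochs=1), plan.folds[0], kept, scalers, ["ICP"])
    assert len(est.history_["train_loss"]) == 1
    assert est.best_epoch_ == 0


def test_reported_train_loss_is_recomputable(tiny_setup):
    """With a zero learning rate the weights never move, so the reported
    epoch loss must equal an independent MAE pass over the same windows."""
    kept, by_id, pool_ids, _, scalers = tiny_setup
    plan = make_folds(pool_ids, 2, seed=1)
    train_ids, val_ids = plan.folds[0]
    # batch == train size: the single batch covers every window exactly once
    est = _tiny_estimator(epochs=2, learning_rate=0.0, batch_size=len(train_ids))
    est = train_fold(est, plan.folds[0], kept, scalers, ["ICP"])
    Xt, yt = windows_to_arrays([by_id[i] for i in train_ids], scalers, ["ICP"])
    independent = float(np.abs(est.predict(Xt) - yt).mean())
    np.testing.assert_allclose(est.history_["train_loss"], independent, rtol=1e-5)


def test_validation_improves_to_checkpoint(tiny_setup):
    kept, by_id, pool_ids, _, scalers = tiny_setup
    plan = make_folds(pool_ids, 2, seed=1)
    est = train_fold(_tiny_estimator(epochs=6), plan.folds[0], kept, scalers, ["ICP"])
    val = est.history_["val_loss"]
    assert val[est.best_epoch_] == val.min()
    assert val[est.best_epoch_] < val[0] or est.best_epoch_ == 0


def test_checkpoint_reload_reproduces_validation_loss(tiny_setup):
    kept, by_id, pool_ids, _, scalers = tiny_setup
    plan = make_folds(pool_ids, 2, seed=1)
    train_ids, val_ids = plan.folds[0]
    est = train_fold(_tiny_estimator(epochs=5), plan.folds[0], kept, scalers, ["ICP"])
    Xv, yv = windows_to_arrays([by_id[i] for i in val_ids], scalers, ["ICP"])
    assert est.validation_loss(Xv, yv) == pytest.approx(est.best_val_loss_, rel=1e-6)


def test_empty_fold_raises(tiny_setup):
    kept, by_id, pool_ids, _, scalers = tiny_setup
    with pytest.raises(ValueError, match="empty"):
        train_fold(_tiny_estimator(), (tuple(pool_ids), ()), kept, scalers, ["ICP"])


def test_predict_shapes_units_and_determinism(tiny_setup):
    kept, by_id, pool_ids, test_ids, scalers = tiny_setup
    plan = make_folds(pool_ids, 2, seed=1)
    est = train_fold(_tiny_estimator(), plan.folds[0], kept, scalers, ["ICP"])
    test = [by_id[i] for i in test_ids][:4]
    preds = predict_windows(est, test, scalers, ["ICP"])
    assert set(preds) == {"ICP"}
    assert preds["ICP"].shape == (4, 100)
    # mmHg scale: predictions land in a physiological ICP neighbourhood
    assert 0 < preds["ICP"].mean() < 40
    again = predict_windows(est, test, scalers, ["ICP"])
    np.testing.assert_array_equal(preds["ICP"], again["ICP"])


def test_scaler_round_trip_preserves_fiducials(tiny_setup):
    kept, _, _, _, scalers = tiny_setup
    w = kept[0]
    y = w.targets["ICP"]
    back = scalers["ICP"].inverse_transform(scalers["ICP"].transform(y))
    assert back.max() == pytest.approx(y.max(), rel=1e-9)
    assert back.mean() == pytest.approx(y.mean(), rel=1e-9)


def test_run_cv_protocol(tiny_setup):
    kept, by_id, _, _, _ = tiny_setup
    cvres = run_cv(kept, _tiny_estimator(), k=3, test_fraction=0.2, seed=5)
    assert cvres.plan.k == 3
    assert len(cvres.estimators) == 3
    assert len(cvres.fold_predictions) == 3
    test_set = set(cvres.plan.test_ids)
    for train_ids, val_ids in cvres.plan.folds:
        assert not test_set & (set(train_ids) | set(val_ids))
    for preds in cvres.fold_predictions:
        assert preds["ICP"].shape == (len(cvres.test_windows), 100)


def test_run_cv_degenerate_single_fold(tiny_setup):
    from hemowave import aggregate_folds
    from hemowave.metrics import evaluate_waveforms

    kept, *_ = tiny_setup
    cvres = run_cv(kept, _tiny_estimator(), k=1, test_fraction=0.3, seed=2)
    ref = np.stack([w.targets["ICP"] for w in cvres.test_windows])
    rep = evaluate_waveforms(ref, cvres.fold_predictions[0]["ICP"])
    agg = aggregate_folds([rep])
    assert agg.mean["MAE"] == rep.mae
    assert agg.std["MAE"] == 0.0


# ------------------------------------------------------------ sklearn API
def test_estimator_sklearn_contract():
    est = MAUDCAERegressor(levels=2, epochs=3)
    params = est.get_params()
    assert params["levels"] == 2 and params["epochs"] == 3
    cloned = clone(est)
    assert cloned.get_params() == params
    cloned.set_params(base_filters=16)
    assert cloned.base_filters == 16


def test_estimator_refit_is_deterministic(tiny_setup):
    kept, by_id, pool_ids, _, scalers = tiny_setup
    Xp, yp = windows_to_arrays([by_id[i] for i in pool_ids], scalers, ["ICP"])
    a = _tiny_estimator().fit(Xp, yp)
    b = _tiny_estimator().fit(Xp, yp)
    np.testing.assert_array_equal(a.predict(Xp[:5]), b.predict(Xp[:5]))
    np.testing.assert_array_equal(a.history_["val_loss"], b.history_["val_loss"])


def test_estimator_rejects_wrong_window_length(tiny_setup):
    kept, by_id, pool_ids, _, scalers = tiny_setup
    Xp, yp = windows_to_arrays([by_id[i] for i in pool_ids], scalers, ["ICP"])
    est = _tiny_estimator().fit(Xp, yp)
    with pytest.raises(ValueError, match="window length"):
        est.predict(Xp[:, :50])
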
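"""End-to-end orchestration: synthesize -> segment -> screen -> cross-validated
training -> prediction -> evaluation -> (optionally) ablation.

`run_pipeline` executes the whole chain from a config dict and writes a
manifest, per-fold metric tables shaped like the clinical fold tables
(rows CV 1..k, Mean, STD) and a machine-readable metrics JSON.  All
randomness flows from the single seed in the config, so re-running a
manifest reproduces byte-identical metrics output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .architecture import (
    CARDIO_ABLATION_SEQUENCE,
    CEREBRAL_ABLATION_SEQUENCE,
    ablate,
)
from .estimator import MAUDCAERegressor
from .metrics import (
    FIDUCIAL_MODES,
    FIDUCIAL_NAMES,
    MetricReport,
    aggregate_folds,
    bland_altman,
    evaluate_fiducials,
    evaluate_waveforms,
    extract_fiducials,
)
from .synth import (
    CARDIO_CHANNELS,
    CEREBRAL_CHANNELS,
    DEFAULT_FS_CARDIO,
    DEFAULT_FS_CEREBRAL,
    generate_corpus,
)
from .training import (
    CVResult,
    mean_baseline_predictions,
    predict as predict_windows,
    run_cv,
    split_test,
    train as train_fold,
    make_folds,
    windows_to_arrays,
)
from .windows import ScreenRules, screen_windows, segment_record, fit_scalers


def default_config(profile: str = "cardio") -> dict:
    """Full pipeline configuration for one of the two study profiles."""
    if profile == "cardio":
        synth = {"n_subjects": 12, "seconds_per_subject": 60.0, "fs": DEFAULT_FS_CARDIO,
                 "channels": list(CARDIO_CHANNELS)}
        model = {"in_len": 256, "out_channels": 3, "levels": 3, "base_filters": 8,
                 "dilation_rates": [1, 2, 4], "skip_connections": None}
    elif profile == "cerebral":
        synth = {"n_subjects": 12, "seconds_per_subject": 60.0, "fs": DEFAULT_FS_CEREBRAL,
                 "channels": list(CEREBRAL_CHANNELS)}
        model = {"in_len": 100, "out_channels": 1, "levels": 2, "base_filters": 8,
                 "dilation_rates": [1, 2, 4],
                 "skip_connections": ["skip_L1", "skip_L2"]}
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return {
        "profile": profile,
        "seed": 0,
        "window_seconds": 2.0,
        "synth": synth,
        "model": model,
        "train": {"epochs": 10, "batch_size": 16, "learning_rate": 2e-3},
        "cv": {"k": 5, "test_fraction": 0.2},
    }


def demo_config(profile: str = "cardio") -> dict:
    """Tiny configuration for smoke runs (3 subjects, 2 epochs, k=2)."""
    cfg = default_config(profile)
    cfg["synth"].update({"n_subjects": 3, "seconds_per_subject": 30.0})
    cfg["model"].update({"levels": 2, "base_filters": 4})
    if profile == "cerebral":
        cfg["model"]["skip_connections"] = ["skip_L1", "skip_L2"]
    else:
        cfg["model"]["skip_connections"] = None
    cfg["train"]["epochs"] = 2
    cfg["cv"]["k"] = 2
    return cfg


def estimator_from_config(cfg: dict) -> MAUDCAERegressor:
    m, t = cfg["model"], cfg["train"]
    skips = m.get("skip_connections")
    return MAUDCAERegressor(
        in_len=m["in_len"],
        out_channels=m["out_channels"],
        levels=m["levels"],
        base_filters=m["base_filters"],
        kernel_size=m.get("kernel_size", 3),
        dilation_rates=tuple(m.get("dilation_rates", (1, 2, 4))),
        skip_connections=tuple(skips) if skips is not None else None,
        head_convs=m.get("head_convs", 2),
        filter_cap=m.get("filter_cap", 64),
        epochs=t["epochs"],
        batch_size=t["batch_size"],
        learning_rate=t["learning_rate"],
        random_state=cfg.get("seed", 0),
    )


def build_windows(cfg: dict):
    """Synthesize the corpus and return screened windows + records."""
    s = cfg["synth"]
    records, params = generate_corpus(
        n_subjects=s["n_subjects"],
        seconds_per_subject=s["seconds_per_subject"],
        fs=s["fs"],
        channels=tuple(s["channels"]),
        seed=cfg.get("seed", 0),
        arrhythmia=s.get("arrhythmia", "none"),
        arrhythmia_probability=s.get("arrhythmia_probability", 0.15),
        noise_free=s.get("noise_free", False),
    )
    windows = []
    for rec in records:
        windows.extend(segment_record(rec, cfg.get("window_seconds", 2.0)))
    kept, rejected = screen_windows(windows, ScreenRules())
    return records, params, kept, rejected


def _fiducial_arrays(windows_2d: np.ndarray, channel: str) -> dict[str, np.ndarray]:
    """Per-window fiducials of a (n_windows, L) array, keyed by fiducial name."""
    mode = FIDUCIAL_MODES[channel]
    names = FIDUCIAL_NAMES[channel]
    sets = [extract_fiducials(w, mode) for w in windows_2d]
    if mode == "maxmin":
        return {names[0]: np.array([f.systolic for f in sets]),
                names[1]: np.array([f.diastolic for f in sets])}
    return {names[0]: np.array([f.mean for f in sets])}


def evaluate_cv(cvres: CVResult) -> dict:
    """Per-channel waveform and fiducial metrics per fold, aggregated, plus
    Bland-Altman agreement from the first fold's test predictions."""
    out: dict = {}
    for c in cvres.target_channels:
        ref = np.stack([w.targets[c] for w in cvres.test_windows])
        wave_reports = [
            evaluate_waveforms(ref, preds[c]) for preds in cvres.fold_predictions
        ]
        entry = {
            "waveform": _reports_entry(wave_reports),
            "fiducials": {},
            "bland_altman": {},
        }
        ref_fids = _fiducial_arrays(ref, c)
        for name in ref_fids:
            fid_reports = []
            for preds in cvres.fold_predictions:
                pred_fids = _fiducial_arrays(preds[c], c)
                fid_reports.append(evaluate_fiducials(ref_fids[name], pred_fids[name]))
            entry["fiducials"][name] = _reports_entry(fid_reports)
            ba = bland_altman(ref_fids[name], _fiducial_arrays(cvres.fold_predictions[0][c], c)[name])
            entry["bland_altman"][name] = {
                "bias_mmHg": ba.bias,
                "loa_lower_mmHg": ba.loa_lower,
                "loa_upper_mmHg": ba.loa_upper,
                "direction": ba.direction,
                "n": ba.n,
            }
        out[c] = entry
    return out


def _reports_entry(reports: list[MetricReport]) -> dict:
    agg = aggregate_folds(reports)
    return {
        "folds": [r.as_dict() for r in reports],
        "mean": agg.mean,
        "std": agg.std,
    }


def metrics_table(evaluation: dict) -> "object":
    """Fold-table DataFrame (rows CV 1..k, Mean, STD) of fiducial metrics."""
    import pandas as pd

    rows = []
    for channel, entry in evaluation.items():
        for fid, rep in entry["fiducials"].items():
            for i, fold in enumerate(rep["folds"], start=1):
                rows.append({"quantity": fid, "channel": channel, "fold": str(i), **fold})
            rows.append({"quantity": fid, "channel": channel, "fold": "Mean", **rep["mean"]})
            rows.append({"quantity": fid, "channel": channel, "fold": "STD", **rep["std"]})
    return pd.DataFrame(rows)


def _corpus_fingerprint(records) -> str:
    h = hashlib.sha256()
    for rec in records:
        h.update(rec.record_id.encode())
        for name in rec.channel_names:
            h.update(np.ascontiguousarray(rec.channels[name]).tobytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce and locate a pipeline run's outputs."""

    config: dict
    seed: int
    package_version: str
    corpus_fingerprint: str
    n_windows_kept: int
    n_windows_rejected: int
    outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def dump_json(obj, path: Path) -> None:
    """Deterministic JSON dump (sorted keys, fixed float formatting)."""
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> RunManifest:
    """Execute the full stage sequence; halts naming the failing stage."""
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configuration"
    try:
        estimator = estimator_from_config(config)
        # architecture validation happens before any data work
        from .architecture import validate_config

        stage = "architecture validation"
        violations = validate_config(estimator.model_config())
        if violations:
            raise ValueError("; ".join(violations))

        stage = "synthesis/segmentation"
        records, params, kept, rejected = build_windows(config)

        stage = "cross-validated training"
        cv = config.get("cv", {})
        cvres = run_cv(
            kept,
            estimator,
            k=cv.get("k", 5),
            test_fraction=cv.get("test_fraction", 0.2),
            seed=config.get("seed", 0),
        )

        stage = "evaluation"
        evaluation = evaluate_cv(cvres)
        metrics_path = out / "metrics.json"
        dump_json(evaluation, metrics_path)
        table_path = out / "metrics.csv"
        metrics_table(evaluation).to_csv(table_path, index=False, float_format="%.6f")
        histories = {
            f"fold_{i + 1}": {k: v.tolist() for k, v in est.history_.items()}
            for i, est in enumerate(cvres.estimators)
        }
        dump_json(histories, out / "histories.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}: {exc}") from exc

    manifest = RunManifest(
        config=config,
        seed=config.get("seed", 0),
        package_version=__version__,
        corpus_fingerprint=_corpus_fingerprint(records),
        n_windows_kept=len(kept),
        n_windows_rejected=len(rejected),
        outputs={
            "metrics_json": str(metrics_path),
            "metrics_csv": str(table_path),
            "histories_json": str(out / "histories.json"),
            "manifest": str(out / "manifest.json"),
        },
    )
    manifest.write(out / "manifest.json")
    return manifest


# ----------------------------------------------------------------------
def learnability_experiment(
    profile: str = "cardio",
    n_subjects: int = 40,
    seconds_per_subject: float = 60.0,
    epochs: int = 25,
    levels: int | None = None,
    base_filters: int = 8,
    seed: int = 1,
) -> dict:
    """Single train/validation/test experiment measuring whether the
    ECG -> pressure mapping is learnable on the synthetic corpus.

    Returns pooled waveform and fiducial metrics per channel on the held-out
    test set, together with the predict-the-training-mean baseline MAE.
    """
    cfg = default_config(profile)
    cfg["seed"] = seed
    cfg["synth"].update({"n_subjects": n_subjects, "seconds_per_subject": seconds_per_subject})
    if levels is not None:
        cfg["model"]["levels"] = levels
        if profile == "cardio":
            cfg["model"]["skip_connections"] = None  # all available at this depth
    cfg["model"]["base_filters"] = base_filters
    cfg["train"]["epochs"] = epochs

    records, params, kept, _ = build_windows(cfg)
    by_id = {w.window_id: w for w in kept}
    pool_ids, test_ids = split_test(by_id, cfg["cv"]["test_fraction"], seed)
    pool = [by_id[i] for i in pool_ids]
    test = [by_id[i] for i in test_ids]
    scalers = fit_scalers(pool)
    target_channels = sorted(kept[0].targets)

    estimator = estimator_from_config(cfg)
    Xp, yp = windows_to_arrays(pool, scalers, target_channels)
    estimator.fit(Xp, yp)  # internal seeded validation split + checkpointing
    preds = predict_windows(estimator, test, scalers, target_channels)
    baseline = mean_baseline_predictions(pool, test, target_channels)

    result: dict = {"profile": profile, "n_windows": len(kept), "n_test": len(test),
                    "epochs": epochs, "channels": {}}
    for c in target_channels:
        ref = np.stack([w.targets[c] for w in test])
        from .metrics import mae as _mae

        wave = evaluate_waveforms(ref, preds[c])
        entry = {
            "waveform": wave.as_dict(),
            # constant predictor: only error metrics are defined for it
            "baseline_waveform_mae": _mae(np.concatenate(ref), np.concatenate(baseline[c])),
            "fiducials": {},
            "bland_altman": {},
        }
        ref_fids = _fiducial_arrays(ref, c)
        pred_fids = _fiducial_arrays(preds[c], c)
        for name in ref_fids:
            entry["fiducials"][name] = evaluate_fiducials(
                ref_fids[name], pred_fids[name]
            ).as_dict()
            ba = bland_altman(ref_fids[name], pred_fids[name])
            entry["bland_altman"][name] = {
                "bias_mmHg": ba.bias, "loa_lower_mmHg": ba.loa_lower,
                "loa_upper_mmHg": ba.loa_upper, "n": ba.n,
            }
        result["channels"][c] = entry
    return result


def run_ablation_study(
    config: dict | None = None,
    connection_sequence: tuple[str, ...] | None = None,
    profile: str = "cardio",
    epochs: int = 5,
    seed: int = 1,
) -> dict:
    """Train the full model and each cumulative skip ablation under identical
    data, fold assignment and seeds; emit per-epoch train/test MAE curves.

    The default connection sequences remove the deepest merge first, then
    shallower ones, finishing (cardiovascular model) with the input merge.
    """
    if config is None:
        cfg = default_config(profile)
        if profile == "cardio":
            # the 4-level geometry exposes all five removable merges
            cfg["model"].update({"levels": 4, "skip_connections": None})
    else:
        cfg = dict(config)
    cfg["seed"] = seed
    cfg["train"] = {**cfg["train"], "epochs": epochs}
    if connection_sequence is None:
        connection_sequence = (
            CARDIO_ABLATION_SEQUENCE if cfg["profile"] == "cardio" else CEREBRAL_ABLATION_SEQUENCE
        )

    records, params, kept, _ = build_windows(cfg)
    by_id = {w.window_id: w for w in kept}
    pool_ids, test_ids = split_test(by_id, cfg["cv"]["test_fraction"], seed)
    plan = make_folds(pool_ids, cfg["cv"].get("k", 5), seed, test_ids=test_ids)
    fold = plan.folds[0]  # identical fold for every variant
    scalers = fit_scalers([by_id[i] for i in pool_ids])
    target_channels = sorted(kept[0].targets)
    test = [by_id[i] for i in test_ids]
    Xe, ye = windows_to_arrays(test, scalers, target_channels)

    base_estimator = estimator_from_config(cfg)
    full_config = base_estimator.model_config()
    variants: list[tuple[str, tuple[str, ...]]] = [("full", ())]
    for i in range(1, len(connection_sequence) + 1):
        removed = tuple(connection_sequence[:i])
        variants.append(("-".join(("ablate",) + removed), removed))

    results: dict = {"profile": cfg["profile"], "epochs": epochs,
                     "fold": {"train": list(fold[0]), "val": list(fold[1]),
                              "test": list(test_ids)},
                     "variants": {}}
    for name, removed in variants:
        mc = ablate(full_config, removed) if removed else full_config
        from sklearn.base import clone

        est = clone(base_estimator)
        est.set_params(skip_connections=mc.skip_connections)
        est = train_fold(est, fold, kept, scalers, target_channels, eval_set=(Xe, ye))
        results["variants"][name] = {
            "removed_connections": list(removed),
            "skip_connections": list(mc.skip_connections),
            "train_mae": est.history_["train_loss"].tolist(),
            "test_mae": est.history_["eval_loss"].tolist(),
            "val_mae": est.history_["val_loss"].tolist(),
        }
    return results
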
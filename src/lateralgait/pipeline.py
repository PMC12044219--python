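"""End-to-end pipeline: simulate -> preprocess -> label -> featurize ->
train -> evaluate, with a manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_to_dict
from .evaluation import evaluation_report
from .features import assemble_samples, feature_columns
from .labeling import label_recording, labels_to_frame, phase_percentage
from .preprocess import synchronize, write_synced
from .simulate import PHASES, simulate_session, write_session
from .twin import TwinBrotherModel, save_model


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_feature_table(config: PipelineConfig):
    """Run the data half of the pipeline in memory; returns
    (features_df, synced, labels)."""
    raw = simulate_session(config.simulation)
    synced = synchronize(raw)
    labels = label_recording(
        synced.pressure, fs=synced.fs, k=config.labeling.threshold_k,
        debounce_ms=config.labeling.debounce_ms,
        on_double_off=config.labeling.on_double_off)
    df = assemble_samples(synced, labels, config.windowing)
    return df, synced, labels, raw


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, writing artifacts and a manifest to
    ``config.out_dir``; returns the evaluation report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    raw = stage("simulate", lambda: simulate_session(config.simulation))
    artifacts.extend(write_session(raw, out / "session").values())

    synced = stage("preprocess", lambda: synchronize(raw))
    artifacts.append(write_synced(synced, out / "synced.csv"))

    labels = stage("label", lambda: label_recording(
        synced.pressure, fs=synced.fs, k=config.labeling.threshold_k,
        debounce_ms=config.labeling.debounce_ms,
        on_double_off=config.labeling.on_double_off))
    lab_path = out / "labels.csv"
    labels_to_frame(labels).to_csv(lab_path, index=False)
    artifacts.append(lab_path)

    df = stage("featurize",
               lambda: assemble_samples(synced, labels, config.windowing))
    feat_path = out / "features.csv"
    df.to_csv(feat_path, index=False)
    artifacts.append(feat_path)

    report = stage("train_evaluate", lambda: _train_and_evaluate(config, df,
                                                                 out))
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    artifacts.append(report_path)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "split_mode": config.evaluation.split,
        "config": config_to_dict(config),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def _fit_eval_once(config: PipelineConfig, train_df, test_df, out: Path | None):
    model = TwinBrotherModel.from_dataframe(
        train_df, elder_config=config.elder, younger_config=config.younger)
    res = model.fit()
    feats = test_df[feature_columns()].to_numpy()
    probs, labels, angles = res.predict(feats)
    true = np.array([PHASES.index(p) for p in test_df["phase"]])
    regression = {name.replace("_deg", ""): (test_df[name].to_numpy(), pred)
                  for name, pred in angles.items()}
    if out is not None:
        save_model(res.fitted, out / "model.npz")
    return evaluation_report(true, labels, score_matrix=probs,
                             regression=regression)


def _train_and_evaluate(config: PipelineConfig, df: pd.DataFrame,
                        out: Path | None = None) -> dict:
    ev = config.evaluation
    if ev.split == "holdout":
        n_test = max(1, int(round(ev.test_fraction * len(df))))
        report = _fit_eval_once(config, df.iloc[:-n_test], df.iloc[-n_test:],
                                out)
        report["split"] = {"mode": "holdout", "test_fraction": ev.test_fraction}
        return report
    # k-fold over windows
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(df))
    folds = np.array_split(idx, ev.n_folds)
    accs, reports = [], []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(idx, test_idx)
        rep = _fit_eval_once(config, df.iloc[train_idx], df.iloc[test_idx],
                             out if i == 0 else None)
        accs.append(rep["accuracy"])
        reports.append(rep)
    agg = reports[0]
    agg["accuracy_folds"] = accs
    agg["accuracy_mean"] = float(np.mean(accs))
    agg["accuracy_sd"] = float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0
    agg["split"] = {"mode": "kfold", "n_folds": ev.n_folds}
    return agg
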
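"""Metrics and experiment harnesses.

Implements the evaluation surface of the pipeline: multiclass confusion
matrix with one-vs-rest per-phase counts, recall / false-positive rate /
F1, one-vs-rest ROC-AUC via the rank (Mann-Whitney) statistic, RMSE and
R-squared for the angle regressions, paired t-tests for model comparison,
and the experiment harnesses (window-geometry sweep, advance prediction,
contiguous-fraction test sets, streaming evaluation).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import PHASES


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows = true phase, columns = predicted phase."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def class_counts(self, c: int) -> dict:
        """One-vs-rest Tp/Fp/Tn/Fn for class ``c``."""
        tp = self.counts[c, c]
        fn = self.counts[c].sum() - tp
        fp = self.counts[:, c].sum() - tp
        tn = self.total - tp - fn - fp
        return {"tp": int(tp), "fp": int(fp), "tn": int(tn), "fn": int(fn)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(PHASES),
                            columns=list(PHASES))


def confusion_and_scores(true_labels, predicted_labels,
                         n_classes: int = 4) -> tuple[ConfusionMatrix, float]:
    t = np.asarray(true_labels, int)
    p = np.asarray(predicted_labels, int)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t, p), 1)
    cm = ConfusionMatrix(counts)
    return cm, cm.accuracy


def recall_fpr_f1(class_counts: dict) -> tuple[float, float, float]:
    """Recall = Tp/(Tp+Fn); Fpr = Fp/(Fp+Tn); F1 = 2Tp/(2Tp+Fp+Fn).

    Zero denominators yield 0 (with a warning) so sweeps never abort.
    """
    import warnings

    tp, fp, tn, fn = (class_counts[k] for k in ("tp", "fp", "tn", "fn"))

    def safe(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0")
            return 0.0
        return num / den

    return (safe(tp, tp + fn, "recall"),
            safe(fp, fp + tn, "fpr"),
            safe(2 * tp, 2 * tp + fp + fn, "f1"))


def roc_auc_ovr(true_labels, score_matrix, n_classes: int = 4) -> dict:
    """One-vs-rest AUC per phase via the rank statistic (ties averaged).

    Returns ``{class_index: auc-or-None}``; a class absent from the truth
    has no defined AUC and is reported as ``None``.
    """
    t = np.asarray(true_labels, int)
    s = np.asarray(score_matrix, float)
    out = {}
    for c in range(n_classes):
        pos = t == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[c] = None
            continue
        ranks = stats.rankdata(s[:, c])
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
        out[c] = float(u / (n_pos * n_neg))
    return out


def roc_curve_ovr(true_labels, scores_c, class_index: int):
    """(fpr, tpr) points for one class, thresholds swept over the scores."""
    t = (np.asarray(true_labels, int) == class_index).astype(int)
    s = np.asarray(scores_c, float)
    order = np.argsort(-s, kind="mergesort")
    t = t[order]
    tps = np.cumsum(t)
    fps = np.cumsum(1 - t)
    # keep the last point of each distinct score
    distinct = np.r_[np.diff(s[order]) != 0, True]
    tps, fps = tps[distinct], fps[distinct]
    tpr = np.r_[0.0, tps / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps / max(fps[-1], 1)]
    return fpr, tpr


def rmse(measured, predicted) -> float:
    """sqrt(sum((theta_M - theta_P)^2) / M)."""
    m = np.asarray(measured, float)
    p = np.asarray(predicted, float)
    if m.size == 0:
        raise ValueError("empty input")
    if m.shape != p.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((m - p) ** 2)))


def r_squared(measured, predicted) -> float:
    """1 - SS_res / SS_tot on the 0-1 scale; negative for bad predictors."""
    m = np.asarray(measured, float)
    p = np.asarray(predicted, float)
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for a constant measured vector")
    return 1.0 - float(np.sum((m - p) ** 2)) / ss_tot


def paired_t_test(scores_a, scores_b) -> tuple[float, int, float]:
    """Classical paired t statistic, df = n-1, two-sided p."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need equal-length score vectors of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), len(a) - 1, float(res.pvalue)


# ---------------------------------------------------------------------------
# experiment harnesses

def advance_shift(features: np.ndarray, labels: np.ndarray,
                  k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pair window i's features with window i+k's label (forecasting).

    The last ``k`` windows are dropped; ``k=0`` is the identity.
    """
    X = np.asarray(features)
    y = np.asarray(labels)
    if k < 0 or k >= len(X):
        raise ValueError(f"shift k={k} outside [0, n_windows)")
    if k == 0:
        return X, y
    return X[:-k], y[k:]


def contiguous_fraction(samples: np.ndarray, fraction: float,
                        offset: int = 0) -> np.ndarray:
    """A contiguous block of round(fraction * n) rows starting at offset."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    x = np.asarray(samples)
    n = len(x)
    m = int(round(fraction * n))
    if offset < 0 or offset + m > n:
        raise ValueError("block extends past the end of the data")
    return x[offset:offset + m]


def evaluation_report(true_phase, pred_phase, score_matrix=None,
                      regression: dict | None = None) -> dict:
    """Assemble the full metric report for one evaluated model."""
    cm, acc = confusion_and_scores(true_phase, pred_phase)
    per_phase = {}
    for c, name in enumerate(PHASES):
        rec, fpr, f1 = recall_fpr_f1(cm.class_counts(c))
        per_phase[name] = {"recall": rec, "fpr": fpr, "f1": f1}
    report = {
        "accuracy": acc,
        "confusion": cm.counts.tolist(),
        "per_phase": per_phase,
        "macro_recall": float(np.mean([v["recall"]
                                       for v in per_phase.values()])),
        "macro_f1": float(np.mean([v["f1"] for v in per_phase.values()])),
    }
    if score_matrix is not None:
        aucs = roc_auc_ovr(true_phase, score_matrix)
        report["auc"] = {PHASES[c]: aucs[c] for c in aucs}
        defined = [a for a in aucs.values() if a is not None]
        report["macro_auc"] = float(np.mean(defined)) if defined else None
    if regression:
        for name, (meas, pred) in regression.items():
            report[f"rmse_{name}"] = rmse(meas, pred)
            report[f"r2_{name}"] = r_squared(meas, pred)
    return report


def sweep_windows(synced, labels, lengths_ms, increments_ms,
                  train_fn, eval_fraction: float = 0.3,
                  seed: int = 0) -> pd.DataFrame:
    """Re-featurize and re-train per (length, increment) cell.

    ``train_fn(features_df, spec, seed) -> (predict(features) -> labels)``
    abstracts the model so the sweep can drive the twin model or a
    baseline.  Cell failures are recorded and the sweep continues.
    """
    from .features import WindowSpec, assemble_samples, feature_columns

    rows = []
    for L in lengths_ms:
        for S in increments_ms:
            cell = {"length_ms": L, "increment_ms": S}
            try:
                spec = WindowSpec(length_ms=L, increment_ms=S, fs=synced.fs)
                df = assemble_samples(synced, labels, spec)
                n = len(df)
                n_test = max(1, int(round(eval_fraction * n)))
                train_df, test_df = df.iloc[:-n_test], df.iloc[-n_test:]
                predict = train_fn(train_df, spec, seed)
                pred = predict(test_df[feature_columns()].to_numpy())
                true = np.array([PHASES.index(p) for p in test_df["phase"]])
                cell["n_windows"] = n
                cell["accuracy"] = confusion_and_scores(true, pred)[1]
            except Exception as exc:  # record, keep sweeping
                cell["error"] = str(exc)
            rows.append(cell)
    return pd.DataFrame(rows)


def streaming_evaluate(predict_fn, synced, spec) -> pd.DataFrame:
    """Simulate increment-by-increment arrival of the synced stream.

    For each sliding window in arrival order, calls ``predict_fn`` on that
    window's samples and records the prediction and the wall-clock latency.
    Latency is reported, never asserted against: it is hardware-dependent.
    """
    from .features import slide_windows

    pairs = slide_windows(len(synced.emg), spec)
    rows = []
    for start, end in pairs:
        t0 = time.perf_counter()
        out = predict_fn(synced.emg[start:end])
        latency = time.perf_counter() - t0
        row = {"window_end_s": (end - 1) / synced.fs,
               "latency_s": latency}
        if isinstance(out, dict):
            row.update(out)
        else:
            row["prediction"] = out
        rows.append(row)
    return pd.DataFrame(rows)
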
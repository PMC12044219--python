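"""Sliding-window time-domain feature extraction.

Each 250 ms window of the six filtered EMG channels yields eight
time-domain features per channel — maximum, variance, mean absolute value,
mean, minimum, root mean square, zero-crossing count, and standard
deviation — assembled with the window-end phase label and the two hip
angles into the 51-column sample

    x = [f1 ... f48, P, theta_left, theta_right].

Note on naming: the feature list is sometimes quoted as "mean absolute
error"; with no reference signal to take an error against, it is
implemented as the mean absolute value (MAV), the standard EMG amplitude
feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .labeling import PhaseLabels
from .preprocess import SyncedRecording
from .simulate import PHASES

#: Fixed feature order within each channel block.
FEATURE_NAMES = ("max", "var", "mav", "mean", "min", "rms", "zc", "sd")


def feature_columns(n_channels: int = 6) -> list[str]:
    return [f"ch{c+1}_{f}" for c in range(n_channels) for f in FEATURE_NAMES]


@dataclass
class WindowSpec:
    """Sliding-window geometry on the synced 1000 Hz timeline."""

    length_ms: float = 250.0
    increment_ms: float = 3.0
    fs: float = 1000.0
    label_policy: str = "window_end"  # {"window_end", "majority"}
    ddof: int = 1                     # sample (n-1) variance/SD
    zc_hysteresis: float = 0.0

    def __post_init__(self) -> None:
        if not self.length_ms > self.increment_ms > 0:
            raise ValueError("require length_ms > increment_ms > 0")
        for ms, name in ((self.length_ms, "length"),
                         (self.increment_ms, "increment")):
            if abs(ms * self.fs / 1000.0 - round(ms * self.fs / 1000.0)) > 1e-9:
                raise ValueError(f"window {name} is not a whole number of "
                                 f"samples at fs={self.fs}")
        if self.label_policy not in ("window_end", "majority"):
            raise ValueError(f"unknown label policy {self.label_policy!r}")

    @property
    def length(self) -> int:
        return int(round(self.length_ms * self.fs / 1000.0))

    @property
    def increment(self) -> int:
        return int(round(self.increment_ms * self.fs / 1000.0))


def slide_windows(n_samples: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open [start, start+L) index pairs; count = floor((n-L)/S) + 1."""
    L, S = spec.length, spec.increment
    if n_samples < L:
        raise ValueError(f"signal of {n_samples} samples shorter than one "
                         f"{L}-sample window")
    starts = np.arange(0, n_samples - L + 1, S)
    return [(int(s), int(s + L)) for s in starts]


def zero_crossings(x: np.ndarray, hysteresis: float = 0.0) -> int:
    """Count of strict sign changes between consecutive samples.

    With a positive ``hysteresis`` both samples must clear the amplitude
    band ``|x| > hysteresis`` for the crossing to count, suppressing
    noise-floor chatter.
    """
    x = np.asarray(x, float)
    prod = x[:-1] * x[1:]
    ok = prod < 0
    if hysteresis > 0:
        ok &= (np.abs(x[:-1]) > hysteresis) & (np.abs(x[1:]) > hysteresis)
    return int(np.count_nonzero(ok))


def td_features(window: np.ndarray, ddof: int = 1,
                zc_hysteresis: float = 0.0) -> np.ndarray:
    """The eight time-domain features of one single-channel window."""
    w = np.asarray(window, float)
    if w.size == 0:
        raise ValueError("empty window")
    return np.array([
        w.max(),
        w.var(ddof=ddof) if w.size > ddof else 0.0,
        np.abs(w).mean(),
        w.mean(),
        w.min(),
        np.sqrt(np.mean(w ** 2)),
        zero_crossings(w, zc_hysteresis),
        w.std(ddof=ddof) if w.size > ddof else 0.0,
    ])


def _windowed_features(channel: np.ndarray, starts: np.ndarray,
                       spec: WindowSpec) -> np.ndarray:
    """(n_windows, 8) features for one channel, vectorized over windows."""
    L = spec.length
    views = sliding_window_view(channel, L)[starts]  # (n_win, L), no copy
    mx = views.max(axis=1)
    mn = views.min(axis=1)
    mean = views.mean(axis=1)
    var = views.var(axis=1, ddof=spec.ddof)
    mav = np.abs(views).mean(axis=1)
    rms = np.sqrt(np.mean(views ** 2, axis=1))
    prod = views[:, :-1] * views[:, 1:]
    ok = prod < 0
    if spec.zc_hysteresis > 0:
        ok &= ((np.abs(views[:, :-1]) > spec.zc_hysteresis)
               & (np.abs(views[:, 1:]) > spec.zc_hysteresis))
    zc = np.count_nonzero(ok, axis=1).astype(float)
    sd = np.sqrt(var)
    return np.column_stack([mx, var, mav, mean, mn, rms, zc, sd])


def assemble_samples(synced: SyncedRecording, labels: PhaseLabels,
                     spec: WindowSpec | None = None) -> pd.DataFrame:
    """One row per window: 48 features, phase, two hip angles, end time.

    The phase label and the angles are taken at the window's final sample
    (the real-time system predicts the present from the trailing window);
    ``label_policy="majority"`` takes the most frequent label instead.
    """
    spec = spec or WindowSpec(fs=synced.fs)
    n = len(synced.emg)
    if len(labels.codes) != n:
        raise ValueError("labels and synced streams differ in length")
    pairs = slide_windows(n, spec)
    starts = np.array([p[0] for p in pairs])
    ends = starts + spec.length - 1  # inclusive final sample
    feats = np.hstack([
        _windowed_features(synced.emg[:, c], starts, spec) for c in range(6)
    ])
    if spec.label_policy == "window_end":
        phase = labels.codes[ends]
    else:
        views = sliding_window_view(labels.codes, spec.length)[starts]
        phase = np.array([np.bincount(v, minlength=4).argmax() for v in views])
    df = pd.DataFrame(feats, columns=feature_columns())
    df["phase"] = np.array(PHASES)[phase]
    df["theta_left_deg"] = synced.hip_angles[ends, 0]
    df["theta_right_deg"] = synced.hip_angles[ends, 1]
    df["window_end_s"] = ends / synced.fs
    return df


class FeatureScaler:
    """Per-feature z-scoring with training-set statistics.

    Raw time-domain features differ by orders of magnitude (a variance vs. a
    zero-crossing count), so models train on z-scored features; the fitted
    statistics travel with the model for inference.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant features pass through centred
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        return (np.asarray(X, float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
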
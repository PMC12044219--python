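"""EMG denoising and multi-rate synchronization.

EMG is band-pass filtered (Butterworth, 20-400 Hz) and notch filtered at
50 Hz; the 200 Hz hip-angle and plantar-pressure streams are brought onto
the 1000 Hz EMG clock by linear interpolation.  Hip angles arrive already
smoothed by the inertial sensor's internal Kalman filter, so no additional
angle filter is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, iirnotch, sosfilt, sosfiltfilt, tf2sos

from .simulate import MUSCLES, PRESSURE_CHANNELS, RawRecording


@dataclass
class FilterSpec:
    """Filter design parameters shared by the band-pass and notch stages."""

    kind: str = "bandpass"          # {"bandpass", "notch"}
    band: tuple = (20.0, 400.0)     # Hz interval, or (f0,) for the notch
    order: int = 4
    zero_phase: bool = True
    notch_q: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "notch"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass
class SyncedRecording:
    """All streams on one shared time axis at a single sampling rate."""

    emg: np.ndarray           # (n, 6) filtered
    pressure: np.ndarray      # (n, 4) upsampled
    hip_angles: np.ndarray    # (n, 2) upsampled
    fs: float

    def __post_init__(self) -> None:
        n = len(self.emg)
        if len(self.pressure) != n or len(self.hip_angles) != n:
            raise ValueError("synced streams must have equal length")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.emg)) / self.fs


def _apply_sos(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    return sosfiltfilt(sos, x) if zero_phase else sosfilt(sos, x)


def bandpass_filter(signal: np.ndarray, fs: float, low: float, high: float,
                    spec: FilterSpec | None = None) -> np.ndarray:
    """Butterworth band-pass, zero-phase by default (forward-backward)."""
    spec = spec or FilterSpec()
    if not 0.0 < low < high < fs / 2.0:
        raise ValueError(f"band ({low}, {high}) Hz outside (0, fs/2)")
    signal = np.asarray(signal, float)
    if signal.shape[0] <= 3 * spec.order:
        raise ValueError("signal too short for the requested filter order")
    sos = butter(spec.order, [low, high], btype="band", fs=fs, output="sos")
    return _apply_sos(sos, signal, spec.zero_phase)


def notch_filter(signal: np.ndarray, fs: float, f0: float = 50.0,
                 spec: FilterSpec | None = None) -> np.ndarray:
    """Narrow IIR notch at ``f0`` (power-line frequency)."""
    spec = spec or FilterSpec(kind="notch", band=(50.0,))
    if f0 >= fs / 2.0 or f0 <= 0:
        raise ValueError(f"notch frequency {f0} Hz outside (0, fs/2)")
    b, a = iirnotch(f0, spec.notch_q, fs=fs)
    return _apply_sos(tf2sos(b, a), np.asarray(signal, float), spec.zero_phase)


def resample_stream(signal: np.ndarray, fs_in: float,
                    fs_out: float) -> np.ndarray:
    """Linear interpolation onto a uniform ``fs_out`` grid sharing t=0.

    Output length is ``round(n * fs_out / fs_in)``; samples beyond the last
    input time hold the final value.  Works on 1-D or (n, k) arrays.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    signal = np.asarray(signal, float)
    n = signal.shape[0]
    if fs_in == fs_out:
        return signal.copy()
    m = int(round(n * fs_out / fs_in))
    t_in = np.arange(n) / fs_in
    t_out = np.arange(m) / fs_out
    if signal.ndim == 1:
        return np.interp(t_out, t_in, signal)
    return np.column_stack([np.interp(t_out, t_in, signal[:, j])
                            for j in range(signal.shape[1])])


def synchronize(raw: RawRecording, spec: FilterSpec | None = None,
                notch_hz: float = 50.0) -> SyncedRecording:
    """Filter EMG and upsample angles/pressure to the EMG clock.

    All streams are trimmed to their common overlapping span (one-sample
    tail mismatches are tolerated).
    """
    if len(raw.emg) == 0 or len(raw.pressure) == 0 or len(raw.hip_angles) == 0:
        raise ValueError("empty stream in recording")
    spec = spec or FilterSpec()
    emg = np.column_stack([
        notch_filter(
            bandpass_filter(raw.emg[:, c], raw.emg_rate, *spec.band, spec),
            raw.emg_rate, notch_hz, FilterSpec(kind="notch",
                                               zero_phase=spec.zero_phase))
        for c in range(raw.emg.shape[1])
    ])
    pressure = resample_stream(raw.pressure, raw.kin_rate, raw.emg_rate)
    angles = resample_stream(raw.hip_angles, raw.kin_rate, raw.emg_rate)
    n = min(len(emg), len(pressure), len(angles))
    return SyncedRecording(emg=emg[:n], pressure=pressure[:n],
                           hip_angles=angles[:n], fs=raw.emg_rate)


# ---------------------------------------------------------------------------
# CSV interface

SYNCED_COLUMNS = (["time_s"] + [f"emg{i+1}" for i in range(6)]
                  + [f"p{i+1}" for i in range(4)]
                  + ["theta_left_deg", "theta_right_deg"])


def write_synced(rec: SyncedRecording, path: str | Path) -> Path:
    df = pd.DataFrame(
        np.column_stack([rec.time_s, rec.emg, rec.pressure, rec.hip_angles]),
        columns=SYNCED_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_synced(path: str | Path) -> SyncedRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = float(round(1.0 / np.median(np.diff(t))))
    return SyncedRecording(
        emg=df[[f"emg{i+1}" for i in range(6)]].to_numpy(),
        pressure=df[[f"p{i+1}" for i in range(4)]].to_numpy(),
        hip_angles=df[["theta_left_deg", "theta_right_deg"]].to_numpy(),
        fs=fs,
    )


def synchronize_files(in_dir: str | Path, out_path: str | Path,
                      zero_phase: bool = True) -> Path:
    """File-level wrapper: read a simulated session directory, write one
    synced CSV."""
    from .simulate import read_session

    raw = read_session(in_dir)
    spec = FilterSpec(zero_phase=zero_phase)
    return write_synced(synchronize(raw, spec), out_path)
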
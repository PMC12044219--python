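"""Contact-based gait-phase labeling from plantar pressure.

Each foot carries two force sensors (first metatarsal and heel).  A foot is
in the touch state "O" when either sensor exceeds its contact threshold,
else in the off state "F".  The four lateral-walking phases follow the
state table

    ==========  ====  ====  ====  ====
    foot        NDS   GFS   WDS   FLS
    ==========  ====  ====  ====  ====
    left        O     O     O     F
    right       O     F     O     O
    ==========  ====  ====  ====  ====

NDS and WDS share the double-support state (O, O) and are disambiguated by
cycle order: double support after a follow-leg swing (or at session start)
is narrow (NDS), after a guided-foot swing it is wide (WDS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PHASES


@dataclass
class ContactThresholds:
    """Per-channel contact threshold in raw pressure units."""

    values: np.ndarray  # shape (4,)


@dataclass
class PhaseLabels:
    """Per-sample phase codes plus derived cycle index."""

    codes: np.ndarray        # (n,) ints in 0..3
    cycle_index: np.ndarray  # (n,) ints, increments on each NDS entry
    fs: float

    def names(self) -> np.ndarray:
        return np.array(PHASES)[self.codes]


def compute_contact_threshold(pressure_channel: np.ndarray, k: float = 0.2,
                              baseline_pct: float = 5.0,
                              max_pct: float = 95.0) -> float:
    """Threshold = baseline + k * (max - baseline), with robust percentiles.

    Baseline and maximum default to the 5th and 95th percentile so isolated
    spikes do not move the threshold.
    """
    x = np.asarray(pressure_channel, float)
    lo = np.percentile(x, baseline_pct)
    hi = np.percentile(x, max_pct)
    if hi <= lo:
        raise ValueError("degenerate pressure channel: no dynamic range")
    return float(lo + k * (hi - lo))


def _debounce(states: np.ndarray, min_samples: int) -> np.ndarray:
    """Merge runs shorter than ``min_samples`` into the preceding state."""
    if min_samples <= 1:
        return states
    out = states.copy()
    n = len(out)
    i = 0
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if j - i < min_samples and i > 0:
            out[i:j] = out[i - 1]
        i = j
    return out


def contact_states(pressure: np.ndarray,
                   thresholds: ContactThresholds | np.ndarray,
                   fs: float = 1000.0,
                   debounce_ms: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-foot boolean contact series (True = touch state "O").

    ``pressure`` columns are (l_toe, l_heel, r_toe, r_heel); a foot is in
    contact when either of its sensors exceeds its threshold.  Contact runs
    shorter than the debounce window are treated as threshold chatter and
    absorbed into the surrounding state.
    """
    thr = thresholds.values if isinstance(thresholds, ContactThresholds) \
        else np.asarray(thresholds, float)
    above = np.asarray(pressure, float) > thr[None, :]
    left = above[:, 0] | above[:, 1]
    right = above[:, 2] | above[:, 3]
    min_samples = int(round(debounce_ms * fs / 1000.0))
    return _debounce(left, min_samples), _debounce(right, min_samples)


def label_phases(left: np.ndarray, right: np.ndarray, fs: float = 1000.0,
                 on_double_off: str = "impute") -> PhaseLabels:
    """Map per-foot contact series to phase codes with cycle-order memory.

    (L=O, R=F) -> GFS; (L=F, R=O) -> FLS; double support resolves to NDS or
    WDS from the last swing phase seen (session assumed to start narrow).
    Simultaneous double-off is not a valid lateral-walking state; it is
    imputed by carrying the previous phase forward (``on_double_off="impute"``,
    default) or raised (``"error"``).
    """
    left = np.asarray(left, bool)
    right = np.asarray(right, bool)
    if left.shape != right.shape:
        raise ValueError("left/right series must be aligned and equal length")
    n = len(left)
    codes = np.empty(n, dtype=int)
    cycle = np.empty(n, dtype=int)
    last_swing = 3  # "after FLS": sessions begin in narrow double support
    cur_cycle = 0
    prev_code = None
    for i in range(n):
        lo, ro = left[i], right[i]
        if lo and not ro:
            code = 1  # GFS
            last_swing = 1
        elif ro and not lo:
            code = 3  # FLS
            last_swing = 3
        elif lo and ro:
            code = 0 if last_swing == 3 else 2  # NDS after FLS, WDS after GFS
        else:
            if on_double_off == "error":
                raise ValueError(f"double-off contact state at sample {i}")
            code = prev_code if prev_code is not None else 0
        if code == 0 and prev_code not in (0, None):
            cur_cycle += 1
        codes[i] = code
        cycle[i] = cur_cycle
        prev_code = code
    return PhaseLabels(codes=codes, cycle_index=cycle, fs=fs)


def label_recording(pressure: np.ndarray, fs: float = 1000.0, k: float = 0.2,
                    debounce_ms: float = 20.0,
                    on_double_off: str = "impute") -> PhaseLabels:
    """Threshold + contact states + state table in one call."""
    thr = ContactThresholds(np.array([
        compute_contact_threshold(pressure[:, c], k=k) for c in range(4)
    ]))
    left, right = contact_states(pressure, thr, fs=fs,
                                 debounce_ms=debounce_ms)
    return label_phases(left, right, fs=fs, on_double_off=on_double_off)


def phase_percentage(labels: PhaseLabels, per_cycle: bool = False) -> np.ndarray:
    """Within-run progress mapped linearly to [0, 100].

    Each maximal run of one phase rises from 0 at its first sample to 100 at
    its last (a single-sample run is 0).  With ``per_cycle=True`` the ramp
    spans a whole gait cycle instead of one phase.
    """
    key = labels.cycle_index if per_cycle else labels.codes
    n = len(key)
    pct = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and key[j] == key[i]:
            j += 1
        if j - i > 1:
            pct[i:j] = np.linspace(0.0, 100.0, j - i)
        i = j
    return pct


def labels_to_frame(labels: PhaseLabels) -> pd.DataFrame:
    return pd.DataFrame({
        "time_s": np.arange(len(labels.codes)) / labels.fs,
        "phase_code": labels.codes,
        "phase": labels.names(),
        "phase_pct": phase_percentage(labels),
        "cycle_index": labels.cycle_index,
    })
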
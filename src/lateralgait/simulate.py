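"""Synthetic lateral-walking sessions: EMG, hip angles, and plantar pressure.

The generator emulates the statistical structure of a lateral-walking
recording: a four-phase gait cycle (narrow double support NDS, guided foot
swing GFS, wide double support WDS, follow leg swing FLS), phase-locked EMG
bursts on the hip abductor group of each leg, smooth hip-angle trajectories,
and quasi-binary heel/toe pressure traces that drive contact-based phase
labeling.  All randomness flows from a single integer seed, so a session is
a pure function of its configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

#: Cyclic phase order.  Integer codes used throughout the package.
PHASES = ("NDS", "GFS", "WDS", "FLS")
PHASE_TO_CODE = {p: i for i, p in enumerate(PHASES)}

#: Channel order: leading (right) leg first, then following (left) leg.
MUSCLES = (
    "r_gluteus_medius",
    "r_tensor_fascia_lata",
    "r_gluteus_maximus",
    "l_gluteus_medius",
    "l_tensor_fascia_lata",
    "l_gluteus_maximus",
)

PRESSURE_CHANNELS = ("l_toe", "l_heel", "r_toe", "r_heel")


def _default_activation() -> np.ndarray:
    """Per-muscle envelope amplitude for each phase (columns NDS,GFS,WDS,FLS).

    Leading-leg muscles burst during GFS, following-leg muscles during FLS.
    Both double-support phases carry weak tonic activity; the wide stance
    (WDS) demands more abductor effort than the narrow one, which is what
    makes the two statically similar phases separable from EMG at all.
    """
    tonic_nds, tonic_wds, off = 0.025, 0.060, 0.040
    peaks = (0.55, 0.45, 0.50)
    rows = []
    for p in peaks:  # right leg: active in GFS
        rows.append([tonic_nds, p, tonic_wds, off])
    for p in peaks:  # left leg: active in FLS
        rows.append([tonic_nds, off, tonic_wds, p])
    return np.array(rows)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic walking session.

    Defaults follow the recording protocol the pipeline targets: ~1.46 s per
    lateral step, 6 EMG channels at 1000 Hz, hip angles and 4 plantar
    pressure channels at 200 Hz.
    """

    n_steps: int = 30
    cycle_duration: float = 1.46
    phase_fractions: tuple = (0.28, 0.22, 0.28, 0.22)
    emg_rate: float = 1000.0
    kin_rate: float = 200.0
    activation_matrix: np.ndarray = field(default_factory=_default_activation)
    noise_sd: float = 0.05
    angle_amplitude: float = 25.0
    seed: int = 0
    # burst shaping: raised-cosine bump centre (fraction of the active swing
    # phase) per muscle, so that the three muscles of a leg peak early / mid /
    # late and within-phase progress is encoded in the feature vector.
    burst_centers: tuple = (0.3, 0.5, 0.7, 0.3, 0.5, 0.7)
    burst_width: float = 0.55
    envelope_smooth_ms: float = 25.0
    # timing variability: each phase duration is multiplied by
    # LogNormal(0, jitter_sigma).
    jitter_sigma: float = 0.05
    pressure_high: float = 1.0
    pressure_low: float = 0.02
    pressure_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.activation_matrix = np.asarray(self.activation_matrix, float)
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.emg_rate <= 0 or self.kin_rate <= 0:
            raise ValueError("sampling rates must be positive")
        fr = np.asarray(self.phase_fractions, float)
        if fr.shape != (4,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(
                "phase_fractions must be 4 nonnegative values summing to 1"
            )
        if self.activation_matrix.shape != (6, 4):
            raise ValueError("activation_matrix must be 6 muscles x 4 phases")
        if np.any(self.activation_matrix < 0):
            raise ValueError("activation_matrix must be nonnegative")
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be positive")


@dataclass
class PhaseSchedule:
    """Ordered, contiguous (phase_code, start_s, end_s) intervals."""

    intervals: list  # list of (code:int, start:float, end:float)

    @property
    def duration(self) -> float:
        return self.intervals[-1][2]

    def phase_at(self, t: np.ndarray) -> np.ndarray:
        """Phase code of each time point (end-exclusive intervals)."""
        t = np.asarray(t, float)
        starts = np.array([iv[1] for iv in self.intervals])
        codes = np.array([iv[0] for iv in self.intervals])
        idx = np.searchsorted(starts, t, side="right") - 1
        idx = np.clip(idx, 0, len(codes) - 1)
        return codes[idx]

    def progress_at(self, t: np.ndarray) -> np.ndarray:
        """Within-interval progress in [0, 1) for each time point."""
        t = np.asarray(t, float)
        starts = np.array([iv[1] for iv in self.intervals])
        ends = np.array([iv[2] for iv in self.intervals])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0,
                      len(starts) - 1)
        return np.clip((t - starts[idx]) / (ends[idx] - starts[idx]), 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(PHASES[c], s, e) for c, s, e in self.intervals],
            columns=["phase", "start_s", "end_s"],
        )


@dataclass
class RawRecording:
    """The three unsynchronized sensor streams of one walking session."""

    emg: np.ndarray          # (n_emg, 6) at emg_rate
    hip_angles: np.ndarray   # (n_kin, 2) degrees: theta_left, theta_right
    pressure: np.ndarray     # (n_kin, 4): l_toe, l_heel, r_toe, r_heel
    emg_rate: float
    kin_rate: float
    schedule: PhaseSchedule  # ground truth, for testing only


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_phase_schedule(config: SimulationConfig) -> PhaseSchedule:
    """Partition ``n_steps`` cycles into NDS-GFS-WDS-FLS intervals.

    With ``jitter_sigma > 0`` each phase duration is multiplied by an
    independent LogNormal(0, sigma) factor drawn from the seeded RNG, so
    repeat calls with the same config give identical schedules.
    """
    rng = _rng(config, 0)
    base = np.asarray(config.phase_fractions) * config.cycle_duration
    intervals = []
    t = 0.0
    for _ in range(config.n_steps):
        durs = base.copy()
        if config.jitter_sigma > 0:
            durs = durs * rng.lognormal(0.0, config.jitter_sigma, size=4)
        for code in range(4):
            intervals.append((code, t, t + durs[code]))
            t += durs[code]
    return PhaseSchedule(intervals)


def _session_times(schedule: PhaseSchedule, rate: float) -> np.ndarray:
    n = int(round(schedule.duration * rate))
    return np.arange(n) / rate


def _burst_profile(progress: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine bump over within-phase progress, clipped to [0, 1]."""
    u = (progress - center) / width
    prof = 0.5 * (1.0 + np.cos(np.pi * u))
    prof[np.abs(u) >= 1.0] = 0.0
    return prof


def simulate_emg(schedule: PhaseSchedule, config: SimulationConfig) -> np.ndarray:
    """6-channel EMG: band-limited noise amplitude-modulated per phase.

    Channel ``m`` carries amplitude ``activation_matrix[m, phase]`` shaped,
    inside the muscle's burst (swing) phase, by a raised-cosine temporal
    profile, plus the ``noise_sd`` baseline.  The carrier is zero-mean
    Gaussian noise band-limited to 20-400 Hz so that most power survives the
    downstream band-pass.
    """
    if schedule.duration <= 0:
        raise ValueError("schedule must cover a positive duration")
    rng = _rng(config, 1)
    t = _session_times(schedule, config.emg_rate)
    phase = schedule.phase_at(t)
    progress = schedule.progress_at(t)
    n = len(t)
    out = np.empty((n, 6))
    # swing phase in which each muscle bursts: right leg -> GFS, left -> FLS
    burst_phase = np.array([1, 1, 1, 3, 3, 3])
    sos = butter(4, [20.0, min(400.0, 0.45 * config.emg_rate)],
                 btype="band", fs=config.emg_rate, output="sos")
    smooth_n = max(1, int(round(config.envelope_smooth_ms * config.emg_rate
                                / 1000.0)))
    kernel = np.hanning(smooth_n + 2)[1:-1]
    kernel = kernel / kernel.sum() if kernel.sum() > 0 else np.ones(1)
    for m in range(6):
        env = config.activation_matrix[m][phase].astype(float)
        mask = phase == burst_phase[m]
        if mask.any():
            prof = _burst_profile(progress[mask], config.burst_centers[m],
                                  config.burst_width)
            env[mask] = env[mask] * prof
        env = env + config.noise_sd
        if smooth_n > 1:
            env = np.convolve(env, kernel, mode="same")
        if np.all(env == 0):
            out[:, m] = 0.0
            continue
        carrier = rng.standard_normal(n)
        if n > 30:  # too-short signals are left broadband
            carrier = sosfiltfilt(sos, carrier)
            sd = carrier.std()
            if sd > 0:
                carrier = carrier / sd
        out[:, m] = env * carrier
    return out


def _leading_leg_angle(phase: np.ndarray, progress: np.ndarray,
                       amplitude: float) -> np.ndarray:
    """Right (leading) hip abduction: 0 in NDS, half-cosine up in GFS,
    hold in WDS, half-cosine down in FLS."""
    ramp_up = 0.5 * (1.0 - np.cos(np.pi * progress))
    angle = np.zeros_like(progress)
    angle[phase == 1] = amplitude * ramp_up[phase == 1]
    angle[phase == 2] = amplitude
    angle[phase == 3] = amplitude * (1.0 - ramp_up[phase == 3])
    return angle


def simulate_kinematics(schedule: PhaseSchedule,
                        config: SimulationConfig) -> np.ndarray:
    """(n, 2) hip-angle trajectories in degrees at ``kin_rate``.

    The leading (right) hip ramps during its swing (GFS) and unloads during
    the contralateral swing; the following (left) hip is the half-cycle
    shifted mirror, so it ramps during FLS.  Both are constant during the
    double-support phases.
    """
    t = _session_times(schedule, config.kin_rate)
    phase = schedule.phase_at(t)
    progress = schedule.progress_at(t)
    right = _leading_leg_angle(phase, progress, config.angle_amplitude)
    # left leg: amplitude in NDS, releases during GFS, re-abducts during FLS
    ramp_up = 0.5 * (1.0 - np.cos(np.pi * progress))
    left = np.full_like(progress, config.angle_amplitude)
    left[phase == 1] = config.angle_amplitude * (1.0 - ramp_up[phase == 1])
    left[phase == 2] = 0.0
    left[phase == 3] = config.angle_amplitude * ramp_up[phase == 3]
    return np.column_stack([left, right])


def simulate_pressure(schedule: PhaseSchedule,
                      config: SimulationConfig) -> np.ndarray:
    """(n, 4) plantar pressure: l_toe, l_heel, r_toe, r_heel at ``kin_rate``.

    The right-foot channels drop to baseline during GFS (leading leg
    airborne), the left-foot channels during FLS; all four are high during
    both double-support phases.  Transitions are sample-aligned with the
    schedule so contact-based relabeling can reproduce it exactly.
    """
    rng = _rng(config, 2)
    t = _session_times(schedule, config.kin_rate)
    phase = schedule.phase_at(t)
    n = len(t)
    high, low = config.pressure_high, config.pressure_low
    left_on = (phase != 3).astype(float)   # left foot off during FLS
    right_on = (phase != 1).astype(float)  # right foot off during GFS
    out = np.empty((n, 4))
    out[:, 0] = out[:, 1] = low + (high - low) * left_on
    out[:, 2] = out[:, 3] = low + (high - low) * right_on
    if config.pressure_noise_sd > 0:
        out = out + rng.normal(0.0, config.pressure_noise_sd, size=out.shape)
    return out


def simulate_session(config: SimulationConfig) -> RawRecording:
    """Compose the three generators on one shared phase schedule."""
    schedule = generate_phase_schedule(config)
    return RawRecording(
        emg=simulate_emg(schedule, config),
        hip_angles=simulate_kinematics(schedule, config),
        pressure=simulate_pressure(schedule, config),
        emg_rate=config.emg_rate,
        kin_rate=config.kin_rate,
        schedule=schedule,
    )


# ---------------------------------------------------------------------------
# CSV round trip

def write_session(rec: RawRecording, out_dir: str | Path) -> dict:
    """Write one session as emg.csv / kin.csv / pressure.csv / schedule.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_emg = np.arange(len(rec.emg)) / rec.emg_rate
    t_kin = np.arange(len(rec.pressure)) / rec.kin_rate
    paths = {}
    emg = pd.DataFrame(rec.emg, columns=list(MUSCLES))
    emg.insert(0, "time_s", t_emg)
    paths["emg"] = out / "emg.csv"
    emg.to_csv(paths["emg"], index=False)
    kin = pd.DataFrame(rec.hip_angles,
                       columns=["theta_left_deg", "theta_right_deg"])
    kin.insert(0, "time_s", t_kin)
    paths["kin"] = out / "kin.csv"
    kin.to_csv(paths["kin"], index=False)
    pres = pd.DataFrame(rec.pressure, columns=list(PRESSURE_CHANNELS))
    pres.insert(0, "time_s", t_kin)
    paths["pressure"] = out / "pressure.csv"
    pres.to_csv(paths["pressure"], index=False)
    paths["schedule"] = out / "schedule.csv"
    rec.schedule.to_frame().to_csv(paths["schedule"], index=False)
    return paths


def read_session(in_dir: str | Path) -> RawRecording:
    """Read a session written by :func:`write_session`."""
    d = Path(in_dir)
    emg = pd.read_csv(d / "emg.csv")
    kin = pd.read_csv(d / "kin.csv")
    pres = pd.read_csv(d / "pressure.csv")
    sched = pd.read_csv(d / "schedule.csv")
    emg_rate = _infer_rate(emg["time_s"].to_numpy())
    kin_rate = _infer_rate(kin["time_s"].to_numpy())
    intervals = [(PHASE_TO_CODE[row.phase], row.start_s, row.end_s)
                 for row in sched.itertuples()]
    return RawRecording(
        emg=emg[list(MUSCLES)].to_numpy(),
        hip_angles=kin[["theta_left_deg", "theta_right_deg"]].to_numpy(),
        pressure=pres[list(PRESSURE_CHANNELS)].to_numpy(),
        emg_rate=emg_rate,
        kin_rate=kin_rate,
        schedule=PhaseSchedule(intervals),
    )


def _infer_rate(time_s: np.ndarray) -> float:
    if len(time_s) < 2:
        raise ValueError("need at least two samples to infer a rate")
    return float(round(1.0 / np.median(np.diff(time_s))))
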
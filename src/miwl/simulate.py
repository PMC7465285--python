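"""Synthetic coupled EEG / vehicular driving-session generator.

Emulates the statistical structure a workload-fusion pipeline assumes: a
slowly varying latent mental-workload (MWL) trace driven by a road/traffic/
event schedule, 15-channel EEG whose frontal-theta power rises and
parietal-alpha power falls with workload, and 10 Hz vehicular telemetry
whose dependence on the latent trace is controlled by a single coupling
parameter.  Ground truth (the latent trace) is returned alongside the
recording so parameter-recovery tests can close the loop.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

EEG_SFREQ = 256
VEH_SFREQ = 10

#: The 15-channel montage (10-20 system) in canonical order.
CHANNELS = (
    "Fpz", "Fz", "Pz", "POz", "Oz",
    "AF3", "AF4", "F3", "F4",
    "P3", "P4", "P5", "P6", "O1", "O2",
)

FRONTAL_CHANNELS = ("Fpz", "Fz", "AF3", "AF4", "F3", "F4")
PARIETAL_CHANNELS = ("Pz", "POz", "Oz", "P3", "P4", "P5", "P6", "O1", "O2")

VEHICULAR_COLUMNS = (
    "velocity", "acceleration", "lateral_acceleration", "longitudinal_acceleration",
)

# Segment-level study conditions: group-mean workload and velocity per
# road-complexity segment, plus the traffic-hour and on-road-event increments
# applied to the latent trace.
MWL_BASELINE = {"Easy": 0.42, "Hard": 0.51}
RUSH_BOOST = 0.05
EVENT_BOOST = {"Car": 0.06, "Pedestrian": 0.14}  # mean 0.10
VELOCITY_BASELINE = {"Easy": 44.69, "Hard": 37.81}  # km/h

# Blink spatial topography: largest at Fpz, decaying toward posterior sites.
BLINK_TOPOGRAPHY = {
    "Fpz": 1.0, "AF3": 0.6, "AF4": 0.6, "Fz": 0.5, "F3": 0.35, "F4": 0.35,
    "Pz": 0.08, "POz": 0.06, "Oz": 0.05, "P3": 0.08, "P4": 0.08,
    "P5": 0.07, "P6": 0.07, "O1": 0.05, "O2": 0.05,
}


@dataclass
class SimulationConfig:
    """Study-condition parameters for one synthetic driving session.

    Parameters
    ----------
    seed
        Master seed; every stochastic component derives its stream from it.
    lap_plan
        Ordered (segment, duration_s) entries, segment in {"Easy", "Hard"}.
        Consecutive groups of ``segments_per_lap`` entries form one lap.
    hour
        Traffic condition, "Normal" or "Rush"; Rush adds ``RUSH_BOOST`` to
        the latent trace everywhere.
    events
        (type, onset_s, duration_s) with type in {"Car", "Pedestrian"};
        events raise the latent trace by a type-specific increment and touch
        vehicular signals only through ``coupling``.
    coupling
        In [0, 1]; 0 makes vehicular signals statistically independent of
        the latent trace.
    iaf_hz
        Individual alpha frequency in [8, 12] Hz; anchors the simulated
        theta (IAF-4) and alpha (IAF) oscillations.
    blink_rate_hz, artifact_rate_hz
        Poisson rates of eye-blink transients and high-amplitude bursts.
    eeg_noise_scale
        Multiplier on the 1/f background (RMS ``12 * eeg_noise_scale`` uV).
    """

    seed: int = 0
    lap_plan: Sequence[tuple[str, float]] = (("Easy", 120.0), ("Hard", 120.0))
    hour: str = "Normal"
    events: Sequence[tuple[str, float, float]] = ()
    coupling: float = 1.0
    iaf_hz: float = 10.0
    blink_rate_hz: float = 0.2
    artifact_rate_hz: float = 0.02
    eeg_noise_scale: float = 1.0
    segments_per_lap: int = 2
    # latent-trace dynamics: AR(1) at 256 Hz, ~20 s autocorrelation time
    trace_ar_coeff: float = 0.9998
    trace_noise_sd: float = 0.10
    # EEG oscillation amplitudes (uV): frontal theta rises with workload,
    # parietal alpha falls with workload
    theta_amp_base: float = 2.0
    theta_amp_gain: float = 10.0
    alpha_amp_base: float = 2.0
    alpha_amp_gain: float = 10.0
    blink_amp_uv: float = 80.0
    # vehicular dynamics
    velocity_gain: float = 40.0  # km/h drop per unit excess workload
    velocity_noise_sd: float = 2.0
    lat_acc_gain: float = 8.0
    lon_acc_gain: float = 5.0
    veh_acc_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if not self.lap_plan:
            raise ValueError("lap_plan must contain at least one segment")
        for seg, dur in self.lap_plan:
            if seg not in MWL_BASELINE:
                raise ValueError(f"unknown segment {seg!r}")
            if dur <= 0:
                raise ValueError("segment durations must be positive")
        if self.hour not in ("Normal", "Rush"):
            raise ValueError(f"unknown hour {self.hour!r}")
        total = self.total_duration_s
        for etype, onset, dur in self.events:
            if etype not in EVENT_BOOST:
                raise ValueError(f"unknown event type {etype!r}")
            if dur <= 0 or onset < 0 or onset + dur > total + 1e-9:
                raise ValueError("events must lie within the session timeline")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if not 8.0 <= self.iaf_hz <= 12.0:
            raise ValueError("iaf_hz must be in [8, 12]")
        if self.blink_rate_hz < 0 or self.artifact_rate_hz < 0:
            raise ValueError("event rates must be non-negative")
        if self.eeg_noise_scale <= 0:
            raise ValueError("eeg_noise_scale must be positive")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.lap_plan))

    @classmethod
    def three_lap_protocol(
        cls,
        segment_duration_s: float = 90.0,
        hour: str = "Normal",
        event_duration_s: float = 20.0,
        **kwargs,
    ) -> "SimulationConfig":
        """Three Easy+Hard laps with one Car and one Pedestrian event in lap 3."""
        plan = [(seg, segment_duration_s) for _ in range(3) for seg in ("Easy", "Hard")]
        lap3_start = 4 * segment_duration_s
        events = [
            ("Car", lap3_start + 0.2 * segment_duration_s, event_duration_s),
            ("Pedestrian", lap3_start + 1.2 * segment_duration_s, event_duration_s),
        ]
        return cls(lap_plan=plan, hour=hour, events=events, **kwargs)

    @classmethod
    def event_study_protocol(
        cls,
        n_blocks: int = 10,
        segment_duration_s: float = 60.0,
        event_duration_s: float = 20.0,
        event_offset_s: float = 20.0,
        **kwargs,
    ) -> "SimulationConfig":
        """Alternating Easy/Hard segments with one event per segment.

        Event types are balanced *within* each segment type (seeded by the
        config seed), so Car vs Pedestrian is statistically independent of
        the road-complexity context and of the velocity baseline; any
        discriminability of the event type from vehicular features must then
        flow through the latent-trace coupling.  ``n_blocks`` must be even.
        """
        if n_blocks % 2:
            raise ValueError("n_blocks must be even to balance event types")
        plan = [(seg, segment_duration_s) for _ in range(n_blocks) for seg in ("Easy", "Hard")]
        rng = np.random.default_rng([int(kwargs.get("seed", 0)), 99])
        easy_types = rng.permutation(["Car", "Pedestrian"] * (n_blocks // 2))
        hard_types = rng.permutation(["Car", "Pedestrian"] * (n_blocks // 2))
        events = []
        for i in range(2 * n_blocks):
            etype = easy_types[i // 2] if i % 2 == 0 else hard_types[i // 2]
            events.append((str(etype), i * segment_duration_s + event_offset_s, event_duration_s))
        return cls(lap_plan=plan, events=events, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lap_plan"] = [list(x) for x in self.lap_plan]
        d["events"] = [list(x) for x in self.events]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["lap_plan"] = [tuple(x) for x in d.get("lap_plan", [])]
        d["events"] = [tuple(x) for x in d.get("events", [])]
        return cls(**d)


@dataclass
class LatentWorkloadTrace:
    """Ground-truth workload trace in [0, 1], sampled at 256 Hz."""

    values: np.ndarray
    sample_rate_hz: int = EEG_SFREQ

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("trace values must lie in [0, 1]")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate_hz


@dataclass
class SessionRecording:
    """Time-synchronized raw EEG (256 Hz), vehicular telemetry (10 Hz) and labels."""

    eeg: np.ndarray            # (15, n_samples) in uV
    channel_names: tuple
    vehicular: np.ndarray      # (4, n_samples_10hz)
    annotations: pd.DataFrame  # columns start_s, end_s, lap, segment, hour, event
    config: SimulationConfig

    def __post_init__(self) -> None:
        if self.eeg.shape[0] != len(CHANNELS):
            raise ValueError(f"expected {len(CHANNELS)} EEG channels")
        eeg_dur = self.eeg.shape[1] / EEG_SFREQ
        veh_dur = self.vehicular.shape[1] / VEH_SFREQ
        if abs(eeg_dur - veh_dur) > 1.0 / VEH_SFREQ + 1e-9:
            raise ValueError("EEG and vehicular durations disagree by more than one vehicular sample")


def schedule_annotations(config: SimulationConfig) -> pd.DataFrame:
    """Interval table (start_s, end_s, lap, segment, hour, event) for the plan.

    Segment intervals are split where events overlap them so every row carries
    a single event label ("None" outside events).
    """
    edges = {0.0, config.total_duration_s}
    t = 0.0
    seg_bounds = []
    for i, (seg, dur) in enumerate(config.lap_plan):
        seg_bounds.append((t, t + dur, i // config.segments_per_lap + 1, seg))
        edges.add(t)
        t += dur
    for _, onset, dur in config.events:
        edges.update((onset, onset + dur))
    edges = sorted(edges)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        lap, segment = next(
            (lp, sg) for s, e, lp, sg in seg_bounds if s - 1e-9 <= mid < e + 1e-9
        )
        event = "None"
        for etype, onset, dur in config.events:
            if onset <= mid < onset + dur:
                event = etype
        rows.append((a, b, lap, segment, config.hour, event))
    return pd.DataFrame(rows, columns=["start_s", "end_s", "lap", "segment", "hour", "event"])


def _baseline_profile(config: SimulationConfig, n: int, sfreq: int) -> np.ndarray:
    """Per-sample piecewise latent-workload baseline from the schedule."""
    t = np.arange(n) / sfreq
    base = np.empty(n)
    start = 0.0
    for seg, dur in config.lap_plan:
        mask = (t >= start - 1e-12) & (t < start + dur)
        base[mask] = MWL_BASELINE[seg]
        start += dur
    base[t >= start] = MWL_BASELINE[config.lap_plan[-1][0]]
    if config.hour == "Rush":
        base += RUSH_BOOST
    for etype, onset, dur in config.events:
        base[(t >= onset) & (t < onset + dur)] += EVENT_BOOST[etype]
    return base


def simulate_workload_trace(config: SimulationConfig) -> LatentWorkloadTrace:
    """Latent workload: schedule-driven baseline plus seeded AR(1) noise, clipped to [0, 1]."""
    n = int(round(config.total_duration_s * EEG_SFREQ))
    base = _baseline_profile(config, n, EEG_SFREQ)
    rng = np.random.default_rng([config.seed, 1])
    phi = config.trace_ar_coeff
    # innovation scaled for a stationary sd of trace_noise_sd
    innov_sd = config.trace_noise_sd * np.sqrt(1.0 - phi**2)
    noise = np.empty(n)
    x = rng.normal(0.0, config.trace_noise_sd)
    innov = rng.normal(0.0, innov_sd, size=n)
    for i in range(n):
        x = phi * x + innov[i]
        noise[i] = x
    return LatentWorkloadTrace(np.clip(base + noise, 0.0, 1.0))


def _one_over_f_noise(rng: np.random.Generator, n: int, rms: float) -> np.ndarray:
    """Gaussian noise with ~1/f amplitude spectrum, scaled to the target RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / EEG_SFREQ)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _raised_cosine(n: int) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / (n - 1)))


def synthesize_eeg(
    trace: LatentWorkloadTrace,
    config: SimulationConfig,
    *,
    alpha_boost: float = 1.0,
) -> np.ndarray:
    """Render a (15, n) uV EEG matrix from the latent trace.

    Each channel is 1/f background noise plus workload-modulated band-limited
    oscillations: a theta component at IAF-4 Hz on frontal channels whose
    amplitude increases affinely with the trace, and an alpha component at IAF
    on parietal/occipital channels whose amplitude decreases affinely with the
    trace.  Blink transients (400 ms raised cosine, frontal topography) and
    sparse high-amplitude bursts are overlaid at their configured Poisson
    rates.  ``alpha_boost`` > 1 emulates a closed-eyes resting condition.
    """
    vals = trace.values
    n = vals.size
    t = trace.times_s
    eeg = np.empty((len(CHANNELS), n))
    theta_hz = config.iaf_hz - 4.0
    rng = np.random.default_rng([config.seed, 2])
    for ci, ch in enumerate(CHANNELS):
        x = _one_over_f_noise(rng, n, 12.0 * config.eeg_noise_scale)
        phase_t, phase_a = rng.uniform(0, 2 * np.pi, size=2)
        if ch in FRONTAL_CHANNELS:
            amp = config.theta_amp_base + config.theta_amp_gain * vals
            x = x + amp * np.sin(2 * np.pi * theta_hz * t + phase_t)
        if ch in PARIETAL_CHANNELS:
            amp = (config.alpha_amp_base + config.alpha_amp_gain * (1.0 - vals)) * alpha_boost
            x = x + amp * np.sin(2 * np.pi * config.iaf_hz * t + phase_a)
        eeg[ci] = x

    blink_rng = np.random.default_rng([config.seed, 3])
    duration = n / EEG_SFREQ
    width = int(round(0.4 * EEG_SFREQ))
    template = _raised_cosine(width) * config.blink_amp_uv
    topo = np.array([BLINK_TOPOGRAPHY[ch] for ch in CHANNELS])
    n_blinks = blink_rng.poisson(config.blink_rate_hz * duration)
    for onset in np.sort(blink_rng.uniform(0, duration - 0.4, size=n_blinks)):
        i0 = int(round(onset * EEG_SFREQ))
        eeg[:, i0:i0 + width] += topo[:, None] * template[None, :]

    art_rng = np.random.default_rng([config.seed, 4])
    burst_w = int(round(0.5 * EEG_SFREQ))
    n_art = art_rng.poisson(config.artifact_rate_hz * duration)
    for onset in np.sort(art_rng.uniform(0, duration - 0.5, size=n_art)):
        i0 = int(round(onset * EEG_SFREQ))
        ch = art_rng.integers(len(CHANNELS))
        eeg[ch, i0:i0 + burst_w] += art_rng.normal(0, 150.0, size=burst_w)
    return eeg


def synthesize_resting_eeg(config: SimulationConfig, duration_s: float = 60.0) -> np.ndarray:
    """Closed-eyes resting EEG: zero workload, alpha amplitude tripled."""
    n = int(round(duration_s * EEG_SFREQ))
    rest = LatentWorkloadTrace(np.zeros(n))
    quiet = dataclasses.replace(config, blink_rate_hz=0.0, artifact_rate_hz=0.0)
    return synthesize_eeg(rest, quiet, alpha_boost=3.0)


def synthesize_vehicular(trace: LatentWorkloadTrace, config: SimulationConfig) -> np.ndarray:
    """Render the (4, n_10hz) vehicular matrix from the latent trace.

    Velocity follows the segment baseline minus a coupling-weighted response
    to excess workload; acceleration is the first difference of velocity;
    lateral/longitudinal accelerations are coupling-weighted band-limited
    functions of the trace plus noise.  coupling = 0 detaches every channel
    from the trace.
    """
    from scipy import signal as sps

    n256 = trace.values.size
    n10 = int(round(n256 / EEG_SFREQ * VEH_SFREQ))
    t10 = np.arange(n10) / VEH_SFREQ
    trace10 = np.interp(t10, trace.times_s, trace.values)

    seg_base_v = np.empty(n10)
    seg_base_m = np.empty(n10)
    start = 0.0
    for seg, dur in config.lap_plan:
        mask = (t10 >= start - 1e-12) & (t10 < start + dur)
        seg_base_v[mask] = VELOCITY_BASELINE[seg]
        seg_base_m[mask] = MWL_BASELINE[seg]
        start += dur
    tail = t10 >= start
    seg_base_v[tail] = VELOCITY_BASELINE[config.lap_plan[-1][0]]
    seg_base_m[tail] = MWL_BASELINE[config.lap_plan[-1][0]]

    rng = np.random.default_rng([config.seed, 5])

    def smooth_noise(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros(n10)
        w = rng.normal(0, sd, size=n10 + 40)
        sos = sps.butter(2, 0.5, btype="low", fs=VEH_SFREQ, output="sos")
        return sps.sosfilt(sos, w)[40:]

    excess = trace10 - seg_base_m
    velocity = seg_base_v - config.coupling * config.velocity_gain * excess + smooth_noise(
        config.velocity_noise_sd
    )
    acceleration = np.diff(velocity, prepend=velocity[:1]) * VEH_SFREQ  # km/h per s

    def band_limited(x: np.ndarray) -> np.ndarray:
        if n10 < 30:
            return x - x.mean()
        sos = sps.butter(2, [0.05, 1.0], btype="band", fs=VEH_SFREQ, output="sos")
        return sps.sosfiltfilt(sos, x)

    lateral = config.coupling * config.lat_acc_gain * band_limited(trace10) + smooth_noise(
        config.veh_acc_noise_sd
    )
    longitudinal = config.coupling * config.lon_acc_gain * band_limited(
        trace10**2
    ) + smooth_noise(config.veh_acc_noise_sd)
    return np.vstack([velocity, acceleration, lateral, longitudinal])


def make_session(config: SimulationConfig) -> tuple[SessionRecording, LatentWorkloadTrace]:
    """Compose trace, EEG, vehicular telemetry and annotations into one session."""
    trace = simulate_workload_trace(config)
    eeg = synthesize_eeg(trace, config)
    veh = synthesize_vehicular(trace, config)
    rec = SessionRecording(
        eeg=eeg,
        channel_names=CHANNELS,
        vehicular=veh,
        annotations=schedule_annotations(config),
        config=config,
    )
    return rec, trace


# ---------------------------------------------------------------------------
# session I/O (wide CSV + YAML config)

def write_session(rec: SessionRecording, out_dir: str | Path, trace: LatentWorkloadTrace | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = rec.eeg.shape[1]
    eeg_df = pd.DataFrame(rec.eeg.T, columns=list(rec.channel_names))
    eeg_df.insert(0, "time_s", np.arange(n) / EEG_SFREQ)
    eeg_df.to_csv(out / "eeg.csv", index=False, float_format="%.6f")
    veh_df = pd.DataFrame(rec.vehicular.T, columns=list(VEHICULAR_COLUMNS))
    veh_df.insert(0, "time_s", np.arange(rec.vehicular.shape[1]) / VEH_SFREQ)
    veh_df.to_csv(out / "vehicular.csv", index=False, float_format="%.6f")
    rec.annotations.to_csv(out / "annotations.csv", index=False)
    (out / "config.yaml").write_text(yaml.safe_dump(rec.config.to_dict()))
    if trace is not None:
        pd.DataFrame({"trace": trace.values}).to_csv(
            out / "trace.csv", index=False, float_format="%.6f"
        )


def read_session(in_dir: str | Path) -> SessionRecording:
    src = Path(in_dir)
    config = SimulationConfig.from_dict(yaml.safe_load((src / "config.yaml").read_text()))
    eeg_df = pd.read_csv(src / "eeg.csv")
    veh_df = pd.read_csv(src / "vehicular.csv")
    ann = pd.read_csv(src / "annotations.csv")
    return SessionRecording(
        eeg=eeg_df[list(CHANNELS)].to_numpy().T,
        channel_names=CHANNELS,
        vehicular=veh_df[list(VEHICULAR_COLUMNS)].to_numpy().T,
        annotations=ann,
        config=config,
    )


def label_epochs(
    annotations: pd.DataFrame, start_times_s: np.ndarray, length_s: float = 2.0
) -> pd.DataFrame:
    """Assign each epoch the annotation row covering its window midpoint."""
    mids = np.asarray(start_times_s) + 0.5 * length_s
    idx = np.searchsorted(annotations["end_s"].to_numpy(), mids, side="right")
    idx = np.clip(idx, 0, len(annotations) - 1)
    out = annotations.iloc[idx][["lap", "segment", "hour", "event"]].reset_index(drop=True)
    out.insert(0, "start_s", np.asarray(start_times_s))
    return out
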
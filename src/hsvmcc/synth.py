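"""Seeded generator of labelled six-activity sensor sessions.

No public recordings accompany the recognition method this package
implements, so the generator emulates the statistical regularities the
classifier relies on, for a phone carried upright in a front trouser pocket:

* gravity loads mostly the +Y axis while upright; sitting reclines the
  device ~70 degrees so the Y-axis mean drops;
* running adds a sustained positive Y bias (impact acceleration), separating
  it from standing/walking on the Y mean;
* motion "wave" energy (Twave) orders sitting < standing < walking < running
  through the per-axis oscillation amplitudes;
* barometric pressure drifts downward while climbing upstairs and upward
  while going downstairs (people descend faster than they climb, so the
  downstairs drift is larger in magnitude), and is flat otherwise.

Oscillations get a fresh random phase offset every stride cycle, making the
signal quasi-periodic rather than strictly periodic — the regime in which
sub-Nyquist sampling with longer windows preserves window statistics.

All randomness flows from the config seed; identical configs produce
bit-identical streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import ParameterError
from .signals import SensorStream, Window, trim_session, window_stream

__all__ = [
    "ActivityParams",
    "SyntheticConfig",
    "ACTIVITIES",
    "DEFAULT_ACTIVITY_PARAMS",
    "default_config",
    "generate_session",
    "generate_training_set",
    "load_config",
    "save_config",
]

GRAVITY = 9.81  # m/s^2
BASE_PRESSURE = 1013.25  # hPa at the session start

#: Canonical activity order.
ACTIVITIES = ("sitting", "standing", "walking", "running", "upstairs", "downstairs")

# fixed per-axis phase offsets decorrelate the three axes of one oscillator
_AXIS_PHASE = np.array([0.0, 2.1, 4.2])


@dataclass(frozen=True)
class ActivityParams:
    """Generative parameters of one activity.

    orientation : unit vector the gravity vector projects onto (device frame)
    accel_bias : sustained non-gravity acceleration offset, m/s^2 per axis
    osc_amplitude : per-axis oscillation amplitude, m/s^2
    osc_freq_hz : stride (oscillation) frequency, Hz
    phase_jitter_sd : SD of the per-cycle random phase offset, rad
    noise_sd : white accelerometer noise SD, m/s^2
    pressure_drift_hpa_s : signed pressure drift rate, hPa/s
        (negative = ascending, positive = descending, 0 on flat ground)
    pressure_noise_sd : white barometer noise SD, hPa
    """

    orientation: tuple[float, float, float]
    osc_amplitude: tuple[float, float, float]
    osc_freq_hz: float
    noise_sd: float
    accel_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase_jitter_sd: float = 0.4
    pressure_drift_hpa_s: float = 0.0
    pressure_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if abs(float(np.linalg.norm(self.orientation)) - 1.0) > 1e-6:
            raise ParameterError("orientation must be a unit vector")
        if self.noise_sd < 0 or self.pressure_noise_sd < 0:
            raise ParameterError("noise SDs must be non-negative")


# Stride frequencies: walking 1.8 Hz, running 2.8 Hz, stairs 1.5 Hz — human
# activity sits around 2 Hz.  Pressure drifts: about 0.12 hPa per metre of
# altitude, climbing ~0.33 m/s and descending faster.
DEFAULT_ACTIVITY_PARAMS: dict[str, ActivityParams] = {
    "sitting": ActivityParams(
        orientation=(0.0, 0.342, 0.93969966),  # device reclined ~70 degrees
        osc_amplitude=(0.03, 0.03, 0.03),
        osc_freq_hz=0.3,
        noise_sd=0.05,
    ),
    "standing": ActivityParams(
        orientation=(0.0, 1.0, 0.0),
        osc_amplitude=(0.05, 0.1, 0.05),  # postural sway
        osc_freq_hz=0.5,
        noise_sd=0.05,
    ),
    "walking": ActivityParams(
        orientation=(0.0, 1.0, 0.0),
        osc_amplitude=(0.6, 1.2, 0.6),
        osc_freq_hz=1.8,
        noise_sd=0.1,
    ),
    "running": ActivityParams(
        orientation=(0.0, 1.0, 0.0),
        accel_bias=(0.0, 3.0, 0.0),  # sustained impact acceleration
        osc_amplitude=(3.5, 1.5, 3.5),
        osc_freq_hz=2.8,
        noise_sd=0.2,
    ),
    "upstairs": ActivityParams(
        orientation=(0.0, 1.0, 0.0),
        osc_amplitude=(0.4, 0.7, 0.4),
        osc_freq_hz=1.5,
        noise_sd=0.1,
        pressure_drift_hpa_s=-0.04,
    ),
    "downstairs": ActivityParams(
        orientation=(0.0, 1.0, 0.0),
        osc_amplitude=(0.4, 0.7, 0.4),
        osc_freq_hz=1.5,
        noise_sd=0.1,
        pressure_drift_hpa_s=+0.06,
    ),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """A full session recipe: activity parameters, schedule, rate and seed."""

    activities: dict[str, ActivityParams] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_PARAMS)
    )
    rate_hz: float = 1.0
    schedule: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name, dur in self.schedule:
            if name not in self.activities:
                raise ParameterError(f"unknown activity in schedule: {name!r}")
            if dur <= 0:
                raise ParameterError(f"schedule durations must be positive ({name})")
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz must be positive")


def default_config(
    schedule=(), rate_hz: float = 1.0, seed: int = 0
) -> SyntheticConfig:
    return SyntheticConfig(schedule=tuple(schedule), rate_hz=rate_hz, seed=seed)


def _oscillation(rng: np.random.Generator, t_rel: np.ndarray, p: ActivityParams):
    """Quasi-periodic per-axis sinusoid with a random phase per stride cycle."""
    if p.osc_freq_hz <= 0:
        return np.zeros((t_rel.size, 3))
    n_cycles = int(np.floor(t_rel[-1] * p.osc_freq_hz)) + 1 if t_rel.size else 1
    base = rng.uniform(0.0, 2.0 * np.pi)
    offsets = rng.normal(0.0, p.phase_jitter_sd, n_cycles)
    cyc = np.minimum((t_rel * p.osc_freq_hz).astype(int), n_cycles - 1)
    phase = 2.0 * np.pi * p.osc_freq_hz * t_rel + base + offsets[cyc]
    amp = np.asarray(p.osc_amplitude, dtype=float)
    return amp[None, :] * np.sin(phase[:, None] + _AXIS_PHASE[None, :])


def generate_session(config: SyntheticConfig) -> SensorStream:
    """Synthesise one labelled session following the config schedule.

    Acceleration per sample = gravity on the device orientation + activity
    bias + quasi-periodic oscillation + white noise; pressure = running
    baseline + cumulative drift + white noise.  Pressure is continuous
    across schedule segments (you end a staircase at the altitude you
    reached).
    """
    if not config.schedule:
        raise ParameterError("config.schedule is empty")
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.rate_hz
    t_cursor = 0.0
    p_level = BASE_PRESSURE
    acc_parts, t_parts, p_parts, label_parts = [], [], [], []
    for name, duration in config.schedule:
        p = config.activities[name]
        n = int(round(duration * config.rate_hz))
        if n == 0:
            continue
        t_rel = np.arange(n) * dt
        gravity = GRAVITY * np.asarray(p.orientation, dtype=float)
        bias = np.asarray(p.accel_bias, dtype=float)
        accel = (
            gravity[None, :]
            + bias[None, :]
            + _oscillation(rng, t_rel, p)
            + rng.normal(0.0, p.noise_sd, (n, 3))
        )
        pressure = (
            p_level
            + p.pressure_drift_hpa_s * t_rel
            + rng.normal(0.0, p.pressure_noise_sd, n)
        )
        acc_parts.append(accel)
        t_parts.append(t_cursor + t_rel)
        p_parts.append(pressure)
        label_parts.append(np.full(n, name, dtype=object))
        p_level += p.pressure_drift_hpa_s * duration
        t_cursor += duration
    t = np.concatenate(t_parts)
    return SensorStream(
        accel_t=t,
        accel=np.vstack(acc_parts),
        pressure_t=t.copy(),
        pressure=np.concatenate(p_parts),
        rate_hz=config.rate_hz,
        labels=np.concatenate(label_parts),
    )


def generate_training_set(
    config: SyntheticConfig | None = None,
    windows_per_class: int = 15,
    window_s: float = 5.0,
) -> list[Window]:
    """Balanced labelled training windows, one short session per activity.

    Each activity is recorded long enough that, after windowing (no overlap)
    and dropping the first and last window of the session, exactly
    ``windows_per_class`` interior windows remain per class.  The default of
    15 windows for each of the six activities yields the 90-window training
    set the classifier is designed around.
    """
    if windows_per_class < 1:
        raise ParameterError("windows_per_class must be >= 1")
    if config is None:
        config = default_config()
    seed_root = np.random.default_rng(config.seed)
    windows: list[Window] = []
    for name in config.activities:
        session_cfg = replace(
            config,
            schedule=((name, (windows_per_class + 2) * window_s),),
            seed=int(seed_root.integers(2**31)),
        )
        stream = generate_session(session_cfg)
        wins = trim_session(window_stream(stream, window_s))
        windows.extend(wins[:windows_per_class])
    return windows


# -- config file I/O -------------------------------------------------------


def save_config(config: SyntheticConfig, path) -> None:
    """Write a config as a flat YAML document (per-activity blocks)."""
    doc = {
        "rate_hz": config.rate_hz,
        "seed": config.seed,
        "schedule": [[name, float(dur)] for name, dur in config.schedule],
        "activities": {
            name: {
                "orientation": list(p.orientation),
                "accel_bias": list(p.accel_bias),
                "osc_amplitude": list(p.osc_amplitude),
                "osc_freq_hz": p.osc_freq_hz,
                "phase_jitter_sd": p.phase_jitter_sd,
                "noise_sd": p.noise_sd,
                "pressure_drift_hpa_s": p.pressure_drift_hpa_s,
                "pressure_noise_sd": p.pressure_noise_sd,
            }
            for name, p in config.activities.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> SyntheticConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    activities = {
        name: ActivityParams(
            orientation=tuple(block["orientation"]),
            accel_bias=tuple(block.get("accel_bias", (0.0, 0.0, 0.0))),
            osc_amplitude=tuple(block["osc_amplitude"]),
            osc_freq_hz=float(block["osc_freq_hz"]),
            phase_jitter_sd=float(block.get("phase_jitter_sd", 0.4)),
            noise_sd=float(block["noise_sd"]),
            pressure_drift_hpa_s=float(block.get("pressure_drift_hpa_s", 0.0)),
            pressure_noise_sd=float(block.get("pressure_noise_sd", 0.02)),
        )
        for name, block in doc.get("activities", {}).items()
    }
    return SyntheticConfig(
        activities=activities or dict(DEFAULT_ACTIVITY_PARAMS),
        rate_hz=float(doc.get("rate_hz", 1.0)),
        schedule=tuple((name, float(dur)) for name, dur in doc.get("schedule", [])),
        seed=int(doc.get("seed", 0)),
    )
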
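"""Sensor streams, fixed windowing, decimation and sampling-scheme algebra.

A :class:`SensorStream` holds time-stamped tri-axial accelerometer samples
(m/s^2, gravity included) and barometric pressure samples (hPa), optionally
with a ground-truth activity label per accelerometer sample.  Streams are cut
into fixed, non-overlapping (or overlapping) windows from which one feature
vector and one prediction are produced.

The module also carries the sampling-rate/window equivalence machinery: for
activity signals one can trade sampling rate against window length — two
schemes with equal ``rate_hz * window_s`` products collect the same number of
samples per window and, for (quasi-)periodic signals, windows with the same
statistical properties.  ``equivalent_window`` computes the window length a
low rate needs to match a reference scheme, and ``scheme_equivalence_stats``
measures how close two schemes' pooled window statistics actually are.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyStreamError, ParameterError

__all__ = [
    "SensorStream",
    "Window",
    "SamplingScheme",
    "SchemeComparison",
    "window_stream",
    "segment_windows",
    "trim_session",
    "decimate",
    "equivalent_window",
    "scheme_equivalence_stats",
    "read_stream_csv",
    "write_stream_csv",
]

STREAM_COLUMNS = ("t", "ax", "ay", "az", "p", "label")


@dataclass
class SensorStream:
    """Time-aligned accelerometer + barometer recording.

    Parameters
    ----------
    accel_t : array of shape (n,)
        Accelerometer sample times in seconds, non-decreasing.
    accel : array of shape (n, 3)
        Tri-axial acceleration in m/s^2, gravity included.
    pressure_t : array of shape (m,)
        Barometer sample times in seconds, non-decreasing.  The two channels
        need not share timestamps.
    pressure : array of shape (m,)
        Barometric pressure in hPa, strictly positive.
    rate_hz : float
        Nominal sampling rate of the accelerometer channel.
    labels : array of shape (n,) of str, optional
        Ground-truth activity label per accelerometer sample.
    """

    accel_t: np.ndarray
    accel: np.ndarray
    pressure_t: np.ndarray
    pressure: np.ndarray
    rate_hz: float
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.accel_t = np.asarray(self.accel_t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.pressure_t = np.asarray(self.pressure_t, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ParameterError("accel must have shape (n, 3)")
        if self.accel_t.shape[0] != self.accel.shape[0]:
            raise ParameterError("accel_t and accel lengths differ")
        if self.pressure_t.shape[0] != self.pressure.shape[0]:
            raise ParameterError("pressure_t and pressure lengths differ")
        for name, t in (("accel_t", self.accel_t), ("pressure_t", self.pressure_t)):
            if t.size and not np.all(np.isfinite(t)):
                raise ParameterError(f"{name} contains non-finite times")
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ParameterError(f"{name} is not sorted by time")
        if self.pressure.size and np.any(self.pressure <= 0):
            raise ParameterError("pressure values must be positive (hPa)")
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz must be positive")
        if self.labels is not None and self.labels.shape[0] != self.accel.shape[0]:
            raise ParameterError("labels must have one entry per accel sample")

    @property
    def n_samples(self) -> int:
        return int(self.accel.shape[0])

    @property
    def duration_s(self) -> float:
        """Recording extent: last-minus-first time plus one sample period."""
        if self.n_samples == 0:
            return 0.0
        return float(self.accel_t[-1] - self.accel_t[0]) + 1.0 / self.rate_hz

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular form with columns ``t, ax, ay, az, p, label``.

        Accelerometer and pressure rows are merged on time; a row carries NaN
        in the channel that has no sample at that instant.
        """
        acc = pd.DataFrame(
            {
                "t": self.accel_t,
                "ax": self.accel[:, 0],
                "ay": self.accel[:, 1],
                "az": self.accel[:, 2],
            }
        )
        if self.labels is not None:
            acc["label"] = self.labels
        pres = pd.DataFrame({"t": self.pressure_t, "p": self.pressure})
        out = acc.merge(pres, on="t", how="outer", sort=True)
        cols = [c for c in STREAM_COLUMNS if c in out.columns]
        return out[cols]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, rate_hz: float) -> "SensorStream":
        missing = {"t", "ax", "ay", "az"} - set(df.columns)
        if missing:
            raise ParameterError(f"stream table missing columns: {sorted(missing)}")
        acc_mask = df[["ax", "ay", "az"]].notna().all(axis=1)
        acc = df.loc[acc_mask]
        labels = None
        if "label" in df.columns and acc["label"].notna().any():
            labels = acc["label"].to_numpy(dtype=object)
        if "p" in df.columns:
            pres = df.loc[df["p"].notna()]
            pressure_t = pres["t"].to_numpy(dtype=float)
            pressure = pres["p"].to_numpy(dtype=float)
        else:
            pressure_t = np.empty(0)
            pressure = np.empty(0)
        return cls(
            accel_t=acc["t"].to_numpy(dtype=float),
            accel=acc[["ax", "ay", "az"]].to_numpy(dtype=float),
            pressure_t=pressure_t,
            pressure=pressure,
            rate_hz=rate_hz,
            labels=labels,
        )


@dataclass
class Window:
    """A fixed-duration, half-open segment [t_start, t_start + duration)."""

    t_start: float
    duration: float
    accel_t: np.ndarray
    accel: np.ndarray
    pressure_t: np.ndarray
    pressure: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterError("window duration must be positive")

    @property
    def n_accel(self) -> int:
        return int(self.accel.shape[0])

    @property
    def n_pressure(self) -> int:
        return int(self.pressure.shape[0])


@dataclass(frozen=True)
class SamplingScheme:
    """A (sampling rate, window length) pair.

    The product ``rate_hz * window_s`` is the number of samples collected per
    window; schemes with equal products are candidates for statistical
    equivalence on activity signals.
    """

    rate_hz: float
    window_s: float

    def __post_init__(self) -> None:
        if self.rate_hz <= 0 or self.window_s <= 0:
            raise ParameterError("rate_hz and window_s must be positive")

    @property
    def samples_per_window(self) -> float:
        return self.rate_hz * self.window_s


def _majority_label(labels: np.ndarray) -> str | None:
    """Strict majority label; ties broken by earliest occurrence in the window."""
    if labels is None or len(labels) == 0:
        return None
    counts = Counter(labels)
    best = max(counts.values())
    for lab in labels:  # earliest-first tie-break
        if counts[lab] == best:
            return lab
    return None  # pragma: no cover


def window_stream(
    stream: SensorStream, window_s: float, overlap_s: float = 0.0
) -> list[Window]:
    """Cut a stream into fixed windows anchored at the first accel timestamp.

    Windows are half-open ``[start, start + window_s)`` and advance by
    ``window_s - overlap_s``; a trailing window that would extend past the end
    of the recording is dropped.  A window's label is the majority label of
    its accelerometer samples when labels are present.
    """
    if stream.n_samples == 0:
        raise EmptyStreamError("cannot window an empty stream")
    if window_s <= 0:
        raise ParameterError("window_s must be positive")
    if overlap_s < 0 or overlap_s >= window_s:
        raise ParameterError(
            f"overlap ({overlap_s}) must satisfy 0 <= overlap < window ({window_s})"
        )
    step = window_s - overlap_s
    t0 = float(stream.accel_t[0])
    extent = stream.duration_s
    eps = 1e-9
    windows: list[Window] = []
    i = 0
    while t0 + i * step + window_s <= t0 + extent + eps:
        start = t0 + i * step
        end = start + window_s
        amask = (stream.accel_t >= start - eps) & (stream.accel_t < end - eps)
        pmask = (stream.pressure_t >= start - eps) & (stream.pressure_t < end - eps)
        label = (
            _majority_label(stream.labels[amask]) if stream.labels is not None else None
        )
        windows.append(
            Window(
                t_start=start,
                duration=window_s,
                accel_t=stream.accel_t[amask],
                accel=stream.accel[amask],
                pressure_t=stream.pressure_t[pmask],
                pressure=stream.pressure[pmask],
                label=label,
            )
        )
        i += 1
    return windows


def trim_session(windows: list[Window]) -> list[Window]:
    """Drop the first and last window of a session.

    Recording sessions start and end with the subject getting in and out of
    the activity, so the boundary windows are discarded to keep only windows
    of a single established activity.  With fewer than three windows nothing
    interior remains; an empty list is returned with a warning.
    """
    if len(windows) < 2:
        raise ParameterError("trim_session needs at least 2 windows")
    if len(windows) < 3:
        warnings.warn(
            "trim_session: fewer than 3 windows, no interior windows remain",
            UserWarning,
            stacklevel=2,
        )
    return windows[1:-1]


def segment_windows(
    stream: SensorStream,
    window_s: float,
    overlap_s: float = 0.0,
    trim: bool = True,
) -> list[Window]:
    """Window a labelled stream per contiguous activity segment.

    The stream is split at label changes; each single-activity segment is
    windowed independently and, when ``trim`` is set, its first and last
    window are removed so every retained window contains one established
    activity.  Streams without labels fall back to plain windowing.
    """
    if stream.labels is None:
        out = window_stream(stream, window_s, overlap_s)
        return trim_session(out) if trim and len(out) >= 2 else out
    change = np.flatnonzero(stream.labels[1:] != stream.labels[:-1]) + 1
    bounds = np.concatenate(([0], change, [stream.n_samples]))
    windows: list[Window] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        t_lo, t_hi = stream.accel_t[lo], stream.accel_t[hi - 1]
        pmask = (stream.pressure_t >= t_lo) & (stream.pressure_t <= t_hi)
        seg = SensorStream(
            accel_t=stream.accel_t[lo:hi],
            accel=stream.accel[lo:hi],
            pressure_t=stream.pressure_t[pmask],
            pressure=stream.pressure[pmask],
            rate_hz=stream.rate_hz,
            labels=stream.labels[lo:hi],
        )
        seg_windows = window_stream(seg, window_s, overlap_s)
        if trim and len(seg_windows) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                seg_windows = trim_session(seg_windows)
        windows.extend(seg_windows)
    return windows


def decimate(stream: SensorStream, target_hz: float) -> SensorStream:
    """Point-sample a stream down to ``target_hz``.

    Keeps every ``rate_hz / target_hz``-th sample starting from the first, on
    both channels.  No interpolation or anti-alias filtering is applied: the
    result is exactly what a sensor genuinely polled at the low rate would
    have recorded, which is the regime this package reasons about.
    """
    stride_f = stream.rate_hz / target_hz
    stride = int(round(stride_f))
    if stride < 1 or abs(stride_f - stride) > 1e-9:
        raise ParameterError(
            f"target rate {target_hz} Hz must evenly divide stream rate "
            f"{stream.rate_hz} Hz (got stride {stride_f})"
        )
    return replace(
        stream,
        accel_t=stream.accel_t[::stride],
        accel=stream.accel[::stride],
        pressure_t=stream.pressure_t[::stride],
        pressure=stream.pressure[::stride],
        rate_hz=target_hz,
        labels=None if stream.labels is None else stream.labels[::stride],
    )


def equivalent_window(
    activity_hz: float, ref_window_s: float, low_rate_hz: float
) -> float:
    """Window length a sub-Nyquist rate needs to match a reference scheme.

    A signal of activity frequency ``activity_hz`` sampled at the Nyquist rate
    ``2 * activity_hz`` for ``ref_window_s`` seconds collects
    ``2 * activity_hz * ref_window_s`` samples.  A sensor polled at
    ``low_rate_hz`` collects the same number of samples — and hence, for
    quasi-periodic activity signals, windows with the same statistical
    properties — in ``2 * activity_hz * ref_window_s / low_rate_hz`` seconds.
    """
    if activity_hz <= 0 or ref_window_s <= 0 or low_rate_hz <= 0:
        raise ParameterError("all arguments must be positive")
    return 2.0 * activity_hz * ref_window_s / low_rate_hz


@dataclass(frozen=True)
class SchemeComparison:
    """Pooled per-axis statistics of two sampling schemes on one stream."""

    scheme_a: SamplingScheme
    scheme_b: SamplingScheme
    mean_a: np.ndarray = field(repr=False)
    mean_b: np.ndarray = field(repr=False)
    var_a: np.ndarray = field(repr=False)
    var_b: np.ndarray = field(repr=False)

    @property
    def rel_mean_diff(self) -> np.ndarray:
        return _rel_diff(self.mean_a, self.mean_b)

    @property
    def rel_var_diff(self) -> np.ndarray:
        return _rel_diff(self.var_a, self.var_b)


def _rel_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    scale = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-12)
    return np.abs(a - b) / scale


def _pooled_stats(
    stream: SensorStream, scheme: SamplingScheme
) -> tuple[np.ndarray, np.ndarray]:
    sub = decimate(stream, scheme.rate_hz)
    windows = window_stream(sub, scheme.window_s)
    if not windows:
        raise EmptyStreamError(
            f"stream too short for scheme {scheme.rate_hz} Hz x {scheme.window_s} s"
        )
    pooled = np.vstack([w.accel for w in windows])
    return pooled.mean(axis=0), pooled.var(axis=0)


def scheme_equivalence_stats(
    stream: SensorStream,
    scheme_a: SamplingScheme,
    scheme_b: SamplingScheme,
) -> SchemeComparison:
    """Compare pooled windowed statistics of two equal-product schemes.

    Both schemes must collect the same number of samples per window
    (``rate_hz * window_s`` equal); each scheme's rate must evenly divide the
    stream's rate so both are aligned point-samplings of the same recording.
    Returns pooled per-axis mean and variance under each scheme along with
    their absolute relative differences.
    """
    if abs(scheme_a.samples_per_window - scheme_b.samples_per_window) > 1e-9:
        raise ParameterError(
            "schemes are not equivalent: rate_hz * window_s products differ "
            f"({scheme_a.samples_per_window} vs {scheme_b.samples_per_window})"
        )
    mean_a, var_a = _pooled_stats(stream, scheme_a)
    mean_b, var_b = _pooled_stats(stream, scheme_b)
    return SchemeComparison(
        scheme_a=scheme_a,
        scheme_b=scheme_b,
        mean_a=mean_a,
        mean_b=mean_b,
        var_a=var_a,
        var_b=var_b,
    )


def read_stream_csv(path, rate_hz: float) -> SensorStream:
    """Read a ``t,ax,ay,az,p,label`` CSV (header required, '.' decimals)."""
    df = pd.read_csv(path)
    return SensorStream.from_dataframe(df, rate_hz=rate_hz)


def write_stream_csv(stream: SensorStream, path) -> None:
    stream.to_dataframe().to_csv(path, index=False)
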
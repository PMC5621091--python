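"""Per-window features for low-sampling-rate activity recognition.

Four feature families computed on each fixed time window:

* ``Pd`` — signed barometric pressure change, last minus first pressure
  sample in the window (hPa).  Pressure falls with altitude, so ``Pd`` is
  negative while ascending stairs and positive while descending.
* ``Pdabs`` — ``|Pd|``; large on stairs in either direction, near the noise
  floor on flat ground.
* ``Xmeans / Ymeans / Zmeans`` — per-axis arithmetic mean of the tri-axial
  acceleration over the window, gravity included.  With the phone upright in
  a trouser pocket gravity loads mostly the Y axis, so ``Ymeans`` drops when
  the wearer sits (the device reclines) and rises during running (sustained
  impact acceleration).
* ``Twave`` — motion intensity: the sum over consecutive sample pairs of the
  Euclidean norm of the acceleration difference,
  ``sum_i sqrt(dX_i^2 + dY_i^2 + dZ_i^2)``.  Orders still < walking < running.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FeatureUndefinedError
from .signals import Window

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "pressure_difference",
    "pressure_difference_abs",
    "axis_means",
    "twave",
    "extract_features",
    "feature_table",
    "read_feature_csv",
    "write_feature_csv",
]

#: Canonical feature order used in tables and models.
FEATURE_NAMES = ("Pd", "Pdabs", "Xmeans", "Ymeans", "Zmeans", "Twave")


@dataclass(frozen=True)
class FeatureVector:
    """The six per-window features (units: hPa for pressure, m/s^2 otherwise)."""

    pd: float
    pd_abs: float
    x_mean: float
    y_mean: float
    z_mean: float
    twave: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.as_array()))

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.pd, self.pd_abs, self.x_mean, self.y_mean, self.z_mean, self.twave]
        )


def pressure_difference(window: Window) -> float:
    """Signed pressure change across the window: last minus first sample."""
    if window.n_pressure < 2:
        raise FeatureUndefinedError(
            f"Pd undefined: window at t={window.t_start} has "
            f"{window.n_pressure} pressure sample(s), needs >= 2"
        )
    return float(window.pressure[-1] - window.pressure[0])


def pressure_difference_abs(window: Window) -> float:
    """Magnitude of the pressure change across the window."""
    return abs(pressure_difference(window))


def axis_means(window: Window) -> tuple[float, float, float]:
    """Arithmetic mean of each acceleration axis over the window."""
    if window.n_accel < 1:
        raise FeatureUndefinedError(
            f"axis means undefined: window at t={window.t_start} has no accel samples"
        )
    m = window.accel.mean(axis=0)
    return float(m[0]), float(m[1]), float(m[2])


def twave(window: Window) -> float:
    """Sum of Euclidean norms of consecutive tri-axial sample differences."""
    if window.n_accel < 2:
        raise FeatureUndefinedError(
            f"Twave undefined: window at t={window.t_start} has "
            f"{window.n_accel} accel sample(s), needs >= 2"
        )
    diffs = np.diff(window.accel, axis=0)
    return float(np.sqrt((diffs**2).sum(axis=1)).sum())


def extract_features(window: Window, impute_missing_pressure: bool = True) -> FeatureVector:
    """Compute the full six-field feature vector for one window.

    When the barometer channel is missing (fewer than two pressure samples)
    and ``impute_missing_pressure`` is set, ``Pd`` and ``Pdabs`` are imputed
    as 0 with a warning so accelerometer-only streams remain classifiable on
    the flat-ground part of the class hierarchy.
    """
    try:
        pd_val = pressure_difference(window)
    except FeatureUndefinedError:
        if not impute_missing_pressure:
            raise
        warnings.warn(
            "window has < 2 pressure samples; imputing Pd = Pdabs = 0 "
            "(flat-ground assumption)",
            UserWarning,
            stacklevel=2,
        )
        pd_val = 0.0
    x_mean, y_mean, z_mean = axis_means(window)
    return FeatureVector(
        pd=pd_val,
        pd_abs=abs(pd_val),
        x_mean=x_mean,
        y_mean=y_mean,
        z_mean=z_mean,
        twave=twave(window),
    )


def feature_table(
    windows: list[Window], impute_missing_pressure: bool = True
) -> pd.DataFrame:
    """Feature matrix for a window list.

    Columns: ``t_start`` + the six features + ``label`` (None when the
    windows are unlabelled).  Row order follows the window order.
    """
    rows = []
    for w in windows:
        fv = extract_features(w, impute_missing_pressure=impute_missing_pressure)
        rows.append({"t_start": w.t_start, **fv.as_dict(), "label": w.label})
    return pd.DataFrame(rows, columns=["t_start", *FEATURE_NAMES, "label"])


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise FeatureUndefinedError(f"feature table missing columns: {sorted(missing)}")
    return df


def write_feature_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
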
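"""Marker filtering and lumbar flexion angle.

Flexion is the sagittal-plane (X-Z) inclination of the L5->L1 marker line
relative to vertical: 0 deg is an upright trunk, 90 deg a horizontal one.
Raw series are smoothed with a zero-phase (forward-backward) Butterworth
low-pass before angles or derivatives are taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    DegenerateGeometryError,
    MissingMarkerError,
    ParameterError,
)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass specification.

    Defaults follow standard motion-capture practice: 4th order, 10 Hz for
    kinematics and 100 Hz for force-plate channels, applied forward and
    backward so the pass is zero-phase (the magnitude response is squared).
    """

    order: int = 4
    cutoff_hz: float = 10.0
    sampling_hz: float = 100.0

    def __post_init__(self) -> None:
        if self.order < 2 or self.order % 2 != 0:
            raise ParameterError("filter order must be even and >= 2")
        if not 0 < self.cutoff_hz < self.sampling_hz / 2:
            raise ParameterError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, Nyquist="
                f"{self.sampling_hz / 2} Hz)"
            )


def butterworth_lowpass(series: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth low-pass; same length as the input."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ParameterError("expected a 1-D series")
    if len(x) < 3 * spec.order:
        raise ParameterError(
            f"series of length {len(x)} too short for order-{spec.order} filtering"
        )
    sos = signal.butter(spec.order, spec.cutoff_hz, fs=spec.sampling_hz, output="sos")
    return signal.sosfiltfilt(sos, x)


@dataclass(frozen=True)
class AngleSeries:
    """Per-frame lumbar flexion angle in degrees."""

    time_s: np.ndarray
    flexion_deg: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        a = np.asarray(self.flexion_deg, dtype=float)
        if t.shape != a.shape:
            raise ParameterError("time and angle series lengths differ")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "flexion_deg", a)

    def __len__(self) -> int:
        return len(self.time_s)


def lumbar_flexion_angle(
    lower: np.ndarray, upper: np.ndarray
) -> float | np.ndarray:
    """Sagittal angle (deg) of the lower->upper line against vertical.

    Accepts single points or (n, 3) stacks, in any consistent length unit.
    """
    v = np.asarray(upper, dtype=float) - np.asarray(lower, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    norm = np.linalg.norm(v[:, [0, 2]], axis=1)
    if np.any(norm == 0):
        raise DegenerateGeometryError("zero-length trunk vector in the sagittal plane")
    ang = np.degrees(np.arctan2(np.abs(v[:, 0]), v[:, 2]))
    return float(ang[0]) if single else ang


def flexion_series(
    markers: pd.DataFrame,
    spec: FilterSpec | None = None,
    lower_label: str = "L5",
    upper_label: str = "L1",
) -> AngleSeries:
    """Flexion angle per frame from a wide-format marker table.

    Marker coordinates are filtered per channel before the angle is formed,
    which keeps additive sensor noise out of the angle nonlinearity.
    """
    time = markers["time_s"].to_numpy(dtype=float)
    if spec is None:
        dt = np.diff(time)
        spec = FilterSpec(sampling_hz=1.0 / float(dt[0])) if len(dt) else FilterSpec()
    pts = {}
    for lab in (lower_label, upper_label):
        cols = [f"{lab}_{ax}" for ax in ("X", "Y", "Z")]
        for c in cols:
            if c not in markers.columns:
                raise MissingMarkerError(f"marker column {c!r} missing")
        raw = markers[cols].to_numpy(dtype=float)
        pts[lab] = np.column_stack([butterworth_lowpass(raw[:, k], spec) for k in range(3)])
    ang = lumbar_flexion_angle(pts[lower_label], pts[upper_label])
    return AngleSeries(time_s=time, flexion_deg=ang)


def range_of_motion(angles: AngleSeries) -> float:
    """Range of motion: max - min of the flexion series, in degrees."""
    if len(angles) == 0:
        raise ParameterError("empty angle series")
    a = angles.flexion_deg
    return float(np.max(a) - np.min(a))
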
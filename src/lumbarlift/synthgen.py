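"""Synthetic deadlift trials with known ground truth.

Each trial prescribes a lumbar flexion curve and a double-peak lumbar
torque curve for one deadlift variant (traditional DL, straight-leg SLDL,
hexagonal/trap-bar TBDL), then constructs marker trajectories, segment
states and external loads that are *exactly* consistent with the prescribed
torque under the rigid-body balance used by inverse dynamics: the barbell
moment arm is solved per frame so the balance closes.  Inverse dynamics run
on the noise-free output therefore recovers the prescribed torque to
machine precision, which is the round-trip oracle the downstream tests use.

Sampling follows optical motion capture at 100 Hz and a force platform at
500 Hz.  Axes: X sagittal (facing direction positive), Y coronal (left
positive), Z vertical (up).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .dynamics import (
    GRAVITY_M_S2,
    ExternalLoad,
    SegmentState,
    TrunkModel,
    WorldConfig,
    newton_euler_torque,
    rotation_about_y,
    sagittal_torque,
)
from .errors import ConfigurationError, OutOfRangeError, ParameterError

MARKER_HZ = 100.0
FORCE_HZ = 500.0

#: Marker labels emitted by the generator (a named subset of the full
#: 49-point layout: lumbar/thoracic spine line, pelvis, barbell midpoints).
MARKER_LABELS = (
    "C7",
    "T2",
    "L1",
    "L3",
    "L5",
    "R_ASIS",
    "L_ASIS",
    "R_PSIS",
    "L_PSIS",
    "BAR_MID_L",
    "BAR_MID_R",
)

#: Newtons of force-plate noise per millimetre of marker noise, so a single
#: noise switch scales both sensors.
GRF_NOISE_N_PER_MM = 4.0


@dataclass(frozen=True)
class ActionTemplate:
    """Parametric description of one deadlift variant.

    ``flexion_start_deg``/``flexion_end_deg`` bound the lumbar flexion
    excursion (end = bottom position, start = lockout); the torque curve
    runs through a configurable baseline at the start of the pull, two
    peaks at ``peak_time_fractions`` of the trial and a trough between
    them.  Peak torques are in newton-metres.
    """

    action_id: str
    flexion_start_deg: float
    flexion_end_deg: float
    first_peak_torque_Nm: float
    second_peak_torque_Nm: float
    peak_time_fractions: tuple[float, float]
    trial_duration_s: float = 2.0
    barbell_mass_kg: float = 120.0
    noise_sd_mm: float = 0.5
    seed: int = 0
    baseline_fraction: float = 0.6
    trough_fraction: float = 0.5
    end_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.action_id not in ("DL", "SLDL", "TBDL"):
            raise ParameterError(f"unknown action_id {self.action_id!r}")
        if self.flexion_end_deg < self.flexion_start_deg:
            raise ParameterError("flexion_end_deg must be >= flexion_start_deg")
        if not self.second_peak_torque_Nm < self.first_peak_torque_Nm:
            raise ParameterError("second torque peak must be below the first")
        f1, f2 = self.peak_time_fractions
        if not 0 < f1 < f2 < 1:
            raise ParameterError("peak_time_fractions must be strictly increasing in (0,1)")
        if self.trial_duration_s <= 0 or self.barbell_mass_kg <= 0:
            raise ParameterError("duration and barbell mass must be positive")
        if self.noise_sd_mm < 0:
            raise ParameterError("noise SD cannot be negative")

    @property
    def baseline_torque_Nm(self) -> float:
        return self.baseline_fraction * self.first_peak_torque_Nm

    def with_noise(self, noise_sd_mm: float) -> "ActionTemplate":
        return replace(self, noise_sd_mm=noise_sd_mm)


def _torque_knots(template: ActionTemplate):
    T = template.trial_duration_s
    f1, f2 = template.peak_time_fractions
    p1 = template.first_peak_torque_Nm
    knots_t = np.array([0.0, f1 * T, 0.5 * (f1 + f2) * T, f2 * T, T])
    knots_q = np.array(
        [
            template.baseline_torque_Nm,
            p1,
            template.trough_fraction * p1,
            template.second_peak_torque_Nm,
            template.end_fraction * p1,
        ]
    )
    return knots_t, knots_q


def torque_template(template: ActionTemplate, t: float | np.ndarray) -> float | np.ndarray:
    """Prescribed lumbar torque (N*m) at time ``t``.

    A monotone piecewise-cubic (PCHIP) spline through the baseline, first
    peak, trough, second peak and end knots: C1, no overshoot, exactly two
    interior maxima with one minimum between them.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > template.trial_duration_s):
        raise OutOfRangeError(
            f"time query outside [0, {template.trial_duration_s}] s"
        )
    knots_t, knots_q = _torque_knots(template)
    out = PchipInterpolator(knots_t, knots_q)(t_arr)
    return float(out) if np.isscalar(t) else out


def flexion_template(template: ActionTemplate, t: float | np.ndarray) -> float | np.ndarray:
    """Prescribed lumbar flexion (deg): cosine ramp from bottom to lockout.

    Monotone decrease from ``flexion_end_deg`` at t=0 (deepest flexion) to
    ``flexion_start_deg`` at the end of the lift, with zero end slopes.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > template.trial_duration_s):
        raise OutOfRangeError(
            f"time query outside [0, {template.trial_duration_s}] s"
        )
    lo, hi = template.flexion_start_deg, template.flexion_end_deg
    out = lo + (hi - lo) * 0.5 * (1.0 + np.cos(np.pi * t_arr / template.trial_duration_s))
    return float(out) if np.isscalar(t) else out


def _flexion_derivatives(template: ActionTemplate, t: np.ndarray):
    """Analytic first/second derivatives of the flexion curve, in rad/s(^2)."""
    lo, hi = np.radians(template.flexion_start_deg), np.radians(template.flexion_end_deg)
    w = np.pi / template.trial_duration_s
    theta = lo + (hi - lo) * 0.5 * (1.0 + np.cos(w * t))
    dtheta = -(hi - lo) * 0.5 * w * np.sin(w * t)
    ddtheta = -(hi - lo) * 0.5 * w**2 * np.cos(w * t)
    return theta, dtheta, ddtheta


@dataclass(frozen=True)
class SyntheticTrial:
    """One generated deadlift trial with its ground truth.

    ``markers``: wide table (frame, time_s, LABEL_X/Y/Z in mm) at 100 Hz;
    ``grf``: (sample, time_s, Fx, Fy, Fz, COPx, COPy) at 500 Hz;
    ``segment_states`` / ``loads``: exact per-frame kinematic states and
    external loads of the supra-L1 trunk segment; ``truth_torque``: the
    prescribed extensor torque (N*m) at marker frames.
    """

    template: ActionTemplate
    trunk: TrunkModel
    markers: pd.DataFrame
    grf: pd.DataFrame
    segment_states: list
    loads: list
    truth_torque: np.ndarray
    truth_flexion_deg: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.markers)


def generate_trial(
    template: ActionTemplate,
    trunk: TrunkModel | None = None,
    world: WorldConfig | None = None,
    marker_hz: float = MARKER_HZ,
    force_hz: float = FORCE_HZ,
) -> SyntheticTrial:
    """Generate a trial whose states/loads reproduce the prescribed torque.

    The trunk rotates about a fixed L1 joint centre following the flexion
    template; the barbell acts as its static weight on a vertical line
    whose sagittal moment arm is solved per frame so that the rigid-body
    balance yields exactly the template torque.
    """
    trunk = trunk or TrunkModel()
    world = world or WorldConfig()
    T = template.trial_duration_s
    n_m = round(T * marker_hz)
    n_f = round(T * force_hz)
    if abs(n_m - T * marker_hz) > 1e-9 or abs(n_f - T * force_hz) > 1e-9:
        raise ConfigurationError("trial duration is not a whole number of samples")
    if force_hz % marker_hz != 0:
        raise ConfigurationError("force rate must be an integer multiple of the marker rate")
    t_m = np.arange(n_m + 1) / marker_hz
    t_f = np.arange(n_f + 1) / force_hz

    theta, dtheta, ddtheta = _flexion_derivatives(template, t_m)
    truth_q = np.asarray(torque_template(template, t_m), dtype=float)

    inertia = trunk.inertia()
    d = float(np.linalg.norm(inertia.com_offset_local))
    p_j = np.asarray(trunk.joint_position_m, dtype=float)
    u = np.column_stack([np.sin(theta), np.zeros_like(theta), np.cos(theta)])
    du = np.column_stack([np.cos(theta), np.zeros_like(theta), -np.sin(theta)])
    com = p_j + d * u
    # a_c = d * (theta'' * du + theta'^2 * d(du)) with d(du)/dtheta = -u
    a_com = d * (ddtheta[:, None] * du - (dtheta**2)[:, None] * u)

    bar_weight = template.barbell_mass_kg * GRAVITY_M_S2
    bar_z = 0.25 + 0.45 * 0.5 * (1.0 - np.cos(np.pi * t_m / T))

    states, loads = [], []
    bar_x = np.empty(n_m + 1)
    for i in range(n_m + 1):
        state = SegmentState(
            orientation=rotation_about_y(theta[i]),
            angular_velocity=np.array([0.0, dtheta[i], 0.0]),
            angular_acceleration=np.array([0.0, ddtheta[i], 0.0]),
            com_position=com[i],
            com_acceleration=a_com[i],
            joint_position=p_j,
        )
        trunk_tau = sagittal_torque(newton_euler_torque(state, inertia, [], world))
        bar_x[i] = (truth_q[i] - trunk_tau) / bar_weight
        load = ExternalLoad(
            force_N=np.array([0.0, 0.0, -bar_weight]),
            point_from_joint_m=np.array([bar_x[i], 0.0, bar_z[i] - p_j[2]]),
        )
        states.append(state)
        loads.append(load)

    rng = np.random.default_rng(template.seed)
    markers = _marker_table(template, trunk, t_m, u, bar_x, bar_z, p_j, rng)
    grf = _grf_table(template, trunk, t_f, rng)
    return SyntheticTrial(
        template=template,
        trunk=trunk,
        markers=markers,
        grf=grf,
        segment_states=states,
        loads=loads,
        truth_torque=truth_q,
        truth_flexion_deg=np.degrees(theta),
    )


def _marker_table(template, trunk, t_m, u, bar_x, bar_z, p_j, rng) -> pd.DataFrame:
    n = len(t_m)
    pos = {}
    for lab, off in trunk.marker_offsets_m.items():
        pos[lab] = p_j + off * u
    half_pelvis = 0.13
    pos["R_ASIS"] = np.tile(p_j + [0.10, -half_pelvis, -0.08], (n, 1))
    pos["L_ASIS"] = np.tile(p_j + [0.10, half_pelvis, -0.08], (n, 1))
    pos["R_PSIS"] = np.tile(p_j + [-0.06, -half_pelvis * 0.6, -0.06], (n, 1))
    pos["L_PSIS"] = np.tile(p_j + [-0.06, half_pelvis * 0.6, -0.06], (n, 1))
    bar = np.column_stack([p_j[0] + bar_x, np.zeros(n), bar_z])
    pos["BAR_MID_L"] = bar + [0.0, 0.25, 0.0]
    pos["BAR_MID_R"] = bar + [0.0, -0.25, 0.0]

    data = {"frame": np.arange(n), "time_s": t_m}
    for lab in MARKER_LABELS:
        xyz = pos[lab] * 1000.0  # m -> mm
        if template.noise_sd_mm > 0:
            xyz = xyz + rng.normal(0.0, template.noise_sd_mm, xyz.shape)
        for k, ax in enumerate("XYZ"):
            data[f"{lab}_{ax}"] = xyz[:, k]
    return pd.DataFrame(data)


def _grf_table(template, trunk, t_f, rng) -> pd.DataFrame:
    n = len(t_f)
    fz = np.full(n, (trunk.subject_mass_kg + template.barbell_mass_kg) * GRAVITY_M_S2)
    if template.noise_sd_mm > 0:
        fz = fz + rng.normal(0.0, GRF_NOISE_N_PER_MM * template.noise_sd_mm, n)
    return pd.DataFrame(
        {
            "sample": np.arange(n),
            "time_s": t_f,
            "Fx": np.zeros(n),
            "Fy": np.zeros(n),
            "Fz": fz,
            "COPx": np.full(n, 60.0),
            "COPy": np.zeros(n),
        }
    )


def recover_torque_from_states(trial: SyntheticTrial, world: WorldConfig | None = None) -> np.ndarray:
    """Exact inverse dynamics on the trial's own states and loads.

    This is the round-trip identity: evaluating the rigid-body balance on
    the stored analytic states must reproduce ``truth_torque`` to floating
    point precision.
    """
    inertia = trial.trunk.inertia()
    return np.array(
        [
            sagittal_torque(newton_euler_torque(s, inertia, [l], world))
            for s, l in zip(trial.segment_states, trial.loads)
        ]
    )
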
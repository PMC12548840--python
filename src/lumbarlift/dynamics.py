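"""Lumbar joint torque by Newton-Euler inverse dynamics, and lift phases.

The trunk above the L1 vertebra is modelled as a single rigid segment
rotating in the sagittal (X-Z) plane about a fixed L1 joint centre.  The
joint moment follows the rigid-body balance, with moments taken about the
joint centre:

    tau = I_c a + w x (I_c w) + m r_c x (a_c - g) - sum_k r_k x F_k

where ``I_c`` is the segment inertia about its centroid, ``w``/``a`` the
angular velocity/acceleration, ``r_c`` the joint-to-centroid vector,
``a_c`` the centroid acceleration, ``g`` gravity and ``F_k`` the external
loads applied at ``r_k`` from the joint.  The scalar lumbar torque reported
everywhere is the sagittal (Y) component with extensor effort positive.

Axis convention: X sagittal (facing direction positive), Y coronal (left
positive), Z vertical (up positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigurationError, ParameterError, SegmentationError
from .kinematics import FilterSpec, butterworth_lowpass, flexion_series

GRAVITY_M_S2 = 9.81


def elliptical_frustum_mass(
    a1: float, b1: float, a2: float, b2: float, h: float, density: float
) -> float:
    """Mass of a solid elliptical frustum (torso idealisation).

    The torso above L1 is treated as a frustum whose elliptical
    cross-section tapers linearly from semi-axes ``(a1, b1)`` to
    ``(a2, b2)`` over height ``h``:

        m = rho * (pi h / 3) * (a1 b1 + a2 b2 + sqrt(a1 b1 a2 b2))

    All lengths in metres, density in kg/m^3.
    """
    if min(a1, b1, a2, b2) < 0:
        raise ParameterError("semi-axes must be non-negative")
    if h <= 0 or density <= 0:
        raise ParameterError("height and density must be positive")
    s1, s2 = a1 * b1, a2 * b2
    if s1 == 0 and s2 == 0:
        raise ParameterError("both end ellipses are degenerate")
    return density * (np.pi * h / 3.0) * (s1 + s2 + np.sqrt(s1 * s2))


@dataclass(frozen=True)
class WorldConfig:
    """Gravity vector and the axis convention tag."""

    gravity: tuple[float, float, float] = (0.0, 0.0, -GRAVITY_M_S2)
    axes: str = "X-sagittal/Y-coronal/Z-up"

    def __post_init__(self) -> None:
        g = float(np.linalg.norm(self.gravity))
        if abs(g - GRAVITY_M_S2) > 0.01:
            raise ParameterError(f"|gravity| = {g:.4f}, expected {GRAVITY_M_S2}")

    @property
    def g(self) -> np.ndarray:
        return np.asarray(self.gravity, dtype=float)


@dataclass(frozen=True)
class SegmentInertia:
    """Inertial parameters of the supra-L1 trunk segment.

    ``com_offset_local`` is the joint-to-centroid vector expressed in the
    segment frame (local z along the trunk axis); ``inertia_local`` is the
    centroidal inertia tensor in the same frame.
    """

    mass_kg: float
    inertia_local: np.ndarray
    com_offset_local: np.ndarray

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ParameterError("segment mass must be positive")
        I = np.asarray(self.inertia_local, dtype=float)
        if I.shape != (3, 3) or not np.allclose(I, I.T, atol=1e-12):
            raise ParameterError("inertia tensor must be symmetric 3x3")
        if np.any(np.linalg.eigvalsh(I) < -1e-12):
            raise ParameterError("inertia tensor must be positive semi-definite")
        object.__setattr__(self, "inertia_local", I)
        object.__setattr__(
            self, "com_offset_local", np.asarray(self.com_offset_local, dtype=float)
        )


@dataclass(frozen=True)
class SegmentState:
    """Kinematic state of the trunk segment at one frame (SI units)."""

    orientation: np.ndarray  # 3x3 rotation, local -> world
    angular_velocity: np.ndarray  # rad/s, world frame
    angular_acceleration: np.ndarray  # rad/s^2, world frame
    com_position: np.ndarray  # m, world frame
    com_acceleration: np.ndarray  # m/s^2, world frame
    joint_position: np.ndarray  # m, world frame (L1 joint centre)


@dataclass(frozen=True)
class ExternalLoad:
    """A force applied to the trunk segment at a point relative to the joint."""

    force_N: np.ndarray
    point_from_joint_m: np.ndarray


@dataclass(frozen=True)
class TrunkModel:
    """Anthropometric model tying the generator and inverse dynamics together.

    The trunk is an elliptical frustum of the given dimensions; its mass,
    centroid distance and a slender-rod inertia are derived from them.
    Marker geometry (distances of the L5/L1/L3/T2/C7 markers from the joint
    along the trunk line) lets inverse dynamics reconstruct the joint
    centre from markers alone.
    """

    frustum_a1_m: float = 0.17
    frustum_b1_m: float = 0.12
    frustum_a2_m: float = 0.16
    frustum_b2_m: float = 0.11
    frustum_h_m: float = 0.50
    density_kg_m3: float = 1050.0
    com_distance_m: float = 0.25
    subject_mass_kg: float = 75.0
    joint_position_m: tuple[float, float, float] = (0.0, 0.0, 1.00)
    marker_offsets_m: dict = field(
        default_factory=lambda: {"L5": -0.05, "L1": 0.10, "L3": 0.025, "T2": 0.35, "C7": 0.45}
    )

    @property
    def mass_kg(self) -> float:
        return elliptical_frustum_mass(
            self.frustum_a1_m,
            self.frustum_b1_m,
            self.frustum_a2_m,
            self.frustum_b2_m,
            self.frustum_h_m,
            self.density_kg_m3,
        )

    def inertia(self) -> SegmentInertia:
        # Slender-rod transverse inertia about the centroid; negligible
        # axial term keeps the tensor SPD without affecting planar motion.
        m = self.mass_kg
        i_t = m * self.frustum_h_m**2 / 12.0
        I = np.diag([i_t, i_t, 0.02 * i_t])
        return SegmentInertia(
            mass_kg=m,
            inertia_local=I,
            com_offset_local=np.array([0.0, 0.0, self.com_distance_m]),
        )


def rotation_about_y(theta_rad: float | np.ndarray) -> np.ndarray:
    """Right-handed rotation about +Y; maps local +z to the tilted trunk axis."""
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def newton_euler_torque(
    state: SegmentState,
    inertia: SegmentInertia,
    loads: Sequence[ExternalLoad],
    world: WorldConfig | None = None,
) -> np.ndarray:
    """Joint moment vector (N*m) of the rigid-body balance at one frame."""
    world = world or WorldConfig()
    R = np.asarray(state.orientation, dtype=float)
    w = np.asarray(state.angular_velocity, dtype=float)
    a = np.asarray(state.angular_acceleration, dtype=float)
    if not (np.all(np.isfinite(R)) and np.all(np.isfinite(w)) and np.all(np.isfinite(a))):
        raise ParameterError("non-finite segment state")
    I_w = R @ inertia.inertia_local @ R.T
    r_c = np.asarray(state.com_position) - np.asarray(state.joint_position)
    a_rel = np.asarray(state.com_acceleration, dtype=float) - world.g
    tau = I_w @ a + np.cross(w, I_w @ w) + inertia.mass_kg * np.cross(r_c, a_rel)
    for load in loads:
        tau -= np.cross(
            np.asarray(load.point_from_joint_m, dtype=float),
            np.asarray(load.force_N, dtype=float),
        )
    return tau


def sagittal_torque(tau: np.ndarray) -> float:
    """Scalar lumbar torque: sagittal (Y) component, extensor positive.

    With X anterior and Z up, gravity and the barbell flex the trunk with a
    negative Y moment; the extensor effort opposing them is reported
    positive.
    """
    return -float(np.asarray(tau)[1])


@dataclass(frozen=True)
class TorqueSeries:
    """Per-frame sagittal lumbar torque (N*m), extensor positive."""

    time_s: np.ndarray
    torque_Nm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        q = np.asarray(self.torque_Nm, dtype=float)
        if t.shape != q.shape:
            raise ConfigurationError("time and torque series lengths differ")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "torque_Nm", q)

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class PhaseSegmentation:
    """Four contiguous frame intervals delimited by the two torque peaks.

    ``intervals`` maps phase name -> (start_frame, end_frame) inclusive;
    boundary frames are shared so the phases jointly cover the whole lift.
    """

    intervals: dict
    peak_frames: tuple[int, int]
    trough_frame: int

    PHASES = ("first_pull", "transition", "second_pull", "standing")

    def __post_init__(self) -> None:
        prev_end = None
        for name in self.PHASES:
            s, e = self.intervals[name]
            if e < s:
                raise SegmentationError(f"phase {name} has negative extent")
            if prev_end is not None and s != prev_end:
                raise SegmentationError("phases are not contiguous")
            prev_end = e


def segment_phases(torque: TorqueSeries, prominence_frac: float = 0.05) -> PhaseSegmentation:
    """Split a lift into first pull / transition / second pull / standing.

    Peaks are strict local maxima with prominence at least
    ``prominence_frac`` of the series range; the two most prominent ones
    (earliest first on ties) delimit the phases, with the trough at the
    minimum between them.
    """
    q = np.asarray(torque.torque_Nm, dtype=float)
    rng = float(q.max() - q.min())
    if rng <= 0:
        raise SegmentationError("torque series is constant; no peaks to segment")
    peaks, props = find_peaks(q, prominence=prominence_frac * rng)
    if len(peaks) < 2:
        raise SegmentationError(
            f"found {len(peaks)} torque peak(s); the four-phase split needs two"
        )
    order = np.argsort(-props["prominences"], kind="stable")[:2]
    p1, p2 = sorted(int(peaks[i]) for i in order)
    trough = p1 + int(np.argmin(q[p1 : p2 + 1]))
    n = len(q)
    intervals = {
        "first_pull": (0, p1),
        "transition": (p1, trough),
        "second_pull": (trough, p2),
        "standing": (p2, n - 1),
    }
    return PhaseSegmentation(intervals=intervals, peak_frames=(p1, p2), trough_frame=trough)


def lumbar_torque_series(
    trial,
    trunk: TrunkModel | None = None,
    kin_filter: FilterSpec | None = None,
    force_filter: FilterSpec | None = None,
    world: WorldConfig | None = None,
) -> TorqueSeries:
    """Inverse dynamics on a trial's marker and force-plate tables.

    Kinematics are low-passed at 10 Hz and forces at 100 Hz (4th-order
    zero-phase Butterworth) before derivatives are taken by second-order
    central differences.  The barbell load is recovered from the vertical
    ground reaction minus the subject's weight (quasi-static barbell) and
    applied at the barbell marker midpoint.
    """
    if trial.grf is None:
        raise ConfigurationError("trial has no force-plate series")
    trunk = trunk if trunk is not None else getattr(trial, "trunk", None) or TrunkModel()
    world = world or WorldConfig()

    markers = trial.markers
    fs_m = _sampling_hz(markers["time_s"].to_numpy())
    kin_filter = kin_filter or FilterSpec(order=4, cutoff_hz=10.0, sampling_hz=fs_m)
    angles = flexion_series(markers, spec=kin_filter)
    theta = np.radians(angles.flexion_deg)
    t = angles.time_s
    dt = t[1] - t[0]

    # Trunk line and joint centre from the filtered L5/L1 markers (mm -> m).
    filt = {
        lab: np.column_stack(
            [
                butterworth_lowpass(markers[f"{lab}_{ax}"].to_numpy(), kin_filter)
                for ax in ("X", "Y", "Z")
            ]
        )
        / 1000.0
        for lab in ("L5", "L1", "BAR_MID_L", "BAR_MID_R")
    }
    u = np.column_stack([np.sin(theta), np.zeros_like(theta), np.cos(theta)])
    joint = filt["L5"] - trunk.marker_offsets_m["L5"] * u
    inertia = trunk.inertia()
    d = float(np.linalg.norm(inertia.com_offset_local))
    com = joint + d * u

    omega = np.gradient(theta, dt)
    alpha = np.gradient(omega, dt)
    a_com = np.empty_like(com)
    for k in range(3):
        a_com[:, k] = np.gradient(np.gradient(com[:, k], dt), dt)

    # Barbell force from the force plate, resampled onto marker frames.
    grf_t = trial.grf["time_s"].to_numpy()
    fs_f = _sampling_hz(grf_t)
    force_filter = force_filter or FilterSpec(order=4, cutoff_hz=100.0, sampling_hz=fs_f)
    fz = butterworth_lowpass(trial.grf["Fz"].to_numpy(), force_filter)
    step = int(round(fs_f / fs_m))
    if step < 1 or len(fz[::step]) < len(t):
        raise ConfigurationError("force series too short for the marker series")
    fz_m = fz[::step][: len(t)]
    bar_weight = fz_m - trunk.subject_mass_kg * GRAVITY_M_S2
    bar_point = 0.5 * (filt["BAR_MID_L"] + filt["BAR_MID_R"])

    tau = np.empty(len(t))
    for i in range(len(t)):
        state = SegmentState(
            orientation=rotation_about_y(theta[i]),
            angular_velocity=np.array([0.0, omega[i], 0.0]),
            angular_acceleration=np.array([0.0, alpha[i], 0.0]),
            com_position=com[i],
            com_acceleration=a_com[i],
            joint_position=joint[i],
        )
        load = ExternalLoad(
            force_N=np.array([0.0, 0.0, -bar_weight[i]]),
            point_from_joint_m=bar_point[i] - joint[i],
        )
        tau[i] = sagittal_torque(newton_euler_torque(state, inertia, [load], world))
    return TorqueSeries(time_s=t, torque_Nm=tau)


def first_peak_torque(torque: TorqueSeries) -> float:
    """Maximum torque within the first hard-pull phase."""
    seg = segment_phases(torque)
    s, e = seg.intervals["first_pull"]
    return float(np.max(torque.torque_Nm[s : e + 1]))


def _sampling_hz(time_s: np.ndarray) -> float:
    dt = np.diff(time_s)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ConfigurationError("series is not uniformly sampled")
    return 1.0 / float(dt[0])
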
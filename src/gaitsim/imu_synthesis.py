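"""Synthesis of triaxial accelerometer and gyroscope signals.

The accelerometer model is additive: the measured acceleration is the sum of
the motion-induced (dynamic) component and the per-axis gravity share,

    a(t) = a_d(t) + a_g(t),

with ``a_d`` the second time derivative of the world sensor position rotated
into the sensor frame, and ``a_g = Q_s(t) j g`` where ``j = (0, 1, 0)`` is
the gravity-carrying global axis and ``g = 9.81 m/s^2``; hence
``||a_g(t)|| = g`` at every sample.  An accelerometer at rest reads
``(0, g, 0)`` in an upright sensor frame (reaction convention).

Angular velocity is extracted from the skew-symmetric body-rate matrix
``Omega(t) = Q_s(t) dQ_s/dt^T`` (central differences), which for a segment
rotating at ``+w`` about the global z axis yields ``omega_z = +w`` in an
aligned sensor frame.

Derivatives use second-order central differences with one-sided stencils of
the same order at the edges, so the dynamic-acceleration error against an
analytic trajectory shrinks ~4x when the sampling rate doubles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, savgol_filter, sosfiltfilt, sosfilt

from .errors import AliasingError, FilterError, InsufficientDataError
from .kinematics_io import G, GRAVITY_AXIS, SensorTrajectory

RAD2DEG = 180.0 / np.pi


@dataclass
class FilterSpec:
    """The preprocessing chain applied to assembled signals.

    Butterworth low-passes (order 2) at 17 Hz for acceleration and 15 Hz for
    angular velocity, optionally followed by a Savitzky-Golay smoother
    (order 5, window 35 samples) to remove outliers.  ``marker_prefilter_hz``
    is the 6 Hz low-pass used upstream on kinematic inputs.
    """

    accel_cutoff_hz: float = 17.0
    gyro_cutoff_hz: float = 15.0
    butter_order: int = 2
    savgol_order: int = 5
    savgol_window: int = 35
    marker_prefilter_hz: float = 6.0
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.accel_cutoff_hz < nyq and 0 < self.gyro_cutoff_hz < nyq):
            raise FilterError(f"cutoffs must lie in (0, {nyq}) Hz")
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise FilterError("savgol window must be odd and > order")


@dataclass
class ImuSignal:
    """Synthesised triaxial IMU channels in the sensor frame.

    ``a`` is the filtered assembled acceleration [m/s^2], ``omega`` the
    filtered angular velocity [rad/s].  The unfiltered dynamic and gravity
    components remain retrievable as ``a_dyn``/``a_grav`` (their sum is the
    unfiltered ``a_raw``).  Convenience accessors expose the vertical
    acceleration axis ``a_y`` and the medio-lateral gyro axis ``omega_z``
    used by the gait detectors.
    """

    t: np.ndarray
    a: np.ndarray
    omega: np.ndarray
    a_dyn: np.ndarray
    a_grav: np.ndarray
    omega_raw: np.ndarray
    fs: float = 100.0

    def __len__(self) -> int:
        return len(self.t)

    @property
    def a_raw(self) -> np.ndarray:
        return self.a_dyn + self.a_grav

    @property
    def a_y(self) -> np.ndarray:
        return self.a[:, 1]

    @property
    def omega_z(self) -> np.ndarray:
        return self.omega[:, 2]

    @property
    def omega_deg(self) -> np.ndarray:
        """Angular velocity in deg/s (reporting units)."""
        return self.omega * RAD2DEG

    def slice(self, t0: float, t1: float) -> "ImuSignal":
        """Samples with t0 <= t < t1."""
        m = (self.t >= t0) & (self.t < t1)
        return ImuSignal(self.t[m], self.a[m], self.omega[m], self.a_dyn[m],
                         self.a_grav[m], self.omega_raw[m], fs=self.fs)


def _second_derivative(x: np.ndarray, dt: float) -> np.ndarray:
    """Central second difference, one-sided (shifted stencil) at the edges."""
    d2 = np.empty_like(x)
    d2[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) / dt**2
    d2[0] = (x[0] - 2.0 * x[1] + x[2]) / dt**2
    d2[-1] = (x[-1] - 2.0 * x[-2] + x[-3]) / dt**2
    return d2


def dynamic_acceleration(st: SensorTrajectory) -> np.ndarray:
    """Motion-induced acceleration in the sensor frame [m/s^2]."""
    if len(st) < 5:
        raise InsufficientDataError("need >= 5 samples for dynamic acceleration")
    dt = 1.0 / st.fs
    a_world = _second_derivative(st.k, dt)
    return np.einsum("nij,nj->ni", st.Q_s, a_world)


def gravity_acceleration(st: SensorTrajectory) -> np.ndarray:
    """Per-axis gravity share in the sensor frame; norm is g everywhere."""
    return G * np.einsum("nij,j->ni", st.Q_s, GRAVITY_AXIS)


def _skew_to_vec(M: np.ndarray) -> np.ndarray:
    """Extract the axial vector of (the skew part of) a stack of matrices."""
    return 0.5 * np.stack([M[..., 2, 1] - M[..., 1, 2],
                           M[..., 0, 2] - M[..., 2, 0],
                           M[..., 1, 0] - M[..., 0, 1]], axis=-1)


def angular_velocity(st: SensorTrajectory, max_step: float = np.pi / 2) -> np.ndarray:
    """Sensor-frame angular velocity [rad/s] from the orientation stream.

    The body rate is the axial vector of ``Q dQ/dt^T`` where ``Q`` maps
    global into sensor coordinates.  Rotation increments larger than
    ``max_step`` per sample are rejected as aliased.
    """
    if len(st) < 3:
        raise InsufficientDataError("need >= 3 samples for angular velocity")
    Q = st.Q_s
    dt = 1.0 / st.fs
    rel = np.einsum("nij,nkj->nik", Q[1:], Q[:-1])  # Q[i+1] Q[i]^T
    cosang = np.clip((np.trace(rel, axis1=1, axis2=2) - 1.0) / 2.0, -1.0, 1.0)
    if np.any(np.arccos(cosang) > max_step):
        raise AliasingError("per-sample rotation increment exceeds pi/2")
    Qd = np.empty_like(Q)
    Qd[1:-1] = (Q[2:] - Q[:-2]) / (2.0 * dt)
    Qd[0] = (Q[1] - Q[0]) / dt
    Qd[-1] = (Q[-1] - Q[-2]) / dt
    Omega = np.einsum("nij,nkj->nik", Q, Qd)  # Q Qd^T = skew(body rate)
    return _skew_to_vec(Omega)


def _lowpass(x: np.ndarray, fs: float, cutoff: float, order: int,
             zero_phase: bool) -> np.ndarray:
    sos = butter(order, cutoff, btype="low", fs=fs, output="sos")
    if zero_phase:
        return sosfiltfilt(sos, x, axis=0)
    return sosfilt(sos, x, axis=0)


def synthesize_imu(st: SensorTrajectory, spec: FilterSpec | None = None,
                   smooth: bool = True) -> ImuSignal:
    """Assemble and filter the full IMU signal for one sensor trajectory.

    The gravity share is computed on the unfiltered orientation stream; the
    low-pass and optional Savitzky-Golay smoother act on the assembled
    acceleration and angular velocity channels only.
    """
    spec = spec or FilterSpec()
    spec.validate(st.fs)
    a_d = dynamic_acceleration(st)
    a_g = gravity_acceleration(st)
    w = angular_velocity(st)
    a = a_d + a_g
    n = len(st)
    min_len = 3 * (2 * spec.butter_order + 1)  # sosfiltfilt padlen requirement
    if n <= min_len:
        raise FilterError(f"series of {n} samples too short to filter")
    a_f = _lowpass(a, st.fs, spec.accel_cutoff_hz, spec.butter_order, spec.zero_phase)
    w_f = _lowpass(w, st.fs, spec.gyro_cutoff_hz, spec.butter_order, spec.zero_phase)
    if smooth:
        if spec.savgol_window >= n:
            raise FilterError("savgol window >= series length")
        a_f = savgol_filter(a_f, spec.savgol_window, spec.savgol_order, axis=0)
        w_f = savgol_filter(w_f, spec.savgol_window, spec.savgol_order, axis=0)
    return ImuSignal(t=st.t.copy(), a=a_f, omega=w_f, a_dyn=a_d, a_grav=a_g,
                     omega_raw=w, fs=st.fs)
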
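"""Synthetic bilateral gait scenarios with exact event ground truth.

The generator emulates treadmill-style periodic sagittal-plane gait at the
segment-kinematics level: per-side stride sequences (optionally jittered and
asymmetric) drive phase-anchored periodic angle profiles for upper leg,
lower leg and shoe, plus segment-origin translations carrying impact and
push-off transients.  Events are anchored at fixed stride fractions:

    IC  at phase 0.0           (vertical-acceleration impact peak)
    MSt at 0.5 * stance        (quiet mid-stance)
    TO  at stance_fraction     (gyro trough; accel trough 20 ms earlier)
    MSw at stance + 0.5*swing  (gyro peak)

With symmetric timing the contralateral side is offset by exactly half a
stride, so the contralateral gyro MSw peak coincides with the ipsilateral
MSt anchor -- which is precisely the signal morphology the bilateral MSt
rule expects.  The sagittal angular-velocity profile has exactly one
positive-to-negative zero crossing per stride, shortly before IC.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .errors import GeometryError, ScenarioError
from .kinematics_io import GrfTrace, SegmentTrajectory
from .sensor_grid import SensorPlacement, _ring_frame

# ---------------------------------------------------------------------------
# periodic profiles (phase in [0, 1])
# ---------------------------------------------------------------------------

# sagittal angular-rate *shape* per segment family: a flat negative stance
# baseline plus wrapped Gaussian bumps (centre phase, width, amplitude).
# Leg: trough at the TO anchor (0.62), swing peak at the MSw anchor (0.81)
# and a short positive pre-IC bump whose decay produces the single
# positive-to-negative zero crossing just before the next IC.
_LEG_RATE_BUMPS = ((0.62, 0.030, -3.0), (0.81, 0.050, 4.0),
                   (0.92, 0.035, 1.5))
# Foot: same event bumps, flatter mid-stance (foot-flat), early-stance
# heel-rock dip absorbing most of the mean correction.
_FOOT_RATE_BUMPS = ((0.15, 0.080, -1.0), (0.62, 0.030, -3.0),
                    (0.81, 0.050, 3.5), (0.92, 0.035, 1.2))

_PHASE_GRID = np.linspace(0.0, 1.0, 4001)


def _wrapped_gaussian(phi: np.ndarray, centre: float, width: float) -> np.ndarray:
    d = np.mod(phi - centre + 0.5, 1.0) - 0.5
    return np.exp(-0.5 * (d / width) ** 2)


def _angle_profile(bumps) -> CubicSpline:
    """Periodic angle profile whose phase-derivative is the bump rate shape.

    The rate is shifted to zero mean (so the angle closes over a cycle); a
    constant shift preserves the phase location of every rate extremum, and
    the bump construction keeps exactly one positive-to-negative zero
    crossing per cycle, shortly before IC.
    """
    rate = np.zeros_like(_PHASE_GRID)
    for centre, width, amp in bumps:
        rate += amp * _wrapped_gaussian(_PHASE_GRID, centre, width)
    rate -= np.trapezoid(rate, _PHASE_GRID)
    angle = np.concatenate([[0.0], np.cumsum(
        0.5 * (rate[1:] + rate[:-1]) * np.diff(_PHASE_GRID))])
    angle[-1] = angle[0]  # closed by construction up to fp error
    return CubicSpline(_PHASE_GRID, angle, bc_type="periodic")

_LEG_ANGLE = _angle_profile(_LEG_RATE_BUMPS)
_FOOT_ANGLE = _angle_profile(_FOOT_RATE_BUMPS)

#: amplitude [rad] applied to the unit angle profiles per segment type
_ANGLE_AMPLITUDE = {"upper_leg": 0.35, "lower_leg": 0.6, "shoe": 0.5}
_SEGMENT_HEIGHT = {"upper_leg": 0.95, "lower_leg": 0.52, "shoe": 0.12}

# vertical transient magnitudes (as peak accelerations) and width:
# transients are wide enough to pass the 17 Hz / Savitzky-Golay chain
# essentially unchanged, and the amplitudes are balanced so that (a) the
# push-off trough is deeper than the impact transient's negative sidelobes
# and (b) every transient sidelobe is either suppressed by the 0.6 s
# minimum-peak-distance rule or falls below the trained height thresholds
_A_IC = 10.0   # m/s^2, impact peak at IC
_A_TO = 6.0    # m/s^2, trough at push-off
_SIGMA = 0.08  # s, transient width
_TO_LEAD = 0.02  # s, accel trough precedes the gyro trough at TO
_BOUNCE = 0.002  # m, 2-per-stride vertical bounce amplitude
_STRIDE_LENGTH = 1.25  # m
_GRF_WEIGHT = 700.0    # N
_GRF_RAMP = 0.03       # s
_PAD = 1.0             # s of quiet standing before/after the walk


@dataclass
class GaitScenario:
    """Parameters of one synthetic walking trial."""

    n_strides: int = 12
    stride_duration: float = 1.2
    stride_jitter_sd: float = 0.0
    stance_fraction: float = 0.62
    asymmetry: float = 1.0
    affected_side: str = "left"
    noise_sd: float = 0.0
    fs: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.stance_fraction < 1.0):
            raise ScenarioError("stance_fraction must lie in (0, 1)")
        if self.stride_duration <= 2 * 0.15:
            raise ScenarioError("stride duration must exceed twice the "
                                "4-phase wait time (0.3 s)")
        if self.n_strides < 1:
            raise ScenarioError("need at least one stride")


@dataclass
class GroundTruth:
    """Exact per-side event times [s], ordered, plus the synthetic GRF."""

    events: dict  # side -> kind -> np.ndarray of times
    grf: dict     # side -> GrfTrace

    def times(self, side: str, kind: str) -> np.ndarray:
        return self.events[side][kind]


@dataclass
class ScenarioResult:
    scenario: GaitScenario
    trajectories: dict  # segment_id -> SegmentTrajectory
    grf: dict           # side -> GrfTrace
    ground_truth: GroundTruth


def _stride_durations(sc: GaitScenario, side: str,
                      rng: np.random.Generator) -> np.ndarray:
    mult = sc.asymmetry if side == sc.affected_side else 1.0
    d = sc.stride_duration * mult * (
        1.0 + sc.stride_jitter_sd / sc.stride_duration
        * rng.standard_normal(sc.n_strides))
    if np.any(d < 0.4):
        raise ScenarioError("stride jitter produced an infeasible stride")
    return d


_RUNIN_PHASE = 0.35  # quiet-stance phase at which the run-in/out freezes


def _phase(t: np.ndarray, starts: np.ndarray, durations: np.ndarray) -> np.ndarray:
    """Monotone stride phase with partial run-in/run-out strides.

    The walk ramps in from the quiet mid-stance phase of a virtual stride
    before the first IC and runs out to the same phase of a virtual stride
    after the last one, so that signal discontinuities sit far from any
    ground-truth event.  Outside that range the phase is frozen.
    """
    ends = starts + durations
    phase = np.full_like(t, _RUNIN_PHASE - 1.0)
    # run-in: virtual stride at the first stride's cadence
    m = (t >= starts[0] - (1.0 - _RUNIN_PHASE) * durations[0]) & (t < starts[0])
    phase[m] = (t[m] - starts[0]) / durations[0]  # in (RUNIN-1, 0)
    for i, (s, d) in enumerate(zip(starts, durations)):
        m = (t >= s) & (t < ends[i])
        phase[m] = i + (t[m] - s) / d
    # run-out: virtual stride at the last stride's cadence
    m = (t >= ends[-1]) & (t < ends[-1] + _RUNIN_PHASE * durations[-1])
    phase[m] = len(starts) + (t[m] - ends[-1]) / durations[-1]
    phase[t >= ends[-1] + _RUNIN_PHASE * durations[-1]] = (
        len(starts) + _RUNIN_PHASE)
    return phase


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _grf_trace(t: np.ndarray, starts: np.ndarray, durations: np.ndarray,
               stance: float, side: str, fs: float) -> GrfTrace:
    f = np.zeros_like(t)
    for s, d in zip(starts, durations):
        t_to = s + stance * d
        rise = _smoothstep((t - s) / _GRF_RAMP)
        fall = _smoothstep((t_to - t) / _GRF_RAMP)
        f += _GRF_WEIGHT * np.minimum(rise, fall) * ((t > s) & (t < t_to))
    return GrfTrace(side=side, t=t, f_v=f, fs=fs)


def _lowpass_noise(n: int, fs: float, sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """6 Hz low-passed Gaussian noise rescaled to the requested sd."""
    if sd <= 0:
        return np.zeros(n)
    sos = butter(2, 6.0, btype="low", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    s = np.std(x)
    return x * (sd / s) if s > 0 else x


def generate_scenario(sc: GaitScenario) -> ScenarioResult:
    """Generate the six segment trajectories, per-side GRF and ground truth."""
    rng = np.random.default_rng(sc.seed)
    fs, dt = sc.fs, 1.0 / sc.fs

    durations = {s: _stride_durations(sc, s, rng) for s in ("left", "right")}
    start0 = {"left": _PAD, "right": _PAD + 0.5 * durations["right"][0]}
    starts = {s: start0[s] + np.concatenate([[0.0], np.cumsum(durations[s][:-1])])
              for s in ("left", "right")}
    t_end = max(starts[s][-1] + durations[s][-1] for s in ("left", "right")) + _PAD
    n = int(np.ceil(t_end * fs)) + 1
    t = np.arange(n) * dt

    stance = sc.stance_fraction
    events = {}
    for s in ("left", "right"):
        ic = starts[s]
        d = durations[s]
        events[s] = {
            "IC": ic.copy(),
            "MSt": ic + 0.5 * stance * d,
            "TO": ic + stance * d,
            "MSw": ic + (stance + 0.5 * (1.0 - stance)) * d,
        }
        if np.any(np.diff(np.sort(np.concatenate(list(events[s].values()))))
                  < 2.0 * dt):
            raise ScenarioError("events closer than two samples")

    grf = {s: _grf_trace(t, starts[s], durations[s], stance, s, fs)
           for s in ("left", "right")}

    # vertical motion shared by the limb chain of each side
    p_y_extra = {}
    for s in ("left", "right"):
        phase = _phase(t, starts[s], durations[s])
        y = _BOUNCE * np.sin(4.0 * np.pi * phase + 0.25 * np.pi)
        for t_ic in events[s]["IC"]:
            y -= (_A_IC * _SIGMA**2) * np.exp(-0.5 * ((t - t_ic) / _SIGMA) ** 2)
        for t_to in events[s]["TO"]:
            y += (_A_TO * _SIGMA**2) * np.exp(
                -0.5 * ((t - (t_to - _TO_LEAD)) / _SIGMA) ** 2)
        y += _lowpass_noise(n, fs, 0.05 * sc.noise_sd, rng)
        p_y_extra[s] = y

    v = _STRIDE_LENGTH / sc.stride_duration  # treadmill-style constant glide
    trajectories = {}
    for s in ("left", "right"):
        phase = _phase(t, starts[s], durations[s])
        z0 = 0.1 if s == "left" else -0.1
        for seg_type in ("upper_leg", "lower_leg", "shoe"):
            profile = _FOOT_ANGLE if seg_type == "shoe" else _LEG_ANGLE
            theta = _ANGLE_AMPLITUDE[seg_type] * profile(np.mod(phase, 1.0))
            theta = theta + _lowpass_noise(n, fs, sc.noise_sd, rng)
            c, si = np.cos(theta), np.sin(theta)
            # Q = R_z(theta)^T : global -> local of a segment rotated by
            # theta about global z
            Q = np.zeros((n, 3, 3))
            Q[:, 0, 0] = c
            Q[:, 0, 1] = si
            Q[:, 1, 0] = -si
            Q[:, 1, 1] = c
            Q[:, 2, 2] = 1.0
            p = np.column_stack([
                v * t,
                _SEGMENT_HEIGHT[seg_type] + p_y_extra[s],
                np.full(n, z0)])
            seg_id = f"{seg_type}_{s}"
            trajectories[seg_id] = SegmentTrajectory(
                segment_id=seg_id, t=t, Q=Q, p=p, fs=fs)

    return ScenarioResult(scenario=sc, trajectories=trajectories, grf=grf,
                          ground_truth=GroundTruth(events=events, grf=grf))


def perturb_placement(placement: SensorPlacement, d_azimuth_deg: float = 0.0,
                      d_axial_m: float = 0.0,
                      geometry: dict | None = None) -> SensorPlacement:
    """Reposition a leg-cylinder sensor around (rotatory) or along
    (translatory) the limb axis; the radial distance is preserved.

    With ``geometry`` (the grid's cylinder record) the shifted position is
    checked to stay on the cylinder surface.
    """
    off = np.asarray(placement.offset_local, dtype=float)
    radius = float(np.hypot(off[0], off[2]))
    if radius <= 0:
        raise GeometryError("placement is on the cylinder axis")
    az = np.arctan2(off[2], off[0]) + np.deg2rad(d_azimuth_deg)
    y = off[1] + d_axial_m
    if geometry is not None:
        length = geometry["length"]
        if not (-length - 1e-12 <= y <= 1e-12):
            raise GeometryError("axial shift leaves the cylinder surface")
        if abs(radius - geometry["radius"]) > 1e-9:
            raise GeometryError("placement radius does not match the cylinder")
    new_off = np.array([radius * np.cos(az), y, radius * np.sin(az)])
    return SensorPlacement(
        segment_id=placement.segment_id, ring=placement.ring,
        slot=placement.slot, offset_local=new_off,
        mount_rotation=_ring_frame(az), region=placement.region)
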
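"""Data model and I/O for segment pose trajectories and vertical GRF traces.

Conventions
-----------
* Time in seconds, positions in metres, sampling nominally uniform at 100 Hz.
* The global frame G is right-handed with x anterior-posterior, y vertical
  (gravity-carrying, unit vector ``j = (0, 1, 0)``) and z medio-lateral.
* Pose rotation matrices ``Q`` map *global-frame* vectors into the *local*
  segment frame (global -> local); they satisfy ``Q^T Q = I`` and
  ``det(Q) = +1``.  A local vector ``v`` is expressed in the world frame as
  ``Q^T v``.
* The canonical storage dialect is a tab-separated columnar text file with a
  ``key=value`` header terminated by an ``endheader`` sentinel, compatible
  with OpenSim ``.sto``/``.mot`` layouts.  Rotation matrices are stored
  row-major in nine columns ``{segment}_R00 .. {segment}_R22`` followed by
  three position columns ``{segment}_px, _py, _pz``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .errors import (
    AttachmentError,
    FormatError,
    InvalidRotationError,
    SamplingError,
    UpsamplingLimitError,
)

#: canonical gravity axis of the global frame
GRAVITY_AXIS = np.array([0.0, 1.0, 0.0])

#: standard gravity magnitude used throughout the package [m/s^2]
G = 9.81

SIDES = ("left", "right")
SEGMENT_TYPES = ("upper_leg", "lower_leg", "shoe")
SEGMENT_IDS = tuple(f"{st}_{side}" for st in SEGMENT_TYPES for side in SIDES)

_ROT_COLS = [f"R{i}{j}" for i in range(3) for j in range(3)]
_POS_COLS = ["px", "py", "pz"]

# orthonormality acceptance thresholds
_ORTHO_STRICT = 1e-9   # invariant after loading / construction
_ORTHO_REPAIR = 1e-4   # worse than this is rejected, better is re-projected


def contralateral(side: str) -> str:
    """Return the opposite body side label."""
    return "right" if side == "left" else "left"


def orthonormality_defect(Q: np.ndarray) -> float:
    """Frobenius norm of ``Q^T Q - I`` (batched over leading axes)."""
    Q = np.asarray(Q, dtype=float)
    eye = np.eye(3)
    prod = np.einsum("...ji,...jk->...ik", Q, Q)
    return float(np.max(np.linalg.norm(prod - eye, axis=(-2, -1))))


def nearest_rotation(Q: np.ndarray) -> np.ndarray:
    """Project (batched) near-rotation matrices onto SO(3) via SVD."""
    Q = np.asarray(Q, dtype=float)
    U, _, Vt = np.linalg.svd(Q)
    R = U @ Vt
    # enforce det = +1 by flipping the smallest singular direction
    det = np.linalg.det(R)
    if np.any(det < 0):
        flip = np.where(det < 0, -1.0, 1.0)
        U = U.copy()
        U[..., :, -1] *= flip[..., None]
        R = U @ Vt
    return R


def _validate_rotations(Q: np.ndarray, repair: bool = True) -> np.ndarray:
    """Check/repair a (n, 3, 3) stack of global->local rotations."""
    Q = np.asarray(Q, dtype=float)
    if Q.ndim == 2:
        Q = Q[None]
    if np.any(np.linalg.det(Q) <= 0):
        raise InvalidRotationError("rotation matrix with non-positive determinant")
    defect = orthonormality_defect(Q)
    if defect >= _ORTHO_REPAIR:
        raise InvalidRotationError(
            f"orthonormality defect {defect:.3e} exceeds repair limit {_ORTHO_REPAIR:g}"
        )
    if defect >= _ORTHO_STRICT:
        if not repair:
            raise InvalidRotationError(
                f"orthonormality defect {defect:.3e} exceeds {_ORTHO_STRICT:g}"
            )
        Q = nearest_rotation(Q)
    return Q


def _validate_timebase(t: np.ndarray, tol: float = 1e-6) -> float:
    """Return the uniform dt of a strictly increasing time vector."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise SamplingError("time vector needs >= 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise SamplingError("time vector must be strictly increasing")
    if np.max(np.abs(dt - dt[0])) > tol:
        raise SamplingError("non-uniform time base")
    return float(dt[0])


@dataclass(frozen=True)
class PoseSample:
    """A single timestamped segment pose.

    Attributes
    ----------
    t : float
        Time in seconds.
    Q : (3, 3) ndarray
        Rotation mapping global-frame vectors into the local segment frame.
    p : (3,) ndarray
        Segment-origin position in the global frame [m].
    """

    t: float
    Q: np.ndarray
    p: np.ndarray


@dataclass
class SegmentTrajectory:
    """Time-uniform stream of segment poses.

    Arrays are stored stacked: ``t`` (n,), ``Q`` (n, 3, 3), ``p`` (n, 3).
    """

    segment_id: str
    t: np.ndarray
    Q: np.ndarray
    p: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if not (len(self.t) == len(self.Q) == len(self.p)):
            raise SamplingError("t, Q, p must have equal length")
        dt = _validate_timebase(self.t)
        if abs(self.fs * dt - 1.0) > 1e-6:
            raise SamplingError(f"fs={self.fs} inconsistent with dt={dt}")
        self.Q = _validate_rotations(self.Q)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def samples(self) -> Iterator[PoseSample]:
        """Iterate the trajectory as :class:`PoseSample` records."""
        for i in range(len(self.t)):
            yield PoseSample(float(self.t[i]), self.Q[i], self.p[i])


@dataclass
class GrfTrace:
    """Vertical ground-reaction-force trace for one body side."""

    side: str
    t: np.ndarray
    f_v: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f_v = np.asarray(self.f_v, dtype=float)
        if len(self.t) != len(self.f_v):
            raise SamplingError("t and f_v must have equal length")
        _validate_timebase(self.t)
        if np.any(self.f_v < 0):
            raise FormatError("vertical GRF must be non-negative")


@dataclass
class SensorTrajectory:
    """World trajectory of a rigidly attached virtual sensor.

    Attributes
    ----------
    k : (n, 3) ndarray
        Sensor position in the global frame [m].
    Q_s : (n, 3, 3) ndarray
        Sensor orientation: rotations mapping global-frame vectors into the
        sensor frame.
    fs : float
        Sampling rate [Hz].
    t : (n,) ndarray
        Sample times [s].
    """

    t: np.ndarray
    k: np.ndarray
    Q_s: np.ndarray
    fs: float = 100.0

    def __len__(self) -> int:
        return len(self.t)


# ---------------------------------------------------------------------------
# canonical columnar dialect (.sto-compatible)
# ---------------------------------------------------------------------------

def _write_sto(path: str, columns: Sequence[str], data: np.ndarray, name: str) -> None:
    n_rows, n_cols = data.shape
    with open(path, "w") as fh:
        fh.write(f"{name}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={n_rows}\n")
        fh.write(f"nColumns={n_cols}\n")
        fh.write("inDegrees=no\n")
        fh.write("endheader\n")
        fh.write("\t".join(columns) + "\n")
        for row in data:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def _read_sto(path: str) -> tuple[list[str], np.ndarray]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        end = next(i for i, ln in enumerate(lines) if ln.strip() == "endheader")
    except StopIteration:
        raise FormatError(f"{path}: missing 'endheader' sentinel") from None
    body = [ln for ln in lines[end + 1:] if ln.strip()]
    if not body:
        raise FormatError(f"{path}: no column-label line after header")
    columns = body[0].split("\t")
    if len(columns) < 2 or columns[0] != "time":
        raise FormatError(f"{path}: first column must be 'time'")
    try:
        data = np.array([[float(v) for v in ln.split("\t")] for ln in body[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric data row ({exc})") from None
    if data.ndim != 2 or data.shape[1] != len(columns):
        raise FormatError(f"{path}: ragged data body")
    return columns, data


def trajectory_columns(segment_id: str) -> list[str]:
    """Column names of one segment in the canonical dialect."""
    return [f"{segment_id}_{c}" for c in _ROT_COLS + _POS_COLS]


def save_pose_trajectory(trajs, path: str) -> None:
    """Write one or more :class:`SegmentTrajectory` to a canonical-dialect file.

    All trajectories must share the same time base.
    """
    if isinstance(trajs, SegmentTrajectory):
        trajs = [trajs]
    t = trajs[0].t
    cols = ["time"]
    blocks = [t[:, None]]
    for tr in trajs:
        if len(tr.t) != len(t) or np.max(np.abs(tr.t - t)) > 1e-9:
            raise SamplingError("all trajectories in one file must share the time base")
        cols += trajectory_columns(tr.segment_id)
        blocks.append(tr.Q.reshape(len(t), 9))
        blocks.append(tr.p)
    _write_sto(path, cols, np.hstack(blocks), name="pose_trajectory")


def load_pose_trajectory(path: str, segment_id: str | None = None,
                         dialect: str = "canonical") -> SegmentTrajectory:
    """Load one segment's pose trajectory from a canonical-dialect file.

    Parameters
    ----------
    path : str
        Storage file with a ``key=value`` header and ``endheader`` sentinel.
    segment_id : str, optional
        Segment to extract.  May be omitted when the file holds one segment.
    dialect : str
        Storage dialect identifier; only ``"canonical"`` is implemented.

    Notes
    -----
    Matrices with orthonormality defect below 1e-4 are re-projected onto the
    nearest rotation (SVD); worse violations and ``det(Q) <= 0`` raise
    :class:`~gaitsim.errors.InvalidRotationError`.
    """
    if dialect != "canonical":
        raise FormatError(f"unknown dialect {dialect!r}")
    columns, data = _read_sto(path)
    present = sorted({c.rsplit("_", 1)[0] for c in columns[1:]
                      if c.rsplit("_", 1)[-1] in _ROT_COLS})
    if segment_id is None:
        if len(present) != 1:
            raise FormatError(
                f"{path}: holds segments {present}, specify segment_id")
        segment_id = present[0]
    want = trajectory_columns(segment_id)
    try:
        idx = [columns.index(c) for c in want]
    except ValueError:
        raise FormatError(f"{path}: missing columns for segment {segment_id!r}") from None
    t = data[:, 0]
    dt = _validate_timebase(t)
    block = data[:, idx]
    Q = block[:, :9].reshape(-1, 3, 3)
    p = block[:, 9:]
    Q = _validate_rotations(Q)  # raises for det<=0 / defect >= 1e-4
    return SegmentTrajectory(segment_id=segment_id, t=t, Q=Q, p=p, fs=1.0 / dt)


def save_grf(traces, path: str) -> None:
    """Write GRF traces (one or both sides) to a canonical-dialect file."""
    if isinstance(traces, GrfTrace):
        traces = [traces]
    t = traces[0].t
    cols = ["time"]
    blocks = [t[:, None]]
    for tr in traces:
        if len(tr.t) != len(t) or np.max(np.abs(tr.t - t)) > 1e-9:
            raise SamplingError("all GRF traces in one file must share the time base")
        cols.append(f"grf_{tr.side}_fy")
        blocks.append(tr.f_v[:, None])
    _write_sto(path, cols, np.hstack(blocks), name="grf")


def load_grf(path: str, side: str) -> GrfTrace:
    """Load the vertical GRF trace of one body side."""
    columns, data = _read_sto(path)
    col = f"grf_{side}_fy"
    if col not in columns:
        raise FormatError(f"{path}: missing column {col!r}")
    t = data[:, 0]
    dt = _validate_timebase(t)
    return GrfTrace(side=side, t=t, f_v=data[:, columns.index(col)], fs=1.0 / dt)


# ---------------------------------------------------------------------------
# resampling and rigid attachment
# ---------------------------------------------------------------------------

def resample_uniform(traj: SegmentTrajectory, fs_target: float) -> SegmentTrajectory:
    """Resample a trajectory to ``fs_target``.

    Positions are interpolated linearly; rotations geodesically (slerp of the
    relative rotation) on the rotation manifold.
    """
    if fs_target <= 0:
        raise SamplingError("fs_target must be positive")
    if len(traj) < 2:
        raise SamplingError("need >= 2 samples to resample")
    if fs_target > 10.0 * traj.fs:
        raise UpsamplingLimitError(
            f"fs_target {fs_target} exceeds 10x input rate {traj.fs}")
    if abs(fs_target - traj.fs) < 1e-12:
        return SegmentTrajectory(traj.segment_id, traj.t.copy(), traj.Q.copy(),
                                 traj.p.copy(), fs=traj.fs)
    t0, t1 = traj.t[0], traj.t[-1]
    n = int(np.floor((t1 - t0) * fs_target + 1e-9)) + 1
    t_new = t0 + np.arange(n) / fs_target
    p_new = np.column_stack([np.interp(t_new, traj.t, traj.p[:, d]) for d in range(3)])
    slerp = Slerp(traj.t, Rotation.from_matrix(traj.Q))
    Q_new = slerp(t_new).as_matrix()
    return SegmentTrajectory(traj.segment_id, t_new, Q_new, p_new, fs=fs_target)


def sensor_world_trajectory(traj: SegmentTrajectory, placement) -> SensorTrajectory:
    """World trajectory of a sensor rigidly attached to a segment.

    ``k(t) = p(t) + Q^T(t) offset_local`` and the sensor orientation is the
    composition ``mount_rotation @ Q(t)`` (global -> sensor).
    """
    if placement.segment_id != traj.segment_id:
        raise AttachmentError(
            f"placement on {placement.segment_id!r} cannot attach to "
            f"trajectory of {traj.segment_id!r}")
    offset = np.asarray(placement.offset_local, dtype=float)
    k = traj.p + np.einsum("nji,j->ni", traj.Q, offset)
    Q_s = np.einsum("ij,njk->nik", np.asarray(placement.mount_rotation, float), traj.Q)
    return SensorTrajectory(t=traj.t.copy(), k=k, Q_s=Q_s, fs=traj.fs)
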
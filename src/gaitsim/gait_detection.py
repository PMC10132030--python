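"""Threshold-based gait event detection (algorithms A1 and A2).

Peak detection, threshold training, the gyro sign-change rule, and the
event-specific pairing/gating rules for the four gait events (IC, MSt, TO,
MSw) across 1-, 2- and 4-phase gait models.

Conventions chosen where the source rules are under-specified:

* two-condition rules report the *later* condition's peak time (the accel
  peak for IC, the gyro trough for TO);
* "followed by ... within 50 ms" is the closed ordered window [0, 50 ms] --
  simultaneity is allowed;
* the minimal-signal-change gate is the maximum absolute second-order
  central difference per 50 ms window, tolerated up to the 75th quantile of
  the per-window statistic over the training signal;
* under the minimum-distance constraint theta_d the more extreme peak
  survives; ties break towards the earlier peak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    BipedalInputError,
    TrainingError,
    UnsupportedCombinationError,
)

EVENT_KINDS = ("IC", "MSt", "TO", "MSw")

#: wait time t_w between gait events per phase model [s]
WAIT_TIMES = {1: 0.6, 2: 0.3, 4: 0.15}

#: cyclic event order of the 4-phase model
CYCLE_4 = ("IC", "MSt", "TO", "MSw")


@dataclass(frozen=True)
class Peak:
    """A detected signal extremum: timestamp [s] and signed height."""

    t: float
    h: float


@dataclass(frozen=True)
class GaitEvent:
    kind: str
    t: float
    side: str


@dataclass
class EventSeries:
    side: str
    events: list[GaitEvent]
    phase_model: int = 4

    def times(self, kind: str) -> np.ndarray:
        return np.array([e.t for e in self.events if e.kind == kind])

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class ThetaSet:
    """Trained minimum peak heights, one per detector rule."""

    ic_accel: float | None = None    # positive accel peaks, fraction 0.15
    to_accel: float | None = None    # negative accel peaks, fraction 0.15
    to_gyro: float | None = None     # negative gyro peaks, fraction 0.25
    msw_gyro: float | None = None    # positive ipsilateral gyro peaks, 0.25
    mst_gyro: float | None = None    # positive contralateral gyro peaks, 0.25
    msw_grad_tol: float | None = None  # contralateral accel gradient tolerance
    mst_grad_tol: float | None = None  # ipsilateral accel gradient tolerance

    @staticmethod
    def average(thetas: Sequence["ThetaSet"]) -> "ThetaSet":
        """Fieldwise mean over a list of trained threshold sets."""
        out = ThetaSet()
        for name in out.__dataclass_fields__:
            vals = [getattr(th, name) for th in thetas
                    if getattr(th, name) is not None]
            if vals:
                setattr(out, name, float(np.mean(vals)))
        return out


@dataclass
class DetectionParams:
    """Detector parameterisation.

    ``theta_d`` is the minimum distance between two same-kind events [s];
    the wait time ``t_w`` between gait events follows the phase model
    (0.6 / 0.3 / 0.15 s for the 1-/2-/4-phase models).
    """

    phase_model: int = 4
    theta_d: float = 0.6
    fraction_accel: float = 0.15
    fraction_gyro: float = 0.25
    pair_window: float = 0.05
    grad_window: float = 0.05
    grad_quantile: float = 0.75
    thetas: ThetaSet | None = None

    def __post_init__(self) -> None:
        if self.phase_model not in WAIT_TIMES:
            raise UnsupportedCombinationError(
                f"phase model must be one of {sorted(WAIT_TIMES)}")
        if not (0.0 < self.fraction_accel < 1.0 and 0.0 < self.fraction_gyro < 1.0):
            raise ValueError("threshold fractions must lie in (0, 1)")

    @property
    def t_w(self) -> float:
        return WAIT_TIMES[self.phase_model]


# ---------------------------------------------------------------------------
# peak detection core
# ---------------------------------------------------------------------------

def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima (no plateau peaks)."""
    if len(x) < 3:
        return np.array([], dtype=int)
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1


def detect_peaks(x: np.ndarray, fs: float, theta_h: float | None = None,
                 theta_d: float = 0.6, polarity: str = "+",
                 t: np.ndarray | None = None) -> list[Peak]:
    """Detect local extrema with minimum height and minimum spacing.

    Negative polarity is positive detection on ``-x`` (``theta_h`` then acts
    as a ceiling: peaks with ``h <= theta_h`` qualify).  When two candidates
    conflict under ``theta_d`` the more extreme one survives; ties break
    towards the earlier peak.  Returned peaks are time-ordered.
    """
    x = np.asarray(x, dtype=float)
    if t is None:
        t = np.arange(len(x)) / fs
    if polarity == "-":
        flipped = detect_peaks(-x, fs,
                               None if theta_h is None else -theta_h,
                               theta_d, "+", t)
        return [Peak(p.t, -p.h) for p in flipped]
    idx = _local_maxima(x)
    if theta_h is not None:
        idx = idx[x[idx] >= theta_h]
    if len(idx) == 0:
        return []
    # greedy: most extreme first, earlier time wins ties
    order = sorted(range(len(idx)), key=lambda i: (-x[idx[i]], t[idx[i]]))
    kept_t: list[float] = []
    kept: list[int] = []
    for i in order:
        ti = t[idx[i]]
        if all(abs(ti - tk) >= theta_d for tk in kept_t):
            kept.append(idx[i])
            kept_t.append(ti)
    kept.sort()
    return [Peak(float(t[i]), float(x[i])) for i in kept]


def fit_theta_h(train: np.ndarray | Sequence[np.ndarray], fs: float,
                polarity: str = "+", fraction: float = 0.15,
                theta_d: float = 0.6) -> float:
    """Train the minimum peak height from candidate peaks.

    Candidates are detected with the spacing constraint only (no height
    gate); ``theta_h`` is then the mean candidate height shrunk towards zero
    by ``fraction``:  ``h - |h| f`` for positive polarity and ``h + |h| f``
    for negative polarity.
    """
    segments = [train] if isinstance(train, np.ndarray) else list(train)
    heights: list[float] = []
    for seg in segments:
        heights += [p.h for p in detect_peaks(np.asarray(seg, float), fs,
                                              None, theta_d, polarity)]
    if not heights:
        raise TrainingError("no candidate peaks in training data")
    h_bar = float(np.mean(heights))
    if polarity == "+":
        return h_bar - abs(h_bar) * fraction
    return h_bar + abs(h_bar) * fraction


def sign_changes(w: np.ndarray, fs: float, t: np.ndarray | None = None) -> np.ndarray:
    """Timestamps of strict positive-to-negative sign changes.

    A change is flagged at sample ``i`` when ``w[i-1] > 0`` and ``w[i] < 0``;
    exact zeros break eligibility.
    """
    w = np.asarray(w, dtype=float)
    if t is None:
        t = np.arange(len(w)) / fs
    idx = np.flatnonzero((w[:-1] > 0) & (w[1:] < 0)) + 1
    return t[idx]


# ---------------------------------------------------------------------------
# gradient (minimal signal change) gate
# ---------------------------------------------------------------------------

def _window_gradient_stats(a: np.ndarray, fs: float,
                           window_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-window max |second central difference| over consecutive windows.

    Returns (window start times, statistic per window).
    """
    n = len(a)
    d2 = np.zeros(n)
    if n >= 3:
        d2[1:-1] = np.abs(a[2:] - 2.0 * a[1:-1] + a[:-2])
    w = max(1, int(round(window_s * fs)))
    n_win = max(1, n // w)
    stats = np.array([np.max(d2[i * w:(i + 1) * w]) for i in range(n_win)])
    starts = np.arange(n_win) * w / fs
    return starts, stats


def gradient_tolerance(a: np.ndarray, fs: float, window_s: float = 0.05,
                       quantile: float = 0.75) -> float:
    """Train the minimal-signal-change tolerance (quantile of window stats)."""
    _, stats = _window_gradient_stats(np.asarray(a, float), fs, window_s)
    return float(np.quantile(stats, quantile))


def _passes_gradient_gate(t_peak: float, t0: float, a: np.ndarray, fs: float,
                          window_s: float, tol: float) -> bool:
    """True when the 50 ms window containing ``t_peak`` changes minimally."""
    starts, stats = _window_gradient_stats(a, fs, window_s)
    w = max(1, int(round(window_s * fs)))
    i = int((t_peak - t0) * fs) // w
    i = min(max(i, 0), len(stats) - 1)
    return bool(stats[i] <= tol)


# ---------------------------------------------------------------------------
# event candidate rules
# ---------------------------------------------------------------------------

def _check_aligned(*channels: np.ndarray) -> None:
    n = {len(c) for c in channels}
    if len(n) != 1:
        raise AlignmentError(f"channel length mismatch: {sorted(n)}")


def _pair_after(anchors: np.ndarray, peaks: list[Peak],
                window: float) -> list[Peak]:
    """Peaks that follow some anchor within [0, window] seconds."""
    out = []
    for p in peaks:
        d = p.t - anchors
        if np.any((d >= 0.0) & (d <= window)):
            out.append(p)
    return out


def _theta(params: DetectionParams, name: str, train_x: np.ndarray, fs: float,
           polarity: str, fraction: float) -> float:
    """Use the trained threshold if provided, else self-fit on the input."""
    if params.thetas is not None and getattr(params.thetas, name) is not None:
        return getattr(params.thetas, name)
    return fit_theta_h(train_x, fs, polarity, fraction, params.theta_d)


def ic_candidates_a1(a_y: np.ndarray, fs: float, params: DetectionParams,
                     t: np.ndarray | None = None) -> list[Peak]:
    th = _theta(params, "ic_accel", a_y, fs, "+", params.fraction_accel)
    return detect_peaks(a_y, fs, th, 0.6, "+", t)


def ic_candidates_a2(a_y: np.ndarray, omega_z: np.ndarray, fs: float,
                     params: DetectionParams,
                     t: np.ndarray | None = None) -> list[Peak]:
    """Gyro +/- sign change followed by a qualifying accel peak within 50 ms."""
    _check_aligned(a_y, omega_z)
    anchors = sign_changes(omega_z, fs, t)
    peaks = ic_candidates_a1(a_y, fs, params, t)
    return _pair_after(anchors, peaks, params.pair_window)


def to_candidates_a2(a_y: np.ndarray, omega_z: np.ndarray, fs: float,
                     params: DetectionParams,
                     t: np.ndarray | None = None) -> list[Peak]:
    """Negative accel peak followed by a negative gyro peak within 50 ms.

    The reported timestamp is the gyro trough.
    """
    _check_aligned(a_y, omega_z)
    th_a = _theta(params, "to_accel", a_y, fs, "-", params.fraction_accel)
    th_w = _theta(params, "to_gyro", omega_z, fs, "-", params.fraction_gyro)
    troughs_a = detect_peaks(a_y, fs, th_a, 0.6, "-", t)
    troughs_w = detect_peaks(omega_z, fs, th_w, 0.6, "-", t)
    anchors = np.array([p.t for p in troughs_a])
    return _pair_after(anchors, troughs_w, params.pair_window)


def msw_candidates_a2(omega_z_ipsi: np.ndarray, a_y_contra: np.ndarray,
                      fs: float, params: DetectionParams,
                      t: np.ndarray | None = None) -> list[Peak]:
    """Positive ipsilateral gyro peaks while the contralateral acceleration
    changes minimally (gradient gate at the trained tolerance)."""
    if a_y_contra is None:
        raise BipedalInputError("MSw detection needs the contralateral accel channel")
    _check_aligned(omega_z_ipsi, a_y_contra)
    th = _theta(params, "msw_gyro", omega_z_ipsi, fs, "+", params.fraction_gyro)
    if params.thetas is not None and params.thetas.msw_grad_tol is not None:
        tol = params.thetas.msw_grad_tol
    else:
        tol = gradient_tolerance(a_y_contra, fs, params.grad_window,
                                 params.grad_quantile)
    peaks = detect_peaks(omega_z_ipsi, fs, th, 0.6, "+", t)
    t0 = 0.0 if t is None else float(t[0])
    return [p for p in peaks
            if _passes_gradient_gate(p.t, t0, a_y_contra, fs,
                                     params.grad_window, tol)]


def mst_candidates_a2(omega_z_contra: np.ndarray, a_y_ipsi: np.ndarray,
                      fs: float, params: DetectionParams,
                      t: np.ndarray | None = None) -> list[Peak]:
    """Mirror of the MSw rule: contralateral gyro peaks gated by minimal
    ipsilateral acceleration change; events land on the ipsilateral timeline."""
    if omega_z_contra is None:
        raise BipedalInputError("MSt detection needs the contralateral gyro channel")
    _check_aligned(omega_z_contra, a_y_ipsi)
    th = _theta(params, "mst_gyro", omega_z_contra, fs, "+", params.fraction_gyro)
    if params.thetas is not None and params.thetas.mst_grad_tol is not None:
        tol = params.thetas.mst_grad_tol
    else:
        tol = gradient_tolerance(a_y_ipsi, fs, params.grad_window,
                                 params.grad_quantile)
    peaks = detect_peaks(omega_z_contra, fs, th, 0.6, "+", t)
    t0 = 0.0 if t is None else float(t[0])
    return [p for p in peaks
            if _passes_gradient_gate(p.t, t0, a_y_ipsi, fs,
                                     params.grad_window, tol)]


def _events(peaks: Iterable[Peak], kind: str, side: str,
            min_gap: float) -> list[GaitEvent]:
    out: list[GaitEvent] = []
    last = -np.inf
    for p in sorted(peaks, key=lambda q: q.t):
        if p.t - last >= min_gap:
            out.append(GaitEvent(kind, p.t, side))
            last = p.t
    return out


def detect_ic_a1(a_y: np.ndarray, fs: float, params: DetectionParams,
                 side: str = "left", t: np.ndarray | None = None) -> list[GaitEvent]:
    """Algorithm A1: IC at each qualifying positive accel peak, >= 0.6 s apart."""
    return _events(ic_candidates_a1(a_y, fs, params, t), "IC", side, 0.6)


def detect_ic_a2(a_y: np.ndarray, omega_z: np.ndarray, fs: float,
                 params: DetectionParams, side: str = "left",
                 t: np.ndarray | None = None) -> list[GaitEvent]:
    return _events(ic_candidates_a2(a_y, omega_z, fs, params, t), "IC", side, 0.6)


def detect_to_a2(a_y: np.ndarray, omega_z: np.ndarray, fs: float,
                 params: DetectionParams, side: str = "left",
                 t: np.ndarray | None = None) -> list[GaitEvent]:
    return _events(to_candidates_a2(a_y, omega_z, fs, params, t), "TO", side, 0.6)


def detect_msw_a2(omega_z_ipsi: np.ndarray, a_y_contra: np.ndarray, fs: float,
                  params: DetectionParams, side: str = "left",
                  t: np.ndarray | None = None) -> list[GaitEvent]:
    return _events(msw_candidates_a2(omega_z_ipsi, a_y_contra, fs, params, t),
                   "MSw", side, 0.6)


def detect_mst_a2(omega_z_contra: np.ndarray, a_y_ipsi: np.ndarray, fs: float,
                  params: DetectionParams, side: str = "left",
                  t: np.ndarray | None = None) -> list[GaitEvent]:
    return _events(mst_candidates_a2(omega_z_contra, a_y_ipsi, fs, params, t),
                   "MSt", side, 0.6)


# ---------------------------------------------------------------------------
# phase-model state machine
# ---------------------------------------------------------------------------

def fit_thetas(a_y: np.ndarray, omega_z: np.ndarray, a_y_contra: np.ndarray,
               omega_z_contra: np.ndarray, fs: float,
               params: DetectionParams) -> ThetaSet:
    """Train all thresholds needed by A1/A2 for one side on one signal set.

    Channels may be lists of contiguous segments (training folds).
    """
    def _fit(x, polarity, fraction):
        try:
            return fit_theta_h(x, fs, polarity, fraction, params.theta_d)
        except TrainingError:
            return None

    def _tol(x):
        segs = [x] if isinstance(x, np.ndarray) else list(x)
        stats = np.concatenate([
            _window_gradient_stats(np.asarray(s, float), fs,
                                   params.grad_window)[1] for s in segs])
        return float(np.quantile(stats, params.grad_quantile))

    return ThetaSet(
        ic_accel=_fit(a_y, "+", params.fraction_accel),
        to_accel=_fit(a_y, "-", params.fraction_accel),
        to_gyro=_fit(omega_z, "-", params.fraction_gyro),
        msw_gyro=_fit(omega_z, "+", params.fraction_gyro),
        mst_gyro=_fit(omega_z_contra, "+", params.fraction_gyro),
        msw_grad_tol=_tol(a_y_contra),
        mst_grad_tol=_tol(a_y),
    )


def _resolve_cycle(candidates: list[tuple[float, str]], side: str,
                   params: DetectionParams) -> EventSeries:
    """Run merged candidates through the cyclic wait-time state machine.

    IC may always restart a cycle (subject to spacing); MSt waits on the last
    TO (or IC for the opening cycle), TO on the last event, MSw on the last
    IC.  Out-of-order candidates are skipped, not reordered, so missing peaks
    propagate as missing events.
    """
    pm = params.phase_model
    t_w = params.t_w
    cycle = {1: ("IC",), 2: ("IC", "TO"), 4: CYCLE_4}[pm]
    nxt = {k: cycle[(i + 1) % len(cycle)] for i, k in enumerate(cycle)}
    last = {k: -np.inf for k in EVENT_KINDS}
    last_event = -np.inf
    expected = "IC"
    out: list[GaitEvent] = []
    for tt, kind in sorted(candidates):
        if tt - last[kind] < 0.6:  # theta_d between same-kind events
            continue
        if kind == "IC":
            ok = (tt - last["IC"] >= 0.6) if pm == 1 else (tt - last_event >= t_w)
        elif kind == "MSt":
            anchor = last["TO"] if np.isfinite(last["TO"]) else last["IC"]
            ok = expected == "MSt" and tt - anchor >= t_w
        elif kind == "TO":
            ok = expected == "TO" and tt - last_event >= t_w
        elif kind == "MSw":
            ok = expected == "MSw" and tt - last["IC"] >= t_w
        else:
            ok = False
        if ok:
            out.append(GaitEvent(kind, tt, side))
            last[kind] = tt
            last_event = tt
            expected = nxt[kind]
    return EventSeries(side=side, events=out, phase_model=pm)


def run_phase_model(imu_left, imu_right, algo: str,
                    params: DetectionParams,
                    thetas: dict[str, ThetaSet] | None = None) -> dict[str, EventSeries]:
    """Detect per-side event series under the chosen algorithm and phase model.

    ``imu_left``/``imu_right`` are :class:`~gaitsim.imu_synthesis.ImuSignal`
    (or objects exposing ``t``, ``a_y``, ``omega_z``, ``fs``).  A1 supports
    the 1-phase model only.  Thresholds come from ``thetas`` (per side) or
    ``params.thetas``; otherwise they are self-fitted on the inputs.
    """
    algo = algo.upper()
    if algo not in ("A1", "A2"):
        raise UnsupportedCombinationError(f"unknown algorithm {algo!r}")
    if algo == "A1" and params.phase_model != 1:
        raise UnsupportedCombinationError("A1 supports the 1-phase model only")
    signals = {"left": imu_left, "right": imu_right}
    result: dict[str, EventSeries] = {}
    for side, imu in signals.items():
        other = signals["right" if side == "left" else "left"]
        if len(imu.t) == 0:
            result[side] = EventSeries(side=side, events=[],
                                       phase_model=params.phase_model)
            continue
        fs = imu.fs
        t = imu.t
        if thetas is not None and side in thetas:
            p = replace(params, thetas=thetas[side])
        elif params.thetas is not None:
            p = params
        else:
            p = replace(params, thetas=fit_thetas(
                imu.a_y, imu.omega_z, other.a_y, other.omega_z, fs, params))
        cands: list[tuple[float, str]] = []
        if algo == "A1":
            cands += [(pk.t, "IC") for pk in ic_candidates_a1(imu.a_y, fs, p, t)]
        else:
            cands += [(pk.t, "IC")
                      for pk in ic_candidates_a2(imu.a_y, imu.omega_z, fs, p, t)]
            if params.phase_model >= 2:
                cands += [(pk.t, "TO")
                          for pk in to_candidates_a2(imu.a_y, imu.omega_z, fs, p, t)]
            if params.phase_model == 4:
                cands += [(pk.t, "MSw")
                          for pk in msw_candidates_a2(imu.omega_z, other.a_y,
                                                      fs, p, t)]
                cands += [(pk.t, "MSt")
                          for pk in mst_candidates_a2(other.omega_z, imu.a_y,
                                                      fs, p, t)]
        result[side] = _resolve_cycle(cands, side, p)
    return result
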
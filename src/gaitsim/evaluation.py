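"""Reference events, timing-error metrics, cross-validation strategies,
rotatory/translatory error decomposition and signal-agreement metrics.

Timing error per event kind is the mean absolute difference between each
reference event and its nearest detected event (reuse permitted), normalised
by the reference average stride duration:

    MAE  = (1/U_n) sum_i |t_i - t_hat_i|        [s]
    nMAE = 100 * MAE / F_bar                    [%]

Missing detections therefore inflate nMAE, possibly beyond 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import (
    InsufficientEventsError,
    NoStanceError,
    StrategyError,
)
from .gait_detection import (
    DetectionParams,
    EventSeries,
    GaitEvent,
    ThetaSet,
    fit_thetas,
    run_phase_model,
)
from .imu_synthesis import FilterSpec, ImuSignal, synthesize_imu
from .kinematics_io import GrfTrace, contralateral, sensor_world_trajectory
from .sensor_grid import build_leg_grid, build_shoe_grid

PHASE_EVENTS = {1: ("IC",), 2: ("IC", "TO"), 4: ("IC", "MSt", "TO", "MSw")}


# ---------------------------------------------------------------------------
# reference events and stride duration
# ---------------------------------------------------------------------------

def extract_reference_events(grf: GrfTrace, ground_truth: dict | None = None,
                             floor_fraction: float = 0.02) -> EventSeries:
    """IC/TO reference events from a vertical GRF trace.

    Stance is where the force rises above a zero-force floor
    (``floor_fraction`` of the trace maximum): IC at each rising edge, TO at
    each falling edge.  MSt/MSw cannot be derived from GRF alone; when a
    ``ground_truth`` mapping (kind -> times) is supplied, its MSt/MSw times
    are merged into the returned series.
    """
    f = np.asarray(grf.f_v, dtype=float)
    peak = float(np.max(f, initial=0.0))
    if peak <= 0:
        raise NoStanceError("GRF trace is identically zero")
    floor = floor_fraction * peak
    mask = f > floor
    if not mask.any():
        raise NoStanceError("GRF never exceeds the zero-force floor")
    rising = np.flatnonzero(mask[1:] & ~mask[:-1]) + 1
    falling = np.flatnonzero(~mask[1:] & mask[:-1]) + 1
    events = [GaitEvent("IC", float(grf.t[i]), grf.side) for i in rising]
    events += [GaitEvent("TO", float(grf.t[i]), grf.side) for i in falling]
    if ground_truth is not None:
        for kind in ("MSt", "MSw"):
            events += [GaitEvent(kind, float(tt), grf.side)
                       for tt in ground_truth.get(kind, [])]
    events.sort(key=lambda e: e.t)
    return EventSeries(side=grf.side, events=events, phase_model=4)


def mean_stride_duration(ref: EventSeries) -> float:
    """Reference average stride duration: mean IC-to-IC interval [s]."""
    ics = np.sort(ref.times("IC"))
    if len(ics) < 2:
        raise InsufficientEventsError("need >= 2 ICs for a stride duration")
    return float(np.mean(np.diff(ics)))


# ---------------------------------------------------------------------------
# timing error
# ---------------------------------------------------------------------------

def match_nearest(detected: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Absolute gap from each reference event to its nearest detection."""
    detected = np.sort(np.asarray(detected, dtype=float))
    reference = np.asarray(reference, dtype=float)
    return np.array([np.min(np.abs(detected - r)) for r in reference])


@dataclass
class ErrorReport:
    """Long-format per-(sensor, event, side, ...) timing errors.

    ``df`` columns: participant, segment, ring, slot, side, event, variant,
    phase_model, fold, mae_s, nmae_pct, n_ref, n_det, undefined.
    ``stride_duration`` maps (participant, side) to the reference F_bar [s].
    """

    df: pd.DataFrame
    stride_duration: dict

    def aggregate(self) -> pd.DataFrame:
        """Fold-averaged errors per sensor, side and event kind."""
        keys = ["participant", "segment", "ring", "slot", "side", "event",
                "variant", "phase_model"]
        return (self.df.groupby(keys, dropna=False, as_index=False)
                [["mae_s", "nmae_pct"]].mean())

    def to_csv(self, path: str) -> None:
        self.df.to_csv(path, index=False)


def timing_error(detected: EventSeries, reference: EventSeries,
                 f_bar: float, **row_meta) -> ErrorReport:
    """Per-event-kind MAE/nMAE between a detected and a reference series."""
    rows = []
    kinds = sorted({e.kind for e in reference.events})
    for kind in kinds:
        ref_t = reference.times(kind)
        det_t = detected.times(kind)
        if len(ref_t) == 0:
            continue
        if len(det_t) == 0:
            mae = np.nan
            undefined = True
        else:
            mae = float(np.mean(match_nearest(det_t, ref_t)))
            undefined = False
        rows.append({"participant": row_meta.get("participant", "p0"),
                     "segment": row_meta.get("segment", ""),
                     "ring": row_meta.get("ring", 0),
                     "slot": row_meta.get("slot", 0),
                     "side": reference.side, "event": kind,
                     "variant": row_meta.get("variant", ""),
                     "phase_model": row_meta.get("phase_model",
                                                 detected.phase_model),
                     "fold": row_meta.get("fold", 0),
                     "mae_s": mae,
                     "nmae_pct": 100.0 * mae / f_bar,
                     "n_ref": len(ref_t), "n_det": len(det_t),
                     "undefined": undefined})
    return ErrorReport(df=pd.DataFrame(rows),
                       stride_duration={(row_meta.get("participant", "p0"),
                                         reference.side): f_bar})


# ---------------------------------------------------------------------------
# dataset model
# ---------------------------------------------------------------------------

@dataclass
class SensorPair:
    """One grid position instantiated on both body sides."""

    segment_type: str
    ring: int
    slot: int
    signals: dict  # side -> ImuSignal

    @property
    def key(self) -> tuple:
        return (self.segment_type, self.ring, self.slot)


@dataclass
class ParticipantData:
    participant_id: str
    sensors: list
    reference: dict  # side -> EventSeries (IC/TO from GRF, MSt/MSw labelled)

    def f_bar(self, side: str) -> float:
        return mean_stride_duration(self.reference[side])


@dataclass
class GaitDataset:
    participants: list


def participant_from_scenario(result, pair_keys, participant_id: str = "p0",
                              filter_spec: FilterSpec | None = None,
                              grids: dict | None = None) -> ParticipantData:
    """Synthesise bilateral IMU signals for selected grid positions.

    ``pair_keys`` is a list of (segment_type, ring, slot); the same position
    is instantiated on the left and right instance of the segment.
    """
    spec = filter_spec or FilterSpec()
    grids = grids or {}
    sensors = []
    cache: dict[tuple, ImuSignal] = {}
    for seg_type, ring, slot in pair_keys:
        signals = {}
        for side in ("left", "right"):
            key = (seg_type, ring, slot, side)
            if key not in cache:
                seg_id = f"{seg_type}_{side}"
                grid = grids.get(seg_id)
                if grid is None:
                    grid = (build_shoe_grid(seg_id) if seg_type == "shoe"
                            else build_leg_grid(seg_id))
                    grids[seg_id] = grid
                placement = grid.find(seg_id, ring, slot)
                st = sensor_world_trajectory(result.trajectories[seg_id],
                                             placement)
                cache[key] = synthesize_imu(st, spec)
            signals[side] = cache[key]
        sensors.append(SensorPair(seg_type, ring, slot, signals))
    reference = {}
    for side in ("left", "right"):
        gt = result.ground_truth.events[side]
        reference[side] = extract_reference_events(result.grf[side],
                                                   ground_truth=gt)
    return ParticipantData(participant_id=participant_id, sensors=sensors,
                           reference=reference)


# ---------------------------------------------------------------------------
# cross-validation strategies
# ---------------------------------------------------------------------------

def stride_folds(ref: EventSeries, n_folds: int = 5) -> list[tuple[float, float]]:
    """Contiguous stride-block test windows [t0, t1) covering every stride
    exactly once.  Strides are the intervals between consecutive ICs."""
    ics = np.sort(ref.times("IC"))
    if len(ics) < n_folds + 1:
        raise InsufficientEventsError(
            f"{len(ics) - 1} strides cannot fill {n_folds} folds")
    blocks = np.array_split(np.arange(len(ics) - 1), n_folds)
    return [(float(ics[b[0]]), float(ics[b[-1] + 1])) for b in blocks]


def _train_segments(x: np.ndarray, t: np.ndarray,
                    test_window: tuple[float, float]) -> list[np.ndarray]:
    t0, t1 = test_window
    before = x[t < t0]
    after = x[t >= t1]
    return [seg for seg in (before, after) if len(seg) >= 3]


def _fold_thetas(imu_ipsi: ImuSignal, imu_contra: ImuSignal,
                 window: tuple[float, float],
                 params: DetectionParams) -> ThetaSet:
    t = imu_ipsi.t
    return fit_thetas(
        _train_segments(imu_ipsi.a_y, t, window),
        _train_segments(imu_ipsi.omega_z, t, window),
        _train_segments(imu_contra.a_y, t, window),
        _train_segments(imu_contra.omega_z, t, window),
        imu_ipsi.fs, params)


def _eval_rows(detected: dict, participant: ParticipantData, pair: SensorPair,
               windows: dict, fold: int, variant: str,
               params: DetectionParams) -> list[dict]:
    rows = []
    for side in ("left", "right"):
        ref = participant.reference[side]
        f_bar = participant.f_bar(side)
        t0, t1 = windows[side]
        for kind in PHASE_EVENTS[params.phase_model]:
            ref_t = ref.times(kind)
            ref_t = ref_t[(ref_t >= t0) & (ref_t < t1)]
            if len(ref_t) == 0:
                continue
            det_t = detected[side].times(kind)
            if len(det_t) == 0:
                mae, undefined = np.nan, True
            else:
                mae = float(np.mean(match_nearest(det_t, ref_t)))
                undefined = False
            rows.append({"participant": participant.participant_id,
                         "segment": pair.segment_type, "ring": pair.ring,
                         "slot": pair.slot, "side": side, "event": kind,
                         "variant": variant,
                         "phase_model": params.phase_model, "fold": fold,
                         "mae_s": mae, "nmae_pct": 100.0 * mae / f_bar,
                         "n_ref": len(ref_t), "n_det": len(det_t),
                         "undefined": undefined})
    return rows


def crossval(dataset: GaitDataset, variant: str = "A2a", phase_model: int = 4,
             params: DetectionParams | None = None,
             n_folds: int = 5) -> ErrorReport:
    """Run one of the validation strategies over a dataset.

    * ``A1``/``A2a`` -- thresholds fitted per participant and per sensor on
      the training stride blocks of a 5-fold split, tested on the held-out
      block, fold results averaged downstream.
    * ``A2b`` -- leave-one-participant-out; per-sensor thresholds averaged
      over the training participants, tested on the held-out participant.
    * ``A2c`` -- as A2a but thresholds averaged across all sensors of the
      same segment before testing (sensor-position independent).
    """
    variant = variant if variant in ("A1", "A2a", "A2b", "A2c") else None
    if variant is None:
        raise StrategyError("variant must be one of A1, A2a, A2b, A2c")
    algo = "A1" if variant == "A1" else "A2"
    params = params or DetectionParams(phase_model=phase_model)
    if params.phase_model != phase_model:
        params = replace(params, phase_model=phase_model)
    rows: list[dict] = []
    sd: dict = {}
    for part in dataset.participants:
        for side in ("left", "right"):
            sd[(part.participant_id, side)] = part.f_bar(side)

    if variant == "A2b":
        if len(dataset.participants) < 2:
            raise StrategyError("A2b needs >= 2 participants")
        # full-signal thresholds per (participant, sensor, side)
        full: dict = {}
        for part in dataset.participants:
            for pair in part.sensors:
                for side in ("left", "right"):
                    ipsi = pair.signals[side]
                    contra = pair.signals[contralateral(side)]
                    full[(part.participant_id, pair.key, side)] = fit_thetas(
                        ipsi.a_y, ipsi.omega_z, contra.a_y, contra.omega_z,
                        ipsi.fs, params)
        for held in dataset.participants:
            others = [p for p in dataset.participants if p is not held]
            for pair in held.sensors:
                thetas = {side: ThetaSet.average(
                    [full[(o.participant_id, pair.key, side)] for o in others])
                    for side in ("left", "right")}
                detected = run_phase_model(pair.signals["left"],
                                           pair.signals["right"], algo,
                                           params, thetas=thetas)
                windows = {s: (held.reference[s].times("IC")[0],
                               held.reference[s].times("IC")[-1])
                           for s in ("left", "right")}
                rows += _eval_rows(detected, held, pair, windows, 0,
                                   variant, params)
        return ErrorReport(df=pd.DataFrame(rows), stride_duration=sd)

    # fold-based strategies (A1, A2a, A2c)
    for part in dataset.participants:
        folds = {s: stride_folds(part.reference[s], n_folds)
                 for s in ("left", "right")}
        for f in range(n_folds):
            windows = {s: folds[s][f] for s in ("left", "right")}
            per_sensor: dict = {}
            for pair in part.sensors:
                per_sensor[pair.key] = {
                    side: _fold_thetas(pair.signals[side],
                                       pair.signals[contralateral(side)],
                                       windows[side], params)
                    for side in ("left", "right")}
            if variant == "A2c":
                # average thresholds across all sensors of a segment
                seg_avg: dict = {}
                for seg in {k[0] for k in per_sensor}:
                    seg_avg[seg] = {side: ThetaSet.average(
                        [per_sensor[k][side] for k in per_sensor
                         if k[0] == seg]) for side in ("left", "right")}
                per_sensor = {k: seg_avg[k[0]] for k in per_sensor}
            for pair in part.sensors:
                detected = run_phase_model(pair.signals["left"],
                                           pair.signals["right"], algo,
                                           params,
                                           thetas=per_sensor[pair.key])
                rows += _eval_rows(detected, part, pair, windows, f,
                                   variant, params)
    return ErrorReport(df=pd.DataFrame(rows), stride_duration=sd)


# ---------------------------------------------------------------------------
# rotatory / translatory decomposition
# ---------------------------------------------------------------------------

def rot_trans_errors(report: ErrorReport, ring: int = 1,
                     slot: int = 1) -> dict:
    """nMAE distributions under simulated sensor repositioning.

    Rotatory: all slots of ring ``ring`` (rotation around the limb axis).
    Translatory: slot ``slot`` across all rings (translation along the limb).
    Shoe rows are excluded.
    """
    agg = report.aggregate()
    agg = agg[agg["segment"] != "shoe"]
    out = {}
    for name, sub in (
            ("rotatory", agg[agg["ring"] == ring]),
            ("translatory", agg[agg["slot"] == slot])):
        vals = sub["nmae_pct"].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        q1, med, q3 = (np.percentile(finite, [25, 50, 75])
                       if len(finite) else (np.nan,) * 3)
        out[name] = {"values": vals, "median": float(med),
                     "iqr": float(q3 - q1), "table": sub}
    return out


def plot_report(report: ErrorReport, outdir: str, vmax: float = 50.0) -> list:
    """Render per-segment nMAE boxplots and per-sensor heatmaps.

    Axes are clipped at ``vmax`` percent to highlight practically relevant
    sensor performance.  Returns the written file paths.  Requires
    matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    agg = report.aggregate()
    written = []

    fig, ax = plt.subplots(figsize=(8, 4))
    groups, labels = [], []
    for (seg, event), sub in agg.groupby(["segment", "event"]):
        vals = sub["nmae_pct"].to_numpy(dtype=float)
        groups.append(np.clip(vals[np.isfinite(vals)], 0, vmax))
        labels.append(f"{seg}\n{event}")
    ax.boxplot(groups, tick_labels=labels)
    ax.set_ylabel("nMAE [%]")
    ax.set_ylim(0, vmax)
    fig.tight_layout()
    path = out / "nmae_boxplot.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    for seg, sub in agg[agg["segment"] != "shoe"].groupby("segment"):
        pivot = sub.pivot_table(index="ring", columns="slot",
                                values="nmae_pct", aggfunc="mean")
        if pivot.size < 2:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(np.clip(pivot.to_numpy(dtype=float), 0, vmax),
                       aspect="auto", origin="upper", vmin=0, vmax=vmax)
        ax.set_xlabel("slot")
        ax.set_ylabel("ring")
        ax.set_title(f"{seg} nMAE [%]")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        path = out / f"nmae_heatmap_{seg}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written


# ---------------------------------------------------------------------------
# signal agreement (measured vs synthesised)
# ---------------------------------------------------------------------------

@dataclass
class AgreementMetrics:
    r_mean: float
    r_ci: tuple
    mad: float
    rmse: float
    nmad_pct: float
    n: int
    undefined: bool = False


def agreement_metrics(pairs) -> AgreementMetrics:
    """Pool per-participant agreement between measured and synthesised series.

    Pearson r per participant is pooled via the Fisher z transform (mean and
    95% CI on the z scale, back-transformed).  MAD is the median absolute
    difference, nMAD normalises by the peak-to-peak range of the measured
    series (configurable convention; the normaliser is not standardised).
    """
    zs, mads, rmses, nmads = [], [], [], []
    undefined = False
    for meas, synth in pairs:
        meas = np.asarray(meas, dtype=float)
        synth = np.asarray(synth, dtype=float)
        if meas.shape != synth.shape:
            raise InsufficientEventsError("paired series must share length")
        d = meas - synth
        mads.append(float(np.median(np.abs(d))))
        rmses.append(float(np.sqrt(np.mean(d**2))))
        ptp = float(np.ptp(meas))
        nmads.append(100.0 * mads[-1] / ptp if ptp > 0 else np.nan)
        if np.std(meas) == 0 or np.std(synth) == 0:
            undefined = True
            continue
        r = float(np.corrcoef(meas, synth)[0, 1])
        zs.append(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)))
    nmad = (float(np.nanmean(nmads))
            if np.any(np.isfinite(nmads)) else np.nan)
    if not zs:
        return AgreementMetrics(np.nan, (np.nan, np.nan),
                                float(np.mean(mads)), float(np.mean(rmses)),
                                nmad, len(mads), undefined=True)
    zs = np.array(zs)
    z_mean = float(np.mean(zs))
    if len(zs) >= 2:
        half = 1.96 * float(np.std(zs, ddof=1)) / np.sqrt(len(zs))
    else:
        half = 0.0
    return AgreementMetrics(
        r_mean=float(np.tanh(z_mean)),
        r_ci=(float(np.tanh(z_mean - half)), float(np.tanh(z_mean + half))),
        mad=float(np.mean(mads)), rmse=float(np.mean(rmses)),
        nmad_pct=nmad, n=len(mads), undefined=undefined)
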
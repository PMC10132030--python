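import numpy as np
import pandas as pd
import pytest

from gaitsim.errors import (
    InsufficientEventsError,
    NoStanceError,
    StrategyError,
)
from gaitsim.evaluation import (
    ErrorReport,
    GaitDataset,
    SensorPair,
    agreement_metrics,
    crossval,
    extract_reference_events,
    match_nearest,
    mean_stride_duration,
    rot_trans_errors,
    stride_folds,
    timing_error,
)
from gaitsim.gait_detection import EventSeries, GaitEvent
from gaitsim.kinematics_io import GrfTrace


def series(side, kind_times):
    events = [GaitEvent(k, t, side) for k, ts in kind_times.items()
              for t in ts]
    events.sort(key=lambda e: e.t)
    return EventSeries(side=side, events=events, phase_model=4)


def trapezoid_grf(t0=1.0, t1=1.7, fs=100.0, total=3.0, ramp=0.03, w=700.0):
    t = np.arange(0.0, total, 1.0 / fs)
    rise = np.clip((t - t0) / ramp, 0.0, 1.0)
    fall = np.clip((t1 - t) / ramp, 0.0, 1.0)
    f = w * np.minimum(rise, fall) * ((t > t0) & (t < t1))
    return GrfTrace(side="left", t=t, f_v=f, fs=fs)


class TestReferenceEvents:
    def test_trapezoid_stance(self):
        ref = extract_reference_events(trapezoid_grf())
        assert ref.times("IC")[0] == pytest.approx(1.0, abs=0.0101)
        assert ref.times("TO")[0] == pytest.approx(1.7, abs=0.0101)

    def test_constant_force_no_events(self):
        t = np.arange(0.0, 1.0, 0.01)
        grf = GrfTrace("left", t, np.full_like(t, 500.0))
        ref = extract_reference_events(grf)
        assert len(ref.events) == 0

    def test_two_stances_interleaved(self):
        t = np.arange(0.0, 5.0, 0.01)
        f = trapezoid_grf(1.0, 1.7, total=5.0).f_v + \
            trapezoid_grf(3.0, 3.7, total=5.0).f_v
        ref = extract_reference_events(GrfTrace("left", t, f))
        assert len(ref.times("IC")) == 2
        assert len(ref.times("TO")) == 2
        order = [e.kind for e in ref.events]
        assert order == ["IC", "TO", "IC", "TO"]

    def test_all_zero_rejected(self):
        t = np.arange(0.0, 1.0, 0.01)
        with pytest.raises(NoStanceError):
            extract_reference_events(GrfTrace("left", t, np.zeros_like(t)))

    def test_ground_truth_merge(self):
        ref = extract_reference_events(
            trapezoid_grf(), ground_truth={"MSt": [1.3], "MSw": [2.0]})
        assert list(ref.times("MSt")) == [1.3]
        assert list(ref.times("MSw")) == [2.0]


class TestStrideDuration:
    def test_equal_intervals(self):
        assert mean_stride_duration(
            series("left", {"IC": [0.0, 1.2, 2.4]})) == pytest.approx(1.2)

    def test_mean_of_unequal(self):
        assert mean_stride_duration(
            series("left", {"IC": [0.0, 1.0, 2.4]})) == pytest.approx(1.2)

    def test_single_ic_rejected(self):
        with pytest.raises(InsufficientEventsError):
            mean_stride_duration(series("left", {"IC": [1.0]}))


class TestTimingError:
    def test_worked_example(self):
        rep = timing_error(series("left", {"IC": [1.02, 1.98]}),
                           series("left", {"IC": [1.00, 2.00]}), f_bar=1.0)
        row = rep.df.iloc[0]
        assert row["mae_s"] == pytest.approx(0.02)
        assert row["nmae_pct"] == pytest.approx(2.0)

    def test_perfect_detection(self):
        rep = timing_error(series("left", {"IC": [1.0, 2.0]}),
                           series("left", {"IC": [1.0, 2.0]}), f_bar=1.0)
        assert rep.df.iloc[0]["nmae_pct"] == 0.0

    def test_missing_peak_inflates(self):
        rep = timing_error(series("left", {"IC": [1.0]}),
                           series("left", {"IC": [1.0, 2.0]}), f_bar=1.0)
        row = rep.df.iloc[0]
        assert row["mae_s"] == pytest.approx(0.5)
        assert row["nmae_pct"] == pytest.approx(50.0)

    def test_zero_detections_flagged(self):
        rep = timing_error(series("left", {}),
                           series("left", {"IC": [1.0, 2.0]}), f_bar=1.0)
        row = rep.df.iloc[0]
        assert bool(row["undefined"])
        assert np.isnan(row["nmae_pct"])

    def test_shift_invariance(self):
        det = [1.02, 1.98, 3.1]
        ref = [1.0, 2.0, 3.0]
        r1 = timing_error(series("left", {"IC": det}),
                          series("left", {"IC": ref}), f_bar=1.0)
        r2 = timing_error(series("left", {"IC": [x + 7.7 for x in det]}),
                          series("left", {"IC": [x + 7.7 for x in ref]}),
                          f_bar=1.0)
        assert r1.df.iloc[0]["mae_s"] == pytest.approx(
            r2.df.iloc[0]["mae_s"], abs=1e-12)

    def test_match_nearest_reuse(self):
        gaps = match_nearest(np.array([1.0]), np.array([0.9, 1.2]))
        assert gaps == pytest.approx([0.1, 0.2])


class TestCrossval:
    def test_fold_partition(self):
        ref = series("left", {"IC": list(np.arange(11) * 1.2)})  # 10 strides
        folds = stride_folds(ref, n_folds=5)
        assert len(folds) == 5
        # every stride in exactly one window
        for i in range(10):
            mid = 1.2 * i + 0.6
            hits = [f for f in folds if f[0] <= mid < f[1]]
            assert len(hits) == 1
        # contiguous coverage
        assert folds[0][0] == 0.0 and folds[-1][1] == pytest.approx(12.0)

    def test_too_few_strides(self):
        ref = series("left", {"IC": [0.0, 1.2, 2.4]})
        with pytest.raises(InsufficientEventsError):
            stride_folds(ref, n_folds=5)

    def test_a2b_single_participant_rejected(self, participant_vd):
        with pytest.raises(StrategyError):
            crossval(GaitDataset([participant_vd]), "A2b", 4)

    def test_unknown_variant(self, participant_vd):
        with pytest.raises(StrategyError):
            crossval(GaitDataset([participant_vd]), "A9", 4)

    def test_a2a_equals_a2c_homogeneous_sensors(self, shank_pair,
                                                participant_vd):
        # clone one sensor pair under several grid keys: identical signals,
        # so averaging thresholds across the segment changes nothing
        import dataclasses
        part = dataclasses.replace(participant_vd, sensors=[
            SensorPair("lower_leg", r, 1, shank_pair.signals)
            for r in (1, 2, 3)])
        rep_a = crossval(GaitDataset([part]), "A2a", 4)
        rep_c = crossval(GaitDataset([part]), "A2c", 4)
        pd.testing.assert_frame_equal(
            rep_a.df.drop(columns="variant"),
            rep_c.df.drop(columns="variant"))

    def test_a2a_close_to_a2b_identical_participants(self, scenario20):
        import copy
        from gaitsim.evaluation import participant_from_scenario
        keys = [("lower_leg", 1, 1)]
        p1 = participant_from_scenario(scenario20, keys, "p1")
        p2 = copy.deepcopy(p1)
        p2.participant_id = "p2"
        ds = GaitDataset([p1, p2])
        med_a = np.nanmedian(crossval(ds, "A2a", 4).aggregate()["nmae_pct"])
        med_b = np.nanmedian(crossval(ds, "A2b", 4).aggregate()["nmae_pct"])
        assert med_a == pytest.approx(med_b, abs=1.0)


class TestRotTrans:
    def _report(self, nmae_fn):
        rows = []
        for ring in range(1, 13):
            for slot in range(1, 17):
                rows.append({"participant": "p0", "segment": "lower_leg",
                             "ring": ring, "slot": slot, "side": "left",
                             "event": "IC", "variant": "A2c",
                             "phase_model": 1, "fold": 0,
                             "mae_s": 0.0, "nmae_pct": nmae_fn(ring, slot),
                             "n_ref": 10, "n_det": 10, "undefined": False})
        return ErrorReport(df=pd.DataFrame(rows), stride_duration={})

    def test_constant_grid_zero_iqrs(self):
        rep = self._report(lambda r, s: 7.0)
        out = rot_trans_errors(rep)
        assert out["rotatory"]["iqr"] == 0.0
        assert out["translatory"]["iqr"] == 0.0

    def test_azimuth_only_variation(self):
        rep = self._report(lambda r, s: float(s))
        out = rot_trans_errors(rep)
        assert out["rotatory"]["iqr"] > 0.0
        assert out["translatory"]["iqr"] == 0.0
        assert len(out["rotatory"]["values"]) == 16
        assert len(out["translatory"]["values"]) == 12

    def test_shoe_excluded(self):
        rep = self._report(lambda r, s: 1.0)
        rep.df.loc[:, "segment"] = "shoe"
        out = rot_trans_errors(rep)
        assert len(out["rotatory"]["values"]) == 0


class TestAgreement:
    @staticmethod
    def _pair_with_r(r, n=4):
        x = np.array([1.0, -1.0, 0.0, 0.0])
        z = np.array([0.0, 0.0, 1.0, -1.0])
        return x, r * x + np.sqrt(1 - r * r) * z

    def test_identical_series(self):
        m = agreement_metrics([(np.array([1.0, 2.0, 3.0]),
                                np.array([1.0, 2.0, 3.0]))])
        assert m.r_mean == pytest.approx(1.0, abs=1e-6)
        assert m.mad == 0.0 and m.rmse == 0.0 and m.nmad_pct == 0.0

    def test_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0])
        m = agreement_metrics([(x, -x)])
        assert m.r_mean == pytest.approx(-1.0, abs=1e-6)

    def test_fisher_z_pooling_worked_example(self):
        pairs = [self._pair_with_r(0.5), self._pair_with_r(0.8)]
        m = agreement_metrics(pairs)
        expected = np.tanh((np.arctanh(0.5) + np.arctanh(0.8)) / 2.0)
        assert m.r_mean == pytest.approx(expected, abs=1e-9)
        assert m.r_ci[0] < m.r_mean < m.r_ci[1]

    def test_constant_series_flagged(self):
        m = agreement_metrics([(np.ones(5), np.zeros(5))])
        assert m.undefined
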
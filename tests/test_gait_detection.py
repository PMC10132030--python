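import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitsim.errors import TrainingError, UnsupportedCombinationError
from gaitsim.gait_detection import (
    DetectionParams,
    ThetaSet,
    detect_ic_a1,
    detect_ic_a2,
    detect_mst_a2,
    detect_msw_a2,
    detect_peaks,
    detect_to_a2,
    fit_theta_h,
    run_phase_model,
    sign_changes,
)


def brute_force_peaks(x, fs, theta_h=None, theta_d=0.6, polarity="+"):
    """Independent oracle: exhaustive local-extrema enumeration, height
    filter, then greedy removal by extremity (ties to the earlier peak)."""
    x = list(map(float, x))
    sign = 1.0 if polarity == "+" else -1.0
    cands = []
    for i in range(1, len(x) - 1):
        if sign * x[i] > sign * x[i - 1] and sign * x[i] > sign * x[i + 1]:
            cands.append(i)
    if theta_h is not None:
        if polarity == "+":
            cands = [i for i in cands if x[i] >= theta_h]
        else:
            cands = [i for i in cands if x[i] <= theta_h]
    cands.sort(key=lambda i: (-sign * x[i], i))
    kept = []
    for i in cands:
        if all(abs(i - j) / fs >= theta_d for j in kept):
            kept.append(i)
    return sorted((i / fs, x[i]) for i in kept)


class TestDetectPeaks:
    def test_worked_example(self):
        # fs=1 so theta_d=1 means one sample
        peaks = detect_peaks(np.array([0, 1, 0, 2, 0]), fs=1.0,
                             theta_h=0.5, theta_d=1.0)
        assert [(p.t, p.h) for p in peaks] == [(1.0, 1.0), (3.0, 2.0)]

    def test_constant_series_empty(self):
        assert detect_peaks(np.full(100, 3.3), fs=100.0) == []

    def test_sinusoid_cycle_count(self):
        t = np.arange(0.0, 5.0, 0.01)
        x = np.sin(2 * np.pi * 1.0 * t)
        peaks = detect_peaks(x, fs=100.0, theta_h=0.5, theta_d=0.6)
        assert len(peaks) == 5

    def test_theta_d_keeps_higher(self):
        x = np.zeros(100)
        x[30] = 1.0
        x[60] = 2.0  # 0.3 s apart at fs=100
        peaks = detect_peaks(x, fs=100.0, theta_h=0.5, theta_d=0.6)
        assert len(peaks) == 1 and peaks[0].t == pytest.approx(0.6)

    def test_negative_polarity(self):
        x = np.array([0.0, -1.0, 0.0, -3.0, 0.0])
        peaks = detect_peaks(x, fs=1.0, theta_h=-0.5, theta_d=1.0,
                             polarity="-")
        assert [(p.t, p.h) for p in peaks] == [(1.0, -1.0), (3.0, -3.0)]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(60):
            n = int(rng.integers(10, 2000))
            x = rng.standard_normal(n).cumsum()
            theta_h = float(rng.normal()) if trial % 3 else None
            theta_d = float(rng.uniform(0.0, 0.5))
            pol = "+" if trial % 2 else "-"
            got = [(p.t, p.h)
                   for p in detect_peaks(x, 100.0, theta_h, theta_d, pol)]
            assert got == brute_force_peaks(x, 100.0, theta_h, theta_d, pol)

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000),
           theta=st.floats(-1.0, 3.0))
    def test_monotone_in_theta_h(self, seed, theta):
        x = np.random.default_rng(seed).standard_normal(300)
        lo = detect_peaks(x, 100.0, theta, 0.1)
        hi = detect_peaks(x, 100.0, theta + 0.5, 0.1)
        assert len(hi) <= len(lo)

    def test_times_on_grid(self):
        x = np.random.default_rng(1).standard_normal(500)
        for p in detect_peaks(x, 100.0, None, 0.05):
            assert (p.t * 100.0) == pytest.approx(round(p.t * 100.0))


class TestFitThetaH:
    def test_positive_example(self):
        x = np.array([0, 1, 0, 2, 0, 3, 0], dtype=float)
        theta = fit_theta_h(x, fs=1.0, polarity="+", fraction=0.15,
                            theta_d=1.0)
        assert theta == pytest.approx(2.0 - 0.3)

    def test_negative_example(self):
        x = np.array([0, -1, 0, -3, 0], dtype=float)
        theta = fit_theta_h(x, fs=1.0, polarity="-", fraction=0.15,
                            theta_d=1.0)
        assert theta == pytest.approx(-2.0 + 0.3)

    def test_single_candidate(self):
        x = np.array([0, 4.0, 0])
        theta = fit_theta_h(x, fs=1.0, polarity="+", fraction=0.25,
                            theta_d=1.0)
        assert theta == pytest.approx(4.0 * 0.75)

    def test_no_candidates(self):
        with pytest.raises(TrainingError):
            fit_theta_h(np.zeros(50), fs=100.0)


class TestSignChanges:
    def test_basic(self):
        assert list(sign_changes(np.array([0.5, -0.2]), fs=1.0)) == [1.0]

    def test_negative_to_positive_ignored(self):
        assert len(sign_changes(np.array([-1.0, 1.0]), fs=1.0)) == 0

    def test_zero_breaks_strictness(self):
        assert len(sign_changes(np.array([1.0, 0.0, -1.0]), fs=1.0)) == 0


def pulse(n, at, width=3, amp=1.0):
    x = np.zeros(n)
    for i in at:
        j = np.arange(max(0, i - width), min(n, i + width + 1))
        x[j] += amp * np.exp(-0.5 * ((j - i) / (width / 2.5)) ** 2)
    return x


class TestRuleDetectors:
    fs = 100.0

    def test_ic_a1_subthreshold_empty(self):
        params = DetectionParams(phase_model=1,
                                 thetas=ThetaSet(ic_accel=10.0))
        assert detect_ic_a1(np.zeros(500), self.fs, params) == []

    def test_ic_a2_pairing_window(self):
        n = 500
        omega = np.ones(n) * 0.1
        omega[100:] = -0.1  # sign change at sample 100 (t = 1.00)
        a = pulse(n, [103])  # accel peak at 1.03
        params = DetectionParams(phase_model=1,
                                 thetas=ThetaSet(ic_accel=0.5))
        ev = detect_ic_a2(a, omega, self.fs, params)
        assert [e.t for e in ev] == [pytest.approx(1.03)]

    def test_ic_a2_window_exceeded(self):
        n = 500
        omega = np.ones(n) * 0.1
        omega[100:] = -0.1
        a = pulse(n, [106])  # 60 ms after sign change
        params = DetectionParams(phase_model=1,
                                 thetas=ThetaSet(ic_accel=0.5))
        assert detect_ic_a2(a, omega, self.fs, params) == []

    def test_ic_a2_peak_before_sign_change(self):
        n = 500
        omega = np.ones(n) * 0.1
        omega[100:] = -0.1
        a = pulse(n, [97])
        params = DetectionParams(phase_model=1,
                                 thetas=ThetaSet(ic_accel=0.5))
        assert detect_ic_a2(a, omega, self.fs, params) == []

    def test_to_a2_pairing(self):
        n = 500
        a = -pulse(n, [140])   # accel trough at 1.40
        w = -pulse(n, [143])   # gyro trough at 1.43
        params = DetectionParams(
            phase_model=2, thetas=ThetaSet(to_accel=-0.5, to_gyro=-0.5))
        ev = detect_to_a2(a, w, self.fs, params)
        assert [e.t for e in ev] == [pytest.approx(1.43)]

    def test_to_a2_order_reversed(self):
        n = 500
        a = -pulse(n, [143])
        w = -pulse(n, [140])
        params = DetectionParams(
            phase_model=2, thetas=ThetaSet(to_accel=-0.5, to_gyro=-0.5))
        assert detect_to_a2(a, w, self.fs, params) == []

    def test_to_a2_window_exceeded(self):
        n = 500
        a = -pulse(n, [140])
        w = -pulse(n, [148])  # 80 ms later
        params = DetectionParams(
            phase_model=2, thetas=ThetaSet(to_accel=-0.5, to_gyro=-0.5))
        assert detect_to_a2(a, w, self.fs, params) == []

    def test_msw_quiet_contralateral_accepted(self):
        n = 500
        w = pulse(n, [250])
        a_contra = np.zeros(n)  # zero gradient passes any tolerance
        params = DetectionParams(
            phase_model=4, thetas=ThetaSet(msw_gyro=0.5, msw_grad_tol=0.0))
        ev = detect_msw_a2(w, a_contra, self.fs, params)
        assert [e.t for e in ev] == [pytest.approx(2.5)]

    def test_msw_impact_transient_rejected(self):
        n = 500
        w = pulse(n, [250])
        a_contra = np.zeros(n)
        a_contra[249:252] = [0.0, 5.0, 0.0]  # sharp transient at the peak
        params = DetectionParams(
            phase_model=4, thetas=ThetaSet(msw_gyro=0.5, msw_grad_tol=1.0))
        assert detect_msw_a2(w, a_contra, self.fs, params) == []

    def test_msw_no_peak(self):
        params = DetectionParams(
            phase_model=4, thetas=ThetaSet(msw_gyro=0.5, msw_grad_tol=1.0))
        assert detect_msw_a2(np.zeros(500), np.zeros(500), self.fs,
                             params) == []

    def test_mst_flat_contralateral_gyro(self):
        params = DetectionParams(
            phase_model=4, thetas=ThetaSet(mst_gyro=0.5, mst_grad_tol=1.0))
        assert detect_mst_a2(np.zeros(500), np.zeros(500), self.fs,
                             params) == []


class TestPhaseModel:
    def test_a1_multiphase_rejected(self, shank_pair):
        params = DetectionParams(phase_model=4)
        with pytest.raises(UnsupportedCombinationError):
            run_phase_model(shank_pair.signals["left"],
                            shank_pair.signals["right"], "A1", params)

    def test_four_phase_one_event_per_stride(self, shank_pair, scenario20):
        params = DetectionParams(phase_model=4)
        series = run_phase_model(shank_pair.signals["left"],
                                 shank_pair.signals["right"], "A2", params)
        for side in ("left", "right"):
            ics = scenario20.ground_truth.times(side, "IC")
            for kind in ("IC", "MSt", "TO", "MSw"):
                det = series[side].times(kind)
                # exactly one event of each kind inside every interior stride
                for i in range(1, len(ics) - 1):
                    inside = det[(det >= ics[i]) & (det < ics[i + 1])]
                    assert len(inside) == 1, (side, kind, i)

    def test_a1_equals_a2_counts_one_phase(self, shank_pair):
        params = DetectionParams(phase_model=1)
        s1 = run_phase_model(shank_pair.signals["left"],
                             shank_pair.signals["right"], "A1", params)
        s2 = run_phase_model(shank_pair.signals["left"],
                             shank_pair.signals["right"], "A2", params)
        for side in ("left", "right"):
            assert len(s1[side].times("IC")) == len(s2[side].times("IC"))

    def test_empty_signals(self):
        class Empty:
            t = np.array([])
            a_y = np.array([])
            omega_z = np.array([])
            fs = 100.0

        params = DetectionParams(phase_model=4)
        series = run_phase_model(Empty(), Empty(), "A2", params)
        assert series["left"].events == []

    def test_same_kind_spacing_invariant(self, shank_pair):
        params = DetectionParams(phase_model=4)
        series = run_phase_model(shank_pair.signals["left"],
                                 shank_pair.signals["right"], "A2", params)
        for side in ("left", "right"):
            for kind in ("IC", "MSt", "TO", "MSw"):
                t = series[side].times(kind)
                assert np.all(np.diff(t) >= 0.6 - 1e-12)

    def test_event_times_on_grid(self, shank_pair):
        params = DetectionParams(phase_model=4)
        series = run_phase_model(shank_pair.signals["left"],
                                 shank_pair.signals["right"], "A2", params)
        grid = shank_pair.signals["left"].t
        for e in series["left"].events:
            assert np.min(np.abs(grid - e.t)) < 1e-9
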
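import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oegait import (EnergySummary, GaitSegment, VelocitySignal,
                    classify_ep_region, compute_energies,
                    ep_graph_coordinates, iso_vte_contour, oep_scaling,
                    oscillatory_velocity_estimate, trajectory_frontal_plane)
from oegait.energetics import StrideTrajectory
from oegait.errors import (InsufficientGaitError, ParameterError,
                           UndefinedRatioError)
from oegait.preprocessing import DisplacementSignal

FS = 100.0


def _segment(start=0.0, n_strides=10, step=0.55):
    events = start + step * np.arange(2 * n_strides + 1)
    return GaitSegment(start_s=start, end_s=start + n_strides * 2 * step,
                       step_events=events, step_period=step,
                       n_periods=n_strides)


def _velocity(v_bar=1.3, ap=None, ml=None, vt=None, seconds=20.0):
    t = np.arange(int(seconds * FS)) / FS
    zero = np.zeros_like(t)

    def centre(x):
        return zero if x is None else x - x.mean()

    return t, VelocitySignal(t=t, v_bar_ap=v_bar, v_ap=centre(ap),
                             v_ml=centre(ml), v_vt=centre(vt))


class TestComputeEnergies:
    def test_sinusoid_closed_form(self):
        """VTE of v_vt = 0.2 cos(2*pi*t/T) is A^2/4 = 0.01 m^2/s^2."""
        T = 0.5
        t = np.arange(int(20 * FS)) / FS
        _, vel = _velocity(vt=0.2 * np.cos(2 * np.pi * t / T))
        seg = _segment(n_strides=18, step=T)
        summary = compute_energies(vel, seg)
        assert summary.vte == pytest.approx(0.01, rel=1e-3)
        assert summary.ape == pytest.approx(0.0, abs=1e-15)

    def test_no_oscillation(self):
        """Pure forward walking: KE0 = 0.845, TOE = 0, OEP = 0."""
        _, vel = _velocity(v_bar=1.3)
        summary = compute_energies(vel, _segment())
        assert summary.ke0 == pytest.approx(0.845)
        assert summary.toe == 0.0
        assert summary.oep == 0.0
        assert not summary.ep_defined

    def test_decomposition_identity_random_signals(self):
        """Ek computed from the full velocity vector equals KE0 + TOE to 1e-6
        relative on zero-mean windows (the cross term vanishes)."""
        rng = np.random.default_rng(42)
        n = int(20 * FS)
        _, vel = _velocity(ap=rng.normal(size=n), ml=rng.normal(size=n),
                           vt=rng.normal(size=n))
        summary = compute_energies(vel, _segment())
        assert abs(summary.ek_bar - (summary.ke0 + summary.toe)) \
            < 1e-6 * summary.ek_bar

    def test_oe_equals_half_variance(self):
        """Each axis OE is exactly half the population variance."""
        rng = np.random.default_rng(7)
        n = int(20 * FS)
        x = rng.normal(size=n)
        t, vel = _velocity(ml=x)
        seg = _segment()
        summary = compute_energies(vel, seg)
        sl = seg.sample_slice(t)
        v = vel.v_ml[sl]
        assert summary.mle == pytest.approx(0.5 * np.var(v), rel=1e-12)

    def test_zero_speed_with_oscillation_undefined(self):
        t = np.arange(int(20 * FS)) / FS
        _, vel = _velocity(v_bar=0.0, vt=0.1 * np.sin(2 * np.pi * t))
        with pytest.raises(UndefinedRatioError):
            compute_energies(vel, _segment())

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(k=st.floats(0.1, 5.0))
    def test_quadratic_scaling_property(self, k):
        """Scaling all oscillatory components by k scales every OE and the
        OEP by exactly k^2 (within 1e-12 relative)."""
        rng = np.random.default_rng(11)
        n = int(20 * FS)
        base = {ax: rng.normal(size=n) for ax in ("ap", "ml", "vt")}
        _, v1 = _velocity(ap=base["ap"], ml=base["ml"], vt=base["vt"])
        _, v2 = _velocity(ap=k * base["ap"], ml=k * base["ml"],
                          vt=k * base["vt"])
        seg = _segment()
        s1, s2 = compute_energies(v1, seg), compute_energies(v2, seg)
        assert s2.toe == pytest.approx(k * k * s1.toe, rel=1e-12)
        assert s2.oep == pytest.approx(k * k * s1.oep, rel=1e-12)
        assert s2.vte == pytest.approx(k * k * s1.vte, rel=1e-12)


class TestScalingRelations:
    def test_displacement_doubles_between_3_and_6_pct(self):
        """4 cm at 3% OEP scales to ~5.66 cm at 6% (sqrt law)."""
        assert oep_scaling(0.04, 0.03, 0.06) == pytest.approx(0.0566, abs=5e-4)

    def test_identity_and_quadruple(self):
        assert oep_scaling(0.04, 0.03, 0.03) == 0.04
        assert oep_scaling(0.04, 0.03, 0.12) == pytest.approx(0.08)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            oep_scaling(-0.04, 0.03, 0.06)
        with pytest.raises(ParameterError):
            oep_scaling(0.04, 0.0, 0.06)

    def test_oscillatory_velocity_estimate(self):
        """Round-trip rule 2*d/T: 2 cm over 0.55 s -> 0.0727 m/s."""
        assert oscillatory_velocity_estimate(0.02, 0.55) \
            == pytest.approx(0.0727, abs=1e-4)
        assert oscillatory_velocity_estimate(0.0, 0.55) == 0.0

    def test_estimate_matches_sinusoid_mean_speed(self):
        """For sinusoidal displacement the round-trip rule 2*d/T equals the
        true mean |velocity| (path 2*d_pp per period); the peak is pi*d/T."""
        d, T = 0.03, 0.55
        t = np.linspace(0.0, T, 100001)
        disp = (d / 2) * np.sin(2 * np.pi * t / T)
        v = np.gradient(disp, t)
        est = oscillatory_velocity_estimate(d, T)
        assert np.mean(np.abs(v)) == pytest.approx(est, rel=1e-3)
        assert np.max(np.abs(v)) == pytest.approx(np.pi * d / T, rel=1e-3)


def _summary(ml, ap, vt, oep=0.03):
    toe = 0.012
    return EnergySummary(ke0=toe / oep, ape=toe * ap / 100,
                         mle=toe * ml / 100, vte=toe * vt / 100, toe=toe,
                         ek_bar=toe / oep + toe, oep=oep, ep_ap_pct=ap,
                         ep_ml_pct=ml, ep_vt_pct=vt)


class TestEPGraph:
    def test_point_and_contour(self):
        """MLE 4 / APE 30 / VTE 66 lands at (4, 30) on the 66% contour."""
        point, level = ep_graph_coordinates(_summary(4.0, 30.0, 66.0))
        assert point == (4.0, 30.0)
        assert level == pytest.approx(66.0)

    def test_all_vertical_is_origin(self):
        point, level = ep_graph_coordinates(_summary(0.0, 0.0, 100.0))
        assert point == (0.0, 0.0)
        assert level == pytest.approx(100.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ml=st.floats(0, 100), frac=st.floats(0, 1))
    def test_contour_level_affine_identity(self, ml, frac):
        """Any EP point lies on exactly the contour L = 100 - x - y."""
        ap = frac * (100.0 - ml)
        vt = max(0.0, 100.0 - ml - ap)
        ml = 100.0 - ap - vt
        _, level = ep_graph_coordinates(_summary(ml, ap, vt))
        assert level == pytest.approx(vt, abs=1e-9)

    def test_iso_contour_endpoints(self):
        assert iso_vte_contour(66.0) == ((0.0, 34.0), (34.0, 0.0))


class TestEPRegion:
    def test_typical_gait(self):
        label, violated = classify_ep_region(_summary(7.0, 29.0, 64.0))
        assert label == "typical" and violated == []

    def test_grossly_lateral_gait(self):
        """MLE 80 / VTE 10 violates both the VTE and MLE bounds."""
        label, violated = classify_ep_region(_summary(80.0, 10.0, 10.0))
        assert label == "atypical"
        assert any("VTE" in v for v in violated)
        assert any("MLE" in v for v in violated)

    def test_boundary_is_strict(self):
        """VTE% exactly 40 fails the strict > 40 bound."""
        label, violated = classify_ep_region(_summary(30.0, 30.0, 40.0))
        assert label == "atypical"
        assert any("VTE" in v for v in violated)


def _polyline_self_intersects(x, y):
    """Any two non-adjacent segments of the closed polyline cross."""
    pts = np.column_stack([x, y])
    segs = list(zip(pts[:-1], pts[1:]))

    def cross2(a, b):
        return a[0] * b[1] - a[1] * b[0]

    def crosses(p1, p2, p3, p4):
        d1 = cross2(p4 - p3, p1 - p3)
        d2 = cross2(p4 - p3, p2 - p3)
        d3 = cross2(p2 - p1, p3 - p1)
        d4 = cross2(p2 - p1, p4 - p1)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    n = len(segs)
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if crosses(*segs[i], *segs[j]):
                return True
    return False


class TestTrajectory:
    def _disp(self, stride=1.1, seconds=20.0, ml_amp=0.01, vt_amp=0.015):
        t = np.arange(int(seconds * FS)) / FS
        ml = ml_amp * np.sin(2 * np.pi * t / stride)
        vt = vt_amp * np.sin(4 * np.pi * t / stride)
        ap = np.zeros_like(t)
        return DisplacementSignal(t=t, d_ap=ap, d_ml=ml, d_vt=vt,
                                  d_pp={"ap": 0, "ml": 2 * ml_amp,
                                        "vt": 2 * vt_amp})

    def test_fold_of_periodic_signal_is_one_period(self):
        """Folding a perfectly stride-periodic signal reproduces a single
        period within 1e-9."""
        stride = 1.0
        disp = self._disp(stride=stride)
        seg = _segment(start=0.0, n_strides=10, step=stride / 2)
        traj = trajectory_frontal_plane(disp, seg, n_points=100)
        expect_ml = 0.01 * np.sin(2 * np.pi * traj.time / stride)
        np.testing.assert_allclose(traj.ml, expect_ml - expect_ml.mean(),
                                   atol=1e-9)

    def test_bowtie_self_intersection(self):
        """Two VT cycles per ML cycle make the frontal-plane curve cross
        itself (the bow-tie)."""
        disp = self._disp(stride=1.0)
        seg = _segment(start=0.0, n_strides=10, step=0.5)
        traj = trajectory_frontal_plane(disp, seg, n_points=120)
        ml = np.append(traj.ml, traj.ml[0])
        vt = np.append(traj.vt, traj.vt[0])
        assert _polyline_self_intersects(ml, vt)

    def test_single_axis_is_degenerate_line(self):
        disp = self._disp(stride=1.0, ml_amp=0.0)
        seg = _segment(start=0.0, n_strides=10, step=0.5)
        traj = trajectory_frontal_plane(disp, seg, n_points=100)
        assert np.ptp(traj.ml) < 1e-12
        assert np.ptp(traj.vt) > 0.01

    def test_needs_four_strides(self):
        disp = self._disp(stride=1.0)
        seg = _segment(start=0.0, n_strides=3, step=0.5)
        with pytest.raises(InsufficientGaitError):
            trajectory_frontal_plane(disp, seg)


def test_pipeline_trajectory_is_bowtie(normal_report, normal_sim):
    """The full pipeline's stride-folded frontal trajectory self-intersects."""
    from oegait.calibration import apply_calibration, estimate_neutral_pose
    from oegait.preprocessing import (bandpass_accel,
                                      integrate_to_displacement,
                                      integrate_to_velocity)
    from oegait.segmentation import detect_steps, select_steady_state

    _, rec, _ = normal_sim
    pose = estimate_neutral_pose(rec, (0.0, 3.0))
    filt = bandpass_accel(apply_calibration(rec, pose), FS)
    events = detect_steps(filt[:, 2], FS)
    seg = select_steady_state((rec.timestamps[0], rec.timestamps[-1]),
                              events, "none")[0]
    vel = integrate_to_velocity(filt, rec.timestamps,
                                forward_speed_source="treadmill",
                                metadata=rec.metadata,
                                centring=seg.sample_slice(rec.timestamps))
    disp = integrate_to_displacement(vel, seg)
    traj = trajectory_frontal_plane(disp, seg, n_points=120)
    ml = np.append(traj.ml, traj.ml[0])
    vt = np.append(traj.vt, traj.vt[0])
    assert _polyline_self_intersects(ml, vt)
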
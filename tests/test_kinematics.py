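"""Kinematics tests: curvature, head-frame integration, turning angle,
phases, velocities, Reynolds number, added-mass estimate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cturnkit as ck
from cturnkit.geometry import BodyGeometry, height_profile
from cturnkit.kinematics import (
    CurvatureField,
    added_mass_force,
    alpha_max_track,
    angular_metrics,
    centroid_velocities,
    curvature_from_midline,
    heading_track,
    integrate_curvature,
    reynolds,
    segment_phases,
    turning_angle,
)
from cturnkit.midline import Midline


def _arc_midline(kappa_L, n=400, L=3.6):
    """Analytic constant-curvature midline (kappa in 1/L units), in cm."""
    s = np.linspace(0.0, 1.0, n)
    if kappa_L == 0:
        pts = np.column_stack([s, np.zeros(n)]) * L
    else:
        pts = np.column_stack([np.sin(kappa_L * s) / kappa_L,
                               (1 - np.cos(kappa_L * s)) / kappa_L]) * L
    return Midline(t=0.0, points=pts, s_grid=s, L_measured=L)


class TestCurvatureFromMidline:
    def test_circular_arc(self):
        m = _arc_midline(2.0)
        k = curvature_from_midline(m)
        assert np.abs(k - 2.0).max() / 2.0 < 0.005

    def test_straight_midline(self):
        m = _arc_midline(0.0)
        assert np.abs(curvature_from_midline(m)).max() < 1e-6

    def test_generated_c_pose_recovery(self):
        """Curvature recovered from a generated C-pose midline matches the
        generator field within 5% of the amplitude A on the interior."""
        tpl = ck.maneuver_template("turn_mid")
        fld = ck.make_cturn_curvature(tpl)
        i = np.unravel_index(np.abs(fld.kappa).argmax(), fld.kappa.shape)[0]
        _, x, y = integrate_curvature(fld.kappa[i], fld.s_grid)
        m = Midline(t=0.0, points=np.column_stack([x, y]) * tpl.L,
                    s_grid=fld.s_grid, L_measured=tpl.L)
        k = curvature_from_midline(m)
        sel = (fld.s_grid >= 0.1) & (fld.s_grid <= 0.9)
        assert np.abs(k - fld.kappa[i])[sel].max() < 0.05 * tpl.A


class TestIntegrateCurvature:
    def test_zero_curvature_is_straight(self):
        alpha, x, y = integrate_curvature(np.zeros(2001))
        assert np.all(alpha == 0)
        assert np.allclose(y, 0)
        assert x[-1] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("c", [0.1, 1.0, np.pi])
    def test_constant_curvature_closed_form(self, c):
        """kappa = c gives a circular arc: alpha(1) = c, endpoint at
        ((sin c)/c, (1-cos c)/c), arc length preserved — all to 1e-6."""
        s = np.linspace(0.0, 1.0, 2001)
        alpha, x, y = integrate_curvature(np.full(s.size, c), s)
        assert alpha[-1] == pytest.approx(c, abs=1e-9)
        assert x[-1] == pytest.approx(np.sin(c) / c, abs=1e-6)
        assert y[-1] == pytest.approx((1 - np.cos(c)) / c, abs=1e-6)
        chord = np.linalg.norm(
            np.diff(np.column_stack([x, y]), axis=0), axis=1).sum()
        assert chord == pytest.approx(1.0, abs=1e-6)

    def test_round_trip_with_curvature_estimate(self):
        """midline -> curvature -> integrate reproduces the head-frame
        midline within 1e-3 L pointwise."""
        s = np.linspace(0.0, 1.0, 800)
        kap = 4.0 * np.exp(-0.5 * ((s - 0.5) / 0.15) ** 2)
        a0, x0, y0 = integrate_curvature(kap, s)
        m = Midline(t=0.0, points=np.column_stack([x0, y0]), s_grid=s,
                    L_measured=1.0)
        k_est = curvature_from_midline(m)
        a1, x1, y1 = integrate_curvature(k_est, s)
        err = np.hypot(x1 - x0, y1 - y0).max()
        assert err < 1e-3


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.floats(0.05, 4.0))
def test_integration_length_preserving(c):
    """Arc-length preservation holds across constant curvatures."""
    s = np.linspace(0.0, 1.0, 2001)
    _, x, y = integrate_curvature(np.full(s.size, c), s)
    chord = np.linalg.norm(np.diff(np.column_stack([x, y]), axis=0),
                           axis=1).sum()
    assert abs(chord - 1.0) < 1e-5


class TestTurningAngle:
    def test_identical_frames_zero(self):
        m = _arc_midline(1.0)
        phi, _ = turning_angle([m, m])
        assert phi == 0.0

    def test_prescribed_angle_recovered(self, roundtrip):
        rt = roundtrip("turn_large")
        phi, sign = turning_angle(rt["midlines"])
        assert phi == pytest.approx(156.3, abs=2.0)
        assert sign == 1

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(5)
        mids = []
        for k in np.linspace(0.5, 3.0, 5):
            mids.append(_arc_midline(k))
        phi0, _ = turning_angle(mids)
        th = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shifted = [Midline(t=m.t, points=m.points @ R.T + 5.0,
                           s_grid=m.s_grid, L_measured=m.L_measured)
                   for m in mids]
        phi1, _ = turning_angle(shifted)
        assert phi1 == pytest.approx(phi0, abs=1e-9)

    def test_requires_two_frames(self):
        with pytest.raises(ValueError):
            turning_angle([_arc_midline(1.0)])


class TestPhases:
    def test_zero_curvature_all_glide(self):
        labels, flags = segment_phases(np.zeros(40), np.zeros(40))
        assert np.all(labels == "glide")
        assert not flags["multi_peak"]

    def test_transition_near_bend_end(self, roundtrip):
        rt = roundtrip("turn_large")
        t = rt["seq"].times
        psi = heading_track(rt["midlines"])
        omega, _, _ = angular_metrics(psi, t)
        a = alpha_max_track(rt["midlines"], smooth_window=21,
                            trim=(0.05, 0.92))
        labels, flags = segment_phases(a, omega)
        trans = next(i for i in range(1, len(labels))
                     if labels[i - 1] == "bending" and labels[i] == "recovery")
        bend_end = rt["template"].phase_fractions[0]
        assert trans / len(labels) == pytest.approx(bend_end, abs=0.05)
        assert not flags["multi_peak"]

    def test_bending_fraction_tracks_template(self):
        tpl = ck.maneuver_template("turn_large", phase_fractions=(0.4, 0.7))
        fld, pose, seq = ck.synthesize_maneuver(tpl)
        mids, _, _ = ck.extract_midlines(seq)
        psi = heading_track(mids)
        omega, _, _ = angular_metrics(psi, seq.times)
        a = alpha_max_track(mids, smooth_window=21, trim=(0.05, 0.92))
        labels, _ = segment_phases(a, omega)
        frac = (labels == "bending").mean()
        assert frac == pytest.approx(0.4, abs=0.06)


class TestVelocities:
    def test_stationary_body(self):
        track = np.tile([1.0, 2.0], (30, 1))
        t = np.linspace(0, 0.2, 30)
        u0, um, ue = centroid_velocities(track, t, 3.6, 0.2)
        for u in (u0, um, ue):
            assert u == pytest.approx(0.0, abs=1e-12)

    def test_unit_speed_translation(self):
        L, T = 3.6, 0.2
        t = np.linspace(0, T, 40)
        track = np.column_stack([L / T * t, np.zeros(40)])
        u0, um, ue = centroid_velocities(track, t, L, T)
        for u in (u0, um, ue):
            assert u == pytest.approx(1.0, rel=0.02)

    def test_generator_initial_speed_recovered(self, roundtrip):
        rt = roundtrip("turn_large")
        u0, um, ue = centroid_velocities(
            rt["centroid"], rt["seq"].times,
            rt["template"].L, rt["template"].T)
        assert u0 == pytest.approx(rt["template"].u0_frac, abs=0.03)


class TestAngularMetrics:
    def test_direct_quotient(self):
        t = np.linspace(0.0, 0.195, 40)
        psi = np.radians(np.linspace(0.0, 156.3, 40))
        _, omega_ave, _ = angular_metrics(psi, t)
        assert omega_ave == pytest.approx(156.3 / 0.195, rel=1e-9)
        assert omega_ave == pytest.approx(801.5, abs=0.5)

    def test_constant_rate(self):
        t = np.linspace(0.0, 1.0, 50)
        psi = 2.0 * t
        omega, omega_ave, omega_m = angular_metrics(psi, t)
        assert omega_m == pytest.approx(omega_ave, rel=0.01)

    def test_zero_turn(self):
        t = np.linspace(0.0, 1.0, 30)
        _, omega_ave, _ = angular_metrics(np.zeros(30), t)
        assert omega_ave == 0.0


class TestReynolds:
    def test_paper_conditions(self):
        assert reynolds(3.60, 0.195, 998.0, 1.00e-3) == pytest.approx(
            6.63e3, rel=0.005)

    def test_quadratic_scaling_in_length(self):
        assert reynolds(7.2, 0.195) == pytest.approx(
            4 * reynolds(3.6, 0.195), rel=1e-12)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            reynolds(-1.0, 0.195)


class TestAddedMass:
    def _field(self, kappa):
        n_t, n_s = kappa.shape
        return CurvatureField(s_grid=np.linspace(0, 1, n_s),
                              t_grid=np.linspace(0, 0.2, n_t),
                              kappa=kappa)

    def test_rigid_body_zero_force(self):
        fld = self._field(np.full((30, 100), 1.5))
        F = added_mass_force(fld, BodyGeometry())
        assert np.abs(F).max() < 1e-12

    def test_sign_flip_antisymmetry(self):
        s = np.linspace(0, 1, 100)
        t = np.linspace(0, 0.2, 30)
        kap = 2.0 * np.sin(2 * np.pi * (s[None, :] - t[:, None] / 0.2))
        fld = self._field(kap)
        fld_neg = self._field(-kap)
        g = BodyGeometry()
        assert np.allclose(added_mass_force(fld, g),
                           -added_mass_force(fld_neg, g), atol=1e-14)

    def test_small_amplitude_wave_matches_closed_form(self):
        """Small lateral wave y = eps sin(ks - wt): the slender-body force
        must match -int m(s) d2/dt2 y_hf ds evaluated analytically, where
        y_hf is the wave re-expressed in the head frame (value and slope at
        s = 0 removed, as the curvature integration does)."""
        eps, k, w = 1e-4, 2 * np.pi, 2 * np.pi / 0.2
        s = np.linspace(0, 1, 600)
        t = np.linspace(0, 0.2, 240)
        g = BodyGeometry()
        # curvature of the prescribed wave (exact to O(eps^2))
        kap = -eps * k**2 * np.sin(k * s[None, :] - w * t[:, None])
        fld = CurvatureField(s_grid=s, t_grid=t, kappa=kap)
        F = added_mass_force(fld, g, rho=998.0)
        L_m = g.L / 100.0
        h = height_profile(g, s) * L_m
        m_lin = 998.0 * np.pi * (h / 2) ** 2
        # y_hf = eps [sin(ks-wt) + sin(wt) - s k cos(wt)], so
        # d2/dt2 y_hf = eps w^2 [-sin(ks-wt) - sin(wt) + s k cos(wt)]
        S, T = s[None, :], t[:, None]
        ytt = eps * w**2 * (-np.sin(k * S - w * T) - np.sin(w * T)
                            + S * k * np.cos(w * T)) * L_m
        F_ref = -np.trapezoid(m_lin[None, :] * ytt, s * L_m, axis=1)
        sel = slice(5, -5)
        scale = np.abs(F_ref).max()
        assert np.abs(F - F_ref)[sel].max() < 0.02 * scale
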
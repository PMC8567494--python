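"""Snell refraction, anisotropic speed model and Fermat travel times."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq, minimize_scalar

from osteoflow import acoustics as ac


def brute_force_fermat(src, dst, zi, c1, c2, n=100_000):
    """Independent oracle: exhaustive crossing-point scan + local refinement."""
    xs = np.linspace(min(src[0], dst[0]) - 20, max(src[0], dst[0]) + 20, n)
    d1 = np.hypot(xs - src[0], zi - src[1]) / (c1 * 1e-3)
    dx2, dz2 = dst[0] - xs, dst[1] - zi
    if callable(c2):
        c = c2(np.arctan2(dz2, dx2)) * 1e-3
    else:
        c = c2 * 1e-3
    t = d1 + np.hypot(dx2, dz2) / c
    i = int(np.argmin(t))

    def f(x):
        dxx, dzz = dst[0] - x, dst[1] - zi
        cl = (c2(math.atan2(dzz, dxx)) if callable(c2) else c2) * 1e-3
        return math.hypot(x - src[0], zi - src[1]) / (c1 * 1e-3) \
            + math.hypot(dxx, dzz) / cl

    r = minimize_scalar(f, bounds=(xs[max(i - 1, 0)], xs[min(i + 1, n - 1)]),
                        method="bounded", options={"xatol": 1e-12})
    return float(r.fun)


class TestRefraction:
    def test_normal_incidence_unchanged(self):
        assert ac.refract_angle(0.0, 1500, 3000) == 0.0

    def test_snell_closed_form(self):
        got = ac.refract_angle(math.radians(20), 1500, 3000)
        assert got == pytest.approx(math.asin(2 * math.sin(math.radians(20))))
        assert math.degrees(got) == pytest.approx(43.16, abs=0.01)

    def test_total_internal_reflection(self):
        with pytest.raises(ac.TotalInternalReflectionError):
            ac.refract_angle(math.radians(35), 1500, 3000)

    @given(theta=st.floats(-0.45, 0.45), ratio=st.floats(0.3, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_snell_consistency_and_sign(self, theta, ratio):
        c1 = 1500.0
        c2 = c1 * ratio
        s = ratio * math.sin(theta)
        if abs(s) > 1:
            with pytest.raises(ac.TotalInternalReflectionError):
                ac.refract_angle(theta, c1, c2)
            return
        t = ac.refract_angle(theta, c1, c2)
        assert abs(math.sin(t) - s) < 1e-12
        assert math.copysign(1, t) == math.copysign(1, theta) or theta == 0


class TestBoneSpeed:
    def test_isotropic_limit(self):
        g = np.random.default_rng(0).uniform(-np.pi, np.pi, 20)
        assert np.allclose(ac.bone_speed(g, (3500, 0, 0)), 3500)

    def test_even_symmetry(self):
        g = np.random.default_rng(1).uniform(-np.pi, np.pi, 100)
        assert np.allclose(ac.bone_speed(g, (3300, 0.06, 0.01)),
                           ac.bone_speed(-g, (3300, 0.06, 0.01)))

    def test_pi_periodicity(self):
        g = np.linspace(0, np.pi, 50)
        assert np.allclose(ac.bone_speed(g, (3300, 0.06, 0.01)),
                           ac.bone_speed(g + np.pi, (3300, 0.06, 0.01)))

    def test_argmax_matches_stationary_points(self):
        """Brute-force grid max against the analytic derivative roots."""
        params = (3300.0, 0.06, 0.01)
        g = np.linspace(0, np.pi, 200_001)
        c = ac.bone_speed(g, params)
        g_max = g[np.argmax(c)]
        # dc/dg = -c0*(2*a2*sin2g + 4*a4*sin4g) = 0; gamma = 0 is a root and
        # with a2, a4 > 0 the global max
        assert g_max == pytest.approx(0.0, abs=2e-5) or \
            g_max == pytest.approx(np.pi, abs=2e-5)

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ac.NonPositiveSpeedError):
            ac.LayeredMediumModel(bone_speed_params=(1000.0, -0.9, -0.4))


class TestTwoLayerTravelTime:
    def test_homogeneous_straight_ray(self):
        t, _ = ac.two_layer_travel_time((0, 0), (0, 30), 8.0, 1500.0, 1500.0)
        assert t == pytest.approx(20.0, abs=1e-9)

    def test_dst_on_interface_single_segment(self):
        t, xc = ac.two_layer_travel_time((0, 0), (3, 8.0), 8.0, 1570.0, 3300.0)
        assert t == pytest.approx(math.hypot(3, 8) / 1.57, abs=1e-9)

    def test_matches_brute_force_oracle(self, medium):
        rng = np.random.default_rng(42)
        for _ in range(25):
            src = (rng.uniform(-10, 10), 0.0)
            dst = (rng.uniform(-10, 10), rng.uniform(8.5, 12.9))
            t, _ = ac.two_layer_travel_time(src, dst, 8.0, 1570.0,
                                            medium.bone_speed)
            tb = brute_force_fermat(src, dst, 8.0, 1570.0, medium.bone_speed)
            assert abs(t - tb) < 1e-3  # 1e-3 us = 1e-9 s

    def test_reciprocity(self, medium):
        rng = np.random.default_rng(3)
        for _ in range(20):
            src = (rng.uniform(-8, 8), rng.uniform(0, 7.9))
            dst = (rng.uniform(-8, 8), rng.uniform(8.1, 12.9))
            t1, _ = ac.two_layer_travel_time(src, dst, 8.0, 1570.0,
                                             medium.bone_speed)
            t2, _ = ac.two_layer_travel_time(dst, src, 8.0, 1570.0,
                                             medium.bone_speed)
            assert abs(t1 - t2) < 1e-3

    def test_fermat_optimality_under_perturbation(self, medium):
        """Moving the crossing by +-0.1 mm never decreases the time."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            src = (rng.uniform(-10, 10), 0.0)
            dst = (rng.uniform(-10, 10), rng.uniform(8.5, 12.9))
            t, (xc, zi) = ac.two_layer_travel_time(src, dst, 8.0, 1570.0,
                                                   medium.bone_speed)
            for dx in (-0.1, 0.1):
                t_p = (ac._segment_time(src, (xc + dx, zi), 1570.0)
                       + ac._segment_time((xc + dx, zi), dst,
                                          medium.bone_speed))
                assert t_p >= t - 1e-12

    def test_isotropic_limit_matches_snell_root(self):
        """a2 = a4 = 0 equals the closed two-layer form from Snell root-finding."""
        c1, c2, zi = 1570.0, 3300.0, 8.0
        src, dst = (-4.0, 0.0), (5.0, 12.0)
        t, _ = ac.two_layer_travel_time(src, dst, zi, c1, c2)

        def mismatch(p):
            # horizontal slowness p; horizontal offsets of the two segments
            s1 = p * c1 * 1e-3
            s2 = p * c2 * 1e-3
            x1 = zi * s1 / math.sqrt(1 - s1 ** 2)
            x2 = (dst[1] - zi) * s2 / math.sqrt(1 - s2 ** 2)
            return x1 + x2 - (dst[0] - src[0])

        p_max = 0.999 / (c2 * 1e-3)
        p = brentq(mismatch, 0, p_max, xtol=1e-15)
        s1 = p * c1 * 1e-3
        s2 = p * c2 * 1e-3
        x1 = zi * s1 / math.sqrt(1 - s1 ** 2)
        t_ref = math.hypot(x1, zi) / (c1 * 1e-3) \
            + math.hypot(dst[0] - src[0] - x1, dst[1] - zi) / (c2 * 1e-3)
        assert abs(t - t_ref) < 1e-3


class TestPlaneWaveArrival:
    def test_homogeneous_closed_form(self):
        hom = ac.LayeredMediumModel(interface_skin_bone_depth=50,
                                    interface_bone_marrow_depth=60,
                                    c_tissue=1540.0)
        th = math.radians(10)
        x, z = 3.0, 20.0
        t = ac.plane_wave_arrival_time(th, (x, z), hom)
        assert t == pytest.approx((z * math.cos(th) + x * math.sin(th))
                                  / 1.54, abs=1e-12)

    def test_pixel_on_interface_at_zero_angle(self, medium):
        t = ac.plane_wave_arrival_time(0.0, (0.0, 8.0), medium)
        assert t == pytest.approx(8.0 / 1.57, abs=1e-12)

    def test_far_field_source_oracle_isotropic(self):
        """Plane wavefront equals the limit of a far point source."""
        iso = ac.LayeredMediumModel(bone_speed_params=(3300.0, 0.0, 0.0))
        th = math.radians(6)
        R = 5e4
        src = (-R * math.sin(th), -R * math.cos(th))
        px, ref = (3.0, 10.0), (0.0, 0.0)
        t_pw = ac.plane_wave_arrival_time(th, px, iso) \
            - ac.plane_wave_arrival_time(th, ref, iso)
        t_far = ac.two_layer_travel_time(src, px, 8.0, 1570.0, 3300.0)[0] \
            - math.hypot(*src) / 1.57
        assert abs(t_pw - t_far) < 1e-4

    def test_evanescent_signal(self, medium):
        with pytest.raises(ac.EvanescentTransmissionError):
            ac.plane_wave_arrival_time(math.radians(40), (0.0, 10.0), medium)


class TestDelayTables:
    def test_shapes(self, tables, probe, grid, angles):
        nx, nz = grid.shape
        assert tables.tx_delays.shape == (angles.size, nx, nz)
        assert tables.rx_delays.shape == (probe.element_count, nx, nz)

    def test_non_negative_and_finite(self, tables):
        assert np.isfinite(tables.rx_delays).all()
        assert np.isfinite(tables.tx_delays).all()
        assert (tables.tx_delays >= 0).all()
        assert (tables.rx_delays >= 0).all()

    def test_rx_monotone_with_depth_homogeneous(self, homogeneous_tables):
        rx = homogeneous_tables.rx_delays
        assert (np.diff(rx, axis=2) > 0).all()

    def test_spot_check_against_scalar_solver(self, tables, probe, grid,
                                              medium):
        rng = np.random.default_rng(5)
        for _ in range(50):
            e = rng.integers(probe.element_count)
            i = rng.integers(grid.shape[0])
            j = rng.integers(grid.shape[1])
            t_s = ac.point_travel_time(
                (probe.element_positions[e], 0.0),
                (grid.x_coords[i], grid.z_coords[j]), medium)
            assert abs(t_s - tables.rx_delays[e, i, j]) < 1e-4

    def test_homogeneous_center_column(self, homogeneous_tables, grid):
        e = 31  # element nearest the center for a 64-element array
        xe = homogeneous_tables.probe.element_positions[e]
        i = int(np.argmin(np.abs(grid.x_coords - xe)))
        expect = np.hypot(grid.x_coords[i] - xe, grid.z_coords) / 1.57
        assert np.allclose(homogeneous_tables.rx_delays[e, i], expect,
                           atol=2e-4)

    def test_evanescent_angles_masked_not_fatal(self, probe, medium):
        g = ac.ImagingGrid.regular(-5, 5, 6, 12, 0.5)
        tabs = ac.build_delay_tables(probe, g, medium,
                                     [0.0, math.radians(35)])
        assert tabs.valid[0].all()
        z_bone = g.z_coords > medium.interface_skin_bone_depth
        assert not tabs.valid[1][:, z_bone].any()
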
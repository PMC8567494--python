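"""Phantoms, waveforms, kinematics and the RF forward model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import hilbert
from scipy.stats import chisquare

from osteoflow import acoustics as ac
from osteoflow import simulator as sim

from conftest import single_scatterer_phantom


class TestWaveform:
    def test_zero_peak_is_constant_baseline(self):
        w = sim.PulsatileWaveform(60.0, 0.0, -0.5)
        t = np.linspace(0, 4, 100)
        assert np.allclose(w.velocity(t), -0.5)

    @given(t=st.floats(0, 100), hr=st.floats(42, 76))
    @settings(max_examples=50, deadline=None)
    def test_periodicity(self, t, hr):
        w = sim.PulsatileWaveform(hr, -9.5, -0.5)
        assert w.velocity(t) == pytest.approx(w.velocity(t + 60.0 / hr),
                                              abs=1e-9)

    @pytest.mark.parametrize("hr", [42.0, 60.0, 76.0])
    def test_physiological_rates_unaliased_at_100hz(self, hr):
        """Rates spanning the reported 42-76 bpm range sampled at 100 Hz."""
        w = sim.PulsatileWaveform(hr, -9.5, -0.5, systolic_fraction=0.3)
        t = np.arange(0, 4, 0.01)
        v = w.velocity(t)
        # the sampled minimum reaches the analytic crest (no aliasing)
        assert v.min() == pytest.approx(-10.0, rel=0.01)

    def test_displacement_matches_numerical_integral(self):
        w = sim.PulsatileWaveform(66.0, -8.0, -0.4, systolic_fraction=0.25)
        t = np.linspace(0, 3.7, 3701)
        num = np.cumsum(w.velocity(t)) * (t[1] - t[0])
        assert w.displacement(t[-1]) == pytest.approx(num[-1], abs=5e-3)


class TestCorticalPhantom:
    def test_zero_blood_density_only_static(self, medium):
        ph = sim.make_cortical_phantom(
            medium, densities=sim.RegionDensities(blood=0.0), seed=0)
        assert ph.n_blood == 0
        assert ph.n_static > 0

    def test_poisson_counts_in_cortex(self, medium):
        """Blood count over the 5x15-ish canal regions is Poisson."""
        counts = [sim.make_cortical_phantom(medium, seed=s).n_blood
                  for s in range(60)]
        lam = 3.0 * 20.0 * 5.0  # density * full-width cortex area
        mean = np.mean(counts)
        assert abs(mean - lam) < 4 * np.sqrt(lam / len(counts))

    def test_poisson_statistics_chisquare(self, medium):
        """Counts over 200 seeds match Poisson(density*area) (alpha=0.01)."""
        lam = 3.0 * 20.0 * 5.0
        counts = np.array([sim.make_cortical_phantom(medium, seed=s).n_blood
                           for s in range(200)])
        edges = [0, lam - 2 * np.sqrt(lam), lam - np.sqrt(lam), lam,
                 lam + np.sqrt(lam), lam + 2 * np.sqrt(lam), np.inf]
        obs, _ = np.histogram(counts, bins=edges)
        from scipy.stats import poisson
        cdf = poisson.cdf(np.array(edges[1:-1], dtype=float), lam)
        p_bins = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
        stat, p = chisquare(obs, p_bins * len(counts))
        assert p > 0.01

    def test_determinism(self, medium):
        a = sim.make_cortical_phantom(medium, seed=11)
        b = sim.make_cortical_phantom(medium, seed=11)
        assert np.array_equal(a.static_pos, b.static_pos)
        assert np.array_equal(a.blood_pos0, b.blood_pos0)
        assert np.array_equal(a.blood_amp, b.blood_amp)

    def test_blood_inside_labeled_regions(self, medium):
        ph = sim.make_cortical_phantom(medium, seed=2)
        for pos, ax in zip(ph.blood_pos0, ph.canal_axis):
            region = ph.region_of(*pos)
            assert region in ("cortex", "vessel")
            if region == "vessel":
                assert tuple(ax) == (0.0, 1.0)

    def test_empty_region_error(self, medium):
        with pytest.raises(sim.EmptyRegionError):
            # densities tiny but nonzero over a large region: first seed that
            # draws zero scatterers must raise
            for s in range(200):
                sim.make_cortical_phantom(
                    medium, densities=sim.RegionDensities(
                        tissue=0.001, cortex=0.001, marrow=0.001, blood=0.001),
                    seed=s)


class TestArteryPhantom:
    def test_parabolic_profile_limits(self):
        ph = sim.make_artery_phantom(seed=0)
        r_scale = ph.velocity_scale
        assert r_scale.max() <= 1.0
        assert r_scale.min() >= 0.0

    def test_mean_speed_half_centerline(self):
        """Uniform scatterers over the tube cross-section: <v> = v_c/2."""
        ph = sim.make_artery_phantom(seed=1, blood_density_3d=30.0)
        mean_scale = ph.velocity_scale.mean()
        assert mean_scale == pytest.approx(0.5, abs=0.02)

    def test_axis_and_wall_speeds(self):
        ph = sim.make_artery_phantom(seed=2, blood_density_3d=30.0)
        # scatterer closest to the axis moves ~v_center, near wall ~0
        assert ph.velocity_scale.max() > 0.99
        assert ph.velocity_scale.min() < 0.01


class TestAdvanceScatterers:
    def test_zero_motion_identity(self, medium):
        ph = sim.make_cortical_phantom(
            medium, seed=0,
            axial_waveform=sim.PulsatileWaveform(60, 0.0, 0.0),
            radial_waveform=sim.PulsatileWaveform(60, 0.0, 0.0),
            drift=sim.DriftModel(amplitude=0.0))
        p0 = sim.advance_scatterers(ph, 0.0)
        p1 = sim.advance_scatterers(ph, 2.0)
        assert np.allclose(p0, p1)

    def test_constant_velocity_displacement(self):
        ph = single_scatterer_phantom(0.0, 10.5, vx=1.0, vz=0.0, moving=True)
        _, b0 = ph.positions_at(0.0)
        _, b1 = ph.positions_at(1.0)
        assert b1[0, 0] - b0[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert b1[0, 1] == b0[0, 1]

    def test_drift_capped_below_half_mm(self, medium):
        """0.4 mm raised-cosine ramp at ~0.1 mm/s peak stays under 0.5 mm."""
        d = sim.DriftModel(amplitude=0.4, duration=4.0)
        t = np.linspace(0, 4, 401)
        disp = np.linalg.norm(d.displacement(t), axis=1)
        assert disp.max() < 0.5
        vel = np.diff(disp) / 0.01
        assert vel.max() == pytest.approx(0.157, abs=0.01)

    def test_reinjection_keeps_blood_in_region(self, medium):
        ph = sim.make_cortical_phantom(medium, seed=4,
                                       drift=sim.DriftModel(amplitude=0.0))
        for t in (0.7, 1.9, 3.6):
            _, blood = ph.positions_at(t)
            inside = (blood[:, 1] >= 8.0) & (blood[:, 1] <= 13.0)
            assert inside.all()

    def test_reinjection_overflow_error(self):
        wf = sim.PulsatileWaveform(60.0, 0.0, 30.0)  # 30 mm per period
        with pytest.raises(sim.ReinjectionError):
            sim.FlowPhantom(
                static_pos=np.zeros((0, 2)), static_amp=np.zeros(0),
                blood_pos0=np.array([[0.0, 10.0]]), blood_amp=np.ones(1),
                canal_axis=np.array([[1.0, 0.0]]),
                waveform_id=np.zeros(1, dtype=np.int64),
                velocity_scale=np.ones(1), wrap_lo=np.array([-5.0]),
                wrap_hi=np.array([5.0]), waveforms=(wf,),
                region_geometry={"z_skin_bone": 8.0, "z_bone_marrow": 13.0})

    def test_negative_time_rejected(self, medium):
        ph = sim.make_cortical_phantom(medium, seed=0)
        with pytest.raises(ValueError):
            sim.advance_scatterers(ph, -0.1)


class TestChannelData:
    def test_empty_phantom_zero_cube(self, probe, medium):
        ph = sim.FlowPhantom(
            static_pos=np.zeros((0, 2)), static_amp=np.zeros(0),
            blood_pos0=np.zeros((0, 2)), blood_amp=np.zeros(0),
            canal_axis=np.zeros((0, 2)),
            waveform_id=np.zeros(0, dtype=np.int64),
            velocity_scale=np.zeros(0), wrap_lo=np.zeros(0),
            wrap_hi=np.zeros(0), waveforms=(),
            drift=sim.DriftModel(amplitude=0.0),
            region_geometry={"z_skin_bone": 8.0, "z_bone_marrow": 13.0})
        cube = sim.simulate_channel_data(
            ph, sim.AcquisitionProtocol(frames=2), probe, medium,
            noise_snr_db=None, seed=0, duration_us=20.0)
        assert not cube.rf.any()

    def test_single_scatterer_peak_time_matches_fermat(self, probe, medium,
                                                       scene_duration_us):
        """Envelope peak of the central element at the two-way Fermat time."""
        target = (2.0, 10.5)
        ph = single_scatterer_phantom(*target)
        cube = sim.simulate_channel_data(
            ph, sim.AcquisitionProtocol(frames=1), probe, medium,
            noise_snr_db=None, seed=0, duration_us=scene_duration_us)
        e = 31
        trace = cube.rf[0, 7, e]   # central angle (index 7 of 15 = 0 deg)
        env = np.abs(hilbert(trace))
        t_peak = cube.t0 + np.argmax(env) / probe.sampling_frequency
        t_tx = ac.plane_wave_arrival_time(0.0, target, medium,
                                          x_ref=-probe.aperture / 2)
        t_rx = ac.point_travel_time((probe.element_positions[e], 0.0),
                                    target, medium)
        assert abs(t_peak - (t_tx + t_rx)) * probe.sampling_frequency < 1.0

    def test_seed_determinism_bit_identical(self, probe, medium):
        ph = sim.make_cortical_phantom(medium, seed=3)
        kw = dict(noise_snr_db=25.0, seed=9, duration_us=40.0)
        a = sim.simulate_channel_data(
            ph, sim.AcquisitionProtocol(frames=2), probe, medium, **kw)
        b = sim.simulate_channel_data(
            ph, sim.AcquisitionProtocol(frames=2), probe, medium, **kw)
        assert np.array_equal(a.rf, b.rf)

    def test_energy_quadratic_in_reflectivity(self, probe, medium):
        ph1 = single_scatterer_phantom(1.0, 10.0, amp=1.0)
        ph2 = single_scatterer_phantom(1.0, 10.0, amp=2.0)
        kw = dict(noise_snr_db=None, seed=0, duration_us=40.0)
        e1 = (sim.simulate_channel_data(
            ph1, sim.AcquisitionProtocol(frames=1), probe, medium,
            **kw).rf ** 2).sum()
        e2 = (sim.simulate_channel_data(
            ph2, sim.AcquisitionProtocol(frames=1), probe, medium,
            **kw).rf ** 2).sum()
        assert e2 == pytest.approx(4 * e1, rel=1e-10)

    def test_noise_level_tracks_snr(self, probe, medium):
        ph = single_scatterer_phantom(0.0, 10.0)
        proto = sim.AcquisitionProtocol(frames=2)
        clean = sim.simulate_channel_data(ph, proto, probe, medium,
                                          noise_snr_db=None, seed=0,
                                          duration_us=40.0)
        noisy = sim.simulate_channel_data(ph, proto, probe, medium,
                                          noise_snr_db=20.0, seed=0,
                                          duration_us=40.0)
        resid = noisy.rf - clean.rf
        snr = 10 * np.log10((clean.rf[0] ** 2).mean()
                            / (resid ** 2).mean())
        assert snr == pytest.approx(20.0, abs=0.5)
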
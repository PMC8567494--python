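"""SVD clutter filtering, velocity estimators and drift tracking."""

import numpy as np
import pytest

from osteoflow import flow as fl
from osteoflow import reconstruction as rec

from conftest import make_to_speckle


def _vector_estimate(seq, lambda0x=3.5, lam_z=1540.0 / 1000.0 / 2.5,
                     ensemble=10, region=np.s_[40:200, 20:80]):
    """Coherent ROI estimate from a TO pair (imposed-shift test harness)."""
    pair = rec.transverse_oscillation_pair(seq, lambda0x)
    vf = fl.to_vector_velocity(pair, ensemble=ensemble, lambda_z_map=lam_z)
    rp = vf.r_plus[region].reshape(-1, vf.r_plus.shape[-1]).sum(axis=0)
    rm = vf.r_minus[region].reshape(-1, vf.r_minus.shape[-1]).sum(axis=0)
    dt = 1.0 / seq.frame_rate
    f_eff = fl.effective_lateral_carrier(pair.s_plus.iq, seq.grid.pixel_pitch)
    va = float(np.mean(-0.5 * (np.angle(rp) - np.angle(rm))
                       / (2 * np.pi * f_eff * dt)))
    vr = float(np.mean(-0.5 * (np.angle(rp) + np.angle(rm))
                       * lam_z / (4 * np.pi * dt)))
    return va, vr


class TestSvdClutterFilter:
    def test_k0_identity(self):
        rng = np.random.default_rng(0)
        seq = rng.standard_normal((6, 7, 20)) + 1j * rng.standard_normal((6, 7, 20))
        blood, clutter = fl.svd_clutter_filter(seq, 0)
        assert np.array_equal(blood, seq)
        assert not clutter.any()

    def test_static_scene_rank_one(self):
        img = (np.random.default_rng(1).standard_normal((8, 9))
               + 1j * np.random.default_rng(2).standard_normal((8, 9)))
        seq = np.repeat(img[..., None], 30, axis=-1)
        blood, _ = fl.svd_clutter_filter(seq, 1)
        assert (np.abs(blood) ** 2).sum() < 1e-10 * (np.abs(seq) ** 2).sum()

    def test_constructed_low_rank_separation(self):
        """Rank-3 slow clutter + orthogonal fast component, k=3."""
        rng = np.random.default_rng(5)
        npix, nt = 300, 100
        t = np.arange(nt)
        slow = np.stack([np.ones(nt), np.cos(2 * np.pi * t / nt),
                         np.sin(2 * np.pi * t / nt)])
        clutter = (rng.standard_normal((npix, 3)) * 50.0) @ slow
        fast_t = np.exp(2j * np.pi * 0.31 * t)
        fast_t -= slow.T @ np.linalg.lstsq(slow.T, fast_t, rcond=None)[0]
        fast = np.outer(rng.standard_normal(npix), fast_t)
        seq = (clutter + fast).reshape(30, 10, nt)
        blood, _ = fl.svd_clutter_filter(seq, 3)
        b = blood.reshape(npix, nt).ravel()
        f = fast.ravel()
        corr = np.abs(np.vdot(b, f)) / (np.linalg.norm(b) * np.linalg.norm(f))
        assert corr >= 0.99

    @pytest.mark.parametrize("k", [0, 1, 5, 20])
    def test_reconstruction_identity(self, k):
        rng = np.random.default_rng(k)
        seq = rng.standard_normal((10, 12, 40)) \
            + 1j * rng.standard_normal((10, 12, 40))
        blood, clutter = fl.svd_clutter_filter(seq, k)
        err = np.linalg.norm(seq - (blood + clutter)) / np.linalg.norm(seq)
        assert err < 1e-10

    def test_blood_energy_monotone_in_k(self):
        rng = np.random.default_rng(9)
        seq = rng.standard_normal((10, 12, 40)) \
            + 1j * rng.standard_normal((10, 12, 40))
        energies = [np.linalg.norm(fl.svd_clutter_filter(seq, k)[0])
                    for k in range(0, 39, 4)]
        assert all(a >= b - 1e-12 for a, b in zip(energies, energies[1:]))

    def test_too_few_frames(self):
        with pytest.raises(fl.RankError):
            fl.svd_clutter_filter(np.zeros((4, 4, 1), complex), 0)


class TestPowerDoppler:
    def test_zero_input(self):
        pd_map, pd_series = fl.power_doppler(np.zeros((4, 5, 30), complex))
        assert not pd_map.any() and not pd_series.any()

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(3)
        seq = rng.standard_normal((6, 6, 30)) + 1j * rng.standard_normal((6, 6, 30))
        pd1, _ = fl.power_doppler(seq)
        pd2, _ = fl.power_doppler(2 * seq)
        assert np.allclose(pd2, 4 * pd1)

    def test_white_noise_moment(self):
        """Unit-variance complex white noise: pd_map ~ 2 within 3 sigma."""
        rng = np.random.default_rng(12)
        nt = 4000
        seq = rng.standard_normal((5, 5, nt)) + 1j * rng.standard_normal((5, 5, nt))
        pd_map, _ = fl.power_doppler(seq, smoothing_window=1)
        # |z|^2 has mean 2, var 4 for CN(0, 2): sd of the mean = 2/sqrt(nt)
        assert np.all(np.abs(pd_map - 2.0) < 3 * 2 / np.sqrt(nt))


class TestToVectorVelocity:
    def test_static_sequence_zero(self):
        seq = make_to_speckle(0, 0.0, 0.0)
        pair = rec.transverse_oscillation_pair(seq, 3.5)
        vf = fl.to_vector_velocity(pair, lambda_z_map=0.616)
        assert np.allclose(vf.v_axial, 0.0, atol=1e-9)
        assert np.allclose(vf.v_radial, 0.0, atol=1e-9)

    @pytest.mark.parametrize("v", [0.5, 2.0, 10.0, -0.5, -10.0])
    def test_imposed_shift_recovery(self, v):
        """Rigid speckle shifts at the physiological 5:1 component ratio."""
        seq = make_to_speckle(1, v, v / 5.0)
        va, vr = _vector_estimate(seq)
        assert va == pytest.approx(v, rel=0.10)
        assert vr == pytest.approx(v / 5.0, rel=0.10)

    def test_time_reversal_negates_velocities(self):
        seq = make_to_speckle(2, 4.0, 1.0)
        rev = rec.IQImageSequence(seq.iq[..., ::-1].copy(), seq.grid,
                                  seq.frame_rate, seq.carrier_frequency, None)
        va, vr = _vector_estimate(seq)
        va_r, vr_r = _vector_estimate(rev)
        assert va_r == pytest.approx(-va, rel=0.02)
        assert vr_r == pytest.approx(-vr, rel=0.05)

    def test_aliasing_flagged_at_quarter_wavelength(self):
        """Axial shift of lambda_z/4 per frame puts phi_sum at pi."""
        lam_z = 1540.0 / 1000.0 / 2.5
        v_alias = (lam_z / 4) / 0.01   # mm/s -> phase pi at lag 1
        seq = make_to_speckle(4, 0.0, 0.98 * v_alias, n_frames=12)
        pair = rec.transverse_oscillation_pair(seq, 3.5)
        vf = fl.to_vector_velocity(pair, ensemble=1, lambda_z_map=lam_z)
        assert vf.alias[40:200, 20:80].mean() > 0.5


class TestKasai:
    def _uniform_ensemble(self, v_along_x, n=30, f0=5.0, c=1540.0,
                          prf=5000.0, steer=np.radians(20)):
        """Speckle ensemble with imposed uniform lateral motion."""
        rng = np.random.default_rng(8)
        nx, nz = 120, 120
        white = rng.standard_normal((nx, nz)) + 1j * rng.standard_normal((nx, nz))
        dx_pitch = 0.1
        fx = np.fft.fftfreq(nx, dx_pitch)
        fz = np.fft.fftfreq(nz, dx_pitch)
        # one-way steered carrier: lateral sin(steer), axial 1 + cos(steer)
        kx = f0 / (c / 1000.0) * np.sin(steer)
        kz = f0 / (c / 1000.0) * (1 + np.cos(steer))
        H = np.exp(-0.5 * ((fx[:, None] - kx) / 0.3) ** 2) \
            * np.exp(-0.5 * ((fz[None, :] - kz) / 0.4) ** 2)
        spec0 = np.fft.fft2(white) * H
        frames = []
        for t in range(n):
            dx = v_along_x * t / prf  # mm per pulse interval
            ramp = np.exp(-2j * np.pi * fx[:, None] * dx)
            frames.append(np.fft.ifft2(spec0 * ramp))
        return np.stack(frames, axis=-1)

    def test_static_ensemble_zero(self):
        ens = self._uniform_ensemble(0.0)
        v, power = fl.kasai_axial_velocity(ens, 5.0, 1540.0, 5000.0,
                                           np.radians(20))
        assert np.allclose(v, 0.0, atol=1e-9)
        assert power > 0

    def test_imposed_motion_recovered(self):
        """300 mm/s along the vessel axis recovered within 5 percent."""
        truth = 300.0
        ens = self._uniform_ensemble(truth)
        v, _ = fl.kasai_axial_velocity(ens, 5.0, 1540.0, 5000.0,
                                       np.radians(20))
        r1 = (ens[..., 1:] * np.conj(ens[..., :-1])).sum()
        # coherent aggregate (uniform motion): single unbiased readout
        phi = np.angle(r1)
        bis = np.radians(10)
        v_est = -phi * 1540e3 / (4 * np.pi * 5e6 * np.cos(bis)) * 5000.0 \
            / np.cos(np.radians(80))
        assert v_est == pytest.approx(truth, rel=0.05)
        # and the map's power-weighted mean agrees
        w = (np.abs(ens) ** 2).sum(axis=-1)
        assert np.average(v, weights=w) == pytest.approx(truth, rel=0.05)

    def test_near_perpendicular_rejected(self):
        ens = self._uniform_ensemble(0.0, n=3)
        with pytest.raises(ValueError):
            fl.kasai_axial_velocity(ens, 5.0, 1540.0, 5000.0,
                                    steer_angle=np.radians(2),
                                    vessel_axis_angle=0.0)

    def test_single_image_rejected(self):
        with pytest.raises(fl.RankError):
            fl.kasai_axial_velocity(np.zeros((4, 4, 1), complex), 5.0,
                                    1540.0, 5000.0, np.radians(20))


class TestDriftTrack:
    def _speckle_stack(self, shifts_px, seed=0, shape=(80, 80)):
        rng = np.random.default_rng(seed)
        white = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        fx = np.fft.fftfreq(shape[0])
        fz = np.fft.fftfreq(shape[1])
        H = np.exp(-0.5 * ((fx[:, None]) / 0.15) ** 2
                   - 0.5 * ((fz[None, :] - 0.3) / 0.1) ** 2)
        spec0 = np.fft.fft2(white) * H
        frames = []
        for (sx, sz) in shifts_px:
            ramp = np.exp(-2j * np.pi * (fx[:, None] * sx + fz[None, :] * sz))
            frames.append(np.fft.ifft2(spec0 * ramp))
        return np.stack(frames, axis=-1)

    def test_static_zero_displacement(self):
        seq = self._speckle_stack([(0, 0)] * 10)
        disp, vel = fl.probe_drift_track(seq, 0.5, 100.0)
        assert np.allclose(disp, 0.0, atol=1e-6)

    def test_imposed_linear_drift_recovered(self):
        """0.1 mm/s for 4 s at 100 Hz: 0.4 mm total within 10 percent."""
        nt = 80  # 0.05 s steps to keep the stack small
        t = np.arange(nt) * 0.05
        pitch = 0.5
        shifts = [(0.1 * ti / pitch, 0.05 * ti / pitch) for ti in t]
        seq = self._speckle_stack(shifts)
        disp, vel = fl.probe_drift_track(seq, pitch, 20.0)
        assert disp[-1, 0] == pytest.approx(0.1 * t[-1], rel=0.10)
        assert disp[-1, 1] == pytest.approx(0.05 * t[-1], rel=0.10)

    def test_decorrelation_detected(self):
        rng = np.random.default_rng(1)
        seq = rng.standard_normal((40, 40, 3)) + 1j * rng.standard_normal((40, 40, 3))
        with pytest.raises(RuntimeError):
            fl.probe_drift_track(seq, 0.5, 100.0)

    def test_cardiac_band_fraction_of_smooth_ramp(self):
        t = np.linspace(0, 4, 400)
        ramp_vel = np.gradient(0.2 * (1 - np.cos(np.pi * t / 4)), t)
        assert fl.cardiac_band_fraction(ramp_vel, 100.0) < 0.2
        pulsatile = np.sin(2 * np.pi * 1.0 * t)
        assert fl.cardiac_band_fraction(pulsatile, 100.0) > 0.8
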
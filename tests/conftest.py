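"""Shared fixtures: default scene geometry and synthetic-speckle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from osteoflow import acoustics as ac
from osteoflow import reconstruction as rec
from osteoflow import simulator as sim


@pytest.fixture(scope="session")
def medium() -> ac.LayeredMediumModel:
    return ac.LayeredMediumModel()


@pytest.fixture(scope="session")
def probe() -> ac.ProbeModel:
    return ac.ProbeModel(64, 0.3, 2.5, 10.0)


@pytest.fixture(scope="session")
def grid() -> ac.ImagingGrid:
    return ac.ImagingGrid.regular(-10, 10, 1.0, 16.0, 0.5, pitch_z=0.125)


@pytest.fixture(scope="session")
def angles() -> np.ndarray:
    return np.radians(np.linspace(-8.0, 8.0, 15))


@pytest.fixture(scope="session")
def tables(probe, grid, medium, angles) -> ac.DelayTables:
    return ac.build_delay_tables(probe, grid, medium, angles)


@pytest.fixture(scope="session")
def homogeneous_tables(probe, grid, angles) -> ac.DelayTables:
    hom = ac.LayeredMediumModel(c_tissue=1570.0, c_marrow=1570.0,
                                bone_speed_params=(1570.0, 0.0, 0.0))
    return ac.build_delay_tables(probe, grid, hom, angles)


@pytest.fixture(scope="session")
def scene_duration_us(tables, homogeneous_tables) -> float:
    d1 = (tables.tx_delays + tables.rx_delays.max(axis=0)).max()
    d2 = (homogeneous_tables.tx_delays
          + homogeneous_tables.rx_delays.max(axis=0)).max()
    return float(max(d1, d2)) + 1.0


def single_scatterer_phantom(x: float, z: float, vx: float = 0.0,
                             vz: float = 0.0, amp: float = 1.0,
                             moving: bool = False) -> sim.FlowPhantom:
    """One-scatterer phantom, optionally translating at constant (vx, vz)."""
    geo = {"z_skin_bone": 8.0, "z_bone_marrow": 13.0}
    if not moving:
        return sim.FlowPhantom(
            static_pos=np.array([[x, z]]), static_amp=np.array([amp]),
            blood_pos0=np.zeros((0, 2)), blood_amp=np.zeros(0),
            canal_axis=np.zeros((0, 2)),
            waveform_id=np.zeros(0, dtype=np.int64),
            velocity_scale=np.zeros(0), wrap_lo=np.zeros(0),
            wrap_hi=np.zeros(0), waveforms=(),
            drift=sim.DriftModel(amplitude=0.0), region_geometry=geo)
    speed = float(np.hypot(vx, vz)) or 1.0
    wf = sim.PulsatileWaveform(60.0, 0.0, speed, 0.3)
    return sim.FlowPhantom(
        static_pos=np.zeros((0, 2)), static_amp=np.zeros(0),
        blood_pos0=np.array([[x, z]]), blood_amp=np.array([amp]),
        canal_axis=np.array([[vx, vz]]) / speed,
        waveform_id=np.zeros(1, dtype=np.int64),
        velocity_scale=np.ones(1), wrap_lo=np.array([-50.0]),
        wrap_hi=np.array([50.0]), waveforms=(wf,),
        drift=sim.DriftModel(amplitude=0.0), region_geometry=geo)


def make_to_speckle(seed: int, v_x: float, v_z: float, dt: float = 0.01,
                    n_frames: int = 30, f0: float = 2.5, c: float = 1540.0
                    ) -> rec.IQImageSequence:
    """Synthetic beamformed-like speckle rigidly translated between frames.

    Complex white noise shaped to a band around the two-way axial carrier
    2*f0/c and a lateral low-pass; motion is imposed with the Fourier shift
    theorem (pattern and carrier move together, as physical motion does).
    The 0.1 mm grid resolves the axial carrier.
    """
    g = ac.ImagingGrid.regular(-12, 12, 0, 10, 0.1)
    nx, nz = g.shape
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((nx, nz)) + 1j * rng.standard_normal((nx, nz))
    fx = np.fft.fftfreq(nx, 0.1)
    fz = np.fft.fftfreq(nz, 0.1)
    kz0 = 2 * f0 / (c / 1000.0)
    H = np.exp(-0.5 * (fx[:, None] / 0.35) ** 2) * \
        np.exp(-0.5 * ((fz[None, :] - kz0) / 0.4) ** 2)
    spec0 = np.fft.fft2(white) * H
    frames = []
    for t in range(n_frames):
        ramp = np.exp(-2j * np.pi * (fx[:, None] * v_x * dt * t
                                     + fz[None, :] * v_z * dt * t))
        frames.append(np.fft.ifft2(spec0 * ramp))
    return rec.IQImageSequence(iq=np.stack(frames, axis=-1), grid=g,
                               frame_rate=1.0 / dt, carrier_frequency=f0,
                               medium=None)
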